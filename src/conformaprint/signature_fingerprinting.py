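"""Matching conformational fingerprints against SBS96 mutational signatures.

A conformational fingerprint is the normalized vector of a rare DNA state's
propensities across trinucleotide contexts.  Each single-base-substitution
(SBS) signature is a probability distribution over 96 channels (6
pyrimidine-centric substitution classes x 16 flanking contexts).  For a
chosen substitution class, the 16 context probabilities of a signature are
restricted to the fingerprint's available contexts, renormalized, and
compared with the fingerprint by Jensen-Shannon divergence (JSD, base-2 logs,
range [0, 1]; 0 = identical).  Significance comes from a resampled null:
context probabilities drawn i.i.d. from the pooled multiset of all channel
probabilities across all signatures, renormalized, and scored the same way.
Matches with JSD <= 0.090 and both p-value and Benjamini-Hochberg FDR < 5%
are flagged as strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .contexts import ALL_CONTEXTS, BASES, TripletContext
from .titration_pka import PKaRecord, population_at_pH

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: JSD threshold for a strong similarity call.
STRONG_JSD = 0.090

#: Canonical SBS96 channel order: substitution class, then 5' then 3' flank.
CHANNELS_96 = tuple(
    f"{z}[{sub}]{w}"
    for sub in SUBSTITUTION_CLASSES
    for z in BASES
    for w in BASES
)

#: Rare state -> substitution classes it can produce (via mispairing or
#: damage + translesion synthesis).
STATE_SUBSTITUTIONS = {
    "GT_anion": ("C>T", "T>C"),
    "AT_hoogsteen": ("T>A", "T>C", "T>G"),
    "GC_hoogsteen": ("C>A", "C>T", "C>G"),
    "AT_opened": ("T>A", "T>G"),
}


def state_substitution_map(state: str) -> tuple[str, ...]:
    """Substitution classes mechanistically linked to a named rare state."""
    try:
        return STATE_SUBSTITUTIONS[state]
    except KeyError:
        raise ValueError(
            f"unknown state {state!r}; known: {sorted(STATE_SUBSTITUTIONS)}"
        ) from None


@dataclass
class Fingerprint:
    """Normalized per-context propensity vector for one rare state."""

    state: str
    contexts: tuple[TripletContext, ...]
    weights: np.ndarray
    reference_pH: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.contexts) != len(self.weights):
            raise ValueError("contexts and weights must have equal length")
        if len(self.contexts) > 16 or len(set(self.contexts)) != len(self.contexts):
            raise ValueError("contexts must be distinct and at most 16")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")


@dataclass
class SignatureMatrix:
    """96-channel probability columns, one per signature, canonical row order."""

    data: pd.DataFrame  # index = CHANNELS_96, columns = signature ids

    def __post_init__(self) -> None:
        if list(self.data.index) != list(CHANNELS_96):
            raise ValueError("rows must be the 96 channels in canonical order")

    @property
    def signatures(self) -> list[str]:
        return list(self.data.columns)

    def pooled_probabilities(self) -> np.ndarray:
        """Multiset of all channel probabilities (null pool).

        Sorted so that draws depend only on the multiset, not on the
        signature column order.
        """
        return np.sort(self.data.to_numpy().ravel())


@dataclass
class MatchResult:
    signature: str
    substitution: str
    jsd: float
    p_value: float
    fdr: float = math.nan
    n_contexts: int = 16
    strong: bool = False


def make_fingerprint(
    records,
    state: str = "GT_anion",
    reference_pH: float = 7.4,
    provenance: str = "",
) -> Fingerprint:
    """Build a fingerprint from pKa records or raw propensities.

    ``records`` is either a list of :class:`PKaRecord` (propensity per
    context = anion population at ``reference_pH``) or a mapping
    ``{TripletContext: propensity}``.  Missing contexts are simply omitted —
    never imputed — and the available propensities are normalized to sum 1.
    """
    if isinstance(records, dict):
        items = sorted(records.items(), key=lambda kv: kv[0])
    else:
        items = sorted(
            (
                (r.context, float(population_at_pH(r.pKa_app, reference_pH)))
                for r in records
            ),
            key=lambda kv: kv[0],
        )
    if len(items) < 2:
        raise ValueError("need at least 2 contexts for a fingerprint")
    contexts = tuple(ctx for ctx, _ in items)
    props = np.array([v for _, v in items], dtype=float)
    total = props.sum()
    if total <= 0:
        raise ValueError("all propensities are zero")
    return Fingerprint(
        state=state,
        contexts=contexts,
        weights=props / total,
        reference_pH=reference_pH,
        provenance=provenance,
    )


def reverse_complement_fingerprint(fp: Fingerprint) -> Fingerprint:
    """Re-express a purine-strand fingerprint on the pyrimidine strand."""
    pairs = sorted(
        zip((c.reverse_complement() for c in fp.contexts), fp.weights),
        key=lambda kv: kv[0],
    )
    return Fingerprint(
        state=fp.state,
        contexts=tuple(c for c, _ in pairs),
        weights=np.array([w for _, w in pairs]),
        reference_pH=fp.reference_pH,
        provenance=fp.provenance + " (reverse-complemented)",
    )


def read_signatures(path, tol: float = 1e-3) -> SignatureMatrix:
    """Read a COSMIC-dialect SBS96 tab-separated file.

    Expects a ``Type`` column of ``X[R>A]Y`` channel labels plus one column
    per signature; rows are canonicalized to the standard channel order and
    columns validated to sum to 1 within ``tol``.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    if set(df.index) != set(CHANNELS_96):
        raise ValueError(
            f"expected the 96 SBS channels, got {len(df.index)} rows "
            f"({sorted(set(df.index) - set(CHANNELS_96))[:3]}... unexpected)"
        )
    df = df.loc[list(CHANNELS_96)].astype(float)
    sums = df.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(
            "signature columns do not sum to 1: "
            + ", ".join(f"{c}={v:.4f}" for c, v in bad.items())
        )
    if (df.to_numpy() < 0).any():
        raise ValueError("signature probabilities must be non-negative")
    return SignatureMatrix(df)


def write_signatures(path, matrix: SignatureMatrix) -> None:
    matrix.data.rename_axis("Type").to_csv(path, sep="\t")


def extract_channel(
    matrix: SignatureMatrix,
    signature: str,
    substitution: str,
    contexts: tuple[TripletContext, ...] = ALL_CONTEXTS,
) -> np.ndarray:
    """Renormalized context probabilities of one substitution channel.

    Restricts the signature's 16 per-context probabilities for the given
    substitution class to ``contexts`` and renormalizes them to sum 1.
    """
    if substitution not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown substitution class {substitution!r}")
    if signature not in matrix.data.columns:
        raise ValueError(f"signature {signature!r} not in matrix")
    labels = [f"{c.five_prime}[{substitution}]{c.three_prime}" for c in contexts]
    vec = matrix.data.loc[labels, signature].to_numpy(float)
    total = vec.sum()
    if total <= 0:
        raise ValueError(
            f"zero probability mass in {signature}/{substitution} over the "
            "requested contexts"
        )
    return vec / total


def _entropy2(p: np.ndarray, axis: int = -1) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -t.sum(axis=axis)


def jsd(p, q) -> float:
    """Jensen-Shannon divergence, base-2 logs: H(M) - (H(P)+H(Q))/2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share support")
    for v in (p, q):
        if abs(v.sum() - 1.0) > 1e-9 or np.any(v < 0):
            raise ValueError("inputs must be normalized probability vectors")
    m = 0.5 * (p + q)
    return float(_entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q)))


def _jsd_rows(P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Vectorized JSD of each row of P against q."""
    m = 0.5 * (P + q[None, :])
    return _entropy2(m, axis=1) - 0.5 * (_entropy2(P, axis=1) + _entropy2(q))


def null_distribution(
    matrix: SignatureMatrix,
    fingerprint: Fingerprint,
    n_draws: int = 1_000_000,
    seed: int | None = None,
    batch: int = 200_000,
) -> np.ndarray:
    """Null JSD samples against the fingerprint from the pooled-probability draw.

    Each draw samples ``len(fingerprint.contexts)`` values i.i.d. from the
    pooled multiset of all channel probabilities (all signatures x all 96
    channels), renormalizes, and computes the JSD to the fingerprint.  Draws
    that come out all-zero are redrawn (the count is recorded on the returned
    array as ``.n_redraws`` is not possible; it is returned via an attribute
    dict when needed — see :func:`scan_all`).
    """
    pool = matrix.pooled_probabilities()
    if pool.size == 0:
        raise ValueError("empty probability pool")
    rng = np.random.default_rng(seed)
    k = len(fingerprint.contexts)
    fw = fingerprint.weights
    out = np.empty(n_draws)
    filled = 0
    redraws = 0
    while filled < n_draws:
        m = min(batch, n_draws - filled)
        draws = rng.choice(pool, size=(m, k), replace=True)
        sums = draws.sum(axis=1)
        ok = sums > 0
        redraws += int(m - ok.sum())
        draws = draws[ok] / sums[ok, None]
        out[filled : filled + len(draws)] = _jsd_rows(draws, fw)
        filled += len(draws)
    null_distribution.last_redraws = redraws  # diagnostic, reported by scan_all
    return out


def p_value(observed_jsd: float, null_samples: np.ndarray) -> float:
    """Left-tail add-one p: small JSD means similar."""
    null_samples = np.asarray(null_samples)
    if null_samples.size == 0:
        raise ValueError("need at least one null sample")
    return float(
        (1 + np.count_nonzero(null_samples <= observed_jsd))
        / (1 + null_samples.size)
    )


def fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("need at least one p-value")
    return false_discovery_control(p_values, method="bh")


def scan_all(
    matrix: SignatureMatrix,
    fingerprint: Fingerprint,
    substitutions=None,
    n_draws: int = 1_000_000,
    seed: int | None = None,
) -> list[MatchResult]:
    """Score every (signature, substitution) pair against the fingerprint.

    One shared null distribution (the pool spans all signatures and classes)
    serves all pairs; FDR is computed across the full scan and results are
    sorted ascending by JSD.  Pairs whose channel has zero mass over the
    fingerprint's contexts are skipped.
    """
    if substitutions is None:
        substitutions = state_substitution_map(fingerprint.state)
    substitutions = tuple(substitutions)
    if not substitutions:
        return []
    null = null_distribution(matrix, fingerprint, n_draws=n_draws, seed=seed)
    results, skipped = [], []
    for sub in substitutions:
        for sig in matrix.signatures:
            try:
                channel = extract_channel(matrix, sig, sub, fingerprint.contexts)
            except ValueError as exc:
                skipped.append((sig, sub, str(exc)))
                continue
            d = jsd(fingerprint.weights, channel)
            results.append(
                MatchResult(
                    signature=sig,
                    substitution=sub,
                    jsd=d,
                    p_value=p_value(d, null),
                    n_contexts=len(fingerprint.contexts),
                )
            )
    if results:
        qs = fdr([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.fdr = float(q)
            r.strong = r.jsd <= STRONG_JSD and r.p_value < 0.05 and r.fdr < 0.05
    results.sort(key=lambda r: r.jsd)
    scan_all.last_skipped = skipped
    return results


def results_to_frame(results: list[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "signature": r.signature,
                "substitution": r.substitution,
                "jsd": r.jsd,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "n_contexts": r.n_contexts,
                "strong": r.strong,
            }
            for r in results
        ]
    )
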