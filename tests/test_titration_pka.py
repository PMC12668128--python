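"""Henderson-Hasselbalch conversions, additivity cycles, partition test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conformaprint.contexts import BASES, TripletContext
from conformaprint.titration_pka import (
    R_KCAL,
    PKaRecord,
    additivity_summary,
    aggregate_pka,
    compare_fingerprints,
    delta_table,
    deshear_decomposition,
    enumerate_additivity_cycles,
    free_energy,
    group_by_three_prime_class,
    partition_test,
    pka_from_population,
    population_at_pH,
)


class TestHendersonHasselbalch:
    def test_midpoint(self):
        assert pka_from_population(7.4, 0.5) == pytest.approx(7.4)
        assert population_at_pH(7.4, 7.4) == pytest.approx(0.5)

    def test_worked_values(self):
        # pH - log10(0.2/0.8) = 8.31 + log10(4)
        assert pka_from_population(8.31, 0.2) == pytest.approx(8.912, abs=5e-4)
        assert population_at_pH(9.7, 7.4) == pytest.approx(0.0049875, rel=1e-3)

    def test_one_unit_above_pka(self):
        p = population_at_pH(8.0, 9.0)
        assert p == pytest.approx(10 / 11)
        assert pka_from_population(9.0, p) == pytest.approx(8.0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.3])
    def test_out_of_range_population_rejected(self, bad):
        with pytest.raises(ValueError):
            pka_from_population(7.4, bad)

    @given(
        p=st.floats(1e-6, 1 - 1e-6),
        pH=st.floats(4.0, 11.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, p, pH):
        assert population_at_pH(pka_from_population(pH, p), pH) == pytest.approx(
            p, rel=1e-9
        )

    def test_fifty_fold_propensity_range(self):
        """pKa extremes ~1.8 units apart give ~50-fold population ratio."""
        ratio = population_at_pH(7.9, 7.4) / population_at_pH(9.7, 7.4)
        assert ratio == pytest.approx(48.2, rel=0.01)


class TestAggregation:
    def test_identical_points(self):
        rec = aggregate_pka([(8.0, 0.5, 0.01), (8.5, 0.75975, 0.01)])
        # both points imply pKa 8.0 (second: 8.5 - log10(0.75975/0.24025))
        assert rec.pKa_app == pytest.approx(8.0, abs=1e-3)

    def test_weighted_mean(self):
        # two pKa values 8.0 and 8.2 with equal sigma 0.1 -> 8.1 +/- 0.0707
        # population sigmas chosen to map onto pKa sigma 0.1 exactly:
        # sigma_pKa = sigma_p / (ln10 * p * (1-p))
        sp = 0.1 * math.log(10) * 0.25
        rec = aggregate_pka([(8.0, 0.5, sp), (8.2, 0.5, sp)])
        assert rec.pKa_app == pytest.approx(8.1)
        assert rec.sigma == pytest.approx(0.0707, abs=2e-4)

    def test_single_point_passthrough(self):
        rec = aggregate_pka([(8.3, 0.5, 0.02)])
        assert rec.pKa_app == pytest.approx(8.3)
        assert rec.pH_points_used == 1

    def test_no_usable_points(self):
        with pytest.raises(ValueError):
            aggregate_pka([(8.0, 0.0, 0.01), (9.0, 1.0, 0.01)])


class TestFreeEnergy:
    def test_zero_at_pka(self):
        assert free_energy(7.4, 7.4, 298.15) == 0.0

    def test_span_value(self):
        ddg = free_energy(9.2, 7.4, 274.15) - free_energy(7.4, 7.4, 274.15)
        assert ddg == pytest.approx(2.26, abs=0.01)

    def test_linear_in_temperature(self):
        assert free_energy(8.0, 7.0, 600.0) == pytest.approx(
            2 * free_energy(8.0, 7.0, 300.0)
        )

    def test_ddG_is_pH_independent(self):
        for pH in (5.0, 7.4, 9.0):
            ddg = free_energy(9.0, pH) - free_energy(8.0, pH)
            assert ddg == pytest.approx(
                R_KCAL * 274.15 * math.log(10), rel=1e-12
            )


def _full_table(values):
    return {
        TripletContext(z, w): values[4 * i + j]
        for i, z in enumerate(BASES)
        for j, w in enumerate(BASES)
    }


class TestDeltaTable:
    def test_reference_zero_and_offsets(self):
        table = {
            TripletContext("C", "A"): (8.0, 0.1),
            TripletContext("G", "A"): (9.0, 0.1),
        }
        deltas = delta_table(table, TripletContext("C", "A"))
        assert deltas[TripletContext("C", "A")] == (0.0, 0.0)
        d, s = deltas[TripletContext("G", "A")]
        assert d == pytest.approx(1.0)
        assert s == pytest.approx(0.1414, abs=2e-4)

    def test_translation_invariance(self, rng):
        vals = rng.normal(8.5, 0.5, 16)
        t1 = {c: (v, 0.05) for c, v in zip(_full_table(vals), vals)}
        t2 = {c: (v + 3.3, 0.05) for c, (v, _) in t1.items()}
        ref = TripletContext("C", "A")
        d1 = delta_table(t1, ref)
        d2 = delta_table(t2, ref)
        for c in d1:
            assert d1[c][0] == pytest.approx(d2[c][0], abs=1e-12)

    def test_missing_reference(self):
        with pytest.raises(ValueError):
            delta_table({TripletContext("A", "A"): (8.0, 0.1)}, TripletContext("C", "A"))


def _brute_force_cycles(table):
    """Independent oracle: iterate all ordered rectangles directly."""
    devs = {}
    for ref_z, ref_w in itertools.product(BASES, repeat=2):
        for dbl_z, dbl_w in itertools.product(BASES, repeat=2):
            if dbl_z == ref_z or dbl_w == ref_w:
                continue
            ref = TripletContext(ref_z, ref_w)
            dbl = TripletContext(dbl_z, dbl_w)
            pred = (
                table[TripletContext(dbl_z, ref_w)]
                - table[ref]
                + table[TripletContext(ref_z, dbl_w)]
                - table[ref]
            )
            obs = table[dbl] - table[ref]
            devs[(ref.label, dbl.label)] = obs - pred
    return devs


class TestAdditivityCycles:
    def test_cycle_count_is_72(self, rng):
        table = _full_table(rng.normal(8.5, 0.5, 16))
        assert len(enumerate_additivity_cycles(table)) == 72

    def test_additive_table_has_zero_deviations(self):
        inc5 = dict(zip(BASES, (0.0, -0.2, 0.1, 0.3)))
        inc3 = dict(zip(BASES, (0.5, -0.4, 0.6, -0.1)))
        table = {
            TripletContext(z, w): 8.9 + inc5[z] + inc3[w]
            for z in BASES
            for w in BASES
        }
        for cyc in enumerate_additivity_cycles(table):
            assert cyc.deviation == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        table = _full_table(rng.normal(8.5, 0.7, 16))
        oracle = _brute_force_cycles(table)
        cycles = enumerate_additivity_cycles(table)
        # brute force enumerates each unordered rectangle from all 4 corners
        # (144 ordered pairs); the 72 canonical cycles must each appear there
        assert len(oracle) == 144
        for cyc in cycles:
            key = (cyc.reference.label, cyc.double.label)
            assert cyc.deviation == pytest.approx(oracle[key], abs=1e-12)

    def test_deviation_antisymmetric_under_diagonal_swap(self, rng):
        table = _full_table(rng.normal(8.5, 0.7, 16))
        by_pair = {}
        for cyc in enumerate_additivity_cycles(table):
            key = frozenset([cyc.reference.label, cyc.double.label])
            by_pair.setdefault(key, []).append(cyc.deviation)
        # traversing the same rectangle from the opposite corner of the same
        # diagonal flips the sign of predicted and observed alike: the
        # deviation built from the other diagonal of the pair differs
        for cyc in enumerate_additivity_cycles(table):
            rev_pred = -cyc.predicted
            rev_obs = -cyc.observed
            assert (rev_obs - rev_pred) == pytest.approx(-cyc.deviation)

    def test_missing_context_rejected(self, rng):
        table = _full_table(rng.normal(8.5, 0.5, 16))
        del table[TripletContext("A", "A")]
        with pytest.raises(ValueError):
            enumerate_additivity_cycles(table)


class TestAdditivitySummary:
    def test_perfect_additivity(self):
        inc5 = dict(zip(BASES, (0.0, -0.2, 0.1, 0.3)))
        inc3 = dict(zip(BASES, (0.5, -0.4, 0.6, -0.1)))
        table = {
            TripletContext(z, w): 8.9 + inc5[z] + inc3[w]
            for z in BASES
            for w in BASES
        }
        rmsd, r, slope, intercept = additivity_summary(
            enumerate_additivity_cycles(table)
        )
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_rmsd_scales_with_table_noise(self, rng):
        """Each deviation combines 4 table cells, so rmsd -> 2*sigma."""
        sigma = 0.1
        rmsds = []
        for _ in range(200):
            table = _full_table(8.9 + rng.normal(0.0, sigma, 16))
            rmsd, *_ = additivity_summary(enumerate_additivity_cycles(table))
            rmsds.append(rmsd)
        assert np.mean(rmsds) == pytest.approx(2 * sigma, rel=0.05)

    def test_anticorrelated_construction(self):
        # observed deviations opposite to predictions
        cycles = enumerate_additivity_cycles(
            _full_table(np.arange(16, dtype=float))
        )
        for c in cycles:
            c.observed = -c.predicted
        _, r, slope, _ = additivity_summary(cycles)
        assert r < 0 and slope < 0


class TestPartitionTest:
    def test_complete_separation_8v8(self):
        p = partition_test(np.arange(8), np.arange(8) + 100)
        assert p == pytest.approx(2 / 12870, rel=1e-12)

    def test_identical_groups(self):
        assert partition_test([1, 1, 1], [1, 1, 1]) == pytest.approx(1.0)

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        x = rng.normal(0, 1, 4)
        y = rng.normal(0.5, 1, 4)
        ours = partition_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matches_brute_force_with_ties(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0, 4.0]
        pooled = np.array(x + y)
        ranks = stats.rankdata(pooled)
        mean = 4 * 9 / 2.0
        obs = abs(ranks[:4].sum() - mean)
        hits = total = 0
        for combo in itertools.combinations(range(8), 4):
            w = abs(ranks[list(combo)].sum() - mean)
            hits += w >= obs - 1e-9
            total += 1
        assert partition_test(x, y) == pytest.approx(hits / total, rel=1e-12)

    def test_grouping_by_three_prime_class(self):
        recs = [
            PKaRecord(TripletContext(z, w), 9.0 if w in "AG" else 8.0, 0.05)
            for z in BASES
            for w in BASES
        ]
        purine, pyrimidine = group_by_three_prime_class(recs)
        assert len(purine) == len(pyrimidine) == 8
        assert partition_test(purine, pyrimidine) == pytest.approx(2 / 12870, abs=1e-3)


class TestCompareFingerprints:
    def test_identity_line(self):
        x = np.linspace(0, 2, 8)
        res = compare_fingerprints(x, x)
        assert res["rmsd"] == pytest.approx(0.0, abs=1e-12)
        assert res["slope"] == pytest.approx(1.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self):
        x = np.linspace(0, 2, 8)
        res = compare_fingerprints(x, x + 0.3)
        assert res["rmsd"] == pytest.approx(0.3)
        assert res["slope"] == pytest.approx(1.0)

    def test_against_normal_equations_oracle(self, rng):
        x = rng.normal(0, 1, 5)
        y = rng.normal(0, 1, 5)
        res = compare_fingerprints(x, y)
        A = np.column_stack([x, np.ones(5)])
        slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
        assert res["slope"] == pytest.approx(slope, rel=1e-9)
        assert res["intercept"] == pytest.approx(intercept, rel=1e-9)
        assert res["slope_ci"][0] < slope < res["slope_ci"][1]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            compare_fingerprints([1, 2], [1, 2])


class TestDeshearDecomposition:
    def test_elementwise_difference(self):
        ctx = TripletContext("A", "A")
        out = deshear_decomposition({ctx: (1.0, 0.1)}, {ctx: (0.4, 0.1)})
        assert out[ctx][0] == pytest.approx(0.6)
        assert out[ctx][1] == pytest.approx(0.1414, abs=2e-4)

    def test_sigma_matches_monte_carlo(self, rng):
        ctx = TripletContext("G", "T")
        s1, s2 = 0.12, 0.07
        out = deshear_decomposition({ctx: (1.0, s1)}, {ctx: (0.4, s2)})
        draws = rng.normal(1.0, s1, 40000) - rng.normal(0.4, s2, 40000)
        assert out[ctx][1] == pytest.approx(np.std(draws), rel=0.05)

    def test_context_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deshear_decomposition(
                {TripletContext("A", "A"): (1.0, 0.1)},
                {TripletContext("A", "C"): (0.4, 0.1)},
            )
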