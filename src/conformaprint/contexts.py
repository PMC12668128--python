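"""Trinucleotide sequence contexts.

A context names the Watson-Crick neighbors flanking a central position:
``"ZTW"`` means 5'-neighbor ``Z``, central base (T or its analog), 3'-neighbor
``W``.  There are exactly 16 such NTN contexts.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True, order=True)
class TripletContext:
    """5' and 3' Watson-Crick neighbors of the central position."""

    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.five_prime not in BASES or self.three_prime not in BASES:
            raise ValueError(
                f"bases must be one of {BASES}, got "
                f"{self.five_prime!r}/{self.three_prime!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.five_prime}T{self.three_prime}"

    @classmethod
    def from_label(cls, label: str) -> "TripletContext":
        """Parse a ``"ZTW"`` (or bare ``"ZW"``) label."""
        if len(label) == 3:
            return cls(label[0], label[2])
        if len(label) == 2:
            return cls(label[0], label[1])
        raise ValueError(f"cannot parse context label {label!r}")

    def reverse_complement(self) -> "TripletContext":
        """Flank pair as seen from the opposite strand.

        The 5' neighbor of the partner strand is the complement of this
        strand's 3' neighbor, and vice versa.
        """
        return TripletContext(
            _COMPLEMENT[self.three_prime], _COMPLEMENT[self.five_prime]
        )


#: All 16 contexts in alphabetical (5', then 3') order.
ALL_CONTEXTS: tuple[TripletContext, ...] = tuple(
    TripletContext(z, w) for z in BASES for w in BASES
)


def context_index(ctx: TripletContext) -> int:
    return BASES.index(ctx.five_prime) * 4 + BASES.index(ctx.three_prime)
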