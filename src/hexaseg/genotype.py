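"""Homoeolog-type genotypes and the algebra on them.

A locus in a (segmental) allohexaploid carries up to twelve copies drawn
from three subgenome-diagnostic classes A, B and C, plus X for copies that
are detected by the nondiscriminatory control probe but null to all three
discriminatory probes.  A genotype is the multiset of those copies; its
canonical text form is the sorted letter string, e.g. ``"AABBBC"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator

TYPES = ("A", "B", "C", "X")

#: Hard cap on copies at one locus.  Observed apparent ploidy tops out at 11
#: in sweetpotato panels; 12 leaves headroom and bounds all enumerations.
MAX_PLOIDY = 12


class GenotypeError(ValueError):
    """Raised for malformed genotype strings or out-of-range copy numbers."""


@dataclass(frozen=True, order=True)
class HomoeologGenotype:
    """Immutable multiset of homoeolog-type copies at one locus.

    Parameters
    ----------
    count_A, count_B, count_C : int
        Copies of the three discriminated homoeolog-types.
    count_X : int
        Null-signaled copies (control probe only), default 0.
    """

    count_A: int
    count_B: int
    count_C: int
    count_X: int = 0

    def __post_init__(self) -> None:
        for t in TYPES:
            c = getattr(self, f"count_{t}")
            if not isinstance(c, int) or c < 0:
                raise GenotypeError(f"count_{t} must be a non-negative integer, got {c!r}")
        if self.total == 0:
            raise GenotypeError("empty genotype: at least one copy required")
        if self.total > MAX_PLOIDY:
            raise GenotypeError(
                f"total copies {self.total} exceed the ploidy cap {MAX_PLOIDY}"
            )

    @property
    def total(self) -> int:
        """Total copy number = apparent ploidy of the locus."""
        return self.count_A + self.count_B + self.count_C + self.count_X

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.count_A, self.count_B, self.count_C, self.count_X)

    def count(self, t: str) -> int:
        if t not in TYPES:
            raise GenotypeError(f"unknown homoeolog-type {t!r}")
        return getattr(self, f"count_{t}")

    def __str__(self) -> str:
        return format_genotype(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"HomoeologGenotype({format_genotype(self)!r})"

    def __iter__(self) -> Iterator[str]:
        """Iterate over individual copies as letters, in canonical order."""
        for t in TYPES:
            yield from t * self.count(t)

    def has_x(self) -> bool:
        return self.count_X > 0


# A gamete is structurally the same multiset; the distinction is contextual
# (a balanced gamete of a 2n-copy parent carries n copies, n or n+1 for odd
# parents with a univalent).
GameteGenotype = HomoeologGenotype


def parse_genotype(s: str) -> HomoeologGenotype:
    """Parse a letter-multiset string such as ``"AABBBC"``.

    Order-insensitive: ``"BCABAB"`` parses to the same genotype.

    Raises
    ------
    GenotypeError
        On empty input, characters outside {A, B, C, X}, or length > 12.
    """
    if not isinstance(s, str) or not s:
        raise GenotypeError("genotype string must be non-empty")
    s = s.strip().upper()
    bad = set(s) - set(TYPES)
    if bad:
        raise GenotypeError(f"illegal character(s) {sorted(bad)} in genotype {s!r}")
    if len(s) > MAX_PLOIDY:
        raise GenotypeError(f"genotype {s!r} has {len(s)} copies, cap is {MAX_PLOIDY}")
    c = Counter(s)
    return HomoeologGenotype(c["A"], c["B"], c["C"], c["X"])


def format_genotype(g: HomoeologGenotype) -> str:
    """Canonical sorted-letter string, A < B < C < X."""
    return "".join(g)


def combine(g1: HomoeologGenotype, g2: HomoeologGenotype) -> HomoeologGenotype:
    """Fertilization: componentwise sum of two gamete multisets."""
    if g1.total + g2.total > MAX_PLOIDY:
        raise GenotypeError(
            f"combined total {g1.total + g2.total} exceeds the ploidy cap {MAX_PLOIDY}"
        )
    return HomoeologGenotype(
        g1.count_A + g2.count_A,
        g1.count_B + g2.count_B,
        g1.count_C + g2.count_C,
        g1.count_X + g2.count_X,
    )


def classify_composition(g: HomoeologGenotype) -> str:
    """Mono-, di- or tri-type composition over the discriminated types.

    Counts the distinct nonzero classes among {A, B, C}.  Genotypes carrying
    X copies cannot be placed (the X could be any of the three types) and
    return ``"unclassifiable"``.
    """
    if g.count_X > 0:
        return "unclassifiable"
    k = sum(1 for t in ("A", "B", "C") if g.count(t) > 0)
    return {1: "mono", 2: "di", 3: "tri"}[k]


def apparent_ploidy(g: HomoeologGenotype) -> int:
    """Total copy count at the locus; 6 for a euploid hexaploid locus."""
    return g.total
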