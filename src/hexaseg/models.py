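"""Exact gamete and offspring distributions under bivalent pairing models.

Three meiotic regimes for a polyploid locus, all under strictly bivalent
configuration and without double reduction:

* **disomic** — preferential pairing: every chromosome pairs with another of
  its own homoeolog-type where possible (AA, BB, CC bivalents); at most one
  leftover copy per type remains, and leftovers pair allosyndetically at
  random.  Gametes have essentially fixed subgenome composition.
* **polysomic** — complete random pairing: a uniform random perfect matching
  of all copies into bivalents, one random member of each transmitted.  This
  is equivalent to drawing a uniform (multivariate-hypergeometric) half-size
  sub-multiset, which the enumeration oracle verifies.
* **mixed** — a segmental-allopolyploid blend: a fraction ``f_di`` of
  meioses (or of gametes, depending on coupling) follow the disomic regime,
  the rest the polysomic one.

Odd-ploidy parents leave exactly one univalent, transmitted with
probability ``univalent_transmission`` (default 1/2).

All probabilities are exact :class:`fractions.Fraction` values.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal

from .genotype import (
    GenotypeError,
    HomoeologGenotype,
    TYPES,
    combine,
    parse_genotype,
)

__all__ = [
    "PairingModel",
    "ProbabilityMap",
    "OffspringClassification",
    "polysomic_gametes",
    "disomic_gametes",
    "mixed_gametes",
    "offspring_distribution",
    "dual_sourced_classes",
    "classify_offspring",
    "matching_enumeration_gametes",
]

_NORM_TOL = Fraction(1, 10**12)


class ProbabilityMap(dict):
    """Exact probability distribution over genotypes.

    A ``dict`` mapping :class:`HomoeologGenotype` to :class:`Fraction`
    (or float after :meth:`to_float`), with zero-mass keys dropped.
    """

    def __init__(self, entries: Iterable[tuple[HomoeologGenotype, Fraction]] | dict = ()):
        super().__init__()
        items = entries.items() if isinstance(entries, dict) else entries
        for g, p in items:
            if p < 0:
                raise ValueError(f"negative probability {p} for {g}")
            if p != 0:
                self[g] = self.get(g, Fraction(0)) + p

    def validate(self) -> "ProbabilityMap":
        s = sum(self.values())
        if abs(s - 1) > _NORM_TOL:
            raise ValueError(f"distribution sums to {s}, not 1")
        return self

    @property
    def support(self) -> set[HomoeologGenotype]:
        return set(self.keys())

    def p(self, g: HomoeologGenotype | str) -> Fraction:
        if isinstance(g, str):
            g = parse_genotype(g)
        return self.get(g, Fraction(0))

    def to_float(self) -> dict[HomoeologGenotype, float]:
        return {g: float(p) for g, p in self.items()}

    def mix(self, other: "ProbabilityMap", w: Fraction) -> "ProbabilityMap":
        """Return ``w*self + (1-w)*other``."""
        out = Counter()
        for g, p in self.items():
            out[g] += w * p
        for g, p in other.items():
            out[g] += (1 - w) * p
        return ProbabilityMap(out)

    def convolve(self, other: "ProbabilityMap") -> "ProbabilityMap":
        """Offspring distribution from independent egg and pollen draws."""
        out = Counter()
        for g1, p1 in self.items():
            for g2, p2 in other.items():
                out[combine(g1, g2)] += p1 * p2
        return ProbabilityMap(out)

    def expected_counts(self) -> dict[str, Fraction]:
        """Expected copy number of each homoeolog-type under the distribution."""
        out = {t: Fraction(0) for t in TYPES}
        for g, p in self.items():
            for t in TYPES:
                out[t] += p * g.count(t)
        return out


@dataclass(frozen=True)
class PairingModel:
    """Meiotic pairing regime and its parameters.

    ``coupling`` decides whether the two gametes of one offspring share the
    drawn regime: ``"individual"`` (default) models fully disomic vs fully
    polysomic individuals, which is the premise of the F_Di estimator
    algebra; ``"gamete"`` mixes at the gamete level instead.
    """

    mode: Literal["disomic", "polysomic", "mixed"] = "polysomic"
    f_di: Fraction | float = Fraction(0)
    univalent_transmission: Fraction | float = Fraction(1, 2)
    coupling: Literal["individual", "gamete"] = "individual"

    def __post_init__(self) -> None:
        f = Fraction(self.f_di).limit_denominator(10**9) if not isinstance(self.f_di, Fraction) else self.f_di
        u = Fraction(self.univalent_transmission).limit_denominator(10**9) if not isinstance(self.univalent_transmission, Fraction) else self.univalent_transmission
        if not 0 <= f <= 1:
            raise ValueError(f"f_di must be in [0, 1], got {self.f_di}")
        if not 0 <= u <= 1:
            raise ValueError(f"univalent_transmission must be in [0, 1], got {self.univalent_transmission}")
        object.__setattr__(self, "f_di", f)
        object.__setattr__(self, "univalent_transmission", u)
        if self.mode not in ("disomic", "polysomic", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.coupling not in ("individual", "gamete"):
            raise ValueError(f"unknown coupling {self.coupling!r}")

    @property
    def effective_f_di(self) -> Fraction:
        if self.mode == "disomic":
            return Fraction(1)
        if self.mode == "polysomic":
            return Fraction(0)
        return self.f_di


DISOMIC = PairingModel(mode="disomic")
POLYSOMIC = PairingModel(mode="polysomic")


def _as_genotype(g: HomoeologGenotype | str) -> HomoeologGenotype:
    return parse_genotype(g) if isinstance(g, str) else g


def _genotype_from_letters(letters: Iterable[str]) -> HomoeologGenotype:
    c = Counter(letters)
    return HomoeologGenotype(c["A"], c["B"], c["C"], c["X"])


def _hypergeometric_subsets(counts: dict[str, int], k: int) -> Counter:
    """P(sub-multiset) for a uniform k-subset of the multiset ``counts``."""
    types = [t for t in TYPES if counts.get(t, 0)]
    m = sum(counts.values())
    denom = math.comb(m, k)
    out = Counter()

    def rec(i: int, remaining: int, picked: dict, ways: int) -> None:
        if i == len(types):
            if remaining == 0:
                g = HomoeologGenotype(*(picked.get(t, 0) for t in TYPES))
                out[g] += Fraction(ways, denom)
            return
        t = types[i]
        for j in range(min(counts[t], remaining) + 1):
            picked[t] = j
            rec(i + 1, remaining - j, picked, ways * math.comb(counts[t], j))
        picked.pop(t, None)

    rec(0, k, {}, 1)
    return out


def polysomic_gametes(
    parent: HomoeologGenotype | str,
    univalent_transmission: Fraction | float = Fraction(1, 2),
) -> ProbabilityMap:
    """Gamete distribution under complete random bivalent pairing.

    Even parents (2n copies): a uniform random perfect matching with
    independent segregation transmits a uniform n-subset, i.e. the gamete
    counts are multivariate hypergeometric.  Odd parents (2n+1): the
    unmatched univalent is uniform over copies by symmetry; it joins the
    gamete with probability ``univalent_transmission``.
    """
    parent = _as_genotype(parent)
    u = Fraction(univalent_transmission).limit_denominator(10**9)
    m = parent.total
    if m < 2:
        raise GenotypeError(f"parent {parent} has fewer than 2 copies; cannot form gametes")
    counts = {t: parent.count(t) for t in TYPES}
    out = Counter()
    if m % 2 == 0:
        out.update(_hypergeometric_subsets(counts, m // 2))
    else:
        n = m // 2
        for t in TYPES:
            if counts[t] == 0:
                continue
            p_uni = Fraction(counts[t], m)
            rest = dict(counts)
            rest[t] -= 1
            for g, p in _hypergeometric_subsets(rest, n).items():
                out[g] += p_uni * p * (1 - u)
                plus = Counter(dict(zip(TYPES, g.counts)))
                plus[t] += 1
                out[HomoeologGenotype(*(plus[x] for x in TYPES))] += p_uni * p * u
    return ProbabilityMap(out).validate()


def _matchings(items: list) -> Iterable[list[tuple]]:
    if not items:
        yield []
        return
    first = items[0]
    for i in range(1, len(items)):
        for rest in _matchings(items[1:i] + items[i + 1:]):
            yield [(first, items[i])] + rest


def disomic_gametes(
    parent: HomoeologGenotype | str,
    univalent_transmission: Fraction | float = Fraction(1, 2),
) -> ProbabilityMap:
    """Gamete distribution under preferential (same-type) bivalent pairing.

    Each type forms ``floor(count/2)`` same-type bivalents, each of which
    transmits exactly one copy of its type.  The at-most-one leftover copy
    per type pairs allosyndetically: leftovers are matched uniformly at
    random into bivalents (uniform univalent choice first when their number
    is odd), and each such bivalent transmits either member with
    probability 1/2.
    """
    parent = _as_genotype(parent)
    u = Fraction(univalent_transmission).limit_denominator(10**9)
    if parent.total < 2:
        raise GenotypeError(f"parent {parent} has fewer than 2 copies; cannot form gametes")
    base: list[str] = []
    leftovers: list[str] = []
    for t in TYPES:
        c = parent.count(t)
        base.extend(t * (c // 2))
        if c % 2:
            leftovers.append(t)
    out = Counter()

    def segregate(pairs: list[tuple[str, str]], weight: Fraction, extra: list[str]) -> None:
        k = len(pairs)
        for mask in range(1 << k):
            letters = base + extra + [
                pairs[j][(mask >> j) & 1] for j in range(k)
            ]
            out[_genotype_from_letters(letters)] += weight / (1 << k)

    if len(leftovers) % 2 == 0:
        ms = list(_matchings(leftovers))
        for mtch in ms:
            segregate(mtch, Fraction(1, len(ms)), [])
    else:
        terms = []
        for i, uni in enumerate(leftovers):
            rest = leftovers[:i] + leftovers[i + 1:]
            for mtch in _matchings(rest):
                terms.append((uni, mtch))
        w = Fraction(1, len(terms))
        for uni, mtch in terms:
            segregate(mtch, w * (1 - u), [])
            segregate(mtch, w * u, [uni])
    return ProbabilityMap(out).validate()


def mixed_gametes(parent: HomoeologGenotype | str, model: PairingModel) -> ProbabilityMap:
    """Gamete-level mixture ``f_di * disomic + (1 - f_di) * polysomic``."""
    f = model.effective_f_di
    u = model.univalent_transmission
    di = disomic_gametes(parent, u)
    po = polysomic_gametes(parent, u)
    return di.mix(po, f).validate()


def offspring_distribution(
    mother: HomoeologGenotype | str,
    father: HomoeologGenotype | str,
    model: PairingModel,
) -> ProbabilityMap:
    """Exact offspring genotype distribution for a cross (or selfing).

    With ``coupling="individual"`` the whole individual is disomic with
    probability ``f_di``:  ``f * (D ⊗ D) + (1 - f) * (P ⊗ P)``; with
    ``coupling="gamete"`` each gamete mixes independently: ``M ⊗ M``.
    """
    mother, father = _as_genotype(mother), _as_genotype(father)
    u = model.univalent_transmission
    f = model.effective_f_di
    if model.coupling == "gamete" and model.mode == "mixed":
        m = mixed_gametes(mother, model)
        p = mixed_gametes(father, model)
        return m.convolve(p).validate()
    di = disomic_gametes(mother, u).convolve(disomic_gametes(father, u))
    if f == 1:
        return di.validate()
    po = polysomic_gametes(mother, u).convolve(polysomic_gametes(father, u))
    if f == 0:
        return po.validate()
    return di.mix(po, f).validate()


def dual_sourced_classes(
    mother: HomoeologGenotype | str,
    father: HomoeologGenotype | str,
    univalent_transmission: Fraction | float = Fraction(1, 2),
) -> tuple[set[HomoeologGenotype], set[HomoeologGenotype]]:
    """Full and partial dual-sourced offspring classes of a cross.

    Full dual-sourced classes are reachable with both gametes from
    preferential pairing (and, by construction, also under random pairing);
    partial dual-sourced classes need exactly one preferential-pairing
    gamete.  Returns ``(full, partial)``.
    """
    mother, father = _as_genotype(mother), _as_genotype(father)
    u = univalent_transmission
    dm, df = disomic_gametes(mother, u), disomic_gametes(father, u)
    pm, pf = polysomic_gametes(mother, u), polysomic_gametes(father, u)
    full = dm.convolve(df).support
    partial = (dm.convolve(pf).support | pm.convolve(df).support) - full
    return full, partial


@dataclass(frozen=True)
class OffspringClassification:
    """Mechanistic class of one offspring genotype given its parents."""

    category: Literal[
        "full_dual_sourced",
        "partial_dual_sourced",
        "polysomic_only",
        "idr_indicative",
        "idr_or_unreduced",
        "aneuploid_dysploid",
    ]
    rationale: str = ""


def _legal_gamete_sizes(parent: HomoeologGenotype) -> set[int]:
    n = parent.total // 2
    return {n} if parent.total % 2 == 0 else {n, n + 1}


def _decompositions(child: HomoeologGenotype, size1: int):
    """All splits of ``child`` into two count-vectors with |g1| = size1."""
    ranges = [range(0, c + 1) for c in child.counts]
    for a in ranges[0]:
        for b in ranges[1]:
            for c in ranges[2]:
                for x in ranges[3]:
                    if a + b + c + x == size1:
                        g1 = (a, b, c, x)
                        g2 = tuple(tc - tg for tc, tg in zip(child.counts, g1))
                        yield g1, g2


def _gamete_feasible(g: tuple[int, ...], parent: HomoeologGenotype, allow_dr: bool) -> bool:
    """Can ``parent`` produce a gamete with counts ``g`` by bivalent
    segregation, optionally with one double-reduction event?

    Without DR every transmitted copy is a distinct parental chromosome, so
    each count is capped by the parental count.  One DR event carries both
    sister chromatids of a single chromosome, allowing one type to exceed
    its parental count by exactly one (the type must end with >= 2 copies).
    """
    excess = 0
    for gt, pt in zip(g, parent.counts):
        if gt > pt:
            if not allow_dr or gt > pt + 1 or gt < 2:
                return False
            excess += gt - pt
    return excess <= (1 if allow_dr else 0)


def classify_offspring(
    mother: HomoeologGenotype | str,
    father: HomoeologGenotype | str,
    child: HomoeologGenotype | str,
) -> OffspringClassification:
    """Assign an offspring genotype to its most parsimonious mechanism.

    Priority: full dual-sourced > partial dual-sourced > polysomic-only >
    IDR-indicative (balanced gamete sizes but an identical-by-double-
    reduction pair required) > IDR-or-unreduced (explainable only with an
    IDR pair or a partially unreduced gamete) > aneuploid/dysploid.
    """
    mother, father, child = map(_as_genotype, (mother, father, child))
    full, partial = dual_sourced_classes(mother, father)
    if child in full:
        return OffspringClassification(
            "full_dual_sourced", "reachable with both gametes from preferential pairing"
        )
    if child in partial:
        return OffspringClassification(
            "partial_dual_sourced", "reachable with exactly one preferential-pairing gamete"
        )
    sizes_m, sizes_f = _legal_gamete_sizes(mother), _legal_gamete_sizes(father)
    balanced_sums = {a + b for a in sizes_m for b in sizes_f}

    def reachable(allow_dr: bool, unreduced: bool) -> bool:
        extra_m = {s + 1 for s in sizes_m} if unreduced else set()
        extra_f = {s + 1 for s in sizes_f} if unreduced else set()

        def gamete_ok(g, parent, size, sizes, extra) -> bool:
            if not _gamete_feasible(g, parent, allow_dr):
                return False
            if size in sizes:
                return True
            # oversize gamete: only legal as partially unreduced, i.e. the
            # extra copy completes a same-type pair already in the gamete
            return size in extra and max(g) >= 2

        for sm in sorted(sizes_m | extra_m):
            sf = child.total - sm
            if sf not in (sizes_f | extra_f):
                continue
            for g1, g2 in _decompositions(child, sm):
                if gamete_ok(g1, mother, sm, sizes_m, extra_m) and gamete_ok(
                    g2, father, sf, sizes_f, extra_f
                ):
                    return True
        return False

    if child.total in balanced_sums:
        if reachable(allow_dr=False, unreduced=False):
            return OffspringClassification(
                "polysomic_only", "reachable under random but not preferential pairing"
            )
        if reachable(allow_dr=True, unreduced=False):
            return OffspringClassification(
                "idr_indicative",
                "balanced gamete sizes but requires an identical-by-double-reduction pair",
            )
    if reachable(allow_dr=True, unreduced=True):
        return OffspringClassification(
            "idr_or_unreduced",
            "explainable only with an IDR pair or a partially unreduced gamete",
        )
    return OffspringClassification(
        "aneuploid_dysploid", "unbalanced gamete required"
    )


def matching_enumeration_gametes(
    parent: HomoeologGenotype | str,
    univalent_transmission: Fraction | float = Fraction(1, 2),
) -> ProbabilityMap:
    """Brute-force oracle for the random-pairing gamete distribution.

    Enumerates every perfect matching of the labeled chromosomes into
    bivalents (every near-perfect matching plus univalent choice for odd
    parents), uniform over matchings, and every segregation pattern.  Kept
    deliberately independent of :func:`polysomic_gametes` so the two can be
    checked against each other.
    """
    parent = _as_genotype(parent)
    u = Fraction(univalent_transmission).limit_denominator(10**9)
    m = parent.total
    if m < 2:
        raise GenotypeError("cannot form gametes from fewer than 2 copies")
    if m > 10:
        raise GenotypeError("enumeration budget: parent total must be <= 10")
    chroms = list(parent)
    out = Counter()

    def segregate(mtch: list[tuple[int, int]], weight: Fraction, extra: list[str]) -> None:
        k = len(mtch)
        for mask in range(1 << k):
            letters = extra + [chroms[mtch[j][(mask >> j) & 1]] for j in range(k)]
            out[_genotype_from_letters(letters)] += weight / (1 << k)

    idx = list(range(m))
    if m % 2 == 0:
        ms = list(_matchings(idx))
        for mtch in ms:
            segregate(mtch, Fraction(1, len(ms)), [])
    else:
        terms = []
        for i in idx:
            rest = [j for j in idx if j != i]
            for mtch in _matchings(rest):
                terms.append((i, mtch))
        w = Fraction(1, len(terms))
        for uni, mtch in terms:
            segregate(mtch, w * (1 - u), [])
            segregate(mtch, w * u, [chroms[uni]])
    return ProbabilityMap(out).validate()
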