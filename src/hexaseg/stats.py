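"""Segregation tests and the disomic-inheritance frequency estimator.

Observed genotype tables from a selfing or cross are compared against the
exact expectations of the bivalent pairing engines; the proportion of
meioses following the disomic regime is estimated from the observed
frequency of the *full dual-sourced* offspring classes — those reachable
with both gametes from preferential pairing — via

    F_Di = (F_Ods − F_Epl) / (1 − F_Epl)

where ``F_Ods`` is their observed total frequency and ``F_Epl`` their
expected total frequency under pure polysomic (random-pairing)
inheritance.  A fully disomic individual always lands in a full
dual-sourced class, while a polysomic one does so with probability
``F_Epl``; solving ``F_Ods = F_Di + (1 − F_Di) · F_Epl`` gives the formula.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .genotype import HomoeologGenotype, apparent_ploidy, classify_composition, parse_genotype
from .models import (
    PairingModel,
    POLYSOMIC,
    DISOMIC,
    ProbabilityMap,
    dual_sourced_classes,
    offspring_distribution,
)

__all__ = [
    "chisq_gof",
    "multinomial_mc_test",
    "per_class_ztest",
    "estimate_f_di",
    "type_totals_test",
    "composition_summary",
    "segregation_report",
    "SegregationReport",
]

MIN_EXPECTED_FOR_CHISQ = 5


def chisq_gof(
    observed: Sequence[int] | np.ndarray,
    expected_p: Sequence[float] | np.ndarray,
) -> tuple[float, float, bool]:
    """Pearson chi-square goodness of fit against class probabilities.

    Returns ``(stat, p, small_expected)`` where ``small_expected`` warns
    that some expected count is below 5, in which regime the chi-square
    approximation misleads and the Monte-Carlo multinomial test should be
    used instead.  A class with zero expected probability but nonzero
    observed count yields an infinite statistic and p = 0.
    """
    obs = np.asarray(observed, dtype=float)
    p = np.asarray(expected_p, dtype=float)
    if obs.shape != p.shape:
        raise ValueError("observed and expected_p must align")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"expected probabilities sum to {p.sum()}, not 1")
    n = obs.sum()
    zero = p == 0
    if np.any(obs[zero] > 0):
        return float("inf"), 0.0, True
    obs, p = obs[~zero], p[~zero]
    exp = p * n
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    pval = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, pval, bool((exp < MIN_EXPECTED_FOR_CHISQ).any())


def _log_multinomial_pmf(tables: np.ndarray, n: int, p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        term = np.where(
            tables > 0, tables * logp - gammaln(tables + 1), -gammaln(tables + 1)
        )
        # a zero-probability class with nonzero count makes the table impossible
        impossible = ((tables > 0) & (p == 0)).any(axis=-1)
    out = gammaln(n + 1) + term.sum(axis=-1)
    out[impossible] = -np.inf
    return out


def multinomial_mc_test(
    observed: Sequence[int] | np.ndarray,
    expected_p: Sequence[float] | np.ndarray,
    n_mc: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo exact multinomial goodness-of-fit p-value.

    Simulates ``n_mc`` tables from the null and reports the proportion
    whose multinomial probability is at most that of the observed table
    (with add-one smoothing, so the smallest attainable p is
    ``1/(n_mc + 1)``).
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10,000 for a stable p-value")
    obs = np.asarray(observed, dtype=float)
    p = np.asarray(expected_p, dtype=float)
    n = int(round(obs.sum()))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.any(obs[p == 0] > 0):
        return 1.0 / (n_mc + 1)
    logp_obs = float(_log_multinomial_pmf(obs[None, :], n, p)[0])
    sims = rng.multinomial(n, p, size=n_mc).astype(float)
    logp_sim = _log_multinomial_pmf(sims, n, p)
    hits = int((logp_sim <= logp_obs + 1e-9).sum())
    return (hits + 1) / (n_mc + 1)


def per_class_ztest(obs_count: int, n: int, p_exp: float) -> tuple[float, float]:
    """Normal-approximation test of one class frequency, no continuity
    correction: z = (obs/n − p) / sqrt(p(1−p)/n)."""
    if not 0 < p_exp < 1:
        raise ValueError("p_exp must be strictly between 0 and 1")
    if n <= 0:
        raise ValueError("n must be positive")
    z = (obs_count / n - p_exp) / np.sqrt(p_exp * (1 - p_exp) / n)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _count_table(observed) -> Counter:
    """Normalize observed genotypes to Counter[HomoeologGenotype]."""
    if isinstance(observed, Mapping):
        items = observed.items()
    else:
        items = Counter(observed).items()
    out = Counter()
    for g, c in items:
        if isinstance(g, str):
            g = parse_genotype(g)
        out[g] += int(c)
    return out


def estimate_f_di(
    observed,
    mother: HomoeologGenotype | str,
    father: HomoeologGenotype | str | None = None,
    euploid_only: bool = False,
) -> tuple[float, float, float]:
    """Estimate the disomic-inheritance frequency from an offspring table.

    ``observed`` maps genotypes (strings or objects) to counts, or is an
    iterable of genotypes; ``father`` defaults to ``mother`` (selfing).
    Partial dual-sourced classes are excluded from the numerator classes
    (making the estimate conservative).  ``euploid_only`` restricts the
    denominator to offspring whose total equals a balanced gamete-sum;
    the default keeps every genotyped line.

    Returns ``(F_Ods, F_Epl, F_Di)`` with F_Di clamped into [0, 1].
    """
    mother = parse_genotype(mother) if isinstance(mother, str) else mother
    father = mother if father is None else (
        parse_genotype(father) if isinstance(father, str) else father
    )
    table = _count_table(observed)
    full, _partial = dual_sourced_classes(mother, father)
    poly = offspring_distribution(mother, father, POLYSOMIC)
    f_epl = float(sum(poly.p(g) for g in full))
    if f_epl >= 1:
        raise ValueError("every offspring class is dual-sourced; F_Di is undefined")
    if euploid_only:
        balanced = {g.total for g in poly.support}
        table = Counter({g: c for g, c in table.items() if g.total in balanced})
    n = sum(table.values())
    if n == 0:
        raise ValueError("empty observed table")
    f_ods = sum(c for g, c in table.items() if g in full) / n
    f_di = (f_ods - f_epl) / (1 - f_epl)
    return f_ods, f_epl, float(min(1.0, max(0.0, f_di)))


def type_totals_test(observed, parent: HomoeologGenotype | str) -> dict:
    """Pooled A:B:C copy totals across a population vs parental proportions.

    Under every bivalent pairing regime each parental chromosome transmits
    with probability 1/2, so offspring homoeolog-type totals keep the
    parental ratio; a significant chi-square flags a skewed population.
    """
    parent = parse_genotype(parent) if isinstance(parent, str) else parent
    table = _count_table(observed)
    totals = {t: 0 for t in "ABC"}
    for g, c in table.items():
        for t in "ABC":
            totals[t] += g.count(t) * c
    par = np.array([parent.count(t) for t in "ABC"], dtype=float)
    keep = par > 0
    p_exp = par[keep] / par[keep].sum()
    obs = np.array([totals[t] for t in "ABC"], dtype=float)
    if obs[~keep].sum() > 0:
        return {"totals": totals, "stat": float("inf"), "p": 0.0,
                "note": "types absent from the parent observed in offspring"}
    stat, p, small = chisq_gof(obs[keep], p_exp)
    return {"totals": totals, "stat": stat, "p": p, "small_expected": small}


def composition_summary(observed) -> dict:
    """Mono/di/tri composition frequencies and apparent-ploidy histogram."""
    table = _count_table(observed)
    n = sum(table.values())
    if n == 0:
        raise ValueError("empty genotype table")
    comp = Counter()
    ploidy = Counter()
    for g, c in table.items():
        comp[classify_composition(g)] += c
        ploidy[apparent_ploidy(g)] += c
    return {
        "n": n,
        "composition": {k: comp.get(k, 0) / n
                        for k in ("mono", "di", "tri", "unclassifiable")},
        "ploidy_hist": {k: ploidy[k] / n for k in sorted(ploidy)},
    }


@dataclass
class SegregationReport:
    """Full per-locus comparison of an offspring table with expectations."""

    locus_id: str
    n: int
    per_class: list[dict] = field(default_factory=list)
    chi2_stat: float = float("nan")
    chi2_p: float = float("nan")
    multinomial_mc_p: float | None = None
    method_used: str = "chi-square"
    F_Ods: float = float("nan")
    F_Epl: float = float("nan")
    F_Di: float = float("nan")
    type_totals: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "n": self.n,
            "per_class": self.per_class,
            "gof": {
                "chi2_stat": self.chi2_stat,
                "chi2_p": self.chi2_p,
                "multinomial_mc_p": self.multinomial_mc_p,
                "method_used": self.method_used,
            },
            "F_Ods": self.F_Ods,
            "F_Epl": self.F_Epl,
            "F_Di": self.F_Di,
            "type_totals": self.type_totals,
        }


def segregation_report(
    observed,
    mother: HomoeologGenotype | str,
    father: HomoeologGenotype | str | None = None,
    locus_id: str = "",
    n_mc: int = 100_000,
    seed: int = 0,
    euploid_only: bool = False,
) -> SegregationReport:
    """Observed-vs-expected segregation analysis at one locus.

    Genotypes outside the polysomic support (aneuploid/dysploid or
    double-reduction classes) stay in the denominator and the per-class
    listing but are pooled out of the goodness-of-fit comparison, which is
    made against the polysomic expectation restricted to its support.  The
    chi-square is replaced by the Monte-Carlo multinomial test whenever an
    expected count falls below 5.
    """
    mother = parse_genotype(mother) if isinstance(mother, str) else mother
    father = mother if father is None else (
        parse_genotype(father) if isinstance(father, str) else father
    )
    table = _count_table(observed)
    n = sum(table.values())
    poly = offspring_distribution(mother, father, POLYSOMIC)
    dis = offspring_distribution(mother, father, DISOMIC)
    classes = sorted(set(poly.support) | set(table), key=str)
    per_class = []
    for g in classes:
        obs_c = table.get(g, 0)
        p_pl = float(poly.p(g))
        p_di = float(dis.p(g))
        z = zp = None
        if 0 < p_pl < 1:
            z, zp = per_class_ztest(obs_c, n, p_pl)
        per_class.append({
            "genotype": str(g), "observed": obs_c,
            "p_disomic": p_di, "p_polysomic": p_pl, "z": z, "z_p": zp,
        })
    # GOF over the polysomic support only, counts restricted accordingly
    support = sorted(poly.support, key=str)
    obs_vec = np.array([table.get(g, 0) for g in support], dtype=float)
    p_vec = np.array([float(poly.p(g)) for g in support])
    report = SegregationReport(locus_id=locus_id, n=n)
    if obs_vec.sum() > 0:
        p_vec = p_vec / p_vec.sum()
        stat, p, small = chisq_gof(obs_vec, p_vec)
        report.chi2_stat, report.chi2_p = stat, p
        if small:
            report.method_used = "multinomial-mc"
            report.multinomial_mc_p = multinomial_mc_test(
                obs_vec, p_vec, n_mc=n_mc, seed=seed
            )
    report.per_class = per_class
    report.F_Ods, report.F_Epl, report.F_Di = estimate_f_di(
        table, mother, father, euploid_only=euploid_only
    )
    report.type_totals = type_totals_test(table, mother)
    return report
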