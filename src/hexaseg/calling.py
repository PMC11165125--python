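"""Genotype calling from multiplex digital quantitative PCR concentrations.

One reaction per sample and locus carries three discriminatory probes (A —
or a composite AB that also detects B — plus B and C) and one
nondiscriminatory control probe that detects every copy at the locus.
Calling proceeds in three stages, mirroring how dosage genotypes are read
off such assays in practice:

1. **Ratio fitting** — the smallest coprime integer ratio a:b:c that the
   measured concentrations best fit (chi-square goodness of fit).
2. **Slope comparison** — the per-genome single-copy slope from the
   discriminatory probes (``S_ABC``) must statistically equal the control
   slope (``S_Ctrl``) at the called total copy number; a control excess of
   one copy-share reveals a null-signaled X copy, a deficit a mutated
   control target.
3. **Cross-locus consensus** — ratios of equal proportions (1:1:1, 1:1:0,
   1:0:0, ...) leave the absolute scale ambiguous from one reaction; the
   consensus slope across unambiguous loci on the same DNA sample fixes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import gcd
from typing import Sequence

import numpy as np
from scipy import stats

from .genotype import HomoeologGenotype, MAX_PLOIDY

__all__ = [
    "DqPCRMeasurement",
    "LocusPanel",
    "GenotypeCall",
    "partitions_to_concentration",
    "fit_ratio",
    "per_copy_slope",
    "resolve_total_copies",
    "call_genotype",
    "joint_call_sample",
]


class SaturationError(ValueError):
    """All partitions positive: concentration beyond the dynamic range."""


@dataclass(frozen=True)
class PartitionCounts:
    """Raw positive-partition counts backing the concentrations."""

    pos_A: int
    pos_B: int
    pos_C: int
    pos_ctrl: int
    n_partitions: int
    partition_vol: float  # µl


@dataclass(frozen=True)
class DqPCRMeasurement:
    """Probe-target concentrations for one sample × locus reaction.

    ``conc_A`` holds the composite AB signal when ``composite_A`` is set
    (the A-specific concentration is then AB − B).  Concentrations are in
    copies/µl, DNA concentration in pg/µl.
    """

    locus_id: str
    conc_A: float
    conc_B: float
    conc_C: float
    conc_ctrl: float
    dna_conc: float
    composite_A: bool = False
    sample_id: str = ""
    partitions: PartitionCounts | None = None

    def __post_init__(self) -> None:
        for name in ("conc_A", "conc_B", "conc_C", "conc_ctrl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dna_conc <= 0:
            raise ValueError("dna_conc must be > 0")


@dataclass(frozen=True)
class LocusPanel:
    """Per-locus calling configuration.

    ``slope_tol`` is the absolute discrepancy between per-genome single-copy
    slopes that flags a one-copy difference (0.06 in the sweetpotato assay,
    about one copy's slope share at S ≈ 0.35 and six copies).
    """

    locus_id: str = ""
    composite_A: bool = False
    p_min: float = 0.80
    slope_tol: float = 0.06
    t_max: int = MAX_PLOIDY
    n_eff: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.p_min < 1:
            raise ValueError("p_min must be in (0, 1)")
        if self.slope_tol <= 0:
            raise ValueError("slope_tol must be > 0")
        if not 1 <= self.t_max <= MAX_PLOIDY:
            raise ValueError(f"t_max must be in [1, {MAX_PLOIDY}]")


@dataclass(frozen=True)
class GenotypeCall:
    """A called genotype with its supporting statistics and flags."""

    genotype: HomoeologGenotype | None
    S_ABC: float
    S_Ctrl: float
    gof_p: float
    ratio: tuple[int, int, int]
    flags: frozenset[str] = frozenset()
    locus_id: str = ""
    sample_id: str = ""

    @property
    def ok(self) -> bool:
        return self.genotype is not None and not self.flags


def partitions_to_concentration(k: int, n: int, v: float) -> float:
    """Poisson-corrected concentration (copies/µl) from partition counts.

    ``-ln(1 - k/n) / v`` for ``k`` positive out of ``n`` partitions of
    volume ``v`` µl.
    """
    if v <= 0:
        raise ValueError("partition volume must be > 0")
    if k < 0 or k > n:
        raise ValueError(f"positive partitions {k} out of range [0, {n}]")
    if k == n:
        raise SaturationError("every partition positive; dilute the sample")
    return -math.log1p(-k / n) / v


_RATIO_CACHE: dict[int, list[tuple[int, int, int]]] = {}


def _candidate_ratios(t_max: int) -> list[tuple[int, int, int]]:
    """All coprime (a, b, c) with 1 <= a+b+c <= t_max."""
    if t_max not in _RATIO_CACHE:
        out = []
        for a in range(t_max + 1):
            for b in range(t_max + 1 - a):
                for c in range(t_max + 1 - a - b):
                    if a + b + c == 0:
                        continue
                    if gcd(gcd(a, b), c) != 1:
                        continue
                    out.append((a, b, c))
        _RATIO_CACHE[t_max] = out
    return _RATIO_CACHE[t_max]


#: Plain-significance floor used when no candidate reaches ``p_min``:
#: the smallest-total ratio not outright rejected at this level is still
#: preferred over a larger ratio that merely fits the noise better.
P_FLOOR = 0.05


def _probe_space_matrix(t_max: int, composite: bool) -> np.ndarray:
    """Expected probe-signal proportions for every candidate ratio.

    The composite AB probe detects A and B targets alike, so a copy ratio
    (a, b, c) presents as signal proportions (a + b, b, c)."""
    key = (t_max, composite)
    if key not in _PROBE_CACHE:
        R = np.array(_candidate_ratios(t_max), dtype=float)
        M = np.column_stack([R[:, 0] + R[:, 1], R[:, 1], R[:, 2]]) if composite else R
        _PROBE_CACHE[key] = M / M.sum(axis=1, keepdims=True)
    return _PROBE_CACHE[key]


_PROBE_CACHE: dict = {}


def fit_ratio(
    conc_A: float,
    conc_B: float,
    conc_C: float,
    panel: LocusPanel,
    partitions: PartitionCounts | None = None,
    composite: bool = False,
) -> list[tuple[tuple[int, int, int], float]]:
    """Rank coprime integer copy ratios by fit to the measured signals.

    ``conc_A`` is the A-specific concentration, or the raw composite AB
    signal with ``composite=True`` (candidate ratios are then compared in
    probe space, where the AB probe sees a + b copies).  Concentrations are
    not counts, so by default the chi-square uses pseudo-counts: observed
    proportions scaled by ``panel.n_eff``.  When raw positive-partition
    counts are available a calibrated binomial-occupancy chi-square is used
    instead.  Ranking is parsimony first: candidates reaching
    ``panel.p_min`` ordered by smallest total then highest p; then those
    not rejected at ``P_FLOOR``, again smallest total first; then the rest
    by p-value — so the best-fitting ratio is always reported even when no
    candidate passes, without letting a large-total ratio win just by
    fitting noise.
    """
    concs = np.array([conc_A, conc_B, conc_C], dtype=float)
    if concs.sum() <= 0:
        raise ValueError("at least one probe concentration must be > 0")
    ratios = _candidate_ratios(panel.t_max)
    P = _probe_space_matrix(panel.t_max, composite)  # (m, 3)
    zero = P == 0
    if partitions is not None:
        counts = np.array(
            [partitions.pos_A, partitions.pos_B, partitions.pos_C], dtype=float
        )
        n, v = partitions.n_partitions, partitions.partition_vol
        # occupancy-calibrated binomial chi-square: expected occupancy per
        # probe is 1 - exp(-p_i C v) with C estimated from the kept probes
        with np.errstate(divide="ignore", invalid="ignore"):
            conc_obs = -np.log1p(-counts / n) / v
            c_tot = np.where(~zero, conc_obs, 0.0).sum(axis=1)
            q = -np.expm1(-P * c_tot[:, None] * v)
            exp = n * q
            var = np.where(q > 0, n * q * (1 - q), 1.0)
            terms = np.where(~zero, (counts - exp) ** 2 / var, 0.0)
        obs = counts
    else:
        obs = concs / concs.sum() * panel.n_eff
        exp = P * obs.sum()
        terms = np.where(~zero, (obs - exp) ** 2 / np.where(zero, 1.0, exp), 0.0)
    stat = terms.sum(axis=1)
    df = (~zero).sum(axis=1) - 1
    pvals = np.where(df > 0, stats.chi2.sf(stat, np.maximum(df, 1)), 1.0)
    impossible = (zero & (obs > 0)).any(axis=1)
    pvals = np.where(impossible, 0.0, pvals)
    scored = list(zip(ratios, pvals.tolist()))
    passing = sorted(
        ((r, p) for r, p in scored if p >= panel.p_min),
        key=lambda rp: (sum(rp[0]), -rp[1], rp[0]),
    )
    plausible = sorted(
        ((r, p) for r, p in scored if P_FLOOR <= p < panel.p_min),
        key=lambda rp: (sum(rp[0]), -rp[1], rp[0]),
    )
    rejected = sorted(
        ((r, p) for r, p in scored if p < P_FLOOR),
        key=lambda rp: (-rp[1], sum(rp[0]), rp[0]),
    )
    return passing + plausible + rejected


def per_copy_slope(total_conc: float, copies: int, dna_conc: float) -> float:
    """Per-genome single-copy slope: concentration / (copies × DNA conc)."""
    if copies < 1:
        raise ZeroDivisionError("copies must be >= 1")
    if dna_conc <= 0:
        raise ValueError("dna_conc must be > 0")
    return total_conc / (copies * dna_conc)


def resolve_total_copies(
    S_ABC: float,
    conc_ctrl: float,
    dna_conc: float,
    t_abc: int,
    panel: LocusPanel,
) -> tuple[int, int, set[str]]:
    """Total copy number (and X count) from the control-probe slope.

    Finds the integer total ``t`` whose control slope ``conc_ctrl/(t ×
    dna_conc)`` is closest to ``S_ABC``; accepts when the discrepancy is
    within ``panel.slope_tol``.  ``x = t - t_abc`` when non-negative; a best
    total *below* ``t_abc`` signals a spontaneously mutated control target
    (``control_null``), and no acceptable total sets ``ambiguous_scale``.

    Returns ``(t_total, x_copies, flags)``.
    """
    if t_abc < 1:
        raise ValueError("t_abc must be >= 1")
    best_t, best_d = t_abc, float("inf")
    for t in range(1, panel.t_max + 1):
        d = abs(per_copy_slope(conc_ctrl, t, dna_conc) - S_ABC)
        if d < best_d:
            best_t, best_d = t, d
    flags: set[str] = set()
    if best_d > panel.slope_tol:
        flags.add("ambiguous_scale")
        return t_abc, 0, flags
    if best_t < t_abc:
        flags.add("control_null")
        return best_t, 0, flags
    return best_t, best_t - t_abc, flags


def _is_equal_proportion(ratio: tuple[int, int, int]) -> bool:
    nz = [r for r in ratio if r > 0]
    return len(set(nz)) == 1


def _scan_combos(
    m: DqPCRMeasurement,
    panel: LocusPanel,
    reference_slope: float | None,
):
    """Shared scan over (ratio, scale) candidates for one measurement.

    Returns ``(flags, ranked, combos, abc_total_conc)`` where each combo is
    ``(tier, t_total, -p, k, ratio, x, S_ABC, resolve_flags)``: the ratio
    fits the probe proportions at fit-tier ``tier`` (0 = not rejected at
    ``P_FLOOR``), and scale ``k`` of it is control-consistent (and within
    ``slope_tol`` of ``reference_slope`` when one is given).
    """
    flags: set[str] = set()
    composite = m.composite_A or panel.composite_A
    if composite:
        a_only = m.conc_A - m.conc_B
        if a_only < 0:
            # composite AB below B alone: beyond measurement noise this is
            # inconsistent; clamp and flag
            if m.conc_B > 0 and a_only < -0.05 * m.conc_B:
                flags.add("composite_negative")
            a_only = 0.0
    else:
        a_only = m.conc_A
    ranked = fit_ratio(
        m.conc_A if composite else a_only, m.conc_B, m.conc_C,
        panel, m.partitions, composite=composite,
    )
    abc_total_conc = a_only + m.conc_B + m.conc_C

    # selection pools candidates not rejected at P_FLOOR and lets parsimony
    # (smallest total) decide among them; p_min only drives the
    # low_confidence flag, so a large ratio cannot win just by fitting noise
    def tier(p: float) -> int:
        return 0 if p >= P_FLOOR else 1

    combos = []
    for ratio, p in ranked:
        # without a reference slope, rejected ratios other than the best
        # fit are not worth scanning (control consistency alone cannot
        # discriminate scale); with one, the slope filter screens them
        if tier(p) == 1 and reference_slope is None and ratio != ranked[0][0]:
            continue
        r_sum = sum(ratio)
        for k in range(1, panel.t_max // r_sum + 1):
            s_abc = per_copy_slope(abc_total_conc, k * r_sum, m.dna_conc)
            if reference_slope is not None and abs(s_abc - reference_slope) > panel.slope_tol:
                continue
            t_total, x, rflags = resolve_total_copies(
                s_abc, m.conc_ctrl, m.dna_conc, k * r_sum, panel
            )
            if "ambiguous_scale" in rflags:
                continue
            combos.append((tier(p), t_total, -p, k, ratio, x, s_abc, rflags))
    combos.sort(key=lambda c: c[:5])
    return flags, ranked, combos, abc_total_conc


def call_genotype(
    m: DqPCRMeasurement,
    panel: LocusPanel,
    reference_slope: float | None = None,
) -> GenotypeCall:
    """Call the homoeolog-type genotype from one dqPCR measurement.

    Composite handling subtracts B from the AB signal first.  Candidate
    ratios from :func:`fit_ratio` are tried at every integer scale ``k``
    (``k × total <= panel.t_max``); each scale's ``S_ABC`` is checked
    against the control slope via :func:`resolve_total_copies`, and the
    consistent combination with the smallest total (best fit on ties) wins.
    Equal-proportion ratios (1:1:1 etc.) accept several scales from a
    single reaction; they are flagged ``ambiguous_scale`` unless
    ``reference_slope`` (the cross-locus consensus, or a known assay
    slope) singles one out.
    """
    flags, ranked, combos, abc_total_conc = _scan_combos(m, panel, reference_slope)

    if not combos:
        ratio, gof_p = ranked[0]
        r_sum = sum(ratio)
        s_abc = per_copy_slope(abc_total_conc, r_sum, m.dna_conc)
        flags.add("ambiguous_scale")
        if gof_p < panel.p_min:
            flags.add("low_confidence")
        geno = HomoeologGenotype(*ratio, 0) if r_sum <= panel.t_max else None
        return GenotypeCall(
            geno, s_abc, per_copy_slope(m.conc_ctrl, r_sum, m.dna_conc),
            gof_p, ratio, frozenset(flags), m.locus_id, m.sample_id,
        )

    if reference_slope is not None:
        # adjacent scales of high-copy genotypes can both sit within
        # slope_tol of the consensus; nearest slope decides before parsimony
        combos.sort(key=lambda c: (c[0], abs(c[6] - reference_slope), c[1], c[2]))
    _t, t_total, neg_p, k, ratio, x, s_abc, rflags = combos[0]
    gof_p = -neg_p
    if gof_p < panel.p_min:
        flags.add("low_confidence")
    if reference_slope is None and _is_equal_proportion(ratio):
        scales = {c[3] for c in combos if c[4] == ratio}
        if len(scales) > 1:
            flags.add("ambiguous_scale")
    flags |= rflags
    geno = HomoeologGenotype(*(r * k for r in ratio), x)
    s_ctrl = per_copy_slope(m.conc_ctrl, t_total, m.dna_conc)
    return GenotypeCall(
        geno, s_abc, s_ctrl, gof_p, ratio, frozenset(flags), m.locus_id, m.sample_id
    )


def joint_call_sample(
    measurements: Sequence[DqPCRMeasurement],
    panels: dict[str, LocusPanel] | LocusPanel,
) -> list[GenotypeCall]:
    """Call several loci of one DNA sample, sharing a consensus slope.

    Per-genome single-copy slopes must be statistically equal across loci
    measured on the same DNA dilution.  Every locus contributes the
    ``S_ABC`` values of its well-fitting, control-consistent (ratio, scale)
    candidates; the consensus slope is the value covering the most loci
    within tolerance (largest slope on ties — i.e. smallest genotypes, as
    an all-loci scale ambiguity is unresolvable in principle).  All loci
    are then re-called against the consensus, which resolves
    equal-proportion ambiguities and gcd-reducible genotypes (e.g. BBBBCC
    vs BBC) alike.  Single-measurement input is returned unchanged, flags
    and all.
    """

    def panel_for(m: DqPCRMeasurement) -> LocusPanel:
        if isinstance(panels, LocusPanel):
            return panels
        return panels.get(m.locus_id, LocusPanel(locus_id=m.locus_id))

    if len(measurements) < 2:
        return [call_genotype(m, panel_for(m)) for m in measurements]

    per_locus_s: list[list[float]] = []
    tols = []
    for m in measurements:
        panel = panel_for(m)
        _fl, _ranked, combos, _conc = _scan_combos(m, panel, None)
        per_locus_s.append(sorted({c[6] for c in combos if c[0] == 0}))
        tols.append(panel.slope_tol)
    pool = sorted({s for ss in per_locus_s for s in ss})
    if not pool:
        return [call_genotype(m, panel_for(m)) for m in measurements]

    def coverage(s_star: float) -> int:
        return sum(
            any(abs(s - s_star) <= tol for s in ss)
            for ss, tol in zip(per_locus_s, tols)
        )

    consensus = max(pool, key=lambda s_star: (coverage(s_star), s_star))
    return [
        call_genotype(m, panel_for(m), reference_slope=consensus)
        for m in measurements
    ]
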