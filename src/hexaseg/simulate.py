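"""Synthetic populations and dqPCR measurements.

Generates offspring populations under the mixed bivalent-pairing model with
optional meiotic aberrations — double reduction (rate ``alpha``), partially
unreduced gametes (``beta``), single-chromosome aneuploidy (``gamma``) —
and genotype-class viability selection; and digital-PCR concentration
measurements with binomial partition occupancy noise.  Every stochastic
step runs through one seeded :class:`numpy.random.Generator`.

The aberration mechanisms are deliberately minimal generative stand-ins:
the exact expectation engines exclude them (they model bivalent
configuration without double reduction), so the rates default to 0 and
exist to produce the rare IDR / unreduced / aneuploid classes that real
populations show at low frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calling import DqPCRMeasurement, PartitionCounts, SaturationError
from .genotype import (
    HomoeologGenotype,
    MAX_PLOIDY,
    TYPES,
    combine,
    parse_genotype,
)
from .models import PairingModel, ProbabilityMap, disomic_gametes, polysomic_gametes

__all__ = [
    "SimulationParams",
    "simulate_gamete",
    "simulate_population",
    "simulate_dqpcr",
    "make_fixture_dataset",
]

#: Default digital-PCR geometry: a 26,000-partition nanoplate with 0.34 nl
#: partitions, typical of the instruments used for multiplex dosage assays.
DEFAULT_N_PARTITIONS = 26_000
DEFAULT_PARTITION_VOL = 0.00034  # µl


@dataclass(frozen=True)
class SimulationParams:
    """Population-simulation settings.

    ``alpha``/``beta``/``gamma`` are per-gamete probabilities of a double
    reduction event, a partially unreduced gamete (one extra copy completing
    a same-type pair), and a ±1-chromosome aneuploid gamete.  The defaults
    of 0 reproduce the exact engines.  ``viability_weights`` maps genotype
    strings to relative survival weights (unlisted genotypes weigh 1).
    """

    model: PairingModel = PairingModel(mode="polysomic")
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    viability_weights: Mapping[str, float] = field(default_factory=dict)
    n: int = 549
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(w < 0 for w in self.viability_weights.values()):
            raise ValueError("viability weights must be >= 0")
        if self.n < 1:
            raise ValueError("population size must be >= 1")


def _sample_from(dist: ProbabilityMap, rng: np.random.Generator) -> HomoeologGenotype:
    keys = sorted(dist, key=str)
    probs = np.array([float(dist[k]) for k in keys])
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


_GAMETE_CACHE: dict = {}


def _gamete_dists(parent: HomoeologGenotype, model: PairingModel):
    key = (parent, model.univalent_transmission)
    if key not in _GAMETE_CACHE:
        _GAMETE_CACHE[key] = (
            disomic_gametes(parent, model.univalent_transmission),
            polysomic_gametes(parent, model.univalent_transmission),
        )
    return _GAMETE_CACHE[key]


def _letters_to_genotype(letters: list[str]) -> HomoeologGenotype:
    c = Counter(letters)
    return HomoeologGenotype(c["A"], c["B"], c["C"], c["X"])


def simulate_gamete(
    parent: HomoeologGenotype | str,
    params: SimulationParams,
    rng: np.random.Generator,
    disomic_mode: bool | None = None,
) -> HomoeologGenotype:
    """Draw one gamete, with optional meiotic aberrations.

    ``disomic_mode`` fixes the pairing regime (used by individual-level
    coupling); ``None`` draws it per gamete with probability ``f_di``.
    Aberration order: double reduction re-types one transmitted slot as a
    sister-chromatid duplicate of another transmitted chromosome; an
    unreduced event appends one extra copy of a type already in the gamete;
    an aneuploid event adds or removes (equal odds) one chromosome, the
    addition sampled by parental type frequencies.
    """
    parent = parse_genotype(parent) if isinstance(parent, str) else parent
    model = params.model
    di, po = _gamete_dists(parent, model)
    if disomic_mode is None:
        disomic_mode = rng.random() < float(model.effective_f_di)
    g = _sample_from(di if disomic_mode else po, rng)
    letters = list(g)
    if params.alpha > 0 and len(letters) >= 2 and rng.random() < params.alpha:
        i, j = rng.choice(len(letters), size=2, replace=False)
        letters[int(i)] = letters[int(j)]  # IDR pair of letters[j]'s type
    if params.beta > 0 and letters and rng.random() < params.beta:
        letters.append(letters[int(rng.integers(len(letters)))])
    if params.gamma > 0 and rng.random() < params.gamma:
        if rng.random() < 0.5 and len(letters) >= 2:
            letters.pop(int(rng.integers(len(letters))))
        else:
            par_letters = list(parent)
            letters.append(par_letters[int(rng.integers(len(par_letters)))])
    return _letters_to_genotype(letters)


def simulate_population(
    mother: HomoeologGenotype | str,
    father: HomoeologGenotype | str | None,
    params: SimulationParams,
) -> list[HomoeologGenotype]:
    """Simulate ``params.n`` surviving offspring of a cross or selfing.

    Individual-level coupling draws the pairing regime once per offspring
    (both gametes share it); gamete-level coupling draws it per gamete.
    Viability selection is rejection sampling on the genotype weights, so
    the output size is exactly ``n``.
    """
    mother = parse_genotype(mother) if isinstance(mother, str) else mother
    father = mother if father is None else (
        parse_genotype(father) if isinstance(father, str) else father
    )
    rng = np.random.default_rng(params.seed)
    weights = {k: float(v) for k, v in params.viability_weights.items()}
    # unlisted genotypes weigh 1, so the sampling cap is at least 1
    w_max = max(max(weights.values(), default=1.0), 1.0)
    out: list[HomoeologGenotype] = []
    attempts = 0
    max_attempts = 1000 * params.n + 1000
    individual = params.model.coupling == "individual"
    while len(out) < params.n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "viability rejection sampling failed; are all weights zero?"
            )
        mode = rng.random() < float(params.model.effective_f_di) if individual else None
        for _retry in range(20):
            g1 = simulate_gamete(mother, params, rng, disomic_mode=mode)
            g2 = simulate_gamete(father, params, rng, disomic_mode=mode)
            if g1.total + g2.total <= MAX_PLOIDY:
                break
        child = combine(g1, g2)
        w = weights.get(str(child), 1.0)
        if w <= 0:
            continue
        if rng.random() < w / w_max:
            out.append(child)
    return out


def simulate_dqpcr(
    genotype: HomoeologGenotype | str,
    dna_conc: float,
    per_copy_slope_true: float = 0.35,
    composite_A: bool = False,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    partition_vol: float = DEFAULT_PARTITION_VOL,
    rng: np.random.Generator | None = None,
    locus_id: str = "",
    sample_id: str = "",
) -> DqPCRMeasurement:
    """Emulate one multiplex dqPCR reaction for a known genotype.

    True concentrations are ``copies × slope × dna_conc`` per probe: the
    control probe sees every copy including X, the composite AB probe sees
    A + B.  With ``rng`` given, positives per probe are drawn
    ``Binomial(N, 1 − exp(−λ v))`` and converted back through the Poisson
    correction; ``rng=None`` gives the noiseless expectation (exact
    round-trip).
    """
    genotype = parse_genotype(genotype) if isinstance(genotype, str) else genotype
    s = per_copy_slope_true
    a, b, c, x = genotype.counts
    eff_a = a + b if composite_A else a
    concs = {
        "A": eff_a * s * dna_conc,
        "B": b * s * dna_conc,
        "C": c * s * dna_conc,
        "ctrl": genotype.total * s * dna_conc,
    }
    if rng is None:
        return DqPCRMeasurement(
            locus_id=locus_id, sample_id=sample_id,
            conc_A=concs["A"], conc_B=concs["B"], conc_C=concs["C"],
            conc_ctrl=concs["ctrl"], dna_conc=dna_conc, composite_A=composite_A,
        )
    pos = {}
    for k, conc in concs.items():
        p_pos = 1.0 - np.exp(-conc * partition_vol)
        if p_pos > 0.99:
            raise SaturationError(
                f"expected occupancy {p_pos:.3f} for probe {k}; dilute the sample"
            )
        pos[k] = int(rng.binomial(n_partitions, p_pos))
        if pos[k] == n_partitions:
            raise SaturationError(f"probe {k} saturated; dilute the sample")
    meas = {
        k: -np.log1p(-pos[k] / n_partitions) / partition_vol for k in concs
    }
    return DqPCRMeasurement(
        locus_id=locus_id, sample_id=sample_id,
        conc_A=meas["A"], conc_B=meas["B"], conc_C=meas["C"],
        conc_ctrl=meas["ctrl"], dna_conc=dna_conc, composite_A=composite_A,
        partitions=PartitionCounts(
            pos["A"], pos["B"], pos["C"], pos["ctrl"], n_partitions, partition_vol
        ),
    )


def make_fixture_dataset(seed: int, out_dir) -> dict:
    """Write a small end-to-end fixture: panel.json, plate.csv, truth.tsv.

    Four loci with the parental genotypes and locus-wise disomic fractions
    of the sweetpotato F2 study design (selfing of a hexaploid F1), 60
    offspring lines plus the parent itself, dqPCR measurements at default
    partition noise.  Byte-identical across runs with the same seed.
    """
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    loci = [
        ("G409HUSZ", "AABBCC", 0.1452, True),
        ("Ibit03014", "AABBBC", 0.0, False),
        ("Ibit11182", "ABBBBCC", 0.0272, False),
        ("Ibit12692", "AAABBBC", 0.3692, False),
    ]
    n_lines = 60
    panel = {
        "defaults": {"p_min": 0.80, "slope_tol": 0.06, "t_max": 12, "n_eff": 1000},
        "loci": [
            {"locus_id": lid, "composite_A": comp} for lid, _, _, comp in loci
        ],
    }
    (out_dir / "panel.json").write_text(json.dumps(panel, indent=1) + "\n")
    rng_master = np.random.default_rng(seed)
    plate_rows = ["sample_id,locus_id,conc_A,conc_B,conc_C,conc_ctrl,dna_conc,"
                  "pos_A,pos_B,pos_C,pos_ctrl,n_partitions,partition_vol"]
    truth_rows = ["line_id\tlocus_id\tgenotype"]
    for lid, parent_s, f_di, comp in loci:
        params = SimulationParams(
            model=PairingModel(mode="mixed", f_di=f_di, coupling="individual"),
            n=n_lines,
            seed=int(rng_master.integers(2**31 - 1)),
        )
        pop = simulate_population(parent_s, None, params)
        rng = np.random.default_rng(int(rng_master.integers(2**31 - 1)))
        samples = [("P1", parse_genotype(parent_s))] + [
            (f"F2_{i:03d}", g) for i, g in enumerate(pop, 1)
        ]
        for sid, g in samples:
            # dilution-tuned loads: high enough partition occupancy that a
            # one-copy slope difference stands clear of counting noise
            dna = float(rng.uniform(250, 400))
            m = simulate_dqpcr(
                g, dna, composite_A=comp, rng=rng, locus_id=lid, sample_id=sid
            )
            p = m.partitions
            plate_rows.append(
                f"{sid},{lid},{m.conc_A:.6g},{m.conc_B:.6g},{m.conc_C:.6g},"
                f"{m.conc_ctrl:.6g},{dna:.6g},{p.pos_A},{p.pos_B},{p.pos_C},"
                f"{p.pos_ctrl},{p.n_partitions},{p.partition_vol:g}"
            )
            truth_rows.append(f"{sid}\t{lid}\t{g}")
    (out_dir / "plate.csv").write_text("\n".join(plate_rows) + "\n")
    (out_dir / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    return {
        "panel": out_dir / "panel.json",
        "plate": out_dir / "plate.csv",
        "truth": out_dir / "truth.tsv",
    }
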