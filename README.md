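# hexaseg

Homoeolog-type segregation analysis for segmental allopolyploids:
exact bivalent pairing models, digital-PCR dosage genotype calling, and
estimation of the disomic-inheritance frequency — built around the kind of
single-locus dosage data produced for hexaploid sweetpotato
(*Ipomoea batatas*, 2n = 6x = 90).

## The problem

At a single-copy locus of an allohexaploid, the six gene copies fall into
three subgenome-diagnostic sequence classes — *homoeolog-types* A, B and C.
A genotype is the multiset of copies, written `AABBBC`, `ABBBBCC`, …; its
length is the locus's *apparent ploidy* (aneuploid/dysploid lines deviate
from six).  How such genotypes segregate tells you how the genome pairs at
meiosis:

* **disomic inheritance** — strictly preferential pairing (AA, BB, CC
  bivalents): gametes have fixed subgenome composition;
* **polysomic inheritance** — complete random pairing of all copies under
  bivalent configuration: gametes are hypergeometric sub-multisets;
* **mixed (segmental) inheritance** — a fraction `f_di` of meioses behaves
  disomically, the rest polysomically, varying by locus.

`hexaseg` computes the exact gamete and offspring genotype distributions
under all three regimes (with univalent handling for odd-ploidy parents),
calls genotypes — including probe-silent "X" copies and aneuploid totals —
from multiplex digital quantitative PCR (dqPCR) concentrations, and
estimates the disomic fraction from an offspring table via

```
F_Di = (F_Ods − F_Epl) / (1 − F_Epl)
```

where `F_Ods` is the observed total frequency of the *full dual-sourced*
offspring classes (those reachable with both gametes from preferential
pairing) and `F_Epl` their expected total frequency under pure polysomic
inheritance.  A seeded simulator generates populations (with optional
double reduction, partially unreduced gametes, aneuploidy and viability
selection) and dqPCR plates with binomial partition noise, so the whole
pipeline is testable end to end without any external data.

## Worked example

```python
from hexaseg import DISOMIC, POLYSOMIC, offspring_distribution

off_d = offspring_distribution("AAABCC", "ABBBCC", DISOMIC)
off_p = offspring_distribution("AAABCC", "ABBBCC", POLYSOMIC)
print(float(off_d.p("AAABCC")))   # 0.25
print(float(off_p.p("AAABCC")))   # 0.105
```

The maternal class `AAABCC` is expected in 25% of F1 offspring under pure
preferential pairing but only 10.5% under random pairing — so its observed
frequency in a cross measures the locus's share of disomic behaviour.
Estimating that share from a simulated selfing population:

```python
from hexaseg import PairingModel, SimulationParams, segregation_report, simulate_population

params = SimulationParams(
    model=PairingModel(mode="mixed", f_di=0.15, coupling="individual"),
    n=549, seed=42,
)
pop = simulate_population("AABBCC", None, params)
rep = segregation_report(pop, "AABBCC", seed=7)
print(round(rep.F_Ods, 4), round(rep.F_Epl, 4), round(rep.F_Di, 4))
# 0.3661 0.22 0.1873   (truth 0.15, binomial error at n = 549)
```

The `examples/` directory has one short narrative script per capability:
exact expectations, dqPCR calling (including the null-signaled-X slope
logic and cross-locus joint calling), disomic-fraction estimation, and the
full simulate → measure → call → estimate pipeline.

A thin CLI wraps the same functions:

```bash
hexaseg expect --mother AABBCC --father AABBCC --model polysomic
hexaseg simulate --mother AABBBC --fdi 0.15 --n 549 --seed 7 --out f2.tsv
hexaseg fdi --table f2.tsv --mother AABBBC --self
hexaseg call --panel panel.json --in plate.csv --out calls.tsv
```

## File formats

* plate CSV: `sample_id, locus_id, conc_A, conc_B, conc_C, conc_ctrl,
  dna_conc` (+ optional `pos_A, pos_B, pos_C, pos_ctrl, n_partitions,
  partition_vol` raw partition counts); `conc_A` carries the composite AB
  signal at loci flagged `composite_A` in the panel JSON.
* genotype tables: TSV/CSV with `line_id, locus_id, genotype`.
* panel JSON: per-locus calling settings (`p_min`, `slope_tol`, `t_max`,
  `n_eff`, `composite_A`) with global defaults.

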