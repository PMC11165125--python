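# Methods

## Genotype representation

A locus genotype is a multiset over four copy classes: the three
subgenome-diagnostic homoeolog-types A, B, C, and X for copies detected by
the nondiscriminatory control probe but null to all three discriminatory
probes (an X is a mutated A, B or C; which one cannot be known without
sequencing, so X is kept opaque and treated as a fourth type label by every
engine).  The canonical text form is the sorted letter string; apparent
ploidy is the total copy count.  Totals are capped at 12: observed apparent
ploidies in hexaploid sweetpotato panels reach 11, and 12 bounds all
enumerations while leaving headroom.  The cap is configurable per locus
(`t_max`).

## Exact pairing models

All engines assume strictly bivalent meiotic configuration and no double
reduction; probabilities are exact `fractions.Fraction` values, converted
to float only at reporting.

**Polysomic (random pairing).**  A uniform random perfect matching of the
2n copies into bivalents, each bivalent transmitting one member
independently with probability 1/2, induces a uniform n-subset of the
copies — i.e. multivariate-hypergeometric gamete counts.  The closed form
is implemented that way and verified *exactly* (Fraction equality) against
an independent brute-force oracle (`matching_enumeration_gametes`, all
matchings × all segregation patterns over labeled chromosomes) for every
type composition with up to 8 copies.

**Disomic (preferential pairing).**  Each type forms `floor(count/2)`
same-type bivalents; each transmits one copy of its type deterministically.
The ≤ 1 leftover copy per type pairs allosyndetically: leftovers are
matched uniformly at random, each leftover bivalent transmits either member
with probability 1/2.  This "maximal same-type pairing, random leftovers"
rule reproduces the printed 25% F1 expectation and the 19 dual-sourced
selfing classes of a 3:3:1 parent, which is why it was chosen over
alternatives (e.g. deterministic leftover assignment).

**Odd ploidy.**  A 2n+1-copy parent leaves exactly one univalent (uniform
over copies under random pairing; uniform over leftover types under
preferential pairing), transmitted with probability
`univalent_transmission` (default 1/2, configurable — the default makes the
polysomic gamete uniform over all n- and (n+1)-subsets and reproduces the
1:2:1 disomic selfing ratio of a 7-ploid parent).

**Mixed inheritance.**  `f_di` of meioses follow the disomic regime.  With
`coupling="individual"` (default) both gametes of an offspring share the
regime — `f·(D⊗D) + (1−f)·(P⊗P)` — which is the premise under which the
F_Di estimator algebra is exact.  `coupling="gamete"` mixes per gamete
(`M⊗M`) for simulation studies.

**Offspring classification.**  Each offspring genotype of a cross is
assigned the most parsimonious mechanism, in priority order: full
dual-sourced (reachable with both gametes from preferential pairing) >
partial dual-sourced (exactly one such gamete) > polysomic-only >
IDR-indicative (balanced gamete sizes but some gamete needs more copies of
a type than the parent holds — an identical-by-double-reduction pair) >
IDR-or-unreduced (explainable only with an IDR pair or a partially
unreduced gamete, one extra copy completing a same-type pair) >
aneuploid/dysploid (no legal gamete-size decomposition).  A double
reduction event is modelled as allowing one type to exceed its parental
count by exactly one, with at least two copies in the gamete.

## F_Di estimator

For a selfing or cross with known parents, let D be the set of full
dual-sourced classes, `F_Ods` their observed total frequency and `F_Epl`
their total probability under pure polysomic inheritance.  A fully disomic
individual lands in D with probability 1, a polysomic one with probability
`F_Epl`, so `F_Ods = F_Di + (1 − F_Di)·F_Epl`, giving
`F_Di = (F_Ods − F_Epl)/(1 − F_Epl)`, clamped to [0, 1] (sampling noise can
push the raw value slightly negative).  Partial dual-sourced classes are
excluded from D, making the estimate conservative.  The denominator of
`F_Ods` is all genotyped lines including aneuploid classes by default (the
population size as genotyped); `euploid_only=True` restricts it to
balanced totals.  Parameter recovery on simulated selfings of a 1:1:1
hexaploid parent (n = 549, individual coupling, truths 0, 0.15, 0.37, 200
seeds) shows mean absolute bias ≤ 0.02; at truth 0 the clamping induces a
small positive bias (≈ 0.01) of the same origin as the printed 0% estimates.

## Goodness of fit

Pearson chi-square (df = classes − 1) when every expected count is ≥ 5;
otherwise a Monte-Carlo exact multinomial test: the p-value is the
proportion of simulated tables (default 100,000, seeded) whose multinomial
probability is at most the observed table's, with add-one smoothing so the
smallest attainable p is 1/(n_mc + 1).  Per-class z-tests
`z = (obs/n − p)/sqrt(p(1−p)/n)` are two-sided, without continuity
correction, and reported unadjusted for multiplicity.  The segregation
report tests observed tables against the polysomic expectation restricted
to its support; classes outside it (aneuploid, IDR) stay in the per-class
listing and in the F_Ods denominator but are pooled out of the GOF vector.

## dqPCR calling

Concentrations follow the standard digital-PCR Poisson correction
`c = −ln(1 − k/N)/v` for k positive of N partitions of volume v.  The
per-genome single-copy slope of a probe set is
`S = concentration/(copies × DNA concentration)`; on one DNA dilution all
probes and loci must share one slope, which anchors the caller:

1. **Ratio fitting.**  All coprime integer triples with total ≤ `t_max`
   are scored by chi-square GOF.  Concentrations are not counts, so the
   default converts observed proportions to pseudo-counts (`n_eff = 1000`,
   configurable); when raw partition counts are available, a calibrated
   binomial-occupancy chi-square is used instead (expected occupancy
   `1 − exp(−p_i·C·v)` with the total concentration estimated from the
   counts, df = probes − 1).  At composite loci the AB probe detects A and
   B alike, so candidate ratios are compared in probe space
   (`a + b : b : c`); the A-specific concentration AB − B (clamped at 0,
   flagged `composite_negative` if materially negative) is used for slopes.
   Ranking is parsimony first: candidates reaching `p_min` (default 0.80)
   by smallest total then best p; then candidates not rejected at the 0.05
   floor; a best-fitting rejected candidate is still reported, flagged
   `low_confidence`.  The floor keeps a large-total ratio from winning by
   merely fitting noise.
2. **Scale and X resolution.**  For each candidate ratio and integer scale
   k, `S_ABC` at `k × total` copies is compared with the control slope at
   every total 1..`t_max`; the nearest total is accepted if the discrepancy
   is ≤ `slope_tol` (default 0.06, about one copy's slope share at S ≈ 0.35
   and six copies; a relative alternative would be S/(2t)).  An accepted
   total above the discriminated copies yields X copies; one *below* flags
   `control_null` (spontaneously mutated control target).  Among consistent
   (ratio, scale) pairs the smallest total wins, best fit on ties.
3. **Cross-locus consensus.**  A single reaction cannot fix the absolute
   scale of gcd-reducible signals (1:1:1 may be ABC or AABBCC; 2:1 may be
   BBC or BBBBCC).  `joint_call_sample` collects each locus's
   control-consistent candidate slopes, takes the consensus value covering
   the most loci within tolerance (largest slope on ties — an all-loci
   scale ambiguity is unresolvable in principle and the smaller genotypes
   are preferred), and re-calls every locus against it, choosing the
   consistent candidate nearest the consensus slope.  Equal-proportion
   single-locus calls keep an `ambiguous_scale` flag instead of being
   forced.  `call_genotype` also accepts a known assay slope directly via
   `reference_slope`.

Flagged calls are exported but should be excluded from downstream
segregation statistics (the wet-lab analogue is confirmation by repeated
reactions).

## Simulator

`simulate_population` draws gametes from the exact engines (pairing regime
per individual or per gamete according to the coupling), then applies
optional aberrations per gamete: double reduction (rate `alpha`) re-types
one transmitted slot as a sister-chromatid duplicate of another transmitted
chromosome, producing IDR pairs; a partially unreduced event (`beta`)
appends one extra copy of a type already present; an aneuploid event
(`gamma`) adds or removes one chromosome with equal odds, additions sampled
by parental type frequency.  These mechanisms are minimal generative
stand-ins — the rates are not estimated anywhere and default to 0, and the
exact expectation engines never include them.  Viability selection is
rejection sampling on per-genotype weights, so output size is exactly n.
With all rates at 0, empirical gamete frequencies converge to the exact
distributions (total-variation distance < 0.02 at 20,000 draws in the
tests) and homoeolog-type totals are conserved in expectation.

`simulate_dqpcr` sets each probe's true concentration to
`copies × slope × DNA concentration` (control sees all copies including X;
composite AB sees A + B) and draws positives `Binomial(N, 1 − exp(−λv))`
per probe on a 26,000-partition, 0.34 nl geometry; `rng=None` returns the
noiseless expectation.  The fixture generator writes a 4-locus, 60-line
selfing panel with the locus-wise disomic fractions and parental genotypes
of the sweetpotato F2 design, at dilution-tuned DNA loads (250–400 pg/µl)
high enough that a one-copy slope difference stands clear of counting
noise — with those loads, single-call accuracy on hexaploid genotypes
exceeds 99% and plate-to-truth concordance exceeds 98%.

## What the synthetic data do and do not show

The simulator reproduces the statistical structure the analysis assumes:
exact pairing-regime mixtures, partition-level counting noise, rare
aberration classes, seeded determinism.  It does not emulate fluorescence
thresholding or chip-loading artifacts, probe cross-hybridization,
template-quality effects on slopes, segregation distortion beyond simple
viability weights, or linkage between loci.  Passing tests therefore
validate the algebra and the calling/estimation logic under the stated
noise model, not instrument-specific behaviour on real chips.

## Numerical and design choices

* Exact rational arithmetic in all distribution engines; normalization is
  asserted to 1e−12 at construction (and holds exactly).
* Enumeration oracle budget: parents ≤ 10 copies (double factorial growth).
* Deterministic ordering everywhere (canonical genotype strings as keys,
  sorted outputs, explicit tie-breaks), so identical seeds give
  byte-identical files.
* The scale of a genotype whose signal ratio is gcd-reducible is
  unidentifiable from one reaction; tests of exact single-call round trips
  supply the assay slope, and a separate test exercises consensus
  resolution across loci.
* `n_eff` is an explicit stand-in for an unstated counting basis in the
  chi-square on concentration proportions; raw partition counts, when
  present, replace it with a properly calibrated statistic.
* Report problem sizes: recovery studies use n = 549 populations and 200
  seeds; empirical-vs-exact comparisons use 20,000 gamete draws.

## Known limitations

* No multivalent pairing models, recombination within bivalents, or
  chromosome-scale linkage; each locus is analysed independently.
* The double-reduction and unreduced-gamete mechanisms are simulation-only
  stand-ins; expectations for those classes are qualitative
  (classification), not quantitative.
* F_Di assumes fully disomic vs fully polysomic individuals
  (individual-level coupling); gamete-level mixing would bias it downward.
* The caller's composite-negative threshold (5% of the B signal) is a
  pragmatic noise allowance, not a calibrated test.
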