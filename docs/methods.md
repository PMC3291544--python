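# Methods

This note documents the models, conventions and parameter choices behind
`mlpagcr`, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user should know before trusting results
on their own data.

## Genome model and target catalog

Coordinates are 1-based inclusive.  Each chromosome carries a centromere
strictly inside it and optional terminal telomere intervals; the two
arms are the intervals flanking the centromere.  Repeat elements are
classified TY1, TY2 or SOLO_DELTA and carry a transcriptional
orientation relative to their arm's telomere.  The GFF3 strand
convention is: on a right arm `+` means telomere-oriented, on a left arm
`-` means telomere-oriented (transcription toward the nearer telomere).
Orientation matters biologically: a translocation into a
telomere-oriented element yields a stable monocentric product, while a
centromere-oriented target yields a dicentric intermediate that must
rearrange further.

The catalog of potential translocation targets counts every Ty1 and solo
delta once and every Ty2 twice — once per terminal LTR, since the LTRs
carry the bulk of Ty1/Ty2 homology.  The two Ty2 sub-targets are placed
on the first and last 334 bp of the element interval (the canonical
delta length); only their count, not their exact position, affects any
downstream statistic.  The per-arm null probabilities used by the
goodness-of-fit machinery are simple target-count fractions: p(arm) =
targets(arm)/total, i.e. the hypothesis that every catalog target
recombines with the assay's seed element at equal frequency.

## Probe design

The package carries no nucleotide sequence, so "unique hybridizable
sequence" is abstracted to a minimum element-free window
(`min_unique_window`, default 300 bp).  Design rules:

* **Telomeric panel** — one probe per arm, mid-window between the most
  distal element and the telomere.  If that window is below the minimum,
  the probe is placed immediately centromeric to the terminal element
  and flagged `FALLBACK_CENTROMERIC`; such a probe cannot report
  duplications mediated by the element(s) it skipped, which is exactly
  why panel coverage is below 100% on genomes with telomere-abutting
  elements.
* **Centromeric panel** — one probe per arm, centromeric to the arm's
  innermost element.  Combined with the telomeric panel it defines
  whole-chromosome duplications (every probed locus ≥ 2 copies).
* **Arm-specific ladders** — one probe per inter-element gap, including
  the centromere-side and telomere-side gaps.  Elements closer together
  than `collocated_gap` (default 1 kb) form a block sharing flanking
  probes, so tandem/clustered Ty loci are localized as a unit.  Gaps
  wider than `long_gap` (default 120 kb) receive a second probe; a
  breakpoint falling between the pair then localizes to an element-free
  interval and is reported with an `UNKNOWN` target rather than being
  attributed to the nearest annotated element.  This mirrors real
  screens, where occasional duplications start at unannotated partial
  repeats.

Product lengths form a deterministic arithmetic ladder (default start
100 bp, step = the 2 bp minimum separability of capillary
electrophoresis), ordered by chromosome, arm (L before R) and position.
Any deterministic assignment respecting the minimum gap would do; the
ladder makes probe identity recoverable from length alone.

Theoretical coverage of the telomeric panel counts a target as covered
iff its arm's probe lies strictly telomeric to it, so the duplication
(target → telomere) necessarily spans the probe.

## Copy-number calling

Two within-sample normalizations are implemented.  `GLOBAL_SUM` divides
each probe's area by the sample's total probe area and is
scale-invariant; it is the default for genome-wide panels, where a
single arm duplication perturbs the denominator by only ~1/32 — a
deliberate, uncorrected bias (no renormalization is applied).  `ANCHOR`
divides by the most centromeric probe's area and is used for
arm-specific ladders, where up to the whole arm may be duplicated and
the anchor is assumed single-copy; if the anchor itself is duplicated
every ratio is systematically halved and the calls are garbage — the
assumption is the user's responsibility and is the reason the ladder
keeps a probe hard against the centromere.

Normalized values are divided by the mean of the control samples'
values, probe by probe, and rounded to the nearest integer (ties round
half away from zero; a x.5 ratio is flagged anyway).  A cell whose
ratio deviates more than `tolerance` (default 0.3) from every integer is
flagged `AMBIGUOUS`; a probe without a matching peak (nearest product
length beyond ±1 bp) is `MISSING`.  The 0.3 default is an
operationalization choice: it cleanly separates copy 1 (ratio ≈ 1) from
copy 2 (ratio ≈ 2) at realistic noise while catching mixed-population
signals near 1.5.

## Event classification

Classification is a pure function of the copy-number matrix and the
annotation.  The assay's selected deletion is a telomeric call of 0 on
chrV-L (configurable).  A whole-chromosome duplication requires call ≥ 2
at every probed OK locus of a chromosome with at least two probed loci;
its arms are then not double-counted as arm duplications.  An arm
duplication is a telomeric call ≥ 2 elsewhere.  Cells flagged
`AMBIGUOUS` contribute no event evidence and make the whole isolate
`AMBIGUOUS`; summaries count such isolates separately and exclude them
from event tallies.  Duplications reported by a fallback telomeric probe
carry a caveat flag, since the skipped terminal element is unprobed.

Breakpoint localization scans the arm ladder centromere → telomere for
the first call ≥ 2; candidate targets are the annotated elements
strictly between that probe and its single-copy centromeric neighbour.
Target orientations determine the predicted product geometry
(monocentric / dicentric-intermediate / mixed).  Non-monotone ladders
(e.g. 1,2,1,2) are flagged `COMPLEX` — the signature of a rearranged
dicentric — but are still tabulated under their most centromeric step.

## Rate statistics

Per-culture rate values are taken as given; the default transform from
fluctuation counts is mutant frequency (count/population), with a
per-culture Lea–Coulson method-of-the-median transform available.  The
median's 95% CI is the narrowest symmetric order-statistic pair with
Binomial(n, ½) coverage ≥ 95%; for small n no pair reaches 95% and the
full range is reported with its actual coverage (93.75% at n = 5).

Fold changes over a reference are rounded to 2 significant figures and
snapped to the nearest integer when within 2% of it; this reproduces the
integer folds a screening table prints while keeping sub-unity folds
informative.

The observed/expected arm-rate comparison scales each control arm rate
by S = Σ(test arm rates)/Σ(control arm rates) — the bulk factor
restricted to duplication-bearing GCRs, which is the point: a strain
with many deletion-only events (e.g. recombination-deficient mutants)
is not penalized for them.  Zero-count conventions: a control arm with
no observed duplication contributes its upper-limit rate (total rate /
number of duplications analyzed, the rate a single hypothetical event
would imply) before scaling; a test arm with no duplication uses its own
upper limit when that is below the expectation, otherwise the ratio is
set to 1; both-zero arms are ratio 1.  "Number of duplications" means
duplication-bearing GCRs in that strain — the upper limit is then the
rate a single hypothetical event would imply — though the denominator is
an explicit argument for users who prefer total GCRs analyzed.
Significance flags compare each observed arm rate
against the control arm rate scaled by the test strain's bulk-rate CI
divided by the control rate; this CI-transfer construction is a
documented convention, not an exact test, and is reported as a flag
rather than a p-value.

The Monte-Carlo multinomial test uses Pearson χ² by default (a
log-likelihood-ratio option exists) and reports the add-one empirical
p-value (k+1)/(R+1), whose smallest attainable value at R = 2000 is
5.00×10⁻⁴ and which is conservative (superuniform) by construction.
All remaining tests (exact binomial tail, two-sided Fisher, paired
exact binomial min(1, 2·P(X ≤ min(b,c))), hypergeometric upper tail,
Wilcoxon rank-sum exact for small untied samples) delegate to scipy and
are cross-checked in the test suite against independent enumeration
oracles.

## Synthetic data

The fixture genome is a 16-chromosome S288C-like karyotype whose
element complement is constrained to the study's aggregate landscape:
32 Ty1, 13 Ty2 and 196 solo deltas, i.e. exactly 254 catalog targets,
with four arms (chrII-L, chrIV-R, chrIX-R, chrXV-L) whose terminal
element abuts the telomere and therefore forces fallback probes.  The
four hotspot arms carry named element clusters at fixed positions — a
tandem delta triplet and a separate delta on chrIII-R (the FS1/FS2
fragile-site pattern), two clusters plus singletons on chrV-R, a
dominant Ty2 on chrXIV-L and a tandem Ty1 pair on chrX-R — and are
excluded from random element placement so their probe ladders and
breakpoint targets are reproducible.  All remaining elements are placed
by a seeded RNG (length-weighted arm choice, ≥ 2 kb separation, ≥ 3 kb
from chromosome ends).  Per-arm counts away from the hotspot arms are
thus synthetic: the generator matches published totals, not the real
genome's per-arm distribution, so goodness-of-fit p-values against the
fixture catalog quantify the method, not the organism.

The reference wild-type cohort encodes the study's event counts exactly
(112 isolates: 17+11 chrIII-R, 27 chrV-R including two
unannotated-target events, 8 chrXIV-L, 10 chrX-R, 33 spread over other
arms, 5 deletion-only, 1 ambiguous); the recombination-deficient
reference cohort is 50 isolates with 34 (68%) deletion-only.  The
stochastic cohort generator draws per-isolate events from a target
probability model whose wild-type defaults are the maximum-likelihood
hotspot fractions of that cohort.  Ambiguous isolates are modelled as a
half-strength (copy 1.5) duplication signal — a mixed population — which
the caller flags at the default tolerance.

Peak noise is multiplicative: area = base × sample-scale ×
probe-efficiency × CN × exp(ε), with lognormal per-probe efficiencies
(σ = 0.2) shared across a run, lognormal per-sample loading scales
(σ = 0.3), measurement CV 0.05 and a small constant background area at
copy 0.  These defaults represent a clean capillary run; the suite
verifies ≥ 99% call accuracy at CV 0.05 and that accuracy degrades
monotonically with CV.  Not emulated: fragment-sizing error, peak
overlap/stutter, dye pull-up, inter-run control drift and
partial-population mosaicism beyond the single ambiguous class — so
passing tests demonstrate correctness of the analysis given
well-behaved peaks, not robustness to instrument pathology.

Fluctuation counts follow a Luria–Delbrück scheme with deterministic
doubling from one founder: each generation's newly born cells mutate
with the per-division rate (Poisson), and a mutant born at generation g
contributes 2^(G−g) descendants.  This reproduces jackpot skew
(mean ≫ median).  Calibration (CI covers the true rate in ≥ 90% of
repetitions) is verified at the study regime of 49 cultures, rate 10⁻⁷,
final population 10⁷ — where the expected mutation number per culture is
~1 and the median mutant frequency is essentially unbiased.  At much
larger expected mutation numbers the frequency transform acquires the
classic upward bias and the Lea–Coulson transform is the better choice.

## Problem sizes and determinism

Every generator takes an explicit seed and is bit-reproducible; no
global RNG state is used.  The shipped calibration experiments use a
200-isolate cohort for call accuracy, 200 fluctuation repetitions of 49
cultures for CI coverage, and 2000 null cohorts × 199 Monte-Carlo
replicates for type-I error (p-granularity 0.005 suffices to score
α = 0.05); the whole acceptance computation runs in seconds.

## Known limitations

* Breakpoints are localized to inter-probe intervals; junction sequences
  and the rearrangement paths of dicentric intermediates are out of
  scope.
* Copy numbers above ~3 are called but the ambiguity tolerance was
  chosen for the 0/1/2 regime that dominates these screens.
* The GLOBAL_SUM depression of non-duplicated ratios grows with panel
  fraction duplicated; for whole-chromosome-heavy samples the calls rely
  on the 0.3 tolerance absorbing it.
* The fixture genome's non-hotspot per-arm target counts are synthetic
  (totals constrained, placement random), so arm-level expected
  distributions differ from the real reference genome's.
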