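# Methods

## The index

The Clinical Kinase Index treats target prioritization as evidence
aggregation: each gene collects one point per binary clinical signal
(tumor overexpression, adverse expression-stratified survival, residue-level
mutation clustering) and up to one point per clinical-staging parameter,
and the sum is normalized by the maximum attainable in that cohort. The
normalization is the load-bearing design choice: cohorts differ in which
evidence they can supply (number of normals, clinical coverage, mutation
data), and dividing by the attainable maximum keeps percentages comparable
across cohorts rather than penalizing genes for data their cohort lacks.
A component that cannot be evaluated cohort-wide is excluded from both the
numerator and the denominator; a component that evaluates to "no signal"
contributes 0 to the numerator only.

All evidence is directional. Overexpression must be positive (an
underexpressed gene is never credited, however significant), the
high-expression survival arm must be the worse arm, and a stage pair only
counts when expression is higher at the more advanced stage. The index is
therefore monotone: strengthening any one component can never lower a
gene's CKI (verified property-based in the test suite).

## Components

### Differential overexpression

Counts are normalized to log₂(CPM + 1); genes with CPM < 1 in more samples
than the smaller group's size are removed before testing. The group test is
Welch's two-sample t on log₂-CPM with Benjamini–Hochberg adjustment
(via statsmodels) across the tested genes; the flag requires log₂FC > 1 and
FDR < 0.01. The defaults follow the stricter of the two thresholds in
common use (0.01 vs 0.05); both are configurable (`dge.fdr_threshold`).
Cohorts with fewer than 3 tumor or 3 normal samples refuse the component
entirely rather than testing underpowered groups.

A deliberate simplification: the test operates on log-CPM rather than on a
count model (negative-binomial GLM). At the effect sizes this index cares
about (log₂FC > 1 with dozens of samples per arm) the two agree; the test
function is the single seam to replace if a count-model engine is wanted.
Note that CPM is compositional: if a large fraction of the panel is
genuinely overexpressed, library-size normalization compresses all observed
fold changes (by ~log₂ of the library inflation). This is visible in the
simulation when planted fractions are high and is the main reason measured
log₂FC sits below the planted value.

### Survival

Per-patient records are (days_to_death, event) for the dead and
(days_to_last_follow_up, censored) for the living; patients with no vital
status or no positive time carry no usable information and are excluded
with a logged count. Patients are split at the 25th/75th percentiles of the
gene's tumor expression (linear-interpolation quantiles; boundary ties go
to the extreme arms; the middle half is excluded). The arms are compared by
the standard two-group log-rank statistic — (ΣO−E)²/ΣV against χ²₁ — on
Kaplan–Meier curves, with deaths processed before censorings at tied times.
The component fires only when p < α (default 0.05) *and* the high arm has
the smaller restricted mean survival, integrated to the shorter arm's
follow-up horizon. RMST was chosen as the direction rule because it is
well-defined under heavy censoring where median survival may not exist.
Both primitives are implemented directly (they are the scoring core, a few
lines each) and are cross-checked exhaustively against lifelines in the
test suite on all small event/censor patterns.

Under the null, the one-directional gate halves the two-sided level: the
component fires for ≈ α/2 of genes, which the calibration checks verify.

### Mutation hotspots

Position-affecting mutations (missense, nonsense, insertion, deletion) are
binned by residue, counting once per (sample, residue) pair; silent/other
classes and records without a parseable position are excluded, and
positions beyond the protein length are dropped with a warning. Protein
lengths come from the annotation catalog, falling back to 1.1 × the maximum
observed position.

Seed residues are those whose count exceeds the binomial quantile expected
under uniform placement over the protein. The seed level `seed_q` (default
0.01) is applied **per gene**, i.e. the per-residue quantile is taken at
1 − seed_q/L: every one of the L residues is an implicit test, and without
this correction a chance two-hit residue would seed a cluster in roughly
L·P(X≥2) ≈ 5–10% of null genes with ~10 mutations, destroying calibration.
A single mutation never seeds regardless of the quantile. Seeds within
`max_gap` (default 5) residues merge; clusters extend through adjacent
residues mutated above the uniform rate. The gene's clustering score is the
fraction of its mutations inside clusters (in [0, 1]).

Significance is relative: each gene's score is z-scored against the
leave-one-out background of scores from genes with ≥ 3 mutations (≥ 20
mutated genes required overall), with a one-sided upper normal tail. When
the background is constant, a score above the common value is reported as
p = 0 (flagged degenerate), one equal to it as p = 0.5. The flag requires
p < α and ≥ 5 mutations. The normal tail is anti-conservative on the
zero-inflated score distribution — effectively, any detected cluster in a
sufficiently mutated gene is significant — so the calibration of the whole
component rests on the seeding step; a per-gene permutation oracle in the
test suite confirms ≥ 90% flag agreement. Equivalence with any published
clustering tool's output is explicitly not a goal.

### Clinical staging

Raw labels collapse by a case-insensitive prefix rule — leading letter plus
first digit (t1b1 → T1, n3a → N3, m1 → M1, g3 → 3); pathologic/clinical
stage labels by roman numeral (stage iib → 2); labels without a digit or
numeral (tx, nx) are missing. The rule is total and idempotent. A parameter
is available when ≥ 2 levels have ≥ 2 patients each.

For each available parameter, every ordered pair of usable levels (i < j)
is tested with two-sided Welch's t; a pair counts iff p < α and the mean at
the higher level is greater. The sub-score is counting/tested pairs, zero
when no pair counts — so one fully concordant parameter is worth exactly 1
and fractional credit (e.g. 0.25) arises naturally, which is what makes
non-integer raw CKI totals possible. Alternatives are configurable:
`clinical.rule: any` (1 if any pair counts) and
`clinical.pairs: consecutive` (adjacent levels only). No within-parameter
multiplicity correction is applied, matching the index's original usage.
The per-gene scorer is the reference; the pipeline uses an exactly
equivalent vectorized path (one Welch test per level pair across all genes)
that the tests check against the reference.

### Dependency benchmark

Dependency scores are dichotomized strictly below −1 (exactly −1 is not
dependent). Per cell line of the cohort's tissue, and once at tissue level
on per-gene mean dependency, the benchmark reports Kruskal–Wallis (CKI |
dependent vs not), tie-aware Spearman correlation, an OLS fit of CKI on
dependency, and ROC AUC with CKI as the score and dependent as the positive
class, computed by the rank (Mann–Whitney) formulation with ties counted
half; the returned curve integrates to the same value. Lines with a single
dependency class are skipped with a reason; genes missing from the matrix
are counted as unmatched.

## The synthetic cohort generator

`simulate_cohort` emulates the statistical structure the index assumes,
with every planted effect recorded in a truth manifest:

* **Counts**: NB(mean 100, dispersion 0.2) per gene/sample, library-size
  factors log-normal (σ = 0.3). Planted overexpression multiplies tumor
  means by 2^log₂FC (default 2).
* **Survival**: a latent high-risk stratum (25% of patients) carries
  hazard × hazard_ratio_high (default 3) in an exponential model (baseline
  rate 1/500 days ≈ 16-month median); independent exponential censoring is
  scaled to the target censoring fraction (default 0.3). Planted prognostic
  genes are overexpressed by 1.5 log₂ units in exactly the risk stratum, so
  each such gene's upper expression quartile is individually the bad arm —
  planting a shared latent stratum rather than per-gene hazards keeps the
  planted genes' effects separable and non-confounded.
* **Stages**: T/N/M/grade/stage levels drawn uniformly per patient with
  realistic substage suffixes; planted stage-trend genes gain
  stage_shift × (T−1) log₂ units (default 0.5/level). Only T carries the
  trend, deliberately: wiring risk or other parameters to stage would
  confound the survival and clinical components.
* **Mutations**: Poisson(10) per gene, placed uniformly over a protein of
  300–800 residues with a realistic class mix (10% silent); planted hotspot
  genes put ⌈0.6·n⌉ of their mutations (as missense) at one recorded
  residue.
* **Dependency**: Normal(0, 0.3) per gene × cell line; planted dependent
  genes Normal(−1.5, 0.3).
* **Annotations**: random TDL/kinase-group labels; genes planted as both
  overexpressed and prognostic are labeled cohort-specific MOA targets, so
  annotation-stratified summaries have a recoverable signal.

One seed sequence is split into named substreams (planting, library,
counts, survival, stages, mutations, dependency, annotations), so each
component is reproducible in isolation; `composite_fraction` plants all
five effects on one common gene set, and `planting_seed` lets two cohorts
with different noise share planted genes. Identical configs give
bit-identical bundles.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real cohorts: per-gene baseline expression
heterogeneity and gene–gene correlation, compositional/batch artifacts
beyond library size, informative censoring, stage–survival dependence,
mutational signatures and per-sample mutation burden variation, and
realistic cohort sizes. It is a correctness and calibration harness, not a
cohort emulator.

## Numerical choices and problem sizes

* CKI percentages are rounded at 1e-9 before ranking so exact rational
  ties (e.g. two genes both at 7/3 of 9) are not split by float-summation
  noise; ranks are competition ranks with lexicographic display order.
* Scorecard TSVs print components at 4 decimals, CKI at 2; dependency
  matrices round-trip bit-exactly (%.17g, round-trip parsing).
* Welch tests with zero variance in both groups yield p = 1 (no evidence),
  consistently in the scalar and vectorized paths.
* Top-quartile sets take ⌈n/4⌉ genes with boundary ties included.
* Calibration and recovery checks run at fixed sizes chosen to give stable
  Monte-Carlo estimates on a single CPU: null DGE at 2000 genes × 50/50,
  null survival/clinical at 1000 genes × 200 patients, null hotspots at
  500 genes, recovery at 100 genes (20 composite-planted) × 200 patients.
  Expected null rates: DGE ≈ 0 (BH at FDR 0.01 plus the fold-change gate),
  survival ≈ α/2, clinical sub-score mean ≈ α/2, hotspot ≈ seed_q.

## Known limitations

* CPM normalization compresses fold changes when a large fraction of the
  panel shifts in one direction (see above); TMM/median-of-ratios
  normalization is out of scope.
* The hotspot p-value is a cross-gene z heuristic, not an exact test; its
  false-positive control comes from the seeding step.
* Genes failing the expression filter receive no scorecard at all, so a
  mutation-only driver with silenced expression is invisible to the index.
* The survival component conditions on expression quartiles per gene
  without multiplicity correction across genes; the index reports evidence
  counts, not genome-wide error rates.
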