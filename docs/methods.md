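# Methods

`epimut` implements two linked analyses from transgenerational environmental
epigenetics: calling differential DNA methylation regions ("epimutations")
in sperm from comparative MeDIP-chip hybridizations, and classifying
adult-onset disease in rat cohorts against control-derived normal ranges,
with incidence statistics per lineage, generation and sex. Because raw
array and necropsy data for this study design are not publicly deposited,
the package ships a first-class synthetic-data generator whose outputs
carry ground truth, so every stage is validated by recovery and calibration
rather than by re-fitting archived data.

## The DMR-calling statistic

**Inputs.** N paired two-channel hybridizations (default N = 3) on a
promoter tiling array. Each comparison hybridizes a treatment MeDIP pool
(cy5 channel) against a control MeDIP pool (cy3); pools combine equal DNA
from three animals. The array design mirrors a rat promoter methylation
array: each promoter tiled from 3,880 bp upstream to 970 bp downstream of
the TSS (a 4,850 bp region, measured in transcription orientation) with
50–75-mer probes at 100 bp median spacing.

**MA transform.** Intensities are taken to log2 (the two-channel
convention; the intensity scale makes M additive in fold change):
M = log2 cy5 − log2 cy3, A = (log2 cy5 + log2 cy3)/2. The transform is a
rotation and exactly invertible; a round-trip reproduces intensities to
<1e-9 (tested).

**Normalization.** Default is per-comparison median-centering of M — the
minimal dye-bias correction consistent with a Z-score null centered on the
experimental mean. A lowess fit of M on A (`normalization="loess"`,
`frac=0.3`) is available for intensity-dependent bias; residuals are
re-centered at median 0.

**Window statistic.** Within each promoter, a 600 bp window is anchored at
every probe center (probe center ± 300 bp, clipped to the promoter
region); membership is by probe start in [start, end), and windows with
identical member sets are emitted once. Windows need at least 3 member
probes (`min_probes=3`: at 100 bp spacing, region edges frequently hold
fewer than 4 probes, and 3 is the minimum for a meaningful median); the
window value is the exact median of member M values (even counts: mean of
the central pair). A fixed end-to-end tiling is available via
`WindowConfig(method="tiling")`; the sliding default cannot miss signal
through unlucky tiling phase.

**Empirical-null scoring.** Window medians are scored against a normal
distribution scaled to the experimental mean and SD of the window medians
in that comparison: z = (median − mean)/sd, two-sided normal p. The null
SD of a sample median shrinks with the number of member probes, so by
default the mean/SD are computed within windows of equal probe count
(classes with fewer than 10 windows fall back to the pooled statistics).
Measured on a 300-promoter null simulation, pooled scaling lets 3-probe
edge windows reject at ~18% versus ~4% for 6-probe windows — and because
the window layout is shared across comparisons this inflates the
all-comparison intersection rate roughly four-fold over alpha^N.
Stratification restores per-class rejection to 4–5% at alpha = 0.05 and
the intersection to ~alpha^N. `stratify_null_by_probe_count=False`
restores a single pooled null per comparison.

**Calling.** A window is a candidate only when p < alpha (default 0.05) in
*every* paired comparison, with a consistent direction of change across
comparisons (`require_consistent_sign=True`). Requiring significance in
all comparisons is the multiple-testing control — a deliberately stringent
intersection that admits only repeated changes; no FDR correction is
applied on top by default (a Benjamini–Hochberg option would act per
comparison before intersection, and the intersection of two-sided
sign-consistent rejections has null rate alpha^N/4, since three symmetric
tails agree in sign with probability 1/4). Overlapping or near-adjacent
candidate windows (gap ≤ 100 bp, one probe spacing) on the same promoter
merge into one DMR carrying its window count, smallest p overall and per
comparison, mean median-M and sign. DMRs export as 6-column BED
(score = −10·log10(min p), capped at 1000; strand column carries the
direction of change) and as a flat table (category, chrom, start, stop,
gene id, p, gene name). Coordinates are 0-based half-open everywhere.

**MeDIP-QPCR confirmation.** `qpcr_fold_change` reports
mean(treatment)/mean(control) with a Mann–Whitney rank-sum p (default) or
Welch t — both procedures are standard for small QPCR groups and neither
is privileged.

## Phenotype classification

Every rule derives from a control reference: the sample mean and SD
(n−1 denominator, the standard choice for small cohorts) of an endpoint in
control-lineage animals of the same generation and sex (pooling sexes
would be biologically wrong for pubertal timing, and generations differ in
rearing history). The normal range is mean ± 2 SD, and all cutoffs are
strict inequalities — a value exactly at the boundary is normal:

- **Pubertal abnormality**: onset day below the range → early; above →
  delayed; either counts as abnormal, with the early/delayed detail kept.
- **Primordial follicle loss**: follicles per ovary section (mean of three
  sections) strictly below mean − 2 SD.
- **Polycystic ovary**: small cysts per section strictly above
  mean + 2 SD.
- **Histopathology (testis, prostate, kidney)**: each of three observers
  has their own control cutoff (mean + 2 SD of that observer's control
  lesion counts, computed per organ); an animal's tissue is diseased only
  when ≥ 2 of 3 observers call it. Observer cutoffs are per organ; a
  per-region refinement (central vs peripheral sections) is not modelled.
- **Obesity**: requires both the gross adiposity observation and a body
  weight strictly above mean + k·SD. The weight component of the rule is a
  judgment call — reported obese/non-obese male means sit ≈ 1.4 control SD
  apart — so k defaults to 1 and is exposed as `k_sd`.
- **Tumor**: a recorded necropsy observation, passed through.

Endpoints missing for an animal yield `not_determined` (ND); histopathology
needs all three observer counts, else ND. The disease matrix CSV mirrors
the field convention: '+', '−', blank.

## Incidence and tests

Individual-disease incidence counts only determinate animals in the
denominator; the derived total-disease (≥1 disease) and multiple-disease
(>1) rows use all listed animals, so they are minimal incidences.
Percentages are integers, rounded half-up (7/9 → 78%). Treated-vs-control
comparisons fit a logistic regression (intercept + treatment indicator, ML
via statsmodels) per generation × sex stratum and report the odds ratio
with a two-sided Wald p — the three lineages are handled as two separate
control-vs-treatment fits, matching per-lineage significance reporting.
Zero cells cause separation, so those tables fall back to Fisher's exact
test, flagged `zero_cell`; both-degenerate tables are flagged
`non_estimable`. Continuous endpoints use Welch's t (no equal-variance
assumption). A litter-representation check compares evaluated
animals-per-litter between lineages per disease (Welch t on per-litter
counts; mean ± SEM reported; single-litter groups flagged). Summary tables
annotate p-values with the conventional stars (* <0.05, ** <0.01,
*** <0.001).

## The synthetic-data generator

**Array arm.** Promoters are placed sequentially per chromosome
(non-overlapping, random inter-promoter gaps), strand random; probes sit on
a deterministic lattice at the design spacing (jitter optional, off by
default — only the median spacing is specified, and a lattice makes window
membership exactly reproducible). Hybridizations follow a log-normal
intensity model: log2 cy5 = A0 + (m + u)/2 + e, log2 cy3 = A0 − (m + u)/2
+ e', with independent channel noise e ~ N(0, noise_sd) (so M noise SD is
noise_sd·√2), an optional per-comparison pool effect u ~ N(0, pool_sd)
(off by default — the decomposition of biological pool variance versus
hybridization noise is not separately specified, so one noise knob plus an
optional pool knob is exposed rather than guessing a split), and m =
dye_bias plus any spike effect. Spikes (promoter, span, delta-M, label)
are the ground truth for recovery tests; a probe is "under" a spike when
its start lies in the span.

**Cohort arm.** Cells are lineage (control, plastics, lower-dose
plastics) × generation (F1, F3) × sex, with `n_per_cell` animals assigned
round-robin to `litters_per_cell` litters (real litters average ~12 pups;
the round-robin scheme guarantees a balanced litter representation, which
the litter check should then not reject). Control endpoint distributions
are Gaussian with defaults chosen as realistic for 1-year Sprague-Dawley
rats: vaginal opening 34 ± 2 d, balano-preputial separation 43 ± 2 d,
primordial follicles 45 ± 8 /section, small cysts 2 ± 1.2 /section, body
weight 283 ± 35 g (F) / 509 ± 32 g (M), lesion counts 1.5 ± 1 per organ
per observer. Treated lineages draw each endpoint shifted by a
per-endpoint multiple of the control SD with a per-endpoint affected
probability (defaults emulate the reported effect directions: severe
follicle loss and cyst excess in most treated females, pubertal shifts in
a subset, lesion increases, adiposity concentrated in treated animals).
Injected abnormalities are recorded per animal in a truth table.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no sequence or CpG-density structure, no
spatial correlation of probe noise, no real genome coordinates, no
litter-level random effects (litters are labels, not variance components),
Gaussian endpoints without the skew/overdispersion of real counts, and no
observer correlation beyond shared truth. Calibration and recovery results
therefore validate the *statistics*, not array chemistry.

## Numerical choices and degenerate inputs

- Seeded `numpy.random.default_rng` everywhere; identical inputs + seed
  give byte-identical outputs. The CLI pipeline derives per-stage seeds
  from one root seed.
- Non-positive intensities are rejected naming the probe; a comparison
  with zero SD of window medians raises "degenerate null distribution";
  a control reference needs ≥ 2 finite values; logistic fits with zero
  cells take the exact path rather than diverging.
- Even-count medians are the mean of the central pair; merge tie-break:
  windows merge when gap ≤ merge_gap_bp (100), scanning left to right.
- Desk-scale defaults (300 promoters, 15 animals per cell) keep an
  end-to-end run near half a minute; the full 15,287-promoter geometry is
  behind `--full-geometry`.

## Known limitations

- The per-window Z against an empirical null assumes window medians are
  identically distributed within a probe-count class; strong global
  methylation shifts would violate the centering assumption (the
  intersection rule mitigates but does not remove this).
- The sliding windows overlap, so neighbouring window p-values are
  correlated; region-level inference derives from merged windows, not
  from an independence assumption.
- Odds ratios from small strata are unstable; the Fisher fallback keeps
  the p-value honest but the point estimate can be infinite.
- The obesity weight threshold (k_sd) is a documented judgment call, not
  an estimated parameter.
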