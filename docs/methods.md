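# Methods

## The prediction problem

A cohort of very preterm infants is characterised at term-equivalent age by
up to 42 quantitative MR measurements — five ¹H-MRS metabolite ratios
(NAA/Cho, NAA/Cr, Cho/Cr, NAA/mI, mI/Cr) and two DTI parameters (MD in
10⁻³ mm²/s, FA unitless in [0, 1]) in each of six supraventricular
white-matter regions — and followed up at 12 months corrected age, when a
Bayley-III scale score below 85 defines motor or cognitive delay. The
delayed class is rare (observed rates 12.6% motor, 6.1% cognitive), so the
predictor is built as a cascade whose first stage is deliberately biased
toward the majority class's removal.

## Localisation degree

For a characteristic with pooled observed values spanning [lo, hi], the
range is cut into 8 equal-width octiles and

LD = (number of octiles containing ≥ 1 delayed subject's value) / 8.

The statistic lives on the grid {1/8, …, 1}; 1/8 means all delayed values
share one octile. It is invariant under strictly increasing affine maps of
the characteristic (octiles transform with the range) and monotone in the
delayed set. Numerical conventions:

- Octiles are left-closed: a value exactly on an internal boundary belongs
  to the octile on its right; the pooled maximum belongs to octile 8.
  Binning is `floor((v − lo)/width)` clamped to [0, 7].
- A zero-range (degenerate) characteristic has no defined LD and is
  skipped by selection with the reason recorded.
- Missing values are handled by per-characteristic pairwise deletion; a
  characteristic is only profiled when at least `min_delayed` (default 3)
  delayed values are present, since an LD computed from one or two points
  is vacuously small.

Selection ranks characteristics by ascending LD, breaking ties first by
the smaller span between lowest and highest occupied octile (a tighter
cluster), then lexicographically by column name, so the ordering is fully
deterministic. Characteristics with LD ≤ `ld_threshold` are selected, and
the lowest-LD `inner_size` of them form the network input set. The defaults
— threshold 0.375, inner size 5 for the motor outcome and 4 for the
cognitive — reproduce the reference configuration of 7 selected
characteristics with a 5- or 4-characteristic inner subset; the numeric
cut is exposed in the config because only the resulting counts, not the
threshold itself, are documented for the original analysis.

## Relaxed screening zones (DDCRZ)

For each selected characteristic with pooled training range R, the zone is

[min(delayed) − relaxation·R, max(delayed) + relaxation·R],

an interval hull of the delayed training values dilated on both sides. A
subject is a zone *member* when the fraction of zone characteristics whose
value falls inside its closed interval reaches `membership_fraction`;
*incomplete* (excluded from the analysis, mirroring missing-metabolite-peak
exclusions) when any zone characteristic is missing; otherwise a
*non-member*, classified normal without consulting the networks. Defaults:
relaxation 0.10, membership fraction 1.0 (strict AND). The single-interval
hull was chosen over a union of occupied octiles because the zones are
meant to be *relaxed* neighbourhoods of the delayed values; the occupied
octile mask remains available in each `LocalisationProfile` should an
octile-shaped variant be wanted.

Containment holds by construction: with any relaxation ≥ 0 and membership
fraction 1, every delayed subject used to build the zones is a member.
Held-out delayed subjects can fall outside — that is the mechanism by which
the cascade produces step-1 false negatives.

## The network ensemble

Zone members are split into four label-stratified folds (each class
shuffled and dealt round-robin, so every fold keeps ≥ 1 delayed member
whenever ≥ 4 exist). For each held-out fold k, 100 single-hidden-layer
feed-forward networks are trained on the other three folds. Architecture
and trainer:

- inputs = the inner characteristic subset, standardised with training-split
  mean/SD (statistics never touch the validation fold);
- one hidden layer, logistic activation (tanh available), width = inputs+1
  by default (5–8 units in practice);
- two softmax outputs (class probabilities summing to 1 by construction);
- full-batch gradient descent with momentum 0.9, learning rate 0.5, up to
  200 epochs, on a cross-entropy in which delayed members are re-weighted
  by the inverse of their prevalence in the training split;
- the weights kept are those of the epoch with the lowest validation-fold
  loss (best-epoch snapshot rather than halting, which keeps the epoch
  count and hence the runtime and the random stream fixed);
- the 100 networks of a type differ only in their random initial weights
  (uniform on ±0.5) and are trained jointly as one stacked tensor
  computation, so the ensemble is cheap and bit-reproducible under a seed.

Voting: a network votes delayed when its delayed-class probability is
≥ 0.5 (an exact tie counts as delayed, favouring sensitivity); a type votes
delayed on ≥ 50 of its 100 networks (a strict majority, with the exact
50/50 split again resolved toward delayed); the final call is delayed when
at least 2 of the 4 types agree. All three thresholds are configurable.

## Metric bookkeeping

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), reported as percentages to one decimal with
round-half-away-from-zero. A metric with a zero denominator is *undefined*
and rendered "n/a", never silently 0 or 100%. Two scopes:

- **in-zone** counts only subjects the ensemble classified;
- **whole-dataset** additionally counts each screened-out delayed subject
  as a false negative and each screened-out normal as a true negative.

`whole_from_zone` performs exactly that lift — (tp, fp, tn+outside,
fn+missed) — and agrees with scoring whole-dataset predictions directly;
both paths are exercised against each other in the tests. A severe-injury
flag supports the exclusion subanalysis: with `exclude_severe`, flagged
subjects are dropped before step 1.

## Pipeline protocols and seeding

One global seed fans out to per-stage seeds through `numpy`'s
`SeedSequence` (stage seeds kept below 2³¹), so stages are individually
reproducible and a fixed config reproduces `metrics.json` byte for byte.

Two zone-fitting protocols:

- `fit_zones="per-fold"` (default, leakage-free): folds are assigned on the
  full analysis set; type k's zones and networks are fitted on folds ≠ k,
  and each subject is screened with the zones of its own held-out fold
  before all four types vote.
- `fit_zones="once"`: one zone set from all delayed subjects, the ensemble
  folded over its members — the resubstitution-style protocol that matches
  in-zone bookkeeping of the reference analysis most directly.

The published account does not state which protocol produced the reported
in-zone figures, so both are provided; the per-fold default is the
defensible choice for honest error estimates.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes rather than any
real infant:

- labels Bernoulli(prevalence); defaults 0.126 (motor) and 7/115
  (cognitive), the printed cohort rates;
- characteristic values drawn from per-class normals with the packaged
  mean/SD table (transcription and its two mechanical corrections are
  documented in `data/distribution_provenance.md`); FA is truncated to
  [0, 1] and MD to (0, ∞) — negligible truncation at the packaged
  parameters — while ratios are left unclipped;
- optional equicorrelation rho couples characteristics within a region
  through a shared per-subject factor; the published summaries do not
  quantify within-subject correlation, so rho is a free parameter
  defaulting to 0, not an estimate;
- planted localisation: for each (characteristic, octile) pair, delayed
  subjects' values are redrawn uniformly inside the strict interior of the
  designated octile of the non-delayed subjects' range (anchoring the grid
  on the non-delayed range guarantees the pooled extremes do not move, so
  the planted LD is exactly 0.125 with probability 1);
- dropout erases individual metabolite-ratio values at a per-cell rate
  (DTI maps are complete in practice, so MD/FA are exempt); the default
  rate of 0 is raised to ~0.01 to emulate the reference cohorts' ~19%
  missing-peak exclusions when missingness is wanted;
- a severe-injury flag drawn independently per subject. The reference
  cohort's severe-injury rate is only reported conditionally (2 of 7
  cognitively delayed infants); as a label-independent flag the default is
  left at 0 and the flag exists to exercise the exclusion toggle, not to
  model injury epidemiology.

What the generator does *not* emulate: realistic cross-characteristic
correlation structure beyond single-factor equicorrelation, measurement
drift between scanners, label noise in the Bayley-III assessment, and any
dependence of missingness on the outcome. Passing tests therefore show the
machinery is correct and recovers planted structure at study-scale n; they
do not certify clinical performance on real infants, and the headline
figures of the original cohort are not reproducible without its data.

## Problem sizes used in the tests

The suite exercises study-scale cohorts (n = 103 and 115) for selection and
screening; ensemble-recovery checks use 20 seeds × (4 × 100) networks on
~64-member tables, and pipeline determinism checks use reduced ensembles
(10–25 networks per type), sizes at which the full suite completes in about
a minute while keeping every contract at its full configuration at least
once (the 4 × 100 ensemble itself is trained in several tests).

## Known limitations

- The LD statistic is implemented in its octile-occupancy form over the
  delayed subgroup; variants (quantile-based bins, weighting all subjects)
  are conceivable and would change rankings. Likewise the exact zone
  construction (relaxation amount, AND vs partial membership) admits
  alternatives, which is why both knobs are explicit config rather than
  constants.
- Whether the 100 networks per type differed by more than initialisation
  (e.g. bootstrap resampling) is unstated; initialisation-only is
  implemented.
- With very tight planted structure the zones can exclude every normal
  subject, making in-zone specificity undefined ("n/a") — the bookkeeping
  is correct but the second stage then has no discriminating work to do.
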