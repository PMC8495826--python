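# Methods

## Problem setting

The package forecasts mountain pine beetle (*Dendroctonus ponderosae*)
infestation presence on a park divided into 100 m × 100 m pixels. For a
pixel *g* and survey year *t*, the target is the infestation indicator
I<sub>g,t+r</sub> at prediction length r ∈ {1, 3, 5, 7} years, predicted
from h ∈ {1..5} consecutive years of 14 covariates
X<sub>g,t</sub> = (N, E, B, D, T<sup>min</sup>, T<sup>max</sup>, W, R, C,
O, IN<sup>Missed</sup>, IN<sup>Managed</sup>, I<sup>Missed</sup>,
I<sup>Managed</sup>): topographic aspect (northerness/easterness), distance
to the initially infested border (km), degree days, winter minimum and
summer maximum temperature, wind, humidity, a cold-tolerance survival index
in [0, 1], the regional outbreak phase (1 = increase, 2 = peak,
3 = decline), and last-year infestation indicators for the pixel and its
neighborhood, split by whether the infestation was detected and controlled
("managed") or escaped control ("missed").

## Dispersal kernel

The short-distance dispersal index is a ring-weighted count of
indicator-positive pixels,

IN<sub>g</sub> = κ · Σ<sub>i=1..3</sub> 2<sup>−i</sup> ·
|{g′ ∈ N<sup>i</sup><sub>g</sub> ∩ park : x<sub>g′</sub> = 1}|,

where ring N<sup>i</sup><sub>g</sub> holds the pixels whose center distance
to g rounds to i × 100 m (the annulus [i − 0.5, i + 0.5) in cell units).
This gives ring sizes 8, 12 and 16 for interior pixels, a raw maximum of
8/2 + 12/4 + 16/8 = 9, and the scale κ = 2/3 pins the maximal attainable
index at exactly 6. The exact annulus geometry is a reconstruction: the
published definition states the weights and the [0, 6] range but not the
ring membership rule, and this is the simplest rule consistent with both.
Rings truncated by the park boundary are not renormalized.

## Synthetic survey generator

The generator's purpose is to produce survey tables with the statistical
structure the evaluation protocol depends on, without any data download.

* **Landscape** — rectangular park; one smoothly varying aspect angle per
  pixel (N = cos, E = sin, so N² + E² = 1); the initially infested border is
  the park's western edge and B is the within-park 4-connected
  shortest-path distance to it (0.1 km per step), zero exactly on border
  cells.
* **Weather** — each covariate is a yearly regional anomaly plus a
  spatially smooth unit-variance Gaussian field (σ ≈ 3 pixels), so adjacent
  pixels correlate far more strongly than distant ones. Anchors: degree
  days 900 ± 120 (year) ± 60 (space), winter minimum −32 ± 6 ± 2 °C, summer
  maximum 28 °C, wind 10 km/h, humidity 55 %. Cold tolerance is
  C = logistic((T<sup>min</sup> + 30)/5), increasing with milder winters.
* **Outbreak phase** — exogenous: the year span is cut into near-equal
  increase / peak / decline segments (configurable lengths). The O column
  reports the phase of year t − 1, matching the survey semantics of the
  other infestation covariates.
* **Infestation process** — pixel-level. Each year every park pixel becomes
  newly infested with probability
  logistic(β₀ + β_IN·IN<sup>Missed</sup><sub>prev</sub> + β_self·I<sup>Missed</sup><sub>prev</sub>
  + β_B·B + β_C·C + β_D·zD + phase effect); each new infestation is
  detected and managed with probability p_detect, otherwise missed, and
  **only missed infestations drive next year's neighbor pressure**.
  Initial seeds are placed on border cells (each with probability
  seed_fraction) and count as missed — they are the undetected source of
  the outbreak.

Default coefficients (β₀ = −4.5, β_IN = 4.0, β_self = 2.0, β_B = −0.3,
β_C = 1.5, β_D = 0.25, phase effects 0 / +1.0 / −1.5, p_detect = 0.5,
seed_fraction = 0.6) were chosen once by reasoning about the ring-kernel
reproduction number so that a border seeding grows into a three-phase
outbreak (typical prevalence rising from a few percent to 30–70 % at peak,
then declining) with strong year-to-year persistence. A single seed drives
all randomness through split `SeedSequence` streams, so every table is
bit-reproducible.

What the generator does *not* emulate: biologically calibrated beetle
demography, long-distance (above-canopy) dispersal, daily weather, tree-level
attack dynamics, and real management targeting (detection is spatially
uniform with probability p_detect — the real protocol is not described in
the source material). Passing tests therefore demonstrate that the pipeline
machinery behaves correctly on data with realistic spatiotemporal
autocorrelation, not that any particular AUC carries over to real surveys.
On small parks some survey years can contain no infestations at all; the
evaluation machinery treats the resulting single-class folds by skipping
them with a warning, and reports estimators that cannot be computed as
missing rather than guessing.

## Features and splits

The dataset D<sup>r,h,c</sup> pairs the top-c ranked covariates at years
t − h + 1 .. t with the target at t + r; for a rectangular table of N
pixels over Y consecutive years it has exactly N × (Y + 1 − r − h) rows.
Static covariates repeat across lags. Three split plans are provided:

* **year-based** — the two latest target years are the test set; training
  and test rows are yearly disjoint. Cross-validation folds hold out one
  training target year at a time.
* **random 70/30** — the conventional i.i.d. row split, which mixes years
  across train and test and therefore measures *current-year* rather than
  *future* predictive skill on autocorrelated data.
* **gap-honoring** — training targets at or before the latest usable
  covariate year t, test target at t + r, years in between quarantined.
  For long r combined with long h this legitimately leaves zero training
  rows and raises a dedicated error.

Discretization (for the discrete models and mutual information) cuts each
non-binary column into five equal-width bins over the *training* range;
out-of-range values at prediction time clip into the end bins. "Five equal
levels" is read as equal-width (the referenced implementation's convention
is not documented); bin edges are stored with the fitted model.

## Covariate ranking

mRMR ranking uses plug-in mutual information (bits) on the discretized
h = 1 training data: the first pick maximizes I(X; target), each later pick
maximizes relevance minus the mean MI with the already-selected covariates
(the MID form; MIQ is available). Constant covariates — e.g. the phase
when a long prediction length leaves only decline-phase training years —
are dropped before ranking. Ties break by input column order. One ranking
is computed per prediction length. The nested sets {X¹}, {X¹,X²}, …
crossed with h ∈ {1..5} give the 70-configuration search grid, versus the
intractable 2⁷⁰ ≈ 10²¹ raw feature subsets.

## Learners

All nine learners expose the same contract: fit on training rows, predict
a probability of infestation in [0, 1].

| name | implementation | notes |
|------|----------------|-------|
| SVM  | linear SVC + Platt sigmoid on decision values | inputs standardized on training statistics |
| GLM  | logistic regression, no penalty | plain MLE |
| GBM  | gradient boosted classification trees | defaults: 10,000 trees, depth 1, shrinkage 0.1 |
| NB   | discrete naive Bayes (from scratch) | Laplace-smoothed; missing evidence marginalizes out, all-missing returns the prior |
| CL   | Chow-Liu tree (from scratch) | maximum-MI spanning tree = KL-closest tree distribution; rooted at the target; exact inference under partial evidence |
| IAMB | incremental-association Markov blanket (from scratch) | grow by max conditional MI with a G² significance gate, then backward shrink; prediction from the smoothed blanket CPT with naive-Bayes back-off for unseen configurations |
| KNN  | k = 15 Euclidean neighbors | raw feature space; distance ties at the k-th neighbor break by training-row order |
| NN   | one hidden layer, ⌈c·h/2⌉ sigmoid units | standardized inputs, seeded optimizer, fixed epoch budget |
| MM   | logistic stacker over the other eight | stacking coefficients fitted on *out-of-fold* base probabilities (year folds), so the stacker cannot reward memorization; bases refitted on the full training set for prediction; constant probability columns excluded; resubstitution stacking available behind a flag |

Unstated hyperparameters (GBM depth/shrinkage, NN optimizer/epochs, SVM
cost and probability mapping) follow the cited packages' defaults or the
simplest seeded choice, and are all configurable. No class-imbalance
handling is applied.

## Evaluation

AUC is the rank-based Mann-Whitney statistic with ties counted ½. For each
learner, (c\*, h\*) maximizes the mean year-fold AUC over the grid, ties
breaking toward smaller c then smaller h; single-class folds are skipped,
and configurations with no valid fold (or no constructible training set,
e.g. r = 7 with h = 5 on a 13-year span) are excluded. The three
estimators of actual skill are the seeded random 70/30 split, the
average fold, and the last fold (latest training year held out); they are
compared by the summed absolute error Σ<sub>L</sub>|ŝ<sub>L</sub> − s<sub>L</sub>|
against the test AUC over learners.

Threshold selection maximizes sensitivity + w × specificity over the
observed score values plus {0, 1} (w = 1 is Youden's index; w = 10 is the
management-oriented weighting); ties break toward the higher cutoff, which
predicts fewer infested pixels, and raising w can only raise the cutoff.
Binary maps mark a pixel infested iff its probability ≥ cutoff, so counts
are non-increasing in the cutoff.

## Problem sizes used by the test suite

The distributed suite runs on synthetic parks sized to finish quickly while
preserving the phenomena of interest, a deliberate package choice:

* split-protocol study: 12 × 12 park, survey years 2006–2018, r = 1,
  h = 1, c = 14, ten seeded replicates, GBM at 100 trees and NN at 100
  epochs;
* end-to-end determinism: 10 × 10 park, 2006–2014, c ∈ {3, 14}, h = 1,
  GBM/NN at 60;
* parameter recovery: n = 20,000 for the logistic MLE check, n = 4,000 for
  Markov-blanket recovery.

## Known limitations

* The detection/management process behind the managed–missed split is a
  free parameter (p_detect); nothing in the source material specifies it.
* The IAMB grow phase takes a maximum over candidate statistics, so its
  effective false-positive level is larger than the nominal α of a single
  G² test.
* Plug-in MI on five levels is biased upward at small n; no bias
  correction is applied, matching the simplicity of the original analysis.
* KNN operates in the raw feature space, so covariates with large numeric
  ranges dominate the metric — faithful to the referenced setup, but a
  known weakness of the learner.
* The random-split estimate uses a single seeded split, not an average
  over many splits.
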