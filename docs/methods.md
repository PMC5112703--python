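# Methods

## Problem and model

`mirmine` screens paired feature-by-sample log2 abundance matrices — miRs and
mRNA probes measured on the same samples — for candidate post-transcriptional
repression. The working model is that an active miR lowers the steady-state
abundance of its targets, so across a heterogeneous panel the (miR, target)
pair shows a strong negative, possibly non-linear but monotone, association.
The pipeline makes no causal claim: it ranks pairs by the joint evidence of
(i) a negative statistical association, (ii) sequence-based target
prediction, and (iii) prior experimental validation, and annotates each pair
with how well it separates two phenotype groups.

## Preprocessing

Probe intensities can optionally be quantile-normalised (all sample columns
forced onto the per-rank cross-sample means; within-column ranks preserved;
ties assigned by stable sort order) and log2-transformed (`log2(v + offset)`,
offset 1 by default). Feature filtering then applies two rules, both with
thresholds computed on the *pre-filter* matrix:

* **Abundance**: the 10th percentile of all values in the matrix (linear
  interpolation) is the noise floor; a feature must have at least
  `floor(0.25·n)` samples strictly above it (14 of 57). "Strictly above" is
  deliberate so that a zero floor excludes zero counts. The count rule
  is exposed (`min_count_above`) because "25 % of observations" and "14/57"
  differ by one at n = 57; the count reading is the default.
* **Dynamic range**: miRs must have `max − min` exceeding the 90th percentile
  of all miR abundance *values*; mRNA probes must exceed 10 % of the global
  data range. Comparing a range against a percentile of values is an
  unusually aggressive rule for the miR side — it retains only features whose
  swing is comparable to the bulk abundance scale — but it is the literal
  reading of the procedure this package operationalises, and it reproduces
  the characteristic outcome that only a small minority of miRs survive.
  An alternative `range_percentile` mode (90th percentile of per-feature
  ranges) is provided as a config switch.

A `FilterReport` records every realised threshold and reconciles
`n_input = n_dropped_abundance + n_dropped_range + n_retained` (a feature
failing both rules is charged to the abundance rule, applied first).
Multiple probes per gene stay distinct throughout; probe→gene collapsing
happens only when matching databases. Cohort-style tables are matched by
full-length sample barcode equality, so two samples from one patient remain
distinct samples.

## Association measures

Pearson correlation is the standard product-moment estimate; constant
features are excluded with a warning (their correlation is undefined).

Mutual information uses the Kraskov–Stögbauer–Grassberger k-NN estimator,
algorithm 2, in nats:

    I = ψ(k) − 1/k − ⟨ψ(n_x) + ψ(n_y)⟩ + ψ(N)

For each point, the k nearest neighbours under the max-norm in the joint
space define per-marginal radii ε_x/2, ε_y/2 (the largest marginal distance
among those k neighbours); n_x and n_y count points within the closed
marginal balls, self excluded. Negative estimates near independence are
expected and kept — the ψ terms are exactly the estimator's bias correction,
and truncating at zero would bias the tail quantiles used downstream.

Numerical choices:

* **k = 4** by default. The estimator's variance grows at small k and its
  bias at large k; 4 is the conventional default of the toolkits that
  popularised the estimator and works well at panel sizes (tens of samples).
* **Tie-breaking jitter**, amplitude 1e-8, seeded. Abundance matrices contain
  exact ties (zeros, quantile-normalised values); KSG assumes distinct
  distances. The amplitude is far below any biological signal but large
  enough to break float ties. In `pairwise_associations` the jitter is drawn
  once per feature row from a single seeded stream, so results are
  deterministic and independent of block size; Pearson is computed on the
  raw (un-jittered) values.
* Neighbour search is brute force O(N²) vectorised over blocks of mRNA
  features. At panel scale (N ≈ 57) a spatial index would be slower; at the
  N = 2000 used in the estimator benchmarks a dense distance matrix is still
  cheap. The block kernel and the single-pair function share one code path.

The estimator is validated three ways in the test suite: against the
bivariate-Gaussian closed form −½ln(1−ρ²) (mean absolute error < 0.05 nats
at N = 2000, k = 4, over 20 seeds and ρ ∈ {0.3, 0.6, 0.9}; measured ≈ 0.02),
against independence (|MI| < 0.05 nats per seed; measured mean ≈ 0.01), and
bitwise against an independent plain-loop implementation of the same formula
on N = 20 datasets.

## Selection and integration

Candidate repressions satisfy `MI > q(MI, 0.90)` AND `r < q(r, 0.025)` with
linear-interpolated quantiles and strict inequalities (matching the
convention of reporting realised cutoffs as "> c" / "< c"). The conjunction
is the default because the target signature is *negative* dependence; an OR
mode exists but is off. A percentile of 100 disables a criterion — with
strict inequalities the extreme row would otherwise always be excluded.
Degenerate inputs (all values tied) produce an empty selection with a
warning rather than an error.

Prediction sources keep their native score semantics: context+-style scores
are filtered to the most-negative 15 % and miTG-style scores to the largest
30 % (percentile of the supplied table's score distribution — a single
global cutoff per source, matching the one-printed-cutoff convention).
Duplicate (miR, gene) records collapse to the pair's best score. Family-level
prediction keys fan out to every mature miR in the family map; probes fan
out to every mapped gene symbol; unmapped identifiers are flagged, never
silently dropped. Validation records count as strong evidence iff their
method is exactly (case-insensitively) luciferase reporter assay, qRT-PCR or
Western blot.

A selected pair becomes a putative relationship iff at least one filtered
source predicts the (miR-or-family, gene) pair; rows carry both support
flags, the validated flag, and later the d_Sep fields.

## Enrichment

No canonical formula exists for "relative enrichment of active associations",
so the package defines a transparent reconstruction: per miR and source,
`fold = (n_active / n_predicted_in_universe) / (Σ n_active / Σ n_predicted)`,
with a one-sided hypergeometric tail P(X ≥ n_active) over the pooled universe
as significance companion. Both components are reported so rankings can use
either. The universe is the identifier-mapped association table (gene level);
miRs with no predicted pair in the universe are omitted rather than reported
as zero-fold. GO categories are selected by case-insensitive name substring
with 5–500 members; the target-list fraction uses the *union* of selected
category members, and its fold is against the same fraction over the
background (all mapped genes). Multiple-testing correction across terms is
deliberately out of scope.

## Phenotype separation

d_Sep,norm is the Euclidean distance between the high- and low-group
centroids in the (miR, mRNA) plane divided by
`d_Sep,max = hypot(range(mRNA), range(miR))`. Centroids are arithmetic means
of log2 abundances (the geometric mean on the linear scale — the two readings
of "centroid/geometric mean" coincide after the log transform). Ranges are
taken over *all* samples with data, labelled or not, since the span of the
panel is a property of the pair, not of the labelled subset; a labelled-only
mode is not provided but unlabelled samples inside the existing ranges
provably leave the statistic unchanged (property-tested). The statistic is
symmetric in the group labels and bounded by 1. Percentile ranks across all
retained pairs use mid-ranked ties: `100·(#{u<v} + ½·#{u=v})/n ∈ [0, 100)`.
Because the statistic factorises over per-feature group means and ranges,
the full pair table is computed without looping over pairs.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes, not any
particular dataset's joint distribution:

* 57 samples; 100 miRs of which 35 % have no reads at all; 1000 probes.
  These defaults are the scale of the recovery study; real-panel widths
  (thousands of miRs, tens of thousands of probes) are reachable by config.
* Feature baselines are normal in log2 space (mean 6, sd 2), mimicking
  sequencing/microarray dynamic range and giving realistic behaviour of the
  global-percentile filters.
* 30 planted repressions with slopes U(−1.5, −0.8) in log2/log2 units and
  residual noise sd 0.5, giving planted |r| well above 0.6; 30 % of pairs use
  a monotone-decreasing logistic `a − b/(1+exp(−s(x−x0)))` instead of a line
  (detectable by MI, under-weighted by r). Planted-regulator miRs draw
  per-sample spreads U(2.2, 3.2) log2 units — a regulator whose abundance
  barely varies cannot express an observable slope, and the dynamic-range
  filter exists precisely to discard such features — while background miRs
  draw U(0.5, 2.0) and are therefore mostly filtered out, mirroring the
  aggressive retention seen on real panels.
* Phenotype labels: 24 of 57 samples, 12 high / 12 low; phenotype-linked
  planted pairs (30 %) shift the miR centroid by ±group_effect/2 between
  groups, and the target inherits the opposite shift through the repression.
* Prediction tables: each planted pair enters each source with probability
  `db_coverage`, scored inside the source's high-confidence region
  (context+ ∈ (−1, −0.9); miTG ∈ (0.8, 1)); one set of `n_decoys` random
  non-planted (miR, gene) pairs is scored in both sources from the full
  score distributions (U(−1, 0) and U(0, 1)). A random half of planted pairs
  appears in the validation table with a method drawn from the four common
  assay names (three strong, one not).
* Deterministic identifier maps: every 10th probe shares its gene with its
  predecessor (multi-probe genes), ~6 % of miRs share a family (prediction
  fan-out). GO-style categories carry the EMP/pigmentation substrings with
  member counts below 5, within [5, 500] and above 500, plus unrelated terms.
* All randomness flows from one `rng_seed`; sub-generators use fixed salts so
  expression, annotations and databases agree on the same phenotype
  assignment. Same config + seed ⇒ byte-identical outputs.

What the generator does **not** emulate: count-level sampling noise,
batch/platform effects, correlated co-expression modules among non-target
genes, miRs regulating many targets at once, or realistic database
false-negative structure. Passing the recovery study therefore shows the
pipeline's machinery is correct and well-calibrated under its own
assumptions — it does not certify discovery rates on real panels, where the
null associations are not independent.

## Recovery study (acceptance conditions)

With the defaults above, full database coverage and 5000 decoys, the
pipeline recovers planted pairs with mean recall ≈ 0.95 and precision ≈ 0.9
over 10 seeds (the suite requires ≥ 0.7 / ≥ 0.8). False positives are null
pairs whose sample correlation lands in both selection tails *and* which a
decoy prediction happens to cover — with 5000 decoys filtered to their
high-confidence tails this is a ~1 % coverage of the screened pair space.

## Problem sizes

Unit and acceptance tests run on matrices up to 100×57 miRs / 1000×57 probes
(≈ 27k–43k pair MI estimates per run, ~2 s each) and estimator benchmarks at
N = 2000; the acceptance script uses 5 pipeline seeds and 7 benchmark seeds
per ρ. These sizes give stable averages while keeping a full run in tens of
seconds; all of them are config knobs, and the pipeline streams pair blocks
with progress logging for larger panels.

## Known limitations

* MI thresholds are percentile-based; no permutation/FDR calibration is
  attempted (none is part of the procedure this package implements).
* The per-miR enrichment formula is a reconstruction (see above); absolute
  fold values should not be compared across datasets with different universe
  definitions.
* The literal miR range rule (percentile of values, not of ranges) is kept as
  default for fidelity; users filtering their own panels may prefer the
  `range_percentile` mode.
* KSG estimates at panel scale (N ≈ 57) carry sd ≈ 0.1 nats; the selection
  tails are meaningful in aggregate, not per pair.
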