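# Methods

This note records the statistical model behind `hcascreen`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer needs.

## Per-feature significance screening and SimIdx

The elementary operation compares one feature between two cell
populations with a two-sided two-sample t-test. The default is the
classical pooled (equal-variance) test; Welch's correction is available
via `variance_mode="welch"`. No multiple-testing correction is applied by
default: the screen's operating point is a raw per-feature α = 0.05, so
under the null each feature is called "changed" with probability α and the
similarity index has null expectation 1 − α = 0.95 rather than 1. Every
calibration in the test suite is written against 1 − α. A
Benjamini–Hochberg option (`correction="bh"`) exists for users who want
family-wise control, at the cost of shifting that null level.

Edge cases are handled explicitly rather than silently:

* features with fewer than 2 non-missing cells in either group are
  *unusable* — excluded from numerator and denominator, with a logged
  warning;
* features constant in both groups with equal means are *degenerate* —
  forced to h = 0 and excluded from the denominator, so padding a table
  with constant columns cannot inflate similarity;
* features constant in both groups with different means are certainly
  different (p = 0);
* missing values are propagated and dropped pairwise per feature, never
  imputed.

MoA-level SimIdx pools the cells of all the MoA's compounds into one
population before testing; per-compound SimIdx (used for the prediction
test set and for PSI) compares each compound alone. Pooling is the default
reading of a single "treatment population vs control" comparison; with
heterogeneous compounds the pooled population is a mixture, which is the
intended meaning, not an artifact.

## Mahalanobis profile distance

Each treatment cell's Mahalanobis distance is computed from the DMSO
mean and covariance. Screens typically have more features (824) than DMSO
cells, so the raw covariance is singular; it is shrunk toward its own
diagonal, `C_reg = (1 − w)·C + w·diag(C)`, with default weight w = 0.1.
Diagonal (rather than identity) shrinkage keeps the distance invariant
under per-feature affine rescaling applied jointly to reference and query,
which a feature-wise heterogeneous assay requires; this invariance is
property-tested. Cells above the 0.99 quantile of their own distance
distribution are discarded as outliers before aggregation (median by
default). The shrinkage weight, outlier quantile and aggregate are
configuration, not facts about any particular screen; the defaults are
this package's documented choices.

## Impact index

ImpIdx is assembled feature-by-feature from the per-MoA significance
vectors; unusable entries stay missing (NaN), never zero. The
conservation identity

    Σ_f ImpIdx_f = Σ_MoA usable_MoA · (1 − SimIdx_MoA)

is asserted exactly on every build. The high-impact threshold defaults to
`round(q · n_MoAs)` with q = 0.9, rounding half away from zero (so 270
MoAs give 243), and the organelle fraction uses strict inequality
(ImpIdx > threshold). The strictness and the explicit threshold parameter
are deliberate: "roughly 90% of the maximum" admits both 240 and 243 as
cutoffs, so the package takes the computed value as the default and lets
the user override it.

## Organelle attribution

Channel membership is recovered by case-insensitive substring search of
the five acronyms (Golgi, ER, Hoechst, Syto, Mito) in the feature label;
token boundaries are not required because CellProfiler labels concatenate
inconsistently. The default mode assigns *all* matching channels (a
cross-channel correlation feature informs both organelles), so per-channel
feature sets may overlap; `first-match` mode scans the acronyms in the
fixed order above and yields disjoint sets for users who need a partition.

## Response modelling

Per-organelle response curves are ordinary least-squares quadratics of
overall SimIdx on organelle SimIdx, with sensitivity defined as the first
derivative 2a·x + b. The subset regressions enumerate all 10 pairs and 10
triples of channels (never singletons or 4-/5-subsets), fit OLS with an
intercept on MoA-level rows, and score on held-out per-compound rows with
R² = 1 − SSE/SST. SST is taken about the *test-set* mean by default — the
plain reading of "1 − SSE/SST" on a held-out set — with a `sst_about="train"`
switch for sensitivity analysis. Negative held-out R² is reported as-is.
Rankings break ties lexicographically by subset, making the top/bottom-5
occurrence analysis bit-reproducible. Note that a single channel can occur
in at most 4 of the 10 pairs, so the maximum top-5 occurrence count is
4 + 5 = 9, not 10.

## Pairwise similarity and heterogeneity

PSI matrices are built for MoAs with strictly more than `min_compounds`
(default 3) profiled compounds. The diagonal is fixed at 1 by convention
(a self-comparison gives t = 0 everywhere) and excluded from summaries.
The scalar per-MoA heterogeneity readout is the *mean* off-diagonal PSI —
the reduction is not canonical, so `median` and `min` switches exist — and
MoAs with mean PSI < 0.3 (strict) are flagged as heterogeneous. For an
agonist/antagonist pair, per-channel PSI is averaged over compound pairs
and ranked within each arm; the rank-1 channel is read as the arm's most
concordantly affected organelle, and differing rank-1 channels between
arms constitute the target-switch signature.

## Synthetic screens

The generator draws DMSO cells as independent per-feature normals with
seed-derived baseline means (N(0, 3)) and log-normal standard deviations;
an optional within-channel-block common factor (`block_correlation`)
stresses the multivariate statistics, but the default keeps features
independent because every downstream test is per-feature. Effects shift
means only — a variance-shifting treatment would need a different power
analysis and is out of scope.

An MoA's effect has a shared **core** — `round(overlap_fraction · k)`
features from its pool, shifted by exactly `+effect_size_sd` (in DMSO SD
units) in every compound — and a per-compound **remainder** of `k − core`
features resampled from outside the core, shifted with a compound-specific
random sign and a magnitude drawn uniformly from `[0.5, 2] ·
effect_size_sd`. The random sign/magnitude on the remainder is what makes
compound heterogeneity *detectable*: if every compound applied the
identical shift, two compounds with large overlapping affected sets would
be indistinguishable on the shared features and pairwise similarity could
never drop below ~0.57 even at overlap 0 with k = 0.8·F, whereas real
same-MoA compounds differ in off-target action. With overlap 1 there is no
remainder, so compounds are distributionally identical and all null
calibrations hold unchanged. Unannotated test compounds reuse randomly
chosen effect specs with fresh compound-level draws, so the prediction
test set follows the training generative law. All draws descend from one
seed; per-compound substreams are keyed by (seed, compound index), so
adding compounds does not reshuffle existing ones.

What the generator does **not** emulate: plate/well layout and batch
effects, cross-feature correlation structure of real CellProfiler
features (beyond the optional block factor), variance effects,
dose–response, and non-Gaussian feature marginals. Passing calibration
tests therefore demonstrates correctness of the statistics under the
stated model, not robustness to those real-data complications.

## Canonical scenarios and problem sizes

`hcascreen.scenarios` freezes the study conditions used by the test suite
and by `scripts/acceptance.py`:

* **Null calibration** — 20 zero-effect MoAs, 824 features, 100
  cells/group; mean SimIdx checked against 0.95 within 3 binomial SE.
  Because every MoA is compared against the same DMSO sample the
  significance indicators are positively correlated across MoAs, so the
  binomial band is conservative in form but adequate at these sizes.
* **Recovery** — one MoA, k = 200 of F = 824 features at 2 SD, 200
  cells/group; SimIdx checked against (F − k)·0.95/F ≈ 0.719 within 0.02.
* **ER-dominated screen** — 20 MoAs, 824 features, 60 cells/compound, 150
  DMSO cells, 30 unannotated test compounds; per MoA and channel the
  affected fraction of the channel block is uniform on mean ± half-width
  with weights ER (0.90 ± 0.10), Golgi (0.45 ± 0.05), Hoechst
  (0.25 ± 0.04), Syto (0.12 ± 0.03), Mito (0.04 ± 0.02). ER is thus both
  the most frequently hit organelle and the dominant variance source for
  prediction. Target-recovery statistics aggregate 20 seeded replicates.
* **PSI overlap grid** — one MoA, 4 compounds, pool 0.8·F = 659 features,
  overlap ∈ {1.0, 0.5, 0.0}, 100 cells/group.
* **Target switch** — agonist pool = Golgi+Mito blocks, antagonist pool =
  Hoechst+ER blocks, 4 compounds/arm, overlap 0.75, 100 cells/group; the
  off-target remainder is what depresses PSI on non-target channels and
  makes the targeted organelles rank first.

These sizes keep the full suite and the acceptance script each well under
a minute on one CPU while leaving all recovery margins wide.

## Known limitations

* The per-feature tests assume approximately normal features; rank-based
  alternatives are not implemented.
* MoA-level pooling treats DMSO as one population; replicate (plate/well)
  structure is not modelled anywhere.
* The Mahalanobis defaults (shrinkage 0.1, quantile 0.99, median) are
  reasonable for 824-feature screens with hundreds of DMSO cells but are
  not tuned per dataset.
* PSI summaries weight all compound pairs equally; no representative-pair
  selection is offered.
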