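# Methods

`npemix` implements an unsupervised trajectory-phenotyping analysis for
birth-cohort data: a non-parametric EM (npEM) mixture model over mixed
continuous/binary features, BIC selection of the number of clusters, a
kernel-density posterior classifier that tolerates arbitrarily missing
features, and leave-one-out Jaccard / silhouette stability assessment.  This
note records the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic cohort does and does not emulate.

## Model

Subjects `i = 1..N` with feature vectors `x_i ∈ R^M` are modelled as draws
from an `L`-component mixture.  Conditional on component `k`, coordinates are
independent, and each coordinate `j` has a free (non-parametric) density
`f_jk` estimated by a weighted kernel density estimate:

    f_jk(u) = Σ_i w_ik · φ((u − x_ij)/h_j) / h_j ,     Σ_i w_ik = 1,

with `φ` the standard normal density and weights `w_ik` equal to the current
posterior membership probabilities of component `k`, normalised.  Fitting
iterates three steps until the posterior matrix stabilises:

1. **E-step** — `P(k|x_i) ∝ λ_k Π_j f_jk(x_ij)`, accumulated in log space;
2. **M-step** — `λ_k = mean_i P(k|x_i)`;
3. **KDE step** — re-estimate every `f_jk` with the new posterior weights.

The initial partition is a seed-controlled k-means clustering converted to a
one-hot posterior.  The fit is fully deterministic given `(data, L, seed)`.

Conditional independence is a deliberate simplification: antibody titres of
different allergen specificities are in truth weakly correlated, but the
product form is what makes the missing-data classifier exact (below) and is
the standard assumption for this model class.  Identifiability of the
non-parametric mixture requires at least three conditionally independent
coordinates (Hall & Zhou); with one or two coordinates the EM iteration
drifts toward the degenerate solution in which every component equals the
marginal density.  The package does not forbid `M < 3`, but tests and the
acceptance checks exercise the identifiable regime only.

The log-likelihood `Σ_i log Σ_k λ_k Π_j f_jk(x_ij)` is recorded but not
asserted monotone: this EM variant has no ascent guarantee, so convergence
is declared on the posteriors (max absolute change `< tol`), not on the
likelihood.

## Preprocessing

Applied in order, driven by per-feature metadata:

* **Half-LOD substitution** — left-censored antibody readings strictly below
  the assay limit of detection are set to `LOD/2` (e.g. IgE with
  LOD 0.03 kU/L → 0.015 kU/L; IgG4 0.0003 μg/L → 0.00015 μg/L; IgG
  0.4 mg/L → 0.2 mg/L).  Values exactly at the LOD are untouched.
* **Cytokine floors** — non-positive stimulated-minus-control responses
  become 0.01 pg/ml (protein) or 1e-6 units (mRNA).
* **log10** of skewed features (antibody, cytokine), after the
  substitutions guarantee positivity.
* **Missingness filters** — features missing in strictly more than 20% of
  subjects are dropped, then subjects missing strictly more than 30% of the
  remaining features.  Both thresholds are strict by design.
* **Complete-case / low-missingness split** — subjects with no missing
  entries train the model; the remainder are classified post hoc.
* **Positional standardisation** — `x ↦ (x − med(x_j)) / (max(x_j) −
  min(x_j))` with statistics computed on the complete-case subset only and
  stored in the model.  Scaled complete-case values lie in `[−1, 1]` with
  median 0; all features, including binary ones, are treated uniformly so
  each contributes comparably to the mixture.  Later data (low-missingness
  subjects, external cohorts) is always scaled with these *stored* training
  statistics — densities are only comparable in the training coordinate
  system.  Out-of-range values are permitted and handled by clipping at
  classification time.

Missing values are never imputed; they flow through to the classifier.
Outcome variables (wheeze/asthma analogues) and derived variables are
excluded from the clustering roster by metadata flags, not by name.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_missing_frac` (features) | 0.20 | strict feature QC threshold |
| `max_missing_frac` (subjects) | 0.30 | strict subject QC threshold |
| `n_clusters` (L) | BIC-selected | mixture components |
| `seed` | 1 | k-means initialisation stream |
| `tol` | 1e-6 | max posterior change declaring convergence |
| `max_iter` | 500 | EM iteration cap |
| bandwidth `h_j` | Silverman | `0.9·min(sd, IQR/1.34)·n^(−1/5)` |
| classification threshold | 0.90 | strict (`>`) posterior cut-off |
| stability seeds | 1..10 | initialisation seeds for LOO refits |

Bandwidths are computed once per feature on the pooled scaled complete-case
column and held constant across iterations and components ("default constant
bandwidths"); adaptive per-iteration bandwidths are deliberately not used.
If `IQR = 0` (very unbalanced binary features) the rule falls back to the
standard deviation alone, floored at 1e-6.  Constant columns are an error
and must be filtered upstream.

## Model selection

`BIC = −2·log p̂ + ν·ln N` with `ν = L·M + (L−1)` (natural log; e.g.
`ν = 524` at `L = 3, M = 174`).  The sweep refits every `L` in the requested
range with the same seed and takes the minimiser, breaking ties toward the
smaller `L` for parsimony.  Non-converged fits are recorded and flagged, not
dropped.  Note that BIC can only resolve clusters that induce cross-feature
dependence when merged: two clusters differing in a single coordinate can be
absorbed losslessly into one component's (multimodal) kernel density, and
BIC will then prefer the smaller `L` — a property of the model class, not a
defect of the selector.

## Classification with missing features

The posterior for a (possibly incomplete) row is

    P(k=K | x_i) = λ_K Π_j f_jK(x_ij) / Σ_k λ_k Π_j f_jk(x_ij)

with two conventions: a missing feature contributes density exactly 1
(equivalently, it drops out of the product — identical to deleting the
feature from the model, which `restrict_model` makes literal and the test
suite verifies to 1e-12), and a query value outside the feature's observed
training range takes the density of the nearest range bound.  The "range"
is the observed complete-case min/max stored per feature: with a Gaussian
kernel every point has non-zero density, so the data range is the natural
reading of the support.  Clipping makes the posterior constant in each tail
and guards against vanishing products from far-out values.

A subject is assigned to its argmax component only when the maximum
posterior strictly exceeds the threshold (default 0.90); otherwise it is
reported unclassified.  Cross-cohort classification restricts the model to
the features the external cohort shares via an explicit injective feature
mapping; the external table is scaled with the training model's reference
statistics (a sensitivity mode using cohort-own statistics is exposed on
the command line).

## Stability and validity

Leave-one-individual-out: refit on the `N−1 × M` table for each left-out
subject, for each stability seed; align each refit partition to the
reference partition (the full-data fit) by the one-to-one assignment
maximising total Jaccard similarity over the `L × L` cluster-overlap matrix
(scipy's linear-sum assignment; optimality is verified against exhaustive
enumeration for `L ≤ 4`); record per-reference-cluster Jaccard indices with
the left-out entity excluded from both sides; average over refits and
seeds.  Leave-one-feature-out is analogous over columns.  The full
`N×10 + M×10` schedule is expensive at cohort scale, so a stride parameter
subsamples the left-out entities (every q-th), with q recorded in the
report; tests and the acceptance script run with stride 12 and three seeds,
a choice documented as the package's desk-scale default.

Silhouette widths `s(i) = (b−a)/max(a,b)` use Euclidean distance in the
scaled feature space; members of singleton clusters take width 0 by
convention.  On realistic high-dimensional mixed data mean silhouettes are
small even when clusters are real and stable (the synthetic default yields
≈ 0.10 with leave-one-out Jaccard of 1.0) — the two diagnostics measure
different things, and low silhouette with high stability is the expected
signature of many weakly informative features.

## Synthetic cohort

The generator emulates the *structure* the analysis assumes, not any real
cohort feature-by-feature: 220 subjects in three latent clusters with
mixing proportions (0.41, 0.49, 0.10); ~60 clustering features in three
blocks — log-normal antibody titres with cluster-shifted log10 means and
left-censoring at an LOD of 0.03 (below-LOD values are recorded as drawn so
preprocessing exercises the half-LOD rule), Poisson infection counts with
cluster-specific rates, Bernoulli demographic covariates with cluster-tilted
probabilities; a binary age-5-wheeze analogue with per-cluster rates
(0.25, 0.21, 0.76), carried as a flagged outcome column outside the
clustering roster.  Cluster offsets are anchored loosely on reported
contrasts in this literature (house-dust-mite IgE geometric means differing
by orders of magnitude between the high-risk and low-risk groups;
lower-respiratory-infection rates of roughly 1.4/1.0/2.2 events per year),
with a single `separation` multiplier so recovery and monotonicity tests
can sweep difficulty.  The default separation is deliberately in the
comfortably identifiable regime.

Missingness is completely at random per entry (0.3%), plus a 10% stratum of
subjects with ~45% missing entries (removed by the subject filter) and two
features with ~30% missingness (removed by the feature filter).  Real
cohort missingness is certainly not MCAR; no informative-missingness
mechanism is simulated, so passing tests demonstrate correctness of the
machinery under MCAR, not robustness to informative dropout.  Other known
gaps between the generator and real data: no longitudinal correlation
beyond cluster-driven shifts, no within-block correlation beyond the
cluster structure, and a reduced roster (~60 features rather than the
full-scale ~174) to keep leave-one-out schedules tractable at desk scale.

## Numerical choices

* Density evaluations are floored at 1e-300 before logs; posterior
  normalisation uses log-sum-exp.  Clipping makes the floor essentially
  inactive in normal operation.
* Even-length medians are midpoints of the central order statistics.
* k-means initialisation uses 10 restarts from a seeded stream; an empty
  cluster (rare, degenerate data) triggers bounded seeded retries and then
  an error.
* Model JSON serialisation round-trips every density (sample points,
  weights, bandwidth, support), the mixing proportions, reference scaling
  statistics, and the convergence record, losslessly.
* Cross-language bit-identity with any other implementation of this model
  class is not a goal; determinism within this package is.

## Known limitations

* The non-parametric mixture is unidentifiable for `M < 3` conditionally
  independent coordinates; the package will fit but results are meaningless
  (see Model above).
* BIC cannot separate clusters that differ in a single feature (see Model
  selection above).
* Stability metrics measure reproducibility of the partition under
  perturbation, not correctness against any external truth.
* The classifier assumes training densities transport to the classified
  data; covariate shift between cohorts is not modelled beyond the shared
  scaling.
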