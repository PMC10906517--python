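# Methods

## Model and estimator

The data are K panels `X_a ∈ R^{N×P}` (stimuli × attributes), one per
dataset (country), measuring the same P attributes on the same N
stimuli. G-PPCA seeks unit loading vectors `α` maximizing the summed
pairwise covariance of projections `Σ_{a<b} Cov(X_a α, X_b α)`. Writing
`C_ab = X̃_aᵀ X̃_b / (N−1)` for the cross-covariance of column-centered
panels, the objective equals `αᵀ M α` with
`M = Σ_{a<b} (C_ab + C_abᵀ)/2`, so the components are the eigenvectors
of the symmetric matrix M in descending eigenvalue order, and each
eigenvalue is the component's total preserved covariance. For K = 2
this is plain PPCA. The formulation treats the eigendecomposition as
given; no iterative fitting is involved.

Conventions: centering is per dataset (each `X_a` by its own column
means), removing dataset-level response-style offsets; covariance uses
the N−1 denominator; eigenvector signs are fixed so each column's
largest-magnitude entry is positive; no variance standardization is
applied by default because inputs are already [0, 1]-scaled per concept
per dataset (a z-scoring flag exists). Components with negative
eigenvalues are kept in the model, ranked last: they describe
anti-preserved contrast structure and are never counted as preserved.

## Input pipeline

Raw ratings are long-format records (stimulus, dataset, rater, concept,
intensity ∈ [0, 100]). Averaging pools all raters of a (dataset,
stimulus) group into one mean per concept; by default a rater who did
not select a concept contributes intensity 0 for it
(`unrated_as_zero=True`), matching a select-then-rate task in which
unselected states carry no reported intensity. Averages are then
min-max scaled to [0, 1] separately for every concept *within every
dataset*; constant columns map to zero and are flagged, not dropped, so
attribute indices stay aligned across datasets. Concept labels are
matched after trimming and case-folding through a lexicon that maps
each dataset's display labels (translations) onto a canonical key
order.

## Cross-validated scores and fold alignment

Preservation tests use leave-one-stimulus-out scores: for each stimulus
the model is refitted on the other N−1 stimuli (via exact rank-one
downdates of the Gram matrices; verified against brute-force refits)
and the held-out stimulus is projected using the fold's training means.
Because eigenvector order and sign are arbitrary per fold, fold
components must be matched to a common reference for "component m" to
mean one dimension everywhere. Matching is greedy on the largest
remaining |Pearson correlation| between loading vectors, sign set by a
positive dot product.

The alignment *target* matters more than it looks. Aligning folds to
the full-data model (the obvious choice, available as `align="full"`)
leaks held-out information: the full-data eigenvector for a weak,
near-degenerate dimension is partly selected by the held-out stimulus
itself, so fold components dragged toward it re-inherit the full fit's
in-sample (overfit) cross-dataset covariance — on six-dataset panels of
pure noise plus planted signal this produced spurious positive
correlations around r ≈ 0.1 on noise dimensions. The default is
therefore cross-fitted alignment (`align="split"`): stimuli are split
deterministically into two halves, a model is fitted to each half and
its components matched once to the full-data reference, and fold i is
aligned to the model of the half *not* containing i. The target then
never sees the held-out stimulus and noise dimensions recover null
behaviour in the preservation pipeline.

## Preservation testing

For dimension k and dataset pair (a, b), the held-out scores
`Z_a[:,k]` and `Z_b[:,k]` are each residualized (least squares with
intercept) on their own dataset's scores for dimensions 1..k−1 and the
residuals Pearson-correlated; the test is one-sided (r > 0) because
preservation requires positive co-variation, with p from the t
distribution on N − 2 − (k−1) degrees of freedom. Within each pair,
p-values across the tested dimensions (default 48) are BH-FDR
corrected at α = 0.05. Each dimension then gets a graph over datasets
with significant pairs as edges; it is retained when the graph cannot
be partitioned — by default both connected across all K datasets *and*
with every dataset linked to at least two others (`connected`,
`min_degree_2`, or `both` are selectable because the informal
"unipartite" criterion admits either operationalization).

The preservation score summarizes how similar per-dataset loading
slices are: r is the correlation between the concatenated per-dataset
loadings and the cross-dataset average loading tiled per dataset, and
r² is the preserved fraction. Note the floor: each dataset contributes
1/K of the self-inclusive average, so fully independent loadings score
r ≈ 1/√K (0.41 at K = 6), not 0; r² at or below 1/K means nothing is
preserved beyond that artifact.

## Extraction pipeline

`extract_dimensions(A, B)` runs the K = 2 machinery between two wide
matrices over concept × dataset attributes. Held-out score pairs per
dimension come from the same leave-one-out sweep; the per-dimension
statistic is a one-sided partial Spearman (ranks, then the partial
Pearson machinery) controlling each side's own previous-dimension
scores. Bootstrap: stimuli are resampled with replacement (default
1000 iterations) and the correlation step recomputed on the resampled
held-out scores; the p-value is one minus the fraction of resampled
statistics above zero, and SNR is the statistic over the bootstrap
standard deviation (ddof 1). Retention requires all three of: BH-FDR
across the first 48 dimensions at α = 0.05, membership in the
ForwardStop prefix (largest k with mean of −log(1−p_i) over i ≤ k at
most α; p clipped at 1 − 1e−12 so exact 1s stay finite), and SNR ≥ 3
(inclusive). Retained loadings are varimax-rotated.

Varimax maximizes the summed per-factor variance of squared loadings by
the SVD fixed-point iteration, without Kaiser row normalization; the
criterion is non-decreasing across iterates, the rotation matrix is
orthogonal to 1e−8, and the M = 2 case matches the closed-form
single-angle solution (also cross-checked against the statsmodels
implementation).

`loading_significance` refits the whole analysis (full PPCA fit of the
resampled stimuli plus varimax of the leading retained-count
dimensions) on each resample; for a reference dimension with attributes
ordered by |rotated loading|, p_N is one minus the fraction of
resamples in which *some* re-extracted dimension's loadings at the top
N attributes all point in the same direction (mutually equal signs; a
dimension's global sign is arbitrary, so both orientations count), and
the significant-loading count is the ForwardStop cut of (p_1 … p_Q).
The inner held-out/bootstrap filtering is not re-run per resample: the
sign test only needs the re-extracted loadings, and the number of
extracted dimensions is held at the reference's retained count.

## Synthetic data

`make_panel` draws latent stimulus scores `S ~ N(0, diag(strengths²))`
and emits `X_a = S_shared A_shared + S_spec,a A_spec,a + ε_a` with
i.i.d. Gaussian noise (default sd 0.3), then scales each concept column
to [0, 1] per dataset. Defaults mirror a six-country, 48-concept panel
with five shared and one culture-specific dimension per country at 500
stimuli. Planted loading rows are mutually orthonormal — random dense
rows by default, or disjoint same-signed supports of a chosen size (a
dimension as a cluster of concepts loading positively together), which
keeps top-loading sign patterns well defined for the loading test.
Shared strengths default to geometric spacing `2·(1/√2)^j`: distinct
strengths are required at all (equal strengths make the eigenvalues
degenerate, so only the shared subspace, not its axes, would be
identifiable), and constant *relative* gaps keep identifiability from
degrading down the spectrum under the per-column scaling, whose
dataset-to-dataset range variation slightly rotates adjacent axes.
Optional select-then-rate sparsity zeroes a fraction of raw cells
before scaling. `make_annotation_pair` reads the same latent scores out
through the same loadings with independent noise and its own scaling,
so the pair shares exactly the planted dimensions.

What the generator does not emulate: per-rater response styles and
rater counts (averaging is emulated at the cell level), bounded 0–100
intensities (cells are Gaussian before scaling), non-Gaussian or
heavy-tailed score distributions, correlated noise across concepts, and
any image-derived structure. Passing tests therefore show the
statistical machinery is correct and calibrated under linear-Gaussian
panels of realistic shape — not that real rating data satisfy those
assumptions.

## Problem sizes used in tests and the acceptance script

Recovery checks use 20 panels at K=6, N=500, P=48 (5 planted shared
dimensions, noise 0.3); type-I checks use 50 null panels at N=300; the
extraction null uses 20 pairs at N=300, Q=96 with 200 bootstrap
iterations; the planted extraction uses N=500, Q=96, support 6, 200
iterations for both the filter bootstrap and the loading test. The
independent maximizer check uses 10⁵ random unit vectors plus
normalized gradient ascent on instances with N ≤ 20, P ≤ 5, K ≤ 4.

## Known limitations

- **Null variance of cross-validated scores.** Under a (near-)fully
  degenerate spectrum, the pooled held-out scores for a dimension lie
  along an essentially common data-fitted direction, so their
  cross-dataset correlation equals the in-sample covariance along that
  direction. Leaving one stimulus out removes the bias (the null mean
  is zero) but not the fluctuation, whose scale is set by the overfit
  spectrum: at N=300, Q=96 the per-dimension null sd is ≈ 0.13 against
  the 1/√N = 0.058 i.i.d. scale. The score-row bootstrap scales as
  1/√N and cannot see this direction-level variance, so the SNR filter
  is anti-conservative at small N: roughly one in seven pure-noise
  extraction runs at N=300 retains a single spurious dimension. A
  bootstrap that refits the whole leave-one-out sweep per resample
  would capture it but multiplies cost by the iteration count. The
  effect shrinks with N (it is negligible for panels of thousands of
  stimuli); results on small panels should treat single marginally
  retained dimensions with caution.
- **Loading-count overshoot.** In the top-N loading test, resamples
  center on the sample fit, so the largest-null-loading attributes
  replicate their own sample signs far above chance; whenever the
  leading null attribute happens to share the support's sign the count
  rides past the true support. The per-dimension overshoot has a
  geometric tail (≈ +1 typically, occasionally +3); the median count
  across dimensions is the stable summary.
- Dimensions are identifiable only up to eigenvalue ties; data with
  exactly exchangeable shared dimensions cannot be resolved into axes.
- The partialling scheme residualizes each side on its *own* previous
  scores; pooling both sides' scores as covariates is a reasonable
  alternative not currently exposed.
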