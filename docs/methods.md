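# Methods

## The model cascade

The package treats biotic dependence explicitly: the parasite's predictors
are not environmental variables but the predicted habitat suitabilities of
its host plants. The pipeline per scenario is

    covariate rasters ── PCA ──► PC stack ── MaxEnt per host ──► host
    suitability stack ── MaxEnt ──► parasite suitability

Models are fitted and selected on the current scenario only and transferred
frozen to futures. The alternative — re-selecting features per future
scenario — is incoherent here because no future occurrences exist; freezing
also keeps the habitat-class areas comparable across scenarios, which is
what the change-ratio analysis consumes. The same freezing logic applies one
level down: PCA means, SDs and loadings come from the current scenario, and
Jenks class breaks come from the current suitability surface.

Hosts are modelled independently (no host–host interaction terms), and host
suitability enters the parasite stage on the cloglog (0,1) scale as an
ordinary covariate with the full linear/quadratic/hinge basis.

## MaxEnt implementation

The model is the Gibbs distribution over a background sample maximising
entropy subject to soft feature-mean constraints, i.e. the concave
penalised likelihood given in the README. Numerical choices:

- **Features.** Linear `(x−min)/(max−min)`, quadratic (its square), and
  forward/reverse hinges at `k_h` equally spaced interior knots per
  covariate (default 20 per direction; the tests and analysis scripts use
  4–8, which changes little at these sample sizes). All features live in
  [0,1]; bounds come from the union of training presences and background.
- **Penalties.** β_j = rm · base(class, m) · s_j/√m with the classic
  interpolated base tables (linear 1.0→0.05 over m=10→100, with the
  linear+quadratic table when quadratic features are present, hinge
  constant 0.5), s_j the presence SD of feature j floored at 1e-4, and rm
  the user's regularisation multiplier.
- **Optimisation.** The L1 problem is solved as the equivalent
  box-constrained split λ = u − v with L-BFGS-B. Convergence is certified
  on the *original* problem's projected gradient (∞-norm); the solver is
  restarted with cleared curvature memory when it reports an ftol stop
  before that residual passes, which reliably resolves line-search stalls
  on kinked coordinates. Default tolerance 1e-4: far below every default
  penalty magnitude, and attainable for hinge-heavy designs where machine
  precision leaves residuals around 1e-5; small smooth problems reach 1e-9
  and the oracle tests run there. Non-convergence raises, carrying the
  final residual.
- **Prediction.** Covariates are clamped to training bounds before feature
  evaluation, so the exponential model is never extrapolated; extrapolation
  is *reported* instead (ExDet, %N). Outputs: raw (sums to 1 over the
  training background), cloglog (default, used by all habitat classing) and
  logistic.
- **Background.** 10,000 cells sampled uniformly without replacement from
  jointly valid cells (all cells when fewer), seeded. Test-scale runs use
  2,000–5,000.

## Evaluation and selection

Four spatial folds come from two nested checkerboards with aggregation
factors (a1, a2) = (2, 2): fine parity g1 at a1 cells, coarse parity g2 at
a1·a2 cells, fold = 1 + g1 + 2·g2, identical for presences and background.
Per fold: AUC (Mann–Whitney, ties ½), omission rate at the training
10th-percentile threshold (linear-interpolation "type 7" quantile — the OR
value depends on this convention, hence it is fixed and stated), and the
CBI with 101 sliding windows of width 0.1× the landscape prediction range.
Selection is argmax of mean CBI, ties broken by lower omission, then higher
AUC, then candidate order; the winner is refit on all presences.

A caveat worth knowing: because CBI windows are *value*-based, the index is
only approximately invariant under monotone rescalings of the predictions,
and its null distribution under the prescribed overlapping windows is wide
(SD ≈ 0.3 with 2,000 evaluation presences — the ~101 windows contribute
only about ten independent P/E ratios). CBI differences of ±0.2 between
candidates are therefore not individually meaningful; the selection uses it
as a ranking heuristic, which is also how the field uses it.

## Transfer diagnostics

ExDet: per covariate the negative exceedance of the reference range,
summed into NT1 ≤ 0; where NT1 = 0, NT2 = Mahalanobis D² to the reference
mean scaled by the maximum reference D², so NT2 > 1 marks novel covariate
combinations. Classes: univariate (NT1 < 0), combinatorial (NT2 > 1),
analogue. MIC is the most negative exceedance (univariate cells) or the
covariate whose omission most reduces NT2, each leave-one-out NT2
renormalised by its own reference maximum (combinatorial cells). The
reference covariance gets a ridge of 1e-8·trace/p when near-singular. The
reference set is the parasite model's training rows (presences +
background) in host-suitability space when diagnosing the parasite stage,
and PC-space rows for host models; both are supported, the parasite space
is the default. %N counts reference rows inside an axis-aligned box of
half-width 1 reference SD per covariate (configurable radius).

Niche similarity normalises two suitability surfaces to probability
distributions over the shared mask: D = 1 − ½Σ|p−q|,
I = 1 − ½Σ(√p−√q)². Both equal 1 exactly iff the normalised surfaces
coincide.

## Habitat classing, trends, reserve

Jenks natural breaks use the exact Fisher dynamic programme (O(k·n²));
inputs beyond 10⁵ values are reduced to a seeded uniform subsample of 10⁴
first. Intervals are right-closed (a value equal to a break falls in the
lower class). Change ratios are per-class relative area changes against the
current classification, with areas from exact spherical cell geometry
(R = 6371.0088 km, the IUGG mean radius). A (species, class) pair counts as
*shrinking* when its ratio is negative in ≥50% of the 16 future keys and
its mean ratio is negative — a fixed operationalisation of what the source
analysis argued case by case. Influential hosts are those with mean
niche-similarity I ≥ 0.9 across scenarios, ranked by univariate-MIC share.
The core reserve defaults to the *intersection* of the parasite's MSH∪HSH
with the shrinking hosts' current classes; a union rule is available in the
configuration because the prose this operationalises is ambiguous between
the two readings (the intersection is the conservative one).

## The synthetic world

`synthetic.make_world` generates: 8 latent Gaussian random fields (white
noise smoothed with a σ = 6-cell kernel, standardised) on a 120×100 grid of
0.05° cells; 30 covariates, each anchored on one latent round-robin with
weak random cross-mixing (SD 0.1) plus independent noise (SD 0.15) — this
reproduces the "many collinear variables, few effective dimensions"
situation that motivates the PCA, and makes the retained component count
equal the latent rank at the 95% target; futures shift the latents by a
smooth trend field scaled per scenario (SSP126/245/370/585 →
0.15/0.3/0.5/0.7 per 20-year step) plus per-GCM noise (SD 0.05, 2 variants);
host truths are logistic in the latents (each host anchored on its own
latent pair); the parasite truth is logistic in the *host truths* with
weights (3, 3, 1, 0, 0); 200 presences per species are drawn without
replacement with probability proportional to truth and jittered uniformly
within their cells (so spatial thinning has real work to do).

What this does *not* emulate: observation bias (GBIF-style roadside
clustering), coordinate error beyond cell jitter, nodata seas/masks,
non-stationary covariate interactions, and dispersal limits. Passing tests
therefore certify the estimator and the pipeline plumbing, not robustness
to messy real occurrence data.

## Problem sizes used by the test suite and acceptance script

Unit tests run on worlds of 30×24 to 60×50 cells with reduced candidate
grids (L/LQ, rm = 1) and backgrounds of 500–4,000 cells. The acceptance
script runs the full default world with candidate grid {L, LQ, LQH} ×
{1, 2}, background 5,000, hinge knots 8; host-ranking recovery uses ten
replicate worlds at the default size with an LQ-only grid. These sizes keep
a complete run in the minutes range on one CPU while exercising every
selection and transfer path.

## Known limitations

- The null distribution of the CBI under the default windowing is wide (see
  above); CBI-based selection is a ranking device, not a significance test.
- Exact Jenks is quadratic in the (sub)sample size; the subsample bound is
  a bias-free but approximate classing of very large rasters.
- Soil-texture-like categorical covariates are treated as numeric, as the
  upstream variable-assembly convention implies; a caveat, not a feature.
- ESRI ASCII grid is the only raster format (portable, plain text);
  GeoTIFF I/O is out of scope.
- Coordinates are WGS84 lon/lat throughout; no reprojection.
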