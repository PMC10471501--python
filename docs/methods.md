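# Methods

`hetmap` implements a multiscale analysis of interindividual heterogeneity in
brain-phenotype deviations: a hierarchical normative model turns each
subject's regional phenotype vector (gray-matter-volume-like, strictly
positive) into a deviation z map; extreme deviations are then aggregated at
three spatial scales — the region itself, the region's normative functional
circuit, and its extended functional network — and case–control differences
in *overlap* (the proportion of a group expressing a deviation at a location)
are tested under two complementary permutation null models. Because the
framework is validated entirely on synthetic cohorts, every stage of the
generator is part of the package and is itself under test.

## Normative model

Per region *j*, the phenotype is Box–Cox transformed (λ_j by bounded
maximum-likelihood on [−2, 2]; near-flat profiles tie toward λ=1) and modelled
linearly in age with batch-specific intercept, slope and noise, where a batch
is a (site, sex) cell. The default backend is an empirical-Bayes two-stage
fit: per-batch OLS followed by shrinkage of intercepts and slopes toward
their across-batch mean, with the between-batch variance τ² estimated by
method of moments. The signal-to-sampling ratio entering τ² is pooled across
regions *before* the positivity floor is applied — this is the "shared
hyperprior" step; pooling before flooring removes the upward bias a
per-region floor would introduce, so truly exchangeable batches shrink
essentially all the way to the grand mean, while real site effects are left
nearly unshrunk. Batch noise variances are pooled toward their mean with a
prior pseudo-count of 10 observations.

Deviations are scored as

    z_ij = (y_ij − ŷ_ij) / sqrt(σ_ij² + σ_nj²)

with σ_ij the epistemic standard error of the linear prediction at the
subject's age and σ_nj the batch's (aleatoric) residual SD. Calibration —
held-out control z approximately N(0, 1) per region — is asserted by test,
as is recovery of the generator's site/sex offsets within 95% intervals
(truth mapped through the fitted λ, since a non-zero λ̂ rescales the
transformed axis).

Splitting follows the multi-site convention: (site, sex) cells with fewer
than 10 controls are excluded outright; sites with ≥30 controls hold out 10%
of them as the normative benchmark (HC_test), smaller sites train-only; a
site that loses cells and retains fewer than 10 cases is dropped wholly (the
case rule applies only to sites that had cases, so pure-control designs
remain usable). Diagnostics: 5-fold cross-validated explained variance,
standardized MSE and mean standardized log-loss; and a site-leakage check —
one-vs-all linear SVMs (C = 1, two-fold, repeated) classifying site from the
z maps, which should sit at the 50% chance level when harmonization worked.
At desk scale (≈24 held-out maps) this estimator carries ≈3 percentage
points of Monte Carlo noise and a genuine ~2-point finite-sample leak (any
model fitted on ~50 subjects per site leaves traces); the acceptance script
averages it over replicate cohorts.

## Regional scale

Extremes are strict threshold crossings, |z| > 2.6 (one-sided Gaussian tail
mass < 0.005), positive and negative processed as fully separate pipelines.
Overlap maps are group proportions (never raw counts); the unit of inference
is the Δ-overlap map (case minus held-out control). A threshold-weighted
variant integrates survival proportions over 100 log-spaced thresholds in
1.64 < z < 3.10 with the linear weight W(th) = 2(th − z_min)/(z_max − z_min),
weights applied before integration and the integral normalized by the maximal
attainable weighted area so values lie in [0, 1] (the printed weight reaches
2 at z_max; normalizing the area — rather than the weight — is the reading
adopted here, flagged as a deliberate interpretation). The weighted map is
the mean over subjects of a per-subject score, which is what the permutation
tests shuffle.

## Circuit scale

The functional circuit of a deviant region is estimated in a normative FC
cohort, lesion-network-mapping style: the seed's mean time course is
correlated with every grayordinate, Fisher r-to-z transformed (|r| clamped at
1 − 1e-12 so seed self-correlation stays finite), aggregated across atlas
subjects with a one-sample t test, TFCE-enhanced on the grayordinate graph
(E = 0.5, H = 2, the field-standard surface defaults; step dh adaptive at
max/100 with a 1e-3 floor, shared between observed and null maps), and
thresholded by sign-flipping max-statistic permutation FWE at α = 0.05/2 —
cortex and subcortex are separate graph components tested independently,
hence the halved level. t values are capped at |t| = 50 before enhancement:
the clamped self-correlation column is near-constant across subjects, its t
is numerically unbounded, and an unbounded maximum would inflate the adaptive
dh until genuine signal fell below the first step. A region joins the
circuit when strictly more than `frac` (default 0.5; 0.75 for robustness) of
its grayordinates survive. Circuits are computed once per unique seed and
cached as a regions × regions binary matrix; a subject's union map is the OR
over the circuits of their extreme regions, so union maps (and hence circuit
overlap) dominate the extreme-indicator maps whenever circuits contain their
own seed.

TFCE uses an incremental union-find over nodes activated in decreasing
height order (numba-compiled), making a 500-permutation FWE run per seed a
few hundred milliseconds at the default problem sizes.

## Network scale

A network is deviant for a subject when any member region is deviant.
Cortical regions carry a 7-network labelling refined into 17 nested
sub-networks; subcortex contributes 3 anatomical groups (medial temporal,
thalamus, basal ganglia), giving the 10- and 20-network schemes. Network
size is deliberately not corrected for: inference is case versus control
within a network, never across networks.

## Inference: two null models

**Group-label permutation** shuffles case/control labels (10,000 draws by
default, add-one tail counting so p ∈ (0, 1]); it is sensitive to any
overlap difference, including those produced solely by a higher deviation
burden in cases. Union maps are precomputed once and re-labelled per
shuffle. **Spatial (spin) permutation** instead rotates each subject's
cortical deviation values on the sphere and shuffles subcortical values,
re-thresholds, and rebuilds the downstream statistic per draw; every
surrogate preserves each subject's burden exactly, so a significant result
means deviations *preferentially target* that region's circuit or network
beyond what burden alone predicts. Significance under both models is the
signature of preferential targeting; group-only significance is attributable
to burden.

The spin bijection draws one uniform rotation, applies it to the left
hemisphere and its x-mirror to the right (homotopy preserved), and reassigns
region values by Hungarian cost-minimizing matching between rotated and
original coordinates — values are permuted, never resampled, so the value
multiset and (approximately) the spatial autocorrelation survive. Because
the assignment depends only on geometry, a pool of `n_perm` permutations is
generated once; within each iteration every subject draws independently from
the pool. Independent per-subject rotations matter: a single shared rotation
per iteration reduces the test to ranking a region within its own map, which
has no FDR-level power against spatially extended effects and would defeat
the burden-vs-targeting dissociation. Subcortical values are shuffled
uniformly per subject per iteration — more lenient than a spatially
constrained surrogate, acknowledged as such. The same seed (hence the same
rotation ensemble) is shared between circuit- and network-level spatial
tests.

Two-tailed p values are `min(1, 2·min(p_upper, p_lower))`. One-sided tails
below 0.10 are refined with a generalized Pareto tail: exceedances over an
adaptively lowered threshold (10 order statistics per step, starting from
the 90th percentile) are fitted by probability-weighted moments and accepted
by an Anderson–Darling test whose null is parametric-bootstrap (B = 60);
if no threshold is accepted — common for heavily tied, discrete null
distributions — the empirical proportion is kept, floored at 1/(n_perm+1).
Extrapolated tail p values are floored at 1e-16. Multiplicity is controlled
by Benjamini–Hochberg at q = 0.05 per sign and per null model, with FDR
flags constrained to the uncorrected flags so the subset invariant holds
even at the lattice corner cases.

A note on discreteness: overlap statistics live on a lattice (counts/n), and
at desk scale most regions host very few extremes, so permutation p values
on thresholded overlap are super-uniform — valid but conservative. The
calibration suite therefore demonstrates exact 5% type-I error on continuous
statistics (per-subject deviation means for the group test, threshold-
weighted scores for the spatial test) and separately asserts that the
discrete-statistic tests never exceed the nominal level.

**Cross-scale contrast.** Δ_circuit − Δ_regional per region, tested by
group-label permutation recomputing both levels per shuffle; positive
significant contrast means case–control differences are larger at the
circuit scale than at the regional scale.

## Synthetic study conditions

The generator defines the study conditions; its defaults are fixed once.
Parcellation: quasi-uniform (golden-angle) points on a per-hemisphere unit
sphere (spin tests only require spherical coordinates), contiguous network
patches by nearest-centre assignment with the 17-network labels nested
inside the 7; every region owns `gray_per_region` jittered grayordinates;
the grayordinate graph is a symmetrised 5-NN graph per compartment, bridged
to exactly one component per compartment. Phenotypes are generated on the
log scale — baseline_j ~ N(6.5, 0.4), age slope −0.004/yr, male offset
+0.08, site offsets ~ N(0, 0.1), site noise SD ~ U(0.08, 0.15), all in log
units — then exponentiated, so the Box–Cox step has real work (λ̂ ≈ 0).
Case deviations are injected in z units through the generator's own noise
scale (a −4 z-unit deficit at a seeded region is a multiplicative
exp(−4·σ_site) shift), with the per-case seed count drawn from a
zero-inflated Poisson (mean 6, 10% structural zeros) and seed locations
uniform (burden-only), confined to regions whose model-implied coupling to a
hub set exceeds its 80th percentile (circuit-convergent), or a fixed list
(region-focal). The FC atlas gives every grayordinate a shared network
latent (weight 0.6), an optional hub latent broadcast to the hub regions'
network (weight 0.5), and unit white noise over T = 200 timepoints for 20–30
subjects.

What the generator does *not* emulate: cortical folding and registration
error, spatially smooth measurement noise, site-by-age interactions,
non-linear lifespan trajectories, heavy-tailed phenotype noise, distance-
dependent FC and BOLD autocorrelation. Passing tests therefore certify the
statistical machinery (calibration, exchangeability, power under the stated
effect sizes), not robustness to those real-data complications.

## Problem sizes and numerical choices

Default analysis/test problem sizes were chosen so the full battery runs on
a single CPU in minutes: 100–200 regions, 3 grayordinates per region,
2,000 permutations for the calibration and dissociation suites (10,000 in
the reference configuration), 500 sign-flip permutations per seed circuit.
Degenerate inputs are handled explicitly: zero-variance batches and seed
time courses are errors naming the offender; zero across-subject FC variance
yields a signed sentinel (capped before TFCE); zero-variance test phenotypes
flag the fit metrics as undefined rather than returning numbers.

## Known limitations

- The empirical-Bayes backend gives approximate (Gaussian) posteriors;
  credible intervals are not MCMC-exact, and coverage is verified only under
  the generator's assumptions.
- The GPD tail re-implementation is compatible with, not bit-identical to,
  the reference permutation-analysis tooling.
- Spin surrogates are exchangeable only on the sphere; subcortical shuffling
  ignores spatial autocorrelation entirely.
- Age enters linearly; no warping or basis expansion (a config hook exists in
  the fit contract but only the linear model is implemented).
- With ≤ 24 held-out controls per cohort the site-leakage diagnostic is noisy;
  interpret single-cohort values only within ±3–4 percentage points.
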