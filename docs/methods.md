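# Methods

`cacyreus` models the distribution of the geranium bronze butterfly
(*Cacyreus marshalli*), an alien species whose larvae develop only on
ornamental *Pelargonium* pots, in an alpine landscape where temperature
falls with elevation and the host plant is confined to villages.  The
package pairs two standard approaches over one synthetic landscape
substrate: a hierarchical N-mixture model of egg abundance fitted to
repeated standardized counts, and a presence-only maximum-entropy
(MaxEnt) suitability model fitted to opportunistic occurrence points.
A scenario engine projects the abundance model under climate-warming and
host-plant-management shifts.

## The egg-abundance model

Latent egg abundance at site *i* follows a count mixture with mean
λ<sub>i</sub> on the log link,

    log λ_i = x_i' β,

where the mixture is Poisson (P), negative binomial (NB, variance
λ + λ²/θ, θ estimated on the log scale), or zero-inflated Poisson (ZIP,
extra mass ψ at zero; ψ is a scalar on the logit scale with no
covariates).  Each of J visits observes a binomial thinning,

    y_ij | N_i ~ Binomial(N_i, p_i),    logit p_i = w_i' α,

with a site-level detection covariate (`pel_ava`, the number of host
pots a surveyor can actually inspect) constant across visits.  The
likelihood marginalizes N_i from max_j y_ij to a truncation bound K:

    L_i = Σ_N g(N; λ_i) Π_j Binom(y_ij; N, p_i).

All computation is in log space.  The gradient is analytic, obtained by
weighting per-N derivatives by the posterior distribution of N_i given
the data; optimization is quasi-Newton (L-BFGS, gradient tolerance 1e-8,
at most 500 iterations) from documented starts (abundance intercept at
log(mean site maximum + 0.5), all other coefficients 0).  Standard
errors come from the observed information (central differences of the
analytic gradient).  Missing visits simply drop their binomial factor.

**Truncation.**  K is chosen adaptively per site: after an interim fit,
each site's bound is raised to the 1−10⁻¹² quantile of its estimated
mixture distribution, and the fit is accepted only when raising every
bound by 50 changes the log-likelihood by less than 1e-8 (bounds are
capped at a configurable maximum, default 8000; a fit that needs more is
flagged non-converged).  Sites are grouped by their bound so that the
(sites × N-grid) arrays stay compact; grouping changes nothing but
runtime.  The likelihood is verified against a brute-force enumeration
oracle to 1e-10 on random small instances for all three mixtures.

**Covariate handling.**  Covariates are screened for collinearity
(greedy Pearson filter, drop at |r| ≥ 0.7: the member of the worst pair
with the larger mean |r| against the other candidates goes first, ties
breaking toward later input order) and then centred and scaled; the
(mean, sd) pairs are stored and reused verbatim when projecting to new
data, so scenario shifts are applied on raw scales and re-standardized
with the training record.

**Model selection.**  The two-step workflow first compares detection
structures (null vs `pel_ava`) with abundance held at the
intercept-only Poisson null, then ranks abundance structures under the
winning detection structure, then refits the winner under P, NB and ZIP.
Ranking uses AICc with n = number of sites (the site is the independent
replicate), computed in exact arithmetic.  A model must lead by more
than 2 AICc units to be declared best outright; within a 2-unit band the
tie is reported and the model with fewest parameters is selected
(parsimony), logged explicitly.  Non-converged candidates are excluded
from rankings and logged.

**Goodness of fit.**  A parametric bootstrap chi-square test: the
statistic is Σ (y_ij − ŷ_ij)²/(ŷ_ij + ε) at the site-visit level with
ŷ_ij = Ê[N_i] p̂_i and ε = 1e-6; each replicate simulates from the
fitted model over the same design, refits the same structure
(warm-started at the parent estimates), and recomputes the statistic.
The p-value is the proportion of bootstrap statistics at or above the
observed one; the overdispersion factor ĉ is the observed statistic over
the bootstrap mean.  When ĉ > 1 the variance matrix is multiplied by ĉ
(standard errors scale by √ĉ); no deflation is applied below 1.  A
warning is emitted above ĉ = 2 (an implementation choice: at that level
the inflated intervals double, which we treat as weak robustness).  The
default is 1000 replicates; the type-I calibration study in the test
suite uses 200 per test at 40 sites, 500 outer simulations.

## The presence-only suitability model

MaxEnt estimates the relative occurrence rate (ROR): a Gibbs density
exp(η(x))/Z over cells, with η built from linear and quadratic features
of min–max scaled covariates (hinge features are omitted for determinism
and small-sample stability).  Background (pseudo-absence) cells are
sampled uniformly within 2.5 km of any presence — a 10-cell radius on
the 250 m grid, distances between cell centres — which confines the
contrast to the accessible, bias-affected landscape; 1000 background
cells by default.  Weights maximize the penalized log-likelihood over
the presence+background set with an L1 penalty per feature
(multiplier × presence-feature sd / √n_presences) by coordinate-wise
damped Newton ascent with soft thresholding; a halving line search makes
every step monotone in the penalized gain.

Percent contribution accumulates the positive gain increments of each
update, pooled by parent covariate and normalized to 100.  Permutation
importance is the AUC drop (presences vs background scores) when a
covariate's values are permuted, averaged over 3 permutations and
normalized to 100.  `raw` output is the density normalized over the
training presence+background set (sums to 1 there); `cloglog` maps it to
[0, 1] as 1 − exp(−e^H · raw) with H the entropy of the raw training
distribution.  Evaluation uses repeated 80/20 splits of the presences
(100 replicas; background re-drawn and split per replica; the threshold
maximizes training TSS and is applied to the held-out split).  The
full-data TSS is computed within-sample and labelled as such.

## The scenario engine

Scenarios shift raw covariates — +1.5 °C on annual mean temperature
(the mid-century Alpine projection under a low-emission pathway) and/or
a 50% multiplier on host-plant pots — then re-standardize with the
training record and recompute Ê[N] per cell.  When the pot field is
scaled and the grid topology is loaded, the neighbouring-pot covariate
is recomputed from the scaled field (a flag allows direct multiplication
instead; for a uniform multiplier the two coincide because the
neighbour sum is linear).  Projection is restricted to pot-bearing cells
by default (the butterfly is host-obligate; a flag projects everywhere).
Changes are classified on expected counts rounded half-up to whole eggs
— eggs are integers, and rounding keeps float drift from manufacturing
spurious changes — into increases, decreases and no change (a
partition), with "new infestation" (rounded 0 → ≥ 1) reported as a
sub-category of increases.  Summaries by municipality use the grid-wide
mean elevation of each municipality and are sorted ascending;
elevation profiles are equal-width binned means (no smoothing, no
trimming).

## The synthetic landscape and survey generator

The generator emulates the study conditions rather than any particular
real valley: a 250 m grid whose elevation ramps 500–2000 m across rows
with mild roughness; bio01 (annual mean temperature) following a
6.5 °C/km lapse from a 13 °C sea-level reference — by default with no
spatial noise, so temperature is a strict function of elevation; bio04
(seasonality) with a weak elevation trend plus independent noise, kept
well below the 0.7 collinearity threshold against bio01; woodland,
ecotone and grassland fractions from per-cell Dirichlet draws with
woodland thinning above the treeline.  Villages grow as contiguous
patches (about 5 cells) from seeds placed preferentially at low
elevation (e-folding 1200 m, none above 1950 m), covering ~25% of cells.
Only village cells hold *Pelargonium* pots (80% of them do); per-cell
counts are Gamma-mixed Poisson, at least 10, with a mean that rises with
elevation so the pot-richest squares sit in high tourist villages — the
pattern real pot censuses in alpine parks show, and the configuration in
which warm cells do not co-occur with extreme pot counts (which would
make expected abundance explode under the positive
temperature × host-plant interaction).

The survey design stratifies three 500 m altitudinal bands, samples 25
cells per band uniformly at random (an "open area or village"
eligibility filter is available and on by default in the pipeline) and
plans 3 visits per cell: 75 cells, 225 site-visits.  Counts are drawn
from the exact hierarchical process the model assumes, with the default
truth a ZIP (ψ = 0.5) whose coefficients are strong positive temperature
and host-plant effects, a positive synergistic interaction, a negative
neighbouring-pots effect, and low detection improving with accessible
pots (per-visit detection ≈ 0.07 at the average site).  The detection
covariate is a binomial thinning of the pot count by a site-specific
Beta(2, 2) accessibility fraction — accessibility genuinely varies
between villages, and making it site-specific keeps `pel_ava` from being
a near-copy of `pel_abu`.  Opportunistic presences are sampled with
probability proportional to expected abundance times an accessibility
bias factor (higher in urban and low-elevation cells), presence-only.

**What the generator does not emulate:** spatial autocorrelation in
counts beyond what covariates induce, observer heterogeneity between
visits, open-population dynamics within a season, imperfect
georeferencing of opportunistic records, and real GIS layers.  Passing
tests therefore demonstrate correctness of the estimation and projection
machinery under the model's own assumptions, not robustness to their
violation in field data.

## Simulation-study sizes and known limitations

The test suite's simulation studies use: parameter recovery at 300
sites × 3 visits × 200 count replicates on one fixed landscape/design;
selection structure recovery over 50 replicates at the same scale;
goodness-of-fit type-I calibration at 40 sites with 200 bootstrap
replicates over 500 outer simulations; MaxEnt checks on constructed
separable landscapes.  These sizes give Monte-Carlo standard errors
small enough for the asserted bands while keeping the default test run
short.

A known, documented limitation: with per-visit detection near 0.07 and
three visits, the binomial N-mixture likelihood has a nearly flat ridge
along which λ is inflated and p deflated jointly.  Covariate effects
(slopes, interaction, zero-inflation) are estimated essentially
unbiasedly with near-nominal Wald coverage at 300 sites, but the two
intercepts acquire a positive (abundance) / negative (detection) median
drift of roughly half a unit with Wald coverage near 0.83, and a few
percent of replicates have effectively divergent maxima (they hit the
truncation cap and are flagged non-converged).  This is the well-known
weak-identifiability regime of N-mixture models at low detection, not a
defect of the optimizer: the likelihood is verified against enumeration,
and the drift shrinks with the number of sites as consistency of the
maximum-likelihood estimator predicts.
Inference on intercept-scale quantities (absolute expected abundance)
from sparse-detection designs should be treated with caution; ranking,
covariate inference and scenario contrasts are unaffected because they
depend on the well-identified product and slope structure.
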