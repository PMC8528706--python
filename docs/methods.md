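# Methods

This note documents the models, estimators, defaults and numerical choices in
`ecoaxes`, and what the synthetic-data validation does and does not show.

## Per-site functional properties

All estimators consume a half-hourly flux table (NEE, GPP, LE, H, T_air, VPD,
SW_in, and optionally R_n, G, u*, u, P, CO2, pressure, transpiration) after
quality filtering (flags 0 = measured and 1 = good gap-filled are kept;
`qc_max_flag` configurable).

**Shared filters.** The growing season is defined per day from daily-mean GPP
smoothed with a 15-day centred running mean: a day is in season when the
smoothed value exceeds q05 + 0.30·(q95 − q05). The q05/q95 amplitude (rather
than min/max) makes the rule robust to outlier days; a flat seasonal cycle
(amplitude < 0.1 µmol m⁻² s⁻¹) puts every day in season. The dry-daytime
filter retains half-hours with SW_in > 200 W m⁻², no precipitation in the
trailing 24 h (48 half-hours strictly before the current one, and the current
one itself dry; disabled with a warning when no precipitation column exists),
and an in-season day. One mask serves G1, uWUE, Gs_max, ET_max and EF.
Quantiles everywhere are linear-interpolation sample quantiles (numpy
default, R type 7).

**Light response.** GPP = αQβ/(αQ + β) is fitted by bounded
Levenberg–Marquardt in 5-day moving windows (stride 1 day, ≥ 20 daytime
points, PPFD = 2.3·SW_in: 0.5 PAR fraction × 4.6 µmol J⁻¹). Windows whose
GPP–light correlation is non-positive (no usable curvature, e.g. constant
GPP) are rejected. Each window is summarised by the curve value at Q = 2000
µmol m⁻² s⁻¹; GPP_sat is the 90th percentile over ≥ 10 windows.

**Respiration.** Night is SW_in < 20 W m⁻². Because the flux product's
night-time partitioning defines GPP ≡ 0 at night, the respiration proxy is
NEE + GPP, which is robust to twilight half-hours with residual light. The
temperature sensitivity E0 of the Lloyd–Taylor curve
R = Rb·exp(E0(1/(T_ref−T0) − 1/(T−T0))) (T_ref = 15 °C, T0 = −46.02 °C) is
estimated by profile least squares: the basal rate is free to differ between
days (it tracks productivity and phenology) while E0 is shared, and for fixed
E0 each day's optimal Rb has a closed form, leaving a 1-D bounded
minimisation for E0 (clipped to [50, 400] K). A single whole-series (Rb, E0)
fit would alias the seasonal Rb cycle into a biased E0 — on synthetic data
the bias reaches tens of K. Identifiability requires ≥ 100 night points and
≥ 5 °C of temperature range. Daily Rb_d is then re-fitted in 5-day windows
(≥ 10 points) with E0 fixed; this one-parameter problem is linear and solved
exactly. Rb is the mean and Rb_max the 95th percentile of Rb_d; aCUE is the
median over in-season days of 1 − Rb_d/GPP_d, with a GPP_d floor of 0.5
µmol m⁻² s⁻¹ against division blow-ups.

**Conductances.** Aerodynamic conductance uses the empirical form
G_a = 1/(u/u*² + 6.2·u*^(−0.67)). Surface conductance inverts
Penman–Monteith,

    G_s = LE·G_a·γ / (Δ(R_n − G − S) + ρ·C_p·G_a·VPD − LE(Δ + γ)),

with Δ from the Tetens saturation curve, γ = C_p·p/(ελ),
λ(T) = (2.501 − 0.00237·T)×10⁶ J kg⁻¹, ρ from the ideal gas law, S = 0 and
G = 0 when absent. VPD is in kPa here (tables store hPa). Inversions with a
non-positive denominator are unphysical and become missing; their fraction is
reported in diagnostics. Forward and inverse forms are algebraically exact
inverses, verified to 1e−8 relative error over a 10⁴-point grid.

**Water-use efficiency.** The Medlyn model
Gs_mol = 1.6(1 + G1/√VPD)·GPP/Ca (Gs converted from m s⁻¹ via the molar air
density, Ca from the CO2 column or 400 µmol mol⁻¹) is linear in G1, so the
stated nonlinear regression has the exact least-squares solution; G1 is
truncated at 0. uWUE = median of GPP·√VPD/ET with VPD in hPa (the convention
flux products print); ET = LE·1800/λ(T) in mm per half-hour. WUE_t = mean
annual GPP (gC m⁻² d⁻¹, 12.011 gC/mol) over mean annual transpiration
(kg m⁻² d⁻¹), missing when no transpiration product is supplied.

**Energy partitioning.** Daily daytime EF = mean(LE)/(mean(H)+mean(LE)) over
dry-daytime half-hours (≥ 3 per day, non-positive available energy dropped);
EF is the mean and EF_ampl the IQR of the daily values. ET_max and Gs_max are
the 95th/90th percentiles of masked ET and G_s.

## Synthetic data

The generator exists to make every estimator testable by parameter recovery;
it forward-models exactly the process forms the estimators invert, plus
realistic nuisance structure.

Drivers: shortwave radiation from solar declination and hour angle scaled by
an AR(1) daily cloud factor in [0.25, 1]; air temperature = raised-cosine
seasonal cycle (−2 to 18 °C at 45° latitude) + 5 °C diurnal cycle lagging
solar noon + AR(1) noise; relative humidity declines with temperature and
rises after rain, VPD via Tetens; precipitation as clustered events
(Bernoulli starts, geometric spell length of mean 6 half-hours, exponential
depths of mean 0.8 mm — both wet and dry 24-h look-backs occur); wind AR(1)
around 2.5 m s⁻¹ with u* = 0.15·u.

Fluxes: GPP from the rectangular hyperbola with a raised-cosine annual cycle
on β; Rb_d = rb15·(0.4 + 0.6·ḡ₇/mean(ḡ₇)) where ḡ₇ is the 7-day trailing
mean of daily GPP (respiration tracks recent productivity); Reco by
Lloyd–Taylor; NEE = Reco − GPP; G_s by Medlyn (VPD floored at 0.05 kPa only
inside 1/√VPD); LE by forward Penman–Monteith with R_n = 0.85·SW_in − 35 and
G = 0.1·R_n; H = R_n − G − LE (closure exact in noiseless mode; negative
night-time LE is kept — clipping would break the inversion identity). A
TEA-like transpiration column is 0.65·ET. Optional multiplicative noise
(1 + ε), ε ~ N(0, 5%) truncated at −0.95, applied independently to NEE, GPP,
LE and H. "Generator-implied truths" for recovery tests are: the 90th
percentile over days of the light curve at Q = 2000, the mean of the
generated Rb_d series, the input E0 and G1, and uWUE/EF evaluated from the
noiseless forward run under the same dry-daytime mask the estimators use.

Ensembles (defaults chosen once as representative of flux-network synthesis
studies): `latent3` draws three independent standard-normal site factors
mixed into twelve standardized EFPs through a fixed block mixing matrix
(blocks of four EFPs with weights 1.0/0.9/0.8) plus N(0, 0.5) noise, mapped
to physical units by fixed per-EFP location/scale; `rf_drivers` draws nine
plausible site covariates and makes factor 1 equal 1.2·z(LAI_max) +
0.9·z(AGB) + N(0, 0.35) — all other covariates, including precipitation,
have exactly zero effect on it; `icp_scm` labels sites E1/E2, shifts the
distributions of LAI_max, T_air and VPD between environments, generates the
response y = 0.9·LAI_max + 0.35·T_air + N(0, 0.8) with an
environment-invariant mechanism, and makes AGB a child of both y and the
environment (so sets containing AGB are never causally sufficient). Site ids
carry country prefixes and PFTs consistent with the environment so the
metadata-based assignment recovers the generating labels. Covariates are
drawn with weak realistic dependence (canopy height on biomass, soil-water
index on precipitation and VPD) — strong collinearity would make permutation
importance non-identifiable, which is a property of the estimand, not the
estimator.

What passing these tests shows: the estimators are unbiased and stable under
the generator's idealised conditions (correct model forms, stationary
parameters, complete records, well-behaved noise). What they do not show:
robustness to gaps and u*-filtering artefacts, storage-flux and
energy-balance-closure errors, instrument drift, or model misspecification
(e.g. non-hyperbolic light responses) in real eddy-covariance data.

## Axes, importance, causal screening

**PCA.** Columns are z-transformed (ddof = 1, complete-case rows with the
drop count recorded); the SVD gives eigenvalues of the correlation structure,
unit-norm loadings (sign convention: the largest-magnitude loading of each
component is positive), scores = Z·V, contributions = 100·loading².
Dimensionality is tested by comparing each observed eigenvalue with the 95th
percentile of eigenvalues from column-wise independently permuted data
(499 permutations by default); the count of the leading run of significant
components is reported. This permutation test is a stand-in with the same
purpose as published dimensionality tests whose exact procedure is not
reproducible from the available description. Loading significance combines
the bootstrapped-eigenvector method (sites resampled with replacement,
components matched and sign-aligned to the original by maximal absolute
loading correlation, 95% percentile CI excluding 0) with the magnitude
threshold |loading| > 1/√p.

**Predictive importance.** A random forest (1000 trees by default) regresses
axis scores on the nine covariates (complete-case, ≥ 30 sites). %IncMSE is
computed per tree: out-of-bag rows are identified by re-deriving the tree's
bootstrap sample, and the importance of a covariate is the mean relative
increase in OOB MSE when that column is permuted (×100), unscaled by its
standard error. Partial dependence averages predictions over the empirical
distribution of the other covariates on a 5th–95th-percentile grid; 2-D
grids are masked outside the convex hull (Delaunay test) of the training
pairs to prevent extrapolated readings. Group contrasts use one-way ANOVA
effect size η² = SS_between/SS_total and Tukey HSD (statsmodels) rendered as
a compact letter display via the insert-absorb algorithm.

**Invariance screening.** Environments: E1 = forest PFTs (DBF, DNF, EBF,
ENF, MF) in North America, Europe or Asia (continent from the site-code
country prefix via a bundled table); E2 = all other sites. For each of the
511 non-empty covariate subsets, a regressor (random forest, or an additive
cubic-spline model built from per-covariate B-spline bases with linear
extrapolation and a light ridge penalty) is fitted on a stratified 80% of
sites; held-out residuals are compared across environments with a Welch
t-test (location) and Brown–Forsythe test (variance), Bonferroni-combined,
p = min(1, 2·min(p_loc, p_var)). The 80/20 split is deliberate: the
regressor's estimation error concentrates in environment-specific covariate
regions and is shared across held-out points, so a 50/50 split inflates the
location test's size under covariate shift; a small test fold keeps the
fit-error term well below the two-sample standard error (with 50/50 the
false-rejection rate of a true parent set roughly doubles in our
simulations). Subsets with p > α are accepted; their intersection is the
invariant-causal-prediction estimate, with flags for degenerate (single)
environments and for the no-invariant-subset case. The additive-spline
regressor is the recommended choice when the response surface is smooth;
tree ensembles carry boundary bias into the residual tests and are better
reserved for strongly non-additive responses.

**Interventional importance.** For a set S, m(x_S) is the mean prediction
with S clamped to x_S and the remaining covariates drawn from their
empirical product marginal (independently permuted columns, 200 draws);
importance(S) = Var(m) over the observed x_S values, normalized so the nine
single-variable importances sum to 1. Groups: structure = {LAI_max, AGB,
H_c, N%}, climate = {T_air, VPD, SW_in, P, CSWI}. Clamping to observed
values makes the measure invariant to units.

## Problem sizes in tests and the acceptance script

Simulation sizes are chosen to probe each property at the smallest scale at
which it is statistically decisive: noiseless recovery on one 3-year site;
noisy recovery over 8 seeds (tests) or 6 (script) at 1 and 3 years; PCA
recovery over 30/20 replicates of 60 sites; importance recovery over 20/12
replicates of 100 sites; invariance level over 300 null simulations of 120
sites; ICP parent recovery over 12/10 replicates of 400 sites with the
additive-spline regressor and 80/20 splitting. Acceptance thresholds are
never adjusted to the replicate counts.

## Known limitations

* The CSWI is a capped bucket recursion (capacity 5 mm, initialised full) —
  a clearly labelled stand-in for more elaborate published water-balance
  indices; only its relative ordering across sites should be interpreted.
* The LaThuile column dialect beyond NEE/GPP_f is reconstructed from common
  usage and may need adjustment for specific releases.
* E0 estimation assumes the basal rate is constant within a calendar day;
  sub-daily Rb variation (e.g. pulse responses to rain) would bias it.
* The invariance test compares only residual location and spread; it is
  blind to higher-moment or dependence changes across environments.
* No gap-filling, u*-threshold estimation or energy-balance-closure
  correction is performed; inputs are expected to be a processed flux
  product.
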