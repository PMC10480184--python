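# Methods

This package reimplements, as one tested pipeline, the analysis chain used to
quantify molecular mobility in living cells by combining single-particle
tracking (SPT) with fluorescence correlation spectroscopy (FCS). Everything
runs against a synthetic-data module that emulates the two experimental
systems involved: a bead benchmark (fluorescent microspheres in water/glycerol
mixtures of known viscosity) and a nuclear-polymerase-like mixture of mobility
classes. No real microscope data are consumed; the purpose is a reproducible,
fully seeded account of what the analysis chain does and how well it recovers
known ground truth.

## Synthetic data

**Bead conditions.** Ground-truth diffusion coefficients follow
Stokes–Einstein, D = kT/(6πrµ), with the CODATA Boltzmann constant, T =
310.15 K by default (samples held at 37 °C) and the water/glycerol viscosity
table (0.8–27.8 cP for 0–80% glycerol by weight). The published reference
table for 40 nm and 100 nm beads sits ~6% above this direct evaluation at
every viscosity — a constant factor consistent with slightly different
constants or temperature on the original side. We treat the formula as
canonical and the published numbers as reference values with 10% relative
agreement (looser only where their printed precision is coarser, e.g. a
single-digit 0.2 µm²/s); the table's internal radius ratio (2.5×) and
viscosity scalings are exact for the formula.

**Trajectories.** 2D positions at 100 Hz (Δt = 10 ms) with independent
Gaussian steps of per-axis variance 2DΔt, plus independent localization noise
of σ = 50 nm per coordinate per frame. Track lengths are drawn from a shifted
geometric law — the memoryless photobleaching model — with mean 20 detections,
truncated at 11, matching the ">10 detections" selection and the observed
mean of ≥20. Subdiffusive and superdiffusive tracks are fractional Brownian
motion per axis with Hurst exponent H = α/2, scaled so the 2D ensemble MSD is
4D_ατ^α; the fGn sampler uses Davies–Harte circulant embedding (exact
covariance; a Cholesky fallback guards numerically indefinite embeddings) and
α = 2 is handled as the ballistic limit. Mixtures subsample several labelled
sets without replacement, honoring requested fractions within ±1 track.

**FCS traces.** Point emitters perform 3D Brownian (or fractional Brownian)
motion in a periodic 3×3×6 µm box around a Gaussian detection profile
exp(−2(x²+y²)/w0² − 2z²/z0²); the number of molecules in the box is set so the
expected occupancy of the effective volume V_eff = π^{3/2}w0²z0 equals the
requested N, which fixes the fluctuation-ACF amplitude at G(0) ≈ 1/N. Photon
counts per bin are Poisson with rate = brightness × Σ profile. The Brownian
path is advanced bin by bin (exact Gaussian increments) by a fused
numba kernel fed with bulk float32 normals from an SFC64 generator — the
default 60 s / 10 µs-bin trace involves ~4.5×10⁹ increments and runs in about
a minute; positions are held in float64. Periodic wrap-around re-entry
preserves mean occupancy, and the box leaves ≥6 beam waists of lateral
clearance so a molecule and its periodic image are never both visible.
Profile contributions below e⁻¹⁶ are truncated. Anomalous traces materialize
whole fGn paths and are intended for shorter durations.

**What the generator does not emulate.** No camera images or PSFs, no
detection/linking errors (track identities are perfect), no motion blur, no
dye blinking/triplet kinetics, no instrument afterpulsing, and no tracking
saturation — the experimental SPT plateau near 4 µm²/s is an
instrument/tracker property and is deliberately absent. Passing tests
therefore validate the analysis chain, not the detection stack upstream of it.

## Per-trajectory MSD analysis

The time-averaged MSD uses all overlapping pairs:
TA-MSD(nΔt) = ⟨|r(t+nΔt) − r(t)|²⟩_t. Two per-track estimates follow.

**D_60ms.** A linear fit of the MSD until τ = 60 ms (points 2–6 at 100 Hz),
excluding the first lag point, which is dominated by the static localization
error. The localization offset is handled as a *fixed* intercept: the known
4σ² is subtracted and the slope fitted through the origin, with lags weighted
by the inverse relative TA-MSD variance for overlapping pairs,
var[MSD(n)]/MSD(n)² ≈ (2n²+1)/(3n(N−n+1)). On tracks of ~20 detections this
roughly halves the estimator spread (per-track SD of log10 D drops from ~0.37
to ~0.17) relative to an unweighted free-intercept OLS, eliminates negative
estimates, and keeps the median within ~6% of truth — the difference between
the two-population benchmark resolving or collapsing. A free-intercept,
unweighted mode remains available for data whose localization error is
unknown. D_60ms = slope/4.

**Anomalous exponent.** α is the slope of ln MSD vs ln τ over the first third
of the curve (minimum 3 points), again excluding lag 1; D_α = e^intercept/4
(the natural-log convention; any log base gives the same D_α when inverted
consistently). The constant noise offset is *not* subtracted here, so α
carries a mild downward bias at low D where 4σ² is comparable to the signal;
on Brownian benchmark tracks the mean fitted α is ~0.88–0.91 with SD ~0.4 —
the irreducible cost of 3–6-point log-log fits on short tracks.

**Immobile class.** Tracks with D_60ms < 5×10⁻³ µm²/s are labelled immobile
(threshold strict; the published figure prints inconsistent units for this
threshold, and µm²/s is the only reading consistent with the D_60ms unit).
Note the threshold sits *inside* the slope-noise floor of short tracks
(SD ≈ 0.02 µm²/s), so only ~60% of truly static tracks fall below it while
genuinely mobile tracks (D ≥ 0.5) essentially never do: the classifier is
specific but not sensitive, and measured immobile fractions understate the
true immobile share at these track lengths.

**Detection density maps** histogram all localizations into pixels, the
projection used to visualize oversampling: a fast molecule revisiting a
subdomain raises its detection count with no static accumulation.

## Population model

Per-track (log10 D_60ms, α) pairs form the feature table; immobile and
unfittable tracks are excluded and reported as a separate fraction. Gaussian
mixtures with full covariances are fitted by EM (scikit-learn; regularization
1e-6 on the diagonal, tolerance 1e-6, ≤500 iterations, best of 10 k-means++
initializations, all seeded). The joint 2D fit is the default — the published
population contours are drawn in the joint plane — with the 1D marginal
available by selecting a single feature column. BIC = −2lnL + p·ln n and
AIC = −2lnL + 2p with p = (k−1) + 2k + 3k.

**Choosing k.** The number of populations is the inflection point of the
criterion curves: among k whose criterion improved over k−1, the k of maximal
discrete second difference (curvature); BIC and AIC are evaluated separately
and the smaller k wins, biasing toward parsimony. A guard keeps k ≤ n/5.
With no improving k the selection is 1.

**Proportion reliability.** Mixture weights are maximum-likelihood under a
Gaussian component model that the features only approximate: per-track
estimates from 11–60-detection tracks are heteroscedastic, so each true
population is a scale mixture with heavier-than-Gaussian tails. At the
benchmark separation (log10 3.6 − log10 1.28 ≈ 0.45, component SD ≈ 0.17) the
EM weights for a 50:50 mixture carry a median maximum relative error of
~13% across seeds — a misspecification bias, not an optimization failure
(truth-initialized EM converges to the same solution) and not an estimator
problem (estimators at the information floor change little). Idealized
Gaussian clusters at the same separation would be recovered within ~5%.
The model therefore also reports hard max-posterior assignment fractions
next to the EM weights; they are a few points more robust here. Component
centers, by contrast, are recovered to within a few hundredths in log10 D.

## FCS analysis

The multi-tau correlator computes G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩² with 16 linear
channels in the first octave and half-octaves thereafter, doubling the bin
width by pairwise averaging; symmetric normalization (separate means over
leading/trailing segments) keeps the estimate unbiased under slow drifts.
Traces whose 1 s-binned intensity shows a fitted fractional decay >20% with a
significantly negative slope (p < 0.01) are excluded as photobleaching — the
quantitative thresholds are this package's choice for a qualitative published
rule.

Model fitting minimizes squared residuals with the trust-region-reflective
algorithm (scipy.optimize.least_squares) over

    normal:     G(τ) = (1/N)·(1+τ/τ_D)⁻¹·(1+(w0²/z0²)(τ/τ_D))^(−1/2)
    anomalous:  G(τ) = (1/N)·(1+(τ/τ_D)^α)⁻¹·(1+(w0²/z0²)(τ/τ_D)^α)^(−1/2)

with N > 0, τ_D > 0, α ∈ (0.1, 2]; the anomalous model at α = 1 equals the
normal model identically. The structure parameter (w0/z0)² is fixed from
calibration by default (a free-structure mode exists). Fits use lags from
10 µs to duration/100, excluding the first two correlator channels, where
real detectors afterpulse; no triplet term is modelled, matching the
diffusion-only equations (and the simulator emits no blinking). Per-lag
inverse-variance weights are applied when uncertainties are supplied,
otherwise fits are unweighted. N = 1/G(0); with a calibration dye of known D
and concentration, w0 = √(4Dτ_D), z0 from the structure parameter, and
V_eff = 1/(G(0)·N_A·c); concentrations follow from N/V_eff.

## Cross-method unification

Anomalous diffusion coefficients carry α-dependent units, so SPT and FCS
results are mapped to a transit time Tt (s/µm³): the published work states
this metric conceptually (isotropic exploration of a reference volume) but
never prints its formula, and no single power-law convention reproduces all
its printed (D, α, Tt) triplets. This package defines, and documents in its
outputs: τ = (L²/6D)^{1/α} with L = V_ref^{1/3} (the isotropic 3D MSD
crossing of the reference length), Tt = τ/V_ref, V_ref = 1 µm³ — dimensionally
consistent and strictly monotone in D, used only to compare the two methods'
sensitivity windows (the comparison report flags overlap when the slowest
SPT transit time fails to exceed the fastest FCS one). No published Tt value
is reproduced or asserted. Populations whose fitted α is below 0.1 (noise-
floor clusters) get no transit time rather than an absurd power-law inversion.

The molecule budget splits a total density (default 37 molecules/µm³) into an
FCS-detected fraction and SPT classes: percent-of-total = class fraction ×
(1 − FCS fraction) × 100, density likewise; rounded values (half away from
zero) are reported beside exact ones, and class densities sum to the
SPT-observable density to 1e-12 before rounding.

## Problem sizes and numerical choices

The test suite and the acceptance script use the study's stated conditions:
500 tracks per bead condition (1000-track mixtures), 20 replicate seeds for
proportion recovery, and one 60 s / 10 µs-bin FCS trace. Every random stage
derives its stream from an explicit seed (numpy SeedSequence spawning); two
runs with the same seed are bit-identical. Reduced-size workflow tests note
where behavior differs at small n (the inflection rule may report 3 instead
of 2 populations at 150 tracks/condition). EM uses a 1e-6 covariance floor;
the fGn embedding falls back to Cholesky with 1e-12 jitter; MSD fits flag
(rather than extrapolate) tracks with too few usable points.

## Known limitations

* Proportion estimates, not centers, are the weak point of the mixture stage
  (see above): ~13% median maximum relative weight error at the benchmark
  separation, against ~10% reported for the original workflow's best case.
* The immobile classifier's sensitivity is ~60% at the stated threshold and
  track lengths; downstream immobile fractions inherit this.
* α estimates from short tracks are noisy (SD ≈ 0.4) and biased low at low D
  by the unsubtracted localization offset.
* The anomalous-trace simulator holds whole fGn paths in memory; long traces
  are only practical for the Brownian kernel.
* The pipeline assumes contiguous frames (no gap closing) and 2D tracks.
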