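# Methods

This note records the models, estimators and numerical choices behind
`dicsnet`, and what the synthetic-data validation does and does not show.

## Generative model (synthetic cohorts)

Source activity is an order-p multivariate autoregressive (MVAR) process
over a small set of fixed dipoles,

    x_t = Σ_{r=1..p} A_r x_{t-r} + u_t ,

whose off-diagonal coefficients define the ground-truth directed graph.
Band-limited rhythms are produced by shaping each source's innovation with
a resonant AR(2) (poles at radius `exp(-π·bw/fs)` and angle `2π·f0/fs`),
so the entire generator remains one linear system with analytically known
partial directed coherence; a `None` profile leaves the innovation white,
which the oracle tests use (e.g. the AR(1) lag-1 autocorrelation check).
Stability (companion spectral radius < 1) is asserted, not assumed.
A burn-in of `10·p·fs` samples is discarded.

Sensor data are `Σ_s l(pos_s, ori_s)·x_s(t)` plus additive noise scaled to
a broadband SNR. The noise is pink (1/f) by default: resting-EEG
background is approximately 1/f, and white noise at EEG sampling rates
would park ~90% of its power above 30 Hz, where it is indistinguishable
from muscle artifact by spectrum alone. Defaults mirror the study
conditions: 4 sources, p = 5, 128 sensors at 1024 Hz, 2-minute recordings
(a desk-scale stand-in for 7-minute sessions), 25 subjects per group,
10 dB SNR. Behavioral scores are a stored linear map of the true coupling
magnitudes plus Gaussian noise (SD 3 standard-score points), clipped to
each group's CELF range (high-language ≥ 100, low-language ≤ 85); all
randomness descends from one master seed via
`SeedSequence([master_seed, subject_index])`.

What the simulator does *not* emulate: nonstationary coupling beyond
piecewise-constant coefficients, head movement, electrode drift,
implant-device artifacts, or realistic anatomy. Passing tests therefore
demonstrate correctness of the estimators under the stated linear model,
not clinical validity on measured EEG.

## Preprocessing

Zero-phase (forward-backward) Butterworth filtering was chosen because
phase distortion would bias the lagged MVAR estimates downstream; the
stated filter orders refer to a single pass. "Visible artifact" screening
is automated as |amplitude| > 500 µV or a ≥ 0.1-s flatline. ICA runs on
PCA-whitened concatenated epochs; FastICA is the default decomposition
(MNE's extended infomax is available but roughly an order of magnitude
slower at equal separation quality on this class of data). Components are
auto-labelled: line (≥ 60% of power within ±1 Hz of 60/120/180 Hz), then
muscle (> 60% of power above 30 Hz), then eye (|correlation| > 0.7 with a
frontal-channel proxy). Muscle is tested before eye because
lateral-frontal muscle bursts leak into the frontal proxy. These
thresholds are a reproducible stand-in for expert review and are
configurable. Residual-artifact interpolation flags samples beyond 5
robust SDs and bridges them with a cubic spline; a cubic cannot follow a
half-cycle excursion, so reconstruction error is small only for gaps well
below half the period of the dominant rhythm (measured: < 5% of amplitude
for a 30-ms gap in a 10-Hz sine, ~20% for a 50-ms gap). Average reference
is applied last; the orchestrator asserts the stage order.

## Spectral estimation

DPSS multitaper with NW = 2, K = 3 by default (K ≤ 2NW−1 enforced);
1000-ms windows and 50-ms steps give 1-Hz bins and ~50-ms frames (the hop
is quantized to the sample grid, 51 samples at 1024 Hz). Power is a
one-sided density (µV²/Hz), so band sums approximate signal variance
(Parseval check in the tests). Band edges are lower-inclusive,
upper-exclusive; delta 0.5–4, theta 4–8, alpha 8–12, beta 13–30, gamma
30–100 Hz; DC is excluded from band power. The peak detector slides a
three-point window: the center must exceed both neighbors and both side
differences must stay below 2 SDs of the band's first differences (a
prominence guard whose reference population — the band's own
first-difference distribution — is our reading of an ambiguous rule); the
highest surviving candidate wins.

## Forward model

The head is three concentric spheres (71/79/85 mm; 0.33/0.0042/0.33 S/m —
classic literature values). Per harmonic order the five shell
coefficients solve continuity of potential and radial current plus a
no-flux scalp condition; because that algebra is independent of the dipole
position, the gains `g_n` are solved once per head model (homogeneous
limit `(2n+1)/n`, verified). The series over harmonics is truncated when
terms fall below 1e-8 of the running sum (cap n = 300). A single series
evaluation per voxel yields all three orientation columns. Sensors are
projected radially onto the scalp; lead-field columns are average-
referenced. The independent oracle in the tests integrates each
harmonic's radial boundary-value problem numerically (scipy `solve_bvp`,
skull and scalp as a coupled smooth two-domain system) and agrees with the
analytic gains to 1e-6, and with the summed potential to well under 1% for
a tangential dipole at 70% eccentricity. Outputs use model head
coordinates (mm); the exported "MNI-like" affine is a documented stub, not
a registration.

## Beamforming and the iterative coherent-source search

DICS operates on the band cross-spectral density averaged over epochs,
tapers and band bins (its diagonal equals multitaper band power by
construction). LCMV weights use `C_λ = C + λ·mean_eig·I` with λ = 0.05 by
default and the power-maximizing orientation from the 3×3 projected
eigenproblem.

Three numerical findings shaped the search implementation:

- **Extraction uses matched filters.** Unit-gain minimum-variance weights
  actively cancel any source coherent with the target (measured: an
  adaptively extracted reference retained coherence 0.006 with a truly
  coupled source whose real coherence was 0.34). Since pooled reference
  signals and connectivity inputs exist precisely to carry that coherence,
  they are extracted with the unit-gain matched filter `w = l/(lᵀl)` at
  the DICS-optimal orientation; adaptive weights are retained for
  localization maps, where cancellation sharpens rather than destroys.
  The price is instantaneous leakage between sources, which the
  time-reversal check downstream is designed to flag.
- **Deflation projects the lead field too.** "Treating a found source as
  noise" is implemented as rank-1 projection of its topography out of
  data, spectra and CSD; the lead field must be projected identically,
  otherwise the next scan satisfies its unit-gain constraint in the
  projected-out direction (cheap under regularization) and the coherence
  map collapses.
- **The first-iteration surrogate re-adapts per permutation.** The
  statistic is the maximum beamformer power over the grid; with weights
  fixed from the observed CSD, surrogate values systematically exceed the
  observed one (adaptive weights minimize the observed variance), so the
  same adaptive functional is re-evaluated on every per-channel
  epoch-shuffled CSD — exchangeable with the observed statistic under the
  no-source null. Later iterations test the maximum coherence to the
  reference with the reference's epochs permuted.

The candidate at each iteration must exceed the 99th percentile of its
1000-permutation surrogate distribution (counts configurable). Clusters
are voxels within one grid spacing of the peak at ≥ 90% of its map value;
pooling weights are proportional to each voxel's band power, normalized to
sum 1, after sign alignment to the cluster's first principal component
(overall polarity is canonicalized to the highest-weight voxel — EEG
source polarity is arbitrary). The first source is found by power and its
reported amplitude is its (unit) coherence with its own pooled reference;
subsequent amplitudes are genuine coherences to that reference, enforced
decreasing.

## Time-varying MVAR and TPDC

The dual filter runs two Kalman filters per sample: a state filter
propagating the companion-form AR model (process noise = the innovation
covariance from an initial least-squares fit; observation noise r = 0.01
on standardized signals) and a parameter filter treating each channel's
coefficient row as a random walk (process noise q = 1e-4, initial
covariance 0.1·I, block-diagonal per channel) regressed on the state
filter's filtered past. Signals are standardized first (PDC is
scale-free). The first 2 s are discarded as warm-up. Divergence
(non-finite coefficients or exploding covariance) raises with a hint to
reduce q. In the stationary limit the time-averaged coefficients match
the least-squares fit to RMSE < 0.01 on 60-s bivariate data, and a 0→0.5
coupling step is crossed at half height within ~5 s at q = 1e-3.

TPDC evaluates `Ā(f,t) = I − Σ_r A_r(t) e^{-i2πfr/fs}` on a 1-Hz frequency
grid and ~512 time frames; the band value is the mean over band bins and
time (the reduction is our choice; nothing finer is asserted). Column
normalization `Σ_i π_ij² = 1` holds to 1e-8.

**Significance.** The window-shuffle bootstrap (1-s windows, shuffled
independently per channel; 1000 iterations by default) must compute its
surrogate TPDC with the *same estimator* as the analysis: the dual
filter's random-walk jitter puts a noise floor (~0.1 for q = 1e-4) under
every TPDC value, far above static-fit surrogate values (~0.01), so a
static-fit threshold would pass every spurious connection. The
protocol-literal threshold (the surrogate *mean*) sits at the center of
the null distribution and admits the reverse direction of a genuine
unidirectional coupling about half the time; the pipeline therefore
defaults to the 99th percentile of the surrogate distribution —
consistent with the 99% confidence limit used for source coherence —
with the mean rule available (`reduction="mean"`, the
`bootstrap_significance` default). The time-reversal check passes a pair
when its net directionality `π_ij − π_ji` (band-averaged) flips sign under
time reversal by more than twice the bootstrap SD of that statistic; it is
a pair-level test — near-symmetric mutual coupling has no net direction to
flip and genuinely fails it (a known limitation of net-based time
reversal). Edges need both threshold exceedance and a time-reversal pass;
both directions surviving sets the bidirectional flag.

For pipeline runs, source signals are decimated (default factor 4) before
MVAR estimation — the analysis bands end at 100 Hz — and near-duplicate
extracted signals (|r| > 0.98, a by-product of deflation) are dropped
before fitting, since they carry no extra connectivity information and
make the regression rank-deficient.

## Prediction

Features per subject: coherence amplitudes of ranked sources per band,
then significant TPDC edge strengths per band in lexicographic edge order
(absent ranks/edges are zero-filled and logged). The SVM uses a
polynomial kernel with fixed γ = 0.25 and an integer grid over degree and
cost C in [1, 10], selected by inner 3-fold cross-validation on the
training split only; features are standardized on the training split
(leakage guard). The stated "fivefold cross validation taking 75% for
training and 25% for testing" is internally inconsistent (five folds imply
80/20), so the default scheme is five repeated stratified 75/25 splits,
with standard stratified five-fold available. For continuous scores the
reported "accuracy" is the percentage of test predictions within half a
population SD of the truth — a documented tolerance-band surrogate, since
what "predictive accuracy" means for a continuous score is otherwise
undefined; group classification is the default headline mode.
Feature-age correlations are plain Pearson r with two-sided p and no
multiplicity correction by default (Bonferroni optional).

## Problem sizes in the test suite

The acceptance tests run desk-scale versions of the protocol, chosen once:
surrogate calibration with 20 replicates × 1000 permutations of 60-s
pairs (the acceptance script uses the full 50 replicates); localization
with 10 seeds at 0 dB on a 10-mm grid; edge recovery over 20 seeds of
40-s bivariate data; cohort-level prediction on ten 75-subject cohorts of
20-s, 24-sensor recordings at 256 Hz with an 18-mm scan grid and
static-PDC connectivity (the dual filter's stationary-limit equivalence
and direction recovery are verified separately at full fidelity). The
null-calibration and chance-level bounds use binomial tolerances at the
stated run counts.

## Known limitations

- The spherical head model localizes on its own geometry; no claims about
  anatomical (MNI/Brodmann) positions are made or tested.
- Near-symmetric bidirectional coupling fails the net time-reversal test
  by construction; such pairs survive only via the bootstrap threshold.
- The matched-filter extraction trades adaptive interference suppression
  for coherence fidelity; in low-SNR regimes its leakage raises the
  coherence floor between nearby sources.
- The mean-rule bootstrap threshold is retained for protocol fidelity but
  is not recommended; see above.
- EDF export is 16-bit; round-trips are exact only to quantization.
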