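# Methods

This note documents the models, parameter conventions, numerical choices and
known limitations of `fibrilwater`. Units follow the neutron-scattering
conventions used throughout the code: energy transfer E and line widths in
μeV, momentum transfer Q in Å⁻¹, time in ps, lengths in Å (jump lengths
reported in nm), diffusion coefficients internally in Å²/ps and reported in
10⁻¹⁰ m²/s (1 Å²/ps = 100 × 10⁻¹⁰ m²/s). Constants: ħ = 658.212 μeV·ps,
k_B = 86.173 μeV/K.

## QENS spectral model

The per-Q model is an elastic delta plus a one- or two-Lorentzian
quasi-elastic term, convolved with the instrument resolution, on a linear
background:

I(Q,E) = scale·[x·δ(E) + (1−x)(p·L(E;Γ₁) + (1−p)·L(E;Γ₂))] ⊗ R(E) + C₁E + C₂.

* S(Q,E) is treated as symmetric in E (classical approximation); no
  detailed-balance correction is applied.
* The resolution is an analytic Gaussian (default FWHM 3.5 μeV, the quoted
  resolution of a backscattering spectrometer with a ±100 μeV window) or a
  tabulated low-temperature curve, renormalised to unit area on the
  analysis grid.
* Convolution is discrete on a uniform E grid: the kernel is sampled at the
  grid step out to 9σ, renormalised so its discrete sum × step is 1, and
  the input is zero-padded by the kernel half-length. A unit-area input
  therefore yields a unit-area output on the padded grid; trimming back to
  the analysis window loses only the mass physically broadened past the
  window edge (relevant for heavy-tailed Lorentzians, negligible for
  in-window curves).
* Fitting is weighted least squares (lmfit/Levenberg–Marquardt) with bounds
  x, p ∈ [0,1], Γ > 0. Initial values: x from the ratio of the data peak to
  the unit-area resolution peak, Γ₁ = 1 μeV, Γ₂ = 20 μeV, p = 0.5 — robust
  starting points for backscattering-like widths. After each fit the
  components are relabelled so Γ₁ ≤ Γ₂ and p always reports the narrow
  component's weight. Non-convergence at one Q flags that row only.
* One- versus two-component choice uses the small-sample-corrected Akaike
  criterion summed over Q (`compare_models`). In practice the published
  analyses of such data choose the component count by inspecting the
  susceptibility representation, which is not algorithmic; the information
  criterion is this package's reproducible stand-in, with a user override.
* The susceptibility is χ″ = S·(e^{E/k_BT} − 1) on 0 < E ≤ 100 μeV with the
  proportionality constant fixed to 1; all χ″ values are arbitrary units.
* The default analysis Q set is 0.3–0.9 Å⁻¹ (step 0.1): above ~1.1 Å⁻¹
  coherent scattering from the crystalline matrix suppresses the apparent
  quasi-elastic width, and the generator can optionally emulate that
  contamination (off by default).

## Elastic scans, transitions, MSD

Elastic scans are modelled piecewise-linear in T: a weak base slope plus
extra slope beyond each transition temperature (sharper at the upper one;
generator defaults 5·10⁻⁴, +2·10⁻³ and +6·10⁻³ per K at 220/260 K, chosen
so the intensity stays positive over 4–292 K and the two breaks are
clearly distinguishable at the 1% noise level used throughout).
`detect_transitions` fits continuous segmented linear models with 0..k
breakpoints placed on the temperature grid by exhaustive search and selects
k by corrected AIC; breakpoint uncertainty is reported as half the local
grid spacing (the resolution of the search). Whether published inflection
points in such scans are assigned by eye or by fit is usually unstated;
segmented regression is this package's explicit choice.

MSD extraction inverts the Gaussian approximation S_el ∝ exp(−Q²⟨Δr²⟩/3) by
a straight-line fit of ln S_el versus Q² over Q = 0.5–0.9 Å⁻¹ (default)
with a free intercept, so any overall intensity scale drops out;
MSD = −3·slope with the propagated regression uncertainty.

## Jump diffusion

Γ(Q) = (ħ/τ₀)[1 − 1/(1 + DQ²τ₀)] is fitted to the narrow-component HWHM by
weighted least squares up to q_max = 0.9 Å⁻¹ (configurable; higher Q is
coherently contaminated). Initial values come from the two regimes
(plateau → τ₀, small-Q slope → D); a 200×200 log-grid search is the
fallback on non-convergence. The jump length l = √(6Dτ₀) carries a
first-order uncertainty from the (D, τ₀) covariance. The fit report
includes the free-diffusion check Γ ≈ ħDQ² for each point.

## SANS

Power law I(Q) = (P·Q)^(−α) + B by weighted least squares, initialised from
the low-Q log-log slope. Two background conventions are provided
(pre-subtracted flat level, or B as a fit parameter); additionally
`vary_background=False` holds B at 0, which is appropriate when the fit is
restricted to low Q (hydrated samples are fitted below 0.08 Å⁻¹, before
the correlation peak, where the power law exceeds any flat background by
orders of magnitude and a free B only absorbs the peak's tail).

The correlation peak is handled subtract-then-fit: the fitted power law is
subtracted and the residual fitted with the Lorentzian peak plus a free
flat offset. Peak detection requires a 3-point-smoothed localized
significance ≥ 4 above the weighted flat level of the residual; otherwise a
flagged no-peak result is returned (the dry-sample outcome, not an error).
Because the peak's tails leak into the power-law window, the sequential
result seeds one final simultaneous fit of power law plus peak over the
full profile (`refine_jointly`, default on); on noiseless fixtures this
recovers the generating parameters exactly. The repeat distance is
d = 2π/σ with relative uncertainty preserved — deliberately distinct from
the Bragg λ/(2 sin θ) convention used for diffraction.

## XRD

Pseudo-Voigt peaks, η·Lorentzian + (1−η)·Gaussian with shared FWHM and
peak-height amplitude, fitted simultaneously with a linear background.
Bragg spacing uses θ = (2θ)/2 in radians internally; the Scherrer size
L = 0.9λ/(β·cos θ) converts the stored FWHM from degrees to radians
explicitly (unit-tested — the classic failure mode). Instrument broadening
is *not* deconvolved from β, so L is a lower bound on the true crystallite
size. The interfibrillar gap is repeat − width with errors in quadrature;
a negative gap raises (inconsistent inputs).

## Water trajectories and populations

Trajectories are 3-D Brownian surrogates: per-molecule D drawn from a
two-Gaussian mixture, per-step displacement SD √(2DΔt) per axis, defaults
2 ps × 2500 frames (a 5 ns production window) and 1000 molecules. They
emulate the diffusive statistics of interfibrillar water but none of the
structure of real simulations — no sub-picosecond ballistic regime, no
cage rattling, no cross-over between populations, no confinement
anisotropy — so passing tests validate the estimator chain, not any MD
force field.

MSD is time-origin averaged over all valid origins (molecule averaging is
available via the per-molecule output). Per-molecule D is the linear MSD
slope over lags 10–400 ps (free intercept, D = slope/6), a window that
excludes the short-time non-diffusive regime while staying well inside the
trajectory span; negative slopes are clipped to 0 and flagged. The fit
quality is the log-log MSD exponent (1 diffusive, 2 ballistic); molecules
with |exponent − 1| > 0.5 are flagged as non-diffusive.

Mixture decomposition: because D samples are non-negative (the generator
re-draws negative values; estimated D̂ is clipped), the default fit
maximises the likelihood of a mixture of at-zero-truncated Gaussians
(Nelder–Mead on 5 parameters, initialised from a 10-restart scikit-learn
EM fit). The fitted (w, m, σ) then describe the underlying un-truncated
Gaussians — the convention in which such population tables are reported.
At the highest temperature the fast component has ~10% nominal mass below
zero, so a plain EM fit on truncated samples overestimates its mean by
~0.3×10⁻¹⁰ m²/s; the truncation-aware likelihood removes that bias. Plain
EM (`method="em"`) and a histogram-curve fit (`method="histogram"`, bin
width 0.1×10⁻¹⁰ m²/s) are retained for comparison and figure parity. A fit
is flagged degenerate when a component weight falls below 0.02 or the mean
separation is less than the average component width.

The canonical mixture rows (213/243/263 K) and jump-diffusion conditions
(250 K: D = 0.86×10⁻¹⁰ m²/s, τ₀ = 142.2 ps; 265 K: 1.77, 110) ship as
generator defaults. The MSD evaluation time for elastic-intensity
comparisons defaults to 800 ps but is an explicit parameter: quoted
spectrometer time windows for a 3.5 μeV resolution range from ~400 ps
(energy-time conversion) to ~800 ps depending on convention, and the two
are not mutually consistent; the package does not resolve that ambiguity,
it exposes it.

## Noise model and synthetic study conditions

All generators add relative Gaussian noise σᵢ = level·max(Iᵢ, floor) — a
simple, invertible stand-in for counting statistics (real count noise is
Poisson and enters through reduction pipelines; nothing here models
detector effects beyond this). The benchmark conditions used by the tests
and the acceptance script are: QENS at 1% relative noise on Q = 0.3–0.9,
E = ±100 μeV step 0.5 μeV, elastic fractions 0.4/0.2 and broad widths
25/30 μeV at 250/265 K (plausible values for a partly frozen hydration
layer; the published tables do not print x, p or Γ₂); SANS with P = 2.3,
α = 3.55, B = 0.1 and peak (A = 1, w = 0.04, σ = 0.094) on 200 log-spaced
points over 0.003–0.4 Å⁻¹, scaled so the power law dominates below
0.08 Å⁻¹ and the peak is the high-Q excess it is in hydrated samples; XRD
with the four cellulose-I reflections at (14.8, 16.9, 20.7, 22.9)°, the
110 FWHM of 1.6224° chosen to encode a 50 Å crystallite. Hydration level
is carried as a label only (experiments and simulations of such systems
use slightly different g/g values).

## Known limitations

* No stretched-exponential (Kohlrausch) spectral fits; two Lorentzians are
  the deliberately simple alternative for data with two dynamic components.
* No multiple-scattering or detailed-balance corrections; no instrument
  geometry (wavelength spread, detector offsets) — reduced data only.
* No Rietveld refinement, crystallinity index, or preferred-orientation
  modelling on the diffraction side; no instrument-broadening deconvolution.
* The exact per-Q resolution tabulation of a real backscattering instrument
  is sample- and configuration-specific; the analytic Gaussian is a
  stand-in, with tabulated curves accepted.
* Segmented-regression breakpoint uncertainties are search-resolution
  bounds, not full profile-likelihood intervals.
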