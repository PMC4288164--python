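# Methods

This note documents the models, numerical choices and known limitations of
`tcspcfit`. It is written for users deciding whether the package's
assumptions match their instrument and sample.

## Discretization and convolution

Histograms live on a uniform channel grid, t(k) = (k − t₀)·Δ with dwell Δ
(default 40 ps, 1024 channels ≈ 41 ns window) and time zero at the IRF peak
channel (default 64, leaving a short pre-trigger baseline). The model decay
is sampled at channel centres, zero before time zero, and convolved with
the unit-area-normalized IRF by discrete causal convolution indexed so that
a delta-function IRF is the identity. A fractional-channel IRF shift
(linear interpolation, bounded to ±5 channels) and a constant background
are fitted as nuisance parameters; both default to free because real
instruments show wavelength-dependent timing shifts and dark counts, and
they cost little precision when truly absent.

Because simulator and fitter share the same discretization, noiseless data
are fitted exactly (the oracle-equivalence tests); against a continuous
decay the channel-centre approximation introduces errors well below
counting noise for IRF widths ≳ Δ/2. The convolution conserves integrated
intensity except for mass shifted past the window edge, so the last ~t₀
channels of a convolved curve are slightly truncated; fit windows stop
earlier in practice (see below).

## Weights, fit window, and fit diagnostics

Counts are Poisson; residuals are weighted by √max(obs, 1), the standard
Neyman approximation for TCSPC. The fit window runs from 10 channels before
the IRF peak (anchoring the rising edge and the shift parameter) to the
last channel with ≥ 5 counts — empty tail channels carry no information and
destabilize the weighted χ². Goodness of fit is reported as the reduced χ²
and the two-sided Wald–Wolfowitz runs test (normal approximation) on
residual signs; "random residuals" is operationalized as p > 0.05. With
Neyman weights E[χ²ᵣ] rises above 1 when a window is dominated by few-count
channels (≈1.2 at ~5 counts/channel); in realistic windows — peaks of 10⁴
counts decaying over the window — calibration tests show E[χ²ᵣ] = 1.00 ±
0.03, and the acceptance band [0.8, 1.2] used informally throughout is met
by ≳90% of correctly specified fits.

## Intensity-decay fitting

Up to four exponential components; lifetimes bounded to [0.01, 100] ns —
below a quarter channel a component is degenerate with the IRF, beyond the
window with the background. Unconstrained non-negative per-component
amplitudes are fitted and normalized afterwards, so Σαᵢ = 1 holds exactly
in the reported parameters with the photon scale carried separately;
components are reported in increasing-lifetime order.

Optimization uses trust-region-reflective least squares (the bounded member
of the Levenberg–Marquardt family, via lmfit/SciPy); the classic MINPACK
implementation stalls when parameters start on a bound, which the
background routinely does. Multi-exponential χ² surfaces have
collapsed-lifetime local minima, so fitting is multi-start: a log-spaced
initialization over [2Δ, window/3], then — if χ²ᵣ exceeds 1.5 — cascaded
starts grown from the (n−1)-component optimum by adding a fast
sub-resolution component or splitting the longest one. The best χ²ᵣ wins.

Model-order selection is parsimony-first: the smallest n whose residuals
pass the runs test and whose χ²ᵣ would improve by < 0.05 with one more
component. Both thresholds are package choices; four components is the
hard ceiling because nucleic-acid 2-AP decays are conventionally described
by at most four stacking sub-states.

## Anisotropy protocol

The pair fit varies only the rotational amplitudes, correlation times and
one photon scale; r₀ and the intensity parameters (from the magic-angle
fit) stay fixed — the constrained protocol that makes sub-IRF correlation
times identifiable. r₀ defaults to 0.31, the value measured for 2-AP
immobilized in 50% glycerol; it can be freed for protocol validation. The
G-factor divides the detected perpendicular channel and is estimated from a
freely rotating standard (2-AP in water, lifetime 11.3 ns) by tail matching
(t ≥ 3 ns ≳ 10× the standard's correlation time); a total-intensity-ratio
estimate is provided as an alternative since tail matching needs adequate
tail counts.

A correlation time longer than the ~41 ns window (ribosome-bound RNA shows
φ₂ ≫ 50 ns) is not identifiable; only its amplitude β₂ is. The optimizer
bound sits at 1 μs, fits with φ₂ ≥ 50 ns are flagged, and φₘ = Σβᵢφᵢ is
computed with the flagged component at the 50 ns reporting cap — capping at
the reporting stage rather than during optimization keeps β₂ unbiased
(recovered within ±0.05 for φ₂ anywhere in 50–500 ns), which matters
because β₂ feeds the binding isotherm. Whether β₂ or φ₂ dominates a given
dataset's plateau should be checked via the `phi2_capped` flag.

The Stokes–Einstein check fits recovered correlation times of a
small-molecule standard against solvent viscosity through the origin
(weighted by the reported uncertainties) and returns the implied
hydrodynamic volume — the standard control that correlation times at the
IRF width are recovered without systematic bias.

## Quenching and binding

Stern–Volmer fits regress τ₀/τ on [Q] by weighted least squares (weights
from propagated lifetime errors; OLS if absent). With τ in ns and [Q] in M
the slope/τ₀ is k_q in 10⁹ M⁻¹s⁻¹ directly. The lifetime entering the
relation is the mean lifetime τₘ of the full multi-exponential fit — for
heterogeneous probes this is an operational choice, documented here and
overridable by passing any lifetime series. The intercept is fitted, not
pinned at 1; deviation > 0.1 flags a static-quenching contribution.

The binding readout is a 1:1 Langmuir isotherm; the "minimum saturating
concentration" is where the predicted amplitude reaches 95% of saturation
(= 19 K_d), flagged as an extrapolation when the titration itself never
gets there. The 95% threshold and the 1:1 stoichiometry are the minimal
model consistent with a saturating amplitude titration; cooperative or
multi-site binding is out of scope.

## Dispersion profiles

Per-site deviations (observed − mean)/mean are computed over the sites
available for a condition; their RMS is the flatness scalar. Comparisons
between conditions report the RMS ratio with a 95% bootstrap interval from
resampling each site value within its reported uncertainty (1000 seeded
normal draws by default). The RMS-of-relative-deviations metric and the
bootstrap are package choices — the underlying literature argues flatness
from bar plots; the computed inequalities (denaturant flattening of the
free-RNA profiles, bound-state flattening of lifetime and quenching
dispersion at 45 °C) are asserted as exact arithmetic on the bundled
tables.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure the fitters assume:
multi-exponential decays (lifetimes anywhere in ~50 ps–10 ns), a Gaussian
IRF of 40 ps FWHM, scaling to 10⁴ expected peak counts, independent Poisson
noise per channel and detector, polarized pairs decomposed before
convolution with the G-factor as a perpendicular detection-efficiency
divisor, Stern–Volmer titrations with multiplicative lifetime scatter
(2% default), and Langmuir amplitude titrations with additive noise.
Ground truth is embedded in each trace's metadata; all randomness descends
from one master seed through `numpy.random.SeedSequence`.

Not emulated: detector dead-time, after-pulsing and pile-up; IRF asymmetry
and drift (the real IRF of a scatterer is not Gaussian — analyses here do
not depend on kernel shape beyond its width); correlated noise from laser
instability; and associated (lifetime-correlated) anisotropy. Passing
recovery tests therefore demonstrate correctness of the estimation chain
under ideal counting statistics, not robustness to these instrumental
artifacts.

## Validation studies and problem sizes

The packaged studies (`tcspcfit.validation`, driven by
`scripts/acceptance.py`) use 100 seeded replicates for histogram-level
recoveries and 200 for titration regressions on the default 1024-channel
grid — enough that the Monte-Carlo standard error of each reported mean is
several times smaller than the tolerance it is compared against, while the
full suite runs in well under a minute. The unit-test suite uses smaller
replicate counts for the same checks plus property-based tests
(hypothesis, derandomized) for the structural invariants.

## Known limitations

* Single-curve fits only: no global analysis linking lifetimes across
  traces.
* No lifetime-distribution (maximum-entropy) analysis; heterogeneity is
  represented by discrete components.
* Neyman weighting biases χ²ᵣ upward in very-low-count windows; fits of
  peaks well below ~10³ counts should use longer collection instead.
* The G-factor estimate assumes the standard depolarizes fully within the
  window; slowly rotating standards will bias G upward.
* Bootstrap intervals for flatness treat site values as independent
  Gaussians with the printed uncertainties; systematic errors shared across
  sites are not propagated.
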