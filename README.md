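# tcspcfit

Time-resolved fluorescence analysis for site-specific nucleic-acid probes,
built around the workflow used to study RNA structural dynamics with the
adenine analog 2-aminopurine (2-AP): time-correlated single-photon counting
(TCSPC) decay simulation, iterative-reconvolution lifetime fitting,
polarized-pair anisotropy analysis, Stern–Volmer quenching, binding
isotherms from slow-anisotropy amplitudes, and site-dispersion profiling.

## Who this is for

Spectroscopists and RNA/DNA biophysicists who measure picosecond-resolved
fluorescence decays of site-specifically labeled nucleic acids and want a
scriptable, tested version of the standard analysis chain — including a
synthetic-data generator for validating the chain at a realistic instrument
scale (≈40 ps IRF, 40 ps/channel, 10⁴ counts in the peak channel, Poisson
statistics).

## The models

**Intensity decay.** A measured histogram is modelled as the causal
convolution of the IRF with a multi-exponential decay

I(t) = Σᵢ αᵢ exp(−t/τᵢ),  Σᵢ αᵢ = 1 (1–4 components),

fitted by Levenberg–Marquardt-family least squares with Poisson weights
w = max(counts, 1) ("iterative reconvolution"). The amplitude-weighted mean
lifetime τₘ = Σ αᵢτᵢ is proportional to the quantum yield. Goodness of fit
is judged by the reduced χ² and a runs test on the residual signs.

**Anisotropy decay.** From parallel/perpendicular detection channels,

r(t) = (I∥ − G·I⊥) / (I∥ + 2G·I⊥),

with G the detection-efficiency ratio (estimated from a freely rotating
standard). Fits target the polarized pair directly through the
decomposition I∥ = ⅓I(1+2r), I⊥ = ⅓I(1−r) with a biexponential
r(t) = r₀[β₁e^(−t/φ₁) + β₂e^(−t/φ₂)], holding r₀ and the intensity
parameters (from the magic-angle fit) fixed. The mean rotational
correlation time is φₘ = Σ βᵢφᵢ; correlation times beyond the observation
window (e.g. ribosome-bound RNA) are flagged and enter φₘ at a 50 ns
reporting cap.

**Quenching and binding.** Collisional quenching follows the Stern–Volmer
relation τ₀/τ = 1 + k_q·τ₀·[Q] (k_q in 10⁹ M⁻¹s⁻¹); the amplitude β₂ of a
very long correlation time grows with binder concentration as a 1:1
Langmuir isotherm β₂([R]) = β₂ᵐᵃˣ·[R]/(K_d + [R]).

**Dispersion profiles.** Site-to-site variation of a parameter is expressed
as (observed − mean)/mean across probe positions; its RMS quantifies the
"non-flatness" that reports on folded structure, with a seeded bootstrap for
comparing conditions. Published site-parameter tables for the MiniROSE RNA
thermometer ship with the package (`load_reference_table`).

## Worked example

```python
from tcspcfit import *
from tcspcfit.simulate import SimulationSpec, make_irf, simulate_decay, \
    simulate_polarized_pair, simulate_quenching_series

truth = MultiExpParams(alphas=[0.5, 0.5], taus=[0.4, 3.0])
spec = SimulationSpec(
    intensity=truth,
    anisotropy=AnisotropyParams(r0=0.31, betas=[0.45, 0.55], phis=[0.4, 4.9]),
    seed=24,
)
trace, irf = simulate_decay(spec), make_irf(spec)

res = fit_intensity_decay(trace, irf, n_components=2)
print(res.params.taus.round(4), mean_lifetime(res.params))
# [0.3978 2.9811] 1.7038  -> lifetimes and tau_m (ns), truth 0.4/3.0, 1.7

aniso, stats = fit_anisotropy(
    simulate_polarized_pair(spec), irf,
    intensity_params=res.params, r0=0.31, n_rot=2,
)
print(aniso.phis.round(3), mean_rotational_correlation(aniso))
# [0.46  5.669] 3.1105  -> correlation times and phi_m (ns)

series = simulate_quenching_series(
    truth, kq=20.4, q_concentrations=[0, .025, .05, .1, .15, .2],
    noise_sd=0.02, seed=24,
)
q = stern_volmer_fit(series, tau0=mean_lifetime(truth))
print(round(q.kq, 2), round(q.intercept, 4))
# 20.74 0.9774  -> recovered kq (1e9 /M/s) and Stern-Volmer intercept
```

The fitted lifetimes, τₘ, rotational correlation times and k_q come back at
the generating values within counting-statistics scatter; reduced χ² of
both fits is ≈1 and the residual runs test passes, as expected for a
correctly specified model.

The same steps are available from the shell (`tcspcfit simulate|fit-decay|
fit-anisotropy|quench|binding|profile`), and
`tcspcfit pipeline --config examples/demo_config.yaml` runs the whole chain
for seven probe sites and writes per-site parameters, dispersion profiles
and a provenance-stamped JSON report.

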