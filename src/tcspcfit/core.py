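"""Core containers and numerics for TCSPC decay analysis.

This module holds the domain types shared by the simulation and fitting
layers — the uniform channel grid, photon-count histograms, multi-exponential
intensity-decay parameters — together with the numerical primitives every
fitter relies on: model evaluation, causal convolution with the instrument
response function (IRF), and the goodness-of-fit statistics (Poisson-weighted
reduced chi-square and the Wald–Wolfowitz runs test on residual signs).

Conventions
-----------
* Time is measured in nanoseconds throughout; a channel ``k`` maps to
  ``t(k) = (k - t0_channel) * dwell``, so the IRF peak sits at ``t = 0``.
* Amplitudes of a multi-exponential decay are normalized to sum to one;
  the overall photon scale is carried separately.
* Components are kept in canonical order of strictly increasing lifetime.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats as _sps

logger = logging.getLogger(__name__)

TraceKind = Literal["decay", "irf", "parallel", "perpendicular"]

MAX_COMPONENTS = 4


class InvalidParameterError(ValueError):
    """Model parameters violate a physical or structural invariant."""


@dataclass(frozen=True)
class ChannelGrid:
    """Uniform TCSPC channel grid.

    Parameters
    ----------
    n_channels : int
        Number of histogram channels.
    dwell : float
        Time per channel in ns (typically ~0.040 ns for ps-resolved setups).
    t0_channel : int
        Channel index of time zero, i.e. where the IRF peaks.
    """

    n_channels: int = 1024
    dwell: float = 0.040
    t0_channel: int = 64

    def __post_init__(self) -> None:
        if self.n_channels <= 0:
            raise InvalidParameterError("n_channels must be positive")
        if self.dwell <= 0:
            raise InvalidParameterError("dwell must be positive")
        if not 0 <= self.t0_channel < self.n_channels:
            raise InvalidParameterError("t0_channel must lie inside the grid")

    @property
    def times(self) -> np.ndarray:
        """Channel centre times in ns, zero at the IRF peak."""
        return (np.arange(self.n_channels) - self.t0_channel) * self.dwell

    @property
    def window(self) -> float:
        """Total time span of the grid in ns."""
        return self.n_channels * self.dwell


@dataclass
class DecayTrace:
    """A photon-count histogram on a channel grid.

    ``kind`` distinguishes magic-angle decays, measured IRFs and the two
    polarized detection channels. ``meta`` carries free-form labels (probe
    position, temperature, condition) and — for simulated traces — the full
    generating ground truth.
    """

    grid: ChannelGrid
    counts: np.ndarray
    kind: TraceKind = "decay"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) != self.grid.n_channels:
            raise InvalidParameterError(
                f"counts length {len(self.counts)} != grid.n_channels "
                f"{self.grid.n_channels}"
            )
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if not np.all(np.isfinite(self.counts)):
            raise InvalidParameterError("counts must be finite")

    @property
    def peak_count(self) -> float:
        return float(self.counts.max())

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.counts))


@dataclass
class MultiExpParams:
    """Parameters of a multi-exponential intensity decay.

    The decay law is ``I(t) = scale * sum_i alpha_i exp(-t / tau_i)`` for
    ``t >= 0`` (zero before time zero) plus a constant ``background`` per
    channel. Up to four components; amplitudes are normalized so that
    ``sum(alphas) == 1`` and components are ordered by increasing lifetime.
    """

    alphas: np.ndarray
    taus: np.ndarray
    scale: float = 1.0
    background: float = 0.0
    shift: float = 0.0  # IRF-to-decay shift in (fractional) channels

    def __post_init__(self) -> None:
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        self.taus = np.atleast_1d(np.asarray(self.taus, dtype=float))
        n = len(self.taus)
        if not 1 <= n <= MAX_COMPONENTS:
            raise InvalidParameterError(
                f"number of components must be 1..{MAX_COMPONENTS}, got {n}"
            )
        if len(self.alphas) != n:
            raise InvalidParameterError("alphas and taus must have equal length")
        if np.any(self.taus <= 0):
            raise InvalidParameterError("all lifetimes must be positive")
        if np.any(self.alphas < 0):
            raise InvalidParameterError("amplitudes must be non-negative")
        if self.alphas.sum() <= 0:
            raise InvalidParameterError("at least one amplitude must be positive")

    @property
    def n_components(self) -> int:
        return len(self.taus)

    def normalized(self) -> "MultiExpParams":
        """Canonical form: amplitudes summing to one, lifetimes increasing.

        The photon scale absorbs the amplitude normalization so the modelled
        counts are unchanged.
        """
        total = float(self.alphas.sum())
        order = np.argsort(self.taus, kind="stable")
        return replace(
            self,
            alphas=self.alphas[order] / total,
            taus=self.taus[order],
            scale=self.scale * total,
        )

    @property
    def is_normalized(self) -> bool:
        return math.isclose(float(self.alphas.sum()), 1.0, rel_tol=1e-9)


@dataclass
class FitResult:
    """Outcome of a weighted least-squares decay fit.

    ``params`` holds the fitted parameter object (:class:`MultiExpParams` or
    an anisotropy parameter set), ``residuals`` the Poisson-weighted residual
    per evaluated channel, ``stderr`` per-parameter standard errors from the
    covariance at the optimum (``None`` where unavailable).
    """

    params: object
    chi2_reduced: float
    residuals: np.ndarray
    runs_test_p: float
    stderr: dict
    n_eval_channels: int
    success: bool = True
    message: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chi2_reduced < 0:
            raise InvalidParameterError("chi2_reduced cannot be negative")
        if len(self.residuals) != self.n_eval_channels:
            raise InvalidParameterError("residuals length != n_eval_channels")


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def evaluate_multiexp(params: MultiExpParams, grid: ChannelGrid) -> np.ndarray:
    """Evaluate the multi-exponential decay law on a channel grid.

    Returns ``scale * sum_i alpha_i exp(-t/tau_i)`` for ``t >= 0``, zero for
    ``t < 0``, plus the constant background on every channel.
    """
    t = grid.times
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    acc = np.zeros_like(tp)
    for a, tau in zip(params.alphas, params.taus):
        acc += a * np.exp(-tp / tau)
    out[pos] = params.scale * acc
    return out + params.background


def mean_lifetime(params: MultiExpParams) -> float:
    """Amplitude-weighted mean lifetime ``tau_m = sum_i alpha_i tau_i`` (ns).

    ``tau_m`` is proportional to the fluorescence quantum yield. Unnormalized
    amplitudes are normalized first (with a logged warning), so the result is
    invariant under joint rescaling of the amplitudes.
    """
    alphas = params.alphas
    total = float(alphas.sum())
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        logger.warning(
            "amplitudes sum to %.6g, normalizing before computing tau_m", total
        )
        alphas = alphas / total
    return float(np.dot(alphas, params.taus))


# ---------------------------------------------------------------------------
# convolution with the IRF
# ---------------------------------------------------------------------------


def shift_irf(irf_counts: np.ndarray, shift: float) -> np.ndarray:
    """Shift an IRF by a (fractional) number of channels, linear interpolation.

    Positive shift moves the IRF to later channels. Samples shifted in from
    outside the grid are zero.
    """
    if shift == 0.0:
        return np.asarray(irf_counts, dtype=float)
    n = len(irf_counts)
    idx = np.arange(n, dtype=float) - shift
    return np.interp(idx, np.arange(n, dtype=float), irf_counts, left=0.0, right=0.0)


def convolve_irf(
    model: np.ndarray, irf: DecayTrace, shift: float = 0.0
) -> np.ndarray:
    """Causal discrete convolution of a model decay with the measured IRF.

    The IRF is unit-area normalized (after optional fractional-channel shift)
    so the convolution conserves integrated intensity. The kernel is indexed
    relative to the grid's time zero: a delta IRF at ``t0_channel`` acts as
    the identity, so model and output live on the same grid. The operation is
    linear in the model.
    """
    model = np.asarray(model, dtype=float)
    if len(model) != irf.grid.n_channels:
        raise InvalidParameterError(
            "model and IRF must share a grid "
            f"({len(model)} channels vs {irf.grid.n_channels})"
        )
    kernel = shift_irf(irf.counts, shift)
    area = kernel.sum()
    if area <= 0:
        raise InvalidParameterError("IRF has zero integrated intensity")
    kernel = kernel / area
    n = irf.grid.n_channels
    t0 = irf.grid.t0_channel
    full = np.convolve(kernel, model)
    return full[t0 : t0 + n]


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def runs_test_p(residuals: np.ndarray) -> float:
    """Two-sided Wald–Wolfowitz runs test on residual signs.

    Tests whether the sequence of positive/negative residuals is consistent
    with random ordering, using the normal approximation to the run-count
    distribution. Exact zeros are dropped. Returns 1.0 when fewer than two
    sign changes are possible (all residuals zero or a single observation)
    and 0.0 when every residual shares one sign over twenty or more channels
    — a one-run sequence that long is itself decisive evidence of structure.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    n = len(signs)
    if n < 2:
        return 1.0
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0 if n >= 20 else 1.0
    n_runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 1.0 + 2.0 * n_pos * n_neg / n
    var = (2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n)) / (n * n * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (n_runs - mu) / math.sqrt(var)
    return float(2.0 * _sps.norm.sf(abs(z)))


def default_fit_window(trace: DecayTrace, min_tail_counts: float = 5.0) -> slice:
    """Channel window used for fitting.

    Starts 10 channels before the IRF peak (to anchor the rise) and ends at
    the last channel with at least ``min_tail_counts`` counts; empty tail
    channels destabilize Poisson-weighted chi-square and carry no signal.
    """
    start = max(0, trace.grid.t0_channel - 10)
    above = np.nonzero(trace.counts >= min_tail_counts)[0]
    stop = int(above[-1]) + 1 if len(above) else trace.grid.n_channels
    if stop <= start:
        stop = trace.grid.n_channels
    return slice(start, stop)


def fit_statistics(
    observed: DecayTrace | np.ndarray,
    expected: np.ndarray,
    n_free_params: int,
    window: slice | None = None,
) -> tuple[float, float]:
    """Reduced chi-square and runs-test p-value of a model against counts.

    Residuals are weighted with the Poisson variance approximation
    ``w = max(observed, 1)``, the standard choice for TCSPC histograms where
    low-count channels would otherwise receive infinite weight.

    Returns
    -------
    (chi2_reduced, runs_test_p)
    """
    counts = observed.counts if isinstance(observed, DecayTrace) else np.asarray(observed, float)
    expected = np.asarray(expected, dtype=float)
    if window is not None:
        counts = counts[window]
        expected = expected[window]
    n_eval = len(counts)
    if n_eval <= n_free_params:
        raise ValueError(
            f"{n_eval} evaluated channels cannot constrain {n_free_params} parameters"
        )
    w = np.maximum(counts, 1.0)
    resid = (counts - expected) / np.sqrt(w)
    chi2_red = float(np.sum(resid**2) / (n_eval - n_free_params))
    return chi2_red, runs_test_p(resid)


def weighted_residuals(counts: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Poisson-weighted residuals ``(obs - exp) / sqrt(max(obs, 1))``."""
    w = np.maximum(counts, 1.0)
    return (counts - expected) / np.sqrt(w)
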