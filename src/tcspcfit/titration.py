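"""Quenching and binding titration analysis.

Two titration readouts are supported:

* **Collisional quenching** — the fluorescence lifetime shortens with
  quencher concentration according to the Stern-Volmer relation
  ``tau0/tau = 1 + kq * tau0 * [Q]``; a weighted linear regression of the
  lifetime ratio on quencher concentration yields the bimolecular quenching
  constant ``kq`` (a solvent-accessibility readout, reported in
  10^9 M^-1 s^-1).

* **Binding** — the amplitude ``beta2`` of the very long (>50 ns) rotational
  correlation time grows with binder (ribosome) concentration as the bound
  fraction grows; a 1:1 Langmuir isotherm ``beta2([R]) = beta2_max * [R] /
  (Kd + [R])`` is fitted to extract the dissociation constant and the
  minimum saturating binder concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from .core import InvalidParameterError


@dataclass
class TitrationSeries:
    """A concentration-indexed response series.

    ``kind`` is ``"quenching"`` (concentrations in M, responses are
    lifetimes in ns) or ``"binding"`` (concentrations in nM, responses are
    slow-anisotropy amplitudes beta2).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    response_errors: np.ndarray | None = None
    kind: str = "quenching"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.atleast_1d(np.asarray(self.concentrations, float))
        self.responses = np.atleast_1d(np.asarray(self.responses, float))
        if self.kind not in ("quenching", "binding"):
            raise InvalidParameterError(f"unknown titration kind {self.kind!r}")
        if len(self.concentrations) != len(self.responses):
            raise InvalidParameterError("concentrations and responses must match")
        if np.any(self.concentrations < 0):
            raise InvalidParameterError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise InvalidParameterError("concentrations must be strictly increasing")
        if self.response_errors is not None:
            self.response_errors = np.atleast_1d(
                np.asarray(self.response_errors, float)
            )
            if len(self.response_errors) != len(self.responses):
                raise InvalidParameterError("response_errors length mismatch")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class QuenchingResult:
    """Stern-Volmer regression outcome.

    ``kq`` is in 10^9 M^-1 s^-1 (the natural unit when lifetimes are in ns
    and concentrations in M). An intercept far from 1 indicates a static
    (ground-state complex) contribution on top of collisional quenching.
    """

    kq: float
    tau0: float
    intercept: float
    r_squared: float
    kq_stderr: float = float("nan")
    intercept_stderr: float = float("nan")
    flags: list = field(default_factory=list)

    def predict_lifetime(self, q: np.ndarray) -> np.ndarray:
        """Predicted lifetime tau([Q]) from the fitted line (ns)."""
        q = np.asarray(q, dtype=float)
        return self.tau0 / (self.intercept + self.kq * self.tau0 * q)


@dataclass
class BindingResult:
    """1:1 Langmuir isotherm fit of the slow-anisotropy amplitude."""

    kd: float
    beta2_max: float
    minimum_saturating_concentration: float
    kd_stderr: float = float("nan")
    beta2_max_stderr: float = float("nan")
    flags: list = field(default_factory=list)

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.beta2_max * conc / (self.kd + conc)


#: Fractional saturation defining the "minimum saturating" concentration.
SATURATION_FRACTION = 0.95


def stern_volmer_fit(series: TitrationSeries, tau0: float) -> QuenchingResult:
    """Fit the Stern-Volmer relation to a quenching titration.

    Regresses ``tau0/tau`` on ``[Q]`` by weighted least squares (weights from
    propagated lifetime errors when available, ordinary least squares
    otherwise). The slope equals ``kq * tau0``; with ``tau0`` in ns and
    ``[Q]`` in M, ``slope / tau0`` is ``kq`` in 10^9 M^-1 s^-1. The intercept
    is fitted rather than pinned at 1; a deviation beyond 0.1 flags a
    static-quenching contribution.
    """
    if series.kind != "quenching":
        raise InvalidParameterError("series.kind must be 'quenching'")
    if tau0 <= 0:
        raise InvalidParameterError("tau0 must be positive")
    if len(series) < 3:
        raise ValueError("Stern-Volmer regression needs at least 3 points")
    tau = series.responses
    if np.any(tau <= 0):
        raise InvalidParameterError("lifetimes must be positive")
    q = series.concentrations
    ratio = tau0 / tau
    if series.response_errors is not None and np.all(series.response_errors > 0):
        sigma_ratio = tau0 * series.response_errors / tau**2
        weights = 1.0 / sigma_ratio**2
    else:
        weights = np.ones_like(ratio)
    with np.errstate(divide="ignore", invalid="ignore"):
        model = sm.WLS(ratio, sm.add_constant(q), weights=weights).fit()
        r_squared = float(model.rsquared)
    if not np.isfinite(r_squared):  # constant response: ratio has no variance
        r_squared = 1.0 if model.ssr < 1e-24 else 0.0
    intercept, slope = model.params
    intercept_se, slope_se = model.bse

    flags: list[str] = []
    if slope < 0:
        if slope < -1e-12:  # a numerically-zero slope is just "no quenching"
            warnings.warn(
                "negative Stern-Volmer slope; reporting kq = 0", stacklevel=2
            )
            flags.append("negative slope")
        slope = 0.0
    if abs(intercept - 1.0) > 0.1:
        warnings.warn(
            f"Stern-Volmer intercept {intercept:.3f} deviates from 1; "
            "possible static quenching",
            stacklevel=2,
        )
        flags.append("static quenching suspected")
    return QuenchingResult(
        kq=float(slope / tau0),
        tau0=float(tau0),
        intercept=float(intercept),
        r_squared=r_squared,
        kq_stderr=float(slope_se / tau0),
        intercept_stderr=float(intercept_se),
        flags=flags,
    )


def _langmuir(conc: np.ndarray, beta2_max: float, kd: float) -> np.ndarray:
    return beta2_max * conc / (kd + conc)


def binding_isotherm_fit(series: TitrationSeries) -> BindingResult:
    """Fit a 1:1 Langmuir isotherm to a beta2-vs-concentration series.

    Returns the dissociation constant (same units as the concentrations),
    the saturation amplitude, and the minimum saturating concentration — the
    smallest binder concentration at which the predicted amplitude reaches
    95% of saturation, i.e. ``19 * Kd`` for a 1:1 isotherm. A titration whose
    highest point has not reached that level is flagged as extrapolating.
    """
    if series.kind != "binding":
        raise InvalidParameterError("series.kind must be 'binding'")
    if len(series) < 4:
        raise ValueError("binding isotherm fit needs at least 4 points")
    conc = series.concentrations
    resp = series.responses
    if np.all(resp <= 0):
        return BindingResult(
            kd=float("nan"),
            beta2_max=0.0,
            minimum_saturating_concentration=float("nan"),
            flags=["no binding detected"],
        )
    bmax0 = float(resp.max())
    half = bmax0 / 2.0
    above = np.nonzero(resp >= half)[0]
    kd0 = float(conc[above[0]]) if len(above) and conc[above[0]] > 0 else float(
        conc[conc > 0][0] if np.any(conc > 0) else 1.0
    )
    sigma = None
    if series.response_errors is not None and np.all(series.response_errors > 0):
        sigma = series.response_errors
    popt, pcov = curve_fit(
        _langmuir,
        conc,
        resp,
        p0=[bmax0, kd0],
        sigma=sigma,
        bounds=([0.0, 1e-12], [1.5, np.inf]),
        maxfev=10000,
    )
    beta2_max, kd = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    min_sat = kd * SATURATION_FRACTION / (1.0 - SATURATION_FRACTION)

    flags: list[str] = []
    if _langmuir(conc[-1], beta2_max, kd) < SATURATION_FRACTION * beta2_max:
        warnings.warn(
            "titration does not reach saturation; the minimum saturating "
            "concentration is an extrapolation",
            stacklevel=2,
        )
        flags.append("saturation extrapolated")
    return BindingResult(
        kd=kd,
        beta2_max=beta2_max,
        minimum_saturating_concentration=float(min_sat),
        kd_stderr=float(perr[1]),
        beta2_max_stderr=float(perr[0]),
        flags=flags,
    )
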