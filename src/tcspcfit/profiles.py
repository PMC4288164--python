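"""Site-specific dispersion profiles across measurement conditions.

A structured nucleic acid imposes position-dependent photophysics on a
site-specifically placed probe: the mean lifetime, quenching constant and
rotational correlation time vary ("disperse") with probe position. Loss of
structure — thermal melting, chemical denaturation, or unfolding on a binding
partner — flattens that dispersion. This module quantifies it: per-site
relative deviations from the cross-site mean,

    deviation_i = (observed_i - mean) / mean,

their root-mean-square as a scalar flatness measure, and a seeded bootstrap
(resampling site values within their reported uncertainties) for comparing
flatness between conditions.

Reference tables of published site parameters for the MiniROSE RNA
thermometer (free, ribosome-bound, and the G15-deletion construct) ship with
the package; see :func:`load_reference_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core import InvalidParameterError

REFERENCE_TABLES = ("minirose_free", "minirose_bound", "minirose_g15del")


@dataclass
class SiteParameterTable:
    """Long-format table of per-site, per-condition parameter values.

    ``data`` columns: site, parameter, condition, value, error. Missing
    (site, condition) cells are simply absent rows; they are excluded from
    means with a note in the profile.
    """

    data: pd.DataFrame
    name: str = ""

    REQUIRED = ("site", "parameter", "condition", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InvalidParameterError(f"table missing columns {missing}")
        if "error" not in self.data.columns:
            self.data = self.data.assign(error=np.nan)
        if (self.data["value"] <= 0).any():
            raise InvalidParameterError("parameter values must be positive")
        dup = self.data.duplicated(subset=["site", "parameter", "condition"])
        if dup.any():
            raise InvalidParameterError("duplicate (site, parameter, condition) rows")

    @property
    def sites(self) -> list:
        return sorted(self.data["site"].unique().tolist())

    @property
    def parameters(self) -> list[str]:
        return sorted(self.data["parameter"].unique().tolist())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique().tolist())

    def select(self, parameter: str, condition: str) -> pd.DataFrame:
        sel = self.data[
            (self.data["parameter"] == parameter)
            & (self.data["condition"] == condition)
        ]
        if sel.empty:
            raise KeyError(
                f"no rows for parameter={parameter!r}, condition={condition!r}"
            )
        return sel.sort_values("site")


@dataclass
class DispersionProfile:
    """Per-site relative deviations from the cross-site mean."""

    sites: np.ndarray
    deviations: np.ndarray
    rms_flatness: float
    mean_value: float
    parameter: str = ""
    condition: str = ""
    missing_sites: list = field(default_factory=list)


@dataclass
class FlatnessComparison:
    """RMS flatness of two conditions with a bootstrap interval on the ratio."""

    rms_a: float
    rms_b: float
    ratio: float  # rms_a / rms_b
    bootstrap_interval: tuple[float, float]
    n_boot: int


def load_reference_table(name: str) -> SiteParameterTable:
    """Load one of the bundled published site-parameter tables.

    ``name`` is one of ``"minirose_free"`` (three conditions: 20C, 45C,
    45C+urea), ``"minirose_bound"`` (ribosome-bound, 20C and 45C) or
    ``"minirose_g15del"`` (lifetimes of the deletion construct).
    """
    if name not in REFERENCE_TABLES:
        raise KeyError(f"unknown reference table {name!r}; choose from {REFERENCE_TABLES}")
    ref = resources.files("tcspcfit.data").joinpath(f"{name}.tsv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return SiteParameterTable(data=df, name=name)


def dispersion_profile(
    table: SiteParameterTable, parameter: str, condition: str
) -> DispersionProfile:
    """Relative per-site deviations of one parameter under one condition.

    The mean is taken over all sites available for the condition; sites
    present elsewhere in the table but missing here are listed in
    ``missing_sites``. Deviations sum to zero by construction.
    """
    sel = table.select(parameter, condition)
    values = sel["value"].to_numpy(dtype=float)
    sites = sel["site"].to_numpy()
    if len(values) < 2:
        raise ValueError("dispersion needs at least 2 sites")
    mean = float(values.mean())
    if mean <= 0:
        raise InvalidParameterError("mean parameter value must be positive")
    dev = (values - mean) / mean
    missing = [s for s in table.sites if s not in set(sites.tolist())]
    return DispersionProfile(
        sites=sites,
        deviations=dev,
        rms_flatness=float(np.sqrt(np.mean(dev**2))),
        mean_value=mean,
        parameter=parameter,
        condition=condition,
        missing_sites=missing,
    )


def _rms_deviation(values: np.ndarray) -> float:
    mean = values.mean()
    return float(np.sqrt(np.mean(((values - mean) / mean) ** 2)))


def flatness_compare(
    table: SiteParameterTable,
    parameter: str,
    condition_a: str,
    condition_b: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> FlatnessComparison:
    """Compare site dispersion of one parameter between two conditions.

    Returns the RMS relative deviation under each condition, their ratio
    (``rms_a / rms_b``; > 1 means condition A is less flat), and a 95%
    bootstrap interval on the ratio obtained by resampling each site's value
    from a normal distribution centred on the reported value with the
    reported uncertainty as standard deviation. Sites without a reported
    uncertainty are held fixed during resampling.
    """
    sel_a = table.select(parameter, condition_a)
    sel_b = table.select(parameter, condition_b)
    va = sel_a["value"].to_numpy(dtype=float)
    vb = sel_b["value"].to_numpy(dtype=float)
    ea = np.nan_to_num(sel_a["error"].to_numpy(dtype=float), nan=0.0)
    eb = np.nan_to_num(sel_b["error"].to_numpy(dtype=float), nan=0.0)
    rms_a = _rms_deviation(va)
    rms_b = _rms_deviation(vb)
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        ra = _rms_deviation(np.maximum(va + ea * rng.standard_normal(len(va)), 1e-12))
        rb = _rms_deviation(np.maximum(vb + eb * rng.standard_normal(len(vb)), 1e-12))
        ratios[i] = ra / rb if rb > 0 else np.inf
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return FlatnessComparison(
        rms_a=rms_a,
        rms_b=rms_b,
        ratio=rms_a / rms_b if rms_b > 0 else float("inf"),
        bootstrap_interval=(float(lo), float(hi)),
        n_boot=n_boot,
    )
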