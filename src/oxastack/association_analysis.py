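"""Aggregation numbers from concentration-dependent diffusion NMR data.

The observed translational diffusion coefficient D_obs(c) of a
self-associating solute slows as associates grow.  With an inert internal
standard (e.g. TMS) measured alongside, bulk-viscosity changes are divided
out,

    D_corr(c) = D_obs(c) * D_ref(c_min) / D_ref(c),

D_0 is recovered by extrapolating D_corr to infinite dilution (ordinary
least squares, linear in c by default, optionally linear in sqrt(c)), and
the aggregation number at any concentration is the Stokes-Einstein cube

    N(c) = (D_0 / D_obs(c))**3,

the effective mean association multiplicity (N = 1: no association; N = 8
would mean diffusion slowed two-fold).

The module exposes both plain functions and a small statsmodels-flavoured
``DiffusionModel`` / ``DiffusionResults`` pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DiffusionSeries", "viscosity_correct", "extrapolate_D0",
           "aggregation_number", "DiffusionModel", "DiffusionResults"]


@dataclass
class DiffusionSeries:
    """Concentrations (mM), observed D, optional internal-standard D.

    Units of D are whatever the experiment reports (typically 1e-10 m^2/s);
    only ratios enter the aggregation number.
    """

    concentration: np.ndarray
    d_obs: np.ndarray
    d_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.d_obs = np.asarray(self.d_obs, dtype=float)
        if self.d_ref is not None:
            self.d_ref = np.asarray(self.d_ref, dtype=float)
        if self.concentration.shape != self.d_obs.shape:
            raise ValueError("concentration and d_obs must have equal length")
        if self.d_ref is not None and self.d_ref.shape != self.d_obs.shape:
            raise ValueError("d_ref length must match d_obs")
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.d_obs <= 0):
            raise ValueError("diffusion coefficients must be positive")

    def __len__(self) -> int:
        return len(self.concentration)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, concentration: str = "c_mM",
                       d_obs: str = "D_obs", d_ref: str = "D_ref") -> "DiffusionSeries":
        ref = df[d_ref].to_numpy() if d_ref in df.columns else None
        return cls(df[concentration].to_numpy(), df[d_obs].to_numpy(), ref)

    @classmethod
    def from_table(cls, path, **kwargs) -> "DiffusionSeries":
        df = pd.read_csv(path, sep=None, engine="python")
        return cls.from_dataframe(df, **kwargs)


def viscosity_correct(series: DiffusionSeries) -> np.ndarray:
    """Internal-standard viscosity correction (reference: lowest measured c).

    D_corr(c) = D_obs(c) * D_ref(c_min) / D_ref(c); a no-op without d_ref.
    """
    if series.d_ref is None:
        return series.d_obs.copy()
    if np.any(series.d_ref == 0):
        raise ValueError("internal-standard diffusion coefficients contain zero")
    return series.d_obs * (series.d_ref[0] / series.d_ref)


def extrapolate_D0(series: DiffusionSeries, trend: str = "linear") -> float:
    """OLS intercept of the viscosity-corrected D at c = 0."""
    return DiffusionModel(series, trend=trend).fit().d0


def aggregation_number(d0: float, d_obs) -> np.ndarray | float:
    """N = (D0 / D_obs)^3."""
    if d0 <= 0 or np.any(np.asarray(d_obs) <= 0):
        raise ValueError("diffusion coefficients must be positive")
    return (d0 / np.asarray(d_obs, dtype=float)) ** 3 if np.ndim(d_obs) else \
        float((d0 / d_obs) ** 3)


class DiffusionModel:
    """Infinite-dilution extrapolation model for a diffusion series.

    ``trend`` selects the regressor: ``"linear"`` (D vs c, the default) or
    ``"sqrt"`` (D vs sqrt(c)).
    """

    def __init__(self, series: DiffusionSeries, trend: str = "linear"):
        if trend not in ("linear", "sqrt"):
            raise ValueError(f"unknown trend {trend!r}")
        if len(series) < 2:
            raise ValueError("need at least two concentrations to extrapolate")
        self.series = series
        self.trend = trend

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, trend: str = "linear",
                       **cols) -> "DiffusionModel":
        return cls(DiffusionSeries.from_dataframe(df, **cols), trend=trend)

    @property
    def exog(self) -> np.ndarray:
        c = self.series.concentration
        return np.sqrt(c) if self.trend == "sqrt" else c

    def fit(self) -> "DiffusionResults":
        d_corr = viscosity_correct(self.series)
        x = self.exog
        if len(self.series) == 2:
            slope = (d_corr[1] - d_corr[0]) / (x[1] - x[0])
            intercept = d_corr[0] - slope * x[0]
            d0_se = slope_se = np.nan
            rvalue = 1.0
        else:
            res = stats.linregress(x, d_corr)
            slope, intercept = res.slope, res.intercept
            d0_se, slope_se = res.intercept_stderr, res.stderr
            rvalue = res.rvalue
        return DiffusionResults(model=self, d_corr=d_corr,
                                d0=float(intercept), slope=float(slope),
                                d0_se=float(d0_se), slope_se=float(slope_se),
                                rvalue=float(rvalue))


@dataclass
class DiffusionResults:
    """Fit results: D0 (+- se), slope, per-concentration aggregation numbers."""

    model: DiffusionModel
    d_corr: np.ndarray
    d0: float
    slope: float
    d0_se: float
    slope_se: float
    rvalue: float

    @property
    def params(self) -> dict[str, float]:
        return {"d0": self.d0, "slope": self.slope}

    @property
    def bse(self) -> dict[str, float]:
        return {"d0": self.d0_se, "slope": self.slope_se}

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.d0 + self.slope * self.model.exog

    @property
    def resid(self) -> np.ndarray:
        return self.d_corr - self.fittedvalues

    @property
    def aggregation_numbers(self) -> np.ndarray:
        return aggregation_number(self.d0, self.d_corr)

    def aggregation_at(self, concentration: float) -> float:
        """N at a measured concentration (nearest measured point)."""
        idx = int(np.argmin(np.abs(self.model.series.concentration - concentration)))
        return float(self.aggregation_numbers[idx])

    def to_dict(self) -> dict:
        s = self.model.series
        return {
            "D0": self.d0,
            "D0_se": self.d0_se,
            "slope": self.slope,
            "trend": self.model.trend,
            "aggregation": [
                {"c_mM": float(c), "D_corr": float(d), "N": float(n)}
                for c, d, n in zip(s.concentration, self.d_corr,
                                   self.aggregation_numbers)
            ],
        }

    def summary(self) -> str:
        s = self.model.series
        lines = [
            "Diffusion association fit",
            "=" * 44,
            f"n points            {len(s):>10d}",
            f"trend               {self.model.trend:>10s}",
            f"D0 (intercept)      {self.d0:>10.4f} +/- {self.d0_se:.4f}",
            f"slope               {self.slope:>10.3e} +/- {self.slope_se:.3e}",
            f"r                   {self.rvalue:>10.4f}",
            "-" * 44,
            f"{'c_mM':>8s} {'D_corr':>10s} {'N':>8s}",
        ]
        for c, d, n in zip(s.concentration, self.d_corr, self.aggregation_numbers):
            lines.append(f"{c:8.1f} {d:10.4f} {n:8.3f}")
        return "\n".join(lines)
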