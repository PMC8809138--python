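"""Setschenow-coefficient extraction from concentration series.

The Setschenow relation, ln[S(0)/S(c_s)] = k_s c_s (natural-log convention),
links the salt-induced solubility change to the change of the solvation free
energy: ddG_sol(c_s) = R T k_s c_s.  The coefficient is therefore obtained as
the ordinary-least-squares slope of the replicate-mean solvation free energy
against salt concentration, divided by R T.  A positive k_s is salting-out
(solubility decreases with added salt), a negative k_s salting-in.  Because
OLS is linear in the response, the decomposed series (per species, per
energy domain, self term) carry k_s contributions that sum exactly to the
total.

Confidence intervals follow the replicate structure of the data:
non-parametric bootstrap resampling of replicate-level free energies,
independently at each concentration, refitting the slope each time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_KCAL, R_LATM

__all__ = [
    "ConcentrationSeries",
    "SetschenowResult",
    "setschenow_from_series",
    "bootstrap_ci",
    "vapor_pressure_from_dG",
    "dG_from_vapor_pressure",
]

#: Default number of bootstrap resamples.
DEFAULT_N_BOOT = 100_000


@dataclass
class ConcentrationSeries:
    """Replicate-level values of one labelled free-energy quantity vs concentration.

    ``data`` columns: concentration (mol/L), replicate_id, value (kcal/mol).
    ``label`` names the quantity (e.g. "total", "anion", "int_water",
    "EV_anion", "self").
    """

    data: pd.DataFrame
    label: str = "total"

    def __post_init__(self) -> None:
        req = {"concentration", "replicate_id", "value"}
        missing = req - set(self.data.columns)
        if missing:
            raise ValueError(f"series data missing columns {sorted(missing)}")
        if (self.data["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.data.empty:
            raise ValueError("empty concentration series")

    @classmethod
    def from_arrays(cls, concentrations, values, replicate_ids=None, label="total"):
        conc = np.asarray(concentrations, dtype=float)
        vals = np.asarray(values, dtype=float)
        if replicate_ids is None:
            replicate_ids = np.zeros(len(conc), dtype=int)
            for c in np.unique(conc):
                sel = conc == c
                replicate_ids[sel] = np.arange(sel.sum())
        return cls(
            data=pd.DataFrame(
                {"concentration": conc, "replicate_id": replicate_ids, "value": vals}
            ),
            label=label,
        )

    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration"].unique())

    def replicate_values(self) -> dict[float, np.ndarray]:
        return {
            float(c): g["value"].to_numpy()
            for c, g in self.data.groupby("concentration", sort=True)
        }

    def means(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.data.groupby("concentration", sort=True)["value"].mean()
        return g.index.to_numpy(dtype=float), g.to_numpy()


@dataclass
class SetschenowResult:
    """Fitted Setschenow coefficient (natural-log convention, 1/(mol/L))."""

    label: str
    ks: float
    slope: float
    intercept: float
    temperature: float
    r_squared: float
    r_squared_points: float
    p_value: float
    ci95: tuple[float, float] = (np.nan, np.nan)
    n_boot: int = 0
    seed: Optional[int] = None

    @property
    def ks_decimal(self) -> float:
        """Decimal-logarithm convention, ks / ln(10)."""
        return self.ks / np.log(10.0)


def _ols(conc: np.ndarray, y: np.ndarray, anchor_zero: bool, y0: float | None):
    """Slope/intercept; optionally anchored at the zero-salt mean."""
    if anchor_zero:
        if y0 is None:
            raise ValueError("anchored fit needs a zero-concentration point")
        mask = conc > 0
        num = float(np.sum(conc[mask] * (y[mask] - y0)))
        den = float(np.sum(conc[mask] ** 2))
        return num / den, y0
    cbar = conc.mean()
    den = float(np.sum((conc - cbar) ** 2))
    slope = float(np.sum((conc - cbar) * (y - y.mean()))) / den
    return slope, float(y.mean() - slope * cbar)


def setschenow_from_series(
    series: ConcentrationSeries,
    temperature: float,
    anchor_zero: bool = False,
) -> SetschenowResult:
    """OLS fit of replicate-mean free energies vs concentration; ks = slope/(R T).

    ``anchor_zero=True`` forces the line through the zero-salt mean instead of
    fitting a free intercept.  R^2 and the two-sided p-value are reported for
    the fit over concentration means; ``r_squared_points`` is the same
    statistic over all replicate-level points.
    """
    conc, y = series.means()
    if len(conc) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    y0 = float(y[conc == 0.0][0]) if np.any(conc == 0.0) else None
    slope, intercept = _ols(conc, y, anchor_zero, y0)
    if np.allclose(y, y[0]):
        r2 = np.nan
        p = np.nan
        r2_pts = np.nan
    else:
        fit = stats.linregress(conc, y)
        r2 = float(fit.rvalue**2)
        p = float(fit.pvalue)
        all_c = series.data["concentration"].to_numpy(dtype=float)
        all_y = series.data["value"].to_numpy(dtype=float)
        if len(np.unique(all_c)) >= 2 and not np.allclose(all_y, all_y[0]):
            r2_pts = float(stats.linregress(all_c, all_y).rvalue ** 2)
        else:
            r2_pts = np.nan
    return SetschenowResult(
        label=series.label,
        ks=slope / (R_KCAL * temperature),
        slope=slope,
        intercept=intercept,
        temperature=temperature,
        r_squared=r2,
        r_squared_points=r2_pts,
        p_value=p,
    )


def bootstrap_ci(
    series: ConcentrationSeries,
    n_boot: int,
    temperature: float,
    seed: int,
    anchor_zero: bool = False,
) -> tuple[float, float]:
    """Percentile 95% CI of ks by non-parametric bootstrap.

    Replicate-level values are resampled with replacement independently at
    each concentration; each resample is refit by the same OLS estimator.
    Deterministic for a given seed.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    groups = series.replicate_values()
    conc = np.array(sorted(groups), dtype=float)
    means = np.empty((n_boot, len(conc)))
    for j, c in enumerate(conc):
        vals = groups[float(c)]
        k = len(vals)
        idx = rng.integers(0, k, size=(n_boot, k))
        means[:, j] = vals[idx].mean(axis=1)
    if anchor_zero:
        if not np.any(conc == 0.0):
            raise ValueError("anchored fit needs a zero-concentration point")
        j0 = int(np.argmax(conc == 0.0))
        mask = conc > 0
        dy = means[:, mask] - means[:, [j0]]
        slopes = (dy * conc[mask]).sum(axis=1) / np.sum(conc[mask] ** 2)
    else:
        cbar = conc.mean()
        w = (conc - cbar) / np.sum((conc - cbar) ** 2)
        slopes = means @ w
    ks = slopes / (R_KCAL * temperature)
    lo, hi = np.percentile(ks, [2.5, 97.5])
    return float(lo), float(hi)


def fit_with_ci(
    series: ConcentrationSeries,
    temperature: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    anchor_zero: bool = False,
) -> SetschenowResult:
    """Convenience: OLS fit plus bootstrap CI in one SetschenowResult."""
    res = setschenow_from_series(series, temperature, anchor_zero=anchor_zero)
    res.ci95 = bootstrap_ci(series, n_boot, temperature, seed, anchor_zero=anchor_zero)
    res.n_boot = n_boot
    res.seed = seed
    return res


def vapor_pressure_from_dG(
    dG: float, liquid_density: float, temperature: float
) -> float:
    """Partial vapour pressure (atm) of a solute with solvation free energy dG.

    Assumes an ideal vapour in equilibrium with the liquid at molar density
    ``liquid_density`` (mol/L): P = rho_l R T exp(dG / R T), so a more
    negative dG gives a lower vapour pressure.
    """
    if liquid_density <= 0:
        raise ValueError("liquid_density must be positive")
    return liquid_density * R_LATM * temperature * np.exp(dG / (R_KCAL * temperature))


def dG_from_vapor_pressure(
    pressure: float, liquid_density: float, temperature: float
) -> float:
    """Inverse of :func:`vapor_pressure_from_dG` (pressure in atm)."""
    if liquid_density <= 0 or pressure <= 0:
        raise ValueError("pressure and liquid_density must be positive")
    return R_KCAL * temperature * np.log(
        pressure / (liquid_density * R_LATM * temperature)
    )
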