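"""Derived soil indexes and the index-index correlation matrix.

Microbial biomass carbon and nitrogen follow the chloroform
fumigation-extraction formulas: the fumigated-minus-unfumigated extractable C
(or N) difference divided by the conversion constant Kc = 0.38 (Kn = 0.54).
Respiration intensity is CO2 mass per kilogram of soil per hour, from the
alkali-absorption measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import INDEX_COLUMNS

__all__ = [
    "KC_DEFAULT",
    "KN_DEFAULT",
    "FumigationMeasurement",
    "IndexCorrelationMatrix",
    "MeasurementOrderError",
    "microbial_biomass_carbon",
    "microbial_biomass_nitrogen",
    "respiration_rate",
    "index_correlation_matrix",
    "permutation_pvalue",
]

#: Fraction of microbial biomass C rendered extractable by fumigation.
KC_DEFAULT = 0.38
#: Fraction of microbial biomass N rendered extractable by fumigation.
KN_DEFAULT = 0.54


class MeasurementOrderError(ValueError):
    """Fumigated extract below unfumigated: inputs are almost surely swapped."""


@dataclass(frozen=True)
class FumigationMeasurement:
    """Paired fumigated/unfumigated extractable C and N, mg per kg soil."""

    c_fumigated: float
    c_unfumigated: float
    n_fumigated: float
    n_unfumigated: float
    kc: float = KC_DEFAULT
    kn: float = KN_DEFAULT


def microbial_biomass_carbon(m: FumigationMeasurement) -> float:
    """MBC = (fumigated C − unfumigated C) / Kc, in mg C per kg soil."""
    ec = m.c_fumigated - m.c_unfumigated
    if ec < 0:
        raise MeasurementOrderError(
            f"fumigated C ({m.c_fumigated}) < unfumigated C ({m.c_unfumigated})"
        )
    return ec / m.kc


def microbial_biomass_nitrogen(m: FumigationMeasurement) -> float:
    """MBN = (fumigated N − unfumigated N) / Kn, in mg N per kg soil."""
    en = m.n_fumigated - m.n_unfumigated
    if en < 0:
        raise MeasurementOrderError(
            f"fumigated N ({m.n_fumigated}) < unfumigated N ({m.n_unfumigated})"
        )
    return en / m.kn


def respiration_rate(co2_mass: float, soil_mass: float, duration: float) -> float:
    """Respiration intensity = CO2 mass / (soil mass * duration), mg CO2/kg.h."""
    if soil_mass <= 0 or duration <= 0:
        raise ValueError("soil_mass and duration must be positive")
    if co2_mass < 0:
        raise ValueError("co2_mass must be non-negative")
    return co2_mass / (soil_mass * duration)


@dataclass(frozen=True)
class IndexCorrelationMatrix:
    """Pairwise index correlations with significance stars.

    ``stars`` holds "" / "*" / "**" for p >= 0.05, p < 0.05 and p < 0.01.
    Cells involving a constant column are NaN and listed in ``undefined``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    method: str
    undefined: tuple = ()

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, r, p, stars), upper triangle only."""
        cols = list(self.r.columns)
        rows = [
            {
                "var1": a,
                "var2": b,
                "r": self.r.loc[a, b],
                "p": self.p.loc[a, b],
                "stars": self.stars.loc[a, b],
            }
            for i, a in enumerate(cols)
            for b in cols[i + 1 :]
        ]
        return pd.DataFrame(rows)


def _stars(p: float, alpha_levels: tuple[float, float]) -> str:
    if np.isnan(p):
        return ""
    if p < alpha_levels[1]:
        return "**"
    if p < alpha_levels[0]:
        return "*"
    return ""


def index_correlation_matrix(
    table: pd.DataFrame,
    method: str = "pearson",
    alpha_levels: tuple[float, float] = (0.05, 0.01),
    columns: tuple = INDEX_COLUMNS,
) -> IndexCorrelationMatrix:
    """All pairwise correlations among the soil/microbial index columns.

    Parameters
    ----------
    table
        Per-sample index table (replicate level by default; pass group means
        for a group-level matrix).
    method
        "pearson" (default) or "spearman".
    alpha_levels
        The (*, **) significance thresholds.

    Constant columns yield NaN r/p for their cells, recorded in
    ``undefined`` rather than raised.
    """
    cols = [c for c in columns if c in table.columns]
    data = table[cols].astype(float)
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")

    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    undefined = []
    constant = {c for c in cols if np.ptp(data[c].to_numpy()) == 0.0}
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in constant or b in constant:
                rv, pv = np.nan, np.nan
                undefined.append((a, b))
            elif method == "pearson":
                rv, pv = stats.pearsonr(data[a], data[b])
            elif method == "spearman":
                rv, pv = stats.spearmanr(data[a], data[b])
            else:
                raise ValueError(f"unknown method {method!r}")
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    for c in constant:
        r.loc[c, c] = np.nan
        p.loc[c, c] = np.nan

    stars = p.map(lambda v: _stars(v, alpha_levels))
    for c in cols:
        stars.loc[c, c] = ""
    return IndexCorrelationMatrix(r=r, p=p, stars=stars, method=method, undefined=tuple(undefined))


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for the Pearson correlation.

    Test oracle: shuffles ``y`` ``n_perm`` times and counts |r| at least as
    large as observed, with the +1 small-sample correction.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(stats.pearsonr(x, y)[0])
    xc = x - x.mean()
    xn = xc / np.sqrt((xc**2).sum())
    hits = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        yc = yp - yp.mean()
        r = abs(np.dot(xn, yc) / np.sqrt((yc**2).sum()))
        if r >= r_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
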