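"""Classification of notable beaching cells from regression residuals.

The number of beaching events per (cell, quarter) record is regressed on
the local standardized dFAD density with quarter as an additive categorical
factor.  Residual percentiles then classify cells as beaching-prone
(residual above the 90th percentile), beaching-resilient (below the 10th,
with high local density) or high-density (central residuals with a high
beaching count).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "BeachingModel",
    "fit_beaching_model",
    "classify_cells",
    "CLASS_HIGH_DENSITY",
    "CLASS_PRONE",
    "CLASS_RESILIENT",
    "CLASS_NONE",
]

CLASS_HIGH_DENSITY = "high_density"
CLASS_PRONE = "beaching_prone"
CLASS_RESILIENT = "beaching_resilient"
CLASS_NONE = "unclassified"

REQUIRED = ["cell", "quarter", "n_beaching", "density"]


@dataclass
class BeachingModel:
    """Fitted OLS of beaching counts on density with a seasonal factor."""

    result: object                 # statsmodels results
    residuals: np.ndarray
    r_squared: float
    p_value: float                 # overall F-test
    used_quarter_factor: bool
    n: int

    @property
    def params(self) -> pd.Series:
        return self.result.params

    def quarter_offsets(self) -> dict:
        """Additive quarter effects relative to the first quarter present."""
        out = {}
        for name, val in self.result.params.items():
            if name.startswith("C(quarter)"):
                q = int(name.split("T.")[1].rstrip("]"))
                out[q] = float(val)
        return out

    def summary_text(self) -> str:
        return str(self.result.summary())


def fit_beaching_model(records: pd.DataFrame) -> BeachingModel:
    """OLS of n_beaching on density plus quarter as a categorical factor.

    With a single quarter (rank-deficient seasonal design) the factor is
    dropped with a warning.
    """
    missing = [c for c in REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns {missing}")
    if len(records) < 8:
        raise ValueError("need at least 8 (cell, quarter) records")
    df = records.copy()
    quarters = df["quarter"].nunique()
    if quarters < 2:
        warnings.warn("single quarter present; dropping the seasonal factor",
                      UserWarning, stacklevel=2)
        formula = "n_beaching ~ density"
        used = False
    else:
        formula = "n_beaching ~ density + C(quarter)"
        used = True
    res = smf.ols(formula, data=df).fit()
    return BeachingModel(res, np.asarray(res.resid), float(res.rsquared),
                         float(res.f_pvalue), used, len(df))


def classify_cells(records: pd.DataFrame, residuals: np.ndarray,
                   *, prone_pct: float = 90.0, resilient_pct: float = 10.0,
                   central_band: tuple = (45.0, 55.0),
                   count_pct: float = 80.0,
                   center_band_on: str = "residuals") -> pd.DataFrame:
    """Classify (cell, quarter) records by residual percentiles.

    beaching_prone: residual strictly above the `prone_pct` percentile.
    beaching_resilient: residual strictly below the `resilient_pct`
    percentile and density above the median (high local density).
    high_density: residual within the central band and n_beaching strictly
    above the `count_pct` percentile of counts.  `center_band_on` selects
    whether the central band is taken over residuals (default) or density.
    """
    if center_band_on not in ("residuals", "density"):
        raise ValueError("center_band_on must be 'residuals' or 'density'")
    resid = np.asarray(residuals, dtype=float)
    if len(resid) != len(records):
        raise ValueError("residuals length does not match records")
    dens = records["density"].to_numpy(float)
    counts = records["n_beaching"].to_numpy(float)

    hi = np.percentile(resid, prone_pct)
    lo = np.percentile(resid, resilient_pct)
    med_density = np.median(dens)
    band_var = resid if center_band_on == "residuals" else dens
    band_lo, band_hi = np.percentile(band_var, central_band)
    count_thr = np.percentile(counts, count_pct)

    cls = np.full(len(records), CLASS_NONE, dtype=object)
    central = (band_var >= band_lo) & (band_var <= band_hi) & (counts > count_thr)
    cls[central] = CLASS_HIGH_DENSITY
    cls[(resid < lo) & (dens > med_density)] = CLASS_RESILIENT
    cls[resid > hi] = CLASS_PRONE

    out = records[["cell", "quarter", "n_beaching", "density"]].copy()
    out["residual"] = resid
    out["cell_class"] = cls
    return out
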