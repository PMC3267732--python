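"""Growth-temperature prediction from 16S rRNA G+C content.

The G+C content of the 16S rRNA gene correlates linearly with growth
temperature in prokaryotes (GC pairs stabilise rRNA secondary structure at
high temperature), so an ordinary least-squares line fitted to known
(GC%, maximum growth temperature) points predicts the thermal class of an
uncultivated organism from its 16S sequence alone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["GCTemperatureRegressor", "fit_points", "predict_temperature"]


class GCTemperatureRegressor(RegressorMixin, BaseEstimator):
    """OLS regression of maximum growth temperature on 16S GC%.

    Attributes (after fit)
    ----------------------
    slope_ : float          degC per GC percentage point
    intercept_ : float      degC
    r_squared_ : float
    residuals_ : ndarray
    n_points_ : int
    gc_range_ : (float, float)   fitted x range, for extrapolation warnings
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size or x.size < 2:
            raise ValueError("need >= 2 (gc, temperature) points")
        if np.ptp(x) == 0:
            raise ValueError("all GC values identical: slope undefined")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.residuals_ = y - (self.slope_ * x + self.intercept_)
        self.n_points_ = int(x.size)
        self.gc_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        lo, hi = self.gc_range_
        if np.any((x < lo) | (x > hi)):
            warnings.warn(
                f"GC value outside the fitted range [{lo:.1f}, {hi:.1f}]: "
                "prediction is an extrapolation",
                stacklevel=2,
            )
        return self.slope_ * x + self.intercept_


def fit_points(points: pd.DataFrame | list[tuple[float, float]]) -> GCTemperatureRegressor:
    """Fit from a (gc_percent, t_max_celsius) table or list of pairs."""
    if isinstance(points, pd.DataFrame):
        x, y = points["gc_percent"].to_numpy(), points["t_max_celsius"].to_numpy()
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    return GCTemperatureRegressor().fit(x, y)


def predict_temperature(model: GCTemperatureRegressor, gc: float) -> float:
    """Predicted maximum growth temperature (degC) at a 16S GC%."""
    return float(model.predict([gc])[0])
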