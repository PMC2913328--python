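"""Univariate logP -> logBCF baseline models.

Four published single-descriptor linear regressions of log10 BCF on a
calculated logP (from the ACD, Kowwin, MDL and Moriguchi/Dragon logP
programs) ship as frozen constants, and a generic univariate fitter
reproduces the same model layout on any dataset.  The hybrid machine-
learning BCF model whose predictions this toolkit assesses is *not*
re-implemented here; its output enters the pipeline as data
(``CompoundRecord.predicted_logbcf``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class DegenerateDesignError(ValueError):
    """x is constant (or too short): the univariate fit is undefined."""


@dataclass(frozen=True)
class LinearModelSpec:
    """A univariate linear model logBCF = slope * logP + intercept.

    ``r``, ``r2`` and ``f_value`` are descriptive statistics of the fit.
    For the built-in published models they are stored verbatim as printed,
    including one row whose printed R and R² are mutually inconsistent
    beyond rounding; :meth:`consistency_gap` exposes |r² − r2| so callers
    can check, while construction never rejects published constants.
    """

    name: str
    slope: float
    intercept: float
    r: float | None = None
    r2: float | None = None
    f_value: float | None = None

    def consistency_gap(self) -> float | None:
        """|r² − r2| when both are present, else None."""
        if self.r is None or self.r2 is None:
            return None
        return abs(self.r**2 - self.r2)

    def predict(self, logp: float) -> float:
        return predict_logbcf(logp, self)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "LinearModelSpec":
        return cls(**json.loads(payload))


# Published regression coefficients of logBCF on four calculated logP
# variants, with the printed R, R² and F statistics.  The underlying
# training data is not shipped, so these are frozen metadata, not re-fits.
_BUILTIN = (
    LinearModelSpec("acd", slope=0.305, intercept=0.767, r=0.605, r2=0.336, f_value=217.442),
    LinearModelSpec("kowwin", slope=0.357, intercept=0.605, r=0.657, r2=0.432, f_value=266.931),
    LinearModelSpec("mdl", slope=0.481, intercept=0.290, r=0.737, r2=0.543, f_value=448.043),
    LinearModelSpec("mlogp", slope=0.555, intercept=0.117, r=0.746, r2=0.556, f_value=471.748),
)


def builtin_models() -> list[LinearModelSpec]:
    """The four published logP→logBCF model specs, in source order."""
    return list(_BUILTIN)


def get_model(name: str) -> LinearModelSpec:
    for m in _BUILTIN:
        if m.name == name:
            return m
    raise KeyError(f"no built-in model {name!r}; choose from "
                   f"{[m.name for m in _BUILTIN]}")


def predict_logbcf(logp: float, model: LinearModelSpec) -> float:
    """slope·logp + intercept for a single logP value."""
    if not math.isfinite(logp):
        raise ValueError(f"logp must be finite, got {logp!r}")
    return model.slope * logp + model.intercept


def fit_univariate(x, y, name: str = "fitted") -> LinearModelSpec:
    """Least-squares fit of y on x with r, r², and the regression F.

    F uses the conventional one-predictor ANOVA definition,
    F = r²(n−2)/(1−r²) with (1, n−2) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise DegenerateDesignError(f"need at least 3 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("x is constant; slope is undefined")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    r2 = r * r
    if r2 >= 1.0:
        f = math.inf
    else:
        f = r2 * (n - 2) / (1.0 - r2)
    return LinearModelSpec(
        name=name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        r2=r2,
        f_value=f,
    )


class UnivariateLogPRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapper around the univariate logP model.

    Parameters
    ----------
    model : str or None, default=None
        Name of a built-in published model ("acd", "kowwin", "mdl",
        "mlogp").  When set, :meth:`fit` freezes the published
        coefficients instead of estimating them; when None, ordinary
        least squares is run on the training data.

    Attributes
    ----------
    slope_, intercept_ : float
        Model coefficients.
    r_, r2_, f_value_ : float or None
        Pearson correlation, its square, and the regression F statistic
        (printed metadata for built-in models).
    spec_ : LinearModelSpec
        The full fitted (or frozen) model spec.
    """

    def __init__(self, model: str | None = None):
        self.model = model

    def fit(self, X, y=None):
        if self.model is not None:
            spec = get_model(self.model)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 2:
                if X.shape[1] != 1:
                    raise ValueError("univariate model: X must have one column")
                X = X[:, 0]
            spec = fit_univariate(X, np.asarray(y, dtype=float))
        self.spec_ = spec
        self.slope_ = spec.slope
        self.intercept_ = spec.intercept
        self.r_ = spec.r
        self.r2_ = spec.r2
        self.f_value_ = spec.f_value
        return self

    def predict(self, X):
        check_is_fitted(self, "spec_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        if not np.all(np.isfinite(X)):
            raise ValueError("logp values must be finite")
        return self.slope_ * X + self.intercept_
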