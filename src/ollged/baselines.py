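"""Nested and rival baseline models: GE, exponential and log-logistic.

These are the comparison models of the applications: the generalized
exponential (GE) and plain exponential are nested inside the OLLGE family
(``gamma = 1`` and ``gamma = alpha = 1`` respectively), so their maximized
log-likelihoods can never exceed the OLLGE one on the same sample; the
two-parameter log-logistic is a non-nested rival.

Each family plugs into the shared multi-start ML machinery of
:mod:`ollged.inference`; the exponential additionally has the textbook
closed-form MLE ``lambda_hat = 1/xbar`` with ``-2l = 2n(1 + ln xbar)``,
which doubles as an analytic oracle for the whole likelihood stack.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

from .distribution import _log1mexp
from .inference import (
    Family,
    FitResult,
    LifetimeResults,
    ParametricLifetimeModel,
    Sample,
    fit_mle,
)

__all__ = [
    "GE_FAMILY",
    "ED_FAMILY",
    "LLD_FAMILY",
    "GeneralizedExponential",
    "Exponential",
    "LogLogistic",
    "BaselineModel",
    "ged_model",
    "ed_model",
    "lld_model",
]


class _GEFamily(Family):
    """Generalized exponential: F(x) = (1 - e^{-lambda x})^alpha."""

    name = "ged"
    param_names = ("lambda", "alpha")
    tie_break_index = 1

    def logpdf(self, x, theta):
        lam, alpha = theta
        xa = np.asarray(x, dtype=float)
        out = np.full(np.atleast_1d(xa).shape, -np.inf)
        x1 = np.atleast_1d(xa)
        pos = x1 > 0
        t = lam * x1[pos]
        with np.errstate(divide="ignore"):
            out[pos] = np.log(alpha) + np.log(lam) - t + (alpha - 1.0) * _log1mexp(-t)
        return out.item() if xa.ndim == 0 else out

    def cdf(self, x, theta):
        lam, alpha = theta
        xa = np.asarray(x, dtype=float)
        x1 = np.atleast_1d(xa)
        out = np.zeros(x1.shape)
        pos = x1 > 0
        out[pos] = np.exp(alpha * _log1mexp(-lam * x1[pos]))
        return out.item() if xa.ndim == 0 else out

    def ppf(self, q, theta):
        lam, alpha = theta
        qa = np.asarray(q, dtype=float)
        if np.any(qa <= 0) or np.any(qa >= 1):
            raise ValueError("q must lie strictly inside (0, 1)")
        return -_log1mexp(np.log(qa) / alpha) / lam

    def start_grid(self, sample: Sample, reduced: bool = False) -> np.ndarray:
        lam0 = 1.0 / sample.mean
        shape_vals = (0.2, 1.0, 5.0)
        scale_vals = (1.0,) if reduced else (0.2, 1.0, 5.0)
        return np.array([[lam0 * s, a] for s in scale_vals for a in shape_vals])


class _EDFamily(Family):
    """Exponential: F(x) = 1 - e^{-lambda x}; closed-form MLE 1/xbar."""

    name = "ed"
    param_names = ("lambda",)
    tie_break_index = 0

    def logpdf(self, x, theta):
        (lam,) = theta
        xa = np.asarray(x, dtype=float)
        x1 = np.atleast_1d(xa)
        out = np.full(x1.shape, -np.inf)
        pos = x1 > 0
        out[pos] = np.log(lam) - lam * x1[pos]
        return out.item() if xa.ndim == 0 else out

    def cdf(self, x, theta):
        (lam,) = theta
        xa = np.asarray(x, dtype=float)
        return -np.expm1(-lam * np.maximum(xa, 0.0))

    def ppf(self, q, theta):
        (lam,) = theta
        qa = np.asarray(q, dtype=float)
        if np.any(qa <= 0) or np.any(qa >= 1):
            raise ValueError("q must lie strictly inside (0, 1)")
        return -np.log1p(-qa) / lam

    def start_grid(self, sample: Sample, reduced: bool = False) -> np.ndarray:
        lam0 = 1.0 / sample.mean
        return np.array([[lam0 * s] for s in (0.2, 1.0, 5.0)])

    def closed_form_fit(self, sample: Sample):
        return np.array([1.0 / sample.mean])


class _LLDFamily(Family):
    """Log-logistic with scale s and shape beta: F(x) = x^beta/(s^beta + x^beta).

    The median equals the scale parameter, which pins the parameter labels:
    the fitted scale lands next to the sample median.
    """

    name = "lld"
    param_names = ("scale", "shape")
    tie_break_index = 1

    def logpdf(self, x, theta):
        s, beta = theta
        xa = np.asarray(x, dtype=float)
        x1 = np.atleast_1d(xa)
        out = np.full(x1.shape, -np.inf)
        pos = x1 > 0
        z = beta * (np.log(x1[pos]) - np.log(s))
        out[pos] = np.log(beta) - np.log(x1[pos]) + z - 2.0 * np.logaddexp(0.0, z)
        return out.item() if xa.ndim == 0 else out

    def cdf(self, x, theta):
        s, beta = theta
        xa = np.asarray(x, dtype=float)
        x1 = np.atleast_1d(xa)
        out = np.zeros(x1.shape)
        pos = x1 > 0
        out[pos] = special.expit(beta * (np.log(x1[pos]) - np.log(s)))
        return out.item() if xa.ndim == 0 else out

    def ppf(self, q, theta):
        s, beta = theta
        qa = np.asarray(q, dtype=float)
        if np.any(qa <= 0) or np.any(qa >= 1):
            raise ValueError("q must lie strictly inside (0, 1)")
        return s * np.exp(special.logit(qa) / beta)

    def start_grid(self, sample: Sample, reduced: bool = False) -> np.ndarray:
        med = float(np.median(sample.values))
        scale_vals = (med,) if reduced else (0.5 * med, med, 2.0 * med)
        return np.array([[sv, b] for sv in scale_vals for b in (0.5, 1.0, 2.0, 4.0)])


GE_FAMILY = _GEFamily()
ED_FAMILY = _EDFamily()
LLD_FAMILY = _LLDFamily()


class GeneralizedExponential(ParametricLifetimeModel):
    """Two-parameter generalized exponential model (OLLGE with gamma = 1)."""

    family = GE_FAMILY


class Exponential(ParametricLifetimeModel):
    """One-parameter exponential model; fit() uses the closed-form MLE."""

    family = ED_FAMILY


class LogLogistic(ParametricLifetimeModel):
    """Two-parameter log-logistic model in (scale, shape) form."""

    family = LLD_FAMILY


@dataclass(frozen=True)
class BaselineModel:
    """Functional bundle for a baseline family: d/p/q plus a fit procedure."""

    name: str
    k_params: int
    pdf: Callable
    cdf: Callable
    quantile: Callable
    fit: Callable[..., FitResult]


def _bundle(family: Family) -> BaselineModel:
    def fit(sample, n_starts=None, seed=0, **kw) -> FitResult:
        return fit_mle(sample, n_starts=n_starts, seed=seed, family=family, **kw)

    return BaselineModel(
        name=family.name,
        k_params=family.k_params,
        pdf=family.pdf,
        cdf=family.cdf,
        quantile=family.ppf,
        fit=fit,
    )


def ged_model() -> BaselineModel:
    """Generalized exponential baseline (two parameters)."""
    return _bundle(GE_FAMILY)


def ed_model() -> BaselineModel:
    """Exponential baseline (one parameter, closed-form MLE)."""
    return _bundle(ED_FAMILY)


def lld_model() -> BaselineModel:
    """Log-logistic rival (scale, shape)."""
    return _bundle(LLD_FAMILY)
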