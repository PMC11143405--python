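"""Model-comparison reports across the OLLGE model and its baselines.

Fits each requested model to the same sample and assembles a table of
goodness-of-fit criteria (-2l, AIC, BIC, W*, A*, KS and its p-value)
together with the estimates and standard errors.  AIC and BIC are always
recomputed from -2l, the parameter count and n -- a stored value is never
echoed, which guards against the class of bookkeeping error where a report
row is internally inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import Exponential, GeneralizedExponential, LogLogistic
from .inference import FitResult, GoFReport, OddLogLogisticGE, as_sample, gof_report

__all__ = ["ComparisonReport", "compare_models", "MODEL_REGISTRY"]

MODEL_REGISTRY = {
    "ollged": OddLogLogisticGE,
    "ged": GeneralizedExponential,
    "ed": Exponential,
    "lld": LogLogistic,
}

#: criteria where the best model takes the smallest value
_MIN_CRITERIA = ("minus2loglik", "aic", "bic", "w_star", "a_star", "ks_stat")


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model goodness-of-fit rows plus the winner by each criterion."""

    label: str
    table: pd.DataFrame
    fits: dict
    winners: dict

    def __str__(self) -> str:
        cols = ["minus2loglik", "aic", "bic", "w_star", "a_star", "ks_stat", "ks_pvalue"]
        show = self.table[cols].copy()
        show.columns = ["-2l", "AIC", "BIC", "W*", "A*", "KS", "p-value"]
        lines = [f"Model comparison on {self.label!r} (n = {self.nobs})"]
        lines.append(show.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("best by criterion: " + ", ".join(f"{k}={v}" for k, v in self.winners.items()))
        for name, fit in self.fits.items():
            if fit is None:
                lines.append(f"{name}: fit failed")
                continue
            ests = ", ".join(
                f"{pn}={est:.4f} ({se:.4f})" if np.isfinite(se) else f"{pn}={est:.4f} (n/a)"
                for pn, est, se in zip(fit.param_names, fit.params_hat, fit.se)
            )
            lines.append(f"{name}: {ests}")
        return "\n".join(lines)

    @property
    def nobs(self) -> int:
        return int(self.table.attrs["nobs"])

    def to_json_dict(self) -> dict:
        out = {"label": self.label, "n": self.nobs, "models": {}, "winners": self.winners}
        for name, fit in self.fits.items():
            if fit is None:
                out["models"][name] = {"error": "fit failed"}
                continue
            row = self.table.loc[name]
            out["models"][name] = {
                "estimates": dict(zip(fit.param_names, map(float, fit.params_hat))),
                "se": dict(zip(fit.param_names, map(float, fit.se))),
                **{c: float(row[c]) for c in self.table.columns if c != "k_params"},
                "k_params": int(row["k_params"]),
            }
        return out


def compare_models(sample, models=("ollged", "ged", "ed", "lld"), seed=0, label="sample") -> ComparisonReport:
    """Fit each model and tabulate all goodness-of-fit statistics.

    ``models`` is a list of registry names ("ollged", "ged", "ed", "lld")
    or model classes.  A model whose fit fails is recorded as a NaN row and
    the report is still produced.  Deterministic for a fixed seed.
    """
    s = as_sample(sample)
    if len(list(models)) < 1:
        raise ValueError("need at least one model")
    rows = {}
    fits: dict[str, FitResult | None] = {}
    for m in models:
        cls = MODEL_REGISTRY[m] if isinstance(m, str) else m
        name = cls.family.name
        try:
            res = cls(s.values).fit(seed=seed)
            fit = res.fit_result
            rep: GoFReport = gof_report(s, fit)
            rows[name] = {
                "minus2loglik": rep.minus2loglik,
                "aic": rep.aic,
                "bic": rep.bic,
                "w_star": rep.w_star,
                "a_star": rep.a_star,
                "ks_stat": rep.ks_stat,
                "ks_pvalue": rep.ks_pvalue,
                "k_params": rep.k_params,
            }
            fits[name] = fit
        except Exception:  # noqa: BLE001 - a failed fit must not sink the report
            rows[name] = {c: np.nan for c in
                          ("minus2loglik", "aic", "bic", "w_star", "a_star",
                           "ks_stat", "ks_pvalue", "k_params")}
            fits[name] = None
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.attrs["nobs"] = s.n
    winners = {}
    for crit in _MIN_CRITERIA:
        col = table[crit]
        if col.notna().any():
            winners[crit] = str(col.idxmin())
    return ComparisonReport(label=label, table=table, fits=fits, winners=winners)
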