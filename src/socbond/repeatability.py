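"""Repeatability (intraclass correlation) of annual social measures.

A Gaussian random-intercept mixed model is fitted by REML with female
identity as the random effect and any social/environmental covariates
as fixed effects; repeatability is the adjusted ICC

    R = var_between / (var_between + var_residual),

the proportion of (residual-adjusted) variance attributable to stable
between-female differences.  The confidence interval comes from a
parametric bootstrap: responses are re-simulated from the fitted model
and the ICC re-estimated on each replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger("socbond")


@dataclass
class RepeatabilityResult:
    measure: str
    icc: float
    ci95: tuple[float, float]
    var_between: float
    var_residual: float
    n_individuals: int
    n_observations: int
    singular: bool

    def __repr__(self) -> str:  # pragma: no cover
        lo, hi = self.ci95
        return (
            f"<RepeatabilityResult {self.measure}: ICC={self.icc:.3f} "
            f"[{lo:.3f}, {hi:.3f}], var_between={self.var_between:.4f}, "
            f"var_residual={self.var_residual:.4f}>"
        )


def _fit_once(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = sm.MixedLM(y, X, groups=groups)
        r = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                r = m.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if r is None:
            raise RuntimeError("mixed-model fit failed with every optimiser")
    return (
        float(np.asarray(r.cov_re)[0, 0]),
        float(r.scale),
        np.asarray(r.fe_params, dtype=float),
    )


class Repeatability:
    """Model object: annual values per subject-year, fixed covariates."""

    def __init__(self, data: pd.DataFrame, value_col: str, id_col: str = "female_id",
                 fixed_effects: tuple[str, ...] = ()):
        d = data.dropna(subset=[value_col, *fixed_effects]).copy()
        counts = d.groupby(id_col)[value_col].size()
        if (counts >= 2).sum() < 2:
            raise ValueError("need at least two individuals with two or more years")
        self.y = d[value_col].to_numpy(float)
        self.groups = d[id_col].to_numpy()
        X = [np.ones(len(d))]
        for c in fixed_effects:
            X.append(d[c].to_numpy(float))
        self.X = np.column_stack(X)
        self.value_col = value_col

    def fit(self, n_bootstrap: int = 200, seed: int = 0,
            measure: str | None = None) -> RepeatabilityResult:
        var_u, var_e, fe = _fit_once(self.y, self.X, self.groups)
        singular = var_u < 1e-10
        icc = 0.0 if singular else var_u / (var_u + var_e)
        if singular:
            log.warning("singular fit: between-individual variance ~ 0; ICC set to 0")

        rng = np.random.default_rng(seed)
        ids, inv = np.unique(self.groups, return_inverse=True)
        mu = self.X @ fe
        boots = []
        for _ in range(n_bootstrap):
            u = rng.normal(0.0, np.sqrt(max(var_u, 0.0)), size=len(ids))
            ysim = mu + u[inv] + rng.normal(0.0, np.sqrt(var_e), size=len(self.y))
            try:
                vu, ve, _ = _fit_once(ysim, self.X, self.groups)
                boots.append(0.0 if vu < 1e-10 else vu / (vu + ve))
            except Exception:  # non-converged bootstrap replicate
                continue
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
        else:
            ci = (np.nan, np.nan)
        return RepeatabilityResult(
            measure=measure or self.value_col,
            icc=float(icc),
            ci95=ci,
            var_between=float(var_u),
            var_residual=float(var_e),
            n_individuals=len(ids),
            n_observations=len(self.y),
            singular=singular,
        )


def fit_repeatability(
    data: pd.DataFrame,
    value_col: str,
    id_col: str = "female_id",
    fixed_effects: tuple[str, ...] = (),
    n_bootstrap: int = 200,
    seed: int = 0,
    measure: str | None = None,
) -> RepeatabilityResult:
    """Convenience wrapper: build the model and fit in one call."""
    return Repeatability(data, value_col, id_col, tuple(fixed_effects)).fit(
        n_bootstrap=n_bootstrap, seed=seed, measure=measure
    )
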