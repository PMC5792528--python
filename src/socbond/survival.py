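"""Fixed-time and time-dependent Cox proportional-hazards models.

Survival is modelled on an age axis with delayed entry: a female enters
the risk set at her age when systematic observation of her began (study
start if she was already adult, else her age at first birth) and leaves
at death or censoring.  The fixed-time model carries one record per
female with multi-year covariate averages; the time-dependent model
carries one (start, stop] interval per subject-year with that year's
covariates.  Numeric covariates are standardised (mean 0, sd 1 over the
analysis units); the strength-consistency class enters as treatment
dummies against a declared reference level (default class 3, the
high-risk strong/inconsistent stratum, so each reported coefficient is a
direct contrast with it).

Model classes follow the statsmodels convention: construct from a
DataFrame, ``fit()`` returns a results object with estimates,
uncertainties, diagnostics and ``summary()``.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import _cox
from ._cox import SeparationError, zph_test  # noqa: F401  (re-exported)

log = logging.getLogger("socbond")

#: Wald multiplier for the reported 95% intervals.
Z95 = 1.96


def standardize(values: Sequence[float], name: str = "covariate") -> np.ndarray:
    """Z-scores with sample (ddof=1) standard deviation.

    Raises ``ValueError`` naming the covariate when its variance is zero.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"covariate {name!r} has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def _design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    class_col: str | None,
    reference,
    standardize_cols: bool | Sequence[str] = True,
) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []
    if class_col is not None:
        levels = sorted(data[class_col].unique())
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} absent from {class_col}")
        for lv in levels:
            if lv == reference:
                continue
            cols.append((data[class_col] == lv).to_numpy(float))
            names.append(f"{class_col}[{lv}]")
    std = set(covariates) if standardize_cols is True else set(standardize_cols or [])
    for c in covariates:
        v = data[c].to_numpy(float)
        cols.append(standardize(v, c) if c in std else v)
        names.append(c)
    if not cols:
        raise ValueError("model has no covariates")
    return np.column_stack(cols), names


class CoxSurvivalResults:
    """Estimates and diagnostics of a fitted Cox model."""

    def __init__(self, model, fit: _cox.CoxFit, names: list[str]):
        self.model = model
        self._fit = fit
        self.names = names
        self.params = pd.Series(fit.beta, index=names)
        self.bse = pd.Series(np.sqrt(np.diag(fit.cov)), index=names)
        self.loglik = fit.loglik
        self.loglik_null = fit.loglik_null
        self.n_events = fit.n_events
        self.nobs = fit.n_rows
        self.converged = fit.converged

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self) -> pd.DataFrame:
        lo = self.params - Z95 * self.bse
        hi = self.params + Z95 * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def significant(self) -> pd.Series:
        """Terms whose 95% CI excludes zero."""
        ci = self.conf_int()
        return (ci["lower"] > 0) | (ci["upper"] < 0)

    @property
    def aicc(self) -> float:
        """AICc with the number of events as the effective sample size."""
        k = len(self.params)
        n_eff = self.n_events
        if n_eff - k - 1 <= 0:
            return float("inf")
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / (n_eff - k - 1)

    def check_proportional_hazards(self, transform: str = "km") -> pd.DataFrame:
        """Schoenfeld-residual test against transformed time (per term + global)."""
        z = zph_test(self._fit, transform=transform)
        rows = pd.DataFrame(
            {"chi2": z["term_chi2"], "p": z["term_p"], "df": 1}, index=self.names
        )
        rows.loc["GLOBAL"] = [z["global_chi2"], z["global_p"], z["df"]]
        return rows

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        z = self.params / self.bse
        from scipy import stats

        return pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.bse,
                "hazard_ratio": self.hazard_ratios,
                "ci95_lower": ci["lower"],
                "ci95_upper": ci["upper"],
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        head = (
            f"<{type(self).__name__}: n={self.nobs}, events={self.n_events}, "
            f"loglik={self.loglik:.3f}, AICc={self.aicc:.2f}, converged={self.converged}>"
        )
        return head + "\n" + self.summary().round(4).to_string()


class CoxSurvival:
    """Fixed-time Cox model with delayed entry, one record per subject.

    Parameters
    ----------
    data
        One row per female with entry/exit ages, event flag, covariates.
    covariates
        Numeric covariate columns (standardised unless listed out).
    class_col, reference
        Optional categorical strength-consistency class column and its
        reference level (dummies are built against it).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: Sequence[str] = (),
        class_col: str | None = None,
        reference=3,
        entry_col: str | None = "entry_age",
        duration_col: str = "exit_age",
        event_col: str = "event",
        standardize_cols: bool | Sequence[str] = True,
    ):
        self.data = data.reset_index(drop=True)
        self.entry = (
            self.data[entry_col].to_numpy(float) if entry_col is not None else None
        )
        self.stop = self.data[duration_col].to_numpy(float)
        self.event = self.data[event_col].to_numpy()
        self.X, self.names = _design(
            self.data, covariates, class_col, reference, standardize_cols
        )
        k = self.X.shape[1]
        d = int(np.asarray(self.event, bool).sum())
        if d and d / k < 5:
            log.warning(
                "only %d events for %d model terms (< 5 events/variable)", d, k
            )

    def fit(self, **kwargs) -> CoxSurvivalResults:
        fit = _cox.cox_fit(self.entry, self.stop, self.event, self.X, **kwargs)
        if not fit.converged:
            log.warning("Cox fit did not converge; results flagged")
        return CoxSurvivalResults(self, fit, self.names)


class TimeVaryingCoxSurvival(CoxSurvival):
    """Counting-process Cox model: one (start, stop] row per subject-year."""

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: Sequence[str] = (),
        class_col: str | None = None,
        reference=3,
        id_col: str = "female_id",
        start_col: str = "start_age",
        stop_col: str = "stop_age",
        event_col: str = "event",
        standardize_cols: bool | Sequence[str] = True,
    ):
        self._validate_intervals(data, id_col, start_col, stop_col, event_col)
        super().__init__(
            data,
            covariates,
            class_col,
            reference,
            entry_col=start_col,
            duration_col=stop_col,
            event_col=event_col,
            standardize_cols=standardize_cols,
        )

    @staticmethod
    def _validate_intervals(data, id_col, start_col, stop_col, event_col) -> None:
        for fid, d in data.groupby(id_col):
            d = d.sort_values(start_col)
            if (d[start_col].to_numpy() >= d[stop_col].to_numpy()).any():
                raise ValueError(f"subject {fid}: empty or inverted interval")
            if (d[stop_col].to_numpy()[:-1] > d[start_col].to_numpy()[1:] + 1e-12).any():
                raise ValueError(f"subject {fid}: overlapping intervals")
            ev = d[event_col].to_numpy().astype(bool)
            if ev.sum() > 1:
                raise ValueError(f"subject {fid}: more than one event")
            if ev.sum() == 1 and not ev[-1]:
                raise ValueError(f"subject {fid}: event on a non-terminal interval")


# ---------------------------------------------------------------------------
# spec-level operations

def fit_cox_fixed(
    records: pd.DataFrame,
    covariates: Sequence[str] = (),
    class_col: str | None = "class_multi",
    reference=3,
    **kwargs,
) -> CoxSurvivalResults:
    """Fit the fixed-time left-truncated Cox model on per-female records."""
    return CoxSurvival(
        records, covariates, class_col=class_col, reference=reference, **kwargs
    ).fit()


def fit_cox_timedep(
    records: pd.DataFrame,
    covariates: Sequence[str] = (),
    class_col: str | None = "class_annual",
    reference=3,
    **kwargs,
) -> CoxSurvivalResults:
    """Fit the time-dependent Cox model on subject-year intervals."""
    return TimeVaryingCoxSurvival(
        records, covariates, class_col=class_col, reference=reference, **kwargs
    ).fit()


def model_average(
    res_a: CoxSurvivalResults,
    res_b: CoxSurvivalResults,
    terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """AICc model averaging of shared terms across two fitted models.

    Akaike weights ``w_m = exp(-delta_m / 2) / sum`` come from the two
    models' AICc; averaged coefficients are the weighted means and the
    unconditional standard error includes the between-model component
    ``se = sum_m w_m sqrt(se_m^2 + (beta_m - beta_bar)^2)``.
    """
    if res_a.n_events != res_b.n_events:
        raise ValueError("models were fitted to different event sets; cannot average")
    if terms is None:
        terms = [t for t in res_a.names if t in res_b.names]
    aicc = np.array([res_a.aicc, res_b.aicc])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2)
    w = w / w.sum()
    rows = []
    for t in terms:
        b = np.array([res_a.params[t], res_b.params[t]])
        se = np.array([res_a.bse[t], res_b.bse[t]])
        bbar = float(w @ b)
        se_u = float(w @ np.sqrt(se**2 + (b - bbar) ** 2))
        rows.append((t, bbar, se_u, bbar - Z95 * se_u, bbar + Z95 * se_u, np.exp(bbar)))
    out = pd.DataFrame(
        rows, columns=["term", "coef", "se(coef)", "ci95_lower", "ci95_upper", "hazard_ratio"]
    ).set_index("term")
    out.attrs["akaike_weights"] = w
    return out


def ph_check(results: CoxSurvivalResults, transform: str = "km") -> pd.DataFrame:
    """Proportional-hazards diagnostics for a fitted model."""
    return results.check_proportional_hazards(transform=transform)


def quadratic_group_size_model(
    records: pd.DataFrame,
    group_size_col: str = "mean_groupmates",
    covariates: Sequence[str] = ("age_first_birth",),
    class_col: str | None = "class_multi",
    reference=3,
    **kwargs,
) -> CoxSurvivalResults:
    """Cox model with linear + quadratic group-size terms.

    The group-size covariate is standardised first and then squared, so
    the quadratic term tests curvature around the typical group size.
    """
    df = records.copy()
    gz = standardize(df[group_size_col], group_size_col)
    df["group_size_z"] = gz
    df["group_size_z2"] = gz**2
    other = [standardize(df[c].to_numpy(float), c) for c in covariates]
    for c, v in zip(covariates, other):
        df[c] = v
    model = CoxSurvival(
        df,
        covariates=["group_size_z", "group_size_z2", *covariates],
        class_col=class_col,
        reference=reference,
        standardize_cols=[],
        **kwargs,
    )
    return model.fit()
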