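"""Cox partial-likelihood machinery.

Newton-Raphson maximisation of the Cox partial likelihood on
counting-process data: each row is an interval (entry, stop] with an
event flag and fixed covariates.  Delayed entry (left truncation) falls
out of the risk-set definition {i : entry_i < t <= stop_i}; a subject
observed from entry age onward simply contributes one row.  Tied event
times use the Efron correction.

Kept dependency-light and array-based because the node-permutation null
refits the model thousands of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class SeparationError(RuntimeError):
    """The partial likelihood is maximised at infinite coefficients."""


@dataclass
class CoxFit:
    beta: np.ndarray
    cov: np.ndarray               # inverse observed information
    loglik: float
    loglik_null: float
    n_events: int
    n_rows: int
    converged: bool
    event_times: np.ndarray = field(repr=False)
    event_counts: np.ndarray = field(repr=False)
    schoenfeld: np.ndarray = field(repr=False)   # one row per event time
    risk_counts: np.ndarray = field(repr=False)  # risk-set size at each event time
    info: np.ndarray = field(repr=False)         # observed information at beta


def _suffix_sums(times: np.ndarray, r: np.ndarray, x: np.ndarray):
    """Sorted times plus suffix sums of r, r*x, r*x x' for {time >= t} queries."""
    o = np.argsort(times, kind="stable")
    ts = times[o]
    rs = r[o]
    xs = x[o]
    rx = rs[:, None] * xs
    rxx = rx[:, :, None] * xs[:, None, :]
    s0 = np.concatenate([np.cumsum(rs[::-1])[::-1], [0.0]])
    s1 = np.concatenate([np.cumsum(rx[::-1], axis=0)[::-1], np.zeros((1, x.shape[1]))])
    s2 = np.concatenate(
        [np.cumsum(rxx[::-1], axis=0)[::-1], np.zeros((1, x.shape[1], x.shape[1]))]
    )
    return ts, s0, s1, s2


def _loglik_parts(entry, stop, event, x, beta):
    """Log partial likelihood, gradient, information, per-event-time pieces.

    Untied event times are handled fully vectorised; tied groups (rare
    on a continuous age axis) go through the Efron loop.
    """
    n, p = x.shape
    eta = x @ beta
    eta -= eta.max()  # overflow guard; cancels exactly in every ratio
    r = np.exp(eta)

    st, s0_t, s1_t, s2_t = _suffix_sums(stop, r, x)
    en, e0_t, e1_t, e2_t = _suffix_sums(entry, r, x)

    ev_stop = stop[event]
    order = np.argsort(ev_stop, kind="stable")
    times, first, d_counts = np.unique(ev_stop[order], return_index=True, return_counts=True)
    x_ev = x[event][order]
    r_ev = r[event][order]
    m = len(times)

    i_s = np.searchsorted(st, times, side="left")
    i_e = np.searchsorted(en, times, side="left")
    S0 = s0_t[i_s] - e0_t[i_e]                      # (m,)
    S1 = s1_t[i_s] - e1_t[i_e]                      # (m, p)
    S2 = s2_t[i_s] - e2_t[i_e]                      # (m, p, p)
    risk_counts = (len(st) - i_s) - (len(en) - i_e)

    # log-numerator (the shift in eta cancels against the denominators)
    ll = float(np.log(r_ev).sum())
    grad = x_ev.sum(axis=0)
    info = np.zeros((p, p))
    sch = np.zeros((m, p))

    untied = d_counts == 1
    if untied.any():
        S0u, S1u, S2u = S0[untied], S1[untied], S2[untied]
        xu = x_ev[first[untied]]
        z = S1u / S0u[:, None]
        ll -= float(np.log(S0u).sum())
        grad -= z.sum(axis=0)
        info += (S2u / S0u[:, None, None]).sum(axis=0) - np.einsum("mi,mj->ij", z, z)
        sch[untied] = xu - z

    if (~untied).any():
        for k in np.nonzero(~untied)[0]:
            g_idx = slice(first[k], first[k] + d_counts[k])
            xd = x_ev[g_idx]
            rd = r_ev[g_idx]
            d = d_counts[k]
            D0, D1 = rd.sum(), (rd[:, None] * xd).sum(axis=0)
            D2 = ((rd[:, None] * xd)[:, :, None] * xd[:, None, :]).sum(axis=0)
            sum_z = np.zeros(p)
            for l in range(d):
                f = l / d
                phi = S0[k] - f * D0
                z1 = (S1[k] - f * D1) / phi
                ll -= np.log(phi)
                grad -= z1
                info += (S2[k] - f * D2) / phi - np.outer(z1, z1)
                sum_z += z1
            sch[k] = xd.sum(axis=0) - sum_z
    return ll, grad, info, times, d_counts, sch, risk_counts.astype(float)


def _loglik_value(entry, stop, event, x, beta) -> float:
    """Log partial likelihood only (cheap path for line searches)."""
    eta = x @ beta
    eta -= eta.max()
    r = np.exp(eta)
    o = np.argsort(stop, kind="stable")
    st, rs = stop[o], r[o]
    s0 = np.concatenate([np.cumsum(rs[::-1])[::-1], [0.0]])
    o2 = np.argsort(entry, kind="stable")
    en, re_ = entry[o2], r[o2]
    e0 = np.concatenate([np.cumsum(re_[::-1])[::-1], [0.0]])

    ev_stop = stop[event]
    order = np.argsort(ev_stop, kind="stable")
    times, first, d_counts = np.unique(ev_stop[order], return_index=True, return_counts=True)
    r_ev = r[event][order]
    S0 = s0[np.searchsorted(st, times, side="left")] - e0[
        np.searchsorted(en, times, side="left")
    ]
    ll = float(np.log(r_ev).sum())
    untied = d_counts == 1
    ll -= float(np.log(S0[untied]).sum())
    for k in np.nonzero(~untied)[0]:
        d = d_counts[k]
        D0 = r_ev[first[k]: first[k] + d].sum()
        for l in range(d):
            ll -= np.log(S0[k] - (l / d) * D0)
    return ll


def cox_fit(
    entry: np.ndarray | None,
    stop: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit the Cox model; raises on no events or complete separation."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(bool)
    entry = np.zeros(len(stop)) if entry is None else np.asarray(entry, dtype=float)
    if np.any(entry >= stop):
        raise ValueError("every interval must satisfy entry < stop")
    if not event.any():
        raise ValueError("no events: the partial likelihood is undefined")
    n, p = x.shape

    # centre covariates for numerical stability (shifts cancel in the risk ratio)
    mean = x.mean(axis=0)
    xc = x - mean

    beta = np.zeros(p)
    ll0 = None
    ll_prev = -np.inf
    converged = False
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for it in range(max_iter):
            ll, grad, info, times, d_counts, sch, risk_counts = _loglik_parts(
                entry, stop, event, xc, beta
            )
            if not (np.isfinite(ll) and np.isfinite(grad).all()):
                raise SeparationError("non-finite likelihood: likely complete separation")
            if ll0 is None and it == 0:
                ll0 = ll
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as e:
                raise SeparationError(f"singular information matrix: {e}") from e
            # step-halving line search
            lam = 1.0
            for _ in range(30):
                cand = beta + lam * step
                ll_c = _loglik_value(entry, stop, event, xc, cand)
                if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                    break
                lam *= 0.5
            beta = beta + lam * step
            if np.abs(beta).max() > 15:
                raise SeparationError("coefficients diverging: likely complete separation")
            if np.abs(grad).max() < tol or abs(ll - ll_prev) < 1e-13:
                converged = True
                break
            ll_prev = ll
        ll, grad, info, times, d_counts, sch, risk_counts = _loglik_parts(
            entry, stop, event, xc, beta
        )
    if not np.isfinite(ll):
        raise SeparationError("non-finite likelihood at optimum")
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as e:
        raise SeparationError(f"singular information at optimum: {e}") from e
    return CoxFit(
        beta=beta,
        cov=cov,
        loglik=float(ll),
        loglik_null=float(ll0),
        n_events=int(event.sum()),
        n_rows=n,
        converged=converged,
        event_times=times,
        event_counts=d_counts,
        schoenfeld=sch,
        risk_counts=risk_counts,
        info=info,
    )


def km_transform(fit: CoxFit) -> np.ndarray:
    """1 - KM(t-) at each event time, the default time transform for the
    proportional-hazards diagnostic (survival estimated from the fit's
    own risk-set and death counts, so delayed entry is respected)."""
    frac = 1.0 - fit.event_counts / np.maximum(fit.risk_counts, 1)
    km_after = np.cumprod(frac)
    km_before = np.concatenate([[1.0], km_after[:-1]])
    return 1.0 - km_before


def zph_test(fit: CoxFit, transform: str = "km") -> dict:
    """Grambsch-Therneau test for non-proportional hazards.

    Correlates (scaled) Schoenfeld residuals with transformed event
    time, using the average-information approximation.  Returns per-term
    and global chi-square statistics with p-values.
    """
    d = fit.event_counts.sum()
    if d < 3:
        raise ValueError("proportional-hazards diagnostics need at least 3 events")
    if transform == "km":
        g = km_transform(fit)
    elif transform == "rank":
        g = stats.rankdata(fit.event_times).astype(float)
    elif transform == "identity":
        g = fit.event_times.astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    w = fit.event_counts.astype(float)
    gbar = (g * w).sum() / w.sum()
    gc = g - gbar
    u = gc @ fit.schoenfeld                      # p-vector
    denom = float((w * gc**2).sum())
    vbar = fit.info / d
    p = len(u)
    chi_global = float(u @ np.linalg.solve(vbar, u) / denom)
    per_term = u**2 / (denom * np.diag(vbar))
    return {
        "term_chi2": per_term,
        "term_p": stats.chi2.sf(per_term, 1),
        "global_chi2": chi_global,
        "global_p": float(stats.chi2.sf(chi_global, p)),
        "df": p,
    }
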