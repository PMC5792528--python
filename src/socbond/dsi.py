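"""Dyadic sociality index (DSI).

The DSI for a within-group dyad-year combines the proportion of dyad
observation time spent grooming (either direction) with the two
directional proportions of focal time spent resting within 1 m, each
normalised by that year's population-wide median::

    DSI = 1/2 * G_ij / G_med  +  1/4 * (R_ij / R_med + R_ji / R_med)

A dyad at exactly median rates scores 1; values above 1 mark stronger
than typical ties.  Records are filtered before aggregation: focal
samples shorter than the minimum bout length are discarded, and a sample
is ignored for a given dyad while either member has a young infant
(mothers of young infants attract extra, infant-driven attention).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import StudyConfig
from .tables import CohortTables

log = logging.getLogger("socbond")


class ZeroMedianError(ValueError):
    """A year's median grooming or resting rate is zero.

    The index normalises by annual medians; a population sparse enough
    to have a zero median is incompatible with the index.
    """


def filter_short_samples(samples: pd.DataFrame, min_sample_min: float) -> pd.DataFrame:
    """Drop focal samples shorter than ``min_sample_min`` minutes."""
    return samples[samples["duration_min"] >= min_sample_min].reset_index(drop=True)


def infant_windows(infants: pd.DataFrame, exclusion_days: int) -> dict[str, np.ndarray]:
    """Per-mother day-number intervals [birth, birth + exclusion_days).

    Days 0..exclusion_days-1 after an infant's birth are excluded; the
    boundary day itself is retained.
    """
    win: dict[str, list[tuple[int, int]]] = {}
    for mid, d in zip(infants["mother_id"], infants["infant_birth_date"]):
        o = pd.Timestamp(d).toordinal()
        win.setdefault(mid, []).append((o, o + exclusion_days))
    out = {}
    for mid, ivals in win.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for a, b in ivals[1:]:
            if a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        out[mid] = np.array(merged)
    return out


def _in_window(windows: dict[str, np.ndarray], fid: str, day_ords: np.ndarray) -> np.ndarray:
    w = windows.get(fid)
    if w is None or len(day_ords) == 0:
        return np.zeros(len(day_ords), dtype=bool)
    starts, ends = w[:, 0], w[:, 1]
    k = np.searchsorted(starts, day_ords, side="right") - 1
    ok = k >= 0
    out = np.zeros(len(day_ords), dtype=bool)
    out[ok] = day_ords[ok] < ends[k[ok]]
    return out


def filter_records(
    tables: CohortTables, config: StudyConfig
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Apply the observation filters.

    Returns the samples surviving the minimum-duration filter (with a
    study-year column added) together with the per-female infant
    exclusion windows; the dyad-specific infant filter is applied during
    aggregation because whether a sample counts depends on the partner.
    """
    samples = filter_short_samples(tables.samples, config.min_sample_min).copy()
    if len(samples):
        samples["year"] = config.year_of(samples["date"]).to_numpy()
    else:
        samples["year"] = pd.Series([], dtype=int)
    windows = infant_windows(tables.infants, config.infant_exclusion_days)
    return samples, windows


def compute_dyad_year(
    tables: CohortTables,
    subject_years: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Aggregate filtered samples into per-dyad per-year records.

    For each coresident pair of included subjects (i, j):
    ``T_dyad`` is the summed focal time of both members valid for the
    dyad (samples during either member's infant-exclusion window do not
    count), ``G_ij`` the pooled grooming minutes between them from
    either focal divided by ``T_dyad``, and ``R_ij`` / ``R_ji`` each
    member's valid focal resting-within-1-m minutes with the other
    divided by her own valid focal time.  Dyads never observed
    (``T_dyad = 0``) are omitted.
    """
    samples, windows = filter_records(tables, config)
    inc = subject_years[subject_years["included"]] if "included" in subject_years else subject_years
    inc_idx = set(zip(inc["female_id"], inc["year"]))

    samples = samples[
        [(f, y) in inc_idx for f, y in zip(samples["focal_id"], samples["year"])]
    ].copy()
    # proleptic-Gregorian day numbers (vectorised toordinal)
    _EPOCH_ORD = 719163  # 1970-01-01
    samples["day_ord"] = (
        samples["date"] - pd.Timestamp("1970-01-01")
    ).dt.days + _EPOCH_ORD

    pm = tables.partners.merge(
        samples[["sample_id", "focal_id", "group_id", "year", "day_ord"]],
        on="sample_id",
        how="inner",
    )
    sample_groups = dict(iter(samples.groupby(["group_id", "year"]))) if len(samples) else {}
    pm_groups = dict(iter(pm.groupby(["group_id", "year"]))) if len(pm) else {}
    _empty_s = samples.iloc[0:0]
    _empty_p = pm.iloc[0:0]

    rows = []
    n_unknown = 0
    for (g, y), roster_df in inc.groupby(["group_id", "year"]):
        roster = sorted(roster_df["female_id"])
        rset = set(roster)
        sg = sample_groups.get((g, y), _empty_s)
        by_focal = {
            f: (d["day_ord"].to_numpy(), d["duration_min"].to_numpy())
            for f, d in sg.groupby("focal_id")
        }
        pg = pm_groups.get((g, y), _empty_p)
        unknown = ~pg["partner_id"].isin(rset)
        n_unknown += int(unknown.sum())
        pg = pg[~unknown]
        # valid affiliation minutes per (focal, partner, behavior)
        if len(pg):
            ex = _mask_pairs(pg["focal_id"], pg["partner_id"], pg["day_ord"], windows)
            agg = (
                pg[~ex]
                .groupby(["focal_id", "partner_id", "behavior"])["minutes"]
                .sum()
                .to_dict()
            )
        else:
            agg = {}

        # valid focal time of i with respect to partner j
        T: dict[tuple[str, str], float] = {}
        for i, (days, durs) in by_focal.items():
            own = _in_window(windows, i, days)
            for j in roster:
                if j == i:
                    continue
                valid = ~own & ~_in_window(windows, j, days)
                T[(i, j)] = float(durs[valid].sum())

        def mins(i: str, j: str, beh: str) -> float:
            return agg.get((i, j, beh), 0.0)

        for ai in range(len(roster)):
            for bi in range(ai + 1, len(roster)):
                i, j = roster[ai], roster[bi]
                t_ij = T.get((i, j), 0.0)
                t_ji = T.get((j, i), 0.0)
                t_dyad = t_ij + t_ji
                if t_dyad <= 0:
                    continue
                g_min = mins(i, j, "groom") + mins(j, i, "groom")
                r_ij = mins(i, j, "rest1m") / t_ij if t_ij > 0 else 0.0
                r_ji = mins(j, i, "rest1m") / t_ji if t_ji > 0 else 0.0
                rows.append((g, y, i, j, t_dyad, g_min / t_dyad, r_ij, r_ji))
    if n_unknown:
        log.warning(
            "ignored %d affiliation rows whose partner is not an included "
            "subject of the same group-year", n_unknown,
        )
    return pd.DataFrame(
        rows, columns=["group_id", "year", "id_i", "id_j", "T_dyad", "G_ij", "R_ij", "R_ji"]
    )


def _mask_pairs(focals, partners, day_ords, windows) -> np.ndarray:
    """Exclusion mask for affiliation rows: either member in an infant window."""
    f = np.asarray(focals)
    p = np.asarray(partners)
    d = np.asarray(day_ords)
    out = np.zeros(len(f), dtype=bool)
    for who in (f, p):
        for fid in np.unique(who):
            sel = who == fid
            out[sel] |= _in_window(windows, fid, d[sel])
    return out


def year_medians(dyads: pd.DataFrame) -> pd.DataFrame:
    """Annual medians: G over all within-group dyads pooled across groups,
    R over the pooled directional components {R_ij, R_ji}."""
    rows = []
    for y, d in dyads.groupby("year"):
        g_med = float(d["G_ij"].median())
        r_med = float(np.median(np.concatenate([d["R_ij"].to_numpy(), d["R_ji"].to_numpy()])))
        rows.append((y, g_med, r_med))
    return pd.DataFrame(rows, columns=["year", "G_med", "R_med"])


def compute_dsi(dyads: pd.DataFrame, medians: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach the DSI to each dyad-year record.

    Raises :class:`ZeroMedianError` if any year's median grooming or
    resting rate is zero.
    """
    medians = year_medians(dyads) if medians is None else medians
    bad = medians[(medians["G_med"] <= 0) | (medians["R_med"] <= 0)]
    if len(bad):
        raise ZeroMedianError(
            f"zero annual median in year(s) {sorted(bad['year'])}: population-level "
            "sparsity is incompatible with a median-normalised index"
        )
    out = dyads.merge(medians, on="year", how="left")
    out["dsi"] = 0.5 * out["G_ij"] / out["G_med"] + 0.25 * (
        out["R_ij"] / out["R_med"] + out["R_ji"] / out["R_med"]
    )
    return out.drop(columns=["G_med", "R_med"])


def dyad_matrix(
    dyads: pd.DataFrame, group_id: str, year: int, value: str = "dsi"
) -> tuple[list[str], np.ndarray]:
    """Symmetric roster-indexed matrix of one group-year's dyadic values."""
    d = dyads[(dyads["group_id"] == group_id) & (dyads["year"] == year)]
    roster = sorted(set(d["id_i"]) | set(d["id_j"]))
    idx = {f: k for k, f in enumerate(roster)}
    m = np.zeros((len(roster), len(roster)))
    for i, j, v in zip(d["id_i"], d["id_j"], d[value]):
        m[idx[i], idx[j]] = m[idx[j], idx[i]] = v
    return roster, m


def matrix_correlation(
    g_matrix: np.ndarray,
    r_matrix: np.ndarray,
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel-style correlation of two dyadic matrices on one roster.

    Pearson correlation of the off-diagonal entries, with a two-sided
    node-permutation p-value (rows and columns of the second matrix are
    relabelled jointly).  Requires a roster of at least 3.
    """
    g = np.asarray(g_matrix, dtype=float)
    r = np.asarray(r_matrix, dtype=float)
    n = g.shape[0]
    if g.shape != r.shape or g.shape[0] != g.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if n < 3:
        raise ValueError("matrix correlation undefined for rosters smaller than 3")
    off = ~np.eye(n, dtype=bool)
    r_obs = stats.pearsonr(g[off], r[off]).statistic
    rng = rng if rng is not None else np.random.default_rng(0)
    hits = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        rp = r[np.ix_(p, p)]
        if abs(stats.pearsonr(g[off], rp[off]).statistic) >= abs(r_obs) - 1e-12:
            hits += 1
    pval = (hits + 1) / (n_permutations + 1)
    return float(r_obs), float(pval)
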