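"""Per-female bond strength, partner consistency, and strength-consistency classes.

Bond strength in a year is the mean DSI over a female's top-k partners
(k = 3 or 6).  Consistency is measured in two directions:

* multi-year (prospective): a top partner in year t is *consistent* if
  she reappears in the top k in year t+1 or t+2 (for the second-to-last
  year, in the last year only).  The female's score is consistent slots
  over total assessable slots (kY - k for a female with k partners in
  each of Y years; fewer-than-k years contribute their actual slots).
* annual (retrospective): the proportion of the current year's top k
  already in the top k of either of the two preceding observation years
  (second year: the previous year alone); undefined in the first year.

Crossing above/below population-mean strength with above/below-mean
consistency yields four classes: 1 = weak/inconsistent,
2 = weak/consistent, 3 = strong/inconsistent, 4 = strong/consistent.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger("socbond")


def _directed(dyads: pd.DataFrame) -> pd.DataFrame:
    """One row per (female, partner, year) with the dyad's DSI."""
    a = dyads.rename(columns={"id_i": "female_id", "id_j": "partner_id"})
    b = dyads.rename(columns={"id_j": "female_id", "id_i": "partner_id"})
    cols = ["group_id", "year", "female_id", "partner_id", "dsi"]
    return pd.concat([a[cols], b[cols]], ignore_index=True)


def top_k_partners(dyads: pd.DataFrame, female_id: str, year: int, k: int) -> list[str]:
    """The female's k closest partners that year, by descending DSI.

    Ties are broken by ascending partner id (deterministic); if fewer
    than k coresident partners were observed, all are returned.
    """
    d = _directed(dyads)
    d = d[(d["female_id"] == female_id) & (d["year"] == year)]
    if len(d) == 0:
        raise KeyError(f"{female_id} has no dyadic records in year {year}")
    d = d.sort_values(["dsi", "partner_id"], ascending=[False, True], kind="stable")
    if len(d) > k and d["dsi"].iloc[k - 1] == d["dsi"].iloc[k]:
        log.info("top-%d tie for %s year %d broken by partner id", k, female_id, year)
    return list(d["partner_id"].iloc[:k])


def annual_tops(dyads: pd.DataFrame, k: int) -> dict[str, dict[int, list[str]]]:
    """Top-k partner lists for every female-year with dyadic records."""
    d = _directed(dyads).sort_values(
        ["female_id", "year", "dsi", "partner_id"], ascending=[True, True, False, True],
        kind="stable",
    )
    out: dict[str, dict[int, list[str]]] = {}
    for (f, y), grp in d.groupby(["female_id", "year"], sort=False):
        out.setdefault(f, {})[y] = list(grp["partner_id"].iloc[:k])
    return out


def multi_year_consistency(tops: list[list[str]]) -> float:
    """Prospective consistency over a chronological sequence of top lists.

    Requires at least two years; raises ``ValueError`` otherwise.
    """
    Y = len(tops)
    if Y < 2:
        raise ValueError("multi-year consistency undefined for a single observed year")
    consistent = 0
    slots = 0
    for t in range(Y - 1):
        future: set[str] = set(tops[t + 1])
        if t + 2 < Y and t < Y - 2:
            future |= set(tops[t + 2])
        slots += len(tops[t])
        consistent += sum(1 for p in tops[t] if p in future)
    return consistent / slots if slots else math.nan


def annual_consistency(tops: list[list[str]], t: int) -> float:
    """Retrospective consistency of year-index ``t`` (0-based) top list.

    Returns NaN for the first observed year (undefined, not an error).
    """
    if t == 0:
        return math.nan
    past = set(tops[t - 1]) | (set(tops[t - 2]) if t >= 2 else set())
    cur = tops[t]
    if not cur:
        return math.nan
    return sum(1 for p in cur if p in past) / len(cur)


def assign_classes(strength: np.ndarray, consistency: np.ndarray) -> np.ndarray:
    """Quadrant classes from population-mean thresholds.

    Strictly above the mean counts as "+"; exactly at the mean falls on
    the "-" side.  Requires at least two units and non-degenerate values.
    """
    s = np.asarray(strength, dtype=float)
    c = np.asarray(consistency, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least two females to place class thresholds")
    if np.ptp(s) == 0 and np.ptp(c) == 0:
        raise ValueError("all strength and consistency values identical; classes degenerate")
    s_hi = s > s.mean()
    c_hi = c > c.mean()
    return np.select(
        [~s_hi & ~c_hi, ~s_hi & c_hi, s_hi & ~c_hi], [1, 2, 3], default=4
    ).astype(int)


def death_attributed_changes(
    tops_by_year: dict[int, list[str]],
    death_year: dict[str, int],
) -> tuple[int, int]:
    """Count top-partner changes and how many are attributable to death.

    A *change* is a partner in year t's top list absent from the next
    observed year's list; it is death-attributed if the partner died in
    year t or before the end of the next observed year.  Returns
    ``(death_changes, total_changes)``; the proportion is undefined when
    no changes occurred.
    """
    years = sorted(tops_by_year)
    deaths = 0
    changes = 0
    for t, t_next in zip(years, years[1:]):
        nxt = set(tops_by_year[t_next])
        for p in tops_by_year[t]:
            if p not in nxt:
                changes += 1
                dy = death_year.get(p)
                if dy is not None and t <= dy <= t_next:
                    deaths += 1
    return deaths, changes
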