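"""Synthetic cohort generator with known ground truth.

Emulates a long-term field study of group-living adult females: focal
samples with per-partner grooming and resting-proximity minutes,
demography (births, deaths, censoring, infants), and decided agonistic
interactions.  Each female carries a latent strength-consistency class
(strong/weak bonds x consistent/inconsistent partners) assigned by
construction; mortality hazards differ by class, giving unambiguous
recovery targets for every downstream stage.

Scale defaults mirror a study of 8 social groups, 3-21 adult females per
group, up to 8 observation years, and 67 +/- 20 focal hours per
subject-year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DAYS_PER_YEAR, StudyConfig
from .tables import CohortTables

log = logging.getLogger("socbond")

#: Latent classes: 1 = weak/inconsistent, 2 = weak/consistent,
#: 3 = strong/inconsistent, 4 = strong/consistent.
STRONG_CLASSES = (3, 4)
CONSISTENT_CLASSES = (2, 4)


class ConfigurationError(ValueError):
    """Generator parameters are infeasible."""


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults are the emulated conditions.

    ``class_log_hr`` maps latent class to log hazard ratio relative to
    ``baseline_hazard`` (the per-year hazard of the reference class 3,
    strong/inconsistent, the study's high-risk stratum).  The default
    contrasts place classes 1, 2 and 4 at -2.1, -1.5 and -3.0 relative
    to class 3, and the baseline is set so the marginal death rate is
    about 0.046 per subject-year.
    """

    n_groups: int = 8
    group_size_range: tuple[int, int] = (3, 21)
    years: int = 8
    start_date: str = "2006-10-01"
    obs_hours_mean: float = 67.0
    obs_hours_sd: float = 20.0
    n_top_latent: int = 3
    strong_multiplier: float = 8.0
    weak_multiplier: float = 4.0
    background_shape: float = 2.0
    turnover_consistent: float = 0.08
    turnover_inconsistent: float = 0.55
    mutuality_weight: float = 6.0
    assortativity_weight: float = 4.0
    class_probs: tuple[float, float, float, float] = (29 / 83, 20 / 83, 11 / 83, 23 / 83)
    baseline_hazard: float = 0.18
    class_log_hr: Mapping[int, float] = field(
        default_factory=lambda: {1: -2.1, 2: -1.5, 3: 0.0, 4: -3.0}
    )
    groom_rate_typical: float = 0.05
    rest_rate_typical: float = 0.10
    strong_rate_factor: float = 1.6
    weak_rate_factor: float = 0.75
    p_groom_sample: float = 0.55
    p_rest_sample: float = 0.80
    age_first_birth_mean: float = 7.2
    age_first_birth_sd: float = 0.7
    max_age_at_start: float = 18.0
    p_adult_at_start: float = 0.85
    interbirth_mean: float = 2.5
    interbirth_sd: float = 0.5
    agonism_rate: float = 4.0
    p_upset: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.group_size_range
        if not (2 <= lo <= hi):
            raise ConfigurationError("group_size_range must satisfy 2 <= lo <= hi")
        if hi - 1 < self.n_top_latent and lo - 1 < self.n_top_latent:
            raise ConfigurationError(
                "all groups smaller than n_top_latent+1: no female can have "
                f"{self.n_top_latent} latent partners"
            )
        for p in (*self.class_probs, self.turnover_consistent, self.turnover_inconsistent,
                  self.p_groom_sample, self.p_rest_sample, self.p_upset,
                  self.p_adult_at_start):
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability {p} outside [0, 1]")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ConfigurationError("class_probs must sum to 1")
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline_hazard must be nonnegative")
        for r in (self.groom_rate_typical, self.rest_rate_typical, self.agonism_rate):
            if r <= 0:
                raise ConfigurationError("rates must be positive")
        if self.obs_hours_sd >= self.obs_hours_mean:
            raise ConfigurationError("obs_hours_sd must be below obs_hours_mean")
        if self.p_upset >= 0.5:
            log.warning("p_upset >= 0.5: the hierarchy is unrecoverable by design")


@dataclass
class GroundTruth:
    """Latent state recorded while generating, for downstream validation."""

    females: pd.DataFrame          # female_id, group_id, latent_class, strong, consistent, ...
    subject_years: pd.DataFrame    # female_id, year, group_id
    preferred: pd.DataFrame        # female_id, year, partner_id (latent top set)
    affinities: pd.DataFrame       # group_id, year, id_i, id_j, affinity
    rank_orders: dict              # (group_id, year) -> list of ids, dominant first


# ---------------------------------------------------------------------------
# mortality

def generate_mortality(
    draft: pd.DataFrame,
    classes: pd.Series,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw exponential death times from adult entry, by latent class.

    ``draft`` needs ``female_id, birth_date, first_birth_date,
    entry_date``.  Event times are exponential with per-year rate
    ``baseline_hazard * exp(class_log_hr[class])`` measured from entry;
    subjects alive at the administrative end of the study are censored
    there.  Returns the demography table plus ``event`` and ``hazard``
    columns.
    """
    if params.baseline_hazard < 0:
        raise ConfigurationError("baseline_hazard must be nonnegative")
    out = draft.copy()
    end = pd.Timestamp(params.start_date) + pd.DateOffset(years=params.years)
    haz = np.array(
        [params.baseline_hazard * math.exp(params.class_log_hr[c]) for c in classes]
    )
    with np.errstate(divide="ignore"):
        t = np.where(haz > 0, rng.exponential(1.0, size=len(out)) / np.maximum(haz, 1e-300), np.inf)
    death = (
        pd.to_datetime(out["entry_date"])
        + pd.to_timedelta(
            np.round(np.minimum(t * DAYS_PER_YEAR, 200 * DAYS_PER_YEAR)), unit="D"
        )
    ).dt.normalize()
    died = death < end
    out["death_date"] = death.where(died, pd.NaT)
    out["censor_date"] = end
    out["event"] = died.astype(int)
    out["hazard"] = haz
    return out


# ---------------------------------------------------------------------------
# agonism

def generate_agonism(
    rosters: Mapping[tuple[str, int], list[str]],
    rank_orders: Mapping[tuple[str, int], list[str]],
    params: GeneratorParams,
    rng: np.random.Generator,
    cfg: StudyConfig,
) -> pd.DataFrame:
    """Decided win/loss records consistent with a latent linear order.

    Interaction counts are Poisson per dyad-year; each interaction is won
    by the higher-ranked opponent with probability ``1 - p_upset``.
    Dyads drawing zero interactions are simply absent (unknown
    relationship).
    """
    rows: list[tuple] = []
    for (g, y), roster in sorted(rosters.items()):
        order = rank_orders[(g, y)]
        pos = {f: k for k, f in enumerate(order)}
        start = cfg.year_start(y)
        ndays = cfg.year_days(y)
        ids = sorted(roster)
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a, b = ids[a_i], ids[b_i]
                n = rng.poisson(params.agonism_rate)
                if n == 0:
                    continue
                hi, lo_ = (a, b) if pos[a] < pos[b] else (b, a)
                upsets = rng.random(n) < params.p_upset
                days = rng.integers(0, ndays, size=n)
                for u, d in zip(upsets, days):
                    w, l = (lo_, hi) if u else (hi, lo_)
                    rows.append((start + pd.Timedelta(days=int(d)), g, w, l))
    return pd.DataFrame(rows, columns=["date", "group_id", "winner_id", "loser_id"])


# ---------------------------------------------------------------------------
# full cohort

def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def generate_cohort(params: GeneratorParams) -> tuple[CohortTables, GroundTruth]:
    """Generate one complete synthetic study; reproducible given the seed."""
    rng = np.random.default_rng(params.seed)
    cfg = StudyConfig(year_anchor=params.start_date, seed=params.seed)
    start = cfg.year_anchor
    end = start + pd.DateOffset(years=params.years)

    # --- rosters and latent classes
    lo, hi = params.group_size_range
    sizes = rng.integers(lo, hi + 1, params.n_groups)
    groups, fids = [], []
    for gi, sz in enumerate(sizes):
        g = f"G{gi + 1}"
        for _ in range(sz):
            fids.append(f"F{len(fids) + 1:03d}")
            groups.append(g)
    n = len(fids)
    classes = rng.choice([1, 2, 3, 4], p=params.class_probs, size=n)

    # --- demography: ages, entries
    afb = _truncated_normal(rng, params.age_first_birth_mean, params.age_first_birth_sd,
                            5.5, 9.5, n)
    adult = rng.random(n) < params.p_adult_at_start
    age0 = np.where(
        adult,
        rng.uniform(afb + 0.2, params.max_age_at_start),
        afb - rng.uniform(0.1, 2.0, n),
    )
    entry_age = np.maximum(age0, afb)
    birth = start - pd.to_timedelta(np.round(age0 * DAYS_PER_YEAR), unit="D")
    first_birth = birth + pd.to_timedelta(np.round(afb * DAYS_PER_YEAR), unit="D")
    draft = pd.DataFrame(
        {
            "female_id": fids,
            "birth_date": birth,
            "first_birth_date": first_birth,
            "entry_date": birth + pd.to_timedelta(np.round(entry_age * DAYS_PER_YEAR), unit="D"),
        }
    )
    demo = generate_mortality(draft, pd.Series(classes), params, rng)
    exit_date = demo["death_date"].fillna(demo["censor_date"])

    # --- infants: births at the first birth then at stochastic intervals
    inf_rows = []
    for i in range(n):
        b = first_birth[i]
        while b < exit_date.iloc[i]:
            inf_rows.append((fids[i], b))
            b = b + pd.Timedelta(days=round(
                max(1.2, rng.normal(params.interbirth_mean, params.interbirth_sd))
                * DAYS_PER_YEAR))
    infants = pd.DataFrame(inf_rows, columns=["mother_id", "infant_birth_date"])

    # --- subject-years: a female-year is populated when she is an adult
    # subject for at least ~47 days of the year (sampling every ~3 days then
    # guarantees the >10%-of-year inclusion rule downstream)
    min_active = int(np.ceil(0.125 * 365.25)) + 1
    active: dict[tuple[str, int], tuple[pd.Timestamp, pd.Timestamp]] = {}
    memb_rows = []
    for i in range(n):
        for y in range(params.years):
            a = max(demo["entry_date"].iloc[i], cfg.year_start(y))
            b = min(exit_date.iloc[i], cfg.year_start(y + 1))
            if (b - a).days >= min_active:
                memb_rows.append((fids[i], y, groups[i]))
                active[(fids[i], y)] = (a, b)
    membership = pd.DataFrame(memb_rows, columns=["female_id", "year", "group_id"])
    rosters = {
        (g, y): sorted(d["female_id"])
        for (g, y), d in membership.groupby(["group_id", "year"])
    }

    # --- latent preferred partner sets with class-dependent turnover.
    # Replacements are biased toward females who already prefer the chooser
    # (mutuality), so strong dyads tend to be reciprocal and a female's own
    # turnover type governs the consistency of her top dyads.
    fclass = dict(zip(fids, classes))
    fgroup0 = dict(zip(fids, groups))
    pref: dict[tuple[str, int], list[str]] = {}
    last_pref: dict[str, list[str]] = {}
    history: dict[str, list[set[str]]] = {}  # previous 2 years' preferred sets
    for y in range(params.years):
        actives = sorted(f for (f, yy) in active if yy == y)
        rng.shuffle(actives)
        this_year: dict[str, list[str]] = {}
        def _turn(i: str) -> float:
            return (
                params.turnover_consistent
                if fclass[i] in CONSISTENT_CLASSES
                else params.turnover_inconsistent
            )

        for f in actives:
            pool = [x for x in rosters[(fgroup0[f], y)] if x != f]
            kept, dropped = [], []
            for p in last_pref.get(f, []):
                if p not in pool:
                    continue
                # a bond persists only while both members are stable: the
                # pair's yearly breakup probability is the larger of the two
                # members' turnover rates
                (dropped if rng.random() < max(_turn(f), _turn(p)) else kept).append(p)
            # breakups are mutual: a dropped partner no longer counts f as
            # preferred either, so the pair does not simply re-form
            for p in dropped:
                if f in last_pref.get(p, []):
                    last_pref[p] = [x for x in last_pref[p] if x != f]
            want = min(params.n_top_latent, len(pool))
            need = max(0, want - len(kept))
            if need:
                # novelty: new bonds go to females outside the recent
                # preferred history, so a dropped partner does not reappear
                # by chance from a small pool
                recent = set().union(*history.get(f, [set()]))
                cand = [
                    x for x in pool
                    if x not in kept and x not in dropped and x not in recent
                ]
                if len(cand) < need:
                    cand = [x for x in pool if x not in kept and x not in dropped]
                if len(cand) < need:
                    cand = [x for x in pool if x not in kept]
                # favour mutual ties and partners of the same consistency
                # type (assortative bonding keeps the latent classes crisp)
                f_cons = fclass[f] in CONSISTENT_CLASSES
                w = np.array(
                    [
                        (
                            params.mutuality_weight
                            if f in this_year.get(c, ()) or f in last_pref.get(c, ())
                            else 1.0
                        )
                        * (
                            params.assortativity_weight
                            if (fclass[c] in CONSISTENT_CLASSES) == f_cons
                            else 1.0
                        )
                        for c in cand
                    ]
                )
                pick = rng.choice(len(cand), size=min(need, len(cand)),
                                  replace=False, p=w / w.sum())
                kept = kept + [cand[i] for i in pick]
            this_year[f] = kept
            pref[(f, y)] = list(kept)
        for f, ps in this_year.items():
            last_pref[f] = ps
            history[f] = (history.get(f, []) + [set(ps)])[-2:]
    pref_df = pd.DataFrame(
        [(f, y, p) for (f, y), ps in pref.items() for p in ps],
        columns=["female_id", "year", "partner_id"],
    )

    # --- dyadic affinities: gamma background redrawn each year (casual
    # associations fluctuate), boosted on latent preferred dyads, which are
    # the only source of across-year persistence (strong females boost more)
    base: dict[tuple[str, str, int], float] = {}

    def base_aff(a: str, b: str, y: int) -> float:
        key = (a, b, y) if a < b else (b, a, y)
        if key not in base:
            base[key] = rng.gamma(params.background_shape, 1.0 / params.background_shape)
        return base[key]

    mult = {
        f: params.strong_multiplier if fclass[f] in STRONG_CLASSES else params.weak_multiplier
        for f in fids
    }
    aff_rows = []
    affinity: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for (g, y), roster in rosters.items():
        m = len(roster)
        w = np.zeros((m, m))
        idx = {f: k for k, f in enumerate(roster)}
        for a_i in range(m):
            for b_i in range(a_i + 1, m):
                a, b = roster[a_i], roster[b_i]
                # additive boosts keep preferred dyads clear of the
                # fluctuating casual background
                v = base_aff(a, b, y)
                if b in pref.get((a, y), ()):
                    v += mult[a]
                if a in pref.get((b, y), ()):
                    v += mult[b]
                w[a_i, b_i] = w[b_i, a_i] = v
                aff_rows.append((g, y, a, b, v))
        affinity[(g, y)] = {"roster": np.array(roster), "w": w, "idx": idx}
    aff_df = pd.DataFrame(aff_rows, columns=["group_id", "year", "id_i", "id_j", "affinity"])

    # --- focal samples (accumulated columnar for speed)
    fgroup = dict(zip(fids, groups))
    s_focal: list[np.ndarray] = []
    s_group: list[np.ndarray] = []
    s_day: list[np.ndarray] = []   # days since epoch
    s_dur: list[np.ndarray] = []
    s_n: list[int] = []
    p_sid: list[np.ndarray] = []
    p_part: list[np.ndarray] = []
    p_beh: list[np.ndarray] = []
    p_min: list[np.ndarray] = []
    sid = 0
    epoch = pd.Timestamp("1970-01-01")
    for (f, y), (a, b) in sorted(active.items()):
        g = fgroup[f]
        info = affinity[(g, y)]
        others = info["roster"][info["roster"] != f]
        if len(others):
            wts = info["w"][info["idx"][f]][[info["idx"][o] for o in others]]
            if wts.sum() <= 0:
                wts = np.ones(len(others))
            wts = wts / wts.sum()

        ndays = (b - a).days
        frac = ndays / cfg.year_days(y)
        hours = max(rng.normal(params.obs_hours_mean, params.obs_hours_sd), 25.0) * frac
        nsamp = min(ndays, max(int(round(hours * 60 / 29.0)), 45))
        days = np.sort(rng.choice(ndays, size=nsamp, replace=False))
        dur = np.where(rng.random(nsamp) < 0.85, 30.0, rng.uniform(12.0, 30.0, nsamp))

        ids = np.arange(sid, sid + nsamp)
        sid += nsamp
        s_focal.append(np.repeat(f, nsamp))
        s_group.append(np.repeat(g, nsamp))
        s_day.append((a - epoch).days + days)
        s_dur.append(np.round(dur, 2))
        s_n.append(nsamp)

        if len(others) == 0:
            continue  # no coresident partners: samples only, no affiliation

        # class-dependent affiliation rates: strongly bonded females spend
        # more of their time grooming/resting with partners
        rate_f = (
            params.strong_rate_factor
            if fclass[f] in STRONG_CLASSES
            else params.weak_rate_factor
        )

        # grooming: zero-inflated gamma total, one partner per sample
        has_g = rng.random(nsamp) < params.p_groom_sample
        gtot = np.minimum(
            rng.gamma(
                1.5, rate_f * dur * params.groom_rate_typical / (params.p_groom_sample * 1.5)
            ),
            0.5 * dur,
        )
        gpart = rng.choice(len(others), size=nsamp, p=wts)
        keep = has_g & (gtot > 0.01)
        p_sid.append(ids[keep])
        p_part.append(others[gpart[keep]])
        p_beh.append(np.repeat("groom", keep.sum()))
        p_min.append(np.round(gtot[keep], 2))

        # resting within 1 m: likewise but more frequent
        has_r = rng.random(nsamp) < params.p_rest_sample
        rtot = np.minimum(
            rng.gamma(
                1.5, rate_f * dur * params.rest_rate_typical / (params.p_rest_sample * 1.5)
            ),
            0.6 * dur,
        )
        rpart = rng.choice(len(others), size=nsamp, p=wts)
        keep = has_r & (rtot > 0.01)
        p_sid.append(ids[keep])
        p_part.append(others[rpart[keep]])
        p_beh.append(np.repeat("rest1m", keep.sum()))
        p_min.append(np.round(rtot[keep], 2))

    def _sid_str(ids: np.ndarray) -> pd.Series:
        return "S" + pd.Series(ids, dtype="int64").astype(str).str.zfill(6)

    samples = pd.DataFrame(
        {
            "sample_id": _sid_str(np.arange(sid)),
            "focal_id": np.concatenate(s_focal) if s_focal else np.array([], dtype=object),
            "group_id": np.concatenate(s_group) if s_group else np.array([], dtype=object),
            "date": pd.to_datetime(
                np.concatenate(s_day) if s_day else np.array([], dtype=int), unit="D"
            ),
            "duration_min": np.concatenate(s_dur) if s_dur else np.array([]),
        }
    )
    partners = pd.DataFrame(
        {
            "sample_id": _sid_str(
                np.concatenate(p_sid) if p_sid else np.array([], dtype=int)
            ).to_numpy(),
            "partner_id": np.concatenate(p_part) if p_part else np.array([], dtype=object),
            "behavior": np.concatenate(p_beh) if p_beh else np.array([], dtype=object),
            "minutes": np.concatenate(p_min) if p_min else np.array([]),
        }
    )

    # --- dominance: one latent order per group, restricted per year
    dom_value = dict(zip(fids, rng.permutation(n)))
    rank_orders = {
        (g, y): sorted(roster, key=lambda f: dom_value[f])
        for (g, y), roster in rosters.items()
    }
    agonism = generate_agonism(rosters, rank_orders, params, rng, cfg)

    demo_out = demo[
        ["female_id", "birth_date", "first_birth_date", "death_date", "censor_date"]
    ].copy()
    tables = CohortTables(
        samples=samples,
        partners=partners,
        demography=demo_out,
        membership=membership,
        infants=infants,
        agonism=agonism,
    )
    females = pd.DataFrame(
        {
            "female_id": fids,
            "group_id": groups,
            "latent_class": classes,
            "strong": np.isin(classes, STRONG_CLASSES),
            "consistent": np.isin(classes, CONSISTENT_CLASSES),
            "age_at_start": age0,
            "entry_age": entry_age,
            "entry_date": demo["entry_date"],
            "death_date": demo["death_date"],
            "event": demo["event"],
            "hazard": demo["hazard"],
            "dominance_value": [dom_value[f] for f in fids],
        }
    )
    truth = GroundTruth(
        females=females,
        subject_years=membership.copy(),
        preferred=pref_df,
        affinities=aff_df,
        rank_orders=rank_orders,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# direct survival simulation (no behavioral layer) for recovery studies

def simulate_survival(
    n: int,
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
    class_probs: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Left-truncated survival records straight from latent classes.

    Used for estimator-recovery simulations where the behavioral layer is
    irrelevant: females enter at staggered adult ages, die with
    class-specific exponential hazards, and are censored at the study
    end.  Returns ``female_id, latent_class, entry_age, exit_age, event``.
    """
    params = params or GeneratorParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    probs = class_probs or params.class_probs
    cls = rng.choice([1, 2, 3, 4], p=probs, size=n)
    entry_age = rng.uniform(7.0, 18.0, size=n)
    haz = np.array([params.baseline_hazard * math.exp(params.class_log_hr[c]) for c in cls])
    with np.errstate(divide="ignore"):
        t = np.where(haz > 0, rng.exponential(1.0, size=n) / np.maximum(haz, 1e-300), np.inf)
    admin = params.years
    event = t < admin
    exit_age = entry_age + np.minimum(t, admin)
    return pd.DataFrame(
        {
            "female_id": [f"F{i + 1:04d}" for i in range(n)],
            "latent_class": cls,
            "entry_age": entry_age,
            "exit_age": exit_age,
            "event": event.astype(int),
        }
    )
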