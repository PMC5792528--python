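"""End-to-end study assembly: tables -> indices -> metrics -> survival records.

:class:`Study` wires the stages together and caches intermediates:
subject-year assignment, dyadic sociality indices, dominance ranks,
per-female annual and multi-year metrics, and the fixed-time and
time-dependent survival records the Cox models consume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import dominance, dsi, partners, survival
from .config import StudyConfig, age_years
from .tables import CohortTables, assign_study_years

log = logging.getLogger("socbond")


class Study:
    """One cohort plus configuration, with every derived product cached."""

    def __init__(self, tables: CohortTables, config: StudyConfig | None = None):
        self.tables = tables
        self.config = config or StudyConfig()
        self._cache: dict = {}

    # -- stage products --------------------------------------------------

    @property
    def subject_years(self) -> pd.DataFrame:
        if "subject_years" not in self._cache:
            self._cache["subject_years"] = assign_study_years(self.tables, self.config)
        return self._cache["subject_years"]

    @property
    def included_years(self) -> pd.DataFrame:
        sy = self.subject_years
        return sy[sy["included"]].reset_index(drop=True)

    @property
    def dyads(self) -> pd.DataFrame:
        """Dyad-year records with DSI attached."""
        if "dyads" not in self._cache:
            raw = dsi.compute_dyad_year(self.tables, self.included_years, self.config)
            self._cache["medians"] = dsi.year_medians(raw)
            self._cache["dyads"] = dsi.compute_dsi(raw, self._cache["medians"])
        return self._cache["dyads"]

    @property
    def medians(self) -> pd.DataFrame:
        self.dyads
        return self._cache["medians"]

    @property
    def rosters(self) -> dict[tuple[str, int], list[str]]:
        return {
            (g, y): sorted(d["female_id"])
            for (g, y), d in self.included_years.groupby(["group_id", "year"])
        }

    @property
    def ranks(self) -> pd.DataFrame:
        """Per female-year I&SI rank proportion (NaN when the roster < 2)."""
        if "ranks" not in self._cache:
            mats = dominance.build_matrices(self.tables.agonism, self.rosters, self.config)
            rows = []
            for (g, y), (roster, counts) in sorted(mats.items()):
                if len(roster) < 2:
                    continue
                order = dominance.isi_order(g, y, roster, counts, seed=self.config.seed)
                props = dominance.rank_proportion(order)
                for pos, f in enumerate(order.order):
                    rows.append((g, y, f, pos + 1, props[f], order.converged))
            self._cache["ranks"] = pd.DataFrame(
                rows,
                columns=["group_id", "year", "female_id", "position", "rank_prop", "converged"],
            )
        return self._cache["ranks"]

    def tops(self, k: int | None = None) -> dict[str, dict[int, list[str]]]:
        k = k or self.config.k_top
        key = ("tops", k)
        if key not in self._cache:
            self._cache[key] = partners.annual_tops(self.dyads, k)
        return self._cache[key]

    # -- female-year metrics ---------------------------------------------

    def female_year(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.config.k_top
        key = ("female_year", k)
        if key in self._cache:
            return self._cache[key]
        directed = partners._directed(self.dyads)
        strength = (
            directed.sort_values(
                ["female_id", "year", "dsi", "partner_id"],
                ascending=[True, True, False, True], kind="stable",
            )
            .groupby(["female_id", "year"])["dsi"]
            .apply(lambda s: s.iloc[:k].mean())
            .rename("bond_strength_annual")
        )
        out = self.included_years[["female_id", "year", "group_id"]].copy()
        out["n_groupmates"] = (
            out.merge(
                self.included_years.groupby(["group_id", "year"]).size().rename("sz"),
                left_on=["group_id", "year"], right_index=True, how="left",
            )["sz"] - 1
        )
        out = out.merge(strength, how="left", left_on=["female_id", "year"], right_index=True)
        out = out.merge(
            self.ranks[["female_id", "year", "rank_prop"]],
            how="left", on=["female_id", "year"],
        )
        tops = self.tops(k)
        cons = []
        order = {}
        for f, d in out.groupby("female_id"):
            yrs = sorted(y for y in tops.get(f, {}))
            order[f] = yrs
        for f, y in zip(out["female_id"], out["year"]):
            yrs = order.get(f, [])
            if y not in yrs:
                cons.append(np.nan)
                continue
            seq = [tops[f][yy] for yy in yrs]
            cons.append(partners.annual_consistency(seq, yrs.index(y)))
        out["consistency_annual"] = cons
        out = out.sort_values(["female_id", "year"]).reset_index(drop=True)
        self._cache[key] = out
        return out

    # -- per-female summaries and survival records ------------------------

    def _demo_ages(self) -> pd.DataFrame:
        d = self.tables.demography.copy()
        start = self.config.year_anchor
        exit_date = d["death_date"].fillna(d["censor_date"])
        d["event"] = d["death_date"].notna().astype(int)
        d["entry_date"] = d["first_birth_date"].where(d["first_birth_date"] > start, start)
        d["entry_age"] = [age_years(e, b) for e, b in zip(d["entry_date"], d["birth_date"])]
        d["exit_age"] = [age_years(e, b) for e, b in zip(exit_date, d["birth_date"])]
        d["age_first_birth"] = [
            age_years(f, b) for f, b in zip(d["first_birth_date"], d["birth_date"])
        ]
        return d

    def summaries(self, k: int | None = None) -> pd.DataFrame:
        """One row per female observed in at least two subject-years."""
        k = k or self.config.k_top
        key = ("summaries", k)
        if key in self._cache:
            return self._cache[key]
        fy = self.female_year(k)
        tops = self.tops(k)
        demo = self._demo_ages().set_index("female_id")
        death_year = {
            f: self.config.year_of(d)
            for f, d in zip(demo.index, demo["death_date"])
            if pd.notna(d)
        }
        rows = []
        for f, d in fy.groupby("female_id"):
            yrs = sorted(d["year"])
            if len(yrs) < 2 or f not in tops:
                continue
            seq = [tops[f][y] for y in yrs if y in tops[f]]
            if len(seq) < 2:
                continue
            cons = partners.multi_year_consistency(seq)
            dth, chg = partners.death_attributed_changes(
                {y: tops[f][y] for y in yrs if y in tops[f]}, death_year
            )
            dm = demo.loc[f]
            rows.append(
                (
                    f, len(yrs), d["bond_strength_annual"].mean(), cons,
                    d["rank_prop"].mean(), d["n_groupmates"].mean(),
                    dm["age_first_birth"], dm["entry_age"], dm["exit_age"],
                    int(dm["event"]),
                    dth / chg if chg else np.nan,
                )
            )
        out = pd.DataFrame(
            rows,
            columns=[
                "female_id", "years_observed", "bond_strength_multi", "consistency_multi",
                "mean_rank", "mean_groupmates", "age_first_birth", "entry_age", "exit_age",
                "event", "death_change_prop",
            ],
        )
        ok = out["bond_strength_multi"].notna() & out["consistency_multi"].notna()
        out.loc[ok, "class_multi"] = partners.assign_classes(
            out.loc[ok, "bond_strength_multi"].to_numpy(),
            out.loc[ok, "consistency_multi"].to_numpy(),
        )
        self._cache[key] = out
        return out

    def fixed_records(self, k: int | None = None) -> pd.DataFrame:
        """Per-female survival records for the fixed-time models."""
        s = self.summaries(k)
        s = s[s["class_multi"].notna() & (s["entry_age"] < s["exit_age"])].copy()
        s["class_multi"] = s["class_multi"].astype(int)
        return s.reset_index(drop=True)

    def timedep_records(self, k: int | None = None) -> pd.DataFrame:
        """Subject-year (start, stop] intervals with annual covariates.

        First observed years (annual consistency undefined) are dropped;
        annual strength-consistency classes are assigned across the
        remaining subject-years.
        """
        k = k or self.config.k_top
        fy = self.female_year(k)
        demo = self._demo_ages().set_index("female_id")
        fy = fy[fy["consistency_annual"].notna() & fy["bond_strength_annual"].notna()].copy()
        fy["class_annual"] = partners.assign_classes(
            fy["bond_strength_annual"].to_numpy(), fy["consistency_annual"].to_numpy()
        )
        rows = []
        for (f, y), r in fy.set_index(["female_id", "year"]).iterrows():
            dm = demo.loc[f]
            birth = dm["birth_date"]
            a = max(dm["entry_age"], age_years(self.config.year_start(y), birth))
            b = min(dm["exit_age"], age_years(self.config.year_start(y + 1), birth))
            if a >= b:
                continue
            rows.append((f, y, a, b, r["class_annual"], r["rank_prop"],
                         r["n_groupmates"], r["bond_strength_annual"],
                         r["consistency_annual"]))
        out = pd.DataFrame(
            rows,
            columns=["female_id", "year", "start_age", "stop_age", "class_annual",
                     "rank_prop", "n_groupmates", "bond_strength_annual",
                     "consistency_annual"],
        )
        out["event"] = 0
        last = out.groupby("female_id")["stop_age"].idxmax()
        for f, idx in last.items():
            dm = demo.loc[f]
            if dm["event"] and abs(dm["exit_age"] - out.loc[idx, "stop_age"]) < 1e-9:
                out.loc[idx, "event"] = 1
        return out.sort_values(["female_id", "start_age"]).reset_index(drop=True)

    # -- model fits -------------------------------------------------------

    def fit_fixed(self, competition: str = "rank", k: int | None = None):
        """One of the two 3-predictor fixed-time models.

        ``competition`` picks dominance rank or number of adult female
        groupmates as the social-competition covariate alongside
        strength-consistency class and age at first birth.
        """
        cov = {"rank": "mean_rank", "groupmates": "mean_groupmates"}[competition]
        rec = self.fixed_records(k).dropna(subset=[cov, "age_first_birth"])
        return survival.fit_cox_fixed(
            rec, covariates=["age_first_birth", cov], class_col="class_multi", reference=3
        )

    def model_averaged(self, k: int | None = None) -> pd.DataFrame:
        """AICc-averaged class and age-at-first-birth terms across the two
        fixed-time models (rank model and groupmates model)."""
        ra = self.fit_fixed("rank", k)
        rb = self.fit_fixed("groupmates", k)
        shared = [t for t in ra.names if t.startswith("class_multi")] + ["age_first_birth"]
        return survival.model_average(ra, rb, shared)

    def fit_timedep(self, k: int | None = None, reference: int = 3):
        rec = self.timedep_records(k).dropna(subset=["rank_prop"])
        return survival.fit_cox_timedep(
            rec, covariates=["rank_prop", "n_groupmates"], class_col="class_annual",
            reference=reference,
        )

    def repeatability(self, measure: str = "bond_strength", n_bootstrap: int = 200,
                      seed: int | None = None):
        """Repeatability (ICC) of an annual measure across females."""
        from . import repeatability as rpt

        col = {
            "bond_strength": "bond_strength_annual",
            "rank": "rank_prop",
            "groupmates": "n_groupmates",
        }[measure]
        fy = self.female_year().dropna(subset=[col]).copy()
        fy["year_index"] = fy["year"] - fy["year"].min()
        fixed = ["n_groupmates", "year_index"] if col != "n_groupmates" else ["year_index"]
        return rpt.fit_repeatability(
            fy, value_col=col, id_col="female_id", fixed_effects=fixed,
            n_bootstrap=n_bootstrap,
            seed=self.config.seed if seed is None else seed, measure=measure,
        )
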