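"""Tabular domain data: focal samples, demography, agonistic records.

All tables are plain :class:`pandas.DataFrame` objects with documented
schemas; this module validates them against the domain invariants, reads
and writes the on-disk CSV layout, and assigns subjects to study years.

CSV layout (UTF-8, ISO-8601 dates)::

    focal_samples.csv   sample_id,focal_id,group_id,date,duration_min
    focal_partners.csv  sample_id,partner_id,behavior,minutes   (behavior in {groom, rest1m})
    demography.csv      female_id,birth_date,first_birth_date,death_date,censor_date
    membership.csv      female_id,year,group_id
    infants.csv         mother_id,infant_birth_date
    agonism.csv         date,group_id,winner_id,loser_id
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd

from .config import StudyConfig

log = logging.getLogger("socbond")

#: Maximum focal-sample bout length in minutes.
MAX_SAMPLE_MIN = 30.0

SCHEMAS = {
    "samples": ["sample_id", "focal_id", "group_id", "date", "duration_min"],
    "partners": ["sample_id", "partner_id", "behavior", "minutes"],
    "demography": ["female_id", "birth_date", "first_birth_date", "death_date", "censor_date"],
    "membership": ["female_id", "year", "group_id"],
    "infants": ["mother_id", "infant_birth_date"],
    "agonism": ["date", "group_id", "winner_id", "loser_id"],
}
_FILES = {
    "samples": "focal_samples.csv",
    "partners": "focal_partners.csv",
    "demography": "demography.csv",
    "membership": "membership.csv",
    "infants": "infants.csv",
    "agonism": "agonism.csv",
}
_DATE_COLS = {
    "samples": ["date"],
    "demography": ["birth_date", "first_birth_date", "death_date", "censor_date"],
    "infants": ["infant_birth_date"],
    "agonism": ["date"],
}


class SchemaError(ValueError):
    """A table is missing a required column."""


@dataclass
class CohortTables:
    """The full observational dataset of one study."""

    samples: pd.DataFrame
    partners: pd.DataFrame
    demography: pd.DataFrame
    membership: pd.DataFrame
    infants: pd.DataFrame
    agonism: pd.DataFrame

    def copy(self) -> "CohortTables":
        return CohortTables(**{f.name: getattr(self, f.name).copy() for f in fields(self)})


def _check_schema(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s): {', '.join(missing)}")


def validate_tables(tables: CohortTables) -> tuple[CohortTables, list[str]]:
    """Validate all tables against the domain invariants.

    Rows violating an invariant are dropped and a human-readable
    diagnostic is recorded per row; a missing column raises
    :class:`SchemaError` instead.  Returns the cleaned tables and the
    list of diagnostics.
    """
    diags: list[str] = []
    for name in SCHEMAS:
        _check_schema(getattr(tables, name), name)
    t = tables.copy()

    # focal samples: durations in (0, 30]
    s = t.samples
    bad = ~(s["duration_min"].gt(0) & s["duration_min"].le(MAX_SAMPLE_MIN))
    for _, r in s[bad].iterrows():
        diags.append(f"samples: sample {r.sample_id} has invalid duration {r.duration_min}")
    t.samples = s[~bad].reset_index(drop=True)

    # partner minutes: known behavior, nonnegative, per-sample per-behavior
    # totals bounded by the sample duration
    p = t.partners
    dur = t.samples.set_index("sample_id")["duration_min"]
    bad_p = ~p["behavior"].isin(["groom", "rest1m"]) | (p["minutes"] < 0)
    bad_p |= ~p["sample_id"].isin(dur.index)
    totals = p[~bad_p].groupby(["sample_id", "behavior"])["minutes"].sum()
    over = totals[totals.gt(dur.reindex(totals.index.get_level_values(0)).to_numpy() + 1e-9)]
    for (sid, beh), tot in over.items():
        diags.append(
            f"partners: sample {sid} {beh} minutes total {tot:g} exceeds sample duration"
        )
        bad_p |= (p["sample_id"] == sid) & (p["behavior"] == beh)
    for _, r in p[~p["behavior"].isin(["groom", "rest1m"]) | (p["minutes"] < 0)].iterrows():
        diags.append(f"partners: sample {r.sample_id} invalid row (behavior/minutes)")
    t.partners = p[~bad_p].reset_index(drop=True)

    # demography: birth < first birth < exit; exit defined
    d = t.demography
    exit_date = d["death_date"].fillna(d["censor_date"])
    bad_d = (
        exit_date.isna()
        | ~(d["birth_date"] < d["first_birth_date"])
        | ~(d["first_birth_date"] < exit_date)
    )
    for _, r in d[bad_d].iterrows():
        diags.append(f"demography: female {r.female_id} violates birth<first_birth<exit ordering")
    t.demography = d[~bad_d].reset_index(drop=True)

    # agonism: decided interactions between distinct coresident members
    a = t.agonism
    bad_a = a["winner_id"] == a["loser_id"]
    for _, r in a[bad_a].iterrows():
        diags.append(f"agonism: self-interaction for {r.winner_id} on {r.date}")
    t.agonism = a[~bad_a].reset_index(drop=True)

    for msg in diags:
        log.warning("rejected row: %s", msg)
    return t, diags


def read_tables(path: str | Path, validate: bool = True) -> CohortTables:
    """Read the cohort CSVs from a directory; see module docstring for layout."""
    path = Path(path)
    parts = {}
    for name, fname in _FILES.items():
        f = path / fname
        if not f.exists():
            raise FileNotFoundError(f"expected {fname} in {path}")
        df = pd.read_csv(f)
        _check_schema(df, name)
        for col in _DATE_COLS.get(name, []):
            try:
                df[col] = pd.to_datetime(df[col], format="ISO8601")
            except (ValueError, TypeError) as e:
                raise ValueError(f"{fname}: unparseable date in column {col}: {e}") from e
        parts[name] = df
    tables = CohortTables(**parts)
    if validate:
        tables, _ = validate_tables(tables)
    return tables


def write_tables(tables: CohortTables, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, fname in _FILES.items():
        df = getattr(tables, name).copy()
        for col in _DATE_COLS.get(name, []):
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(path / fname, index=False)


def assign_study_years(tables: CohortTables, config: StudyConfig) -> pd.DataFrame:
    """Flag each (female, study-year) as an included subject-year or not.

    A female counts as a subject in a study year when the number of
    distinct days on which she was focal-sampled exceeds
    ``subject_year_threshold`` of the days in that year.  Membership rows
    without any samples are excluded with a warning.

    Returns a frame ``female_id, year, group_id, n_sample_days,
    frac_of_year, included``.
    """
    s = tables.samples
    yr = config.year_of(s["date"]) if len(s) else pd.Series([], dtype=int)
    days = (
        pd.DataFrame({"female_id": s["focal_id"], "year": yr, "date": s["date"].dt.normalize()})
        .drop_duplicates()
        .groupby(["female_id", "year"])
        .size()
        .rename("n_sample_days")
    )
    out = tables.membership.copy()
    out = out.merge(days, how="left", left_on=["female_id", "year"], right_index=True)
    out["n_sample_days"] = out["n_sample_days"].fillna(0).astype(int)
    out["frac_of_year"] = [
        n / config.year_days(y) for n, y in zip(out["n_sample_days"], out["year"])
    ]
    out["included"] = out["frac_of_year"] > config.subject_year_threshold
    never = out.groupby("female_id")["n_sample_days"].sum()
    for fid in never[never == 0].index:
        log.warning("female %s has no focal samples in any year; excluded everywhere", fid)
    return out
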