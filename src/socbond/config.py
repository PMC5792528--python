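"""Study-level configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

#: Days per year used whenever a date difference is converted to an age.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class StudyConfig:
    """Constants of the observational protocol and downstream analysis.

    Parameters
    ----------
    k_top
        Number of closest partners defining bond strength and consistency
        (3 or 6).
    n_permutations
        Node permutations used for the network null distribution.
    seed
        Master seed for every stochastic step.
    year_anchor
        First day of study year 0.  Each study year spans 12 months from
        this anchor; the default mirrors an October start of focal
        sampling.
    min_sample_min
        Focal samples shorter than this many minutes are discarded.
    infant_exclusion_days
        Observation records are excluded for a dyad while either member
        has an infant younger than this many days (days 0..d-1 excluded,
        day d retained).
    subject_year_threshold
        Minimum fraction of a study year (days with at least one focal
        sample / days in the year) for a female to count as a subject
        that year.
    """

    k_top: int = 3
    n_permutations: int = 1000
    seed: int = 0
    year_anchor: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2006-10-01"))
    min_sample_min: float = 20.0
    infant_exclusion_days: int = 100
    subject_year_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.k_top not in (3, 6):
            raise ValueError(f"k_top must be 3 or 6, got {self.k_top}")
        if not (0.0 < self.subject_year_threshold < 1.0):
            raise ValueError("subject_year_threshold must lie in (0, 1)")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be nonnegative")
        if self.min_sample_min < 0 or self.infant_exclusion_days < 0:
            raise ValueError("filters cannot be negative")
        object.__setattr__(self, "year_anchor", pd.Timestamp(self.year_anchor))

    # -- study-year arithmetic -------------------------------------------

    def year_start(self, year: int) -> pd.Timestamp:
        return self.year_anchor + pd.DateOffset(years=year)

    def year_of(self, dates) -> pd.Series | int:
        """Map calendar date(s) to study-year index (floor).

        Study year y runs from the y-th anniversary of the anchor to the
        next one.
        """
        scalar = not hasattr(dates, "__len__")
        ts = pd.DatetimeIndex([dates] if scalar else pd.to_datetime(dates))
        a = self.year_anchor
        if a.month == 2 and a.day == 29:  # anniversary ill-defined; walk years
            out = []
            for d in ts:
                y = int((d - a).days // 366)
                while d >= self.year_start(y + 1):
                    y += 1
                out.append(y)
            arr = out
        else:
            before = (ts.month < a.month) | ((ts.month == a.month) & (ts.day < a.day))
            arr = (ts.year - a.year - before.astype(int)).to_numpy()
        if scalar:
            return int(arr[0])
        return pd.Series(arr, index=getattr(dates, "index", None))

    def year_days(self, year: int) -> int:
        return (self.year_start(year + 1) - self.year_start(year)).days

    # -- serialisation ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["year_anchor"] = str(pd.Timestamp(d["year_anchor"]).date())
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def age_years(date, birth_date) -> float:
    """Fractional age in years (whole days / 365.25)."""
    return (pd.Timestamp(date) - pd.Timestamp(birth_date)).days / DAYS_PER_YEAR
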