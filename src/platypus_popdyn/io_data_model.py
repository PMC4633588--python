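"""Core record types, delimited-text I/O and annual-occasion construction.

Field data arrive as one row per capture event (animal id, date, pool, sex,
age class, morphometrics, lactation flag, netting effort), a pool chainage
map (metres along the channel; the river is treated as one-dimensional), and
a monthly river-flow series in gigalitres. Everything downstream — capture
histories, movement pairs, breeding summaries — is built from these three
tables plus a list of annual survey occasions.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

SEXES = ("female", "male")
AGE_CLASSES = ("juvenile", "subadult", "adult")
LACTATION_STATES = ("yes", "no", "untested")

#: The five sex–age classes used throughout: females mature after their first
#: year; males pass through a sub-adult stage (years 1–2) before adulthood.
FIVE_CLASSES = (
    "female_juvenile",
    "female_adult",
    "male_juvenile",
    "male_subadult",
    "male_adult",
)

CAPTURE_COLUMNS = (
    "animal_id",
    "date",
    "pool_id",
    "sex",
    "age_class",
    "weight_g",
    "length_cm",
    "lactating",
    "effort_hours",
)


class DataFormatError(ValueError):
    """A file is structurally unusable (missing columns, empty flow series...)."""


class RowError(ValueError):
    """One or more data rows failed to parse; message lists row numbers."""


class CoverageError(ValueError):
    """The flow series does not cover an occasion's flow look-back window."""


def sex_age_class(sex: str, age_class: str) -> str:
    """Map (sex, age class) to one of the five analysis classes."""
    if sex == "female" and age_class == "subadult":
        raise ValueError("sub-adult is not a female field class")
    return f"{sex}_{age_class}"


@dataclass(frozen=True)
class CaptureRecord:
    """One capture event of one marked animal."""

    animal_id: str
    date: dt.date
    pool_id: str
    sex: str
    age_class: str
    weight_g: Optional[float] = None
    length_cm: Optional[float] = None
    lactating: str = "untested"
    effort_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"unknown age class {self.age_class!r}")
        if self.lactating not in LACTATION_STATES:
            raise ValueError(f"unknown lactation state {self.lactating!r}")
        if self.lactating == "yes" and self.sex != "female":
            raise ValueError("lactating=yes requires sex=female")
        if self.sex == "female" and self.age_class == "subadult":
            raise ValueError("sub-adult is not a female field class")
        if self.weight_g is not None and not self.weight_g > 0:
            raise ValueError("weight must be positive when present")
        if self.length_cm is not None and not self.length_cm > 0:
            raise ValueError("length must be positive when present")
        if self.effort_hours < 0:
            raise ValueError("effort must be non-negative")

    @property
    def five_class(self) -> str:
        return sex_age_class(self.sex, self.age_class)


@dataclass(frozen=True)
class PoolMap:
    """Pool id → chainage in metres from an arbitrary downstream origin."""

    chainage_m: dict[str, float]

    def __post_init__(self) -> None:
        for pool, chain in self.chainage_m.items():
            if chain < 0:
                raise ValueError(f"negative chainage for pool {pool!r}")

    def distance(self, a: str, b: str) -> float:
        try:
            return abs(self.chainage_m[a] - self.chainage_m[b])
        except KeyError as exc:
            raise KeyError(f"pool {exc.args[0]!r} not in pool map") from None

    @classmethod
    def read_csv(cls, path) -> "PoolMap":
        df = pd.read_csv(path, dtype={"pool_id": str})
        if not {"pool_id", "chainage_m"} <= set(df.columns):
            raise DataFormatError("pools file needs columns pool_id,chainage_m")
        if df["pool_id"].duplicated().any():
            raise DataFormatError("duplicate pool_id in pool map")
        return cls(dict(zip(df["pool_id"], df["chainage_m"].astype(float))))

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {"pool_id": list(self.chainage_m), "chainage_m": list(self.chainage_m.values())}
        ).to_csv(path, index=False)


class FlowSeries:
    """Monthly total flow volumes (GL), contiguous over the study span."""

    def __init__(self, series: pd.Series):
        if len(series) == 0:
            raise DataFormatError("empty flow series")
        series = series.sort_index()
        idx = series.index
        if not isinstance(idx, pd.PeriodIndex) or idx.freqstr not in ("M", "ME"):
            raise DataFormatError("flow series must have a monthly PeriodIndex")
        expected = pd.period_range(idx[0], idx[-1], freq="M")
        if len(idx) != len(expected) or (idx != expected).any():
            raise DataFormatError("flow series months must be contiguous")
        if (series < 0).any():
            raise ValueError("flows must be non-negative")
        self.series = series.astype(float)

    @classmethod
    def read_csv(cls, path) -> "FlowSeries":
        df = pd.read_csv(path)
        if not {"year", "month", "flow_gl"} <= set(df.columns):
            raise DataFormatError("flows file needs columns year,month,flow_gl")
        idx = pd.PeriodIndex(
            [pd.Period(year=int(y), month=int(m), freq="M") for y, m in zip(df["year"], df["month"])]
        )
        return cls(pd.Series(df["flow_gl"].to_numpy(float), index=idx))

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {
                "year": self.series.index.year,
                "month": self.series.index.month,
                "flow_gl": self.series.to_numpy(),
            }
        ).to_csv(path, index=False)

    def cumulative(self, end: pd.Period, months: int) -> float:
        """Total flow over the ``months`` months ending at (and including) ``end``."""
        start = end - (months - 1)
        if start < self.series.index[0] or end > self.series.index[-1]:
            raise CoverageError(
                f"flow series does not cover {start}..{end} "
                f"(available {self.series.index[0]}..{self.series.index[-1]})"
            )
        return float(self.series.loc[start:end].sum())

    def max_monthly(self, year: int, month_lo: int, month_hi: int) -> float:
        months = [pd.Period(year=year, month=m, freq="M") for m in range(month_lo, month_hi + 1)]
        for m in months:
            if m < self.series.index[0] or m > self.series.index[-1]:
                raise CoverageError(f"flow series does not cover {m}")
        return float(max(self.series.loc[m] for m in months))


@dataclass(frozen=True)
class Occasion:
    """One annual survey window, half-open [start, end)."""

    index: int
    start: dt.date
    end: dt.date
    effort_hours: float
    flow_1m: float
    flow_6m: float
    flow_12m: float
    flow_24m: float
    flow_max_jan_dec: float = float("nan")
    flow_max_jan_apr: float = float("nan")
    zero_effort: bool = False

    def contains(self, date: dt.date) -> bool:
        return self.start <= date < self.end


def read_capture_records(path) -> list[CaptureRecord]:
    """Parse a capture-record CSV, rejecting bad rows with row-numbered messages."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataFormatError("empty capture-record file")
        missing = set(CAPTURE_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise DataFormatError(f"missing columns: {sorted(missing)}")
        records: list[CaptureRecord] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                problems.append(f"row {lineno}: {exc}")
    if problems:
        raise RowError("; ".join(problems))
    return records


def _parse_row(row: dict) -> CaptureRecord:
    def opt_float(key: str) -> Optional[float]:
        val = (row.get(key) or "").strip()
        return float(val) if val else None

    return CaptureRecord(
        animal_id=row["animal_id"].strip(),
        date=dt.date.fromisoformat(row["date"].strip()),
        pool_id=row["pool_id"].strip(),
        sex=row["sex"].strip().lower(),
        age_class=row["age_class"].strip().lower(),
        weight_g=opt_float("weight_g"),
        length_cm=opt_float("length_cm"),
        lactating=(row.get("lactating") or "untested").strip().lower() or "untested",
        effort_hours=float(row["effort_hours"]),
    )


def write_capture_records(records: Iterable[CaptureRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CAPTURE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.animal_id,
                    r.date.isoformat(),
                    r.pool_id,
                    r.sex,
                    r.age_class,
                    "" if r.weight_g is None else repr(float(r.weight_g)),
                    "" if r.length_cm is None else repr(float(r.length_cm)),
                    r.lactating,
                    repr(float(r.effort_hours)),
                ]
            )


def survey_year(date: dt.date, season_start_month: int) -> int:
    """The survey year a date belongs to (year in which its window starts)."""
    return date.year if date.month >= season_start_month else date.year - 1


def build_occasions(
    records: Sequence[CaptureRecord],
    flows: FlowSeries,
    season_start_month: int = 7,
) -> list[Occasion]:
    """One 12-month occasion per survey year spanned by the records.

    Windows start on the first of ``season_start_month`` (default 1 July so a
    December–March field season falls inside a single window). Effort is the
    sum of per-survey net-hours — a survey being one (date, pool) combination —
    and the four flow covariates are cumulative totals over the 1/6/12/24
    months ending at the window midpoint.
    """
    if not records:
        raise ValueError("no capture records")
    if not 1 <= season_start_month <= 12:
        raise ValueError("season_start_month must be in 1..12")

    years = [survey_year(r.date, season_start_month) for r in records]
    y0, y1 = min(years), max(years)

    # one effort figure per survey (date, pool), not per captured animal
    survey_effort: dict[tuple[dt.date, str], float] = {}
    for r in records:
        survey_effort[(r.date, r.pool_id)] = r.effort_hours

    occasions = []
    for i, year in enumerate(range(y0, y1 + 1)):
        start = dt.date(year, season_start_month, 1)
        end = dt.date(year + 1, season_start_month, 1)
        effort = sum(
            e for (date, _pool), e in survey_effort.items() if start <= date < end
        )
        mid = start + (end - start) / 2
        mid_month = pd.Period(year=mid.year, month=mid.month, freq="M")
        occasions.append(
            Occasion(
                index=i,
                start=start,
                end=end,
                effort_hours=effort,
                flow_1m=flows.cumulative(mid_month, 1),
                flow_6m=flows.cumulative(mid_month, 6),
                flow_12m=flows.cumulative(mid_month, 12),
                flow_24m=flows.cumulative(mid_month, 24),
                flow_max_jan_dec=flows.max_monthly(mid.year, 1, 12)
                if _calendar_year_covered(flows, mid.year)
                else float("nan"),
                flow_max_jan_apr=flows.max_monthly(mid.year, 1, 4)
                if _calendar_year_covered(flows, mid.year, 4)
                else float("nan"),
                zero_effort=effort == 0,
            )
        )
    return occasions


def _calendar_year_covered(flows: FlowSeries, year: int, last_month: int = 12) -> bool:
    idx = flows.series.index
    return (
        pd.Period(year=year, month=1, freq="M") >= idx[0]
        and pd.Period(year=year, month=last_month, freq="M") <= idx[-1]
    )


def assign_occasion(record: CaptureRecord, occasions: Sequence[Occasion]) -> int:
    for occ in occasions:
        if occ.contains(record.date):
            return occ.index
    raise ValueError(f"record dated {record.date} falls outside all occasions")
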