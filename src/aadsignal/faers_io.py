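"""Reading and writing FAERS-style quarterly tables.

The FDA Adverse Event Reporting System distributes each quarter as five
"$"-delimited ASCII tables: DEMO (one row per report version), DRUG, REAC,
OUTC and THER (child rows keyed by ``primaryid``).  This module parses those
tables — plus a plain-CSV dialect for fixtures — into string DataFrames,
handles the FAERS date convention (8-digit day, 6-digit month, 4-digit year
precision), and converts raw DEMO rows into typed report records.

Nothing here deduplicates or filters; that is the job of :mod:`.cleaning`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidDateError

TABLES = ("demo", "drug", "reac", "outc", "ther")

#: Mandatory columns per table (FAERS ASCII naming). Extra columns are kept
#: but ignored by the pipeline.
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "event_dt", "age", "age_cod", "sex",
             "occp_cod", "reporter_country"),
    "drug": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "drug_seq", "start_dt"),
}

DIALECT_DELIMS = {"dollar": "$", "csv": ","}

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "DS", "CA", "HO", "RI", "OT")

_SEX_MAP = {"M": "male", "F": "female"}
_REPORTER_MAP = {
    "CN": "consumer",
    "LW": "lawyer",
    "HP": "other health-professional",
    "PH": "pharmacist",
    "MD": "physician",
}
# Multipliers converting FAERS age units to years.
_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
    # Blank unit with a numeric age is treated as years (the de-facto FAERS
    # convention for legacy rows).
    "": 1.0,
}


def strip_ids(series: pd.Series) -> pd.Series:
    """Identifier column → stripped python strings (object dtype)."""
    arr = series.to_numpy(dtype=object)
    return pd.Series([str(v).strip() for v in arr], index=series.index,
                     dtype=object)


def norm_categories(series: pd.Series, upper: bool = True) -> pd.Series:
    """Strip/uppercase a low-cardinality string column via its factorized
    uniques (orders of magnitude cheaper than per-element ``.str`` chains)."""
    codes, uniques = pd.factorize(series, use_na_sentinel=False)
    normed = np.empty(len(uniques), dtype=object)
    for i, u in enumerate(uniques):
        s = "" if u is None or (isinstance(u, float) and np.isnan(u)) \
            or u is pd.NA else str(u).strip()
        normed[i] = s.upper() if upper else s
    return pd.Series(normed[codes], index=series.index)


@dataclass(frozen=True)
class CalendarDate:
    """A possibly partial Gregorian date.

    FAERS encodes dates as 8-digit (YYYYMMDD), 6-digit (YYYYMM) or 4-digit
    (YYYY) strings; ``precision`` records which of the three was present.
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day without month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def toordinal(self) -> int:
        """Proleptic-Gregorian ordinal; only defined at day precision."""
        import datetime

        if self.precision != "day":
            raise ValueError("ordinal undefined for partial dates")
        return datetime.date(self.year, self.month, self.day).toordinal()

    def to_faers(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


@dataclass(frozen=True)
class ReportCase:
    """One safety report (a single version of a case)."""

    primaryid: str
    caseid: str
    age_years: float | None
    sex: str
    reporter: str
    country: str | None
    continent: str
    event_date: CalendarDate | None
    year: int | None


@dataclass(frozen=True)
class DrugEntry:
    primaryid: str
    seq: str
    verbatim_name: str
    ingredient: str | None
    role: str


@dataclass(frozen=True)
class ReactionEntry:
    primaryid: str
    pt_code: int | None
    pt_name: str


@dataclass(frozen=True)
class OutcomeEntry:
    primaryid: str
    code: str


@dataclass(frozen=True)
class TherapyEntry:
    primaryid: str
    drug_seq: str
    start_date: CalendarDate | None


@dataclass
class TableSet:
    """The five raw FAERS tables for one extract, as string DataFrames."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    source_quarter: str = ""

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLES}

    def orphan_counts(self) -> dict[str, int]:
        """Child rows whose primaryid is absent from DEMO (kept, not dropped)."""
        known = set(self.demo["primaryid"])
        return {
            name: int((~self.table(name)["primaryid"].isin(known)).sum())
            for name in TABLES[1:]
        }

    def diagnostics(self) -> str:
        lines = [f"table set{' ' + self.source_quarter if self.source_quarter else ''}:"]
        orphans = self.orphan_counts()
        for name, n in self.row_counts().items():
            extra = f", orphans={orphans[name]}" if name in orphans else ""
            lines.append(f"  {name}: rows={n}{extra}")
        return "\n".join(lines)


def _empty_frame(table: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=str) for c in REQUIRED_COLUMNS[table]})


def empty_table_set(source_quarter: str = "") -> TableSet:
    return TableSet(*[_empty_frame(t) for t in TABLES], source_quarter=source_quarter)


def _read_delimited(path: Path, table: str, delim: str,
                    column_map: Mapping[str, str] | None) -> pd.DataFrame:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{table}: {path} is empty (no header row)")
        header = [h.strip() for h in header]
        if column_map:
            header = [column_map.get(h, h) for h in header]
        ncol = len(header)
        rows: list[list[str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != ncol:
                raise FormatError(
                    f"{table}: line {lineno} of {path} has {len(row)} fields, "
                    f"expected {ncol}"
                )
            rows.append(row)
    missing = [c for c in REQUIRED_COLUMNS[table] if c not in header]
    if missing:
        raise FormatError(f"{table}: missing mandatory column(s) {missing} in {path}")
    frame = pd.DataFrame(rows, columns=header, dtype=str) if rows else \
        pd.DataFrame({c: pd.Series(dtype=str) for c in header})
    return frame


def read_table_set(paths: Mapping[str, str | Path], dialect: str = "dollar",
                   column_map: Mapping[str, str] | None = None,
                   source_quarter: str = "") -> TableSet:
    """Read the five tables named in ``paths`` (keys demo/drug/reac/outc/ther).

    Raises :class:`FormatError` for a missing mandatory column or a row whose
    field count disagrees with the header (reported with its line number).
    ``column_map`` renames raw header names to the FAERS conventions above.
    """
    if dialect not in DIALECT_DELIMS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of "
                          f"{sorted(DIALECT_DELIMS)}")
    delim = DIALECT_DELIMS[dialect]
    frames = {}
    for table in TABLES:
        if table not in paths:
            raise FormatError(f"no path given for table {table!r}")
        frames[table] = _read_delimited(Path(paths[table]), table, delim, column_map)
    return TableSet(**frames, source_quarter=source_quarter)


def read_table_dir(directory: str | Path, dialect: str = "dollar",
                   **kwargs) -> TableSet:
    """Read ``<dir>/{demo,drug,reac,outc,ther}.txt`` (the layout ``write_table_set``
    produces)."""
    directory = Path(directory)
    paths = {t: directory / f"{t}.txt" for t in TABLES}
    return read_table_set(paths, dialect=dialect, **kwargs)


def write_table_set(ts: TableSet, directory: str | Path,
                    dialect: str = "dollar") -> dict[str, Path]:
    """Write the five tables to ``<dir>/<table>.txt``; round-trips with
    :func:`read_table_set` field-for-field (delimiter characters inside fields
    are quoted)."""
    if dialect not in DIALECT_DELIMS:
        raise FormatError(f"unknown dialect {dialect!r}")
    delim = DIALECT_DELIMS[dialect]
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for table in TABLES:
        frame = ts.table(table)
        path = directory / f"{table}.txt"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=delim, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(list(frame.columns))
            for row in frame.itertuples(index=False):
                writer.writerow(["" if v is None or (isinstance(v, float) and np.isnan(v))
                                 else str(v) for v in row])
        out[table] = path
    return out


# ---------------------------------------------------------------------------
# dates


def parse_faers_date(raw: str | None) -> CalendarDate | None:
    """Parse one FAERS date string; blank → ``None``.

    8 digits give day precision, 6 month, 4 year.  Anything else — wrong
    length, non-digits, month 13, day 40 — raises :class:`InvalidDateError`;
    callers choose between dropping and failing.
    """
    import datetime

    if raw is None:
        return None
    s = str(raw).strip()
    if not s:
        return None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        raise InvalidDateError(f"malformed date string {raw!r}")
    year = int(s[:4])
    if len(s) == 4:
        return CalendarDate(year)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        raise InvalidDateError(f"impossible month in {raw!r}")
    if len(s) == 6:
        return CalendarDate(year, month)
    day = int(s[6:8])
    try:
        datetime.date(year, month, day)
    except ValueError:
        raise InvalidDateError(f"impossible day in {raw!r}") from None
    return CalendarDate(year, month, day)


def parse_date_column(series: pd.Series) -> pd.DataFrame:
    """Vectorised :func:`parse_faers_date` over a string column.

    Returns a frame with columns ``year``/``month``/``day`` (nullable Int64),
    ``ordinal`` (float; NaN unless day precision), ``precision`` ("day",
    "month", "year" or "" for blank) and boolean ``invalid``.
    """
    vals = series.to_numpy(dtype=object)
    raw = np.empty(len(vals), dtype=object)
    for i, v in enumerate(vals):
        raw[i] = "" if v is None or v is pd.NA \
            or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
    n = len(raw)
    year = np.full(n, np.nan)
    month = np.full(n, np.nan)
    day = np.full(n, np.nan)
    ordinal = np.full(n, np.nan)
    precision = np.full(n, "", dtype=object)
    invalid = np.zeros(n, dtype=bool)
    if n:
        blank = np.fromiter((v == "" for v in raw), dtype=bool, count=n)
        digits = np.fromiter((v.isdigit() for v in raw), dtype=bool, count=n)
        length = np.fromiter((len(v) for v in raw), dtype=int, count=n)

        is8 = digits & (length == 8)
        if is8.any():
            dt = pd.to_datetime(pd.Series(raw[is8]), format="%Y%m%d",
                                errors="coerce")
            ok = dt.notna().to_numpy()
            pos = np.flatnonzero(is8)
            good = pos[ok]
            year[good] = dt.dt.year.to_numpy()[ok]
            month[good] = dt.dt.month.to_numpy()[ok]
            day[good] = dt.dt.day.to_numpy()[ok]
            # 719163 = proleptic ordinal of 1970-01-01, the pandas epoch
            ordinal[good] = dt.dropna().to_numpy().astype(
                "datetime64[D]").astype(np.int64) + 719163
            precision[good] = "day"
            invalid[pos[~ok]] = True

        is6 = digits & (length == 6)
        if is6.any():
            pos = np.flatnonzero(is6)
            yy = np.array([int(v[:4]) for v in raw[is6]])
            mm = np.array([int(v[4:6]) for v in raw[is6]])
            ok = (mm >= 1) & (mm <= 12)
            year[pos[ok]] = yy[ok]
            month[pos[ok]] = mm[ok]
            precision[pos[ok]] = "month"
            invalid[pos[~ok]] = True

        is4 = digits & (length == 4)
        if is4.any():
            pos = np.flatnonzero(is4)
            year[pos] = [int(v) for v in raw[is4]]
            precision[pos] = "year"

        invalid |= ~(blank | is8 | is6 | is4)
        year[invalid] = np.nan
        month[invalid] = np.nan
        day[invalid] = np.nan
        ordinal[invalid] = np.nan
        precision[invalid] = ""
    out = pd.DataFrame({
        "year": pd.array(year, dtype="Int64"),
        "month": pd.array(month, dtype="Int64"),
        "day": pd.array(day, dtype="Int64"),
        "ordinal": ordinal,
        "precision": precision,
        "invalid": invalid,
    }, index=series.index)
    return out


# ---------------------------------------------------------------------------
# DEMO parsing

_CONTINENTS = ("Africa", "Asia", "Europe", "North America", "Oceania",
               "South America")


def _load_continent_map() -> dict[str, str]:
    import importlib.resources as res

    path = res.files("aadsignal.data") / "country_continent.csv"
    frame = pd.read_csv(io.StringIO(path.read_text()), dtype=str)
    return dict(zip(frame["country"].str.upper(), frame["continent"]))


_continent_map_cache: dict[str, str] | None = None


def continent_of(country: str | None) -> str:
    """ISO-3166 alpha-2 code → continent name, "unknown" if unmapped."""
    global _continent_map_cache
    if _continent_map_cache is None:
        _continent_map_cache = _load_continent_map()
    if not country:
        return "unknown"
    return _continent_map_cache.get(str(country).strip().upper(), "unknown")


def parse_demo(demo: pd.DataFrame, invalid_dates: str = "drop"
               ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Convert a raw DEMO frame to typed per-report columns.

    Output columns: primaryid, caseid (str); age_years (float, NaN missing);
    sex, reporter, continent (str); country (str, "" missing); event_y/m/d
    (Int64), event_ordinal (float), event_precision (str); year (Int64,
    reporting year — ``rept_dt`` when present, else the event year).

    ``invalid_dates="drop"`` blanks unparseable event dates and counts them in
    the returned diagnostics; ``"strict"`` raises :class:`InvalidDateError`.
    """
    if invalid_dates not in ("drop", "strict"):
        raise ValueError("invalid_dates must be 'drop' or 'strict'")
    d = demo
    out = pd.DataFrame(index=d.index)
    out["primaryid"] = strip_ids(d["primaryid"])
    out["caseid"] = strip_ids(d["caseid"])

    age_raw = pd.to_numeric(d["age"], errors="coerce")
    unit = norm_categories(d["age_cod"])
    mult = unit.map(_AGE_UNIT_TO_YEARS)
    age_years = age_raw * pd.to_numeric(mult, errors="coerce")
    age_years[age_years < 0] = np.nan
    out["age_years"] = age_years.astype(float)

    sex = norm_categories(d["sex"])
    out["sex"] = sex.map(_SEX_MAP).fillna("unknown")
    occ = norm_categories(d["occp_cod"])
    out["reporter"] = occ.map(_REPORTER_MAP).fillna("unknown")

    country = norm_categories(d["reporter_country"])
    out["country"] = country.astype(str)
    cmap = _load_continent_map() if _continent_map_cache is None else _continent_map_cache
    out["continent"] = country.map(cmap).fillna("unknown").astype(str)

    ev = parse_date_column(d["event_dt"])
    n_invalid = int(ev["invalid"].sum())
    if n_invalid and invalid_dates == "strict":
        bad = d["event_dt"][ev["invalid"]].iloc[0]
        raise InvalidDateError(f"invalid event_dt {bad!r} in DEMO")
    out["event_y"] = ev["year"]
    out["event_m"] = ev["month"]
    out["event_d"] = ev["day"]
    out["event_ordinal"] = ev["ordinal"]
    out["event_precision"] = ev["precision"]

    if "rept_dt" in d.columns:
        # only the year of the receipt date is used; avoid a full date parse
        rp_raw = d["rept_dt"].to_numpy(dtype=object)
        rp_year = pd.array([
            int(str(v)[:4]) if v is not None and str(v)[:4].isdigit()
            and len(str(v).strip()) >= 4 else None
            for v in rp_raw], dtype="Int64")
        year = pd.Series(rp_year, index=d.index).where(
            pd.Series(rp_year, index=d.index).notna(), ev["year"])
    else:
        year = ev["year"]
    out["year"] = year.astype("Int64")
    return out.reset_index(drop=True), {"invalid_event_dates": n_invalid}


def report_cases(parsed_demo: pd.DataFrame) -> list[ReportCase]:
    """Materialise :class:`ReportCase` records from a :func:`parse_demo` frame."""
    cases = []
    for row in parsed_demo.itertuples(index=False):
        if row.event_precision == "day":
            ev = CalendarDate(int(row.event_y), int(row.event_m), int(row.event_d))
        elif row.event_precision == "month":
            ev = CalendarDate(int(row.event_y), int(row.event_m))
        elif row.event_precision == "year":
            ev = CalendarDate(int(row.event_y))
        else:
            ev = None
        cases.append(ReportCase(
            primaryid=row.primaryid, caseid=row.caseid,
            age_years=None if pd.isna(row.age_years) else float(row.age_years),
            sex=row.sex, reporter=row.reporter,
            country=row.country or None, continent=row.continent,
            event_date=ev,
            year=None if pd.isna(row.year) else int(row.year),
        ))
    return cases


def age_group(age_years: float | None) -> str:
    """Bin an age in years into the reporting groups <18 / 18-64 / >=65."""
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    return ">=65"
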