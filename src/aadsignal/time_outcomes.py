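"""Time-to-onset and outcome-severity summaries for flagged AAD reports.

Time to onset is the number of days from the primary-suspect antibiotic's
therapy start date to the adverse-event date; it is only defined when both
dates carry full day precision, and negative differences (event before
therapy) are excluded with a count.  Onset is computed per drug-report pair,
which is what per-drug medians need.

Outcomes use the FAERS codes and the severity grades of oncology-style
adverse-event grading: DE death (5); LT life-threatening, DS disability, CA
congenital anomaly (4, "severe"); HO hospitalization (3, "moderate"); RI
required intervention (2) and OT other serious (1, "mild").  The severe
proportion divides grade-4/5 events by all outcome events.  The mortality
rate is death events over outcome events by default, with a per-report
denominator available — the two conventions coexist in the pharmacovigilance
literature, so both are exposed rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaning import CleanDataset, DrugDictionary
from .errors import ConfigurationError, NoDataError
from .faers_io import CalendarDate, norm_categories, parse_date_column, strip_ids

ONSET_BIN_LABELS = ("<1 week", "1-4 weeks", "4-8 weeks", "8-12 weeks", ">12 weeks")
#: Half-open day boundaries [0,7), [7,28), [28,56), [56,84), [84, inf)
ONSET_BIN_EDGES = (0, 7, 28, 56, 84)

OUTCOME_GRADES = {"DE": 5, "LT": 4, "DS": 4, "CA": 4, "HO": 3, "RI": 2, "OT": 1}
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "HO": "Hospitalization-Initial or Prolonged",
    "RI": "Required Intervention to Prevent Permanent Impairment",
    "OT": "Other Serious (Important Medical Event)",
}


def compute_onset(start: CalendarDate | None,
                  event: CalendarDate | None) -> int | None:
    """Days from therapy start to event; ``None`` unless both dates have day
    precision and the difference is non-negative."""
    if start is None or event is None:
        return None
    if start.precision != "day" or event.precision != "day":
        return None
    delta = event.toordinal() - start.toordinal()
    return delta if delta >= 0 else None


def bin_onset(days: int) -> str:
    """Bin label for a non-negative onset in days."""
    if days < 0:
        raise ValueError("onset days must be non-negative")
    for label, lo, hi in zip(ONSET_BIN_LABELS, ONSET_BIN_EDGES,
                             ONSET_BIN_EDGES[1:] + (None,)):
        if hi is None or days < hi:
            return label
    raise AssertionError("unreachable")


def onset_quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise NoDataError("no onset values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def grade_outcome(code: str) -> int:
    """Severity grade 1-5 for one FAERS outcome code."""
    key = str(code).strip().upper()
    if key not in OUTCOME_GRADES:
        _raise_invalid_code(code)
    return OUTCOME_GRADES[key]


def _raise_invalid_code(code):
    raise ConfigurationError(f"unknown outcome code {code!r}")


# ---------------------------------------------------------------------------
# dataset-level summaries


@dataclass
class OnsetSummary:
    """Binned onset counts plus per-drug quartiles (days)."""

    bin_counts: dict[str, int]
    total: int
    excluded_negative: int
    per_drug: pd.DataFrame  # ingredient, n, median, q1, q3

    def bin_percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.bin_counts}
        return {k: 100.0 * v / self.total for k, v in self.bin_counts.items()}


def onset_records(clean: CleanDataset, flagged: set[str]) -> tuple[pd.DataFrame, int]:
    """One onset per (flagged report, PS ingredient with a therapy record).

    Uses the earliest day-precision therapy start for the drug within the
    report; reports whose PS drug has no therapy record, or whose dates are
    partial, produce no record.  Returns (records frame with columns
    primaryid/ingredient/onset_days, negative-onset exclusion count).
    """
    cols = ["primaryid", "ingredient", "onset_days"]
    if clean.drugs.empty or clean.therapies.empty:
        return pd.DataFrame(columns=cols), 0
    flagged = {str(p) for p in flagged}
    role = norm_categories(clean.drugs["role_cod"])
    pid = strip_ids(clean.drugs["primaryid"])
    ps = clean.drugs.loc[
        ((role == "PS") & pid.isin(flagged)).to_numpy()
        & clean.drugs["ingredient"].notnull().to_numpy(),
        ["drug_seq", "ingredient"]].copy()
    if ps.empty:
        return pd.DataFrame(columns=cols), 0
    ps["primaryid"] = pid[ps.index]
    ps["drug_seq"] = strip_ids(ps["drug_seq"])

    ther = clean.therapies.copy()
    ther["primaryid"] = strip_ids(ther["primaryid"])
    ther = ther[ther["primaryid"].isin(flagged).to_numpy()]
    start = parse_date_column(ther["start_dt"])
    ther["start_ordinal"] = start["ordinal"].to_numpy()
    ther = ther[(start["precision"] == "day").to_numpy()]
    ther["drug_seq"] = strip_ids(ther["drug_seq"])
    # earliest start per drug-report pair ("beginning of antibiotic use")
    ther = (ther.groupby(["primaryid", "drug_seq"], sort=False, as_index=False)
            ["start_ordinal"].min())

    merged = ps.merge(ther, on=["primaryid", "drug_seq"], how="inner")
    if merged.empty:
        return pd.DataFrame(columns=cols), 0

    ev = clean.reports[["primaryid", "event_ordinal", "event_precision"]].copy()
    ev = ev[ev["event_precision"] == "day"]
    merged = merged.merge(ev[["primaryid", "event_ordinal"]], on="primaryid",
                          how="inner")
    if merged.empty:
        return pd.DataFrame(columns=cols), 0
    merged["onset_days"] = (merged["event_ordinal"] - merged["start_ordinal"]).astype(int)
    neg = int((merged["onset_days"] < 0).sum())
    merged = merged[merged["onset_days"] >= 0]
    # one record per report x ingredient (a drug listed twice keeps the earliest start)
    merged = (merged.groupby(["primaryid", "ingredient"], sort=False, as_index=False)
              ["onset_days"].min())
    return merged[cols].reset_index(drop=True), neg


def summarize_onsets(records: pd.DataFrame, excluded_negative: int = 0,
                     min_per_drug: int = 1) -> OnsetSummary:
    """Bin all onsets and compute per-drug quartiles.

    ``min_per_drug`` drops drugs with fewer onset records from the per-drug
    table (the binned totals always include every record)."""
    counts = {label: 0 for label in ONSET_BIN_LABELS}
    days = records["onset_days"].to_numpy(dtype=int) if len(records) else \
        np.empty(0, dtype=int)
    edges = list(ONSET_BIN_EDGES[1:]) + [np.inf]
    idx = np.searchsorted(np.asarray(edges), days, side="right")
    for i, label in enumerate(ONSET_BIN_LABELS):
        counts[label] = int((idx == i).sum())
    rows = []
    if len(records):
        for ing, grp in records.groupby("ingredient", sort=True):
            if len(grp) < min_per_drug:
                continue
            q1, med, q3 = onset_quartiles(grp["onset_days"])
            rows.append({"ingredient": ing, "n": len(grp),
                         "median": med, "q1": q1, "q3": q3})
    per_drug = pd.DataFrame(rows, columns=["ingredient", "n", "median", "q1", "q3"])
    return OnsetSummary(bin_counts=counts, total=int(len(records)),
                        excluded_negative=excluded_negative, per_drug=per_drug)


def format_median_iqr(median: float, q1: float, q3: float) -> str:
    """Publication-style "median (Q1-Q3)" with trailing .0 trimmed."""

    def fmt(x: float) -> str:
        return f"{x:g}"

    return f"{fmt(median)} ({fmt(q1)}-{fmt(q3)})"


@dataclass
class OutcomeSummary:
    """Per-category outcome-event counts with severity-derived rates."""

    counts: dict[str, int]  # keyed by outcome code
    n_events: int
    n_reports: int
    severe_proportion: float
    mortality_rate: float
    denominator_mode: str


def summarize_outcomes(outcomes: pd.DataFrame,
                       denominator_mode: str = "outcome_events") -> OutcomeSummary:
    """Tally outcome events (a report may contribute several) and derive the
    severe proportion and mortality rate.

    ``denominator_mode="outcome_events"`` divides deaths by all outcome
    events; ``"reports"`` divides by distinct reports with any outcome event.
    """
    if denominator_mode not in ("outcome_events", "reports"):
        raise ValueError("denominator_mode must be 'outcome_events' or 'reports'")
    if outcomes.empty:
        raise NoDataError("no outcome events")
    codes = norm_categories(outcomes["outc_cod"])
    bad = sorted(set(codes) - set(OUTCOME_GRADES))
    if bad:
        _raise_invalid_code(bad[0])
    counts = {code: int((codes == code).sum()) for code in OUTCOME_GRADES}
    n_events = int(len(outcomes))
    n_reports = int(strip_ids(outcomes["primaryid"]).nunique())
    severe = sum(n for code, n in counts.items() if OUTCOME_GRADES[code] >= 4)
    deaths = counts["DE"]
    denom = n_events if denominator_mode == "outcome_events" else n_reports
    return OutcomeSummary(
        counts=counts, n_events=n_events, n_reports=n_reports,
        severe_proportion=severe / n_events,
        mortality_rate=deaths / denom,
        denominator_mode=denominator_mode,
    )


def mortality_by_target(clean: CleanDataset, flagged: set[str],
                        exposures: dict[str, set[str]],
                        dictionary: DrugDictionary,
                        level: str = "drug",
                        denominator_mode: str = "outcome_events") -> pd.DataFrame:
    """Death rate among flagged reports exposed to each target drug/class.

    Columns: target, level, n_reports, n_events, deaths, mortality_rate.
    """
    flagged = {str(p) for p in flagged}
    outc = clean.outcomes.copy()
    outc["primaryid"] = strip_ids(outc["primaryid"])
    outc = outc[outc["primaryid"].isin(flagged).to_numpy()]
    codes = norm_categories(outc["outc_cod"])

    def targets_of(ings: set[str]) -> set[str]:
        if level == "drug":
            return ings
        return {c for c in (dictionary.class_of(i) for i in ings) if c}

    rows = []
    all_targets = sorted({t for pid in flagged
                          for t in targets_of(exposures.get(pid, set()))})
    pid_targets = {pid: targets_of(exposures.get(pid, set())) for pid in flagged}
    for target in all_targets:
        pids = {pid for pid, ts in pid_targets.items() if target in ts}
        sub = outc["primaryid"].isin(pids)
        n_events = int(sub.sum())
        deaths = int((sub & (codes == "DE")).sum())
        n_reports = int(outc.loc[sub, "primaryid"].nunique())
        denom = n_events if denominator_mode == "outcome_events" else n_reports
        rows.append({
            "target": target, "level": level, "n_reports": n_reports,
            "n_events": n_events, "deaths": deaths,
            "mortality_rate": deaths / denom if denom else float("nan"),
        })
    return pd.DataFrame(rows, columns=["target", "level", "n_reports",
                                       "n_events", "deaths", "mortality_rate"])
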