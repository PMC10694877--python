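"""End-to-end pipeline orchestration and publication-shaped output tables.

``run_pipeline`` wires the stages together — read → clean → flag AAD cases →
drug- and class-level ROR signals → onset → outcomes → demographics — and
writes one TSV per summary table plus an attrition log.  Every percentage
column in the emitted tables is recomputed from its count column with
half-up rounding at two decimals, and no file embeds a timestamp, so reruns
on identical input are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .case_definition import CaseDefinition, flag_aad_reports
from .cleaning import CleanDataset, DrugDictionary, clean_table_set, \
    primary_suspect_exposures
from .errors import ConfigurationError
from .faers_io import TableSet, age_group, read_table_dir, read_table_set
from .signal_stats import SignalResult, signal_table
from .time_outcomes import ONSET_BIN_LABELS, OUTCOME_GRADES, OUTCOME_LABELS, \
    OnsetSummary, OutcomeSummary, mortality_by_target, onset_records, \
    summarize_onsets, summarize_outcomes

log = logging.getLogger("aadsignal")

OUTPUT_FILES = (
    "table3_demographics.tsv", "table4_onset_bins.tsv",
    "tableS1_onset_quartiles.tsv", "table5_outcomes.tsv",
    "fig2_signals_drug.tsv", "fig2_signals_class.tsv",
    "fig3_mortality.tsv", "attrition.log",
)


def format_percent(count: int, denom: int) -> str:
    """``count/denom`` as a percentage string, half-up at two decimals."""
    if denom == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    pct = Decimal(int(count)) / Decimal(int(denom)) * 100
    return f"{pct.quantize(Decimal('0.01'), rounding=ROUND_HALF_UP)}%"


def round2(x: float) -> float:
    """Half-up rounding to two decimals for reported point estimates."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


class PipelineConfig(BaseModel):
    """Everything one pipeline run needs; see ``docs/methods.md`` for the
    flat key=value config-file schema (schema_version 1)."""

    input_dir: Optional[Path] = None
    table_paths: Optional[dict[str, Path]] = None
    dialect: str = "dollar"
    drug_names_csv: Optional[Path] = None
    drug_classes_csv: Optional[Path] = None
    case_definition_csv: Optional[Path] = None
    match_mode: str = "either"
    year_min: Optional[int] = None
    year_max: Optional[int] = None
    dedup: bool = True
    invalid_dates: str = "drop"
    denominator_mode: str = "outcome_events"
    min_onset_per_drug: int = 1
    out_dir: Path = Path("aadsignal_out")
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self):
        if self.input_dir is None and self.table_paths is None:
            raise ValueError("either input_dir or table_paths is required")
        if self.year_min is not None and self.year_max is not None \
                and self.year_min > self.year_max:
            raise ValueError("year bounds out of order")
        if self.denominator_mode not in ("outcome_events", "reports"):
            raise ValueError("denominator_mode must be outcome_events or reports")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config (# comments allowed)."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key = value")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        values.pop("schema_version", None)
        for flag in ("dedup",):
            if flag in values:
                values[flag] = values[flag].lower() in ("1", "true", "yes", "on")
        try:
            return cls(**values)
        except Exception as exc:  # pydantic ValidationError or ours
            raise ConfigurationError(f"{path}: {exc}") from exc


def load_inputs(cfg: PipelineConfig) -> tuple[TableSet, DrugDictionary,
                                              CaseDefinition]:
    if cfg.table_paths is not None:
        ts = read_table_set(cfg.table_paths, dialect=cfg.dialect)
    else:
        ts = read_table_dir(cfg.input_dir, dialect=cfg.dialect)
    if cfg.drug_classes_csv is not None:
        dictionary = DrugDictionary.from_files(cfg.drug_names_csv,
                                               cfg.drug_classes_csv)
    else:
        dictionary = DrugDictionary.default()
    if cfg.case_definition_csv is not None:
        cd = CaseDefinition.from_csv(cfg.case_definition_csv, cfg.match_mode)
    else:
        cd = CaseDefinition.default(cfg.match_mode)
    return ts, dictionary, cd


@dataclass
class PipelineResult:
    """In-memory results of one run (what the TSV files serialize)."""

    clean: CleanDataset
    flagged: set[str]
    exposures: dict[str, set[str]]
    signals_drug: list[SignalResult]
    signals_class: list[SignalResult]
    onset: OnsetSummary
    outcomes: Optional[OutcomeSummary]
    demographics: pd.DataFrame
    mortality: pd.DataFrame


def analyze_tables(ts: TableSet, dictionary: DrugDictionary,
                   cd: CaseDefinition,
                   year_range: tuple[int | None, int | None] = (None, None),
                   dedup: bool = True, invalid_dates: str = "drop",
                   denominator_mode: str = "outcome_events",
                   min_onset_per_drug: int = 1) -> PipelineResult:
    """The full analysis on in-memory tables (no file output)."""
    clean = clean_table_set(ts, dictionary, invalid_dates=invalid_dates,
                            year_range=year_range, dedup=dedup)
    flagged = flag_aad_reports(clean.reactions, cd)
    exposures = primary_suspect_exposures(clean.drugs)
    ids = clean.reports["primaryid"].tolist()
    signals_drug = signal_table(ids, flagged, exposures, dictionary, "drug")
    signals_class = signal_table(ids, flagged, exposures, dictionary, "class")
    records, neg = onset_records(clean, flagged)
    onset = summarize_onsets(records, excluded_negative=neg,
                             min_per_drug=min_onset_per_drug)
    outc = clean.outcomes.copy()
    outc["primaryid"] = outc["primaryid"].astype(str).str.strip()
    outc = outc[outc["primaryid"].isin(flagged)]
    outcomes = summarize_outcomes(outc, denominator_mode) if len(outc) else None
    demo = summarize_demographics(clean.reports, flagged)
    mort_drug = mortality_by_target(clean, flagged, exposures, dictionary,
                                    "drug", denominator_mode)
    mort_class = mortality_by_target(clean, flagged, exposures, dictionary,
                                     "class", denominator_mode)
    mortality = pd.concat([mort_drug, mort_class], ignore_index=True)
    return PipelineResult(clean=clean, flagged=flagged, exposures=exposures,
                          signals_drug=signals_drug,
                          signals_class=signals_class, onset=onset,
                          outcomes=outcomes, demographics=demo,
                          mortality=mortality)


def summarize_demographics(reports: pd.DataFrame,
                           flagged: set[str] | None = None) -> pd.DataFrame:
    """Counts and percentages of the flagged reports by age group, sex,
    reporter, continent and year (unknowns are categories, not exclusions).

    Columns: characteristic, category, count, percent.
    """
    if flagged is not None:
        pid = reports["primaryid"].astype(str).str.strip()
        reports = reports[pid.isin({str(p) for p in flagged})]
    total = len(reports)
    rows: list[dict] = []

    def add(characteristic: str, series: pd.Series, order=None) -> None:
        counts = series.value_counts()
        cats = order if order is not None else sorted(counts.index)
        for cat in cats:
            cnt = int(counts.get(cat, 0))
            rows.append({
                "characteristic": characteristic, "category": cat,
                "count": cnt,
                "percent": format_percent(cnt, total) if total else "",
            })

    if total:
        add("age_group", reports["age_years"].map(age_group),
            ["<18", "18-64", ">=65", "unknown"])
        add("sex", reports["sex"], ["male", "female", "unknown"])
        add("reporter", reports["reporter"],
            ["consumer", "lawyer", "other health-professional", "pharmacist",
             "physician", "unknown"])
        add("continent", reports["continent"],
            ["Africa", "Asia", "Europe", "North America", "Oceania",
             "South America", "unknown"])
        years = reports["year"].dropna().astype(int)
        add("year", years, sorted(years.unique()))
    else:
        log.warning("demographics: no flagged reports")
    return pd.DataFrame(rows, columns=["characteristic", "category", "count",
                                       "percent"])


# ---------------------------------------------------------------------------
# serialization


def _signals_frame(results: list[SignalResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "target": r.target, "level": r.level, "a": r.a,
            "ror": round2(r.ror) if r.computable else "",
            "ci_lower": round2(r.ci_lower) if r.computable else "",
            "ci_upper": round2(r.ci_upper) if r.computable else "",
            "is_signal": str(bool(r.is_signal)).lower(),
        })
    return pd.DataFrame(rows, columns=["target", "level", "a", "ror",
                                       "ci_lower", "ci_upper", "is_signal"])


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Serialize every summary table; returns the file map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    emit("table3_demographics.tsv", result.demographics)

    onset = result.onset
    emit("table4_onset_bins.tsv", pd.DataFrame({
        "bin": list(ONSET_BIN_LABELS),
        "count": [onset.bin_counts[b] for b in ONSET_BIN_LABELS],
        "percent": [format_percent(onset.bin_counts[b], onset.total)
                    if onset.total else "" for b in ONSET_BIN_LABELS],
    }))
    pd_frame = onset.per_drug.copy()
    emit("tableS1_onset_quartiles.tsv", pd_frame)

    if result.outcomes is not None:
        oc = result.outcomes
        emit("table5_outcomes.tsv", pd.DataFrame({
            "category": [OUTCOME_LABELS[c] for c in OUTCOME_GRADES],
            "code": list(OUTCOME_GRADES),
            "grade": [OUTCOME_GRADES[c] for c in OUTCOME_GRADES],
            "count": [oc.counts[c] for c in OUTCOME_GRADES],
            "percent": [format_percent(oc.counts[c], oc.n_events)
                        for c in OUTCOME_GRADES],
        }))
    else:
        emit("table5_outcomes.tsv", pd.DataFrame(
            columns=["category", "code", "grade", "count", "percent"]))

    only_computable_drug = [r for r in result.signals_drug if r.computable]
    only_computable_class = [r for r in result.signals_class if r.computable]
    skipped = (len(result.signals_drug) - len(only_computable_drug)
               + len(result.signals_class) - len(only_computable_class))
    if skipped:
        log.warning("%d target(s) had a zero cell; excluded from ranked output",
                    skipped)
    emit("fig2_signals_drug.tsv", _signals_frame(only_computable_drug))
    emit("fig2_signals_class.tsv", _signals_frame(only_computable_class))

    mort = result.mortality.copy()
    if len(mort):
        mort["mortality_percent"] = [
            f"{round2(100 * r)}%" if pd.notna(r) else ""
            for r in mort["mortality_rate"]
        ]
        mort = mort.drop(columns=["mortality_rate"])
    else:
        mort = pd.DataFrame(columns=["target", "level", "n_reports",
                                     "n_events", "deaths", "mortality_percent"])
    emit("fig3_mortality.tsv", mort)

    attr_path = out_dir / "attrition.log"
    attr_path.write_text(result.clean.attrition_report() + "\n"
                         + f"flagged AAD reports: {len(result.flagged)}\n")
    paths["attrition.log"] = attr_path
    return paths


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Validate, execute every stage and write all outputs.

    Any stage failure removes partial outputs and re-raises with the stage
    name; zero flagged reports is a warning, not an error.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stage = "read"
    out_dir = Path(cfg.out_dir)
    try:
        ts, dictionary, cd = load_inputs(cfg)
        log.info("loaded tables: %s", ts.row_counts())
        stage = "analyze"
        result = analyze_tables(
            ts, dictionary, cd, year_range=(cfg.year_min, cfg.year_max),
            dedup=cfg.dedup, invalid_dates=cfg.invalid_dates,
            denominator_mode=cfg.denominator_mode,
            min_onset_per_drug=cfg.min_onset_per_drug)
        if not result.flagged:
            log.warning("no reports matched the AAD case definition")
        stage = "write"
        return write_outputs(result, out_dir)
    except Exception:
        for name in OUTPUT_FILES:
            path = out_dir / name
            if path.exists():
                path.unlink()
        log.error("pipeline failed during stage %r", stage)
        raise
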