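"""Case deduplication, drug-name normalization and primary-suspect exposure.

Spontaneous reports are revised over time: versions of one case share a
``caseid`` and must be collapsed to the latest version before counting,
otherwise a single patient inflates the contingency table.  Verbatim drug
strings are mapped to ingredient names through a flat dictionary (the flat
stand-in for an RxNorm normalization step), and ingredients to one of the
fourteen antibiotic groups used for class-level disproportionality.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .faers_io import TableSet, norm_categories, parse_demo, strip_ids

#: The antibiotic grouping used at class level.
ANTIBIOTIC_CLASSES = (
    "first/second-generation cephalosporins",
    "third-generation cephalosporins",
    "fourth-generation cephalosporins",
    "novel cephalosporins",
    "penicillins",
    "beta-lactamase inhibitors",
    "carbapenems",
    "lincomycins",
    "fluoroquinolones",
    "erythromycins",
    "aminoglycosides",
    "tetracyclines",
    "other antibiotics",
    "antifungal drugs",
)


def _norm_key(name: str) -> str:
    return " ".join(str(name).upper().split())


@dataclass
class DrugDictionary:
    """Verbatim drug string → ingredient, and ingredient → antibiotic class.

    Lookups are case-insensitive and whitespace-collapsed.  Every ingredient
    that appears in the class map is also accepted as its own verbatim name,
    so extracts that already carry ingredient names resolve without extra
    dictionary rows.
    """

    name_to_ingredient: dict[str, str] = field(default_factory=dict)
    ingredient_to_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.name_to_ingredient = {
            _norm_key(k): v.strip().lower()
            for k, v in self.name_to_ingredient.items()
        }
        self.ingredient_to_class = {
            k.strip().lower(): v.strip()
            for k, v in self.ingredient_to_class.items()
        }
        for ing in self.ingredient_to_class:
            self.name_to_ingredient.setdefault(_norm_key(ing), ing)

    def ingredient_of(self, verbatim: str) -> str | None:
        return self.name_to_ingredient.get(_norm_key(verbatim))

    def class_of(self, ingredient: str | None) -> str | None:
        if ingredient is None:
            return None
        return self.ingredient_to_class.get(str(ingredient).strip().lower())

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.ingredient_to_class.values()))

    @property
    def ingredients(self) -> list[str]:
        return sorted(set(self.ingredient_to_class))

    @classmethod
    def from_files(cls, names_csv: str | Path | None,
                   classes_csv: str | Path) -> "DrugDictionary":
        """Load from a two-column (verbatim,ingredient) and a two-column
        (ingredient,class) UTF-8 CSV."""
        n2i: dict[str, str] = {}
        if names_csv is not None:
            names = pd.read_csv(names_csv, dtype=str)
            _require_cols(names, ("verbatim", "ingredient"), names_csv)
            n2i = dict(zip(names["verbatim"], names["ingredient"]))
        classes = pd.read_csv(classes_csv, dtype=str)
        _require_cols(classes, ("ingredient", "class"), classes_csv)
        dup = classes["ingredient"].str.strip().str.lower().duplicated()
        if dup.any():
            bad = classes["ingredient"][dup].iloc[0]
            raise ConfigurationError(f"ingredient {bad!r} mapped to more than one class")
        i2c = dict(zip(classes["ingredient"], classes["class"]))
        return cls(n2i, i2c)

    @classmethod
    def default(cls) -> "DrugDictionary":
        """The packaged dictionary: every antibiotic named in the source study
        plus common brand/salt synonyms."""
        import importlib.resources as res

        data = res.files("aadsignal.data")
        names = pd.read_csv(io.StringIO((data / "drug_names.csv").read_text()), dtype=str)
        classes = pd.read_csv(io.StringIO((data / "antibiotic_classes.csv").read_text()),
                              dtype=str)
        return cls(dict(zip(names["verbatim"], names["ingredient"])),
                   dict(zip(classes["ingredient"], classes["class"])))


def _require_cols(frame: pd.DataFrame, cols, src) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ConfigurationError(f"{src}: missing column(s) {missing}")


def assign_class(ingredient: str, dictionary: DrugDictionary) -> str | None:
    """Single deterministic class lookup; unknown ingredient → ``None``."""
    return dictionary.class_of(ingredient)


# ---------------------------------------------------------------------------
# deduplication


def deduplicate_cases(parsed_demo: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep one report version per ``caseid``.

    The retained version is the one with the numerically greatest
    ``primaryid`` (FAERS convention: higher version = later submission),
    tie-broken by latest event date, then lexicographically greatest
    ``primaryid``.  Returns (kept frame, number of removed versions).
    """
    if parsed_demo.empty:
        return parsed_demo.copy(), 0
    d = parsed_demo
    case_codes = pd.factorize(d["caseid"], use_na_sentinel=False)[0]
    pid_num = pd.to_numeric(d["primaryid"], errors="coerce"
                            ).fillna(-np.inf).to_numpy()
    ev = d["event_ordinal"].fillna(-np.inf).to_numpy() \
        if "event_ordinal" in d else np.zeros(len(d))
    # lexicographic primaryid rank as the last tie-break
    pid_rank = pd.factorize(d["primaryid"], sort=True)[0]
    order = np.lexsort((pid_rank, ev, pid_num, case_codes))
    sorted_codes = case_codes[order]
    is_last = np.ones(len(order), dtype=bool)
    is_last[:-1] = sorted_codes[1:] != sorted_codes[:-1]
    keep_pos = np.sort(order[is_last])
    kept = d.iloc[keep_pos].copy()
    removed = len(d) - len(kept)
    return kept.reset_index(drop=True), removed


# ---------------------------------------------------------------------------
# drug normalization and exposure


def normalize_drugs(drug: pd.DataFrame, dictionary: DrugDictionary
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Fill an ``ingredient`` column from the dictionary.

    Unmapped verbatim names keep ``ingredient`` missing (they remain in the
    "other drugs" comparator) and are tallied, by frequency, into the returned
    Series for manual review.  Row count is never changed.
    """
    if not dictionary.name_to_ingredient and not dictionary.ingredient_to_class:
        raise ConfigurationError("drug dictionary is empty")
    out = drug.copy()
    codes, uniques = pd.factorize(out["drugname"], use_na_sentinel=False)
    mapped = np.array([
        None if u is None or (isinstance(u, float) and np.isnan(u))
        else dictionary.name_to_ingredient.get(_norm_key(u))
        for u in uniques], dtype=object)
    out["ingredient"] = mapped[codes] if len(out) else \
        np.empty(0, dtype=object)
    unmapped = (
        out.loc[out["ingredient"].isnull(), "drugname"]
        .astype(str).str.strip().value_counts()
    )
    return out, unmapped


def primary_suspect_exposures(drug: pd.DataFrame) -> dict[str, set[str]]:
    """Map primaryid → set of primary-suspect (role PS) ingredients.

    Only PS rows with a mapped ingredient contribute; reports with no mapped
    PS antibiotic are simply absent from the map.
    """
    role = norm_categories(drug["role_cod"])
    ps = drug.loc[(role == "PS").to_numpy() & drug["ingredient"].notnull(),
                  ["primaryid", "ingredient"]]
    out: dict[str, set[str]] = {}
    for pid, ing in zip(strip_ids(ps["primaryid"]), ps["ingredient"]):
        out.setdefault(pid, set()).add(ing)
    return out


# ---------------------------------------------------------------------------
# end-to-end cleaning


@dataclass
class CleanDataset:
    """A deduplicated extract: parsed reports plus child tables restricted to
    the surviving report versions."""

    reports: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    therapies: pd.DataFrame
    attrition: dict[str, int]
    unmapped_drugs: pd.Series

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def attrition_report(self) -> str:
        a = self.attrition
        lines = [
            "attrition:",
            f"  demo rows in: {a['demo_rows_in']}",
            f"  invalid event dates blanked: {a['invalid_event_dates']}",
            f"  duplicate case versions removed: {a['duplicates_removed']}",
            f"  reports kept: {a['reports_kept']}",
        ]
        for t in ("drug", "reac", "outc", "ther"):
            lines.append(f"  {t} rows kept: {a[f'{t}_rows_kept']} "
                         f"(dropped with removed versions: {a[f'{t}_rows_dropped']})")
        return "\n".join(lines)


def clean_table_set(ts: TableSet, dictionary: DrugDictionary,
                    invalid_dates: str = "drop",
                    year_range: tuple[int | None, int | None] = (None, None),
                    dedup: bool = True) -> CleanDataset:
    """Parse DEMO, optionally filter by reporting year, deduplicate case
    versions, restrict child tables to surviving primaryids, and normalize
    drug names."""
    parsed, demo_diag = parse_demo(ts.demo, invalid_dates=invalid_dates)
    attrition = {"demo_rows_in": len(ts.demo),
                 "invalid_event_dates": demo_diag["invalid_event_dates"]}

    lo, hi = year_range
    if lo is not None or hi is not None:
        if lo is not None and hi is not None and lo > hi:
            raise ConfigurationError(f"year bounds out of order: {lo} > {hi}")
        mask = pd.Series(True, index=parsed.index)
        if lo is not None:
            mask &= parsed["year"].notna() & (parsed["year"] >= lo)
        if hi is not None:
            mask &= parsed["year"].notna() & (parsed["year"] <= hi)
        attrition["outside_year_range"] = int((~mask).sum())
        parsed = parsed[mask].reset_index(drop=True)

    if dedup:
        kept, removed = deduplicate_cases(parsed)
    else:
        kept, removed = parsed.reset_index(drop=True), 0
    attrition["duplicates_removed"] = removed
    attrition["reports_kept"] = len(kept)

    keep_ids = set(kept["primaryid"])
    children = {}
    for name, frame in (("drug", ts.drug), ("reac", ts.reac),
                        ("outc", ts.outc), ("ther", ts.ther)):
        pid = strip_ids(frame["primaryid"])
        sub = frame[pid.isin(keep_ids).to_numpy()].reset_index(drop=True)
        children[name] = sub
        attrition[f"{name}_rows_kept"] = len(sub)
        attrition[f"{name}_rows_dropped"] = len(frame) - len(sub)

    drugs, unmapped = normalize_drugs(children["drug"], dictionary)
    return CleanDataset(
        reports=kept, drugs=drugs, reactions=children["reac"],
        outcomes=children["outc"], therapies=children["ther"],
        attrition=attrition, unmapped_drugs=unmapped,
    )
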