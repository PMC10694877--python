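"""FAERS-like spontaneous-report simulator with known ground truth.

The generator emits the five quarterly tables (DEMO/DRUG/REAC/OUTC/THER) for
``n_reports`` synthetic cases and, alongside them, exact per-report
bookkeeping: which antibiotics each case was exposed to (as primary suspect),
whether it is an AAD case, and the onset drawn for the causal drug.  Planted
per-drug odds multipliers make the reporting odds ratio identifiable: an
unexposed report is an AAD case with baseline probability ``p0``, an exposed
one with the probability whose odds are ``theta`` times the baseline odds,

    p1 = theta * p0 / (1 - p0 + theta * p0),

so the population odds ratio of the exposure/case table is exactly ``theta``.
When a report is exposed to several planted drugs the largest theta wins
(negligible at the small exposure probabilities used here).

Realism knobs mirror the failure modes of real spontaneous data: duplicate
case versions sharing a caseid, partial (6- or 4-digit) and missing dates,
antibiotics appearing in non-suspect roles, a pool of comparator drugs absent
from the dictionary, and demographic mixes.  Onset is drawn log-normal per
drug and the event date is therapy start plus onset, so time-to-onset is
recoverable downstream.  What the simulator does not model: correlated
co-prescription, conflicting demographics between versions of a case, or
MedDRA coding noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .case_definition import CaseDefinition
from .cleaning import DrugDictionary
from .errors import ConfigurationError
from .faers_io import TableSet, write_table_set
from .signal_stats import ContingencyTable

_NOISE_PTS = (
    "Nausea", "Headache", "Vomiting", "Rash", "Fatigue",
    "Dizziness", "Pyrexia", "Abdominal pain", "Pruritus", "Insomnia",
)

_EPOCH_OFFSET = 719163  # proleptic ordinal of 1970-01-01


class PlantedDrugSpec(BaseModel):
    """One simulated antibiotic: exposure rate, planted odds multiplier and
    log-normal onset parameters (days)."""

    ingredient: str
    class_name: str = "other antibiotics"
    exposure_prob: float = Field(0.02, gt=0, lt=1)
    theta: float = Field(1.0, gt=0)
    onset_log_mean: float = math.log(6.0)
    onset_log_sd: float = Field(0.9, ge=0)


class Demographics(BaseModel):
    """Categorical mixes; defaults approximate the marginals of published
    AAD case series (≈43% aged 65+, ≈51% female, mostly North America/Europe)."""

    age_group_probs: dict[str, float] = Field(default_factory=lambda: {
        "<18": 0.043, "18-64": 0.346, ">=65": 0.432, "unknown": 0.179})
    sex_probs: dict[str, float] = Field(default_factory=lambda: {
        "M": 0.369, "F": 0.515, "": 0.116})
    reporter_probs: dict[str, float] = Field(default_factory=lambda: {
        "CN": 0.195, "LW": 0.003, "HP": 0.225, "PH": 0.164, "MD": 0.315,
        "": 0.098})
    country_probs: dict[str, float] = Field(default_factory=lambda: {
        "US": 0.42, "CA": 0.05, "GB": 0.08, "DE": 0.08, "FR": 0.07,
        "IT": 0.05, "ES": 0.04, "NL": 0.03, "JP": 0.03, "CN": 0.02,
        "IN": 0.01, "BR": 0.01, "AU": 0.003, "ZA": 0.004, "": 0.103})
    year_probs: dict[int, float] = Field(default_factory=lambda: {
        y: 1.0 / 19.0 for y in range(2004, 2023)})

    @model_validator(mode="after")
    def _check_sums(self):
        for name in ("age_group_probs", "sex_probs", "reporter_probs",
                     "country_probs", "year_probs"):
            probs = list(getattr(self, name).values())
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be non-negative and sum to 1")
        return self


class SyntheticConfig(BaseModel):
    """Full generator configuration; every stochastic element is driven by
    ``seed`` alone, so identical configs produce identical tables."""

    n_reports: int = Field(50_000, gt=0)
    background_aad_prob: float = Field(0.01, gt=0, lt=1)
    drugs: list[PlantedDrugSpec] = Field(default_factory=lambda: [
        PlantedDrugSpec(ingredient="lincomycin", class_name="lincomycins",
                        theta=25.0),
        PlantedDrugSpec(ingredient="ceftriaxone",
                        class_name="third-generation cephalosporins",
                        theta=15.0),
        PlantedDrugSpec(ingredient="amoxicillin", class_name="penicillins",
                        theta=6.5),
        PlantedDrugSpec(ingredient="tobramycin", class_name="aminoglycosides",
                        theta=1.0),
    ])
    comparator_drug_pool: int = Field(200, gt=0)
    demographics: Demographics = Field(default_factory=Demographics)
    outcome_probs: dict[str, float] = Field(default_factory=lambda: {
        "DE": 0.120, "LT": 0.080, "DS": 0.038, "CA": 0.001, "HO": 0.654,
        "RI": 0.021, "OT": 0.086})
    extra_outcome_prob: float = Field(0.25, ge=0, le=1)
    extra_reaction_prob: float = Field(0.30, ge=0, le=1)
    nonsuspect_antibiotic_rate: float = Field(0.01, ge=0, le=1)
    duplicate_rate: float = Field(0.10, ge=0, lt=1)
    partial_date_rate: float = Field(0.05, ge=0, le=1)
    missing_date_rate: float = Field(0.10, ge=0, le=1)
    seed: int = 0

    @field_validator("outcome_probs")
    @classmethod
    def _check_outcomes(cls, v):
        from .faers_io import OUTCOME_CODES

        if set(v) - set(OUTCOME_CODES):
            raise ValueError(f"unknown outcome codes {set(v) - set(OUTCOME_CODES)}")
        if abs(sum(v.values()) - 1.0) > 1e-6 or any(p < 0 for p in v.values()):
            raise ValueError("outcome_probs must be non-negative and sum to 1")
        return v

    @model_validator(mode="after")
    def _check_drugs(self):
        names = [d.ingredient for d in self.drugs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate planted ingredients")
        if self.partial_date_rate + self.missing_date_rate > 1:
            raise ValueError("date degradation rates exceed 1")
        return self


def exposed_aad_prob(theta: float, p0: float) -> float:
    """Exposed-group AAD probability whose odds are ``theta`` times the
    baseline odds of ``p0``."""
    if not 0 < p0 < 1:
        raise ConfigurationError("baseline probability must be strictly inside (0, 1)")
    if theta <= 0:
        raise ConfigurationError("odds multiplier must be positive")
    return theta * p0 / (1 - p0 + theta * p0)


@dataclass
class GroundTruth:
    """Exact bookkeeping emitted with a synthetic table set.

    ``report`` has one row per case (pre-duplicate-injection): caseid,
    primaryid, one boolean exposure column per planted ingredient, ``aad``,
    the causal ingredient (for flagged exposed cases) and its drawn
    ``onset_days``.  ``duplicated_caseids`` lists cases given an extra
    earlier version.
    """

    report: pd.DataFrame
    drugs: list[PlantedDrugSpec]
    duplicated_caseids: list[str]
    config: SyntheticConfig

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicated_caseids)

    def dictionary(self) -> DrugDictionary:
        """A drug dictionary covering exactly the planted ingredients."""
        return DrugDictionary(
            name_to_ingredient={},
            ingredient_to_class={d.ingredient: d.class_name for d in self.drugs},
        )

    def to_frame(self) -> pd.DataFrame:
        return self.report.copy()


def ground_truth_contingency(gt: GroundTruth, target: str,
                             level: str = "drug") -> ContingencyTable:
    """The exact 2x2 cells implied by the generator's bookkeeping (one count
    per case; duplicates do not exist at this level)."""
    rep = gt.report
    if level == "drug":
        col = f"exposed_{target}"
        if col not in rep.columns:
            raise ConfigurationError(f"unknown planted ingredient {target!r}")
        exposed = rep[col].to_numpy(dtype=bool)
    elif level == "class":
        members = [d.ingredient for d in gt.drugs if d.class_name == target]
        if not members:
            raise ConfigurationError(f"no planted drug in class {target!r}")
        exposed = np.zeros(len(rep), dtype=bool)
        for m in members:
            exposed |= rep[f"exposed_{m}"].to_numpy(dtype=bool)
    else:
        raise ConfigurationError(f"unknown level {level!r}")
    aad = rep["aad"].to_numpy(dtype=bool)
    return ContingencyTable(
        a=int((exposed & aad).sum()), b=int((exposed & ~aad).sum()),
        c=int((~exposed & aad).sum()), d=int((~exposed & ~aad).sum()),
    )


# ---------------------------------------------------------------------------
# generation


def _choice(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    keys = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), size=n, p=p)]


def _ordinal_to_faers(ordinals: np.ndarray) -> np.ndarray:
    dt = pd.to_datetime(np.asarray(ordinals, dtype=np.int64) - _EPOCH_OFFSET,
                        unit="D")
    num = dt.year * 10_000 + dt.month * 100 + dt.day
    return num.to_numpy().astype("U8").astype(object)


def _degrade_dates(dates: np.ndarray, rng: np.random.Generator,
                   partial_rate: float, missing_rate: float) -> np.ndarray:
    """Blank a fraction of date strings and truncate another fraction to
    month (6-digit) or year (4-digit) precision."""
    out = dates.copy()
    r = rng.random(len(out))
    keep_len = rng.choice(np.array([6, 4]), size=len(out), p=[0.7, 0.3])
    missing = r < missing_rate
    partial = (~missing) & (r < missing_rate + partial_rate)
    out[missing] = ""
    for i in np.flatnonzero(partial):
        out[i] = out[i][: keep_len[i]]
    return out


def generate_dataset(cfg: SyntheticConfig,
                     case_definition: CaseDefinition | None = None
                     ) -> tuple[TableSet, GroundTruth]:
    """Simulate one FAERS-like table set plus its ground truth."""
    cd = case_definition or CaseDefinition.default()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    drugs = cfg.drugs
    J = len(drugs)

    caseid = (10_000_001 + np.arange(n)).astype(np.int64)
    primaryid = caseid * 10 + 2  # current version; injected dups get suffix 1
    caseid_s = caseid.astype(str).astype(object)
    primaryid_s = primaryid.astype(str).astype(object)

    # exposures and case status -------------------------------------------
    if J:
        exposed = rng.random((n, J)) < np.array([d.exposure_prob for d in drugs])
        thetas = np.array([d.theta for d in drugs])
        masked = np.where(exposed, thetas, -np.inf)
        any_exp = exposed.any(axis=1)
        causal_idx = masked.argmax(axis=1)  # max-theta exposed drug
        theta_eff = np.where(any_exp, masked.max(axis=1), 1.0)
    else:
        exposed = np.zeros((n, 0), dtype=bool)
        any_exp = np.zeros(n, dtype=bool)
        causal_idx = np.zeros(n, dtype=int)
        theta_eff = np.ones(n)
    p0 = cfg.background_aad_prob
    p_case = theta_eff * p0 / (1 - p0 + theta_eff * p0)
    aad = rng.random(n) < p_case

    # demographics ---------------------------------------------------------
    dem = cfg.demographics
    age_grp = _choice(rng, dem.age_group_probs, n)
    age = np.empty(n, dtype=object)
    u = rng.random(n)
    for grp, lo, hi in (("<18", 1, 18), ("18-64", 18, 65), (">=65", 65, 95)):
        m = age_grp == grp
        age[m] = np.floor(lo + u[m] * (hi - lo)).astype(int).astype(str)
    age[age_grp == "unknown"] = ""
    sex = _choice(rng, dem.sex_probs, n)
    occp = _choice(rng, dem.reporter_probs, n)
    country = _choice(rng, dem.country_probs, n)
    year = _choice(rng, dem.year_probs, n).astype(int)

    # dates ----------------------------------------------------------------
    import datetime

    year_start = np.array([datetime.date(int(y), 1, 1).toordinal() for y in year])
    start_ord = year_start + rng.integers(0, 330, size=n)
    onset = np.zeros(n, dtype=np.int64)
    if J:
        mu = np.array([d.onset_log_mean for d in drugs])[causal_idx]
        sd = np.array([d.onset_log_sd for d in drugs])[causal_idx]
        drawn = np.rint(rng.lognormal(mu, sd)).astype(np.int64)
        flagged_exposed = aad & any_exp
        onset[flagged_exposed] = drawn[flagged_exposed]
    other_gap = rng.integers(0, 60, size=n)
    event_ord = np.where(aad & any_exp, start_ord + onset, start_ord + other_gap)
    rept_ord = event_ord + rng.integers(1, 90, size=n)

    start_str = _ordinal_to_faers(start_ord)
    event_str = _ordinal_to_faers(event_ord)
    rept_str = _ordinal_to_faers(rept_ord)
    start_str = _degrade_dates(start_str, rng, cfg.partial_date_rate,
                               cfg.missing_date_rate)
    event_str = _degrade_dates(event_str, rng, cfg.partial_date_rate,
                               cfg.missing_date_rate)

    demo = pd.DataFrame({
        "primaryid": primaryid_s, "caseid": caseid_s,
        "event_dt": event_str, "rept_dt": rept_str,
        "age": age, "age_cod": np.where(age == "", "", "YR").astype(object),
        "sex": sex, "occp_cod": occp, "reporter_country": country,
    }, dtype=object)

    # drug + therapy rows --------------------------------------------------
    rep_idx_parts: list[np.ndarray] = []
    name_parts: list[np.ndarray] = []
    role_parts: list[np.ndarray] = []
    for j, spec in enumerate(drugs):
        rows = np.flatnonzero(exposed[:, j])
        rep_idx_parts.append(rows)
        name_parts.append(np.full(len(rows), spec.ingredient.upper(), dtype=object))
        role_parts.append(np.full(len(rows), "PS", dtype=object))
    # antibiotics in non-suspect roles (never counted as exposure)
    if J and cfg.nonsuspect_antibiotic_rate > 0:
        rows = np.flatnonzero(rng.random(n) < cfg.nonsuspect_antibiotic_rate)
        pick = rng.integers(0, J, size=len(rows))
        names = np.array([drugs[k].ingredient.upper() for k in pick], dtype=object)
        rep_idx_parts.append(rows)
        name_parts.append(names)
        role_parts.append(np.full(len(rows), "C", dtype=object))
    # comparator drugs: every report gets one (PS unless an antibiotic is
    # already the suspect), a fraction get a second concomitant
    comp_names = np.array(
        [f"INVESTIGATIONAL COMPOUND {k:03d}" for k in range(cfg.comparator_drug_pool)],
        dtype=object)
    first = comp_names[rng.integers(0, len(comp_names), size=n)]
    rep_idx_parts.append(np.arange(n))
    name_parts.append(first)
    role_parts.append(np.where(any_exp, "C", "PS").astype(object))
    second_rows = np.flatnonzero(rng.random(n) < 0.4)
    rep_idx_parts.append(second_rows)
    name_parts.append(comp_names[rng.integers(0, len(comp_names),
                                              size=len(second_rows))])
    role_parts.append(np.full(len(second_rows), "C", dtype=object))

    rep_idx = np.concatenate(rep_idx_parts)
    order = np.argsort(rep_idx, kind="stable")
    rep_idx = rep_idx[order]
    drug_names = np.concatenate(name_parts)[order]
    roles = np.concatenate(role_parts)[order]
    seq = np.ones(len(rep_idx), dtype=np.int64)
    if len(rep_idx):
        same = np.concatenate([[False], rep_idx[1:] == rep_idx[:-1]])
        grp_start = np.flatnonzero(~same)
        seq = np.arange(len(rep_idx)) - np.repeat(grp_start,
                                                  np.diff(np.append(grp_start,
                                                                    len(rep_idx)))) + 1
    drug = pd.DataFrame({
        "primaryid": primaryid_s[rep_idx],
        "drug_seq": seq.astype(str).astype(object),
        "drugname": drug_names,
        "role_cod": roles,
    }, dtype=object)
    ther = pd.DataFrame({
        "primaryid": primaryid_s[rep_idx],
        "drug_seq": seq.astype(str).astype(object),
        "start_dt": start_str[rep_idx],
    }, dtype=object)

    # reactions ------------------------------------------------------------
    pt_codes = np.array([c for c, _ in cd.pts])
    pt_names = np.array([nme for _, nme in cd.pts], dtype=object)
    case_rows = np.flatnonzero(aad)
    pick = rng.integers(0, len(cd.pts), size=len(case_rows))
    reac_parts = [pd.DataFrame({
        "primaryid": primaryid_s[case_rows],
        "pt_cod": pt_codes[pick].astype(str).astype(object),
        "pt": pt_names[pick],
    }, dtype=object)]
    noise = np.array(_NOISE_PTS, dtype=object)
    noncase_rows = np.flatnonzero(~aad)
    reac_parts.append(pd.DataFrame({
        "primaryid": primaryid_s[noncase_rows],
        "pt_cod": np.full(len(noncase_rows), "", dtype=object),
        "pt": noise[rng.integers(0, len(noise), size=len(noncase_rows))],
    }, dtype=object))
    extra_rows = np.flatnonzero(rng.random(n) < cfg.extra_reaction_prob)
    reac_parts.append(pd.DataFrame({
        "primaryid": primaryid_s[extra_rows],
        "pt_cod": np.full(len(extra_rows), "", dtype=object),
        "pt": noise[rng.integers(0, len(noise), size=len(extra_rows))],
    }, dtype=object))
    reac = pd.concat(reac_parts, ignore_index=True)

    # outcomes -------------------------------------------------------------
    outc_parts = []
    o_rows = case_rows
    outc_parts.append(pd.DataFrame({
        "primaryid": primaryid_s[o_rows],
        "outc_cod": _choice(rng, cfg.outcome_probs, len(o_rows)),
    }, dtype=object))
    extra = o_rows[rng.random(len(o_rows)) < cfg.extra_outcome_prob]
    outc_parts.append(pd.DataFrame({
        "primaryid": primaryid_s[extra],
        "outc_cod": _choice(rng, cfg.outcome_probs, len(extra)),
    }, dtype=object))
    # non-cases occasionally carry an unrelated outcome event
    nc = noncase_rows[rng.random(len(noncase_rows)) < 0.15]
    outc_parts.append(pd.DataFrame({
        "primaryid": primaryid_s[nc],
        "outc_cod": np.where(rng.random(len(nc)) < 0.8, "OT", "HO").astype(object),
    }, dtype=object))
    outc = pd.concat(outc_parts, ignore_index=True)

    # duplicate case versions ---------------------------------------------
    n_dup = int(round(cfg.duplicate_rate * n))
    dup_caseids: list[str] = []
    if n_dup:
        dup_rows = rng.choice(n, size=n_dup, replace=False)
        dup_rows.sort()
        dup_caseids = [str(c) for c in caseid[dup_rows]]
        old_pid = (caseid[dup_rows] * 10 + 1).astype(str).astype(object)
        dup_demo = demo.iloc[dup_rows].copy()
        dup_demo["primaryid"] = old_pid
        demo = pd.concat([demo, dup_demo], ignore_index=True)
        pid_map = dict(zip(primaryid_s[dup_rows], old_pid))
        for name, frame in (("drug", drug), ("reac", reac),
                            ("outc", outc), ("ther", ther)):
            sub = frame[frame["primaryid"].isin(pid_map)].copy()
            sub["primaryid"] = sub["primaryid"].map(pid_map)
            if name == "drug":
                drug = pd.concat([drug, sub], ignore_index=True)
            elif name == "reac":
                reac = pd.concat([reac, sub], ignore_index=True)
            elif name == "outc":
                outc = pd.concat([outc, sub], ignore_index=True)
            else:
                ther = pd.concat([ther, sub], ignore_index=True)

    ts = TableSet(demo=demo, drug=drug, reac=reac, outc=outc, ther=ther,
                  source_quarter="synthetic")

    gt_frame = pd.DataFrame({"caseid": caseid_s, "primaryid": primaryid_s})
    for j, spec in enumerate(drugs):
        gt_frame[f"exposed_{spec.ingredient}"] = exposed[:, j]
    gt_frame["aad"] = aad
    if J:
        causal = np.where(aad & any_exp,
                          np.array([d.ingredient for d in drugs],
                                   dtype=object)[causal_idx], "")
    else:
        causal = np.full(n, "", dtype=object)
    gt_frame["causal_ingredient"] = causal
    gt_frame["onset_days"] = pd.array(
        np.where(aad & any_exp, onset, -1), dtype="Int64")
    gt_frame.loc[gt_frame["onset_days"] == -1, "onset_days"] = pd.NA

    gt = GroundTruth(report=gt_frame, drugs=list(drugs),
                     duplicated_caseids=dup_caseids, config=cfg)
    return ts, gt


def simulate_to_dir(cfg: SyntheticConfig, out_dir: str | Path,
                    dialect: str = "dollar") -> dict[str, Path]:
    """Generate and write the five tables plus ``ground_truth.tsv`` and the
    exact config used (``config.json``)."""
    out_dir = Path(out_dir)
    ts, gt = generate_dataset(cfg)
    paths = write_table_set(ts, out_dir, dialect=dialect)
    gt_path = out_dir / "ground_truth.tsv"
    gt.to_frame().to_csv(gt_path, sep="\t", index=False)
    cfg_path = out_dir / "config.json"
    cfg_path.write_text(cfg.model_dump_json(indent=2))
    paths["ground_truth"] = gt_path
    paths["config"] = cfg_path
    return paths
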