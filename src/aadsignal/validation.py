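"""Simulation studies that exercise the whole pipeline against ground truth.

Each study generates FAERS-like datasets with :mod:`.synthetic_data`, pushes
them through the real cleaning → case-flagging → ROR path, and compares the
result with the generator's bookkeeping:

* :func:`coverage_study` — does the Woolf 95% CI cover a planted odds
  multiplier at roughly nominal frequency?
* :func:`null_signal_rate` — with every multiplier at 1, how often does the
  signal rule (lower bound > 1, a >= 3) fire?  The rule is a one-sided 2.5%
  test, so the expected rate is ~2.5%.
* :func:`onset_bin_study` — do empirical onset-bin fractions match the
  generating log-normal's bin probabilities?

Replicate seeds are ``base_seed + i``; every study is fully deterministic
given its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .case_definition import CaseDefinition, flag_aad_reports
from .cleaning import clean_table_set, primary_suspect_exposures
from .signal_stats import ContingencyTable, SignalResult, compute_ror
from .synthetic_data import PlantedDrugSpec, SyntheticConfig, generate_dataset


def pipeline_drug_ror(cfg: SyntheticConfig, target: str,
                      case_definition: CaseDefinition | None = None
                      ) -> tuple[SignalResult, ContingencyTable]:
    """Generate one dataset and estimate the target drug's ROR through the
    full cleaning pipeline."""
    cd = case_definition or CaseDefinition.default()
    ts, gt = generate_dataset(cfg, cd)
    clean = clean_table_set(ts, gt.dictionary())
    flagged = flag_aad_reports(clean.reactions, cd)
    exposures = primary_suspect_exposures(clean.drugs)
    exposed = {pid for pid, ings in exposures.items() if target in ings}
    n = clean.n_reports
    n_aad = len(flagged)
    a = len(exposed & flagged)
    b = len(exposed) - a
    table = ContingencyTable(a=a, b=b, c=n_aad - a, d=n - n_aad - b)
    return compute_ror(table, target=target), table


def _single_drug_config(theta: float, n_reports: int, seed: int,
                        exposure_prob: float = 0.02,
                        p0: float = 0.01) -> SyntheticConfig:
    return SyntheticConfig(
        n_reports=n_reports, background_aad_prob=p0, seed=seed,
        drugs=[PlantedDrugSpec(ingredient="lincomycin",
                               class_name="lincomycins",
                               exposure_prob=exposure_prob, theta=theta)])


@dataclass
class CoverageResult:
    theta: float
    n_replicates: int
    n_covered: int
    n_computable: int

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_replicates


def coverage_study(theta: float, n_replicates: int = 200,
                   n_reports: int = 50_000, base_seed: int = 0,
                   exposure_prob: float = 0.02,
                   p0: float = 0.01) -> CoverageResult:
    """Fraction of replicates whose pipeline-estimated 95% CI covers the
    planted odds multiplier (non-computable tables count as non-covered)."""
    covered = computable = 0
    for i in range(n_replicates):
        cfg = _single_drug_config(theta, n_reports, base_seed + i,
                                  exposure_prob, p0)
        res, _ = pipeline_drug_ror(cfg, "lincomycin")
        if res.computable:
            computable += 1
            if res.ci_lower <= theta <= res.ci_upper:
                covered += 1
    return CoverageResult(theta=theta, n_replicates=n_replicates,
                          n_covered=covered, n_computable=computable)


def null_signal_rate(n_replicates: int = 400, n_reports: int = 50_000,
                     base_seed: int = 0) -> tuple[float, int, int]:
    """(flagged fraction, n flagged, n drug-tests) with every theta = 1.

    Uses the default four-drug configuration with all multipliers nulled, so
    each replicate contributes four drug-level tests.
    """
    flagged_n = total = 0
    base = SyntheticConfig()
    null_drugs = [d.model_copy(update={"theta": 1.0}) for d in base.drugs]
    cd = CaseDefinition.default()
    for i in range(n_replicates):
        cfg = base.model_copy(update={
            "drugs": [d.model_copy() for d in null_drugs],
            "n_reports": n_reports, "seed": base_seed + i})
        ts, gt = generate_dataset(cfg, cd)
        clean = clean_table_set(ts, gt.dictionary())
        flags = flag_aad_reports(clean.reactions, cd)
        exposures = primary_suspect_exposures(clean.drugs)
        n = clean.n_reports
        n_aad = len(flags)
        for spec in cfg.drugs:
            exposed = {pid for pid, ings in exposures.items()
                       if spec.ingredient in ings}
            a = len(exposed & flags)
            b = len(exposed) - a
            res = compute_ror(ContingencyTable(a, b, n_aad - a,
                                               n - n_aad - b),
                              target=spec.ingredient)
            total += 1
            flagged_n += int(res.is_signal)
    return flagged_n / total, flagged_n, total


def lognormal_bin_probs(log_mean: float, log_sd: float,
                        edges: tuple[int, ...]) -> list[float]:
    """P(rounded log-normal draw lands in each half-open day bin).

    Rounding to integer days means bin [lo, hi) collects X in
    [lo - 0.5, hi - 0.5); the first bin additionally takes X < 0.5.
    """

    def cdf(x: float) -> float:
        if x <= 0:
            return 0.0
        return 0.5 * (1 + math.erf((math.log(x) - log_mean)
                                   / (log_sd * math.sqrt(2))))

    bounds = [e - 0.5 for e in edges[1:]]
    probs = []
    prev = 0.0
    for b in bounds:
        probs.append(cdf(b) - prev)
        prev = cdf(b)
    probs.append(1.0 - prev)
    return probs


@dataclass
class OnsetBinResult:
    labels: tuple[str, ...]
    empirical: list[float]
    expected: list[float]
    n: int

    def max_se_distance(self) -> float:
        """Largest |empirical - expected| in Monte-Carlo standard errors."""
        worst = 0.0
        for emp, exp in zip(self.empirical, self.expected):
            se = math.sqrt(max(exp * (1 - exp), 1e-12) / self.n)
            worst = max(worst, abs(emp - exp) / se)
        return worst


def onset_bin_study(n_reports: int = 50_000, seed: int = 0,
                    log_mean: float = math.log(6.0),
                    log_sd: float = 0.9) -> OnsetBinResult:
    """Empirical pipeline onset-bin fractions vs the generating
    distribution's bin probabilities, on a high-signal single-drug dataset."""
    from .time_outcomes import ONSET_BIN_EDGES, ONSET_BIN_LABELS, \
        onset_records, summarize_onsets

    cfg = SyntheticConfig(
        n_reports=n_reports, background_aad_prob=0.01, seed=seed,
        duplicate_rate=0.0, partial_date_rate=0.0, missing_date_rate=0.0,
        drugs=[PlantedDrugSpec(ingredient="lincomycin",
                               class_name="lincomycins",
                               exposure_prob=0.30, theta=25.0,
                               onset_log_mean=log_mean, onset_log_sd=log_sd)])
    cd = CaseDefinition.default()
    ts, gt = generate_dataset(cfg, cd)
    clean = clean_table_set(ts, gt.dictionary())
    flags = flag_aad_reports(clean.reactions, cd)
    records, _ = onset_records(clean, flags)
    summary = summarize_onsets(records)
    total = summary.total
    empirical = [summary.bin_counts[b] / total for b in ONSET_BIN_LABELS]
    expected = lognormal_bin_probs(log_mean, log_sd, ONSET_BIN_EDGES)
    return OnsetBinResult(labels=ONSET_BIN_LABELS, empirical=empirical,
                          expected=expected, n=total)
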