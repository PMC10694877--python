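"""Reporting odds ratio (ROR) disproportionality statistics.

For a target drug (or class) and a target event, the deduplicated reports are
cross-classified as

    ==================  =========  ==================
                        AAD        all other reactions
    target exposure     a          b
    all other drugs     c          d
    ==================  =========  ==================

and the reporting odds ratio is ``ROR = ad / bc`` with the Woolf (log-normal)
95% confidence interval ``exp(ln ROR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.
A target is a *signal* when the lower confidence bound exceeds 1 and there are
at least three exposed cases (a >= 3).  The ROR measures reporting
disproportion, not causal risk.

Counting is report-level: every deduplicated report contributes exactly one
count to exactly one cell, so the table margins a+c and b+d are the same for
every target in a fixed dataset.  Exposure means a primary-suspect (PS) drug
record; the comparator is "all other drugs", not "other antibiotics".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cleaning import DrugDictionary
from .errors import ConfigurationError

Z_95 = 1.96  # fixed multiplier of the published interval


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of one 2x2 drug-or-class x event table (report counts)."""

    a: int  # event,  exposed
    b: int  # no event, exposed
    c: int  # event,  unexposed
    d: int  # no event, unexposed

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate, 95% CI and signal classification for one target."""

    target: str
    level: str  # "drug" or "class"
    a: int
    ror: float | None
    ci_lower: float | None
    ci_upper: float | None
    computable: bool
    is_signal: bool


def build_contingency(report_ids, flagged: set[str],
                      exposures: dict[str, set[str]], target: str,
                      level: str = "drug",
                      dictionary: DrugDictionary | None = None) -> ContingencyTable:
    """Count reports into the 2x2 table for one target.

    ``report_ids`` is the deduplicated report universe; ``flagged`` the AAD
    case ids; ``exposures`` the primaryid → PS-ingredient-set map.  At
    ``level="class"`` a report is exposed when any of its PS ingredients maps
    to the target class (a report with two PS drugs of the class still counts
    once).
    """
    if level not in ("drug", "class"):
        raise ConfigurationError(f"unknown level {level!r}")
    if level == "class":
        if dictionary is None:
            raise ConfigurationError("class-level table needs a drug dictionary")
        if target not in set(dictionary.ingredient_to_class.values()):
            raise ConfigurationError(f"class {target!r} not in dictionary")

        def exposed(ings: set[str]) -> bool:
            return any(dictionary.class_of(i) == target for i in ings)
    else:
        def exposed(ings: set[str]) -> bool:
            return target in ings

    a = b = c = d = 0
    for pid in report_ids:
        pid = str(pid)
        is_exp = exposed(exposures.get(pid, set()))
        is_case = pid in flagged
        if is_exp:
            if is_case:
                a += 1
            else:
                b += 1
        elif is_case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def compute_ror(t: ContingencyTable, target: str = "",
                level: str = "drug") -> SignalResult:
    """ROR and Woolf 95% CI for one table.

    Any zero cell makes the estimate non-computable (no continuity
    correction is applied); numeric fields are then ``None`` and the result
    can never be a signal.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return SignalResult(target=target, level=level, a=t.a, ror=None,
                            ci_lower=None, ci_upper=None, computable=False,
                            is_signal=False)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo = math.exp(math.log(ror) - Z_95 * se)
    hi = math.exp(math.log(ror) + Z_95 * se)
    res = SignalResult(target=target, level=level, a=t.a, ror=ror,
                       ci_lower=lo, ci_upper=hi, computable=True,
                       is_signal=False)
    return SignalResult(**{**res.__dict__, "is_signal": classify_signal(res)})


def classify_signal(r: SignalResult) -> bool:
    """Published signal rule: computable, lower 95% bound > 1, and a >= 3."""
    return bool(r.computable and r.ci_lower is not None
                and r.ci_lower > 1.0 and r.a >= 3)


def rank_signals(results) -> list[SignalResult]:
    """Descending by ROR; non-computable entries last; ties alphabetical."""
    computable = [r for r in results if r.computable]
    rest = [r for r in results if not r.computable]
    computable.sort(key=lambda r: (-r.ror, r.target))
    rest.sort(key=lambda r: r.target)
    return computable + rest


def signal_table(report_ids, flagged: set[str], exposures: dict[str, set[str]],
                 dictionary: DrugDictionary, level: str = "drug",
                 targets: list[str] | None = None) -> list[SignalResult]:
    """Ranked :class:`SignalResult` for every target at one level.

    Default targets are all dictionary ingredients (drug level) or all
    classes (class level) with at least one exposed report.
    """
    ids = [str(p) for p in report_ids]
    flagged = {str(p) for p in flagged}
    if targets is None:
        if level == "drug":
            seen: set[str] = set()
            for ings in exposures.values():
                seen |= ings
            targets = sorted(seen)
        else:
            seen = set()
            for ings in exposures.values():
                for ing in ings:
                    cls = dictionary.class_of(ing)
                    if cls:
                        seen.add(cls)
            targets = sorted(seen)

    # One pass over reports, classifying against all targets at once.
    n_aad = sum(1 for p in ids if p in flagged)
    n_tot = len(ids)
    counts: dict[str, list[int]] = {t: [0, 0] for t in targets}  # [a, b]
    tset = set(targets)
    for pid in ids:
        ings = exposures.get(pid, set())
        if not ings:
            continue
        if level == "drug":
            hit = ings & tset
        else:
            hit = {dictionary.class_of(i) for i in ings} & tset
        is_case = pid in flagged
        for t in hit:
            counts[t][0 if is_case else 1] += 1
    results = []
    for t in targets:
        a, b = counts[t]
        table = ContingencyTable(a, b, n_aad - a, n_tot - n_aad - b)
        results.append(compute_ror(table, target=t, level=level))
    return rank_signals(results)
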