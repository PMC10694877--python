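"""Flag antibiotic-associated-diarrhea (AAD) case reports.

A report is an AAD case when at least one of its reaction records matches a
configurable list of MedDRA preferred terms (PTs).  The packaged default is
the eight C. difficile / antibiotic-colitis PTs used in the source study; the
list deliberately does not include the PT "Antibiotic-associated diarrhoea"
itself, reproducing that study's published definition as printed — pass a
custom CSV to run sensitivity analyses with a wider net.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

MATCH_MODES = ("code", "name", "either")


@dataclass
class CaseDefinition:
    """A list of (pt_code, pt_name) pairs plus how to match them.

    ``match_mode="code"`` matches on the numeric PT code, ``"name"`` on the
    case-folded PT name, ``"either"`` (default) on both — real FAERS REAC
    tables carry names while coded extracts carry numbers.
    """

    pts: list[tuple[int, str]]
    match_mode: str = "either"

    def __post_init__(self) -> None:
        if not self.pts:
            raise ConfigurationError("case definition is empty")
        if self.match_mode not in MATCH_MODES:
            raise ConfigurationError(
                f"match_mode {self.match_mode!r} not in {MATCH_MODES}")
        codes = [int(c) for c, _ in self.pts]
        names = [str(n).strip().casefold() for _, n in self.pts]
        if len(set(codes)) != len(codes):
            raise ConfigurationError("duplicate PT codes in case definition")
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate PT names in case definition")
        self.pts = [(int(c), str(n).strip()) for c, n in self.pts]

    @property
    def codes(self) -> set[int]:
        return {c for c, _ in self.pts}

    @property
    def names_folded(self) -> set[str]:
        return {n.casefold() for _, n in self.pts}

    @classmethod
    def from_csv(cls, path: str | Path, match_mode: str = "either") -> "CaseDefinition":
        frame = pd.read_csv(path, dtype={"pt_code": int, "pt_name": str})
        for col in ("pt_code", "pt_name"):
            if col not in frame.columns:
                raise ConfigurationError(f"{path}: missing column {col!r}")
        return cls(list(zip(frame["pt_code"], frame["pt_name"])), match_mode)

    @classmethod
    def default(cls, match_mode: str = "either") -> "CaseDefinition":
        import importlib.resources as res

        text = (res.files("aadsignal.data") / "aad_case_definition.csv").read_text()
        frame = pd.read_csv(io.StringIO(text), dtype={"pt_code": int, "pt_name": str})
        return cls(list(zip(frame["pt_code"], frame["pt_name"])), match_mode)


def flag_aad_reports(reactions: pd.DataFrame, cd: CaseDefinition) -> set[str]:
    """Primaryids with at least one reaction matching the case definition.

    A report with several matching PTs still appears once (set semantics), so
    enlarging the PT list can only grow the flagged set.
    """
    if reactions.empty:
        return set()
    import numpy as np

    from .faers_io import strip_ids

    hit = np.zeros(len(reactions), dtype=bool)
    if cd.match_mode in ("name", "either"):
        codes, uniques = pd.factorize(reactions["pt"], use_na_sentinel=False)
        match = np.array([
            not (u is None or (isinstance(u, float) and np.isnan(u)))
            and str(u).strip().casefold() in cd.names_folded
            for u in uniques], dtype=bool)
        hit |= match[codes]
    if cd.match_mode in ("code", "either") and "pt_cod" in reactions.columns:
        codes_num = pd.to_numeric(reactions["pt_cod"], errors="coerce")
        hit |= codes_num.isin(list(cd.codes)).to_numpy()
    return set(strip_ids(reactions["primaryid"])[hit])
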