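"""Fatty-acid "C:D n-x" nomenclature parsing and class accounting.

Class sums follow double-bond count: 0 -> SAFA (branched acids such as
phytanic included), 1 -> MUFA, >= 2 -> PUFA.  Omega sums only draw from
acids carrying that omega designation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .environment import round_half_up

__all__ = [
    "FattyAcidRecord",
    "FAClassSummary",
    "parse_fa_name",
    "classify",
    "class_sums",
    "load_fa_table",
    "records_for_site",
    "reconcile_printed_sums",
    "PRINTED_CLASS_SUMS",
]

_FA_RE = re.compile(
    r"^\s*(?P<chain>\d+)\s*:\s*(?P<db>\d+)"
    r"(?:\s*n\s*-\s*(?P<omega>\d+))?"
    r"(?:\s+(?P<qualifier>[A-Za-z][A-Za-z0-9_-]*))?\s*$"
)

EPA = "20:5 n-3"
DHA = "22:6 n-3"
#: The four dominant acids whose combined share is reported per site.
BIG_FOUR = ("14:0", "16:0", "16:1 n-7", "20:5 n-3")

#: Class sums as printed in the source table (per site), for reconciliation
#: against sums of the displayed rows only.  Printed sums may include acids
#: below the display threshold; differences > 0.5 are reported, never
#: silently corrected.
PRINTED_CLASS_SUMS = {
    "outer": {"safa": 30.0, "mufa": 54.0, "pufa": 16.0, "omega3": 10.0,
              "omega6": 3.3, "omega9": 4.1, "epa_plus_dha": 7.8},
    "inner": {"safa": 35.0, "mufa": 38.0, "pufa": 28.0, "omega3": 16.0,
              "omega6": 5.0, "omega9": 13.0, "epa_plus_dha": 13.0},
}


@dataclass(frozen=True)
class FattyAcidRecord:
    """One parsed fatty acid with its share of total FA."""

    raw_name: str
    chain_length: int
    n_double_bonds: int
    omega: int | None = None
    qualifier: str | None = None
    percent_total_fa: float = 0.0

    def __post_init__(self) -> None:
        if self.chain_length < 4:
            raise ValueError(f"{self.raw_name!r}: chain length must be >= 4")
        if self.n_double_bonds < 0:
            raise ValueError(f"{self.raw_name!r}: double-bond count must be >= 0")
        if self.percent_total_fa < 0:
            raise ValueError(f"{self.raw_name!r}: percent must be >= 0")
        if self.n_double_bonds == 0 and self.omega is not None:
            raise ValueError(
                f"{self.raw_name!r}: omega designation on a saturated (0 double-bond) acid"
            )
        if self.n_double_bonds >= 1 and self.omega is None:
            raise ValueError(
                f"{self.raw_name!r}: unsaturated acid lacks an omega (n-x) designation"
            )


def parse_fa_name(name: str, percent_total_fa: float = 0.0) -> FattyAcidRecord:
    """Parse names like ``16:1 n-7``, ``22:6 n-3`` or ``17:0 Phytanic``.

    Malformed tokens (no colon, non-integer fields, omega on a saturated
    acid) raise a ValueError naming the offending token.
    """
    if not name or not name.strip():
        raise ValueError("empty fatty-acid name")
    m = _FA_RE.match(name)
    if m is None:
        raise ValueError(f"malformed fatty-acid name {name!r}")
    omega = m.group("omega")
    return FattyAcidRecord(
        raw_name=name.strip(),
        chain_length=int(m.group("chain")),
        n_double_bonds=int(m.group("db")),
        omega=None if omega is None else int(omega),
        qualifier=m.group("qualifier"),
        percent_total_fa=float(percent_total_fa),
    )


def classify(fa: FattyAcidRecord) -> str:
    """SAFA (0 double bonds), MUFA (1) or PUFA (>= 2)."""
    if fa.n_double_bonds == 0:
        return "SAFA"
    if fa.n_double_bonds == 1:
        return "MUFA"
    return "PUFA"


@dataclass(frozen=True)
class FAClassSummary:
    """Class and omega-series percent sums (each % of total FA, 1 decimal)."""

    safa: float
    mufa: float
    pufa: float
    omega3: float
    omega6: float
    omega9: float
    epa_plus_dha: float
    big_four: float

    def __post_init__(self) -> None:
        if self.safa + self.mufa + self.pufa > 100.0 + 0.5:
            raise ValueError("SAFA + MUFA + PUFA exceeds 100% beyond rounding slack")


def class_sums(profile: Sequence[FattyAcidRecord]) -> FAClassSummary:
    """Sum percents by class and omega series, reported to 1 decimal.

    ``epa_plus_dha`` sums 20:5 n-3 and 22:6 n-3; ``big_four`` sums
    14:0, 16:0, 16:1 n-7 and 20:5 n-3.  Duplicate acid names raise.
    """
    profile = list(profile)
    if not profile:
        raise ValueError("empty fatty-acid profile")
    names = [fa.raw_name for fa in profile]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate fatty-acid names: {sorted(dupes)}")
    cls = {"SAFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    omega = {3: 0.0, 6: 0.0, 9: 0.0}
    by_name = {}
    for fa in profile:
        cls[classify(fa)] += fa.percent_total_fa
        if fa.omega in omega:
            omega[fa.omega] += fa.percent_total_fa
        by_name[fa.raw_name] = fa.percent_total_fa
    epa_dha = by_name.get(EPA, 0.0) + by_name.get(DHA, 0.0)
    big4 = sum(by_name.get(n, 0.0) for n in BIG_FOUR)
    r1 = lambda x: round_half_up(x, 1)
    return FAClassSummary(
        safa=r1(cls["SAFA"]), mufa=r1(cls["MUFA"]), pufa=r1(cls["PUFA"]),
        omega3=r1(omega[3]), omega6=r1(omega[6]), omega9=r1(omega[9]),
        epa_plus_dha=r1(epa_dha), big_four=r1(big4),
    )


# ---------------------------------------------------------------------------
# Packaged community fatty-acid table
# ---------------------------------------------------------------------------

def load_fa_table(path: str | Path | None = None) -> pd.DataFrame:
    """Packaged community FA table: fa_name, outer_pct, inner_pct."""
    if path is None:
        path = Path(str(resources.files("icealgae").joinpath("data/fatty_acid_profiles.csv")))
    df = pd.read_csv(path, comment="#")
    for c in ("outer_pct", "inner_pct"):
        df[c] = pd.to_numeric(df[c])
    return df


def records_for_site(df: pd.DataFrame | None = None, site: str = "outer") -> list[FattyAcidRecord]:
    if df is None:
        df = load_fa_table()
    col = f"{site}_pct"
    if col not in df.columns:
        raise ValueError(f"unknown site {site!r}; expected one of outer/inner")
    return [parse_fa_name(r["fa_name"], r[col]) for _, r in df.iterrows()]


def reconcile_printed_sums(summary: FAClassSummary, site: str,
                           slack: float = 0.5) -> list[str]:
    """Notes where computed sums differ from printed sums by more than slack.

    Printed sums that disagree with the column sums (e.g. inner EPA+DHA
    printed as 13 vs a 12.1 column sum) are reported, not corrected: the
    printed table omits acids below its display threshold.
    """
    printed = PRINTED_CLASS_SUMS[site]
    notes = []
    for key, pval in printed.items():
        cval = getattr(summary, key)
        if abs(cval - pval) > slack:
            notes.append(
                f"{site} {key}: printed sum {pval:g} vs displayed-row sum {cval:g} "
                f"(difference {abs(cval - pval):.1f}; rows < 0.1% are not displayed)"
            )
    return notes
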