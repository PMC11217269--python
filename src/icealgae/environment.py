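"""Sea-ice environment physics and chemistry.

Brine salinity follows the Frankenstein-Garner relation
``Sb = 1000 / (1 - 54.11/T)`` (T in degC, valid -22.9 <= T < 0); brine
volume fraction uses the density-ratio form
``Vb/V = (S_bulk / Sb) * (rho_ice / rho_brine)`` with rho_ice = 917 kg/m3
and rho_brine = 1000 + 0.8 * Sb kg/m3.  A Cox-Weeks polynomial variant is
available behind the ``method`` switch.  Nutrient stoichiometry is judged
against the diatom-amended Redfield reference 106C : 16N : 15Si : 1P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IceCoreRecord",
    "BrineState",
    "STOICHIOMETRY_REFERENCE",
    "DETECTION_LIMITS",
    "brine_salinity",
    "brine_volume_fraction",
    "brine_state",
    "albedo",
    "NutrientRatios",
    "nutrient_ratios",
    "SeriesSummary",
    "summarize_series",
    "round_half_up",
    "load_environment_table",
    "environment_records",
    "site_summary",
]

#: Amended Redfield molar reference for diatoms: C : N : Si : P.
STOICHIOMETRY_REFERENCE = {"C": 106.0, "N": 16.0, "Si": 15.0, "P": 1.0}

#: Analyser detection limits (uM); values at or below are treated as missing.
DETECTION_LIMITS = {"nox": 0.01, "po4": 0.02, "si": 0.02}

_FG_VALID_MIN = -22.9  # lower bound of the brine-salinity relation's validity

RHO_ICE = 917.0  # kg/m3


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up at printed precision, robust to float fuzz.

    ``4.95`` rounds to ``5.0`` (as printed sources do), where banker's
    rounding on the nearest float would give 4.9.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.12g}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class IceCoreRecord:
    """One site x date environmental record (ice core + under-ice water)."""

    date: str
    site: str
    week: str | None = None
    snow_depth: float | None = None
    snow_depth_sd: float | None = None
    albedo: float | None = None
    ice_thickness: float | None = None
    ice_thickness_sd: float | None = None
    ice_temperature: float | None = None
    bulk_salinity: float | None = None
    chl_a_ice: float | None = None
    chl_a_water: float | None = None
    cn_ratio: float | None = None
    d13c: float | None = None
    d15n: float | None = None
    si: float | None = None
    nox: float | None = None
    po4: float | None = None
    water_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.ice_temperature is not None and not self.ice_temperature < 0:
            raise ValueError(f"{self.date}/{self.site}: ice temperature must be < 0 degC")
        if self.bulk_salinity is not None and self.bulk_salinity < 0:
            raise ValueError(f"{self.date}/{self.site}: bulk salinity must be >= 0")
        for nut in ("si", "nox", "po4"):
            v = getattr(self, nut)
            if v is not None and v < 0:
                raise ValueError(f"{self.date}/{self.site}: {nut} must be >= 0")
        if self.albedo is not None and not 0 <= self.albedo <= 100:
            raise ValueError(f"{self.date}/{self.site}: albedo must be in [0, 100] %")


@dataclass(frozen=True)
class BrineState:
    brine_salinity: float  # ppt
    brine_volume_fraction: float  # % of ice volume


def brine_salinity(t_ice: float) -> float:
    """Brine salinity (ppt) from ice temperature (degC).

    Strictly decreasing in T on its domain.  T >= 0 raises (no brine in
    melting ice); temperatures below -22.9 degC fall outside the
    relation's stated validity and emit a warning.
    """
    t = float(t_ice)
    if t >= 0:
        raise ValueError(f"no brine at ice temperature {t} degC (requires T < 0)")
    if t < _FG_VALID_MIN:
        warnings.warn(
            f"ice temperature {t} degC below the relation's validity range "
            f"({_FG_VALID_MIN} degC); extrapolating"
        )
    return 1000.0 / (1.0 - 54.11 / t)


def _brine_density(sb: float) -> float:
    return 1000.0 + 0.8 * sb  # kg/m3


def brine_volume_fraction(s_bulk: float, t_ice: float, method: str = "density_ratio") -> float:
    """Brine volume as % of ice volume from bulk salinity and temperature.

    ``method='density_ratio'`` (default) reproduces the packaged ice-core
    table within +/-1 percentage point; ``method='cox_weeks'`` uses the
    Cox-Weeks phase-relation polynomials instead.
    """
    s = float(s_bulk)
    if s < 0:
        raise ValueError("bulk salinity must be >= 0")
    if s == 0:
        if t_ice >= 0:
            raise ValueError(f"no brine at ice temperature {t_ice} degC (requires T < 0)")
        return 0.0
    if method == "density_ratio":
        sb = brine_salinity(t_ice)
        return (s / sb) * (RHO_ICE / _brine_density(sb)) * 100.0
    if method == "cox_weeks":
        t = float(t_ice)
        if t >= 0:
            raise ValueError(f"no brine at ice temperature {t} degC (requires T < 0)")
        if t < _FG_VALID_MIN:
            warnings.warn("temperature below Cox-Weeks validity range; extrapolating")
        if t >= -2.0:
            f1 = -4.1221e-2 + -18.407 * t + 5.8402e-1 * t**2 + 2.1454e-1 * t**3
            f1 = abs(f1)
        else:
            f1 = -4.732 - 22.45 * t - 6.397e-1 * t**2 - 1.074e-2 * t**3
        rho = 0.917 - 1.403e-4 * t  # Mg/m3
        return (rho * s / f1) * 100.0
    raise ValueError(f"unknown brine-volume method {method!r}")


def brine_state(s_bulk: float, t_ice: float, method: str = "density_ratio") -> BrineState:
    return BrineState(
        brine_salinity=brine_salinity(t_ice),
        brine_volume_fraction=brine_volume_fraction(s_bulk, t_ice, method=method),
    )


def albedo(incoming_par: float, reflected_par: float) -> float:
    """Albedo (%) = 100 * reflected PAR / incoming PAR."""
    if incoming_par <= 0:
        raise ValueError("incoming PAR must be > 0")
    if reflected_par < 0:
        raise ValueError("reflected PAR must be >= 0")
    if reflected_par > incoming_par:
        raise ValueError("reflected PAR cannot exceed incoming PAR")
    return 100.0 * reflected_par / incoming_par


# ---------------------------------------------------------------------------
# Nutrient stoichiometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NutrientRatios:
    n_si: float | None
    si_p: float | None
    nitrogen_limited: bool | None
    silicate_limited: bool | None


def _detected(value: float | None, key: str) -> float | None:
    """Below-detection values are treated as missing, never as zero."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value <= DETECTION_LIMITS[key]:
        return None
    return float(value)


def nutrient_ratios(r: IceCoreRecord, nitrogen_threshold: float = 1.0) -> NutrientRatios:
    """Molar N:Si and Si:P with amended-Redfield limitation flags.

    N:Si = NOx/Si and Si:P = Si/PO4, computed only where the denominator
    is detected.  Flags: nitrogen_limited when NOx falls below the
    (configurable) threshold; silicate_limited when N:Si exceeds 16/15 or
    Si:P falls below 15.  Missing inputs propagate to ``None`` flags where
    nothing can be concluded.
    """
    nox = _detected(r.nox, "nox")
    si = _detected(r.si, "si")
    po4 = _detected(r.po4, "po4")
    n_si = (nox / si) if (nox is not None and si is not None) else None
    si_p = (si / po4) if (si is not None and po4 is not None) else None
    nitrogen_limited = None if nox is None else bool(nox < nitrogen_threshold)
    ref_n_si = STOICHIOMETRY_REFERENCE["N"] / STOICHIOMETRY_REFERENCE["Si"]
    ref_si_p = STOICHIOMETRY_REFERENCE["Si"] / STOICHIOMETRY_REFERENCE["P"]
    checks = []
    if n_si is not None:
        checks.append(n_si > ref_n_si)
    if si_p is not None:
        checks.append(si_p < ref_si_p)
    silicate_limited = any(checks) if checks else None
    return NutrientRatios(n_si=n_si, si_p=si_p,
                          nitrogen_limited=nitrogen_limited,
                          silicate_limited=silicate_limited)


# ---------------------------------------------------------------------------
# Seasonal summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesSummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int


def summarize_series(values: Iterable[float], single_value_sd: float = float("nan")) -> SeriesSummary:
    """Mean, sample sd (ddof=1), min and max of a series.

    For a single value the sd is undefined and reported as
    ``single_value_sd`` (NaN by default, configurable to 0).
    """
    vals = np.asarray([v for v in values], dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("summarize_series requires at least one non-missing value")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float(single_value_sd)
    return SeriesSummary(mean=float(np.mean(vals)), sd=sd,
                         min=float(np.min(vals)), max=float(np.max(vals)),
                         n=int(vals.size))


# ---------------------------------------------------------------------------
# Packaged ice-core table
# ---------------------------------------------------------------------------

_NUMERIC_COLS = [
    "snow_depth_cm", "snow_depth_sd", "albedo_pct", "ice_thickness_cm",
    "ice_thickness_sd", "ice_temperature_c", "bulk_salinity_ppt",
    "brine_salinity_ppt", "brine_volume_pct", "chl_a_ice", "chl_a_ice_sd",
    "cn_ratio", "d13c", "d15n", "si_um", "nox_um", "po4_um", "chl_a_water",
    "cn_ratio_water", "d13c_water", "d15n_water", "si_water_um",
    "nox_water_um", "po4_water_um", "water_temperature_c",
]


def load_environment_table(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged site x date ice-core/water table (8 rows, 2 sites).

    Not-detected cells are NaN; the printed brine salinity and brine
    volume columns are retained for round-trip validation of the physics.
    """
    if path is None:
        path = Path(str(resources.files("icealgae").joinpath("data/ice_cores.csv")))
    df = pd.read_csv(path, comment="#", dtype={"week": str})
    for c in _NUMERIC_COLS:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def _nan_to_none(v) -> float | None:
    return None if pd.isna(v) else float(v)


def environment_records(df: pd.DataFrame | None = None) -> list[IceCoreRecord]:
    if df is None:
        df = load_environment_table()
    records = []
    for _, r in df.iterrows():
        records.append(
            IceCoreRecord(
                date=str(r["date"]), site=str(r["site"]), week=str(r["week"]),
                snow_depth=_nan_to_none(r.get("snow_depth_cm")),
                snow_depth_sd=_nan_to_none(r.get("snow_depth_sd")),
                albedo=_nan_to_none(r.get("albedo_pct")),
                ice_thickness=_nan_to_none(r.get("ice_thickness_cm")),
                ice_thickness_sd=_nan_to_none(r.get("ice_thickness_sd")),
                ice_temperature=_nan_to_none(r.get("ice_temperature_c")),
                bulk_salinity=_nan_to_none(r.get("bulk_salinity_ppt")),
                chl_a_ice=_nan_to_none(r.get("chl_a_ice")),
                chl_a_water=_nan_to_none(r.get("chl_a_water")),
                cn_ratio=_nan_to_none(r.get("cn_ratio")),
                d13c=_nan_to_none(r.get("d13c")),
                d15n=_nan_to_none(r.get("d15n")),
                si=_nan_to_none(r.get("si_um")),
                nox=_nan_to_none(r.get("nox_um")),
                po4=_nan_to_none(r.get("po4_um")),
                water_temperature=_nan_to_none(r.get("water_temperature_c")),
            )
        )
    return records


def site_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-site seasonal summaries of the key measured/derived quantities."""
    if df is None:
        df = load_environment_table()
    rows = []
    for site, sub in df.groupby("site"):
        recs = environment_records(sub)
        derived = {
            "bulk_salinity_ppt": [r.bulk_salinity for r in recs],
            "brine_salinity_ppt": [brine_salinity(r.ice_temperature) for r in recs],
            "brine_volume_pct": [
                brine_volume_fraction(r.bulk_salinity, r.ice_temperature) for r in recs
            ],
            "nox_um": [r.nox for r in recs],
            "si_um": [r.si for r in recs],
            "po4_um": [r.po4 for r in recs],
            "n_si": [nutrient_ratios(r).n_si for r in recs],
            "si_p": [nutrient_ratios(r).si_p for r in recs],
        }
        for key, vals in derived.items():
            clean = [v for v in vals if v is not None]
            if not clean:
                continue
            s = summarize_series(clean)
            rows.append({"site": site, "variable": key, "mean": s.mean,
                         "sd": s.sd, "min": s.min, "max": s.max, "n": s.n})
    return pd.DataFrame(rows)
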