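"""IR band registry and band-area quantification on preprocessed spectra.

Second-derivative absorption peaks are negative-lobed, so band areas are
taken over a rectified signal: by default the positive side-lobes inside
the integration window are zero-clipped and the magnitude of the negative
lobe is integrated (trapezoid rule).  This is the only nonnegative choice
that stays linear in the amplitude of a pure injected peak.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import Spectrum

__all__ = [
    "BandAssignment",
    "CellBiomolecularProfile",
    "default_band_registry",
    "load_band_registry",
    "registry_by_name",
    "validate_registry",
    "integrate_band",
    "integrate_bands",
    "profile_cell",
    "profiles_to_frame",
    "NormalityResult",
    "normality_check",
    "safa_usfa_ratio",
]

#: Band names entering the SAFA:USFA ratio.
SAFA_BANDS = ("lipid_ch2_asym", "lipid_ch2_sym")
USFA_BAND = "lipid_unsaturated"


@dataclass(frozen=True)
class BandAssignment:
    """One named IR band: centre, integration window and assignment text."""

    name: str
    centre: float
    window: tuple[float, float]
    assignment: str = ""
    biomolecule_class: str = "storage"
    reference: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < self.centre < hi:
            raise ValueError(
                f"band {self.name!r}: centre {self.centre} outside window [{lo}, {hi}]"
            )
        if self.biomolecule_class not in ("storage", "functional"):
            raise ValueError(f"band {self.name!r}: unknown class {self.biomolecule_class!r}")

    @property
    def width(self) -> float:
        return self.window[1] - self.window[0]


def _registry_path() -> Path:
    return Path(str(resources.files("icealgae").joinpath("data/band_registry.csv")))


def load_band_registry(path: str | Path) -> list[BandAssignment]:
    """Load a band registry CSV (name, centre, window_lo, window_hi, class...)."""
    df = pd.read_csv(path, comment="#")
    required = {"name", "centre", "window_lo", "window_hi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: registry missing columns {sorted(missing)}")
    bands = [
        BandAssignment(
            name=str(r["name"]),
            centre=float(r["centre"]),
            window=(float(r["window_lo"]), float(r["window_hi"])),
            assignment=str(r.get("assignment", "")),
            biomolecule_class=str(r.get("biomolecule_class", "storage")),
            reference=str(r.get("reference", "")),
        )
        for _, r in df.iterrows()
    ]
    validate_registry(bands)
    return bands


def default_band_registry() -> list[BandAssignment]:
    """The nine-band registry shipped with the package.

    Centres: 3011, 2921, 2852, 1744, 1549, 1400, 1241, 1168 (window
    1146-1191) and 1080 cm^-1.  Window half-widths are +/-15 cm^-1 for the
    sharp CH-stretch bands and +/-25 cm^-1 in the fingerprint region; the
    carbohydrate window is fixed at [1146, 1191].
    """
    return load_band_registry(_registry_path())


def registry_by_name(registry: Sequence[BandAssignment]) -> dict[str, BandAssignment]:
    return {b.name: b for b in registry}


def validate_registry(registry: Sequence[BandAssignment]) -> None:
    """Warn when two band windows overlap by more than 25% of the narrower."""
    for i, a in enumerate(registry):
        for b in registry[i + 1:]:
            lo = max(a.window[0], b.window[0])
            hi = min(a.window[1], b.window[1])
            overlap = max(0.0, hi - lo)
            if overlap > 0.25 * min(a.width, b.width):
                warnings.warn(
                    f"band windows of {a.name!r} and {b.name!r} overlap by "
                    f"{overlap:.0f} cm^-1 (> 25% of the narrower window)"
                )


# ---------------------------------------------------------------------------
# Area integration
# ---------------------------------------------------------------------------

def integrate_band(s: Spectrum, band: BandAssignment, rectify: str = "clip") -> float:
    """Trapezoidal band area of the rectified second-derivative signal.

    ``rectify='clip'`` integrates ``max(-y, 0)`` (negative lobes carry the
    peak; positive side-lobes are zero-clipped); ``rectify='abs'``
    integrates ``|y|``.  Requires a derivative- or normalized-stage
    spectrum whose grid covers the band window.
    """
    if s.stage not in ("derivative", "normalized"):
        raise ValueError(
            f"band integration requires a derivative/normalized spectrum, got {s.stage!r}"
        )
    lo, hi = band.window
    wmin, wmax = float(np.min(s.wavenumbers)), float(np.max(s.wavenumbers))
    if lo < wmin or hi > wmax:
        raise ValueError(
            f"band {band.name!r} window [{lo}, {hi}] outside grid [{wmin}, {wmax}]"
        )
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if mask.sum() < 2:
        raise ValueError(f"band {band.name!r}: fewer than 2 grid points in window")
    x = s.wavenumbers[mask]
    y = s.absorbance[mask]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if rectify == "clip":
        r = np.clip(-y, 0.0, None)
    elif rectify == "abs":
        r = np.abs(y)
    else:
        raise ValueError(f"unknown rectify mode {rectify!r}")
    return float(np.trapezoid(r, x))


def integrate_bands(s: Spectrum, registry: Sequence[BandAssignment],
                    rectify: str = "clip") -> dict[str, float]:
    return {b.name: integrate_band(s, b, rectify=rectify) for b in registry}


# ---------------------------------------------------------------------------
# Per-cell aggregation
# ---------------------------------------------------------------------------

@dataclass
class CellBiomolecularProfile:
    """Per-cell band areas: mean over the cell's point spectra."""

    cell_id: str
    site: str | None
    week: str | None
    areas: dict[str, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        for name, a in self.areas.items():
            if a < 0:
                raise ValueError(f"negative area for band {name!r}")

    @property
    def log10_areas(self) -> dict[str, float]:
        """log10 of each area; zero areas map to NaN (missing)."""
        return {k: (math.log10(v) if v > 0 else math.nan) for k, v in self.areas.items()}


def profile_cell(points: Sequence[Spectrum], registry: Sequence[BandAssignment],
                 rectify: str = "clip") -> CellBiomolecularProfile:
    """Aggregate one cell's point spectra into a biomolecular profile.

    Per-band area is the arithmetic mean over the cell's points; all point
    spectra must share one ``cell_id``.
    """
    points = list(points)
    if not points:
        raise ValueError("profile_cell requires at least one point spectrum")
    cell_ids = {p.cell_id for p in points}
    if len(cell_ids) != 1:
        raise ValueError(f"mixed cell_ids in profile_cell: {sorted(map(str, cell_ids))}")
    per_point = [integrate_bands(p, registry, rectify=rectify) for p in points]
    areas = {
        b.name: float(np.mean([pp[b.name] for pp in per_point])) for b in registry
    }
    ref = points[0]
    return CellBiomolecularProfile(
        cell_id=str(ref.cell_id), site=ref.site, week=ref.week,
        areas=areas, n_points=len(points),
    )


def profiles_to_frame(profiles: Iterable[CellBiomolecularProfile]) -> pd.DataFrame:
    """Tidy table: one row per (cell, band) with area and log10_area."""
    rows = []
    for p in profiles:
        logs = p.log10_areas
        for band, area in p.areas.items():
            rows.append(
                {
                    "cell_id": p.cell_id,
                    "site": p.site,
                    "week": p.week,
                    "band": band,
                    "area": area,
                    "log10_area": logs[band],
                    "n_points": p.n_points,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution checks and derived ratios
# ---------------------------------------------------------------------------

@dataclass
class NormalityResult:
    w: float
    p: float
    transformed: bool
    w_log: float | None = None
    p_log: float | None = None
    n_excluded: int = 0


def normality_check(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk on raw values; retried on log10 values when rejected.

    When the raw test rejects at ``alpha``, the test is repeated on log10
    of the positive values and the transform is flagged for downstream
    use.  Nonpositive values are excluded from the log test with the count
    reported.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 3:
        raise ValueError(f"normality check requires n >= 3, got n = {vals.size}")
    w, p = sps.shapiro(vals)
    if p >= alpha:
        return NormalityResult(w=float(w), p=float(p), transformed=False)
    pos = vals[vals > 0]
    n_excluded = int(vals.size - pos.size)
    if pos.size < 3:
        raise ValueError("too few positive values for log10 normality check")
    w_log, p_log = sps.shapiro(np.log10(pos))
    return NormalityResult(
        w=float(w), p=float(p), transformed=True,
        w_log=float(w_log), p_log=float(p_log), n_excluded=n_excluded,
    )


def safa_usfa_ratio(profile: CellBiomolecularProfile) -> float:
    """Saturated-to-unsaturated fatty-acid band ratio for one cell.

    (area ~2921 + area ~2852) / (area ~3011); NaN with a warning when the
    unsaturated band area is zero.
    """
    try:
        usfa = profile.areas[USFA_BAND]
        safa = sum(profile.areas[b] for b in SAFA_BANDS)
    except KeyError as e:
        raise ValueError(f"profile lacks band {e.args[0]!r}") from None
    if usfa <= 0:
        warnings.warn(f"cell {profile.cell_id}: zero unsaturated-FA area; ratio undefined")
        return math.nan
    return safa / usfa
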