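"""Spectrum data model, wide-CSV I/O and the spectral preprocessing chain.

The preprocessing chain applied to every point spectrum is::

    raw  --Savitzky-Golay second derivative-->  derivative  --SNV-->  normalized

Order is enforced through the ``stage`` tag carried by each
:class:`Spectrum`; the Savitzky-Golay step refuses anything but a raw
spectrum, so derivative/normalised data cannot be differentiated twice by
accident.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "read_spectra",
    "write_spectra",
    "savitzky_golay_second_derivative",
    "snv",
    "crop",
    "concatenate_ranges",
    "preprocess",
    "DEFAULT_ANALYSIS_RANGES",
]

#: Wavenumber windows (cm^-1) over which the biomolecular bands live; SNV is
#: computed over the union of these by default (CH-stretch + fingerprint).
DEFAULT_ANALYSIS_RANGES: tuple[tuple[float, float], ...] = (
    (2800.0, 3050.0),
    (1000.0, 1770.0),
)

_STAGES = ("raw", "derivative", "normalized")

#: Relative tolerance on grid-spacing constancy required for derivatives.
_UNIFORM_RTOL = 1e-6


@dataclass
class Spectrum:
    """A single point measurement of absorbance over a wavenumber grid.

    Parameters
    ----------
    wavenumbers
        Strictly monotone grid in cm^-1 (ascending or descending).
    absorbance
        Values of the same length; dimensionless absorbance for ``raw``
        spectra, absorbance * cm^2 after the second derivative.
    point_id, cell_id, site, week
        Free-text metadata labels; ``None`` when unknown.
    stage
        One of ``raw``, ``derivative``, ``normalized``.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    point_id: str | None = None
    cell_id: str | None = None
    site: str | None = None
    week: str | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D arrays")
        if self.wavenumbers.size == 0:
            raise ValueError("empty wavenumber grid")
        if self.wavenumbers.size != self.absorbance.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber values")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("non-finite absorbance values")
        d = np.diff(self.wavenumbers)
        if self.wavenumbers.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")

    # -- convenience -------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.wavenumbers.size)

    def spacing(self) -> float:
        """Absolute grid spacing; raises when the grid is not uniform."""
        d = np.diff(self.wavenumbers)
        if d.size == 0:
            raise ValueError("spacing undefined for single-point spectrum")
        h = d[0]
        if np.max(np.abs(d - h)) > _UNIFORM_RTOL * abs(h):
            raise ValueError("wavenumber grid is not uniform")
        return float(abs(h))

    def is_uniform(self) -> bool:
        try:
            self.spacing()
        except ValueError:
            return False
        return True

    def replace_values(self, absorbance: np.ndarray, stage: str | None = None) -> "Spectrum":
        return replace(self, absorbance=np.asarray(absorbance, float),
                       stage=self.stage if stage is None else stage)


# ---------------------------------------------------------------------------
# I/O: wide CSV (first column wavenumber, one column per point spectrum)
# ---------------------------------------------------------------------------

_META_COLS = ("point_id", "cell_id", "site", "week")


def write_spectra(spectra: Sequence[Spectrum], path: str | Path,
                  metadata_path: str | Path | None = None) -> None:
    """Write spectra to wide CSV plus a metadata sidecar table.

    All spectra must share the same wavenumber grid and stage.  The sidecar
    defaults to ``<path stem>_meta.csv``.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.n != spectra[0].n or not np.array_equal(s.wavenumbers, grid):
            raise ValueError("all spectra in one file must share one wavenumber grid")
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_name(path.stem + "_meta.csv")
    cols = {"wavenumber": grid}
    for i, s in enumerate(spectra):
        pid = s.point_id if s.point_id is not None else f"point_{i:04d}"
        if pid in cols:
            raise ValueError(f"duplicate point id {pid!r}")
        cols[pid] = s.absorbance
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = pd.DataFrame(
        [
            {
                "point_id": s.point_id if s.point_id is not None else f"point_{i:04d}",
                "cell_id": s.cell_id,
                "site": s.site,
                "week": s.week,
            }
            for i, s in enumerate(spectra)
        ]
    )
    meta.to_csv(metadata_path, index=False)


def read_spectra(path: str | Path, metadata_path: str | Path | None = None,
                 stage: str = "raw") -> list[Spectrum]:
    """Read a wide-CSV spectra file (and metadata sidecar if present).

    Points without a metadata row are retained with null metadata and a
    warning; ragged rows, non-numeric cells, duplicated or non-monotone
    wavenumbers raise with row/column context.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a wavenumber column plus >=1 spectrum column")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric cell at row {row + 2}, column {col!r}")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
        df[col] = vals
    wn = df.iloc[:, 0].to_numpy(float)
    if pd.Series(wn).duplicated().any():
        dup = pd.Series(wn)[pd.Series(wn).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated wavenumber row ({dup:g} cm^-1)")
    d = np.diff(wn)
    if wn.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{path}: wavenumber column is not monotone")

    if metadata_path is None:
        candidate = path.with_name(path.stem + "_meta.csv")
        metadata_path = candidate if candidate.exists() else None
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, dtype=str, comment="#")
        missing = [c for c in _META_COLS if c not in mdf.columns]
        if missing:
            raise ValueError(f"{metadata_path}: missing metadata columns {missing}")
        meta = {row["point_id"]: row for _, row in mdf.iterrows()}

    out: list[Spectrum] = []
    for col in df.columns[1:]:
        m = meta.get(str(col))
        if meta and m is None:
            warnings.warn(f"no metadata row for point {col!r}; retained with null metadata")
        out.append(
            Spectrum(
                wavenumbers=wn.copy(),
                absorbance=df[col].to_numpy(float),
                point_id=str(col),
                cell_id=None if m is None else _opt(m["cell_id"]),
                site=None if m is None else _opt(m["site"]),
                week=None if m is None else _opt(m["week"]),
                stage=stage,
            )
        )
    return out


def _opt(v) -> str | None:
    return None if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def savitzky_golay_second_derivative(
    s: Spectrum,
    half_window: int = 4,
    polyorder: int = 3,
    edge: str = "drop",
) -> Spectrum:
    """Smoothed second derivative in a single Savitzky-Golay pass.

    The default 9-point window (four points either side) with a cubic
    polynomial smooths and differentiates in one filter application.  The
    output is scaled by 1/h^2 (h = grid spacing in cm^-1) so values carry
    physical units of absorbance * cm^2.

    ``edge='drop'`` removes ``half_window`` samples at each end of the grid
    (the fitted polynomial is not trusted outside the interior);
    ``edge='keep'`` retains scipy's polynomial-extrapolated edge values.
    """
    if s.stage != "raw":
        raise ValueError(f"second derivative requires a raw spectrum, got stage {s.stage!r}")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    window = 2 * half_window + 1
    if window > s.n:
        raise ValueError(f"window of {window} points exceeds spectrum length {s.n}")
    if not (2 <= polyorder < window):
        raise ValueError("polyorder must satisfy 2 <= polyorder < window")
    h = s.spacing()  # raises on non-uniform grids
    d2 = savgol_filter(s.absorbance, window_length=window, polyorder=polyorder,
                       deriv=2, delta=h)
    if edge == "drop":
        sl = slice(half_window, s.n - half_window)
        return replace(s, wavenumbers=s.wavenumbers[sl], absorbance=d2[sl],
                       stage="derivative")
    if edge == "keep":
        return s.replace_values(d2, stage="derivative")
    raise ValueError(f"unknown edge mode {edge!r}")


def snv(s: Spectrum) -> Spectrum:
    """Standard Normal Variate: per-spectrum centring and unit scaling.

    Uses the sample standard deviation (ddof=1).  Raises on spectra with
    fewer than two points or zero variance.
    """
    if s.n < 2:
        raise ValueError("SNV requires at least 2 points")
    sd = float(np.std(s.absorbance, ddof=1))
    if sd == 0.0:
        raise ValueError("SNV undefined for a zero-variance (degenerate) spectrum")
    vals = (s.absorbance - float(np.mean(s.absorbance))) / sd
    return s.replace_values(vals, stage="normalized")


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Retain samples with lo <= wavenumber <= hi (inclusive both ends)."""
    if not lo < hi:
        raise ValueError(f"crop bounds must satisfy lo < hi, got ({lo}, {hi})")
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"crop to [{lo}, {hi}] cm^-1 leaves no samples")
    return replace(s, wavenumbers=s.wavenumbers[mask], absorbance=s.absorbance[mask])


def concatenate_ranges(s: Spectrum, ranges: Iterable[tuple[float, float]]) -> Spectrum:
    """Crop to the union of wavenumber ranges, preserving grid direction."""
    ranges = list(ranges)
    if not ranges:
        raise ValueError("no analysis ranges given")
    mask = np.zeros(s.n, dtype=bool)
    for lo, hi in ranges:
        if not lo < hi:
            raise ValueError(f"range bounds must satisfy lo < hi, got ({lo}, {hi})")
        mask |= (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError("analysis ranges do not overlap the spectrum grid")
    return replace(s, wavenumbers=s.wavenumbers[mask], absorbance=s.absorbance[mask])


def preprocess(
    s: Spectrum,
    half_window: int = 4,
    polyorder: int = 3,
    analysis_ranges: Iterable[tuple[float, float]] = DEFAULT_ANALYSIS_RANGES,
    normalize: bool = True,
) -> Spectrum:
    """Full chain: SG second derivative, crop to analysis ranges, then SNV.

    SNV statistics are computed over the cropped analysis range (the
    analysed signal), not the full acquisition range; set
    ``analysis_ranges`` to the full grid span to get full-range SNV, or
    ``normalize=False`` to stop at the derivative stage (used for
    amount-recovery checks, since SNV deliberately removes per-spectrum
    scale).
    """
    d2 = savitzky_golay_second_derivative(s, half_window=half_window, polyorder=polyorder)
    cropped = concatenate_ranges(d2, analysis_ranges)
    return snv(cropped) if normalize else cropped
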