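"""Synthetic single-cell spectra, cohorts and environmental tables.

Spectra are Gaussian band mixtures over a smooth polynomial baseline with
iid Gaussian noise.  Each injected band contributes
``amount * exp(-(v - centre)^2 / (2 sigma^2))``, so the analytic area of a
band is ``amount * sigma * sqrt(2*pi)`` — a Beer-Lambert stand-in where
``amount`` plays the role of concentration.  Every generator is a pure
function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import BandAssignment, default_band_registry, registry_by_name
from .environment import IceCoreRecord
from .spectra import Spectrum

__all__ = [
    "BandConcentration",
    "GroupSpec",
    "CohortDesign",
    "default_grid",
    "default_sigma",
    "generate_cell_spectrum",
    "generate_cohort",
    "generate_environment_table",
]

#: Default Gaussian widths (cm^-1): sharper bands in the CH-stretch region,
#: broader ones in the fingerprint region.
SIGMA_CH_REGION = 8.0
SIGMA_FINGERPRINT = 12.0


def default_grid() -> np.ndarray:
    """The acquisition grid: 4000 down to 800 cm^-1 at 4 cm^-1 steps."""
    return np.arange(4000.0, 799.0, -4.0)


def default_sigma(centre: float) -> float:
    return SIGMA_CH_REGION if centre >= 2800.0 else SIGMA_FINGERPRINT


@dataclass(frozen=True)
class BandConcentration:
    """Injected amount (peak height) and Gaussian width for one band."""

    band_name: str
    amount: float
    peak_sigma: float | None = None  # None -> region default

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"band {self.band_name!r}: amount must be >= 0")
        if self.peak_sigma is not None and self.peak_sigma <= 0:
            raise ValueError(f"band {self.band_name!r}: peak_sigma must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """One site x week cohort group."""

    site: str
    week: str
    n_cells: int
    composition: Mapping[str, float]  # band name -> mean amount
    cv: float = 0.0  # between-cell coefficient of variation

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"group {self.site}/{self.week}: n_cells must be >= 1")
        if self.cv < 0:
            raise ValueError(f"group {self.site}/{self.week}: cv must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    groups: tuple[GroupSpec, ...]
    noise_sd: float = 0.0
    baseline_coefficients: tuple[float, ...] = ()
    points_per_cell: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.baseline_coefficients) > 4:
            raise ValueError("baseline polynomial degree must be <= 3")
        if self.points_per_cell < 1:
            raise ValueError("points_per_cell must be >= 1")


def _baseline(grid: np.ndarray, coefficients: Sequence[float]) -> np.ndarray:
    """Polynomial baseline evaluated on the grid scaled to [0, 1].

    Coefficients are low-order first in u = (v - v_min)/(v_max - v_min);
    the unit-interval parametrisation keeps coefficient magnitudes
    interpretable as absorbance offsets.
    """
    if not coefficients:
        return np.zeros_like(grid)
    span = grid.max() - grid.min()
    u = (grid - grid.min()) / span if span > 0 else np.zeros_like(grid)
    return np.polynomial.polynomial.polyval(u, np.asarray(coefficients, float))


def generate_cell_spectrum(
    composition: Sequence[BandConcentration],
    baseline_coefficients: Sequence[float] = (),
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
    registry: Sequence[BandAssignment] | None = None,
    **metadata: str | None,
) -> Spectrum:
    """One synthetic point spectrum from a band composition.

    Absorbance = sum of Gaussians (height = amount) + baseline polynomial
    + iid Gaussian noise.  Bands whose centre falls outside the grid raise
    an error naming the band.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if registry is None:
        registry = default_band_registry()
    by_name = registry_by_name(registry)

    signal = _baseline(grid, baseline_coefficients)
    lo, hi = float(grid.min()), float(grid.max())
    for bc in composition:
        if bc.band_name not in by_name:
            raise KeyError(f"unknown band {bc.band_name!r} (not in registry)")
        band = by_name[bc.band_name]
        if not lo <= band.centre <= hi:
            raise ValueError(
                f"band {bc.band_name!r} centre {band.centre} cm^-1 outside grid "
                f"[{lo}, {hi}]"
            )
        sigma = bc.peak_sigma if bc.peak_sigma is not None else default_sigma(band.centre)
        signal = signal + bc.amount * np.exp(-((grid - band.centre) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(wavenumbers=grid, absorbance=signal, stage="raw", **metadata)


def generate_cohort(
    design: CohortDesign,
    registry: Sequence[BandAssignment] | None = None,
    grid: np.ndarray | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate a cohort of cells plus the ground-truth amount table.

    Between-cell variability is lognormal with the requested mean and CV
    (exact mean preservation; cv=0 gives every cell the group mean).  All
    point spectra of one cell share its drawn amounts and its ``cell_id``;
    points differ only by measurement noise.

    Returns ``(spectra, truth)`` where ``truth`` has one row per
    (cell, band) with the exact injected amount.
    """
    if registry is None:
        registry = default_band_registry()
    by_name = registry_by_name(registry)
    for g in design.groups:
        for name in g.composition:
            if name not in by_name:
                raise KeyError(f"unknown band {name!r} in group {g.site}/{g.week}")

    rng = np.random.default_rng(design.seed)
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    for g in design.groups:
        for i in range(g.n_cells):
            cell_id = f"{g.site}_{g.week}_c{i:03d}"
            amounts: dict[str, float] = {}
            for name, mean in g.composition.items():
                if mean < 0:
                    raise ValueError(f"negative mean amount for band {name!r}")
                if g.cv == 0 or mean == 0:
                    amounts[name] = float(mean)
                else:
                    # mean-preserving lognormal: E = mean, CV = g.cv
                    s2 = np.log1p(g.cv**2)
                    mu = np.log(mean) - s2 / 2
                    amounts[name] = float(rng.lognormal(mu, np.sqrt(s2)))
                truth_rows.append(
                    {"cell_id": cell_id, "site": g.site, "week": g.week,
                     "band": name, "amount": amounts[name]}
                )
            composition = [BandConcentration(n, a) for n, a in amounts.items()]
            for j in range(design.points_per_cell):
                point_seed = int(rng.integers(0, 2**63 - 1))
                spectra.append(
                    generate_cell_spectrum(
                        composition,
                        baseline_coefficients=design.baseline_coefficients,
                        noise_sd=design.noise_sd,
                        grid=grid,
                        seed=point_seed,
                        registry=registry,
                        point_id=f"{cell_id}_p{j}",
                        cell_id=cell_id,
                        site=g.site,
                        week=g.week,
                    )
                )
    return spectra, pd.DataFrame(truth_rows)


def generate_environment_table(
    seed: int, n_dates: int, site_labels: Sequence[str]
) -> list[IceCoreRecord]:
    """Synthetic ice-core/water records within physically plausible ranges.

    Ice temperature in [-10, -0.5] degC, bulk salinity in [2, 15] ppt,
    nutrients >= 0; every record passes the ice-core invariants.
    """
    if n_dates < 1:
        raise ValueError("n_dates must be >= 1")
    if not site_labels:
        raise ValueError("at least one site label required")
    rng = np.random.default_rng(seed)
    records: list[IceCoreRecord] = []
    for d in range(n_dates):
        for site in site_labels:
            t_ice = float(rng.uniform(-10.0, -0.5))
            # bulk salinity always below the brine salinity of the same ice
            sb = 1000.0 / (1.0 - 54.11 / t_ice)
            s_hi = min(15.0, 0.8 * sb)
            records.append(
                IceCoreRecord(
                    date=f"date_{d:02d}",
                    week=str(d + 1),
                    site=str(site),
                    snow_depth=float(rng.uniform(5, 40)),
                    albedo=float(rng.uniform(40, 98)),
                    ice_thickness=float(rng.uniform(40, 120)),
                    ice_temperature=t_ice,
                    bulk_salinity=float(rng.uniform(2.0, s_hi)),
                    chl_a_ice=float(rng.lognormal(0.0, 0.8)),
                    chl_a_water=float(rng.lognormal(-1.5, 0.8)),
                    cn_ratio=float(rng.uniform(2.5, 12.0)),
                    d13c=float(rng.uniform(-32.0, -16.0)),
                    d15n=float(rng.uniform(0.5, 5.0)),
                    si=float(rng.lognormal(0.0, 1.0)),
                    nox=float(rng.lognormal(0.5, 1.0)),
                    po4=float(rng.lognormal(-1.0, 0.6)),
                    water_temperature=float(rng.uniform(-1.9, -1.4)),
                )
            )
    return records
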