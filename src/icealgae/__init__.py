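"""icealgae: single-cell FTIR biomolecular profiling of sea-ice algae.

Spectral preprocessing (Savitzky-Golay second derivative + SNV), band-area
quantification, sea-ice brine physics, nutrient stoichiometry, fatty-acid
class accounting and permutation-based multivariate statistics, with a
synthetic-data module standing in for synchrotron measurements.
"""

from .bands import (
    BandAssignment,
    CellBiomolecularProfile,
    default_band_registry,
    integrate_band,
    normality_check,
    profile_cell,
    safa_usfa_ratio,
)
from .environment import (
    IceCoreRecord,
    albedo,
    brine_salinity,
    brine_volume_fraction,
    load_environment_table,
    nutrient_ratios,
    summarize_series,
)
from .fatty_acids import FAClassSummary, class_sums, classify, load_fa_table, parse_fa_name
from .mvstats import anosim, bray_curtis, linear_regression, pca, rda
from .pipeline import PipelineConfig, compute_targets, reproduce_paper, run_pipeline
from .spectra import (
    Spectrum,
    crop,
    preprocess,
    read_spectra,
    savitzky_golay_second_derivative,
    snv,
    write_spectra,
)
from .synthetic import (
    BandConcentration,
    CohortDesign,
    GroupSpec,
    default_grid,
    generate_cell_spectrum,
    generate_cohort,
    generate_environment_table,
)

__version__ = "0.1.0"
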