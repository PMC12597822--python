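"""Somatic mtDNA hotspot inference and heteroplasmy-dosage analysis.

The package covers the computational arc of a population-scale tumor mtDNA
study: somatic-call filtering, trinucleotide-context mutability modelling
with a one-sided binomial recurrence test (hotspot detection),
germline-constraint and structural enrichment statistics, tissue and
nuclear co-occurrence tests, and a single-cell pipeline relating gene
expression to heteroplasmic dosage — plus seeded synthetic-data generators
so every stage runs without controlled-access data.
"""

from importlib import resources as _resources

import pandas as _pd

from .reference import (
    CONTEXTS,
    DEFAULT_BLACKLIST,
    DEFAULT_CONTROL_REGION,
    Gene,
    MtReference,
    PositionError,
    load_rcrs_gene_map,
    load_reference,
    synthetic_genome_sequence,
    toy_reference,
)
from .filtering import MalformedCallError, filter_somatic
from .hotspots import (
    ModelFitError,
    MutabilityModel,
    bh_adjust,
    binomial_upper_tail,
    detect_hotspots,
    fit_mutability,
    position_probability,
)
from .enrichment import (
    Fisher2x2Result,
    GermlineTable,
    conservation_comparison,
    constraint_enrichment,
    cooccurrence_tests,
    fisher_2x2,
    is_germline_constrained,
    mt_alteration_levels,
    structure_enrichment,
    tissue_enrichment,
)
from .simulate import (
    CohortSimConfig,
    EffectGene,
    SimConfigError,
    SingleCellSimConfig,
    SpikedHotspot,
    dosage_multiplier,
    expected_substitution_spectrum,
    heteroplasmy_mixture_cdf,
    simulate_annotations,
    simulate_cohort,
    simulate_germline_table,
    simulate_singlecell,
)
from .singlecell import (
    CorrelationResult,
    ThresholdScan,
    ZeroCoverageError,
    cell_heteroplasmy,
    compute_heteroplasmy,
    correlate_all_genes,
    covariate_regression,
    export_ranked_list,
    fisher_z,
    gene_het_correlation,
    qc_filter_cells,
    threshold_scan,
)

__version__ = "0.1.0"


def load_filter_fixture() -> tuple[_pd.DataFrame, list[str]]:
    """The packaged 12-row boundary fixture and its committed survivor IDs."""
    base = _resources.files("mthotspot.data")
    with _resources.as_file(base.joinpath("filter_fixture.tsv")) as p:
        fixture = _pd.read_csv(p, sep="\t", comment="#")
    with _resources.as_file(base.joinpath("filter_fixture_truth.tsv")) as p:
        truth = _pd.read_csv(p, sep="\t", comment="#")["sample_id"].tolist()
    return fixture, truth
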