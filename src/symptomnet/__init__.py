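"""symptomnet: regularized Ising symptom networks for binary clinical data.

Estimation (nodewise eLASSO with EBIC selection), centrality and
small-world inference, case-dropping bootstrap stability (CS-coefficient),
permutation-based network comparison (NCT), severity-adjusted symptom
frequency comparison, and an exact synthetic-cohort generator for Ising
ground truths under DSM-5 diagnostic constraints.
"""

__version__ = "0.1.0"

from .comparison import NCTResult, global_strength, nct
from .datasets import DSM5_SYMPTOMS, SymptomDataset, read_cohorts, write_cohorts
from .estimation import (
    CorrelationMatrix,
    EstimatorConfig,
    IsingNetwork,
    LayoutCoordinates,
    fit_ising,
    fr_layout,
    pearson_matrix,
)
from .frequency import adjusted_comparison, symptom_frequencies
from .metrics import (
    METRICS,
    CentralityTable,
    SmallWorldResult,
    betweenness,
    centrality_table,
    closeness,
    expected_influence,
    small_world,
    standardize,
    strength,
)
from .simulate import (
    CohortSpec,
    IsingParameters,
    calibrate_thresholds,
    enumerate_distribution,
    exact_marginals,
    gibbs_sample,
    paper_like_cohorts,
    paper_like_parameters,
    sample_cohort,
)
from .stability import StabilityResult, case_drop_bootstrap

__all__ = [
    "DSM5_SYMPTOMS",
    "METRICS",
    "AnalysisConfig",
    "CentralityTable",
    "CohortSpec",
    "CorrelationMatrix",
    "EstimatorConfig",
    "IsingNetwork",
    "IsingParameters",
    "LayoutCoordinates",
    "NCTResult",
    "SmallWorldResult",
    "StabilityResult",
    "SymptomDataset",
    "adjusted_comparison",
    "betweenness",
    "calibrate_thresholds",
    "case_drop_bootstrap",
    "centrality_table",
    "closeness",
    "enumerate_distribution",
    "exact_marginals",
    "expected_influence",
    "fit_ising",
    "fr_layout",
    "gibbs_sample",
    "global_strength",
    "nct",
    "paper_like_cohorts",
    "paper_like_parameters",
    "pearson_matrix",
    "read_cohorts",
    "run_pipeline",
    "sample_cohort",
    "small_world",
    "standardize",
    "strength",
    "symptom_frequencies",
    "write_cohorts",
]


def __getattr__(name):
    # pipeline imports back from the package root; load lazily
    if name in ("AnalysisConfig", "run_pipeline"):
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
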