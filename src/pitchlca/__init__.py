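"""pitchlca: latent class analysis of trial-by-trial vocal pitch-shift responses.

Pipeline stages: synthetic experiment generation (:mod:`pitchlca.simulate`),
per-trial f0 classification (:mod:`pitchlca.preprocess`), polytomous latent
class analysis (:mod:`pitchlca.lca`), latent class regression with the
stimulus-direction covariate (:mod:`pitchlca.regression`), and descriptive
reporting (:mod:`pitchlca.reporting`).
"""

from .matrix import DIRECTION_CODES, OUTCOME_CODES, ResponseMatrix
from .simulate import (
    F0Trace,
    LatentProfile,
    PerturbationSchedule,
    ResponseKinematics,
    default_profiles,
    generate_dataset,
    make_schedule,
    sample_response_sequence,
    synthesize_trace,
    truth_to_matrix,
)
from .preprocess import (
    ResponseRecord,
    TrialWindow,
    classify_response,
    extract_window,
    measure_onset,
    measure_peak,
    process_dataset,
    to_cents,
)
from .lca import (
    LatentClassAnalysis,
    fit_indices,
    fit_lca,
    loglikelihood,
    n_parameters,
    select_model,
)
from .regression import (
    DegreesOfFreedomError,
    LatentClassRegression,
    coefficient_table,
    fit_lca_regression,
    fit_phases,
    predicted_priors_table,
)
from .reporting import CountTable, acoustic_summary, count_table, transition_table

__version__ = "0.1.0"

__all__ = [
    "DIRECTION_CODES", "OUTCOME_CODES", "ResponseMatrix",
    "F0Trace", "LatentProfile", "PerturbationSchedule", "ResponseKinematics",
    "default_profiles", "generate_dataset", "make_schedule",
    "sample_response_sequence", "synthesize_trace", "truth_to_matrix",
    "ResponseRecord", "TrialWindow", "classify_response", "extract_window",
    "measure_onset", "measure_peak", "process_dataset", "to_cents",
    "LatentClassAnalysis", "fit_indices", "fit_lca", "loglikelihood",
    "n_parameters", "select_model",
    "DegreesOfFreedomError", "LatentClassRegression", "coefficient_table",
    "fit_lca_regression", "fit_phases", "predicted_priors_table",
    "CountTable", "acoustic_summary", "count_table", "transition_table",
]
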