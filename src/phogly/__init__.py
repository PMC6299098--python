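"""phogly: structure-based prediction of phosphoglycerylated lysine residues.

The pipeline: per-residue structural property tracks (ASA, coil/strand/helix
probabilities, backbone angles phi/psi/theta/tau) are windowed around each
annotated lysine with mirror padding at sequence termini, the heavy negative
class is thinned by a k-nearest-neighbour cleaning treatment, and a
single-hidden-layer momentum-SGD perceptron is evaluated by target
cross-validation (only training folds are rebalanced).  Property groups are
ranked by wrapper backward elimination on the mean cross-validated G-Mean.
"""

from .io import (
    PROPERTIES,
    FormatError,
    ProteinRecord,
    ResiduePropertyTable,
    SiteAnnotation,
    read_dataset,
    read_fasta,
    read_property_table,
    read_site_labels,
    write_dataset,
)
from .features import (
    FULL_MASK,
    FeatureDataset,
    PeptideWindow,
    SiteInstance,
    WindowError,
    apply_property_mask,
    build_dataset,
    build_site_vector,
    canonical_mask,
    window_indices,
)
from .imbalance import (
    CleaningReport,
    KNNCleaner,
    escalate_k,
    initial_k,
    knn_clean_at_k,
    pairwise_distance_table,
    rebalance_training,
)
from .mlp import (
    MLPConfig,
    MomentumMLPClassifier,
    classify,
    hidden_size_rule_a,
    predict_scores,
    train_mlp,
)
from .evaluation import (
    ConfusionCounts,
    CVResult,
    MetricSet,
    compute_metrics,
    confusion,
    roc_auc,
    score_metrics,
    target_cross_validate,
)
from .selection import (
    EliminationTrace,
    backward_eliminate,
    scan_window_sizes,
)
from .synth import SynthBundle, SynthConfig, generate, make_worked_toy, simulate

__version__ = "0.1.0"

__all__ = [
    "PROPERTIES", "FULL_MASK", "FormatError", "WindowError",
    "ProteinRecord", "ResiduePropertyTable", "SiteAnnotation",
    "read_fasta", "read_property_table", "read_site_labels",
    "read_dataset", "write_dataset",
    "PeptideWindow", "SiteInstance", "FeatureDataset",
    "window_indices", "build_site_vector", "build_dataset",
    "apply_property_mask", "canonical_mask",
    "CleaningReport", "KNNCleaner", "pairwise_distance_table",
    "knn_clean_at_k", "escalate_k", "rebalance_training", "initial_k",
    "MLPConfig", "MomentumMLPClassifier", "train_mlp", "predict_scores",
    "classify", "hidden_size_rule_a",
    "ConfusionCounts", "MetricSet", "CVResult", "confusion",
    "compute_metrics", "roc_auc", "score_metrics", "target_cross_validate",
    "EliminationTrace", "backward_eliminate", "scan_window_sizes",
    "SynthBundle", "SynthConfig", "simulate", "generate", "make_worked_toy",
]
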