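"""End-to-end orchestration: windows -> features -> embedding -> microstates.

``run_pipeline`` chains the library stages with one configuration object and
one seed, and returns every intermediate product.  Preprocessing is either
``"basic"`` (per-channel z-score + 0.5-45 Hz band-pass; the band-pass already
excludes mains frequency and most ocular energy from the analysis band) or
``"ica"`` (additionally decompose each window and subtract flagged blink and
line-noise components, collecting per-window artifact reports).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import cluster as clu
from . import dynamics as dyn
from .features import FeatureConfig, extract_feature_matrix
from .preprocess import ArtifactReport, bandpass, clean_window, zscore_normalize
from .reduce import ReductionResult, reduce_features
from .segment import segment_dataset
from .types import FeatureMatrix, PreictalWindow, SegmentSet

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "preprocess_windows",
    "run_pipeline",
    "k_selection_preset",
]


@dataclass
class PipelineConfig:
    """Every stage's tunable parameters, with the study defaults."""

    window_s: float = 30.0
    seg_len_s: float = 5.0
    bandpass_low: float = 0.5
    bandpass_high: float = 45.0
    bandpass_order: int = 4
    preprocess: str = "ica"          # "basic" | "ica" | "none"
    mains_hz: float = 50.0
    ica_max_iter: int = 200
    pca_var_threshold: float = 0.95
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    umap_metric: str = "euclidean"
    k_min: int = 2
    k_max: int = 10
    kmeans_n_init: int = 10
    min_cluster_size: int = 20
    smoothing_window: int = 2
    seed: int = 42
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if self.preprocess not in ("basic", "ica", "none"):
            raise ValueError(f"unknown preprocess mode {self.preprocess!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    segments: SegmentSet
    features: FeatureMatrix
    reduction: ReductionResult
    selected_k: int
    elbow_k: int
    silhouette_k: int
    k_diagnostics: dict
    clustering: clu.ClusterResult
    filtered: clu.ClusterResult
    removed_mask: np.ndarray
    validation_pre: clu.ValidationReport
    validation_post: clu.ValidationReport
    sequences: list[dyn.LabelSequence]
    smoothed_sequences: list[dyn.LabelSequence]
    transitions: dyn.TransitionMatrix
    dynamics: dict
    artifact_reports: list[ArtifactReport]


def preprocess_windows(
    windows: list[PreictalWindow], config: PipelineConfig
) -> tuple[list[PreictalWindow], list[ArtifactReport]]:
    """Apply the configured preprocessing to every window."""
    out: list[PreictalWindow] = []
    reports: list[ArtifactReport] = []
    for i, win in enumerate(windows):
        if config.preprocess == "none":
            out.append(win)
            continue
        w = win
        if config.preprocess == "ica":
            # clean in physical units first so artifact reports stay in uV
            w, report, _ = clean_window(
                w,
                mains_hz=config.mains_hz,
                seed=config.seed + i,
                max_iter=config.ica_max_iter,
            )
            reports.append(report)
        w = zscore_normalize(w)
        w = bandpass(
            w,
            low=config.bandpass_low,
            high=config.bandpass_high,
            order=config.bandpass_order,
        )
        out.append(w)
    return out, reports


def k_selection_preset(
    seed: int,
    n_subjects: int = 25,
    windows_per_subject: int = 8,
) -> tuple["PipelineResult", list]:
    """One k-recovery replicate on the default synthetic preset (200 windows).

    Generates the default 4-state cohort, runs z-score + band-pass
    preprocessing (the band-pass already excludes both planted artifact
    classes from the analysis band, so per-window ICA is redundant for this
    scan), then features, PCA, UMAP, and the k scan.  Returns the pipeline
    result and the planted ground truths.
    """
    from .synthetic import default_spec, generate_dataset

    spec = default_spec(seed)
    windows, truths = generate_dataset(
        spec, n_subjects=n_subjects, windows_per_subject=windows_per_subject
    )
    config = PipelineConfig(preprocess="basic", seed=seed)
    return run_pipeline(windows, config), truths


def run_pipeline(
    windows: list[PreictalWindow],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run preprocessing, segmentation, features, reduction, clustering,
    noise filtering, and transition analysis on a set of windows."""
    if config is None:
        config = PipelineConfig()

    pre, artifact_reports = preprocess_windows(windows, config)
    seg_set = segment_dataset(pre, seg_len_s=config.seg_len_s)
    features = extract_feature_matrix(seg_set.segments, config.feature_config)
    reduction = reduce_features(
        features,
        var_threshold=config.pca_var_threshold,
        n_neighbors=config.umap_n_neighbors,
        min_dist=config.umap_min_dist,
        metric=config.umap_metric,
        seed=config.seed,
    )
    E = reduction.embedding
    k, elbow_k, sil_k, diagnostics = clu.select_k(
        E,
        k_min=config.k_min,
        k_max=config.k_max,
        seed=config.seed,
        n_init=config.kmeans_n_init,
    )
    clustering = clu.kmeans(E, k, seed=config.seed, n_init=config.kmeans_n_init)
    filtered, removed, pre_rep, post_rep = clu.noise_filter(
        E, clustering, min_size=config.min_cluster_size
    )
    sequences = dyn.build_sequences(seg_set.segments, filtered.labels)
    smoothed = [
        dyn.smooth_labels(s, window=config.smoothing_window) for s in sequences
    ]
    tm = dyn.transition_matrix(smoothed, exclude_noise=True)
    report = dyn.dynamics_report(
        tm, sequences, smoothing_window=config.smoothing_window
    )
    return PipelineResult(
        segments=seg_set,
        features=features,
        reduction=reduction,
        selected_k=k,
        elbow_k=elbow_k,
        silhouette_k=sil_k,
        k_diagnostics=diagnostics,
        clustering=clustering,
        filtered=filtered,
        removed_mask=removed,
        validation_pre=pre_rep,
        validation_post=post_rep,
        sequences=sequences,
        smoothed_sequences=smoothed,
        transitions=tm,
        dynamics=report,
        artifact_reports=artifact_reports,
    )
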