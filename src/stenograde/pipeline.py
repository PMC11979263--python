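"""End-to-end experiment orchestration over the library modules.

The canonical study flow mirrors the standard workflow: synthesize (or load) a
cohort, extract ROIs, compute radiomic features, train an autoencoder on the
training partition and encode every image, then fit and evaluate the cascade
in one of three modes — ``radiomic``, ``ae`` or ``combined``.

Functions here are deliberately stateless over explicit artifacts so the CLI,
the examples and the test suite share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autoencoder import AEConfig, DenseAutoencoder, TrainConfig, ssim
from .cascade import CascadeModel, fuse
from .evaluation import EvaluationReport, SplitPlan, compute_metrics, make_splits
from .radiomics import extract_feature_table
from .roi import ROIImage, extract_cohort_rois
from .synthetic import CohortSpec, GroundTruth, generate_cohort

__all__ = [
    "StudyArtifacts",
    "stage_seeds",
    "prepare_cohort",
    "encode_rois",
    "train_autoencoder",
    "run_mode",
    "run_study",
    "MODES",
]

MODES = ("radiomic", "ae", "combined")


def stage_seeds(global_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from one global seed (< 2**31)."""
    state = np.random.SeedSequence(global_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


@dataclass
class StudyArtifacts:
    """Everything produced up to (but excluding) cascade fitting."""

    rois: list[ROIImage]
    radiomic: pd.DataFrame
    labels: pd.Series  # patient_id -> class label
    truths: list[GroundTruth]


def prepare_cohort(
    spec: CohortSpec, target_rows: int = 854
) -> StudyArtifacts:
    """Generate a cohort, extract ROIs and the radiomic feature table."""
    images, truths = generate_cohort(spec)
    rois = extract_cohort_rois(images, target_rows=target_rows)
    radiomic = extract_feature_table(rois)
    labels = pd.Series({t.patient_id: t.class_label for t in truths})
    return StudyArtifacts(rois=rois, radiomic=radiomic, labels=labels, truths=truths)


def roi_matrix(rois: list[ROIImage]) -> tuple[np.ndarray, pd.MultiIndex]:
    """Row-major flattened ROI stack plus its (patient, vessel, view) index."""
    x = np.stack([r.flatten() for r in rois])
    index = pd.MultiIndex.from_tuples(
        [r.source for r in rois], names=["patient_id", "vessel_id", "view_index"]
    )
    return x, index


def train_autoencoder(
    rois: list[ROIImage],
    train_patients: set[str] | list[str],
    config: AEConfig,
    tc: TrainConfig,
) -> DenseAutoencoder:
    """Train an AE on the training patients' ROIs only (no test leakage)."""
    train_patients = set(train_patients)
    x, index = roi_matrix(rois)
    mask = index.get_level_values("patient_id").isin(train_patients)
    model = DenseAutoencoder(config, seed=tc.seed)
    return model.fit(x[mask], tc)


def encode_rois(model: DenseAutoencoder, rois: list[ROIImage]) -> pd.DataFrame:
    """Latent features for every ROI, columns ae_0..ae_{latent_dim-1}."""
    x, index = roi_matrix(rois)
    z = model.encode(x)
    return pd.DataFrame(
        z, index=index, columns=[f"ae_{k}" for k in range(z.shape[1])]
    )


def reconstruction_ssim(
    model: DenseAutoencoder, rois: list[ROIImage]
) -> np.ndarray:
    """Per-image SSIM between each ROI and its reconstruction."""
    shape = rois[0].pixels.shape
    x, _ = roi_matrix(rois)
    xhat = model.reconstruct(x)
    return np.array(
        [ssim(xi.reshape(shape), ri.reshape(shape)) for xi, ri in zip(x, xhat)]
    )


def run_mode(
    mode: str,
    radiomic: pd.DataFrame,
    ae: pd.DataFrame | None,
    labels: pd.Series,
    train_patients: list[str],
    eval_patients: list[str],
    seed: int = 0,
    n_trees: int = 500,
    fit_labels: pd.Series | None = None,
) -> tuple[EvaluationReport, CascadeModel]:
    """Fit the cascade on training patients and evaluate on held-out patients.

    ``fit_labels`` optionally replaces the labels used for fitting (e.g. a
    permuted copy for null-model checks); evaluation always scores against
    ``labels``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "radiomic":
        features = radiomic
    elif mode == "ae":
        if ae is None:
            raise ValueError("mode 'ae' requires AE features")
        features = ae
    else:
        if ae is None:
            raise ValueError("mode 'combined' requires AE features")
        features = fuse(radiomic, ae)
    pid = features.index.get_level_values("patient_id")
    x_train = features.loc[pid.isin(set(train_patients))]
    x_eval = features.loc[pid.isin(set(eval_patients))]
    model = CascadeModel.fit(
        x_train, labels if fit_labels is None else fit_labels,
        seed=seed, n_trees=n_trees,
    )
    pred = model.predict(x_eval)
    y_true = [labels[p] for p in pred.index]
    report = compute_metrics(
        y_true,
        pred["final_label"],
        scores=pred[["score_noCAD", "score_nonobstructive", "score_obstructive"]],
    )
    return report, model


def run_study(
    spec: CohortSpec,
    modes: tuple[str, ...] = MODES,
    seed: int = 0,
    target_rows: int = 854,
    ae_config: AEConfig | None = None,
    ae_epochs: int = 300,
    n_trees: int = 500,
    artifacts: StudyArtifacts | None = None,
    plan: SplitPlan | None = None,
) -> dict[str, EvaluationReport]:
    """The full pipeline at one seed: cohort -> features -> cascade -> test metrics.

    ``artifacts`` may carry a pre-generated cohort (radiomic features are
    deterministic per cohort, so callers sweeping pipeline seeds can reuse
    them); the AE, selection, balancing and forests are governed by ``seed``.
    """
    seeds = stage_seeds(seed)
    art = artifacts if artifacts is not None else prepare_cohort(spec, target_rows)
    the_plan = plan or SplitPlan(seed=seeds[0])
    splits = make_splits(list(art.labels.index), art.labels, the_plan)

    ae_feats = None
    if any(m in ("ae", "combined") for m in modes):
        input_dim = art.rois[0].n_values
        config = ae_config or AEConfig(input_dim=input_dim)
        tc = TrainConfig(max_epochs=ae_epochs, seed=seeds[1])
        model_ae = train_autoencoder(art.rois, splits.train_pool, config, tc)
        ae_feats = encode_rois(model_ae, art.rois)

    reports: dict[str, EvaluationReport] = {}
    for mode in modes:
        report, _ = run_mode(
            mode,
            art.radiomic,
            ae_feats,
            art.labels,
            splits.train_pool,
            splits.test_patients,
            seed=seeds[2],
            n_trees=n_trees,
        )
        reports[mode] = report
    return reports
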