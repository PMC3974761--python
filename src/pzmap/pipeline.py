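"""End-to-end pipeline: phantom -> standardize -> features -> select ->
train -> predict -> evaluate, with every intermediate written to disk.

Each phantom slice plays the role of one patient: standardization is trained
per modality across slices, features are extracted inside the
peripheral-zone stand-in mask, the Spearman filter prunes collinear columns,
the incremental ensemble is trained one increment per training slice, and
evaluation is slice-wise (patient-wise) nested cross-validation.  The run is
fully reproducible from the resolved config plus its seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .config import RunConfig
from .ensemble import (
    EnsembleConfig,
    EnsembleModel,
    TrainingSet,
    bootstrap_balance,
    clean_training_set,
    learnpp_increment,
    predict_probability,
    predict_probability_map,
)
from .evaluate import EvalReport, nested_cv
from .phantom import Phantom, PhantomSpec, generate_phantom
from .select import spearman_filter
from .standardize import standardize_stack, train_standard_scale, zscore_normalize
from .texture import FeatureStack, LPQConfig, TextureConfig, extract_feature_stack

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "phantom_from_config",
    "texture_config",
    "ensemble_config",
    "standardize_phantom",
    "build_training_set",
    "train_ensemble",
]


def phantom_from_config(cfg: RunConfig) -> Phantom:
    spec = PhantomSpec(
        n_slices=cfg.n_slices,
        height=cfg.height,
        width=cfg.width,
        n_lesions_per_slice=cfg.n_lesions_per_slice,
        lesion_radius_range=(cfg.lesion_radius_min, cfg.lesion_radius_max),
        background_mean=cfg.background_mean,
        lesion_mean=cfg.lesion_mean,
        background_sigma=cfg.background_sigma,
        lesion_sigma=cfg.lesion_sigma,
        background_smoothing_sigma=cfg.background_smoothing_sigma,
        lesion_smoothing_sigma=cfg.lesion_smoothing_sigma,
        bias_amplitude=cfg.bias_amplitude,
        slice_gain_sigma=cfg.slice_gain_sigma,
        slice_offset_sigma=cfg.slice_offset_sigma,
        label_noise_fraction=cfg.label_noise_fraction,
        min_lesion_area=cfg.min_lesion_area,
        seed=cfg.seed,
    )
    return generate_phantom(spec)


def texture_config(cfg: RunConfig) -> TextureConfig:
    return TextureConfig(
        first_order_window=cfg.first_order_window,
        n_levels=cfg.n_levels,
        ngtdm_window=cfg.ngtdm_window,
        ngtdm_nbhd=cfg.ngtdm_nbhd,
        ngldm_window=cfg.ngldm_window,
        ngldm_d=cfg.ngldm_d,
        ngldm_a=cfg.ngldm_a,
        scale_range=cfg.s2 - cfg.s1,
        lpq=LPQConfig(
            k=cfg.lpq_k,
            n_angles=cfg.lpq_n_angles,
            hist_window=cfg.lpq_hist_window,
        ),
        include_functional=cfg.include_functional,
        include_texture=cfg.include_texture,
    )


def ensemble_config(cfg: RunConfig) -> EnsembleConfig:
    return EnsembleConfig(
        T=cfg.T,
        max_retries=cfg.max_retries,
        inner_cv_folds=cfg.inner_cv_folds,
        optimize_every=cfg.optimize_every,
        seed=cfg.seed,
    )


def standardize_phantom(
    phantom: Phantom, cfg: RunConfig
) -> list[np.ndarray]:
    """Landmark-standardize and z-score each modality across slices."""
    out = []
    for stack in phantom.channels:
        slices = [stack[z] for z in range(stack.shape[0])]
        masks = [phantom.roi_mask[z] for z in range(stack.shape[0])]
        scale = train_standard_scale(slices, s1=cfg.s1, s2=cfg.s2, masks=masks)
        std = standardize_stack(stack, scale, mask=phantom.roi_mask)
        out.append(zscore_normalize(std, mask=phantom.roi_mask))
    return out


def build_training_set(
    stack: FeatureStack, cfg: RunConfig, seed: int | None = None
) -> TrainingSet:
    """Feature stack -> TrainingSet with a per-slice pixel subsample.

    Each slice acts as one patient.  A stratified subsample caps the pixel
    count per slice at ``max_pixels_per_slice`` while keeping every lesion
    pixel (the minority class).
    """
    if stack.y is None:
        raise ValueError("feature stack carries no labels")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pid = stack.pixel_index[:, 0]
    keep = []
    for z in np.unique(pid):
        sel = np.nonzero(pid == z)[0]
        pos = sel[stack.y[sel] == 1]
        neg = sel[stack.y[sel] == -1]
        budget = max(cfg.max_pixels_per_slice - pos.size, pos.size)
        if neg.size > budget:
            neg = rng.choice(neg, size=budget, replace=False)
        keep.append(np.concatenate([pos, neg]))
    keep = np.sort(np.concatenate(keep))
    return TrainingSet(
        X=stack.X[keep], y=stack.y[keep], patient_id=pid[keep]
    )


def train_ensemble(
    train: TrainingSet, ecfg: EnsembleConfig, seed: int
) -> EnsembleModel:
    """One incremental-ensemble increment per patient batch."""
    model = EnsembleModel()
    for k, p in enumerate(np.unique(train.patient_id)):
        batch = train.subset(np.nonzero(train.patient_id == p)[0])
        learnpp_increment(model, batch, config=ecfg, seed=seed + k)
    return model


def run_pipeline(cfg: RunConfig) -> EvalReport:
    """Run the full pipeline, writing artifacts under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_file(out / "config_resolved.txt")
    logger.info("running pipeline with seed %d", cfg.seed)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("phantom")
        phantom = phantom_from_config(cfg)
        for ci, ch in enumerate(phantom.channels):
            pio.write_image(out / f"channel_{ci}.nii.gz", ch)
        pio.write_image(out / "roi_mask.nii.gz", phantom.roi_mask.astype(np.uint8))
        pio.write_image(
            out / "label_mask.nii.gz", phantom.label_mask.astype(np.int8)
        )
    except Exception as e:
        raise RuntimeError(f"stage phantom failed: {e}") from e

    try:
        stage("standardize")
        channels = standardize_phantom(phantom, cfg)
        for ci, ch in enumerate(channels):
            pio.write_image(out / f"channel_{ci}_standardized.nii.gz", ch)
    except Exception as e:
        raise RuntimeError(f"stage standardize failed: {e}") from e

    try:
        stage("features")
        stack = extract_feature_stack(
            channels,
            phantom.roi_mask,
            config=texture_config(cfg),
            labels=phantom.label_mask,
        )
        pio.write_feature_stack(out / "features.tsv", stack)
        (out / "feature_names.txt").write_text(
            "\n".join(stack.feature_names) + "\n"
        )
    except Exception as e:
        raise RuntimeError(f"stage features failed: {e}") from e

    try:
        stage("select")
        selection = spearman_filter(stack, threshold=cfg.spearman_threshold)
        pio.write_selection_result(out / "selection.json", selection)
        selected = stack.select(selection.kept_indices)
    except Exception as e:
        raise RuntimeError(f"stage select failed: {e}") from e

    try:
        stage("train")
        train = build_training_set(selected, cfg)
        if cfg.clean_outliers:
            train = clean_training_set(train, nu=cfg.oneclass_nu)
        if cfg.balance_classes:
            train = bootstrap_balance(train, seed=cfg.seed)
        ecfg = ensemble_config(cfg)
        model = train_ensemble(train, ecfg, seed=cfg.seed)
        pio.save_model(out / "model", model)
    except Exception as e:
        raise RuntimeError(f"stage train failed: {e}") from e

    try:
        stage("predict")
        prob_map = predict_probability_map(
            model, selected, shape=phantom.roi_mask.shape
        )
        pio.write_image(out / "probability_map.nii.gz", prob_map)
    except Exception as e:
        raise RuntimeError(f"stage predict failed: {e}") from e

    try:
        stage("evaluate")
        grid = np.round(
            np.arange(cfg.threshold_step, 0.9501, cfg.threshold_step), 6
        )

        def trainer(tr, seed):
            m = EnsembleModel()
            for k, p in enumerate(np.unique(tr.patient_id)):
                batch = tr.subset(np.nonzero(tr.patient_id == p)[0])
                learnpp_increment(m, batch, config=ecfg, seed=seed + k)
            return lambda X: predict_probability(m, X)

        report = nested_cv(
            train,
            trainer=trainer,
            outer_k=cfg.outer_k,
            inner_k=cfg.inner_cv_folds,
            seed=cfg.seed,
            threshold_grid=grid,
        )
        rows = pd.DataFrame(report.folds).drop(columns=["test_patients"])
        rows.to_csv(out / "metrics.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [(k, m, s) for k, (m, s) in report.summary.items()],
            columns=["metric", "mean", "sd"],
        )
        summary.to_csv(out / "metrics_summary.tsv", sep="\t", index=False)
        np.savetxt(
            out / "roc_curve.tsv",
            np.column_stack([report.curves["roc_fpr"], report.curves["roc_tpr"]]),
            header="fpr\ttpr",
            delimiter="\t",
            comments="",
        )
    except Exception as e:
        raise RuntimeError(f"stage evaluate failed: {e}") from e

    return report
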