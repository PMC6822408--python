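"""End-to-end workflows: fit a counting model from images, count new images.

Ties the stages together: preprocess each image to a stem-free branch
mask, extract CD/Sk/Co, min–max normalise with training-set extremes, fit
the least-squares counting model, and evaluate on a held-out set. R² and
RMSE are reported on raw (un-rounded) predictions; counting accuracy on
integer counts (rounded half-away-from-zero, clamped at 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (FeatureVector, NormStats, feature_table,
                       compute_features, fit_normalizer, normalize_features)
from .preprocess import PreprocessConfig, preprocess_image
from .regression import CountModel, EvalReport, fit_count_model, predict_count
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything a training run produces."""

    model: CountModel
    report: EvalReport           # held-out evaluation
    train_features: pd.DataFrame
    val_features: pd.DataFrame
    predictions: pd.DataFrame    # per validation image: raw, count, truth


def extract_features(
    images: list[np.ndarray], cfg: PreprocessConfig | None = None
) -> list[FeatureVector]:
    """Preprocess each RGB image and extract its feature vector."""
    cfg = cfg or PreprocessConfig()
    out = []
    for i, img in enumerate(images):
        try:
            res = preprocess_image(img, cfg)
            fv = compute_features(
                res.stemless_mask, img.shape[0] * img.shape[1], cfg.connectivity
            )
        except Exception as e:
            raise RuntimeError(f"pipeline failed at image {i}: {e}") from e
        out.append(fv)
    return out


def evaluate_predictions(raw: np.ndarray, counts: np.ndarray, truths: np.ndarray) -> EvalReport:
    """R²/RMSE on raw predictions, accuracy on rounded counts."""
    from .regression import evaluate_model

    cont = evaluate_model(raw, truths)
    disc = evaluate_model(counts, truths)
    return EvalReport(r2=cont.r2, rmse=cont.rmse, accuracy_pct=disc.accuracy_pct, n=cont.n)


def run_pipeline(
    train_images: list[np.ndarray],
    train_counts: list[int],
    val_images: list[np.ndarray],
    val_counts: list[int],
    cfg: PreprocessConfig | None = None,
    terms: tuple[str, ...] = ("cd",),
    group: tuple[str, str, str] | None = None,
) -> PipelineResult:
    """Fit a counting model on training images; evaluate on held-out ones."""
    if len(train_images) < len(terms) + 2:
        raise ValueError("too few training images")
    cfg = cfg or PreprocessConfig()
    train_fvs = extract_features(train_images, cfg)
    val_fvs = extract_features(val_images, cfg)
    stats = fit_normalizer(train_fvs, group=group)
    train_nfs = [normalize_features(fv, stats) for fv in train_fvs]
    val_nfs = [normalize_features(fv, stats) for fv in val_fvs]
    model = fit_count_model(train_nfs, train_counts, terms=terms, group=group,
                            norm_stats=stats)
    raw = np.array([predict_count(model, nf)[0] for nf in val_nfs])
    counts = np.array([predict_count(model, nf)[1] for nf in val_nfs])
    report = evaluate_predictions(raw, counts, np.asarray(val_counts, dtype=float))
    preds = pd.DataFrame({
        "gn_raw": raw, "gn_count": counts, "truth": val_counts,
    })
    return PipelineResult(
        model=model,
        report=report,
        train_features=feature_table(train_fvs, stats=stats),
        val_features=feature_table(val_fvs, stats=stats),
        predictions=preds,
    )


def count_images(
    images: list[np.ndarray],
    model: CountModel,
    cfg: PreprocessConfig | None = None,
    image_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Predict grain counts for new images with a fitted model."""
    if model.norm_stats is None:
        raise ValueError("model carries no normalisation stats; fit or load them first")
    cfg = cfg or PreprocessConfig()
    if image_ids is None:
        image_ids = [f"img_{i:04d}" for i in range(len(images))]
    rows = []
    for image_id, img in zip(image_ids, images, strict=True):
        fv = extract_features([img], cfg)[0]
        nf = normalize_features(fv, model.norm_stats)
        raw, count = predict_count(model, nf)
        rows.append({"image_id": image_id, "gn_raw": raw, "gn_count": count})
    return pd.DataFrame(rows, columns=["image_id", "gn_raw", "gn_count"])


def run_synthetic_experiment(
    n_train: int = 160,
    n_val: int = 100,
    seed: int = 42,
    scale: float = 0.25,
    base_spec: SyntheticSpec | None = None,
    terms: tuple[str, ...] = ("cd",),
    remove_stem: bool = True,
    count_range: tuple[int, int] = (60, 220),
) -> PipelineResult:
    """Train/validate the counting pipeline on freshly rendered panicles.

    Renders ``n_train + n_val`` panicles from the (scaled) default spec in
    one deterministic batch, uses the first ``n_train`` for fitting and the
    rest for evaluation, with the preprocessing config scaled to match.
    """
    base = (base_spec or SyntheticSpec()).at_scale(scale)
    cfg = PreprocessConfig(remove_stem=remove_stem).at_scale(base.scale)
    panicles, meta = generate_dataset(n_train + n_val, seed=seed, base_spec=base,
                                      count_range=count_range)
    images = [p.image for p in panicles]
    truths = list(meta["true_count"])
    return run_pipeline(
        images[:n_train], truths[:n_train], images[n_train:], truths[n_train:],
        cfg=cfg, terms=terms,
    )
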