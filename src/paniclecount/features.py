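"""Pixel-fraction features of the stem-free branch mask.

Three features drive the counting models, each a foreground pixel count
divided by the size of the original image ``S_im = H × W``:

* coverage degree ``CD = N_cd / S_im`` — the branch mask itself;
* skeleton ``Sk = N_sk / S_im`` — its 1-px thinning;
* contour ``Co = N_co / S_im`` — its inner boundary.

Counts are taken per primary branch (connected component) and summed over
the panicle; for disjoint branches the sum equals the whole-mask count,
which is asserted. Features are min–max normalised with training-set
extremes before entering a regression model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import thin as _thin

from .preprocess import _binary_structure

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("cd", "sk", "co")


@dataclass(frozen=True)
class FeatureVector:
    """Raw pixel counts and fractions of one panicle image."""

    n_cd: int
    n_sk: int
    n_co: int
    s_im: int
    n_branches: int = 0
    per_branch: pd.DataFrame | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.s_im <= 0:
            raise ValueError("s_im must be positive")

    @property
    def cd(self) -> float:
        return self.n_cd / self.s_im

    @property
    def sk(self) -> float:
        return self.n_sk / self.s_im

    @property
    def co(self) -> float:
        return self.n_co / self.s_im

    def as_dict(self) -> dict[str, float]:
        return {"cd": self.cd, "sk": self.sk, "co": self.co}


@dataclass(frozen=True)
class NormStats:
    """Per-feature training-set extremes for min–max normalisation."""

    cd_min: float
    cd_max: float
    sk_min: float
    sk_max: float
    co_min: float
    co_max: float
    group: tuple[str, ...] | None = None

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, f"{name}_min"), getattr(self, f"{name}_max")


@dataclass(frozen=True)
class NormalizedFeatures:
    """Min–max normalised features CDʹ, Skʹ, Coʹ.

    Training-set values lie in [0, 1]; values from unseen images may fall
    outside and are deliberately not clamped.
    """

    cd_n: float
    sk_n: float
    co_n: float

    def as_dict(self) -> dict[str, float]:
        return {"cd": self.cd_n, "sk": self.sk_n, "co": self.co_n}


def split_branches(stemless: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """One full-size mask per connected component (primary branch)."""
    stemless = np.asarray(stemless, dtype=bool)
    labels, n = ndi.label(stemless, structure=_binary_structure(connectivity))
    return [labels == k for k in range(1, n + 1)]


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning to an (approximately) 1-px skeleton."""
    return _thin(np.asarray(mask, dtype=bool))


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Inner boundary: foreground pixels with a background 4-neighbour.

    The image border counts as background, so foreground touching the
    border is contour.
    """
    mask = np.asarray(mask, dtype=bool)
    interior = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def compute_features(
    stemless: np.ndarray, s_im: int, connectivity: int = 8
) -> FeatureVector:
    """CD/Sk/Co counts of a stem-free mask, per branch then summed.

    ``s_im`` is the pixel count H×W of the *original* image (the feature
    denominator), which may differ from the mask area only in pathological
    use; normally ``s_im == mask.size``.
    """
    if s_im <= 0:
        raise ValueError("s_im must be positive")
    stemless = np.asarray(stemless, dtype=bool)
    labels, n_branches = ndi.label(stemless, structure=_binary_structure(connectivity))
    skel = skeletonize(stemless)
    contour = extract_contour(stemless)

    # Thinning and the 4-neighbour boundary test are local (3×3 windows), and
    # 8-connected components are Chebyshev-separated, so restricting the
    # whole-mask skeleton/contour to each branch equals computing them per
    # branch; counting per label then summing keeps the per-branch table.
    cd_b = np.bincount(labels.ravel(), minlength=n_branches + 1)[1:]
    sk_b = np.bincount(labels[skel].ravel(), minlength=n_branches + 1)[1:]
    co_b = np.bincount(labels[contour].ravel(), minlength=n_branches + 1)[1:]

    n_cd, n_sk, n_co = int(cd_b.sum()), int(sk_b.sum()), int(co_b.sum())
    assert n_cd == int(stemless.sum())
    assert n_sk == int(skel.sum()) and n_co == int(contour.sum())

    per_branch = pd.DataFrame(
        {"branch": np.arange(1, n_branches + 1), "n_cd": cd_b, "n_sk": sk_b, "n_co": co_b}
    )
    return FeatureVector(
        n_cd=n_cd, n_sk=n_sk, n_co=n_co, s_im=int(s_im),
        n_branches=n_branches, per_branch=per_branch,
    )


def fit_normalizer(
    train: list[FeatureVector], group: tuple[str, ...] | None = None
) -> NormStats:
    """Per-feature min/max over the training set."""
    if len(train) < 2:
        raise ValueError("need at least 2 feature vectors to fit a normalizer")
    values = {name: np.array([getattr(fv, name) for fv in train]) for name in FEATURE_NAMES}
    stats: dict[str, float] = {}
    for name, v in values.items():
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            raise ValueError(f"degenerate feature range for {name!r}: min == max == {lo}")
        stats[f"{name}_min"], stats[f"{name}_max"] = lo, hi
    return NormStats(group=group, **stats)


def normalize_features(fv: FeatureVector, stats: NormStats) -> NormalizedFeatures:
    """Map each feature through (x − min)/(max − min); no clamping."""
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        lo, hi = stats.bounds(name)
        x = (getattr(fv, name) - lo) / (hi - lo)
        if not 0.0 <= x <= 1.0:
            logger.warning("normalized %s = %.4f outside [0, 1] (unseen-range image)", name, x)
        out[f"{name}_n"] = x
    return NormalizedFeatures(**out)


def feature_table(
    fvs: list[FeatureVector],
    image_ids: list[str] | None = None,
    stats: NormStats | None = None,
) -> pd.DataFrame:
    """One row per image: counts, fractions and (optionally) normalised values."""
    if image_ids is None:
        image_ids = [f"img_{i:04d}" for i in range(len(fvs))]
    rows = []
    for image_id, fv in zip(image_ids, fvs, strict=True):
        row = {
            "image_id": image_id,
            "n_branches": fv.n_branches,
            "s_im": fv.s_im,
            "n_cd": fv.n_cd,
            "n_sk": fv.n_sk,
            "n_co": fv.n_co,
            "cd": fv.cd,
            "sk": fv.sk,
            "co": fv.co,
        }
        if stats is not None:
            nf = normalize_features(fv, stats)
            row.update({"cd_n": nf.cd_n, "sk_n": nf.sk_n, "co_n": nf.co_n})
        rows.append(row)
    return pd.DataFrame(rows)
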