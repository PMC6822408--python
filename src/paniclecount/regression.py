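"""Linear counting models: GN from normalised pixel-fraction features.

The grain number per panicle GN is predicted by ordinary least squares on
a subset of the normalised features (CDʹ, Skʹ, Coʹ), e.g.

    GN = b_cd · CDʹ + b_sk · Skʹ + b_co · Coʹ + intercept

Predictions are rounded half-away-from-zero to integers for counting;
negative rounded counts are clamped to 0 in the reported count only (the
raw prediction is always returned, and R²/RMSE are computed on raw
predictions). ``printed_models`` ships the eight published multivariate
models (2 subspecies × 2 devices × 2 panicle shapes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .features import FEATURE_NAMES, NormStats, NormalizedFeatures


@dataclass(frozen=True)
class CountModel:
    """A linear grain-counting model over normalised features."""

    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    group: tuple[str, str, str] | None = None  # (subspecies, device, shape)
    norm_stats: NormStats | None = field(default=None, compare=False)
    fit_r2: float | None = None
    fit_rmse: float | None = None
    val_r2: float | None = None
    val_rmse: float | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.terms):
            raise ValueError("one coefficient per term required")
        unknown = set(self.terms) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")

    def to_json(self) -> str:
        payload = {
            "terms": list(self.terms),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "group": list(self.group) if self.group else None,
            "fit_r2": self.fit_r2,
            "fit_rmse": self.fit_rmse,
            "val_r2": self.val_r2,
            "val_rmse": self.val_rmse,
        }
        if self.norm_stats is not None:
            payload["norm_stats"] = {
                f"{n}_{b}": getattr(self.norm_stats, f"{n}_{b}")
                for n in FEATURE_NAMES
                for b in ("min", "max")
            }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CountModel":
        d = json.loads(text)
        stats = None
        if d.get("norm_stats"):
            stats = NormStats(**d["norm_stats"])
        return cls(
            terms=tuple(d["terms"]),
            coefficients=tuple(d["coefficients"]),
            intercept=float(d["intercept"]),
            group=tuple(d["group"]) if d.get("group") else None,
            norm_stats=stats,
            fit_r2=d.get("fit_r2"),
            fit_rmse=d.get("fit_rmse"),
            val_r2=d.get("val_r2"),
            val_rmse=d.get("val_rmse"),
        )


@dataclass(frozen=True)
class EvalReport:
    """Goodness-of-fit and counting accuracy on one image set."""

    r2: float
    rmse: float
    accuracy_pct: float
    n: int


def _design_matrix(
    rows: Sequence[NormalizedFeatures | Mapping[str, float]], terms: Sequence[str]
) -> np.ndarray:
    cols = []
    for row in rows:
        vals = row.as_dict() if isinstance(row, NormalizedFeatures) else dict(row)
        try:
            cols.append([vals[t] for t in terms])
        except KeyError as e:
            raise ValueError(f"missing model term {e.args[0]!r} in features") from None
    X = np.asarray(cols, dtype=np.float64)
    return np.column_stack([X, np.ones(len(X))])


def fit_count_model(
    rows: Sequence[NormalizedFeatures | Mapping[str, float]],
    counts: Iterable[float],
    terms: Sequence[str] = ("cd",),
    group: tuple[str, str, str] | None = None,
    norm_stats: NormStats | None = None,
) -> CountModel:
    """Ordinary least squares of grain counts on the selected terms."""
    terms = tuple(terms)
    y = np.asarray(list(counts), dtype=np.float64)
    if len(rows) != len(y):
        raise ValueError("rows and counts must have equal length")
    if len(y) < len(terms) + 1:
        raise ValueError(f"need at least {len(terms) + 1} rows to fit {terms}")
    X = _design_matrix(rows, terms)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design: features are collinear or constant")
    pred = X @ beta
    resid = y - pred
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CountModel(
        terms=terms,
        coefficients=tuple(float(b) for b in beta[:-1]),
        intercept=float(beta[-1]),
        group=group,
        norm_stats=norm_stats,
        fit_r2=r2,
        fit_rmse=rmse,
    )


def round_half_away_from_zero(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def predict_count(
    model: CountModel, nf: NormalizedFeatures | Mapping[str, float]
) -> tuple[float, int]:
    """Raw predicted grain number and the reported integer count.

    The integer count is the raw value rounded half-away-from-zero and
    clamped to >= 0; the raw value is returned unclamped.
    """
    vals = nf.as_dict() if isinstance(nf, NormalizedFeatures) else dict(nf)
    try:
        raw = model.intercept + sum(
            c * vals[t] for c, t in zip(model.coefficients, model.terms)
        )
    except KeyError as e:
        raise ValueError(f"missing model term {e.args[0]!r} in features") from None
    return raw, max(0, round_half_away_from_zero(raw))


def evaluate_model(preds: Iterable[float], truths: Iterable[float]) -> EvalReport:
    """R², RMSE and mean per-image relative counting accuracy.

    accuracy = mean over images of (1 − |pred − truth| / truth) × 100.
    """
    p = np.asarray(list(preds), dtype=np.float64)
    t = np.asarray(list(truths), dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1 or len(p) < 1:
        raise ValueError("preds and truths must be equal-length 1-D sequences")
    if np.any(t <= 0):
        raise ValueError("truths must be positive grain counts")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    ss_res = float(np.sum((p - t) ** 2))
    # zero variance in the truths leaves R^2 undefined; flag it as NaN
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    accuracy = float(np.mean(1.0 - np.abs(p - t) / t) * 100.0)
    return EvalReport(r2=r2, rmse=rmse, accuracy_pct=accuracy, n=len(p))


# Published multivariate models: (subspecies, device, shape) ->
# coefficients (CDʹ, Skʹ, Coʹ), intercept, training R²/RMSE, validation R²/RMSE.
_PRINTED: dict[tuple[str, str, str], tuple[tuple[float, float, float], float, float, float, float, float]] = {
    ("indica", "scanner", "B"): ((364.93, 0.70, -3.90), 2.801, 0.990, 4.6732, 0.980, 6.3254),
    ("indica", "scanner", "C"): ((363.72, 10.50, -13.48), 5.348, 0.990, 4.6345, 0.980, 6.3574),
    ("indica", "camera", "B"): ((396.82, -21.70, -7.32), 11.823, 0.974, 7.6989, 0.965, 8.3016),
    ("indica", "camera", "C"): ((395.60, -11.90, -16.90), 14.369, 0.975, 7.5595, 0.964, 8.3956),
    ("japonica", "scanner", "B"): ((481.49, 178.22, -164.85), -18.485, 0.979, 6.0957, 0.975, 6.4714),
    ("japonica", "scanner", "C"): ((482.28, 178.63, -164.00), -17.031, 0.980, 5.9838, 0.976, 6.4587),
    ("japonica", "camera", "B"): ((500.64, 188.62, -205.06), -5.477, 0.954, 9.1121, 0.953, 8.5389),
    ("japonica", "camera", "C"): ((501.43, 189.03, -204.22), -4.023, 0.954, 9.0961, 0.953, 8.5910),
}


def printed_models() -> dict[tuple[str, str, str], CountModel]:
    """Registry of the eight published multivariate counting models.

    Keys are ``(subspecies, device, shape)`` with subspecies in
    {"indica", "japonica"}, device in {"scanner", "camera"} and shape in
    {"B", "C"}. Coefficients are transcribed exactly as published; note the
    accompanying normalisation extremes were not published, so these models
    can only be applied to features normalised against a comparable
    training set.
    """
    return {
        key: CountModel(
            terms=("cd", "sk", "co"),
            coefficients=coefs,
            intercept=intercept,
            group=key,
            fit_r2=tr2,
            fit_rmse=trmse,
            val_r2=vr2,
            val_rmse=vrmse,
        )
        for key, (coefs, intercept, tr2, trmse, vr2, vrmse) in _PRINTED.items()
    }
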