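"""Two-class linear discriminant over the 11 facial distances.

The discriminant axis is the classic closed form w = Sw^{-1} (mu_male -
mu_female) with the pooled within-class covariance Sw (lightly
regularized). Sex is assigned by which projected class mean is closer,
with ties at the exact midpoint going to male. The 0-20 masculinity score
is an affine recalibration of the projection: the female class mean maps
to 5, the male class mean to 15, the midpoint to 10, clipped to [0, 20].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenderModel", "fit_lda", "normalize_sex", "SCORE_FEMALE_ANCHOR",
           "SCORE_MALE_ANCHOR", "SCORE_MIN", "SCORE_MAX"]

SCORE_MIN, SCORE_MAX = 0.0, 20.0
SCORE_FEMALE_ANCHOR, SCORE_MALE_ANCHOR = 5.0, 15.0

_SEX_ALIASES = {
    "m": "male", "male": "male", "boy": "male", "boys": "male", "1": "male",
    "f": "female", "female": "female", "girl": "female", "girls": "female", "0": "female",
}


class ClassCountError(ValueError):
    """Training labels do not contain exactly two classes with n >= 2 each."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular and no regularization was requested."""


class CalibrationError(ValueError):
    """Projected class means coincide; no score scale exists."""


def normalize_sex(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _SEX_ALIASES:
        raise ValueError(f"unrecognized sex label {label!r}")
    return _SEX_ALIASES[key]


@dataclass
class GenderModel:
    """Trained discriminant axis with score calibration."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    female_mean: np.ndarray
    male_mean: np.ndarray
    projected_female_mean: float
    projected_male_mean: float
    pooled_within_covariance: np.ndarray
    regularization: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.female_mean = np.asarray(self.female_mean, dtype=float)
        self.male_mean = np.asarray(self.male_mean, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite discriminant weights")
        if not self.projected_male_mean > self.projected_female_mean:
            raise CalibrationError("axis must be oriented male-positive")

    # -- projection ---------------------------------------------------------

    def _vector(self, x) -> np.ndarray:
        if isinstance(x, Mapping):
            missing = [f for f in self.feature_names if f not in x]
            if missing:
                raise KeyError(f"missing features: {', '.join(missing)}")
            return np.array([float(x[f]) for f in self.feature_names])
        arr = np.asarray(x, dtype=float)
        if arr.shape[-1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {arr.shape[-1]}"
            )
        return arr

    def project(self, x) -> np.ndarray | float:
        v = self._vector(x)
        return v @ self.weights

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.projected_female_mean + self.projected_male_mean)

    @property
    def half_gap(self) -> float:
        return 0.5 * (self.projected_male_mean - self.projected_female_mean)

    # -- outputs ------------------------------------------------------------

    def classify(self, x) -> str | np.ndarray:
        """'male' iff projection >= midpoint (ties to male, documented)."""
        p = self.project(x)
        if np.ndim(p) == 0:
            return "male" if p >= self.midpoint else "female"
        return np.where(p >= self.midpoint, "male", "female")

    def masculinity_score(self, x) -> float | np.ndarray:
        """clip(10 + 5 * (proj - midpoint) / half_gap, 0, 20)."""
        if self.half_gap <= 0:
            raise CalibrationError("projected class means coincide")
        u = (self.project(x) - self.midpoint) / self.half_gap
        score = np.clip(10.0 + 5.0 * u, SCORE_MIN, SCORE_MAX)
        return float(score) if np.ndim(score) == 0 else score

    def classification_accuracy(self, X, labels: Sequence[str]) -> dict[str, float]:
        """Fraction of correct calls per true class."""
        labels = [normalize_sex(l) for l in labels]
        if len(labels) == 0:
            raise ValueError("empty input")
        pred = self.classify(np.atleast_2d(self._vector(X)))
        out: dict[str, float] = {}
        for cls in sorted(set(labels)):
            idx = [i for i, l in enumerate(labels) if l == cls]
            out[cls] = float(np.mean([pred[i] == cls for i in idx]))
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": "facedim.gender_model/1",
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "female_mean": self.female_mean.tolist(),
            "male_mean": self.male_mean.tolist(),
            "projected_female_mean": self.projected_female_mean,
            "projected_male_mean": self.projected_male_mean,
            "pooled_within_covariance": np.asarray(self.pooled_within_covariance).tolist(),
            "regularization": self.regularization,
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GenderModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        if data.get("schema") != "facedim.gender_model/1":
            raise ValueError(f"unsupported model schema {data.get('schema')!r}")
        return cls(
            feature_names=tuple(data["feature_names"]),
            weights=np.array(data["weights"]),
            female_mean=np.array(data["female_mean"]),
            male_mean=np.array(data["male_mean"]),
            projected_female_mean=float(data["projected_female_mean"]),
            projected_male_mean=float(data["projected_male_mean"]),
            pooled_within_covariance=np.array(data["pooled_within_covariance"]),
            regularization=float(data["regularization"]),
            metadata=data.get("metadata", {}),
        )


def fit_lda(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    regularization: float | None = None,
    feature_names: Sequence[str] | None = None,
    seed: int | None = None,
) -> GenderModel:
    """Fit the two-class discriminant.

    ``features`` may be a DataFrame carrying a ``sex`` column (labels then
    optional) or a plain array. ``regularization`` defaults to
    1e-6 * mean(diag(Sw)); pass 0 to forbid it, in which case a singular
    pooled covariance raises.
    """
    if isinstance(features, pd.DataFrame):
        df = features
        if labels is None:
            if "sex" not in df.columns:
                raise ClassCountError("no labels given and no 'sex' column present")
            labels = df["sex"].tolist()
        if feature_names is None:
            from .tables import FEATURES

            feature_names = [c for c in FEATURES if c in df.columns]
        X = df[list(feature_names)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ClassCountError("labels are required with array input")
        if feature_names is None:
            feature_names = [f"feature_{i}" for i in range(X.shape[1])]
    y = np.array([normalize_sex(l) for l in labels])
    if X.shape[0] != y.size:
        raise ValueError("features and labels length mismatch")
    classes = sorted(set(y))
    if classes != ["female", "male"]:
        raise ClassCountError(f"need both classes female and male, got {classes}")
    Xf, Xm = X[y == "female"], X[y == "male"]
    if len(Xf) < 2 or len(Xm) < 2:
        raise ClassCountError("need at least 2 subjects per class")

    p = X.shape[1]
    n = len(Xf) + len(Xm)
    sw = ((len(Xf) - 1) * np.cov(Xf, rowvar=False) +
          (len(Xm) - 1) * np.cov(Xm, rowvar=False)) / (n - 2)
    sw = np.atleast_2d(sw)
    if regularization is None:
        regularization = 1e-6 * float(np.mean(np.diag(sw)))
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    if n <= p and regularization == 0:
        raise SingularCovarianceError("n <= p requires regularization > 0")
    sw_reg = sw + regularization * np.eye(p)
    mu_f, mu_m = Xf.mean(axis=0), Xm.mean(axis=0)
    try:
        w = np.linalg.solve(sw_reg, mu_m - mu_f)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(str(exc)) from exc
    if not np.all(np.isfinite(w)):
        raise SingularCovarianceError("singular pooled covariance")
    return GenderModel(
        feature_names=tuple(feature_names),
        weights=w,
        female_mean=mu_f,
        male_mean=mu_m,
        projected_female_mean=float(mu_f @ w),
        projected_male_mean=float(mu_m @ w),
        pooled_within_covariance=sw_reg,
        regularization=float(regularization),
        metadata={"n_female": int(len(Xf)), "n_male": int(len(Xm)), "seed": seed},
    )
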