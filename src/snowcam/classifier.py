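"""Snow classification: the fixed scene-category top-5 rule and a
transfer-learned linear SVM on image feature vectors.

The SVM mirrors the LIBLINEAR configuration used at full scale:
L2-regularized L2-loss (squared hinge) support vector classification solved
in the primal, cost parameter 0.0078.  Features are fed raw (no scaling);
the decision threshold resolves exact zeros to NO_SNOW.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

#: Scene categories whose presence in the top five marks an image as snow.
SNOW_CATEGORIES = frozenset(
    {
        "iceberg",
        "ice_skating_rink/outdoor",
        "mountain_snowy",
        "ski_resort",
        "ski_slope",
        "snowfield",
    }
)

DEFAULT_COST = 0.0078


@dataclass(frozen=True)
class ScenePrediction:
    """Ranked scene-category scores for one image."""

    image_id: str
    categories: Tuple[Tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.categories]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("category scores must be non-increasing")


def top5_snow_rule(prediction: ScenePrediction) -> bool:
    """True (snow) iff any of the five highest-scoring categories is a snow
    category.  Rank-5 score ties break by category name so the cutoff is
    deterministic."""
    if len(prediction.categories) < 5:
        raise ValueError("top-5 rule needs at least 5 ranked categories")
    ranked = sorted(prediction.categories, key=lambda c: (-c[1], c[0]))[:5]
    return any(name in SNOW_CATEGORIES for name, _ in ranked)


# ---------------------------------------------------------------------------
# feature extraction backbones
# ---------------------------------------------------------------------------


def toy_backbone(image: np.ndarray) -> np.ndarray:
    """Hand-crafted image statistics standing in for deep-network features.

    Per-channel 8-bin histograms, whiteness fractions of the upper and lower
    image halves, channel means/standard deviations, local-contrast energy
    and a saturation summary: 34 deterministic values.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 raster")
    feats: List[float] = []
    for c in range(3):
        hist, _ = np.histogram(img[:, :, c], bins=8, range=(0, 256))
        feats.extend(hist / img[:, :, c].size)
    white = np.all(img > 200, axis=2)
    h = img.shape[0]
    feats.append(float(white[: h // 2].mean()))
    feats.append(float(white[h // 2 :].mean()))
    for c in range(3):
        feats.append(float(img[:, :, c].mean()) / 255.0)
        feats.append(float(img[:, :, c].std()) / 255.0)
    gray = img.mean(axis=2)
    feats.append(float(np.abs(np.diff(gray, axis=0)).mean()) / 255.0)
    feats.append(float((img.max(axis=2) - img.min(axis=2)).mean()) / 255.0)
    return np.asarray(feats)


BACKBONES: Dict[str, Callable[[np.ndarray], np.ndarray]] = {"toy": toy_backbone}


def register_backbone(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register an external feature extractor (e.g. a pretrained scene
    network) under a name."""
    BACKBONES[name] = fn


def extract_features(image: np.ndarray, backbone: str = "toy") -> np.ndarray:
    """Deterministic feature vector for one image raster."""
    if backbone not in BACKBONES:
        raise KeyError(f"unknown backbone {backbone!r}; registered: {sorted(BACKBONES)}")
    return BACKBONES[backbone](image)


# ---------------------------------------------------------------------------
# linear SVM
# ---------------------------------------------------------------------------


class LinearSnowSVM(BaseEstimator, ClassifierMixin):
    """L2-regularized squared-hinge linear SVC for snow/no-snow.

    Parameters
    ----------
    C : float
        Cost parameter (default 0.0078; accuracies are insensitive to it
        over reasonable values).
    tol, max_iter : solver controls.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    classes_ : ndarray([False, True]) — positive class is snow.
    solver_descriptor_ : str
    """

    def __init__(self, C: float = DEFAULT_COST, tol: float = 1e-4, max_iter: int = 10_000):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "LinearSnowSVM":
        X, y = check_X_y(X, np.asarray(y, dtype=bool))
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        svc = LinearSVC(
            penalty="l2",
            loss="squared_hinge",
            dual=False,
            C=self.C,
            tol=self.tol,
            max_iter=self.max_iter,
            fit_intercept=True,
        )
        svc.fit(X, y.astype(int))
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        self.n_iter_ = getattr(svc, "n_iter_", None)
        self.solver_descriptor_ = (
            f"l2r_l2loss_svc_primal(C={self.C}, tol={self.tol}, max_iter={self.max_iter})"
        )
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: model has {self.n_features_in_} features, "
                f"got {X.shape[1]}"
            )
        return X @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Snow iff the decision score is strictly positive (ties → no snow)."""
        return self.decision_function(X) > 0.0


@dataclass(frozen=True)
class LinearModel:
    """Portable trained hyperplane: weights, bias, and provenance."""

    weights: np.ndarray
    bias: float
    cost_parameter: float = DEFAULT_COST
    solver_descriptor: str = ""

    @property
    def dim(self) -> int:
        return len(self.weights)

    def decision(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(
                f"dimension mismatch: model has {self.dim} features, got {X.shape[1]}"
            )
        return X @ self.weights + self.bias

    def save(self, path: Union[str, Path]) -> None:
        """Plain-text model file: header (dim, cost, solver), then weights
        and bias, one value per line."""
        path = Path(path)
        lines = [
            f"dim {self.dim}",
            f"cost_parameter {self.cost_parameter!r}",
            f"solver {self.solver_descriptor}",
            "weights",
        ]
        lines += [f"{w:.12e}" for w in self.weights]
        lines += ["bias", f"{self.bias:.12e}", ""]
        path.write_text("\n".join(lines))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "LinearModel":
        lines = Path(path).read_text().splitlines()
        dim = int(lines[0].split()[1])
        cost = float(lines[1].split(maxsplit=1)[1])
        solver = lines[2].split(maxsplit=1)[1] if len(lines[2].split()) > 1 else ""
        w_start = lines.index("weights") + 1
        weights = np.array([float(v) for v in lines[w_start : w_start + dim]])
        bias = float(lines[lines.index("bias") + 1])
        return cls(weights=weights, bias=bias, cost_parameter=cost, solver_descriptor=solver)


def train_svm(
    features: Union[pd.DataFrame, np.ndarray],
    labels: Union[pd.Series, np.ndarray],
    cost_parameter: float = DEFAULT_COST,
) -> LinearModel:
    """Fit the linear SVM and return the portable hyperplane.

    ``features`` may be an image_id-indexed DataFrame; labels must be
    binary with snow as the positive class.  Bad-consensus images are
    expected to be excluded upstream.
    """
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    est = LinearSnowSVM(C=cost_parameter).fit(X, np.asarray(labels, dtype=bool))
    return LinearModel(
        weights=est.coef_,
        bias=est.intercept_,
        cost_parameter=cost_parameter,
        solver_descriptor=est.solver_descriptor_,
    )


def predict(
    model: LinearModel, features: Union[pd.DataFrame, np.ndarray]
) -> pd.DataFrame:
    """Per-image binary labels and decision scores.

    Returns a frame with ``label`` (bool, snow) and ``score`` columns,
    indexed by image_id when features carry one.
    """
    scores = model.decision(np.asarray(features, dtype=float))
    index = (
        features.index
        if isinstance(features, pd.DataFrame)
        else pd.RangeIndex(len(scores))
    )
    return pd.DataFrame({"label": scores > 0.0, "score": scores}, index=index)
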