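"""Cross-validation designs and pooled evaluation.

Two 10-fold designs are supported: a fully random split (estimates accuracy
on new images from known sites) and a site-grouped split that never places
images from one camera site in both training and testing (estimates
accuracy on unseen sites).  Metrics are pooled over folds — every image is
tested exactly once, so the pooled confusion matrix is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classifier import DEFAULT_COST, LinearSnowSVM
from .metrics import ConfusionCounts, UndefinedMetricError
from .synthetic import stable_rng


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of the image set into folds 1..k."""

    mapping: Dict[str, int]
    k: int
    scheme: str  # 'random' | 'by_site'
    seed: int

    def fold_ids(self, fold: int) -> List[str]:
        return [i for i, f in self.mapping.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.mapping.items())
        return pd.DataFrame(
            {
                "image_id": [i for i, _ in items],
                "fold": [f for _, f in items],
                "scheme": self.scheme,
                "seed": self.seed,
            }
        )


def make_random_folds(
    image_ids: Sequence[str], k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Seeded shuffle then round-robin; fold sizes differ by at most one."""
    ids = list(image_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} images, got {len(ids)}")
    rng = stable_rng(seed, "random_folds")
    order = rng.permutation(len(ids))
    mapping = {ids[j]: (pos % k) + 1 for pos, j in enumerate(order)}
    return FoldAssignment(mapping=mapping, k=k, scheme="random", seed=seed)


def make_site_folds(
    records: pd.DataFrame, k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Site-grouped folds: sites sorted by image count descending are
    assigned greedily to the currently smallest fold; a seeded shuffle
    breaks count ties.  No site ever spans folds."""
    counts = records.groupby("site_id")["image_id"].count()
    if len(counts) < k:
        raise ValueError(f"need at least k={k} sites, got {len(counts)}")
    rng = stable_rng(seed, "site_folds")
    sites = counts.index.to_numpy()
    shuffled = sites[rng.permutation(len(sites))]
    n_images = counts.loc[shuffled].to_numpy()
    order = np.argsort(-n_images, kind="stable")  # largest first, ties in shuffled order

    fold_sizes = np.zeros(k, dtype=int)
    site_fold: Dict[str, int] = {}
    for idx in order:
        f = int(np.argmin(fold_sizes))
        site_fold[shuffled[idx]] = f + 1
        fold_sizes[f] += n_images[idx]

    mapping = {
        row.image_id: site_fold[row.site_id] for row in records.itertuples(index=False)
    }
    return FoldAssignment(mapping=mapping, k=k, scheme="by_site", seed=seed)


@dataclass
class CvReport:
    """Per-fold and pooled confusion for one cross-validation run."""

    scheme: str
    dataset: str
    per_fold: List[ConfusionCounts]

    @property
    def pooled(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.per_fold:
            total = total + c
        return total

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "dataset": self.dataset,
            "pooled": self.pooled.to_dict(percent=True),
            "per_fold": [c.to_dict(percent=True) for c in self.per_fold],
        }


def run_cross_validation(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: FoldAssignment,
    cost_parameter: float = DEFAULT_COST,
    dataset: str = "all",
) -> CvReport:
    """Train on each fold's complement, test on the fold, pool confusion.

    ``features`` must be image_id-indexed; ``labels`` a boolean series on
    the same ids (snow positive).  A training complement containing a
    single class aborts the run with a diagnostic.
    """
    ids = features.index.to_numpy()
    fold_of = np.array([folds.mapping[i] for i in ids])
    y = labels.loc[features.index].to_numpy(dtype=bool)
    X = features.to_numpy(dtype=float)
    per_fold = []
    for f in range(1, folds.k + 1):
        test = fold_of == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"fold {f} failed: training complement contains a single class"
            )
        est = LinearSnowSVM(C=cost_parameter).fit(X[train], y[train])
        pred = est.predict(X[test])
        per_fold.append(ConfusionCounts.from_labels(y[test], pred))
    return CvReport(scheme=folds.scheme, dataset=dataset, per_fold=per_fold)


def overfit_bound(
    features: pd.DataFrame,
    labels: pd.Series,
    cost_parameter: float = DEFAULT_COST,
) -> ConfusionCounts:
    """Train and evaluate on the identical set — the upper bound on what
    the transfer-learned classifier can achieve on these data."""
    y = labels.loc[features.index].to_numpy(dtype=bool)
    X = features.to_numpy(dtype=float)
    est = LinearSnowSVM(C=cost_parameter).fit(X, y)
    return ConfusionCounts.from_labels(y, est.predict(X))


def pairwise_agreement(
    predictions_a: pd.Series,
    predictions_b: pd.Series,
    restrict_ids: Optional[Sequence[str]] = None,
) -> float:
    """Fraction of shared images on which two binary label sets agree.

    ``restrict_ids`` limits the comparison (e.g. to reference-snow images)
    before intersecting.
    """
    a, b = predictions_a, predictions_b
    shared = a.index.intersection(b.index)
    if restrict_ids is not None:
        shared = shared.intersection(pd.Index(restrict_ids))
    if len(shared) == 0:
        raise UndefinedMetricError("no shared image_ids after restriction")
    return float(
        (a.loc[shared].astype(bool).to_numpy() == b.loc[shared].astype(bool).to_numpy()).mean()
    )
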