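"""Evaluation battery for distance matrices.

PCoA ordination, PERMANOVA / ANOSIM / multivariate dispersion permutation
tests (all at 999 permutations by default, significance threshold 0.01),
and leave-one-out KNN classification scored by ROC/AUC.  The permutation
tests are delegated to scikit-bio with an explicit seed so every run is
reproducible; PERMANOVA's R-squared is recovered from the pseudo-F closed
form, R^2 = F(k-1) / (F(k-1) + N-k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats import distance as skbio_distance
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "OrdinationResult",
    "PermTestResult",
    "RocResult",
    "pcoa",
    "permanova",
    "anosim",
    "dispersion_test",
    "knn_loo_scores",
    "roc_auc",
]

#: Significance threshold used throughout the evaluation battery.
ALPHA = 0.01


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes, descending eigenvalue order
    eigenvalues: np.ndarray  # all eigenvalues incl. negative ones
    proportion_explained: np.ndarray


@dataclass
class PermTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    r_squared: float | None = None


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical MDS (double-centering of -D^2/2).

    Negative eigenvalues are reported but their axes carry no coordinates.
    """
    res = _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    pos = eig > 0
    coords = res.samples.iloc[:, np.nonzero(pos)[0]].copy()
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig,
        proportion_explained=res.proportion_explained.to_numpy(),
    )


def _labels(labels, ids) -> pd.Series:
    s = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    if set(s.index) >= set(ids):
        s = s.loc[list(ids)]
    elif len(s) == len(ids):
        s = pd.Series(s.to_numpy(), index=list(ids))
    else:
        raise ValueError("labels do not cover the distance-matrix samples")
    return s.astype(str)


def _degenerate(dm: DistanceMatrix) -> bool:
    # all off-diagonal distances (numerically) equal: no structure to test
    vals = dm.condensed_form()
    return vals.size == 0 or float(np.ptp(vals)) < 1e-12


def permanova(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int | None = None
) -> PermTestResult:
    """Anderson's PERMANOVA: pseudo-F with label-permutation p-value."""
    grouping = _labels(labels, dm.ids)
    _validate_groups(grouping, n_perm)
    if _degenerate(dm):
        return PermTestResult("PERMANOVA", 0.0, 1.0, n_perm, r_squared=0.0)
    res = skbio_distance.permanova(dm, grouping.to_numpy(), permutations=n_perm, seed=seed)
    f = float(res["test statistic"])
    n, k = len(dm.ids), grouping.nunique()
    r2 = f * (k - 1) / (f * (k - 1) + (n - k))
    return PermTestResult("PERMANOVA", f, float(res["p-value"]), n_perm, r_squared=r2)


def anosim(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int | None = None
) -> PermTestResult:
    """Clarke's ANOSIM R on rank dissimilarities with permutation p-value."""
    grouping = _labels(labels, dm.ids)
    _validate_groups(grouping, n_perm)
    if _degenerate(dm):
        return PermTestResult("ANOSIM", 0.0, 1.0, n_perm)
    res = skbio_distance.anosim(dm, grouping.to_numpy(), permutations=n_perm, seed=seed)
    return PermTestResult(
        "ANOSIM", float(res["test statistic"]), float(res["p-value"]), n_perm
    )


def dispersion_test(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int | None = None
) -> PermTestResult:
    """PERMDISP: F-test on per-sample distances to the group centroid in
    PCoA space, with label-permutation p-value."""
    grouping = _labels(labels, dm.ids)
    _validate_groups(grouping, n_perm)
    if _degenerate(dm):
        return PermTestResult("PERMDISP", 0.0, 1.0, n_perm)
    with np.errstate(invalid="ignore"):
        res = skbio_distance.permdisp(
            dm, grouping.to_numpy(), test="centroid", permutations=n_perm,
            seed=seed, dimensions=len(dm.ids), warn_neg_eigval=False,
        )
    return PermTestResult(
        "PERMDISP", float(res["test statistic"]), float(res["p-value"]), n_perm
    )


def _validate_groups(grouping: pd.Series, n_perm: int) -> None:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = grouping.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 1).any():
        raise ValueError("empty group")


def knn_loo_scores(
    dm: DistanceMatrix,
    labels,
    positive_label: str,
    k: int = 3,
    distance_weighted: bool = False,
) -> pd.Series:
    """Leave-one-out KNN positive-class score per sample.

    Each sample is scored by its k nearest other samples: the fraction of
    positive neighbors (or, with ``distance_weighted``, their 1/(d+eps)
    weighted fraction).  Ties at the k-th distance are broken by sample
    order in the matrix, so scores are deterministic.
    """
    grouping = _labels(labels, dm.ids)
    n = len(dm.ids)
    if not 0 < k < n:
        raise ValueError(f"k must be in [1, n-1], got {k}")
    if positive_label not in set(grouping):
        raise ValueError(f"positive label {positive_label!r} not present")
    is_pos = (grouping == positive_label).to_numpy()
    D = dm.data
    scores = np.empty(n)
    order_key = np.arange(n)
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        # stable sort on distance, sample order breaks ties
        nn = np.lexsort((order_key, d))[:k]
        if distance_weighted:
            w = 1.0 / (d[nn] + 1e-9)
            scores[i] = float(w[is_pos[nn]].sum() / w.sum())
        else:
            scores[i] = float(is_pos[nn].mean())
    return pd.Series(scores, index=list(dm.ids))


def roc_auc(scores, labels, positive_label: str) -> RocResult:
    """ROC curve and AUC (Mann–Whitney identity; ties get half credit)."""
    s = pd.Series(scores)
    grouping = _labels(labels, s.index)
    y = (grouping == positive_label).to_numpy().astype(int)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(y, s.to_numpy())
    auc = float(roc_auc_score(y, s.to_numpy()))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
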