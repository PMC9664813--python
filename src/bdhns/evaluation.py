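"""Cross-validation drivers and ranking metrics.

Two protocols over the known associations: leave-one-out, where each
positive in turn is masked, the pipeline refit, and the held-out pair
ranked against every pair unobserved in the full data; and five-fold,
where the positives are split into five groups and, per fold, a
training-sized sample of negatives is held out of testing. AUC is the
rank-based Mann-Whitney statistic (tie mid-ranks): the probability a
random positive outranks a random negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .config import BDHNSConfig
from .io import AnnotationBundle, AssociationMatrix
from .model import BDHNSModel


@dataclass(frozen=True)
class FoldRecord:
    """Held-out pairs of one fold with the scores the refit gave them."""

    held_out: tuple[tuple[int, int], ...]  # (disease index, microbe index)
    positive_scores: np.ndarray
    negative_scores: np.ndarray


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome: per-fold records, pooled ranking, AUC."""

    protocol: str
    auc: float
    fold_aucs: tuple[float, ...]
    folds: tuple[FoldRecord, ...]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    seed: int | None = None
    roc_points: tuple[np.ndarray, np.ndarray] = field(default=None, repr=False)

    def plot_roc(self, ax=None):
        """Plot the pooled ROC curve; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        fpr, tpr = self.roc_points
        ax.plot(fpr, tpr, label=f"{self.protocol} (AUC = {self.auc:.3f})")
        ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points and rank-based AUC for binary labels.

    AUC is computed from mid-ranks (Mann-Whitney U / (n+ * n-)), which
    equals the probability that a uniformly chosen positive scores above
    a uniformly chosen negative, counting ties as half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative sample")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return (fpr, tpr), float(auc)


def _positive_pairs(A: AssociationMatrix) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(A.values)
    return list(zip(rows.tolist(), cols.tolist()))


def loocv(
    associations: AssociationMatrix,
    annotations: AnnotationBundle | None = None,
    config: BDHNSConfig | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over the known associations.

    Each known pair is masked in turn and the pipeline refit (the
    association-independent similarity channels are cached across
    folds). The negatives of every fold are the pairs unobserved in the
    FULL data — a masked positive is never counted as a negative — and
    the AUC pools (score, label) pairs across folds.
    """
    positives = _positive_pairs(associations)
    if len(positives) < 2:
        raise ValueError("leave-one-out needs at least 2 known associations")
    model = BDHNSModel(associations, annotations, config)
    negative_mask = associations.values == 0  # disease x microbe

    folds = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for d_idx, m_idx in positives:
        masked = associations.mask_pair(d_idx, m_idx)
        res = model.fit(masked)
        selected_dm = res.scores.selected.T  # disease x microbe
        pos_score = np.array([selected_dm[d_idx, m_idx]])
        neg_scores = selected_dm[negative_mask]
        folds.append(FoldRecord(((d_idx, m_idx),), pos_score, neg_scores))
        pooled_scores.extend([pos_score, neg_scores])
        pooled_labels.extend(
            [np.ones(1, dtype=int), np.zeros(neg_scores.size, dtype=int)]
        )
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    roc_points, auc = roc_auc(scores, labels)
    return CVResult(
        protocol="loocv",
        auc=auc,
        fold_aucs=(),
        folds=tuple(folds),
        pooled_scores=scores,
        pooled_labels=labels,
        roc_points=roc_points,
    )


def fivefold_cv(
    associations: AssociationMatrix,
    annotations: AnnotationBundle | None = None,
    config: BDHNSConfig | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> CVResult:
    """Five-fold cross-validation over the known associations.

    The positives are shuffled by ``seed`` into ``n_folds`` groups. Per
    fold, four groups stay in the training matrix and one is masked for
    testing; a without-replacement sample of negatives equal in size to
    the training positives is excluded from testing, and the remaining
    negatives form the test negatives. The reported AUC is the mean of
    the per-fold AUCs.
    """
    positives = _positive_pairs(associations)
    if len(positives) < n_folds:
        raise ValueError(f"{n_folds}-fold CV needs at least {n_folds} positives")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    groups = np.array_split(order, n_folds)
    negatives = np.argwhere(associations.values == 0)
    model = BDHNSModel(associations, annotations, config)

    folds = []
    fold_aucs = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for group in groups:
        test_pos = [positives[i] for i in group]
        values = associations.values.copy()
        for d_idx, m_idx in test_pos:
            values[d_idx, m_idx] = 0
        n_train_pos = len(positives) - len(test_pos)
        train_neg_idx = rng.choice(
            len(negatives), size=min(n_train_pos, len(negatives)), replace=False
        )
        test_neg = np.ones(len(negatives), dtype=bool)
        test_neg[train_neg_idx] = False
        res = model.fit(associations.with_values(values))
        selected_dm = res.scores.selected.T
        pos_scores = np.array([selected_dm[d, m] for d, m in test_pos])
        neg_scores = np.array(
            [selected_dm[d, m] for d, m in negatives[test_neg]]
        )
        _, fold_auc = roc_auc(
            np.concatenate([pos_scores, neg_scores]),
            np.concatenate(
                [np.ones(pos_scores.size, dtype=int), np.zeros(neg_scores.size, dtype=int)]
            ),
        )
        fold_aucs.append(fold_auc)
        folds.append(
            FoldRecord(tuple((int(d), int(m)) for d, m in test_pos), pos_scores, neg_scores)
        )
        pooled_scores.extend([pos_scores, neg_scores])
        pooled_labels.extend(
            [np.ones(pos_scores.size, dtype=int), np.zeros(neg_scores.size, dtype=int)]
        )
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    roc_points, _ = roc_auc(scores, labels)
    return CVResult(
        protocol="fivefold",
        auc=float(np.mean(fold_aucs)),
        fold_aucs=tuple(fold_aucs),
        folds=tuple(folds),
        pooled_scores=scores,
        pooled_labels=labels,
        seed=seed,
        roc_points=roc_points,
    )


def ablation_config(variant: str, base: BDHNSConfig | None = None) -> BDHNSConfig:
    """Configuration for one ablation arm.

    ``'full'`` is the complete pipeline; ``'no_walk'`` feeds the raw
    transition matrix to the graph convolution without diffusion;
    ``'no_selection'`` always reports the full-neighborhood score.
    """
    base = base or BDHNSConfig()
    if variant == "full":
        return base
    if variant == "no_walk":
        return base.replace(use_walk=False, attributes="transition_matrix")
    if variant == "no_selection":
        return base.replace(use_selection=False)
    raise ValueError(f"unknown ablation variant: {variant!r}")
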