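"""Graph-convolution scoring with causal-effect branch selection.

Two parameter-free graph-convolution passes produce node embeddings:
one aggregating the full neighborhood of every node ("full" mode) and
one where the cross-type edges are severed so only same-type neighbors
are aggregated ("intervened" mode, the causal intervention). Each
embedding yields a score surface over (microbe, disease) pairs; the
per-pair difference e = y_full - y_intervened is the causal effect of
the cross-type neighborhood, and the branch whose score is reported is
chosen by thresholding e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heteronet import HeteroAdjacency
from .io import AssociationMatrix


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Node embeddings, disease rows first then microbe rows."""

    H: np.ndarray
    mode: str
    layers: int
    n_diseases: int

    @property
    def disease_rows(self) -> np.ndarray:
        return self.H[: self.n_diseases]

    @property
    def microbe_rows(self) -> np.ndarray:
        return self.H[self.n_diseases :]


@dataclass(frozen=True)
class ScoreMatrix:
    """Paired score surfaces and the selected scores, microbe x disease."""

    y_full: np.ndarray
    y_intervened: np.ndarray
    effects: np.ndarray
    threshold: float
    selected: np.ndarray
    branch_full: np.ndarray  # True where the full-neighborhood score won
    microbe_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (disease, microbe) pair in
        disease-major order."""
        rows = []
        for j, d in enumerate(self.disease_ids):
            for i, m in enumerate(self.microbe_ids):
                rows.append(
                    (
                        d,
                        m,
                        self.y_full[i, j],
                        self.y_intervened[i, j],
                        self.effects[i, j],
                        "full" if self.branch_full[i, j] else "intervened",
                        self.selected[i, j],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "disease",
                "microbe",
                "score_full",
                "score_intervened",
                "causal_effect",
                "branch",
                "score",
            ],
        )


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetrically normalized adjacency with self-loops,
    ``D^{-1/2} (A + I) D^{-1/2}``. Self-loops keep degrees positive even
    for nodes isolated by the intervention."""
    A = np.asarray(adjacency, dtype=float)
    A_tilde = A + np.eye(A.shape[0])
    degrees = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def random_projection(n_features: int, dim: int, seed: int) -> np.ndarray:
    """Seeded Gaussian random projection, scaled to roughly preserve
    inner products."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_features, dim)) / np.sqrt(dim)


def gcn_aggregate(
    adjacency: HeteroAdjacency,
    X: np.ndarray,
    mode: str = "full",
    layers: int = 2,
    dim: int | None = 64,
    seed: int = 13,
    projection: np.ndarray | None = None,
    center: bool = True,
) -> EmbeddingMatrix:
    """Propagate node attributes over the (possibly intervened) network.

    ``H = Ahat^layers @ X @ R`` with Ahat the normalized adjacency of the
    full network or, in ``'intervened'`` mode, of its same-type-only
    part, and R a fixed seeded random projection to ``dim`` columns
    (identity when ``dim`` is None). The same R must be used for both
    modes of one run so the two score surfaces are comparable; passing
    the same ``seed`` guarantees this.

    With ``center`` (the default) the propagated features are centered
    within each node type before projection. Propagation over the dense
    similarity network concentrates every node's features around its
    type's dominant diffusion component; removing that shared component
    keeps the downstream within-type cosine similarities discriminative
    instead of saturating near 1.
    """
    if layers < 1:
        raise ValueError("layers must be >= 1")
    if mode == "full":
        base = adjacency.values
    elif mode == "intervened":
        base = adjacency.block_diagonal()
    else:
        raise ValueError(f"mode must be 'full' or 'intervened', got {mode!r}")
    X = np.asarray(X, dtype=float)
    if X.shape[0] != base.shape[0]:
        raise ValueError("attribute matrix row count does not match the network")
    A_hat = normalized_adjacency(base)
    H = X
    for _ in range(layers):
        H = A_hat @ H
    if center:
        nd = adjacency.n_diseases
        H = H.copy()
        H[:nd] -= H[:nd].mean(axis=0)
        H[nd:] -= H[nd:].mean(axis=0)
    if projection is not None:
        H = H @ projection
    elif dim is not None:
        H = H @ random_projection(X.shape[1], dim, seed)
    return EmbeddingMatrix(H, mode, layers, adjacency.n_diseases)


def _clamped_cosine(rows: np.ndarray) -> np.ndarray:
    """Pairwise cosine among rows, clamped to [0, 1]; zero rows get 0."""
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = rows / safe[:, None]
    sims = unit @ unit.T
    sims[norms == 0, :] = 0.0
    sims[:, norms == 0] = 0.0
    return np.clip(sims, 0.0, 1.0)


def pair_scores(H: EmbeddingMatrix, A_train: AssociationMatrix) -> np.ndarray:
    """Association score for every (microbe, disease) pair.

    The score blends two similarity-weighted association profiles: how
    strongly microbes similar to m(i) associate with disease d(j), and
    how strongly diseases similar to d(j) associate with microbe m(i),
    normalized by the total similarity mass so scores stay in [0, 1].
    Embedding similarity is cosine clamped to [0, 1]. Returns a
    microbe x disease matrix.
    """
    A = A_train.values
    nd, nm = A.shape
    if H.n_diseases != nd or H.H.shape[0] != nd + nm:
        raise ValueError("embedding rows do not match the association matrix")
    sim_m = _clamped_cosine(H.microbe_rows)  # n_m x n_m
    sim_d = _clamped_cosine(H.disease_rows)  # n_d x n_d
    # numerator(i, j) = sum_k sim_m(i,k) A(j,k) + sum_k sim_d(j,k) A(k,i)
    numerator = sim_m @ A.T + (sim_d @ A).T
    denominator = sim_m.sum(axis=1)[:, None] + sim_d.sum(axis=1)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denominator > 0, numerator / denominator, 0.0)
    return scores


def select_scores(
    y_full: np.ndarray,
    y_intervened: np.ndarray,
    threshold: float,
    microbe_ids: tuple[str, ...],
    disease_ids: tuple[str, ...],
) -> ScoreMatrix:
    """Pick, per pair, the full or intervened score by causal effect.

    The effect ``e = y_full - y_intervened`` measures what the
    cross-type neighborhood added; where ``e >= threshold`` the full
    score is reported, otherwise the intervened one (ties go to the full
    branch).
    """
    y_full = np.asarray(y_full, dtype=float)
    y_intervened = np.asarray(y_intervened, dtype=float)
    if y_full.shape != y_intervened.shape:
        raise ValueError("score surfaces have mismatched shapes")
    effects = y_full - y_intervened
    branch_full = effects >= threshold
    selected = np.where(branch_full, y_full, y_intervened)
    return ScoreMatrix(
        y_full,
        y_intervened,
        effects,
        float(threshold),
        selected,
        branch_full,
        tuple(microbe_ids),
        tuple(disease_ids),
    )
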