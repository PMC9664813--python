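"""Bi-directional heterogeneous network assembly.

The network joins the disease similarity graph and the microbe
similarity graph with direction-specific weighted cross edges: the
disease -> microbe correlation A'_SD weighs each association by how
similar the target microbe's known diseases are to the source disease,
and symmetrically for A'_SM. From these the row-stochastic block
transition matrix W is built with jump probability phi between the two
sub-networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityMatrix, _as_array

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeteroAdjacency:
    """Adjacency of the heterogeneous network, diseases first.

    Block layout: ``[[SD, A'_SD], [A'_SM^T, SM]]`` where A'_SD and A'_SM
    are both disease x microbe, so the bottom-left block stores the
    transpose to keep the assembled matrix square.
    """

    values: np.ndarray
    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def block_diagonal(self) -> np.ndarray:
        """The same-type-only network: cross blocks zeroed."""
        nd = self.n_diseases
        out = self.values.copy()
        out[:nd, nd:] = 0.0
        out[nd:, :nd] = 0.0
        return out


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix over all nodes, diseases first."""

    values: np.ndarray
    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]
    phi: float

    def __post_init__(self) -> None:
        rowsums = self.values.sum(axis=1)
        if np.abs(rowsums - 1.0).max() > 1e-10:
            raise ValueError("transition matrix rows must sum to 1")
        if (self.values < 0).any():
            raise ValueError("transition probabilities must be non-negative")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


def bidirectional_correlations(SD, SM, A) -> tuple[np.ndarray, np.ndarray]:
    """Disease->microbe and microbe->disease correlation matrices.

    ``A'_SD = SD @ A`` sums, for each (disease i, microbe j), the
    similarity from i to every disease known to associate with j;
    ``A'_SM = A @ SM`` is the mirror image through microbe similarity.
    Both are disease x microbe.
    """
    SD, SM, A = _as_array(SD), _as_array(SM), np.asarray(A, dtype=float)
    nd, nm = A.shape
    if SD.shape != (nd, nd) or SM.shape != (nm, nm):
        raise ValueError("similarity matrices do not conform with A")
    return SD @ A, A @ SM


def assemble_hetero_adjacency(
    SD: SimilarityMatrix, SM: SimilarityMatrix, A_sd: np.ndarray, A_sm: np.ndarray
) -> HeteroAdjacency:
    nd, nm = len(SD.entity_ids), len(SM.entity_ids)
    if A_sd.shape != (nd, nm) or A_sm.shape != (nd, nm):
        raise ValueError("cross-correlation blocks do not conform")
    values = np.block([[SD.values, A_sd], [A_sm.T, SM.values]])
    return HeteroAdjacency(values, SD.entity_ids, SM.entity_ids)


def transition_matrix(
    SD: SimilarityMatrix,
    SM: SimilarityMatrix,
    A: np.ndarray,
    A_sd: np.ndarray,
    A_sm: np.ndarray,
    phi: float = 0.5,
) -> TransitionMatrix:
    """Assemble the row-stochastic block transition matrix W.

    Disease rows split mass (1 - phi) over similar diseases and phi over
    associated microbes, weighted by the bi-directional correlations; a
    node with no associations keeps all its mass within its own type.
    Microbe rows are symmetric. Raises if a similarity row sums to zero
    (such a node has nowhere to walk).
    """
    if not 0 < phi < 1:
        raise ValueError("phi must lie in (0, 1)")
    sd, sm = _as_array(SD), _as_array(SM)
    A = np.asarray(A, dtype=float)
    nd, nm = A.shape

    sd_rowsum = sd.sum(axis=1)
    sm_rowsum = sm.sum(axis=1)
    if (sd_rowsum <= 0).any():
        bad = SD.entity_ids[int(np.argmax(sd_rowsum <= 0))]
        raise ValueError(f"disease {bad!r} has zero similarity row sum")
    if (sm_rowsum <= 0).any():
        bad = SM.entity_ids[int(np.argmax(sm_rowsum <= 0))]
        raise ValueError(f"microbe {bad!r} has zero similarity row sum")

    # disease -> microbe jumps, weighted by microbe-side correlation
    W_dm = np.zeros((nd, nm))
    cross_d = np.zeros(nd, dtype=bool)  # disease rows that actually jump
    for i in range(nd):
        weights = A[i, :] * A_sm[i, :]
        denom = weights.sum()
        if A[i, :].any():
            if denom > 0:
                W_dm[i, :] = phi * weights / denom
                cross_d[i] = True
            else:
                logger.warning(
                    "disease %r has associations but zero cross weight; "
                    "keeping its walk within the disease network",
                    SD.entity_ids[i],
                )

    # microbe -> disease jumps, weighted by disease-side correlation
    W_md = np.zeros((nm, nd))
    cross_m = np.zeros(nm, dtype=bool)
    for i in range(nm):
        weights = A[:, i] * A_sd[:, i]
        denom = weights.sum()
        if A[:, i].any():
            if denom > 0:
                W_md[i, :] = phi * weights / denom
                cross_m[i] = True
            else:
                logger.warning(
                    "microbe %r has associations but zero cross weight; "
                    "keeping its walk within the microbe network",
                    SM.entity_ids[i],
                )

    W_d = sd / sd_rowsum[:, None]
    W_d[cross_d] *= 1.0 - phi
    W_m = sm / sm_rowsum[:, None]
    W_m[cross_m] *= 1.0 - phi

    values = np.block([[W_d, W_dm], [W_md, W_m]])
    return TransitionMatrix(values, SD.entity_ids, SM.entity_ids, phi)
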