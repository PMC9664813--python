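"""Similarity channels for microbes and diseases, and their fusion.

Microbe side: the Gaussian interaction profile (GIP) kernel over
association profiles (GM) and an organ/disease co-annotation count (FM),
fused into SM. Disease side: GIP (GD), hierarchy-based semantic
similarity (DSS), gene-network functional similarity (DF) and symptom
cosine similarity (TD), averaged into SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import AnnotationBundle, AssociationMatrix


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix over one entity type."""

    values: np.ndarray
    entity_ids: tuple[str, ...]
    kind: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if values.shape != (n, n):
            raise ValueError(f"{self.kind}: shape {values.shape} does not match ids")
        if np.abs(values - values.T).max(initial=0.0) > 1e-12:
            raise ValueError(f"{self.kind}: matrix is not symmetric")
        object.__setattr__(self, "values", values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, SimilarityMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def gip_similarity(
    associations: AssociationMatrix,
    axis: str,
    bandwidth_scale: float = 1.0,
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel over association profiles.

    ``axis='microbe'`` uses matrix columns as profiles, ``axis='disease'``
    uses rows. The bandwidth is ``bandwidth_scale`` divided by the mean
    squared profile norm, so the kernel adapts to association density.
    """
    if bandwidth_scale <= 0:
        raise ValueError("bandwidth_scale must be positive")
    if axis == "microbe":
        profiles = associations.values.T
        ids = associations.microbe_ids
        kind = "GM"
    elif axis == "disease":
        profiles = associations.values
        ids = associations.disease_ids
        kind = "GD"
    else:
        raise ValueError(f"axis must be 'disease' or 'microbe', got {axis!r}")
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError(
            "all association profiles are zero: GIP bandwidth is undefined"
        )
    rate = bandwidth_scale / mean_sq_norm
    if profiles.shape[0] == 1:
        sq_dists = np.zeros((1, 1))
    else:
        sq_dists = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-rate * sq_dists)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix((values + values.T) / 2.0, tuple(ids), kind)


def minmax_normalize(matrix: np.ndarray, degenerate: str = "zeros") -> np.ndarray:
    """Elementwise min-max rescaling of a matrix to [0, 1].

    When every entry is equal the rescaling is undefined; ``degenerate``
    picks the convention: ``'zeros'`` (no evidence — used for the organ
    co-annotation counts) or ``'ones'`` (a constant weight is still
    evidence of linkage — used for gene-network weights).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    if not np.isfinite(matrix).all():
        raise ValueError("matrix entries must be finite")
    lo, hi = matrix.min(), matrix.max()
    if hi == lo:
        if degenerate == "zeros":
            return np.zeros_like(matrix)
        if degenerate == "ones":
            return np.ones_like(matrix)
        raise ValueError(f"degenerate must be 'zeros' or 'ones', got {degenerate!r}")
    return (matrix - lo) / (hi - lo)


def microbe_functional_similarity(
    bundle: AnnotationBundle, microbe_ids: tuple[str, ...]
) -> SimilarityMatrix:
    """Organ/disease co-annotation similarity between microbes (FM).

    Two microbes resident in the same organ and annotated to the same
    disease there contribute one unit; units accumulate over (organ,
    disease) coincidences, and the count matrix is min-max normalized.
    The raw diagonal is zero so normalization spans the off-diagonal
    evidence.
    """
    index = {m: i for i, m in enumerate(microbe_ids)}
    effects: dict[str, set[tuple[str, str]]] = {m: set() for m in microbe_ids}
    for microbe, organ, disease in bundle.organ_annotations:
        if microbe in effects:
            effects[microbe].add((organ, disease))
    n = len(microbe_ids)
    raw = np.zeros((n, n))
    for i, mi in enumerate(microbe_ids):
        for j in range(i + 1, n):
            shared = len(effects[mi] & effects[microbe_ids[j]])
            raw[i, j] = raw[j, i] = shared
    values = minmax_normalize(raw, degenerate="zeros") if raw.any() else raw
    return SimilarityMatrix(values, tuple(microbe_ids), "FM")


def fuse_microbe_similarity(GM: SimilarityMatrix, FM: SimilarityMatrix) -> SimilarityMatrix:
    """Fused microbe similarity SM: the GIP kernel, averaged with the
    functional channel wherever the latter has evidence."""
    if GM.entity_ids != FM.entity_ids:
        raise ValueError("GM and FM label mismatch")
    gm, fm = GM.values, FM.values
    values = np.where(fm == 0.0, gm, (gm + fm) / 2.0)
    return SimilarityMatrix(values, GM.entity_ids, "SM")


def _semantic_contributions(
    disease: str, parents: dict[str, set[str]], delta: float
) -> dict[str, float]:
    """Contribution of every node in ``disease``'s ancestor closure.

    The focal disease contributes 1; each other node contributes
    ``delta`` times the maximum contribution among its children inside
    the closure, computed by dynamic programming from the focal node
    upward.
    """
    closure = {disease}
    frontier = [disease]
    while frontier:
        node = frontier.pop()
        for parent in parents.get(node, ()):
            if parent not in closure:
                closure.add(parent)
                frontier.append(parent)
    contrib = {disease: 1.0}
    # children within the closure, for the max-over-children recursion
    children: dict[str, list[str]] = {node: [] for node in closure}
    for node in closure:
        for parent in parents.get(node, ()):
            if parent in closure:
                children[parent].append(node)
    sub = nx.DiGraph()
    sub.add_nodes_from(closure)
    for parent, kids in children.items():
        for kid in kids:
            sub.add_edge(kid, parent)  # child -> parent
    for node in nx.topological_sort(sub):
        if node == disease:
            continue
        contrib[node] = delta * max(contrib[kid] for kid in children[node])
    return contrib


def disease_semantic_similarity(
    dag_edges: set[tuple[str, str]],
    disease_ids: tuple[str, ...],
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Hierarchy-based semantic similarity between diseases (DSS).

    Each disease is represented by itself plus its ancestors in the
    (child -> parent) hierarchy; ancestors contribute a value attenuated
    by ``delta`` per step away from the focal disease. Similarity is the
    shared contribution mass over the two total semantic values.
    Diseases absent from the hierarchy get identity rows.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    graph = nx.DiGraph(list(dag_edges))
    if dag_edges and not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"disease hierarchy has a cycle through {cycle[0][:2]}")
    parents: dict[str, set[str]] = {}
    for child, parent in dag_edges:
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    in_dag = set(parents)

    contribs = {
        d: _semantic_contributions(d, parents, delta)
        for d in disease_ids
        if d in in_dag
    }
    semantic_value = {d: sum(c.values()) for d, c in contribs.items()}

    n = len(disease_ids)
    values = np.eye(n)
    for i in range(n):
        di = disease_ids[i]
        if di not in contribs:
            continue
        for j in range(i + 1, n):
            dj = disease_ids[j]
            if dj not in contribs:
                continue
            shared = set(contribs[di]) & set(contribs[dj])
            if not shared:
                continue
            num = sum(contribs[di][t] + contribs[dj][t] for t in shared)
            values[i, j] = values[j, i] = num / (
                semantic_value[di] + semantic_value[dj]
            )
    return SimilarityMatrix(values, tuple(disease_ids), "DSS")


def disease_functional_similarity(
    gene_sets: dict[str, frozenset[str]],
    gene_edges: set[tuple[str, str, float]],
    disease_ids: tuple[str, ...],
) -> SimilarityMatrix:
    """Gene-network functional similarity between diseases (DF).

    Gene-gene log-likelihood scores are min-max rescaled over the whole
    network; a gene matches itself with score 1, a neighbour with its
    rescaled weight, and any other gene with 0. A disease pair's
    similarity is the average best-match score of each gene against the
    other disease's gene set. Diseases with no annotated genes get
    identity rows.
    """
    weights = np.array([w for _, _, w in gene_edges], dtype=float)
    fss: dict[frozenset[str], float] = {}
    if len(weights):
        rescaled = minmax_normalize(weights.reshape(1, -1), degenerate="ones").ravel()
        for (g1, g2, _), w in zip(gene_edges, rescaled):
            key = frozenset((g1, g2))
            fss[key] = max(fss.get(key, 0.0), float(w))

    def best_match(gene: str, gene_set: frozenset[str]) -> float:
        best = 0.0
        for other in gene_set:
            if other == gene:
                return 1.0
            best = max(best, fss.get(frozenset((gene, other)), 0.0))
        return best

    n = len(disease_ids)
    values = np.eye(n)
    for i in range(n):
        gi = gene_sets.get(disease_ids[i], frozenset())
        if not gi:
            continue
        for j in range(i + 1, n):
            gj = gene_sets.get(disease_ids[j], frozenset())
            if not gj:
                continue
            total = sum(best_match(g, gj) for g in gi)
            total += sum(best_match(g, gi) for g in gj)
            values[i, j] = values[j, i] = total / (len(gi) + len(gj))
    return SimilarityMatrix(values, tuple(disease_ids), "DF")


def symptom_similarity(
    symptom_table, disease_ids: tuple[str, ...]
) -> SimilarityMatrix:
    """Cosine similarity of disease symptom profiles (TD).

    All-zero rows (or diseases absent from the table) are treated as
    dissimilar to everything but themselves.
    """
    n = len(disease_ids)
    if symptom_table is None or getattr(symptom_table, "size", 0) == 0:
        return SimilarityMatrix(np.eye(n), tuple(disease_ids), "TD")
    table = symptom_table.reindex(list(disease_ids)).fillna(0.0)
    vectors = table.to_numpy(dtype=float)
    if (vectors < 0).any():
        raise ValueError("symptom weights must be non-negative")
    norms = np.linalg.norm(vectors, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = vectors / safe[:, None]
    values = unit @ unit.T
    values[norms == 0, :] = 0.0
    values[:, norms == 0] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(values, tuple(disease_ids), "TD")


def fuse_disease_similarity(
    GD: SimilarityMatrix,
    DSS: SimilarityMatrix,
    TD: SimilarityMatrix,
    DF: SimilarityMatrix,
) -> SimilarityMatrix:
    """Fused disease similarity SD: elementwise mean of the four channels."""
    ids = GD.entity_ids
    for channel in (DSS, TD, DF):
        if channel.entity_ids != ids:
            raise ValueError("disease similarity channels have mismatched labels")
    values = (GD.values + DSS.values + TD.values + DF.values) / 4.0
    return SimilarityMatrix(values, ids, "SD")
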