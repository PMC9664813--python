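"""Seeded synthetic datasets with planted block structure.

The generator emulates the five real inputs — association edge list,
microbe organ annotations, disease hierarchy, disease gene sets with a
weighted gene network, and a disease x symptom table — with diseases and
microbes partitioned into blocks. Within-block associations are denser
than background, and every similarity channel (shared organ, shared
hierarchy ancestry, shared gene pool, shared symptom prototype) is
correlated with block membership, so multi-source fusion has signal to
recover held-out associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotationBundle, AssociationMatrix, write_labeled_matrix


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults give a 15 x 60, 3-block dataset."""

    n_diseases: int = 15
    n_microbes: int = 60
    blocks: int = 3
    p_in: float = 0.3
    p_out: float = 0.02
    genes_per_block: int = 12
    genes_per_disease: int = 4
    lls_range: tuple[float, float] = (1.0, 5.0)
    cross_pool_edge_prob: float = 0.05
    own_pool_gene_prob: float = 0.8
    symptom_dims: int = 10
    symptom_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.blocks > min(self.n_diseases, self.n_microbes):
            raise ValueError("more blocks than diseases or microbes")
        if min(
            self.n_diseases,
            self.n_microbes,
            self.blocks,
            self.genes_per_block,
            self.genes_per_disease,
            self.symptom_dims,
        ) < 1:
            raise ValueError("all counts must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated input bundle plus its planted ground truth."""

    associations: AssociationMatrix
    annotations: AnnotationBundle
    disease_blocks: dict[str, int]
    microbe_blocks: dict[str, int]
    params: SyntheticParams = field(repr=False)


def _block_assignment(ids: list[str], blocks: int) -> dict[str, int]:
    pieces = np.array_split(np.arange(len(ids)), blocks)
    out = {}
    for b, piece in enumerate(pieces):
        for i in piece:
            out[ids[i]] = b
    return out


def generate_dataset(params: SyntheticParams) -> SyntheticDataset:
    """Generate a complete seeded input bundle.

    The same seed gives byte-identical outputs; degenerate draws (an
    all-zero association matrix) are resampled once before failing with
    guidance to raise the association probabilities.
    """
    rng = np.random.default_rng(params.seed)
    disease_ids = [f"d{i:02d}" for i in range(params.n_diseases)]
    microbe_ids = [f"m{i:02d}" for i in range(params.n_microbes)]
    d_blocks = _block_assignment(disease_ids, params.blocks)
    m_blocks = _block_assignment(microbe_ids, params.blocks)

    probs = np.empty((params.n_diseases, params.n_microbes))
    for i, d in enumerate(disease_ids):
        for j, m in enumerate(microbe_ids):
            probs[i, j] = params.p_in if d_blocks[d] == m_blocks[m] else params.p_out
    values = (rng.random(probs.shape) < probs).astype(float)
    if not values.any():
        values = (rng.random(probs.shape) < probs).astype(float)
        if not values.any():
            raise ValueError(
                "sampled an empty association matrix twice; "
                "increase p_in/p_out or the matrix size"
            )
    associations = AssociationMatrix(values, tuple(disease_ids), tuple(microbe_ids))

    bundle = AnnotationBundle()
    # organ residence: each block lives in one organ, and a microbe is
    # annotated there with its block's diseases
    for m in microbe_ids:
        organ = f"organ{m_blocks[m]}"
        for d in disease_ids:
            if d_blocks[d] == m_blocks[m]:
                bundle.organ_annotations.add((m, organ, d))

    # hierarchy: per-block branch nodes under a shared root
    for b in range(params.blocks):
        bundle.dag_edges.add((f"branch{b}", "root"))
    for d in disease_ids:
        bundle.dag_edges.add((d, f"branch{d_blocks[d]}"))

    pools = [
        [f"g{b}_{k}" for k in range(params.genes_per_block)]
        for b in range(params.blocks)
    ]
    all_genes = [g for pool in pools for g in pool]
    gene_sets = {}
    for d in disease_ids:
        own = pools[d_blocks[d]]
        chosen: set[str] = set()
        while len(chosen) < params.genes_per_disease:
            source = own if rng.random() < params.own_pool_gene_prob else all_genes
            chosen.add(source[rng.integers(len(source))])
        gene_sets[d] = frozenset(chosen)
    bundle.gene_sets = gene_sets

    lo, hi = params.lls_range
    for pool in pools:
        for a in range(len(pool)):
            for b in range(a + 1, len(pool)):
                bundle.gene_edges.add(
                    (pool[a], pool[b], float(rng.uniform(lo, hi)))
                )
    for b1 in range(params.blocks):
        for b2 in range(b1 + 1, params.blocks):
            for g1 in pools[b1]:
                for g2 in pools[b2]:
                    if rng.random() < params.cross_pool_edge_prob:
                        bundle.gene_edges.add((g1, g2, float(rng.uniform(lo, hi))))

    # symptoms: each block owns a band of symptom dimensions
    band = max(1, params.symptom_dims // params.blocks)
    prototypes = np.zeros((params.blocks, params.symptom_dims))
    for b in range(params.blocks):
        start = (b * band) % params.symptom_dims
        prototypes[b, start : start + band] = 1.0
    rows = np.clip(
        prototypes[[d_blocks[d] for d in disease_ids]]
        + rng.normal(0.0, params.symptom_noise_sd, (params.n_diseases, params.symptom_dims)),
        0.0,
        None,
    )
    bundle.symptom_table = pd.DataFrame(
        rows,
        index=disease_ids,
        columns=[f"s{k:02d}" for k in range(params.symptom_dims)],
    )

    bundle.validate()
    return SyntheticDataset(associations, bundle, d_blocks, m_blocks, params)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as the tool's tab-separated input files.

    Returns the path mapping accepted by :func:`bdhns.io.read_annotations`
    (plus an ``associations`` entry).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    A = dataset.associations
    paths = {
        "associations": out / "associations.tsv",
        "organs": out / "organs.tsv",
        "dag": out / "disease_hierarchy.tsv",
        "genes": out / "disease_genes.tsv",
        "gene_network": out / "gene_network.tsv",
        "symptoms": out / "symptoms.tsv",
    }
    with paths["associations"].open("w", encoding="utf-8") as fh:
        fh.write("disease\tmicrobe\n")
        for i, d in enumerate(A.disease_ids):
            for j, m in enumerate(A.microbe_ids):
                if A.values[i, j]:
                    fh.write(f"{d}\t{m}\n")
    with paths["organs"].open("w", encoding="utf-8") as fh:
        fh.write("# microbe\torgan\tdisease\n")
        for m, organ, d in sorted(dataset.annotations.organ_annotations):
            fh.write(f"{m}\t{organ}\t{d}\n")
    with paths["dag"].open("w", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for child, parent in sorted(dataset.annotations.dag_edges):
            fh.write(f"{child}\t{parent}\n")
    with paths["genes"].open("w", encoding="utf-8") as fh:
        fh.write("# disease\tgene\n")
        for d in A.disease_ids:
            for g in sorted(dataset.annotations.gene_sets.get(d, ())):
                fh.write(f"{d}\t{g}\n")
    with paths["gene_network"].open("w", encoding="utf-8") as fh:
        fh.write("# gene\tgene\tlls\n")
        for g1, g2, w in sorted(dataset.annotations.gene_edges):
            fh.write(f"{g1}\t{g2}\t{w:.12g}\n")
    write_labeled_matrix(dataset.annotations.symptom_table, paths["symptoms"])
    return paths
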