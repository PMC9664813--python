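"""Reading and writing the tabular inputs and outputs.

All files are tab-separated UTF-8 text. Lines starting with ``#`` are
comments. The association file is a two-column edge list (disease id,
microbe id); a header row is optional and detected by name. Labeled
matrices (similarities, transition matrices) are written with ids in the
first row and first column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ASSOC_HEADER_NAMES = {"disease", "disease_id", "microbe", "microbe_id"}


class InputFormatError(ValueError):
    """A tabular input file does not match its expected schema."""


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary disease x microbe association matrix with labeled axes.

    Rows are diseases, columns are microbes, entries are {0, 1}. Label
    order is first appearance in the source file so matrices are
    reproducible from the same input.
    """

    values: np.ndarray
    disease_ids: tuple[str, ...]
    microbe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if values.shape != (len(self.disease_ids), len(self.microbe_ids)):
            raise ValueError("association matrix shape does not match labels")
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("association entries must be 0 or 1")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        if len(set(self.microbe_ids)) != len(self.microbe_ids):
            raise ValueError("duplicate microbe ids")
        object.__setattr__(self, "values", values)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def mask_pair(self, disease_idx: int, microbe_idx: int) -> "AssociationMatrix":
        """Return a copy with one association removed (for held-out folds)."""
        values = self.values.copy()
        if values[disease_idx, microbe_idx] != 1:
            raise ValueError("cannot mask a pair that is not an association")
        values[disease_idx, microbe_idx] = 0
        return AssociationMatrix(values, self.disease_ids, self.microbe_ids)

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(values, self.disease_ids, self.microbe_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.disease_ids), columns=list(self.microbe_ids)
        )


@dataclass
class AnnotationBundle:
    """Raw annotation material behind the non-GIP similarity channels.

    ``organ_annotations`` feed microbe functional similarity,
    ``dag_edges`` (child -> parent) the disease semantic similarity,
    ``gene_sets``/``gene_edges`` the disease functional similarity, and
    ``symptom_table`` the symptom cosine similarity. Any component may be
    empty; downstream code falls back to identity-like rows.
    """

    organ_annotations: set[tuple[str, str, str]] = field(default_factory=set)
    dag_edges: set[tuple[str, str]] = field(default_factory=set)
    gene_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_edges: set[tuple[str, str, float]] = field(default_factory=set)
    symptom_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        if self.dag_edges:
            graph = nx.DiGraph(list(self.dag_edges))
            if not nx.is_directed_acyclic_graph(graph):
                cycle = nx.find_cycle(graph)
                raise InputFormatError(
                    f"disease hierarchy contains a cycle through edge {cycle[0][:2]}"
                )
        for _, _, weight in self.gene_edges:
            if not np.isfinite(weight):
                raise InputFormatError("gene network weights must be finite")
        if self.symptom_table.size:
            if (self.symptom_table.to_numpy(dtype=float) < 0).any():
                raise InputFormatError("symptom weights must be non-negative")


def _data_rows(path: Path) -> list[list[str]]:
    try:
        text = path.read_text(encoding="utf-8")
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rows.append([f.strip() for f in line.rstrip("\n").split("\t")])
    return rows


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a disease-microbe edge list into an association matrix.

    Duplicate (disease, microbe) records are collapsed to a single
    association; axis label order is first appearance.
    """
    path = Path(path)
    rows = _data_rows(path)
    if not rows:
        raise InputFormatError(f"association file is empty: {path}")
    if rows and rows[0][0].lower() in _ASSOC_HEADER_NAMES:
        rows = rows[1:]
        if not rows:
            raise InputFormatError(f"association file has a header but no data: {path}")
    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    for row in rows:
        if len(row) < 2:
            raise InputFormatError(
                f"association row needs 2 columns, got {len(row)}: {row!r}"
            )
        d, m = row[0], row[1]
        diseases.setdefault(d, len(diseases))
        microbes.setdefault(m, len(microbes))
        pairs.add((d, m))
    values = np.zeros((len(diseases), len(microbes)))
    for d, m in pairs:
        values[diseases[d], microbes[m]] = 1.0
    return AssociationMatrix(values, tuple(diseases), tuple(microbes))


def read_annotations(
    paths: Mapping[str, str | Path],
    associations: AssociationMatrix | None = None,
) -> AnnotationBundle:
    """Read the annotation files named in ``paths`` into a bundle.

    Recognised keys: ``organs`` (microbe, organ, disease), ``dag``
    (child, parent), ``genes`` (disease, gene), ``gene_network``
    (gene, gene, LLS weight), ``symptoms`` (labeled matrix). Missing keys
    yield empty components. When ``associations`` is given, annotation
    rows referring to unknown disease/microbe ids are dropped with a
    logged warning rather than rejected.
    """
    bundle = AnnotationBundle()
    known_d = set(associations.disease_ids) if associations else None
    known_m = set(associations.microbe_ids) if associations else None
    dropped = 0

    if "organs" in paths:
        for row in _data_rows(Path(paths["organs"])):
            if len(row) < 3:
                raise InputFormatError(f"organ annotation row needs 3 columns: {row!r}")
            microbe, organ, disease = row[0], row[1], row[2]
            if known_m is not None and microbe not in known_m:
                dropped += 1
                continue
            bundle.organ_annotations.add((microbe, organ, disease))
    if "dag" in paths:
        for row in _data_rows(Path(paths["dag"])):
            if len(row) < 2:
                raise InputFormatError(f"hierarchy row needs 2 columns: {row!r}")
            bundle.dag_edges.add((row[0], row[1]))
    if "genes" in paths:
        gene_sets: dict[str, set[str]] = {}
        for row in _data_rows(Path(paths["genes"])):
            if len(row) < 2:
                raise InputFormatError(f"disease-gene row needs 2 columns: {row!r}")
            disease, gene = row[0], row[1]
            if known_d is not None and disease not in known_d:
                dropped += 1
                continue
            gene_sets.setdefault(disease, set()).add(gene)
        bundle.gene_sets = {d: frozenset(g) for d, g in gene_sets.items()}
    if "gene_network" in paths:
        for row in _data_rows(Path(paths["gene_network"])):
            if len(row) < 3:
                raise InputFormatError(f"gene network row needs 3 columns: {row!r}")
            try:
                weight = float(row[2])
            except ValueError:
                raise InputFormatError(f"gene network weight is not numeric: {row!r}")
            bundle.gene_edges.add((row[0], row[1], weight))
    if "symptoms" in paths:
        bundle.symptom_table = read_labeled_matrix(paths["symptoms"])
        if known_d is not None:
            unknown = [d for d in bundle.symptom_table.index if d not in known_d]
            dropped += len(unknown)
            bundle.symptom_table = bundle.symptom_table.drop(index=unknown)

    if dropped:
        logger.warning("dropped %d annotation rows with unknown ids", dropped)
    bundle.validate()
    return bundle


def read_labeled_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled numeric matrix (first row and column are ids)."""
    frame = pd.read_csv(Path(path), sep="\t", index_col=0, comment="#")
    return frame.astype(float)


def write_labeled_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(Path(path), sep="\t", float_format="%.12g")


def write_predictions(scores, path: str | Path) -> None:
    """Write per-pair scores as TSV, one row per (disease, microbe) pair.

    Rows are emitted disease-major, then by microbe, so the output is
    deterministic. Values round-trip through :func:`read_predictions`
    to better than 1e-12 relative.
    """
    frame = scores.to_frame()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t", comment="#")
    expected = {"disease", "microbe", "score_full", "score_intervened",
                "causal_effect", "branch", "score"}
    missing = expected - set(frame.columns)
    if missing:
        raise InputFormatError(f"prediction file missing columns: {sorted(missing)}")
    return frame
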