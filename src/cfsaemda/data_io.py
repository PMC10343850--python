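"""Readers and writers for association lists, ontology edges and similarity matrices.

All on-disk formats are plain TSV (UTF-8, tab-separated, ``#`` comment lines,
``.`` decimal point).  Missing similarity entries are encoded as empty cells or
``NA``.  These containers are shared by every other module in the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "DiseaseOntology",
    "SimilarityMatrix",
    "read_association_pairs",
    "write_association_pairs",
    "read_ontology_edges",
    "write_ontology_edges",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "write_run_log",
]

_MISSING_TOKENS = {"", "NA", "nan", "NaN"}


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease adjacency matrix with id registries.

    Row ``i`` of ``A`` is the interaction profile of miRNA ``i``; column ``j``
    is the interaction profile of disease ``j``.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {self.A.shape} does not match id lists "
                f"({len(self.mirna_ids)} x {len(self.disease_ids)})"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.A = self.A.astype(np.int8)

    @property
    def nm(self) -> int:
        return len(self.mirna_ids)

    @property
    def nd(self) -> int:
        return len(self.disease_ids)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def mirna_profiles(self) -> np.ndarray:
        """Interaction profiles IP(m_i), one per row."""
        return self.A.astype(float)

    def disease_profiles(self) -> np.ndarray:
        """Interaction profiles IP(d_j), one per row."""
        return self.A.T.astype(float)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids), self.A.copy())


@dataclass
class DiseaseOntology:
    """A global child->parent DAG over disease terms.

    ``disease_to_term`` maps disease identifiers (as used in the association
    matrix) onto ontology terms; the identity mapping is the common case.
    Diseases absent from the mapping simply have no semantic similarity.
    """

    terms: set[str]
    parent_edges: set[tuple[str, str]]
    disease_to_term: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent in self.parent_edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge ({child},{parent}) references unregistered term")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through term {cycle[0][0]!r}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.parent_edges)
        return g

    def term_for(self, disease_id: str) -> str | None:
        """Ontology term for a disease id, or None when uncovered."""
        term = self.disease_to_term.get(disease_id, disease_id)
        return term if term in self.terms else None


@dataclass
class SimilarityMatrix:
    """Symmetric square similarity matrix in [0,1] with a missing-entry mask."""

    ids: list[str]
    values: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n},{n})")
        if self.missing is None:
            self.missing = np.zeros((n, n), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, n):
                raise ValueError("missing mask shape mismatch")
        if not np.array_equal(self.missing, self.missing.T):
            raise ValueError("missing mask must be symmetric")
        obs = ~self.missing
        if not np.allclose(self.values[obs], self.values.T[obs.T], atol=1e-12):
            raise ValueError("similarity values must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, identifier: str) -> int:
        return self.ids.index(identifier)

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(list(self.ids), self.values.copy(), self.missing.copy())


def _data_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_association_pairs(
    path: str | Path,
    mirna_universe: Sequence[str] | None = None,
    disease_universe: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read a two-column TSV of (miRNA id, disease id) pairs.

    Id order is first-appearance order; when an explicit universe is given it
    is used verbatim (and ids outside it are an error).  Duplicate pairs are
    deduplicated with a warning; malformed rows raise with their line number.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, fieldsrow in _data_rows(path):
        if len(fieldsrow) != 2 or not fieldsrow[0] or not fieldsrow[1]:
            raise ValueError(f"{path}:{lineno}: expected 'mirna<TAB>disease', got {fieldsrow!r}")
        pair = (fieldsrow[0], fieldsrow[1])
        if pair in seen:
            warnings.warn(f"{path}:{lineno}: duplicate pair {pair}, deduplicated")
            continue
        seen.add(pair)
        pairs.append(pair)

    if mirna_universe is not None:
        mirna_ids = list(mirna_universe)
    else:
        mirna_ids = list(dict.fromkeys(m for m, _ in pairs))
    if disease_universe is not None:
        disease_ids = list(disease_universe)
    else:
        disease_ids = list(dict.fromkeys(d for _, d in pairs))

    mi = {m: i for i, m in enumerate(mirna_ids)}
    di = {d: j for j, d in enumerate(disease_ids)}
    offenders = [m for m, _ in pairs if m not in mi] + [d for _, d in pairs if d not in di]
    if offenders:
        raise ValueError(f"ids outside the declared universe: {sorted(set(offenders))}")

    A = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for m, d in pairs:
        A[mi[m], di[d]] = 1
    return AssociationMatrix(mirna_ids, disease_ids, A)


def write_association_pairs(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mirna_id\tdisease_id\n")
        rows, cols = np.nonzero(assoc.A)
        for i, j in zip(rows, cols):
            fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")


def read_ontology_edges(
    path: str | Path, disease_to_term: Mapping[str, str] | None = None
) -> DiseaseOntology:
    """Read a two-column TSV of (child term, parent term) edges.

    Terms appearing only as a bare single-column row are registered as
    isolated roots.  A cycle raises an error naming one member.
    """
    terms: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, fieldsrow in _data_rows(path):
        if len(fieldsrow) == 1 and fieldsrow[0]:
            terms.add(fieldsrow[0])
            continue
        if len(fieldsrow) != 2 or not fieldsrow[0] or not fieldsrow[1]:
            raise ValueError(f"{path}:{lineno}: expected 'child<TAB>parent', got {fieldsrow!r}")
        child, parent = fieldsrow
        terms.update((child, parent))
        edges.add((child, parent))
    return DiseaseOntology(terms, edges, dict(disease_to_term or {}))


def write_ontology_edges(onto: DiseaseOntology, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for child, parent in sorted(onto.parent_edges):
            fh.write(f"{child}\t{parent}\n")
        linked = {t for e in onto.parent_edges for t in e}
        for term in sorted(onto.terms - linked):
            fh.write(f"{term}\n")


def read_similarity_matrix(
    path: str | Path, expected_ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Read a square similarity TSV with an id header row and id first column.

    Empty cells and ``NA`` are missing.  Asymmetric cell pairs are symmetrized
    by averaging (with a warning beyond 1e-8); values outside [0,1] by more
    than 1e-6 trigger a warning and are clipped.
    """
    rows = list(_data_rows(path))
    if not rows:
        raise ValueError(f"{path}: empty similarity file")
    header = rows[0][1]
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        raise ValueError(f"{path}: duplicate header ids")
    n = len(col_ids)
    row_ids: list[str] = []
    values = np.full((n, n), np.nan)
    for k, (lineno, fieldsrow) in enumerate(rows[1:]):
        if len(fieldsrow) != n + 1:
            raise ValueError(f"{path}:{lineno}: expected {n + 1} columns, got {len(fieldsrow)}")
        row_ids.append(fieldsrow[0])
        for j, cell in enumerate(fieldsrow[1:]):
            if cell.strip() in _MISSING_TOKENS:
                continue
            values[k, j] = float(cell)
    if len(row_ids) != n or row_ids != col_ids:
        raise ValueError(f"{path}: matrix is not square with matching row/column ids")
    if expected_ids is not None and list(expected_ids) != col_ids:
        offenders = sorted(set(expected_ids) ^ set(col_ids))
        raise ValueError(f"similarity ids do not match the association universe: {offenders}")

    missing = np.isnan(values) | np.isnan(values.T)
    both = ~missing
    asym = np.abs(np.where(both, values - values.T, 0.0))
    if asym.max(initial=0.0) > 1e-8:
        warnings.warn(f"{path}: asymmetric entries up to {asym.max():.3g}; symmetrized by averaging")
    sym = np.where(both, (values + np.where(np.isnan(values.T), 0, values.T)) / 2.0, 0.0)
    out_of_range = both & ((sym < -1e-6) | (sym > 1 + 1e-6))
    if out_of_range.any():
        warnings.warn(f"{path}: {out_of_range.sum()} entries outside [0,1]; clipped")
    sym = np.clip(sym, 0.0, 1.0)
    sym[missing] = 0.0
    return SimilarityMatrix(col_ids, sym, missing)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as TSV; round-trips values bit-exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, ident in enumerate(sim.ids):
            cells = [
                "" if sim.missing[i, j] else repr(float(sim.values[i, j]))
                for j in range(sim.n)
            ]
            fh.write(ident + "\t" + "\t".join(cells) + "\n")


def write_run_log(path: str | Path, config: Mapping, seeds: Mapping[str, int]) -> None:
    """Persist the resolved configuration and every RNG seed of a run."""
    payload = {"config": dict(config), "seeds": dict(seeds)}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
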