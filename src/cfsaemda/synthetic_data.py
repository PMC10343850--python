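"""Synthetic ontologies, association matrices and functional-similarity matrices.

The generators emulate the three inputs of the pipeline — a disease ontology,
a binary miRNA-disease adjacency matrix, and a miRNA functional-similarity
matrix with missing entries — so that every downstream stage can be exercised
and benchmarked without any database download.  Associations carry a planted
low-rank logistic signal whose strength is tunable, which gives recovery
benchmarks a continuous dial from pure noise (``signal=0``) to an easily
learnable structure.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import AssociationMatrix, DiseaseOntology, SimilarityMatrix

__all__ = [
    "PlantedModel",
    "generate_ontology",
    "generate_associations",
    "generate_functional_similarity",
    "make_worked_example",
]


@dataclass
class PlantedModel:
    """Latent factors behind a generated association matrix.

    ``A(i,j) ~ Bernoulli(sigmoid(scale * U_i . V_j + bias))``; the bias is
    calibrated by bisection so the expected density matches ``density_target``.
    """

    U: np.ndarray
    V: np.ndarray
    bias: float
    scale: float
    density_target: float

    def probabilities(self) -> np.ndarray:
        return expit(self.scale * (self.U @ self.V.T) + self.bias)


def generate_ontology(
    n_terms: int,
    max_parents: int = 2,
    seed: int = 0,
    term_ids: list[str] | None = None,
) -> DiseaseOntology:
    """Random DAG forest: term k may take 1..max_parents parents among terms < k.

    Term 0 is always a root; each later term is a root with probability 0.1.
    Edges point child -> parent, so the graph is acyclic by construction.
    """
    if n_terms < 1 or max_parents < 1:
        raise ValueError("n_terms and max_parents must be >= 1")
    if term_ids is None:
        term_ids = [f"t{k:04d}" for k in range(n_terms)]
    elif len(term_ids) != n_terms:
        raise ValueError("term_ids length must equal n_terms")
    rng = np.random.default_rng(seed)
    edges: set[tuple[str, str]] = set()
    for k in range(1, n_terms):
        if rng.random() < 0.1:
            continue  # extra root
        n_par = int(rng.integers(1, min(max_parents, k) + 1))
        parents = rng.choice(k, size=n_par, replace=False)
        for p in parents:
            edges.add((term_ids[k], term_ids[int(p)]))
    return DiseaseOntology(set(term_ids), edges)


def generate_associations(
    nm: int,
    nd: int,
    rank: int = 5,
    density: float = 0.1,
    signal: float = 0.0,
    seed: int = 0,
    mirna_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> tuple[AssociationMatrix, PlantedModel]:
    """Planted low-rank Bernoulli association matrix.

    With ``signal=0`` entries are i.i.d. Bernoulli(density).  The bias is
    calibrated by bisection so the expected density hits ``density`` despite
    the nonlinearity of the sigmoid.
    """
    if nm < 2 or nd < 2:
        raise ValueError("nm and nd must be >= 2")
    if not 0 < density < 1:
        raise ValueError("density must be in (0,1)")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((nm, rank)) / np.sqrt(rank)
    V = rng.standard_normal((nd, rank)) / np.sqrt(rank)
    logits = signal * (U @ V.T)

    lo, hi = -50.0, 50.0
    bias = 0.0
    for _ in range(100):
        bias = (lo + hi) / 2.0
        mean_p = float(expit(logits + bias).mean())
        if abs(mean_p - density) < 1e-12:
            break
        if mean_p < density:
            lo = bias
        else:
            hi = bias
    mean_p = float(expit(logits + bias).mean())
    if abs(mean_p - density) > 0.2 * density:
        raise RuntimeError(
            f"density calibration failed: expected {density}, achieved {mean_p:.4g}"
        )

    A = (rng.random((nm, nd)) < expit(logits + bias)).astype(np.int8)
    if mirna_ids is None:
        mirna_ids = [f"m{i:04d}" for i in range(nm)]
    if disease_ids is None:
        disease_ids = [f"d{j:04d}" for j in range(nd)]
    model = PlantedModel(U=U, V=V, bias=float(bias), scale=float(signal), density_target=density)
    return AssociationMatrix(mirna_ids, disease_ids, A), model


def generate_functional_similarity(
    model: PlantedModel,
    missing_frac: float = 0.0,
    seed: int = 0,
    mirna_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Cosine-derived functional similarity ``(1 + cos(U_i, U_j)) / 2``.

    A random symmetric subset of off-diagonal pairs (fraction ``missing_frac``)
    is masked missing, emulating miRNAs absent from curated similarity data.
    """
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must be in [0,1)")
    U = model.U
    norms = np.linalg.norm(U, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm latent row: cosine similarity undefined")
    cos = (U / norms[:, None]) @ (U / norms[:, None]).T
    values = np.clip((1.0 + cos) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    values = (values + values.T) / 2.0

    nm = U.shape[0]
    rng = np.random.default_rng(seed)
    missing = np.zeros((nm, nm), dtype=bool)
    iu, ju = np.triu_indices(nm, k=1)
    n_mask = int(round(missing_frac * len(iu)))
    if n_mask:
        pick = rng.choice(len(iu), size=n_mask, replace=False)
        missing[iu[pick], ju[pick]] = True
        missing |= missing.T
    values = values.copy()
    values[missing] = 0.0
    if mirna_ids is None:
        mirna_ids = [f"m{i:04d}" for i in range(nm)]
    return SimilarityMatrix(mirna_ids, values, missing)


def make_worked_example() -> tuple[AssociationMatrix, DiseaseOntology, SimilarityMatrix]:
    """Fixed 4 miRNA x 3 disease fixture with hand-checkable similarity values.

    Diseases d1 and d2 share the ontology parent p; d3 is absent from the
    ontology, so its semantic similarities are missing and the integration
    step must fall back to the GIP kernel.  MFS(m1,m2) is missing for the
    same reason on the miRNA side.
    """
    mirna_ids = ["m1", "m2", "m3", "m4"]
    disease_ids = ["d1", "d2", "d3"]
    A = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]], dtype=np.int8)
    assoc = AssociationMatrix(mirna_ids, disease_ids, A)

    onto = DiseaseOntology(terms={"d1", "d2", "p"}, parent_edges={("d1", "p"), ("d2", "p")})

    values = np.array(
        [
            [1.0, 0.0, 0.4, 0.2],
            [0.0, 1.0, 0.6, 0.3],
            [0.4, 0.6, 1.0, 0.5],
            [0.2, 0.3, 0.5, 1.0],
        ]
    )
    missing = np.zeros((4, 4), dtype=bool)
    missing[0, 1] = missing[1, 0] = True
    mfs = SimilarityMatrix(mirna_ids, values, missing)
    return assoc, onto, mfs
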