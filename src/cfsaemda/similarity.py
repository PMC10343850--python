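"""Disease semantic similarity, GIP kernel similarity and their integration.

Two semantic schemes are computed over each disease's ancestor closure in the
ontology DAG.  The Wang scheme assigns a disease's own term contribution 1 and
decays by a factor mu (default 0.5) per step toward the root, taking the
maximum over children at each ancestor:

    C1_d(d) = 1;   C1_d(k) = mu * max{ C1_d(k') : k' child of k in the closure }

The Xuan scheme is an information-content weighting shared across diseases:
``C2(k) = -log(NG(k) / nd)`` where NG(k) counts the disease closures that
contain k.  Both schemes score a disease pair by the sum of their shared-term
contributions normalised by the two semantic values, and the final semantic
similarity is the elementwise mean of the two schemes.

GIP kernel similarity is an RBF kernel on binary interaction profiles with a
bandwidth normalised by the mean squared profile norm:

    KS(i,j)   = exp(-alpha * ||IP_i - IP_j||^2)
    alpha     = alpha' / mean_i ||IP_i||^2         (alpha' = 1 by default)

Integration takes the mean of the primary similarity (functional or semantic)
and the GIP kernel where the primary entry exists, and falls back to the GIP
kernel alone where it is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import AssociationMatrix, DiseaseOntology, SimilarityMatrix

__all__ = [
    "SemanticParams",
    "GIPParams",
    "DiseaseDAG",
    "ancestor_closure",
    "semantic_contribution_wang",
    "semantic_value",
    "semantic_contribution_xuan",
    "semantic_similarity",
    "combined_semantic_similarity",
    "gip_bandwidth",
    "gip_kernel",
    "mirna_gip_similarity",
    "disease_gip_similarity",
    "integrate_similarity",
    "integrated_similarities",
]


@dataclass
class SemanticParams:
    """mu: semantic contribution decay per ancestor step; log_base for the
    information-content weighting (natural log by default)."""

    mu: float = 0.5
    log_base: float = math.e

    def __post_init__(self) -> None:
        if not 0 < self.mu < 1:
            raise ValueError("mu must be in (0,1)")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


@dataclass
class GIPParams:
    """Bandwidth numerators alpha'_m / alpha'_d of the GIP kernels."""

    alpha_prime_m: float = 1.0
    alpha_prime_d: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_prime_m <= 0 or self.alpha_prime_d <= 0:
            raise ValueError("bandwidth numerators must be positive")


@dataclass
class DiseaseDAG:
    """Ancestor closure of one disease: the node set G(d) and induced edges E(d).

    ``root`` is the ontology term the disease maps onto (the closure source).
    """

    disease: str
    root: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def ancestor_closure(onto: DiseaseOntology, disease_id: str) -> DiseaseDAG | None:
    """G(d) = {d} plus everything reachable along child->parent edges.

    Returns None (semantic similarity unavailable) when the disease has no
    ontology coverage.
    """
    term = onto.term_for(disease_id)
    if term is None:
        return None
    g = onto.graph()
    nodes = {term} | nx.descendants(g, term)  # descendants along child->parent = ancestors
    edges = {(c, p) for c, p in onto.parent_edges if c in nodes and p in nodes}
    return DiseaseDAG(
        disease=disease_id, root=term, nodes=frozenset(nodes), edges=frozenset(edges)
    )


def semantic_contribution_wang(dag: DiseaseDAG, params: SemanticParams | None = None) -> dict[str, float]:
    """Per-ancestor contributions C1 computed in topological (child-first) order."""
    params = params or SemanticParams()
    g = dag.graph()
    start = dag.root
    children: dict[str, list[str]] = {n: [] for n in g.nodes}
    for c, p in dag.edges:
        children[p].append(c)
    contrib: dict[str, float] = {}
    for node in nx.topological_sort(g):  # children before parents (edges child->parent)
        if node == start:
            contrib[node] = 1.0
        else:
            contrib[node] = params.mu * max(contrib[c] for c in children[node])
    return contrib


def semantic_value(contributions: dict[str, float]) -> float:
    """Semantic value of a disease: the sum of contributions over its closure."""
    if not contributions:
        raise ValueError("empty contribution map")
    return float(sum(contributions.values()))


def semantic_contribution_xuan(
    onto: DiseaseOntology,
    diseases: list[str],
    params: SemanticParams | None = None,
    closures: dict[str, DiseaseDAG | None] | None = None,
) -> dict[str, float]:
    """Shared information-content contributions C2(k) = -log(NG(k)/nd)."""
    params = params or SemanticParams()
    if not diseases:
        raise ValueError("disease list is empty")
    nd = len(diseases)
    if closures is None:
        closures = {d: ancestor_closure(onto, d) for d in diseases}
    ng: dict[str, int] = {}
    for d in diseases:
        dag = closures[d]
        if dag is None:
            continue
        for k in dag.nodes:
            ng[k] = ng.get(k, 0) + 1
    base = math.log(params.log_base)
    return {k: -math.log(count / nd) / base for k, count in ng.items()}


def _pair_score(
    shared: frozenset[str],
    ci: dict[str, float],
    cj: dict[str, float],
    vi: float,
    vj: float,
    i_eq_j: bool,
) -> float:
    denom = vi + vj
    if denom == 0.0:
        return 1.0 if i_eq_j else 0.0
    num = sum(ci[k] + cj[k] for k in shared)
    return num / denom


def semantic_similarity(
    onto: DiseaseOntology,
    diseases: list[str],
    params: SemanticParams | None = None,
    scheme: str = "wang",
) -> SimilarityMatrix:
    """Disease-disease semantic similarity under the Wang or Xuan scheme.

    Pairs where either disease lacks ontology coverage are marked missing
    (including the diagonal of uncovered diseases), so downstream integration
    falls back to the GIP kernel there.
    """
    params = params or SemanticParams()
    if scheme not in {"wang", "xuan"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    n = len(diseases)
    closures = {d: ancestor_closure(onto, d) for d in diseases}

    contribs: dict[str, dict[str, float]] = {}
    if scheme == "wang":
        for d in diseases:
            if closures[d] is not None:
                contribs[d] = semantic_contribution_wang(closures[d], params)
    else:
        c2 = semantic_contribution_xuan(onto, diseases, params, closures)
        for d in diseases:
            if closures[d] is not None:
                contribs[d] = {k: c2[k] for k in closures[d].nodes}

    values = np.zeros((n, n))
    missing = np.ones((n, n), dtype=bool)
    sem_value = {d: semantic_value(contribs[d]) for d in contribs}
    covered = [i for i, d in enumerate(diseases) if d in contribs]
    for a, i in enumerate(covered):
        di = diseases[i]
        for j in covered[a:]:
            dj = diseases[j]
            shared = closures[di].nodes & closures[dj].nodes
            s = _pair_score(
                frozenset(shared), contribs[di], contribs[dj],
                sem_value[di], sem_value[dj], i == j,
            )
            values[i, j] = values[j, i] = s
            missing[i, j] = missing[j, i] = False
    for i in covered:
        values[i, i] = 1.0
    return SimilarityMatrix(list(diseases), np.clip(values, 0.0, 1.0), missing)


def combined_semantic_similarity(
    dss1: SimilarityMatrix, dss2: SimilarityMatrix
) -> SimilarityMatrix:
    """Elementwise mean of the two semantic schemes; missing if either is."""
    if dss1.ids != dss2.ids:
        raise ValueError("semantic similarity matrices have different id orderings")
    missing = dss1.missing | dss2.missing
    values = np.where(missing, 0.0, (dss1.values + dss2.values) / 2.0)
    return SimilarityMatrix(list(dss1.ids), values, missing)


def gip_bandwidth(profiles: np.ndarray, alpha_prime: float = 1.0) -> float:
    """alpha = alpha' / mean squared profile norm."""
    profiles = np.asarray(profiles, dtype=float)
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("degenerate interaction profiles: all-zero matrix")
    return alpha_prime / mean_sq


def gip_kernel(profiles: np.ndarray, alpha: float, ids: list[str] | None = None) -> SimilarityMatrix:
    """RBF kernel exp(-alpha * ||IP_i - IP_j||^2) with exact unit diagonal."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    profiles = np.asarray(profiles, dtype=float)
    sq = (profiles**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (profiles @ profiles.T)
    d2 = np.maximum(d2, 0.0)
    values = np.exp(-alpha * d2)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    if ids is None:
        ids = [str(i) for i in range(profiles.shape[0])]
    return SimilarityMatrix(ids, values)


def mirna_gip_similarity(assoc: AssociationMatrix, params: GIPParams | None = None) -> SimilarityMatrix:
    params = params or GIPParams()
    profiles = assoc.mirna_profiles()
    alpha = gip_bandwidth(profiles, params.alpha_prime_m)
    return gip_kernel(profiles, alpha, list(assoc.mirna_ids))


def disease_gip_similarity(assoc: AssociationMatrix, params: GIPParams | None = None) -> SimilarityMatrix:
    params = params or GIPParams()
    profiles = assoc.disease_profiles()
    alpha = gip_bandwidth(profiles, params.alpha_prime_d)
    return gip_kernel(profiles, alpha, list(assoc.disease_ids))


def integrate_similarity(primary: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Mean of primary and GIP where the primary exists, GIP alone elsewhere."""
    if primary.ids != gip.ids:
        raise ValueError("similarity matrices have different id orderings")
    if gip.missing.any():
        raise ValueError("GIP similarity must have no missing entries")
    values = np.where(primary.missing, gip.values, (primary.values + gip.values) / 2.0)
    return SimilarityMatrix(list(primary.ids), values)


def integrated_similarities(
    assoc: AssociationMatrix,
    onto: DiseaseOntology | None = None,
    mfs: SimilarityMatrix | None = None,
    sem_params: SemanticParams | None = None,
    gip_params: GIPParams | None = None,
    keep_intermediates: bool = False,
) -> tuple[SimilarityMatrix, SimilarityMatrix] | tuple[SimilarityMatrix, SimilarityMatrix, dict]:
    """Full similarity stage: (MS, DS) from associations, ontology and MFS.

    Without an ontology (or MFS) the corresponding integrated similarity
    reduces to the GIP kernel alone.
    """
    ksm = mirna_gip_similarity(assoc, gip_params)
    ksd = disease_gip_similarity(assoc, gip_params)

    intermediates: dict[str, SimilarityMatrix] = {"KSM": ksm, "KSD": ksd}
    if mfs is not None:
        ms = integrate_similarity(mfs, ksm)
    else:
        ms = ksm
    if onto is not None:
        dss1 = semantic_similarity(onto, list(assoc.disease_ids), sem_params, "wang")
        dss2 = semantic_similarity(onto, list(assoc.disease_ids), sem_params, "xuan")
        dss = combined_semantic_similarity(dss1, dss2)
        intermediates.update({"DSS1": dss1, "DSS2": dss2, "DSS": dss})
        ds = integrate_similarity(dss, ksd)
    else:
        ds = ksd
    if keep_intermediates:
        return ms, ds, intermediates
    return ms, ds
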