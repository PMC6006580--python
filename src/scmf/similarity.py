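"""Drug-drug and disease-disease similarity measures.

Drug similarity is the Jaccard index of binary descriptor vectors
(substructures, targets, enzymes, pathways, interaction partners, ...):

    J(P, Q) = |P ∩ Q| / |P ∪ Q|

Disease similarity is a MeSH-based semantic measure.  Each disease maps to
one or more dot-delimited MeSH tree numbers; the union of all ancestor
prefixes forms a directed acyclic graph DAG(A) whose edges point from
ancestors toward the disease term.  A node d contributes

    C_A(d) = 1                                  if d is the disease term
    C_A(d) = max{ delta * C_A(d') : d' child of d }   otherwise

with semantic contribution factor ``delta`` (0.5 by default).  The semantic
value DV(A) is the sum of all contributions, and two diseases are compared
through their shared ancestors:

    S(A, B) = sum_{d in N(A) ∩ N(B)} (C_A(d) + C_B(d)) / (DV(A) + DV(B))

which is 1 exactly when the two DAGs coincide and 0 when they share no term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .containers import BinaryFeatureTable, SimilarityMatrix

__all__ = [
    "DEFAULT_DELTA",
    "DiseaseDAG",
    "jaccard",
    "pairwise_jaccard",
    "build_dag",
    "contributions",
    "semantic_value",
    "semantic_similarity",
    "pairwise_semantic",
]

#: Semantic contribution factor: per-edge decay of an ancestor's contribution.
DEFAULT_DELTA = 0.5


# ---------------------------------------------------------------------------
# Drug side: Jaccard over binary descriptor vectors
# ---------------------------------------------------------------------------

def jaccard(p, q) -> float:
    """Jaccard similarity of two equal-length binary vectors.

    A pair of all-zero vectors has an empty union; the similarity is
    defined as 0 in that case (no descriptor evidence of relatedness).
    """
    p = np.asarray(p, dtype=int).ravel()
    q = np.asarray(q, dtype=int).ravel()
    if p.shape != q.shape:
        raise ValueError(f"feature vectors differ in length: {p.size} vs {q.size}")
    inter = int(np.sum((p == 1) & (q == 1)))
    union = int(np.sum((p == 1) | (q == 1)))
    if union == 0:
        return 0.0
    return inter / union


def pairwise_jaccard(table: BinaryFeatureTable) -> SimilarityMatrix:
    """All-pairs Jaccard similarity of the rows of a binary feature table.

    Entities with no set bits get zero similarity to everything, including
    themselves (a warning is emitted since an all-zero self-similarity
    breaks the usual unit diagonal).
    """
    bits = np.asarray(table.bits, dtype=float)
    counts = bits.sum(axis=1)
    inter = bits @ bits.T
    union = counts[:, None] + counts[None, :] - inter
    empty = counts == 0
    if empty.any():
        ids = [table.entity_ids[i] for i in np.flatnonzero(empty)[:5]]
        warnings.warn(
            f"{int(empty.sum())} entities have no descriptors set "
            f"(e.g. {ids}); their similarities (incl. self) are 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(list(table.entity_ids), sim)


# ---------------------------------------------------------------------------
# Disease side: MeSH DAG semantic similarity
# ---------------------------------------------------------------------------

@dataclass
class DiseaseDAG:
    """Ancestor DAG of a disease's MeSH terms.

    Edges run parent -> child, i.e. from ancestors toward the disease's own
    term(s).  Nodes are MeSH term identifiers; two diseases share a node in
    the semantic similarity exactly when their DAGs contain the same term
    identifier.
    """

    disease_id: str
    graph: nx.DiGraph
    terms: frozenset  # the disease's own term(s), contribution fixed to 1

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ValueError(f"disease {self.disease_id!r}: empty DAG")
        if not self.terms:
            raise ValueError(f"disease {self.disease_id!r}: no disease term")
        if not self.terms <= set(self.graph.nodes):
            raise ValueError(
                f"disease {self.disease_id!r}: disease terms missing from DAG nodes"
            )


def build_dag(
    tree_numbers: Sequence[str],
    disease_id: str = "",
    term_map: Mapping[str, str] | None = None,
) -> DiseaseDAG:
    """Build the ancestor DAG from dot-delimited MeSH tree numbers.

    Every prefix of every tree number becomes a node; each prefix is linked
    to its one-segment extension.  Multiple tree numbers for the same
    disease are merged into a single DAG (union of nodes and edges), and the
    full tree numbers themselves mark the disease's own term(s).

    ``term_map`` optionally translates tree-number prefixes to MeSH term
    identifiers (the same descriptor can carry several tree numbers); by
    default the prefix string itself is the node identity.
    """
    tree_numbers = [t.strip() for t in tree_numbers if t and t.strip()]
    if not tree_numbers:
        raise ValueError(f"disease {disease_id!r}: no MeSH tree numbers given")
    lookup = (lambda s: term_map.get(s, s)) if term_map else (lambda s: s)

    g = nx.DiGraph()
    terms = set()
    for tn in tree_numbers:
        parts = tn.split(".")
        if any(not p for p in parts):
            raise ValueError(f"malformed tree number {tn!r}")
        prefixes = [".".join(parts[: i + 1]) for i in range(len(parts))]
        nodes = [lookup(p) for p in prefixes]
        g.add_nodes_from(nodes)
        g.add_edges_from(zip(nodes[:-1], nodes[1:]))
        terms.add(nodes[-1])
    return DiseaseDAG(disease_id=disease_id, graph=g, terms=frozenset(terms))


def contributions(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> dict:
    """Per-node semantic contributions C_A(d), by reverse-topological sweep.

    The disease's own term(s) contribute 1; every ancestor contributes the
    maximum of ``delta`` times its children's contributions, so a node's
    contribution is ``delta`` to the power of its shortest descendant path
    to a disease term.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    try:
        order = list(nx.topological_sort(dag.graph))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError(
            f"disease {dag.disease_id!r}: DAG contains a cycle"
        ) from exc
    cmap: dict = {}
    for node in reversed(order):  # children before parents
        if node in dag.terms:
            cmap[node] = 1.0
            continue
        children = list(dag.graph.successors(node))
        if not children:
            raise ValueError(
                f"disease {dag.disease_id!r}: node {node!r} is not an ancestor "
                "of any disease term"
            )
        cmap[node] = max(delta * cmap[c] for c in children)
    return cmap


def semantic_value(cmap: Mapping) -> float:
    """Semantic value DV(A): the sum of all node contributions."""
    if not cmap:
        raise ValueError("empty contribution map")
    return float(sum(cmap.values()))


def semantic_similarity(
    dag_a: DiseaseDAG, dag_b: DiseaseDAG, delta: float = DEFAULT_DELTA
) -> float:
    """Semantic similarity S(A, B) between two diseases.

    Shared nodes are matched by term identifier.  Identical DAGs give
    exactly 1; disjoint DAGs give 0.
    """
    ca = contributions(dag_a, delta)
    cb = contributions(dag_b, delta)
    shared = set(ca) & set(cb)
    if not shared:
        return 0.0
    num = sum(ca[d] + cb[d] for d in shared)
    return float(num / (semantic_value(ca) + semantic_value(cb)))


def pairwise_semantic(
    dags: Sequence[DiseaseDAG], delta: float = DEFAULT_DELTA
) -> SimilarityMatrix:
    """All-pairs semantic similarity; contribution maps computed once each."""
    cmaps = [contributions(d, delta) for d in dags]
    dvs = [semantic_value(c) for c in cmaps]
    n = len(dags)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = cmaps[i].keys() & cmaps[j].keys()
            if shared:
                num = sum(cmaps[i][d] + cmaps[j][d] for d in shared)
                sim[i, j] = sim[j, i] = num / (dvs[i] + dvs[j])
    return SimilarityMatrix([d.disease_id for d in dags], sim)
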