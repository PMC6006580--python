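"""Planted-structure synthetic data for end-to-end testing.

Real drug-disease networks are large, curated downloads; the generator
instead plants exactly the structure the model assumes — a low-rank
association signal plus similarity matrices coherent with the planted latent
factors — so recovery, the value of the similarity constraint, and the whole
cross-validation protocol can be exercised at desk scale with full knowledge
of the ground truth.

Latent factors are i.i.d. nonnegative (Gamma(0.5, 1): the heavy lower tail
gives rows distinct sparsity patterns, so cosine similarity between rows is
genuinely informative about the planted neighborhoods).  Associations are
the top-scoring fraction of X_true Y_true^T cells ("richness" = fraction of
pairs that are associations), optionally corrupted by relocating a fraction
of positives (label noise emulating imperfect curation); similarities
interpolate between the cosine similarity of the true factor rows and
symmetric uniform noise with mixing weight alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix, as_array
from .similarity import DiseaseDAG, build_dag

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "richness_filter",
    "mesh_fixture",
]


@dataclass
class SyntheticSpec:
    """Parameters of a planted dataset.

    ``richness`` is the fraction of drug-disease pairs that are positive
    (association count / (n*m)); ``alpha`` in [0, 1] is the informativeness
    of the similarity matrices (1 = pure factor-derived cosine similarity,
    0 = pure noise); ``noise`` is the fraction of the positive labels
    relocated to random unassociated cells, emulating curation errors and
    incompleteness.  With ``noise=0`` the labels are an exact function of
    the planted scores and association data alone identifies the factors,
    which makes the similarity constraint redundant by construction; the
    default 0.3 keeps supervision imperfect the way curated association
    databases are.
    """

    n: int = 60
    m: int = 80
    k_true: int = 4
    richness: float = 0.1
    alpha: float = 0.9
    noise: float = 0.3
    seed: int = 0
    bernoulli: bool = False  # sample labels instead of exact-count threshold

    def __post_init__(self) -> None:
        if not 0.0 < self.richness < 1.0:
            raise ValueError(f"richness must be in (0, 1), got {self.richness}")
        if not 1 <= self.k_true < min(self.n, self.m):
            raise ValueError(
                f"k_true={self.k_true} outside [1, {min(self.n, self.m) - 1}]"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.noise < 1.0:
            raise ValueError(f"noise must be in [0, 1), got {self.noise}")


@dataclass
class SyntheticDataset:
    A: AssociationMatrix
    Wd: SimilarityMatrix
    Ws: SimilarityMatrix
    X_true: np.ndarray
    Y_true: np.ndarray
    positive_cells: np.ndarray  # (q, 2) indices of planted positives


def _cosine_rows(F: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(F, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    C = (F / norms[:, None]) @ (F / norms[:, None]).T
    C = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def _noise_similarity(n: int, rng: np.random.Generator) -> np.ndarray:
    raw = rng.uniform(0.0, 1.0, size=(n, n))
    sym = 0.5 * (raw + raw.T)
    off = ~np.eye(n, dtype=bool)
    lo, hi = sym[off].min(), sym[off].max()
    if hi > lo:
        sym = (sym - lo) / (hi - lo)
    sym = np.clip(sym, 0.0, 1.0)
    np.fill_diagonal(sym, 1.0)
    return sym


def _mixed_similarity(F: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    W = alpha * _cosine_rows(F) + (1.0 - alpha) * _noise_similarity(F.shape[0], rng)
    np.fill_diagonal(W, 1.0)
    return W


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a planted dataset; fully deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    X = rng.gamma(shape=0.5, scale=1.0, size=(spec.n, spec.k_true))
    Y = rng.gamma(shape=0.5, scale=1.0, size=(spec.m, spec.k_true))
    S = X @ Y.T

    total = spec.n * spec.m
    q = int(round(spec.richness * total))
    if not 1 <= q < total:
        raise ValueError(
            f"richness {spec.richness} gives {q} positives for {total} cells; "
            "no threshold achieves it"
        )
    A = np.zeros_like(S)
    if spec.bernoulli:
        # probability proportional to score, scaled to hit richness in expectation
        p = np.clip(S / S.sum() * q, 0.0, 1.0)
        A = (rng.uniform(size=S.shape) < p).astype(float)
        if A.sum() == 0:
            raise ValueError("Bernoulli sampling produced no positives")
    else:
        flat = np.argpartition(-S.ravel(), q - 1)[:q]
        A.ravel()[flat] = 1.0

    if spec.noise > 0:
        # relocate a fraction of positives to random zero cells: false
        # associations plus an equal number of missed true ones, at
        # unchanged richness
        pos = np.flatnonzero(A.ravel() == 1)
        neg = np.flatnonzero(A.ravel() == 0)
        n_flip = int(round(spec.noise * pos.size))
        if n_flip:
            A.ravel()[rng.choice(pos, n_flip, replace=False)] = 0.0
            A.ravel()[rng.choice(neg, n_flip, replace=False)] = 1.0

    Wd = _mixed_similarity(X, spec.alpha, rng)
    Ws = _mixed_similarity(Y, spec.alpha, rng)

    drug_ids = [f"DR{i:04d}" for i in range(spec.n)]
    disease_ids = [f"DI{j:04d}" for j in range(spec.m)]
    return SyntheticDataset(
        A=AssociationMatrix(drug_ids, disease_ids, A),
        Wd=SimilarityMatrix(drug_ids, Wd),
        Ws=SimilarityMatrix(disease_ids, Ws),
        X_true=X,
        Y_true=Y,
        positive_cells=np.argwhere(A == 1),
    )


def richness_filter(A: AssociationMatrix, min_count: int = 1) -> AssociationMatrix:
    """Iteratively drop sparse drugs/diseases until the matrix is stable.

    Drugs with fewer than ``min_count`` associations and diseases with fewer
    than ``min_count`` associations are removed; because removing one side
    can push the other below threshold, removal repeats to a fixed point.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    vals = A.values
    rows = np.arange(A.n_drugs)
    cols = np.arange(A.n_diseases)
    while True:
        sub = vals[np.ix_(rows, cols)]
        keep_r = sub.sum(axis=1) >= min_count
        keep_c = sub.sum(axis=0) >= min_count
        if keep_r.all() and keep_c.all():
            break
        rows = rows[keep_r]
        cols = cols[keep_c]
        if rows.size == 0 or cols.size == 0:
            raise ValueError(
                f"richness filter with min_count={min_count} removed everything"
            )
    return AssociationMatrix(
        [A.drug_ids[i] for i in rows],
        [A.disease_ids[j] for j in cols],
        vals[np.ix_(rows, cols)].copy(),
    )


def mesh_fixture(
    depth: int = 3,
    branching: int = 2,
    disease_count: int = 10,
    seed: int = 0,
) -> list[DiseaseDAG]:
    """Random MeSH-like hierarchies for similarity tests.

    A synthetic vocabulary tree with ``branching`` roots and ``branching``
    children per node is sampled; every disease receives one or two
    full-depth tree numbers.  With few roots relative to diseases, shared
    prefixes (hence nondegenerate pairwise similarities) are guaranteed;
    with ``branching=1`` all diseases share the single full path and are
    pairwise identical.
    """
    if depth < 1 or branching < 1 or disease_count < 1:
        raise ValueError("depth, branching and disease_count must be >= 1")
    rng = np.random.default_rng(seed)

    def random_path() -> str:
        parts = [f"C{rng.integers(branching) + 1:02d}"]
        for _ in range(depth - 1):
            parts.append(f"{rng.integers(branching) + 1:03d}")
        return ".".join(parts)

    dags = []
    for d in range(disease_count):
        numbers = {random_path()}
        if rng.random() < 0.3:
            numbers.add(random_path())
        dags.append(build_dag(sorted(numbers), disease_id=f"SYN{d:03d}"))
    return dags
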