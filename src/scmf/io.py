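"""Readers and writers for the delimited text formats.

All formats are plain delimited text (tab by default; disease names may
contain commas).  Associations are accepted either as a two-column edge list
(drug ID, disease ID) or as a dense labeled 0/1 matrix; similarity and
feature tables are dense labeled matrices.  Round-trips preserve values and
identifier order exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AssociationMatrix, BinaryFeatureTable, SimilarityMatrix
from .factorization import FactorPair

__all__ = [
    "read_associations",
    "write_associations",
    "write_edge_list",
    "read_similarity",
    "write_similarity",
    "read_features",
    "write_features",
    "read_mesh",
    "write_mesh",
    "align_entities",
    "write_model",
    "read_model",
    "write_ranked_pairs",
    "load_config",
]

FLOAT_FORMAT = "%.6g"  # printed precision; computation stays full double


def _read_table(path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, index_col=0, dtype={0: str})


def read_associations(path, delimiter: str = "\t") -> AssociationMatrix:
    """Read an association matrix from an edge list or a dense labeled matrix.

    A file whose rows have exactly two fields is treated as an edge list
    (drug ID, disease ID; no header); anything wider is a dense matrix with
    an ID header row and ID first column.  Edge-list identifier order is
    first appearance; duplicate edges collapse to a single 1 with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if len(first.split(delimiter)) == 2:
        edges = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
        if edges.shape[1] != 2:
            raise ValueError(f"{path}: inconsistent column count in edge list")
        drugs = list(dict.fromkeys(edges[0]))
        diseases = list(dict.fromkeys(edges[1]))
        di = {d: i for i, d in enumerate(drugs)}
        dj = {d: j for j, d in enumerate(diseases)}
        vals = np.zeros((len(drugs), len(diseases)))
        dupes = 0
        for a, b in edges.itertuples(index=False):
            if vals[di[a], dj[b]] == 1.0:
                dupes += 1
            vals[di[a], dj[b]] = 1.0
        if dupes:
            warnings.warn(f"{path}: {dupes} duplicate edges collapsed")
        return AssociationMatrix(drugs, diseases, vals)
    df = _read_table(path, delimiter)
    vals = df.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError(f"{path}: dense association matrix has non-binary values")
    return AssociationMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], vals
    )


def write_associations(A: AssociationMatrix, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(A.values.astype(int), index=A.drug_ids, columns=A.disease_ids)
    df.to_csv(path, sep=delimiter)


def write_edge_list(A: AssociationMatrix, path, delimiter: str = "\t") -> None:
    """Write the positive cells as a (drug, disease) edge list, row-major."""
    with open(path, "w") as fh:
        for i, j in np.argwhere(A.values == 1):
            fh.write(f"{A.drug_ids[i]}{delimiter}{A.disease_ids[j]}\n")


def read_similarity(path, delimiter: str = "\t", tol: float = 1e-8) -> SimilarityMatrix:
    """Read a labeled square similarity matrix; validates and repairs it.

    Row and column identifiers must match exactly (same order); asymmetry
    beyond ``tol`` is averaged away and negatives are clipped, both with
    warnings.
    """
    df = _read_table(path, delimiter)
    rows = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row and column identifiers differ")
    return SimilarityMatrix(rows, df.to_numpy(dtype=float)).validated(tol)


def write_similarity(W: SimilarityMatrix, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(W.values, index=W.entity_ids, columns=W.entity_ids)
    df.to_csv(path, sep=delimiter, float_format=FLOAT_FORMAT)


def read_features(path, delimiter: str = "\t") -> BinaryFeatureTable:
    """Read a binary descriptor table: header of descriptor IDs, ID first column."""
    df = _read_table(path, delimiter)
    return BinaryFeatureTable(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=int),
    )


def write_features(t: BinaryFeatureTable, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(t.bits, index=t.entity_ids, columns=t.descriptors)
    df.to_csv(path, sep=delimiter)


def read_mesh(path, delimiter: str = "\t") -> dict[str, list[str]]:
    """Read (disease ID, tree number) pairs; repeated IDs accumulate numbers."""
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: MeSH file must have exactly two columns")
    mapping: dict[str, list[str]] = {}
    for did, tn in df.itertuples(index=False):
        mapping.setdefault(str(did), []).append(str(tn))
    return mapping


def write_mesh(mapping: dict[str, list[str]], path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for did, numbers in mapping.items():
            for tn in numbers:
                fh.write(f"{did}{delimiter}{tn}\n")


def align_entities(
    A: AssociationMatrix, Wd: SimilarityMatrix, Ws: SimilarityMatrix
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Reindex similarity matrices to the association matrix's ID orders.

    The similarity files may cover supersets of the association entities in
    any order; entities missing from a similarity matrix are an error that
    names the offenders.
    """

    def subset(W: SimilarityMatrix, ids: list[str], what: str) -> SimilarityMatrix:
        pos = {e: i for i, e in enumerate(W.entity_ids)}
        missing = [e for e in ids if e not in pos]
        if missing:
            raise ValueError(
                f"{what} similarity matrix is missing {len(missing)} "
                f"identifiers: {missing[:10]}"
            )
        idx = [pos[e] for e in ids]
        return SimilarityMatrix(list(ids), W.values[np.ix_(idx, idx)].copy())

    return A, subset(Wd, A.drug_ids, "drug"), subset(Ws, A.disease_ids, "disease")


def write_model(factors: FactorPair, drug_ids, disease_ids, outdir) -> None:
    """Write factor matrices X.tsv / Y.tsv with ID row labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = factors.X.shape[1]
    cols = [f"f{c}" for c in range(k)]
    pd.DataFrame(factors.X, index=drug_ids, columns=cols).to_csv(
        outdir / "X.tsv", sep="\t"
    )
    pd.DataFrame(factors.Y, index=disease_ids, columns=cols).to_csv(
        outdir / "Y.tsv", sep="\t"
    )


def read_model(outdir) -> tuple[FactorPair, list[str], list[str]]:
    outdir = Path(outdir)
    xf = pd.read_csv(outdir / "X.tsv", sep="\t", index_col=0)
    yf = pd.read_csv(outdir / "Y.tsv", sep="\t", index_col=0)
    factors = FactorPair(xf.to_numpy(float), yf.to_numpy(float))
    return factors, [str(i) for i in xf.index], [str(i) for i in yf.index]


def write_ranked_pairs(
    scores: np.ndarray,
    drug_ids,
    disease_ids,
    path,
    top: int | None = None,
    exclude: np.ndarray | None = None,
    delimiter: str = "\t",
) -> None:
    """Write (drug, disease, raw_score, normalized_score) sorted descending.

    ``exclude`` is an optional boolean mask of cells to drop (e.g. known
    training associations when ranking novel candidates).
    """
    from .factorization import normalize_scores

    norm = normalize_scores(scores)
    keep = np.ones(scores.shape, dtype=bool) if exclude is None else ~exclude
    cells = np.argwhere(keep)
    vals = scores[keep.nonzero()]
    order = np.argsort(-vals, kind="mergesort")
    if top is not None:
        order = order[:top]
    with open(path, "w") as fh:
        fh.write(delimiter.join(["drug", "disease", "raw_score", "normalized_score"]) + "\n")
        for idx in order:
            i, j = cells[idx]
            fh.write(
                delimiter.join(
                    [
                        str(drug_ids[i]),
                        str(disease_ids[j]),
                        FLOAT_FORMAT % scores[i, j],
                        FLOAT_FORMAT % norm[i, j],
                    ]
                )
                + "\n"
            )


def load_config(path) -> dict:
    """Load a YAML config mapping flag names to values."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
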