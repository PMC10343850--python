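"""Pairwise feature construction, negative sampling and sample splitting.

A pair (miRNA i, disease j) is represented by the concatenation of four
blocks: the i-th row of the integrated miRNA similarity MS, the j-th column
of the adjacency matrix A, the j-th row of the integrated disease similarity
DS, and the i-th row of A — 2*nm + 2*nd values in total.

The adjacency blocks contain the pair's own entry A(i,j) twice.  By default
the entry is left in place, reproducing the original construction; with
``mask_target=True`` both occurrences are zeroed, which removes the label
from its own feature vector and is required for honest recovery benchmarks
and leave-one-disease-out case studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data_io import AssociationMatrix, SimilarityMatrix

__all__ = [
    "PairFeatureSet",
    "build_pair_features",
    "sample_negatives",
    "balanced_pair_sample",
    "split_train_test",
    "kfold_partition",
]


@dataclass
class PairFeatureSet:
    """Labeled pair table: one feature row per (miRNA, disease) pair.

    ``layout`` records the column extent of each of the four blocks
    [MS_i | A_col_j | DS_j | A_row_i] so tests and downstream code can
    address blocks without re-deriving offsets.
    """

    pairs: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray
    layout: dict[str, slice]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.shape[0] != len(self.pairs) or self.y.shape[0] != len(self.pairs):
            raise ValueError("rows of X/y must match the pair list")

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "PairFeatureSet":
        idx = np.asarray(idx)
        return PairFeatureSet(
            [self.pairs[int(i)] for i in idx], self.X[idx], self.y[idx], dict(self.layout)
        )


def build_pair_features(
    ms: SimilarityMatrix,
    ds: SimilarityMatrix,
    assoc: AssociationMatrix,
    pairs: list[tuple[int, int]],
    mask_target: bool = False,
) -> PairFeatureSet:
    """Assemble the 2*nm + 2*nd feature rows for the requested pairs.

    Deterministic and order-preserving: permuting ``pairs`` permutes the rows
    identically.  The full nm*nd universe is never materialised here; callers
    pass only the pairs they need.
    """
    nm, nd = assoc.nm, assoc.nd
    if ms.n != nm or ds.n != nd:
        raise ValueError(
            f"similarity dims (MS {ms.n}, DS {ds.n}) do not match associations ({nm} x {nd})"
        )
    A = assoc.A.astype(float)
    layout = {
        "ms_row": slice(0, nm),
        "a_col": slice(nm, 2 * nm),
        "ds_row": slice(2 * nm, 2 * nm + nd),
        "a_row": slice(2 * nm + nd, 2 * nm + 2 * nd),
    }
    X = np.empty((len(pairs), 2 * nm + 2 * nd))
    y = np.empty(len(pairs), dtype=np.int8)
    for r, (i, j) in enumerate(pairs):
        if not (0 <= i < nm and 0 <= j < nd):
            raise ValueError(f"pair ({i},{j}) outside the {nm} x {nd} universe")
        a_col = A[:, j].copy()
        a_row = A[i, :].copy()
        y[r] = assoc.A[i, j]
        if mask_target:
            a_col[i] = 0.0
            a_row[j] = 0.0
        X[r, layout["ms_row"]] = ms.values[i]
        X[r, layout["a_col"]] = a_col
        X[r, layout["ds_row"]] = ds.values[j]
        X[r, layout["a_row"]] = a_row
    return PairFeatureSet(list(pairs), X, y, layout)


def sample_negatives(assoc: AssociationMatrix, n: int, seed: int) -> list[tuple[int, int]]:
    """Uniform sample of n distinct unknown (zero) pairs, without replacement."""
    zeros = np.flatnonzero(assoc.A == 0)
    if n > zeros.size:
        raise ValueError(f"requested {n} negatives but only {zeros.size} unknown pairs exist")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zeros, size=n, replace=False)
    return [(int(k) // assoc.nd, int(k) % assoc.nd) for k in chosen]


def balanced_pair_sample(
    assoc: AssociationMatrix, seed: int, exclude_diseases: set[int] | None = None
) -> list[tuple[int, int]]:
    """All positive pairs plus an equal number of sampled negatives.

    ``exclude_diseases`` removes the given disease columns from both pools
    (used by the leave-one-disease-out case study).
    """
    work = assoc
    if exclude_diseases:
        work = assoc.copy()
        for j in exclude_diseases:
            work.A[:, j] = 1  # mark as non-candidates for negative sampling
        positives = [
            (int(i), int(j))
            for i, j in zip(*np.nonzero(assoc.A))
            if int(j) not in exclude_diseases
        ]
        negatives = sample_negatives(work, len(positives), seed)
    else:
        positives = [(int(i), int(j)) for i, j in zip(*np.nonzero(assoc.A))]
        negatives = sample_negatives(assoc, len(positives), seed)
    return positives + negatives


def split_train_test(
    samples: PairFeatureSet, ratio: float = 0.8, seed: int = 0
) -> tuple[PairFeatureSet, PairFeatureSet]:
    """Stratified train/test partition with |train| = round(ratio * N)."""
    n = samples.n
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    classes, counts = np.unique(samples.y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members for a stratified split")
    n_train = int(round(ratio * n))
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=n_train, stratify=samples.y, random_state=seed, shuffle=True
    )
    return samples.subset(np.sort(train_idx)), samples.subset(np.sort(test_idx))


def kfold_partition(samples: PairFeatureSet, k: int = 4, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold index partition; fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(samples.X, samples.y)]
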