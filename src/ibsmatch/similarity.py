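"""Pairwise genetic similarity: the averaged identity-by-state score.

For individuals i, j the score is

    s_ij = 1 - (1 / 2N) * sum_k |g_ik - g_jk|

with the sum running over the N loci observed in both individuals and
g in {0, 1, 2} the minor-allele dosage.  s_ij lies in [0, 1]; s_ij = 1
means identical genotypes at all shared loci.  Optional nonnegative
per-locus weights generalise both the sum and 2N to weighted forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codec import MISSING, PackedGenotypes


class UndefinedSimilarityError(ValueError):
    """A pair of individuals shares no successfully genotyped locus."""


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise IBS scores with shared-locus counts."""

    scores: np.ndarray  # (n, n) float
    n_pairwise_loci: np.ndarray  # (n, n) number of loci observed in both
    individual_ids: list[str] = field(default_factory=list)
    locus_subset: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        ids = self.individual_ids or [f"ind{i}" for i in range(self.n)]
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(ids) + "\n")
            for i, iid in enumerate(ids):
                fh.write(iid + "\t" + "\t".join(f"{v:.6g}" for v in self.scores[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        with open(path) as fh:
            header = fh.readline().split("\t")[1:]
            ids = [h.strip() for h in header]
            rows = [line.split("\t")[1:] for line in fh if line.strip()]
        scores = np.array(rows, dtype=float)
        n = scores.shape[0]
        return cls(scores=scores, n_pairwise_loci=np.zeros((n, n), dtype=int), individual_ids=ids)


def ibs_pair(
    g_i: Sequence[int] | np.ndarray,
    g_j: Sequence[int] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
) -> float:
    """IBS score between two genotype vectors (MISSING-aware).

    Raises
    ------
    UndefinedSimilarityError
        If no locus is observed in both individuals (N = 0).
    """
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    if g_i.shape != g_j.shape:
        raise ValueError("genotype vectors must have equal length")
    shared = (g_i != MISSING) & (g_j != MISSING)
    if weights is None:
        n = int(shared.sum())
        if n == 0:
            raise UndefinedSimilarityError("no shared non-missing loci")
        diff = np.abs(g_i[shared].astype(np.int64) - g_j[shared].astype(np.int64)).sum()
        return 1.0 - diff / (2.0 * n)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    wsum = w[shared].sum()
    if wsum == 0:
        raise UndefinedSimilarityError("zero total weight over shared loci")
    diff = (w[shared] * np.abs(g_i[shared].astype(float) - g_j[shared].astype(float))).sum()
    return 1.0 - diff / (2.0 * wsum)


def ibs_matrix(
    pg: PackedGenotypes,
    locus_subset: Sequence[int] | np.ndarray | None = None,
    weights: Sequence[float] | np.ndarray | None = None,
    on_empty_pair: str = "error",
) -> SimilarityMatrix:
    """Dense IBS similarity matrix over all individual pairs.

    Implemented with one-hot dosage indicator matmuls, so the cost is a
    handful of BLAS products on (n x S) matrices.  |a - b| over dosage
    codes decomposes as 2*[a=0][b=2] + 2*[a=2][b=0] + [a=1][b in {0,2}]
    + [a in {0,2}][b=1].

    Parameters
    ----------
    on_empty_pair
        ``"error"`` raises when some pair shares no locus; ``"zero"``
        assigns that pair a score of 0 with a warning.
    """
    if pg.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    codes = pg.codes()
    subset = None
    if locus_subset is not None:
        subset = np.asarray(locus_subset)
        codes = codes[:, subset]
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if subset is not None and w.shape[0] == pg.n_snps:
            w = w[subset]
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")

    obs = codes != MISSING
    i0 = ((codes == 0) & obs).astype(np.float64)
    i1 = (codes == 1).astype(np.float64)
    i2 = (codes == 2).astype(np.float64)
    if w is not None:
        denom_mat = obs.astype(np.float64) * w
        i0w, i1w, i2w = i0 * w, i1 * w, i2 * w
    else:
        denom_mat = obs.astype(np.float64)
        i0w, i1w, i2w = i0, i1, i2

    mismatch = (
        2.0 * (i0w @ i2.T + i2w @ i0.T) + i1w @ (i0 + i2).T + (i0w + i2w) @ i1.T
    )
    n_shared_w = denom_mat @ obs.astype(np.float64).T
    n_shared = obs.astype(np.float64) @ obs.T.astype(np.float64)

    empty = n_shared_w == 0
    if empty.any():
        if on_empty_pair == "error":
            raise UndefinedSimilarityError("some pair shares no non-missing locus")
        warnings.warn("pairs with no shared loci assigned similarity 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = 1.0 - mismatch / (2.0 * n_shared_w)
    scores[empty] = 0.0
    scores = np.clip((scores + scores.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(scores, np.where(np.diag(n_shared_w) > 0, 1.0, 0.0))
    return SimilarityMatrix(
        scores=scores,
        n_pairwise_loci=n_shared.astype(np.int64),
        individual_ids=list(pg.individual_ids),
        locus_subset=subset,
    )
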