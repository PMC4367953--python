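"""Model-free agglomerative clustering driven by the assignment solver.

Each level pairs the current clusters with their most similar distinct
counterparts by solving a maximum-weight assignment on the cluster-level
average-linkage similarity matrix (self-pairing forbidden through a
strongly negative diagonal).  A proposed pairing (a, b) merges only if
it passes a cohesion-consistency vicinity criterion: at least one of the
two clusters must find the between-cluster similarity statistically
consistent with its own internal cohesion,

    c - mean(s[a x b])  <=  T_all * SE   for c in {cohesion(a), cohesion(b)},

where SE combines the sampling error of the cross-block mean and of the
cohesion mean.  Clusters whose cohesion is undefined (singletons)
always accept a merge, so agglomeration starts from individuals and
stray individuals are absorbed by their nearest cluster.  Validated
pairings are merged (following connected components, so assignment
cycles collapse in one step) and the procedure repeats until no pairing
validates; the number of clusters is emergent.

The default threshold is T_all = 3 ln(n).  The multiple of ln(n)
absorbs the upward selection bias of greedy agglomeration (clusters
form from the most similar pairs first, inflating early cohesion
estimates by a few pairwise standard deviations, an extreme-value
effect of order sqrt(2 ln n)); on stratified data the final
between-stratum cohesion deficit exceeds the allowance by orders of
magnitude, so the stopping decision is insensitive to the exact
multiplier.  Raising the threshold makes the criterion more permissive
and can only coarsen the clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .codec import Phenotype
from .similarity import SimilarityMatrix

_NEG = -1e9  # finite stand-in for -inf on the assignment diagonal


@dataclass
class ClusterAssignment:
    """Per-individual cluster labels; the cluster count is emergent."""

    labels: np.ndarray  # int, 0..n_clusters-1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_tsv(self, path: str | Path, individual_ids: Sequence[str] | None = None) -> None:
        ids = individual_ids or [str(i) for i in range(len(self.labels))]
        with open(path, "w") as fh:
            fh.write("individual_id\tcluster_id\n")
            for iid, lab in zip(ids, self.labels):
                fh.write(f"{iid}\t{lab}\n")

    @classmethod
    def from_tsv(
        cls, path: str | Path, individual_ids: Sequence[str] | None = None
    ) -> "ClusterAssignment":
        index = {iid: i for i, iid in enumerate(individual_ids)} if individual_ids else None
        pairs: list[tuple[int, int]] = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                iid, lab = line.split()
                pairs.append((index[iid] if index else int(iid), int(lab)))
        labels = np.zeros(len(pairs), dtype=np.int64)
        for i, lab in pairs:
            labels[i] = lab
        return cls(labels)


def _merge_valid(
    scores: np.ndarray, a: np.ndarray, b: np.ndarray, threshold: float
) -> bool:
    """Cohesion-consistency check for merging member sets a and b.

    The merge is accepted when at least one side's cohesion deficit is
    within ``threshold`` standard errors; sides without a defined
    cohesion (singletons) abstain, and a merge with no defined side is
    always accepted.
    """
    block = scores[np.ix_(a, b)]
    s_ab = float(block.mean())
    var_cross = float(block.var(ddof=0)) / block.size
    verdicts: list[bool] = []
    for m in (a, b):
        if len(m) >= 2:
            within = scores[np.ix_(m, m)]
            iu = np.triu_indices(len(m), k=1)
            deficit = float(within[iu].mean()) - s_ab
            se = math.sqrt(var_cross + float(within[iu].var(ddof=0)) / len(iu[0]))
            verdicts.append(deficit <= threshold * se + 1e-12)
    return (not verdicts) or any(verdicts)


def hungarian_cluster(
    sim: SimilarityMatrix,
    vicinity_param: float | None = None,
    max_levels: int | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of a similarity matrix; deterministic.

    Parameters
    ----------
    vicinity_param
        Merge-validation threshold T_all; defaults to 3 ln(n).
    """
    n = sim.n
    if n < 2:
        warnings.warn("fewer than 2 individuals: returning a single cluster", stacklevel=2)
        return ClusterAssignment(np.zeros(max(n, 1), dtype=np.int64))
    threshold = 3.0 * math.log(n) if vicinity_param is None else float(vicinity_param)
    scores = sim.scores
    clusters: list[np.ndarray] = [np.array([i]) for i in range(n)]
    levels = max_levels if max_levels is not None else n
    for _ in range(levels):
        k = len(clusters)
        if k == 1:
            break
        # average-linkage cluster-cluster similarity
        ind = np.zeros((k, n))
        for idx, members in enumerate(clusters):
            ind[idx, members] = 1.0 / len(members)
        linkage = ind @ scores @ ind.T
        np.fill_diagonal(linkage, _NEG)
        rows, cols = linear_sum_assignment(linkage, maximize=True)
        # validate each proposed pairing; merge components of valid edges
        parent = list(range(k))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        merged_any = False
        seen: set[tuple[int, int]] = set()
        for a, b in zip(rows.tolist(), cols.tolist()):
            key = (min(a, b), max(a, b))
            if a == b or key in seen:
                continue
            seen.add(key)
            if _merge_valid(scores, clusters[a], clusters[b], threshold):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
                    merged_any = True
        if not merged_any:
            break
        groups: dict[int, list[int]] = {}
        for idx in range(k):
            groups.setdefault(find(idx), []).append(idx)
        clusters = [
            np.concatenate([clusters[i] for i in members])
            for members in groups.values()
        ]
    labels = np.zeros(n, dtype=np.int64)
    for lab, members in enumerate(sorted(clusters, key=lambda m: int(m.min()))):
        labels[members] = lab
    return ClusterAssignment(labels)


def cluster_summary(assignment: ClusterAssignment, phen: Phenotype):
    """Per-cluster case/control counts as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in np.unique(assignment.labels):
        members = assignment.labels == c
        rows.append(
            {
                "cluster": int(c),
                "n": int(members.sum()),
                "n_cases": int((phen.labels[members] == 1).sum()),
                "n_controls": int((phen.labels[members] == 0).sum()),
            }
        )
    return pd.DataFrame(rows)
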