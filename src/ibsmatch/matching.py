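"""Case-control matching structures: optimal pairs, groups and clusters.

A *unit* is a matched set with at least one case and one control; trend
statistics and permutation are later computed within units.  Pairwise
matching solves one optimal assignment between cases and controls
(unbalanced samples are squared with zero-weight sinks and sink-matched
individuals dropped).  Groupwise matching iteratively re-matches the
dropped individuals onto already-matched partners, growing pairs into
small groups.  Stratum validation removes matches that straddle
population strata, either by requiring both members to share a cluster
or through the vicinity check: a pair (case x, control y) is kept when

    (t_x < T_cc and t_y < T_cc)  or  t_x == 0  or  t_y == 0

where t_x counts controls with a higher similarity to x than y has,
t_y counts cases with a higher similarity to y than x has (strict
inequalities, over the full control and case sets), and
T_cc = ln(|O| |A|).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .assignment import pad_with_sinks, solve_max_assignment
from .codec import Phenotype
from .similarity import SimilarityMatrix

Strategy = Literal["cluster", "vicinity", "none"]


@dataclass
class Unit:
    cases: list[int]
    controls: list[int]

    @property
    def members(self) -> list[int]:
        return self.cases + self.controls


@dataclass
class UnitStructure:
    """A partition of (part of) the sample into case-control units."""

    units: list[Unit]
    kind: Literal["pair", "group", "cluster"]
    removed: list[int] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def matched(self) -> list[int]:
        return [m for u in self.units for m in u.members]

    def validate(self) -> None:
        seen: set[int] = set()
        for u in self.units:
            if not u.cases or not u.controls:
                raise ValueError("every unit needs >=1 case and >=1 control")
            if self.kind == "pair" and (len(u.cases), len(u.controls)) != (1, 1):
                raise ValueError("pair units must be 1 case + 1 control")
            for m in u.members:
                if m in seen:
                    raise ValueError(f"individual {m} occurs in two units")
                seen.add(m)

    def to_tsv(self, path: str | Path, individual_ids: Sequence[str] | None = None) -> None:
        name = (lambda i: individual_ids[i]) if individual_ids else (lambda i: str(i))
        with open(path, "w") as fh:
            fh.write("individual_id\tunit_id\trole\n")
            for k, u in enumerate(self.units):
                for i in u.cases:
                    fh.write(f"{name(i)}\t{k}\tcase\n")
                for i in u.controls:
                    fh.write(f"{name(i)}\t{k}\tcontrol\n")
            for i in self.removed:
                fh.write(f"{name(i)}\t-1\tremoved\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        kind: Literal["pair", "group", "cluster"] = "group",
        individual_ids: Sequence[str] | None = None,
    ) -> "UnitStructure":
        index = {iid: i for i, iid in enumerate(individual_ids)} if individual_ids else None
        units: dict[int, Unit] = {}
        removed: list[int] = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                iid, uid, role = line.split()
                i = index[iid] if index else int(iid)
                if role == "removed":
                    removed.append(i)
                    continue
                u = units.setdefault(int(uid), Unit([], []))
                (u.cases if role == "case" else u.controls).append(i)
        return cls(units=[units[k] for k in sorted(units)], kind=kind, removed=removed)


def match_pairs(sim: SimilarityMatrix, phen: Phenotype) -> UnitStructure:
    """Optimal one-to-one case-control pairing by total IBS.

    Produces exactly min(|O|, |A|) pairs; individuals assigned to
    zero-weight sinks land in ``removed``.
    """
    cases = phen.cases
    controls = phen.controls
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need at least one case and one control")
    w = sim.scores[np.ix_(cases, controls)]
    square, sink_rows, sink_cols = pad_with_sinks(w)
    sol = solve_max_assignment(square)
    units: list[Unit] = []
    removed: list[int] = []
    for r, c in sol.pairs:
        if r in sink_rows:
            removed.append(int(controls[c]))
        elif c in sink_cols:
            removed.append(int(cases[r]))
        else:
            units.append(Unit(cases=[int(cases[r])], controls=[int(controls[c])]))
    return UnitStructure(units=units, kind="pair", removed=sorted(removed))


def vicinity_threshold(n_controls: int, n_cases: int) -> float:
    """T_cc = ln(|O| |A|)."""
    if n_controls < 1 or n_cases < 1:
        raise ValueError("both counts must be >= 1")
    return math.log(n_controls * n_cases)


def vicinity_check(
    case: int,
    control: int,
    sim: SimilarityMatrix,
    phen: Phenotype,
    t_cc: float | None = None,
) -> bool:
    """Vicinity validation of one case-control pair (strict better-mate counts)."""
    if t_cc is None:
        t_cc = vicinity_threshold(phen.n_controls, phen.n_cases)
    w_xy = sim.scores[case, control]
    t_x = int((sim.scores[case, phen.controls] > w_xy).sum())
    t_y = int((sim.scores[phen.cases, control] > w_xy).sum())
    return (t_x < t_cc and t_y < t_cc) or t_x == 0 or t_y == 0


def validate_units(
    structure: UnitStructure,
    sim: SimilarityMatrix,
    phen: Phenotype,
    strategy: Strategy,
    clusters: np.ndarray | None = None,
    t_cc: float | None = None,
) -> tuple[UnitStructure, list[int]]:
    """Remove units that fail stratum validation.

    ``cluster`` keeps a unit only when all members share one cluster;
    ``vicinity`` applies :func:`vicinity_check` to every case-control
    pair inside the unit.  Returns the surviving structure and the
    individuals rejected by validation (also appended to ``removed``).
    """
    if strategy == "cluster" and clusters is None:
        raise ValueError("cluster validation requires a cluster assignment")
    kept: list[Unit] = []
    rejected: list[int] = []
    for u in structure.units:
        if strategy == "none":
            ok = True
        elif strategy == "cluster":
            ok = len({int(clusters[m]) for m in u.members}) == 1
        else:
            ok = all(
                vicinity_check(x, y, sim, phen, t_cc) for x in u.cases for y in u.controls
            )
        if ok:
            kept.append(u)
        else:
            rejected.extend(u.members)
    out = UnitStructure(
        units=kept, kind=structure.kind, removed=sorted(structure.removed + rejected)
    )
    return out, sorted(rejected)


def match_within_clusters(
    sim: SimilarityMatrix, phen: Phenotype, clusters: np.ndarray
) -> UnitStructure:
    """Pairwise matching performed separately inside every cluster.

    Clusters lacking cases or controls contribute no units; their
    members are removed.
    """
    clusters = np.asarray(clusters)
    units: list[Unit] = []
    removed: list[int] = []
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        labels = phen.labels[members]
        if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
            removed.extend(int(m) for m in members)
            continue
        sub = match_pairs(
            SimilarityMatrix(
                scores=sim.scores[np.ix_(members, members)],
                n_pairwise_loci=sim.n_pairwise_loci[np.ix_(members, members)],
            ),
            Phenotype(labels),
        )
        for u in sub.units:
            units.append(
                Unit(
                    cases=[int(members[i]) for i in u.cases],
                    controls=[int(members[i]) for i in u.controls],
                )
            )
        removed.extend(int(members[i]) for i in sub.removed)
    return UnitStructure(units=units, kind="pair", removed=sorted(removed))


def cluster_units(phen: Phenotype, clusters: np.ndarray) -> UnitStructure:
    """Use whole clusters as units (clusters lacking a case or control drop out)."""
    clusters = np.asarray(clusters)
    units: list[Unit] = []
    removed: list[int] = []
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        ca = [int(m) for m in members if phen.labels[m] == 1]
        co = [int(m) for m in members if phen.labels[m] == 0]
        if ca and co:
            units.append(Unit(cases=ca, controls=co))
        else:
            removed.extend(int(m) for m in members)
    return UnitStructure(units=units, kind="cluster", removed=sorted(removed))


def _rematch_round(
    sim: SimilarityMatrix,
    phen: Phenotype,
    units: list[Unit],
    unmatched: set[int],
    member_unit: dict[int, int],
    validation: Strategy,
    clusters: np.ndarray | None,
    t_cc: float | None,
    new_are_controls: bool,
) -> int:
    """One assignment of unmatched controls onto matched cases (or vice versa).

    Returns the number of newly matched individuals.  A new edge is
    validated like a fresh pair; failures return the candidate to the
    unmatched pool.
    """
    if new_are_controls:
        anchors = [i for u in units for i in u.cases]
        pool = sorted(i for i in unmatched if phen.labels[i] == 0)
    else:
        anchors = [i for u in units for i in u.controls]
        pool = sorted(i for i in unmatched if phen.labels[i] == 1)
    if not anchors or not pool:
        return 0
    w = sim.scores[np.ix_(anchors, pool)].copy()
    if validation == "cluster":
        # re-matching confined within clusters: cross-cluster edges get weight 0
        same = clusters[np.asarray(anchors)][:, None] == clusters[np.asarray(pool)][None, :]
        w = np.where(same, w, 0.0)
    square, sink_rows, sink_cols = pad_with_sinks(w)
    sol = solve_max_assignment(square)
    n_new = 0
    for r, c in sol.pairs:
        if r in sink_rows or c in sink_cols:
            continue
        anchor, cand = anchors[r], pool[c]
        case, control = (anchor, cand) if new_are_controls else (cand, anchor)
        if validation == "cluster":
            ok = int(clusters[case]) == int(clusters[control])
        elif validation == "vicinity":
            ok = vicinity_check(case, control, sim, phen, t_cc)
        else:
            ok = True
        if ok:
            u = units[member_unit[anchor]]
            (u.controls if new_are_controls else u.cases).append(cand)
            member_unit[cand] = member_unit[anchor]
            unmatched.discard(cand)
            n_new += 1
    return n_new


def match_groups(
    sim: SimilarityMatrix,
    phen: Phenotype,
    validation: Strategy = "vicinity",
    clusters: np.ndarray | None = None,
) -> UnitStructure:
    """Groupwise matching: validated pairs, then iterative re-matching.

    Unmatched controls are assigned to already-matched cases and
    unmatched cases to already-matched controls; every new edge is
    validated with the chosen strategy and the newcomer joins its
    partner's unit.  Rounds repeat until a full round matches nobody.
    The vicinity threshold uses the original full |O| and |A|
    throughout.
    """
    if validation == "cluster" and clusters is None:
        raise ValueError("cluster validation requires a cluster assignment")
    t_cc = vicinity_threshold(phen.n_controls, phen.n_cases)
    if validation == "cluster":
        initial = match_within_clusters(sim, phen, clusters)
    else:
        initial = match_pairs(sim, phen)
        initial, _ = validate_units(initial, sim, phen, validation, clusters, t_cc)
    units = [Unit(list(u.cases), list(u.controls)) for u in initial.units]
    unmatched = set(range(len(phen))) - {m for u in units for m in u.members}
    member_unit = {m: k for k, u in enumerate(units) for m in u.members}
    max_rounds = phen.n_cases + phen.n_controls
    for _ in range(max_rounds):
        n_new = _rematch_round(
            sim, phen, units, unmatched, member_unit, validation, clusters, t_cc, True
        )
        n_new += _rematch_round(
            sim, phen, units, unmatched, member_unit, validation, clusters, t_cc, False
        )
        if n_new == 0 or not unmatched:
            break
    return UnitStructure(units=units, kind="group", removed=sorted(unmatched))
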