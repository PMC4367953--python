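"""Pair/group matching, vicinity validation, stratum separation."""

import math

import numpy as np
import pytest

from ibsmatch import (
    Phenotype,
    match_groups,
    match_pairs,
    match_within_clusters,
    validate_units,
    vicinity_check,
    vicinity_threshold,
)
from ibsmatch.matching import UnitStructure
from ibsmatch.popsim import SimDesign, sample_h0_study
from ibsmatch.similarity import SimilarityMatrix, ibs_matrix

def _sim(scores):
    scores = np.asarray(scores, dtype=float)
    return SimilarityMatrix(scores=scores, n_pairwise_loci=np.full(scores.shape, 100))


def test_match_pairs_unique_optimum_brute_force():
    """2 cases x 2 controls: the pairing maximising total IBS wins."""
    # individuals 0,1 controls; 2,3 cases
    s = np.eye(4)
    s[2, 0] = s[0, 2] = 0.9
    s[2, 1] = s[1, 2] = 0.2
    s[3, 0] = s[0, 3] = 0.8
    s[3, 1] = s[1, 3] = 0.6
    phen = Phenotype(np.array([0, 0, 1, 1], dtype=np.int8))
    structure = match_pairs(_sim(s), phen)
    got = {(u.cases[0], u.controls[0]) for u in structure.units}
    # brute force: {(2,0),(3,1)} totals 1.5 > {(2,1),(3,0)} totals 1.0
    assert got == {(2, 0), (3, 1)}
    assert structure.removed == []


def test_match_pairs_reduces_to_min_side():
    s = np.full((4, 4), 0.5)
    np.fill_diagonal(s, 1.0)
    s[3, 0] = s[0, 3] = 0.9  # case 3's preferred control
    phen = Phenotype(np.array([0, 0, 0, 1], dtype=np.int8))
    structure = match_pairs(_sim(s), phen)
    assert structure.n_units == 1
    assert structure.units[0].cases == [3] and structure.units[0].controls == [0]
    assert sorted(structure.removed) == [1, 2]


def test_match_pairs_requires_both_phenotypes():
    with pytest.raises(ValueError):
        match_pairs(_sim(np.eye(3)), Phenotype(np.zeros(3, dtype=np.int8)))


@pytest.mark.parametrize(
    "n_co, n_ca, expected",
    [(10, 10, math.log(100)), (1, 1, 0.0), (967, 878, math.log(849026))],
)
def test_vicinity_threshold(n_co, n_ca, expected):
    assert vicinity_threshold(n_co, n_ca) == pytest.approx(expected)
    with pytest.raises(ValueError):
        vicinity_threshold(0, 5)


def _vicinity_fixture():
    """5 controls (0-4), 5 cases (5-9); hand-set weights around pair (5, 0)."""
    s = np.full((10, 10), 0.3)
    np.fill_diagonal(s, 1.0)
    s[5, 0] = s[0, 5] = 0.5  # the candidate pair
    return s


def test_vicinity_mutual_nearest_neighbours_valid():
    s = _vicinity_fixture()
    phen = Phenotype(np.array([0] * 5 + [1] * 5, dtype=np.int8))
    # no control beats 0.5 for case 5, no case beats 0.5 for control 0
    assert vicinity_check(5, 0, _sim(s), phen)


def test_vicinity_zero_clause_overrides_large_other_count():
    s = _vicinity_fixture()
    # four cases closer to control 0 than case 5 is, but case 5 has no better mate
    for i in (6, 7, 8, 9):
        s[i, 0] = s[0, i] = 0.9
    phen = Phenotype(np.array([0] * 5 + [1] * 5, dtype=np.int8))
    assert vicinity_check(5, 0, _sim(s), phen)  # t_x = 0 clause


def test_vicinity_strict_threshold_rejects():
    """t_x = ceil(T_cc) >= T_cc with t_y = 1 fails all three clauses."""
    s = _vicinity_fixture()
    t_cc = vicinity_threshold(5, 5)  # ln 25 ~ 3.22
    for j in (1, 2, 3, 4):  # 4 = ceil(T_cc) better controls for case 5
        s[5, j] = s[j, 5] = 0.8
    s[6, 0] = s[0, 6] = 0.7  # one better case for control 0
    phen = Phenotype(np.array([0] * 5 + [1] * 5, dtype=np.int8))
    assert 4 >= t_cc
    assert not vicinity_check(5, 0, _sim(s), phen)


def test_vicinity_ties_do_not_count_as_better():
    s = _vicinity_fixture()
    for j in (1, 2, 3, 4):
        s[5, j] = s[j, 5] = 0.5  # exactly equal weights
    phen = Phenotype(np.array([0] * 5 + [1] * 5, dtype=np.int8))
    assert vicinity_check(5, 0, _sim(s), phen)


def test_validate_units_cluster_and_vicinity(two_block_sim):
    sim, blocks = two_block_sim
    labels = np.zeros(20, dtype=np.int8)
    labels[5:10] = 1  # block 0: 5 controls, 5 cases
    labels[15:20] = 1  # block 1: 5 controls, 5 cases
    phen = Phenotype(labels)
    from ibsmatch.matching import Unit

    intra = UnitStructure(
        units=[Unit([c], [c - 5]) for c in range(5, 10)], kind="pair"
    )
    ok, rejected = validate_units(intra, sim, phen, "cluster", clusters=blocks)
    assert rejected == [] and ok.n_units == 5

    cross = UnitStructure(units=[Unit([5], [10])], kind="pair")  # case blk0, ctrl blk1
    ok, rejected = validate_units(cross, sim, phen, "vicinity")
    assert ok.n_units == 0 and sorted(rejected) == [5, 10]

    empty = UnitStructure(units=[], kind="pair")
    ok, rejected = validate_units(empty, sim, phen, "vicinity")
    assert ok.n_units == 0 and rejected == []

    with pytest.raises(ValueError):
        validate_units(intra, sim, phen, "cluster")


def test_match_within_clusters_two_blocks(two_block_sim):
    sim, blocks = two_block_sim
    labels = np.zeros(20, dtype=np.int8)
    labels[[5, 6, 15, 16]] = 1
    phen = Phenotype(labels)
    structure = match_within_clusters(sim, phen, blocks)
    assert structure.n_units == 4
    for u in structure.units:
        assert blocks[u.cases[0]] == blocks[u.controls[0]]


def test_match_within_clusters_caseless_cluster_removed(two_block_sim):
    sim, blocks = two_block_sim
    labels = np.zeros(20, dtype=np.int8)
    labels[5:10] = 1  # block 1 has no cases at all
    phen = Phenotype(labels)
    structure = match_within_clusters(sim, phen, blocks)
    assert structure.n_units == 5
    assert sorted(structure.removed) == list(range(10, 20))


def test_single_cluster_reduces_to_match_pairs(two_block_sim):
    sim, _ = two_block_sim
    labels = np.zeros(20, dtype=np.int8)
    labels[10:] = 1
    phen = Phenotype(labels)
    one = np.zeros(20, dtype=int)
    a = match_within_clusters(sim, phen, one)
    b = match_pairs(sim, phen)
    assert {frozenset(u.members) for u in a.units} == {
        frozenset(u.members) for u in b.units
    }


def test_groupwise_absorbs_surplus_controls():
    """1 case + 3 same-stratum controls end in a single validated group."""
    s = np.full((4, 4), 0.8)
    np.fill_diagonal(s, 1.0)
    phen = Phenotype(np.array([0, 0, 0, 1], dtype=np.int8))
    structure = match_groups(_sim(s), phen, "vicinity")
    assert structure.n_units == 1
    assert structure.removed == []
    assert sorted(structure.units[0].members) == [0, 1, 2, 3]
    assert len(structure.units[0].cases) == 1 and len(structure.units[0].controls) == 3


def test_groupwise_balanced_equals_validated_pairs(two_block_sim):
    sim, blocks = two_block_sim
    labels = np.zeros(20, dtype=np.int8)
    labels[5:10] = 1
    labels[15:20] = 1
    phen = Phenotype(labels)
    groups = match_groups(sim, phen, "cluster", blocks)
    pairs = match_within_clusters(sim, phen, blocks)
    assert {frozenset(u.members) for u in groups.units} == {
        frozenset(u.members) for u in pairs.units
    }


def test_groupwise_no_cross_stratum_units_on_separated_strata():
    """Asymmetric two-stratum data: units never straddle strata."""
    design = SimDesign(
        controls_per_stratum=(30, 10),
        cases_per_stratum=(10, 30),
        n_snps=800,
        fst=0.2,
    )
    study = sample_h0_study(design, 99)
    sim = ibs_matrix(study.genotypes)
    for validation, clusters in (("vicinity", None), ("cluster", study.strata)):
        structure = match_groups(sim, study.phenotype, validation, clusters)
        structure.validate()
        cross = sum(
            1 for u in structure.units if len(set(study.strata[u.members])) > 1
        )
        assert cross == 0
        # surplus individuals are either grouped within-stratum or removed
        assert len(structure.matched) + len(structure.removed) == 80


def test_groupwise_covers_validated_pairwise(small_study):
    sim = ibs_matrix(small_study.genotypes)
    phen = small_study.phenotype
    pairs = match_within_clusters(sim, phen, small_study.strata)
    groups = match_groups(sim, phen, "cluster", small_study.strata)
    assert set(groups.matched) >= set(pairs.matched)
    groups.validate()
    for u in groups.units:
        assert u.cases and u.controls


def test_unit_structure_tsv_roundtrip(tmp_path):
    from ibsmatch.matching import Unit

    structure = UnitStructure(
        units=[Unit([3], [0, 1]), Unit([4, 5], [2])], kind="group", removed=[6]
    )
    structure.to_tsv(tmp_path / "u.tsv")
    back = UnitStructure.from_tsv(tmp_path / "u.tsv", kind="group")
    assert [sorted(u.members) for u in back.units] == [
        sorted(u.members) for u in structure.units
    ]
    assert back.removed == [6]
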