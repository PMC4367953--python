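"""Permutation inference, minP, asymptotics and genomic control."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import chi2

from ibsmatch import (
    CHI2_MEDIAN,
    PermutationPlan,
    Phenotype,
    asymptotic_pvalues,
    gc_correct,
    inflation_factor,
    minp_adjust,
    pack_genotypes,
    permutation_pvalue,
    permute_within_units,
)
from ibsmatch.matching import Unit, UnitStructure
from ibsmatch.significance import permutation_null, pvalues_from_null
from ibsmatch.trend import genotype_onehot


def _structure(units):
    return UnitStructure(units=[Unit(c, o) for c, o in units], kind="group")


def test_pair_permutation_keeps_or_swaps():
    phen = Phenotype(np.array([0, 1], dtype=np.int8))
    structure = _structure([([1], [0])])
    rng = np.random.default_rng(0)
    seen = set()
    for _ in range(50):
        p = permute_within_units(phen, structure, rng)
        seen.add(tuple(p.labels.tolist()))
        assert p.labels.sum() == 1
    assert seen == {(0, 1), (1, 0)}


def test_unit_permutation_enumerates_three_arrangements():
    phen = Phenotype(np.array([1, 1, 0], dtype=np.int8))
    structure = _structure([([0, 1], [2])])
    rng = np.random.default_rng(1)
    seen = {
        tuple(permute_within_units(phen, structure, rng).labels.tolist())
        for _ in range(200)
    }
    assert seen == {(1, 1, 0), (1, 0, 1), (0, 1, 1)}


def test_permutation_preserves_global_counts_and_outsiders():
    labels = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
    phen = Phenotype(labels)
    structure = _structure([([1], [0]), ([3, 4], [2])])  # 5 is outside any unit
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = permute_within_units(phen, structure, rng)
        assert p.labels.sum() == labels.sum()
        assert p.labels[5] == 0


def test_same_seed_same_stream():
    labels = np.array([0, 1, 0, 1], dtype=np.int8)
    structure = _structure([([1], [0]), ([3], [2])])
    a = [
        permute_within_units(Phenotype(labels), structure, np.random.default_rng(9)).labels
        for _ in range(1)
    ]
    b = [
        permute_within_units(Phenotype(labels), structure, np.random.default_rng(9)).labels
        for _ in range(1)
    ]
    assert np.array_equal(a[0], b[0])


def test_permutation_pvalue_modes():
    phen = Phenotype(np.array([0, 1], dtype=np.int8))
    structure = _structure([([1], [0])])
    const = lambda p: 1.0
    plan = PermutationPlan(b_cycles=99, seed=0, mode="fraction")
    assert permutation_pvalue(const, phen, structure, plan) == 1.0
    plan = PermutationPlan(b_cycles=99, seed=0)
    assert permutation_pvalue(const, phen, structure, plan) == 1.0
    # observed strictly maximal: add-one p attains its lower bound 1/(B+1)
    strictly_max = lambda p: float(np.array_equal(p.labels, [0, 1]))
    assert permutation_pvalue(strictly_max, phen, structure,
                              PermutationPlan(49, 0)) >= 1 / 50


def test_exhaustive_two_pair_enumeration_fraction_mode():
    """With 2 pairs there are 4 equiprobable relabelings; a strictly
    maximal observed statistic has fraction-mode p = 1/4."""
    labels = np.array([0, 1, 0, 1], dtype=np.int8)
    structure = _structure([([1], [0]), ([3], [2])])

    def stat(p):
        # statistic maximal only for the observed labeling
        return float(p.labels[1] == 1) + float(p.labels[3] == 1)

    phen = Phenotype(labels)
    plan = PermutationPlan(b_cycles=20000, seed=2, mode="fraction")
    p = permutation_pvalue(stat, phen, structure, plan)
    assert p == pytest.approx(0.25, abs=0.02)


def test_batched_engine_matches_exhaustive_enumeration():
    """Fraction-mode p-values from the batched engine agree with the
    exhaustive within-unit relabeling distribution."""
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 3, size=(6, 30)).astype(np.uint8)
    labels = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
    pg = pack_genotypes(codes)
    phen = Phenotype(labels)
    structure = _structure([([1], [0]), ([3, 4], [2, 5])])
    onehot = genotype_onehot(pg)
    res = permutation_null(onehot, phen, structure, 40000, 11, ("mcat2",))["mcat2"]
    p_engine = pvalues_from_null(res["observed"], res["null"], mode="fraction")

    # exhaustive: 2 arrangements for the pair x C(4,2)=6 for the quad
    from ibsmatch.trend import unit_statistics

    exhaustive = []
    for pair_case in (1, 0):
        for quad_cases in combinations((3, 4, 2, 5), 2):
            lab = np.zeros(6, dtype=np.int8)
            lab[pair_case] = 1
            lab[list(quad_cases)] = 1
            exhaustive.append(unit_statistics(onehot, lab, structure)["y_t2"])
    exhaustive = np.array(exhaustive)  # (12, S) equiprobable labelings
    obs = res["observed"]
    p_exact = (exhaustive >= obs[None, :]).mean(axis=0)
    assert np.allclose(p_engine, p_exact, atol=0.02)


def test_minp_single_snp_equals_raw():
    rng = np.random.default_rng(1)
    null = rng.chisquare(1, size=(500, 1))
    obs = np.array([2.5])
    adj = minp_adjust(null, obs)
    raw = (null[:, 0] >= obs[0]).mean()
    assert adj[0] == pytest.approx(raw)


def test_minp_duplicated_snp_not_penalised():
    rng = np.random.default_rng(2)
    col = rng.chisquare(1, size=(800, 1))
    obs = np.array([4.0])
    single = minp_adjust(col, obs)[0]
    dup = minp_adjust(np.hstack([col, col]), np.array([4.0, 4.0]))[0]
    assert dup == pytest.approx(single, abs=1e-12)


def test_minp_approaches_sidak_for_independent_snps():
    # adj p is ~S times as sensitive to each column's rank noise as the raw
    # p, so B must be large for a tight Monte-Carlo comparison
    rng = np.random.default_rng(3)
    s, b = 10, 40_000
    null = rng.chisquare(1, size=(b, s))
    obs = np.full(s, 5.0)
    adj = minp_adjust(null, obs)
    raw = chi2.sf(5.0, 1)
    sidak = 1 - (1 - raw) ** s
    assert np.allclose(adj, sidak, atol=0.03)
    assert np.all(adj >= (null >= obs).mean(axis=0) - 1e-12)


def test_asymptotic_pvalues():
    assert asymptotic_pvalues(3.841, "chi2_1") == pytest.approx(0.05, abs=1e-3)
    assert asymptotic_pvalues(0.0, "normal", m=4) == 1.0
    assert asymptotic_pvalues(1.96 * np.sqrt(9), "normal", m=9) == pytest.approx(
        0.05, abs=1e-3
    )
    assert np.isnan(asymptotic_pvalues(1.0, "normal", m=0))


def test_inflation_factor_reference_points():
    assert CHI2_MEDIAN == pytest.approx(0.4549364, abs=1e-6)
    assert inflation_factor(statistics=np.full(10, CHI2_MEDIAN)) == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    sample = 2.0 * rng.chisquare(1, size=100_000)
    assert inflation_factor(statistics=sample) == pytest.approx(2.0, rel=0.02)
    assert inflation_factor(pvalues=rng.uniform(size=100_000)) == pytest.approx(
        1.0, rel=0.02
    )
    with pytest.raises(ValueError):
        inflation_factor(statistics=np.array([np.nan]))


def test_gc_correct():
    p = np.array([0.01, 0.3173, 0.9])
    assert np.allclose(gc_correct(p, 1.0), p)
    assert gc_correct(np.array([0.3173]), 2.0)[0] == pytest.approx(0.4795, abs=1e-3)
    corrected = gc_correct(p, 1.5)
    assert np.all(corrected >= p)
    with pytest.raises(ValueError):
        gc_correct(np.array([0.0]), 1.0)
    with pytest.raises(ValueError):
        gc_correct(p, 0.0)


def test_null_permutation_pvalues_are_superuniform():
    """Stratified null, true-unit permutation: P(p <= a) stays near a."""
    rng = np.random.default_rng(8)
    n, s = 60, 400
    codes = rng.binomial(2, 0.3, size=(n, s)).astype(np.uint8)
    labels = np.tile([0, 1], n // 2).astype(np.int8)
    pg = pack_genotypes(codes)
    phen = Phenotype(labels)
    units = [Unit([i + 1], [i]) for i in range(0, n, 2)]
    structure = UnitStructure(units=units, kind="pair")
    res = permutation_null(genotype_onehot(pg), phen, structure, 499, 21, ("mcat2",))[
        "mcat2"
    ]
    p = pvalues_from_null(res["observed"], res["null"])
    for alpha in (0.01, 0.05, 0.1):
        mc = 3 * np.sqrt(alpha * (1 - alpha) / s)
        assert (p <= alpha).mean() <= alpha + mc + 0.01
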