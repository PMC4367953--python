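"""Inference: within-unit permutation, minP, asymptotics, genomic control.

Permutation preserves each unit's case/control counts (within-pair,
-group or -cluster relabelling), which is the exchangeability that the
matched trend statistics are calibrated against.  The minP adjustment
(Westfall-Young) reuses one shared permutation stream across SNPs to
control the familywise error rate without nested simulation.  Genomic
control estimates the inflation factor lambda as the median observed
statistic over the chi^2_1 median (0.4549364, printed as ~0.456) and
rescales statistics accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import comb
from scipy.stats import chi2, norm

from .codec import Phenotype
from .matching import UnitStructure
from .trend import _stats_from_counts

CHI2_MEDIAN: float = float(chi2.median(1))  # 0.4549364...

_ENUM_LIMIT = 64  # max label arrangements enumerated per unit


@dataclass(frozen=True)
class PermutationPlan:
    """Within-unit resampling plan: B cycles from one master seed."""

    b_cycles: int
    seed: int
    mode: Literal["add-one", "fraction"] = "add-one"


def permute_within_units(
    phen: Phenotype, structure: UnitStructure, rng: np.random.Generator
) -> Phenotype:
    """Permute case-control labels independently inside every unit."""
    labels = phen.labels.copy()
    for u in structure.units:
        members = np.asarray(u.members)
        labels[members] = labels[rng.permutation(members)]
    return Phenotype(labels)


def permutation_pvalue(
    stat_fn: Callable[[Phenotype], float],
    phen: Phenotype,
    structure: UnitStructure,
    plan: PermutationPlan,
) -> float:
    """Generic one-sided permutation p-value for a scalar statistic.

    ``add-one`` mode returns (1 + #{stat_b >= stat_obs}) / (B + 1);
    ``fraction`` mode the plain fraction #{stat_b >= stat_obs} / B.
    """
    if plan.b_cycles < 1:
        raise ValueError("need at least one cycle")
    rng = np.random.default_rng(plan.seed)
    obs = stat_fn(phen)
    if not np.isfinite(obs):
        return float("nan")
    hits = 0
    for _ in range(plan.b_cycles):
        if stat_fn(permute_within_units(phen, structure, rng)) >= obs:
            hits += 1
    if plan.mode == "fraction":
        return hits / plan.b_cycles
    return (1 + hits) / (plan.b_cycles + 1)


# -- batched per-SNP permutation engine ------------------------------------


def _unit_arrangement_counts(block: np.ndarray, case_sets: list[tuple[int, ...]]):
    """(A, S, 3) case genotype counts for each label arrangement of a unit."""
    out = np.empty((len(case_sets), block.shape[2], 3), dtype=np.float64)
    for a, subset in enumerate(case_sets):
        out[a] = block[:, list(subset), :].sum(axis=1).T
    return out


def permutation_null(
    onehot: np.ndarray,
    phen: Phenotype,
    structure: UnitStructure,
    b_cycles: int,
    seed: int,
    statistics: Sequence[str] = ("mcat2",),
) -> dict[str, dict[str, np.ndarray]]:
    """Observed and null per-SNP statistics under within-unit permutation.

    Statistics: ``"mcat2"`` (|Y_T2|), ``"mcat1"`` (|Y_U|) and ``"cat"``
    (whole-matched-sample X_T2 recomputed per cycle).  One shared
    permutation stream drives all SNPs and all requested statistics, as
    minP requires.  Units with at most 64 distinct case-subsets are
    enumerated once and cycles merely index into the table; larger units
    fall back to dense relabelling.

    Returns ``{stat: {"observed": (S,), "null": (B, S), "m": (S,)}}``.
    """
    rng = np.random.default_rng(seed)
    n_snps = onehot.shape[2]
    want_pool = "cat" in statistics
    want_m2 = "mcat2" in statistics
    want_m1 = "mcat1" in statistics

    y2_obs = np.zeros(n_snps)
    yu_obs = np.zeros(n_snps)
    m_units = np.zeros(n_snps, dtype=np.int64)
    y2_null = np.zeros((b_cycles, n_snps)) if want_m2 else None
    yu_null = np.zeros((b_cycles, n_snps)) if want_m1 else None
    ca_pool_obs = np.zeros((n_snps, 3)) if want_pool else None
    ca_pool_null = np.zeros((b_cycles, n_snps, 3), dtype=np.float32) if want_pool else None
    tot_pool = np.zeros((n_snps, 3)) if want_pool else None

    for u in structure.units:
        members = np.asarray(u.members)
        q = len(members)
        n_case = len(u.cases)
        block = onehot[:, members, :]  # (3, q, S)
        tot = block.sum(axis=1).T.astype(np.float64)  # (S, 3)
        obs_set = tuple(i for i, m in enumerate(members) if phen.labels[m] == 1)
        if comb(q, n_case, exact=True) <= _ENUM_LIMIT:
            case_sets = list(combinations(range(q), n_case))
            ca = _unit_arrangement_counts(block, case_sets)  # (A, S, 3)
            co = tot[None] - ca
            x_t2, x_u, sign, usable = _stats_from_counts(co, ca)
            a_obs = case_sets.index(obs_set)
            idx = rng.integers(0, len(case_sets), size=b_cycles)
            if want_m2 or want_m1:
                contrib2 = sign * x_t2
                y2_obs += contrib2[a_obs]
                yu_obs += x_u[a_obs]
                if want_m2:
                    y2_null += contrib2[idx]
                if want_m1:
                    yu_null += x_u[idx]
            m_units += usable[a_obs].astype(np.int64)
            if want_pool:
                ca_pool_obs += ca[a_obs]
                ca_pool_null += ca[idx].astype(np.float32)
                tot_pool += tot
        else:
            # dense path: B random within-unit labelings via argsort
            order = np.argsort(rng.random((b_cycles, q)), axis=1)
            lab = np.zeros((b_cycles, q), dtype=np.float32)
            np.put_along_axis(lab, order[:, :n_case], 1.0, axis=1)
            obs_lab = np.zeros(q, dtype=np.float32)
            obs_lab[list(obs_set)] = 1.0
            ca_obs = (block * obs_lab[None, :, None]).sum(axis=1).T.astype(np.float64)
            ca_b = np.einsum("bq,kqs->bsk", lab, block).astype(np.float64)
            co_obs = tot - ca_obs
            co_b = tot[None] - ca_b
            xo_t2, xo_u, so, usable = _stats_from_counts(co_obs, ca_obs)
            xb_t2, xb_u, sb, _ = _stats_from_counts(co_b, ca_b)
            if want_m2 or want_m1:
                y2_obs += so * xo_t2
                yu_obs += xo_u
                if want_m2:
                    y2_null += sb * xb_t2
                if want_m1:
                    yu_null += xb_u
            m_units += usable.astype(np.int64)
            if want_pool:
                ca_pool_obs += ca_obs
                ca_pool_null += ca_b.astype(np.float32)
                tot_pool += tot

    out: dict[str, dict[str, np.ndarray]] = {}
    if want_m2:
        out["mcat2"] = {
            "observed": np.abs(y2_obs),
            "null": np.abs(y2_null),
            "m": m_units.copy(),
        }
    if want_m1:
        out["mcat1"] = {
            "observed": np.abs(yu_obs),
            "null": np.abs(yu_null),
            "m": m_units.copy(),
        }
    if want_pool:
        co_obs = tot_pool - ca_pool_obs
        x_obs, _, _, usable = _stats_from_counts(co_obs, ca_pool_obs)
        ca64 = ca_pool_null.astype(np.float64)
        co64 = tot_pool[None] - ca64
        x_null, _, _, _ = _stats_from_counts(co64, ca64)
        out["cat"] = {
            "observed": np.where(usable, x_obs, np.nan),
            "null": x_null,
            "m": np.full(n_snps, len(structure.units), dtype=np.int64),
        }
    for stat in out.values():
        stat["observed"] = np.where(stat["m"] > 0, stat["observed"], np.nan)
    return out


def pvalues_from_null(
    observed: np.ndarray, null: np.ndarray, mode: str = "add-one"
) -> np.ndarray:
    """Per-SNP one-sided permutation p-values from a (B, S) null matrix."""
    hits = (null >= observed[None, :]).sum(axis=0)
    b = null.shape[0]
    if mode == "fraction":
        p = hits / b
    else:
        p = (1 + hits) / (b + 1)
    return np.where(np.isfinite(observed), p, np.nan)


def minp_adjust(null_stat_matrix: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Westfall-Young minP familywise adjustment.

    Per-permutation p-values are computed rank-wise against each SNP's
    own null distribution; the adjusted p of SNP s is the fraction of
    permutations whose minimum p over all SNPs is <= the observed p of
    s.  Requires the same permutations for all SNPs.
    """
    null = np.asarray(null_stat_matrix, dtype=float)
    obs = np.asarray(observed, dtype=float)
    b, s = null.shape
    if b < 20:
        warnings.warn("very small B: minP resolution is 1/B", stacklevel=2)
    # p-value of every null statistic within its own column: fraction >=,
    # ties sharing the whole tie-group count
    sorted_desc = -np.sort(-null, axis=0)
    p_null = np.empty((b, s))
    for j in range(s):
        p_null[:, j] = np.searchsorted(-sorted_desc[:, j], -null[:, j], side="right") / b
    p_obs = (null >= obs[None, :]).sum(axis=0) / b
    min_p = p_null.min(axis=1)
    adjusted = (min_p[:, None] <= p_obs[None, :]).sum(axis=0) / b
    return np.maximum(adjusted, p_obs)


def asymptotic_pvalues(
    statistic: np.ndarray | float,
    law: Literal["chi2_1", "normal"] = "chi2_1",
    m: np.ndarray | float | None = None,
) -> np.ndarray:
    """Asymptotic p-values: upper-tail chi^2_1, or two-sided N(0, M)."""
    stat = np.asarray(statistic, dtype=float)
    if law == "chi2_1":
        return chi2.sf(stat, 1)
    if m is None:
        raise ValueError("normal law needs the unit count M")
    m_arr = np.asarray(m, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(m_arr > 0, stat / np.sqrt(m_arr), np.nan)
    return 2.0 * norm.sf(np.abs(z))


def inflation_factor(
    statistics: np.ndarray | None = None, pvalues: np.ndarray | None = None
) -> float:
    """Genomic-control lambda: median statistic over the chi^2_1 median.

    P-value input is first converted through the upper-tail chi^2_1
    quantile.
    """
    if statistics is None and pvalues is None:
        raise ValueError("provide statistics or pvalues")
    if statistics is None:
        pv = np.asarray(pvalues, dtype=float)
        pv = pv[np.isfinite(pv)]
        statistics = chi2.isf(pv, 1)
    stats = np.asarray(statistics, dtype=float)
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(stats) / CHI2_MEDIAN)


def gc_correct(pvalues: np.ndarray, lam: float) -> np.ndarray:
    """Rescale p-values by lambda through the chi^2_1 quantile map."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    pv = np.asarray(pvalues, dtype=float)
    if np.any(((pv <= 0) | (pv > 1)) & np.isfinite(pv)):
        raise ValueError("p-values must lie in (0, 1]")
    return chi2.sf(chi2.isf(pv, 1) / lam, 1)
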