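"""Synthetic stratified case-control studies for calibration and power.

Strata are simulated under the Balding-Nichols model: each SNP has an
ancestral frequency p ~ Uniform(0.05, 0.5) and per-stratum frequencies
drawn from Beta(p (1-F)/F, (1-p) (1-F)/F), so the between-stratum
variance of the frequency is F p (1-p).  Within a stratum, individuals
receive two haplotypes from a first-order Markov chain across loci
whose transition probabilities realise a target adjacent-locus
haplotype correlation (pairwise LD only; no higher-order LD), and the
genotype is the haplotype sum (HWE within stratum).  SNPs monomorphic
in any stratum are removed.  Merging strata with strongly asymmetric
per-stratum case/control quotas manufactures population stratification
exactly as over/under-sampling of cases from different ancestries does.

Power-mode studies add one causal SNP with multiplicative penetrances
f_g = f0 * rr^g (rr = 1.5 by default), f0 normalised so the stratum
prevalence matches ``prevalence``; case and control genotypes at the
causal locus are drawn from the exact conditional distributions
P(g | status) within each stratum.  The matching panel is kept free of
the causal SNP.

The packaged 14-population design reproduces the published asymmetric
distribution of 967 controls and 878 cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codec import PackedGenotypes, Phenotype, pack_genotypes
from .comparators import logistic_lrt_scan, mds_components
from .matching import (
    UnitStructure,
    cluster_units,
    match_groups,
    match_pairs,
    match_within_clusters,
    validate_units,
)
from .significance import (
    asymptotic_pvalues,
    gc_correct,
    inflation_factor,
    permutation_null,
    pvalues_from_null,
)
from .similarity import ibs_matrix
from .trend import genotype_onehot, pooled_cat

#: Published 14-population asymmetric case-control distribution
#: (ASW, LWK, YRI, CLM, MXL, PUR, CHB, CHS, JPT, CEU, FIN, GBR, IBS, TSI).
POP14_NAMES = (
    "ASW", "LWK", "YRI", "CLM", "MXL", "PUR", "CHB",
    "CHS", "JPT", "CEU", "FIN", "GBR", "IBS", "TSI",
)
POP14_CONTROLS = (85, 96, 66, 30, 88, 36, 130, 66, 45, 31, 92, 120, 9, 73)
POP14_CASES = (42, 48, 66, 60, 44, 73, 65, 133, 88, 61, 46, 60, 18, 74)


@dataclass(frozen=True)
class SimDesign:
    """Strata layout and generative parameters of a simulated study."""

    controls_per_stratum: tuple[int, ...] = POP14_CONTROLS
    cases_per_stratum: tuple[int, ...] = POP14_CASES
    n_snps: int = 10_000
    fst: float = 0.05
    ld: float = 0.0
    rr: float = 1.5
    prevalence: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if len(self.controls_per_stratum) != len(self.cases_per_stratum):
            raise ValueError("per-stratum count vectors differ in length")
        if not 0 <= self.fst < 1:
            raise ValueError("F must lie in [0, 1)")
        if self.rr <= 0:
            raise ValueError("relative risk must be positive")

    @property
    def n_strata(self) -> int:
        return len(self.controls_per_stratum)

    @property
    def n_controls(self) -> int:
        return int(sum(self.controls_per_stratum))

    @property
    def n_cases(self) -> int:
        return int(sum(self.cases_per_stratum))

    @property
    def n_individuals(self) -> int:
        return self.n_controls + self.n_cases


def fourteen_population_design(n_snps: int = 10_000, **kw) -> SimDesign:
    """The full 14-population design (1,845 individuals)."""
    return SimDesign(POP14_CONTROLS, POP14_CASES, n_snps=n_snps, **kw)


def scaled_design(n_snps: int = 2_000, fst: float = 0.05, **kw) -> SimDesign:
    """Scaled 5-stratum design (400 individuals) preserving the published
    per-population asymmetry pattern.

    The five strata carry the counts of five representative populations
    of the 14-population design -- the largest control-heavy (YRI,
    GBR), the largest case-heavy (CHS, JPT) and the balanced (TSI)
    ones -- rescaled to 400 individuals, so per-stratum case:control
    ratios keep the published ~2:1 / ~1:2 / 1:1 mix.
    """
    return SimDesign(
        controls_per_stratum=(61, 56, 31, 21, 35),
        cases_per_stratum=(30, 28, 62, 41, 35),
        n_snps=n_snps,
        fst=fst,
        **kw,
    )


@dataclass
class SimulatedStudy:
    """A merged stratified sample with hidden truth for evaluation."""

    genotypes: PackedGenotypes
    phenotype: Phenotype
    strata: np.ndarray  # true stratum label per individual
    design: SimDesign
    matching_snps: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    causal_snp: int | None = None

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.genotypes.individual_ids,
                "stratum": self.strata,
                "phenotype": self.phenotype.labels,
            }
        )


def balding_nichols_freqs(
    p: np.ndarray | float, fst: float, n_strata: int, rng: np.random.Generator
) -> np.ndarray:
    """(K, S) per-stratum frequencies; F = 0 returns the ancestral p exactly."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("ancestral frequencies must lie in (0, 1)")
    if fst == 0:
        return np.tile(p, (n_strata, 1))
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(a, b, size=(n_strata, p.size))


def _haplotypes(freqs: np.ndarray, ld: float, n_hap: int, rng: np.random.Generator):
    """First-order Markov haplotypes hitting per-locus freqs and adjacent r."""
    s = len(freqs)
    q = np.clip(freqs, 1e-9, 1 - 1e-9)
    h = np.empty((n_hap, s), dtype=np.uint8)
    h[:, 0] = rng.random(n_hap) < q[0]
    for k in range(1, s):
        qa, qb = q[k - 1], q[k]
        lo = max(0.0, qa + qb - 1.0)
        hi = min(qa, qb)
        p11 = qa * qb + ld * np.sqrt(qa * (1 - qa) * qb * (1 - qb))
        p11 = min(max(p11, lo), hi)
        p1_given1 = p11 / qa
        p1_given0 = (qb - p11) / (1 - qa)
        prev = h[:, k - 1].astype(bool)
        u = rng.random(n_hap)
        h[:, k] = np.where(prev, u < p1_given1, u < p1_given0)
    return h


def simulate_stratum(
    freqs: np.ndarray, ld: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, S) genotype dosages for one stratum (HWE; pairwise LD only)."""
    if n < 1:
        raise ValueError("need at least one individual")
    h = _haplotypes(np.asarray(freqs, dtype=float), ld, 2 * n, rng)
    return (h[:n].astype(np.uint8) + h[n:].astype(np.uint8)).astype(np.uint8)


def filter_monomorphic(
    genotypes: np.ndarray, strata: np.ndarray
) -> np.ndarray:
    """Indices of SNPs carrying both alleles in every stratum."""
    keep = np.ones(genotypes.shape[1], dtype=bool)
    for k in np.unique(strata):
        g = genotypes[strata == k]
        sums = g.sum(axis=0, dtype=np.int64)
        keep &= (sums > 0) & (sums < 2 * g.shape[0])
    return np.flatnonzero(keep)


def _simulate_strata_panel(
    design: SimDesign, counts: Sequence[int], rng: np.random.Generator
):
    """Raw per-stratum genotypes for ``counts`` individuals per stratum."""
    lo, hi = design.maf_range
    p = rng.uniform(lo, hi, size=design.n_snps)
    freqs = balding_nichols_freqs(p, design.fst, design.n_strata, rng)
    blocks = [
        simulate_stratum(freqs[k], design.ld, counts[k], rng)
        for k in range(design.n_strata)
    ]
    geno = np.vstack(blocks)
    strata = np.repeat(np.arange(design.n_strata), counts)
    return geno, strata, freqs


def sample_h0_study(design: SimDesign, rng: np.random.Generator | int) -> SimulatedStudy:
    """Null study: phenotype independent of genotype within every stratum."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = [
        c + a for c, a in zip(design.controls_per_stratum, design.cases_per_stratum)
    ]
    if min(counts) < 1:
        raise ValueError("every stratum needs at least one individual")
    geno, strata, _ = _simulate_strata_panel(design, counts, rng)
    keep = filter_monomorphic(geno, strata)
    if keep.size == 0:
        raise ValueError("all SNPs monomorphic in some stratum")
    geno = geno[:, keep]
    labels = np.zeros(len(strata), dtype=np.int8)
    for k in range(design.n_strata):
        members = np.flatnonzero(strata == k)
        cases = rng.choice(members, size=design.cases_per_stratum[k], replace=False)
        labels[cases] = 1
    order = rng.permutation(len(strata))
    pg = pack_genotypes(geno[order])
    return SimulatedStudy(
        genotypes=pg,
        phenotype=Phenotype(labels[order]),
        strata=strata[order],
        design=design,
        matching_snps=np.arange(geno.shape[1]),
    )


def causal_genotype_distributions(
    q: float, rr: float, prevalence: float
) -> tuple[np.ndarray, np.ndarray]:
    """P(g | case) and P(g | control) at a causal locus, stratum frequency q.

    Multiplicative penetrances f_g = f0 * rr^g with f0 set so the
    prevalence matches; raises if the implied f2 exceeds 1.
    """
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    mult = rr ** np.arange(3)
    f0 = prevalence / float(hwe @ mult)
    pen = f0 * mult
    if pen[2] > 1:
        raise ValueError("infeasible penetrance: prevalence * rr^2 exceeds 1")
    p_case = hwe * pen / prevalence
    p_ctrl = hwe * (1 - pen) / (1 - prevalence)
    return p_case, p_ctrl


def sample_power_study(design: SimDesign, rng: np.random.Generator | int) -> SimulatedStudy:
    """Alternative study: one causal SNP, disjoint from the matching panel."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = [
        c + a for c, a in zip(design.controls_per_stratum, design.cases_per_stratum)
    ]
    geno, strata, _ = _simulate_strata_panel(design, counts, rng)
    keep = filter_monomorphic(geno, strata)
    geno = geno[:, keep]

    # causal SNP simulated separately (>= the panel gap by construction)
    lo, hi = design.maf_range
    while True:
        p = float(rng.uniform(lo, hi))
        q = balding_nichols_freqs(p, design.fst, design.n_strata, rng)[:, 0]
        if ((q > 0.01) & (q < 0.99)).all():
            break
    labels = np.zeros(len(strata), dtype=np.int8)
    causal = np.zeros(len(strata), dtype=np.uint8)
    for k in range(design.n_strata):
        members = np.flatnonzero(strata == k)
        n_ca = design.cases_per_stratum[k]
        cases = rng.choice(members, size=n_ca, replace=False)
        labels[cases] = 1
        p_case, p_ctrl = causal_genotype_distributions(q[k], design.rr, design.prevalence)
        is_case = labels[members] == 1
        causal[members[is_case]] = rng.choice(3, size=int(is_case.sum()), p=p_case)
        causal[members[~is_case]] = rng.choice(3, size=int((~is_case).sum()), p=p_ctrl)

    order = rng.permutation(len(strata))
    study = SimulatedStudy(
        genotypes=pack_genotypes(geno[order]),
        phenotype=Phenotype(labels[order]),
        strata=strata[order],
        design=design,
        matching_snps=np.arange(geno.shape[1]),
    )
    return _append_causal(study, causal[order][:, None], design)


def _append_causal(
    study: SimulatedStudy, causal_col: np.ndarray, design: SimDesign
) -> SimulatedStudy:
    codes = study.genotypes.codes()
    causal_col = causal_col.reshape(len(codes), 1)
    full = np.hstack([codes, causal_col])
    pg = pack_genotypes(
        full,
        snp_ids=study.genotypes.snp_ids + ["causal"],
        individual_ids=list(study.genotypes.individual_ids),
    )
    return SimulatedStudy(
        genotypes=pg,
        phenotype=study.phenotype,
        strata=study.strata,
        design=design,
        matching_snps=np.arange(codes.shape[1]),
        causal_snp=codes.shape[1],
    )


def realized_fst(genotypes: np.ndarray, strata: np.ndarray) -> float:
    """Weir-Cockerham multi-population FST (ratio-of-sums over SNPs)."""
    labels = np.unique(strata)
    r = len(labels)
    n_i = np.array([(strata == k).sum() for k in labels], dtype=float)
    p_i = np.stack([genotypes[strata == k].mean(axis=0) / 2 for k in labels])
    h_i = np.stack([(genotypes[strata == k] == 1).mean(axis=0) for k in labels])
    n_bar = n_i.mean()
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i[:, None] * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i[:, None] * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i[:, None] * h_i).sum(axis=0) / (r * n_bar)
    a = n_bar / n_c * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a.sum() / (a + b + c).sum())


# -- experiment drivers ----------------------------------------------------

H0_METHODS = (
    "cat_naive",
    "cat_pairs_cluster",
    "cat_pairs_vicinity",
    "mcat2_pairs_cluster",
    "mcat2_clusters",
    "mcat2_groups_cluster",
    "mcat1_clusters",
    "lr_mds",
)


def _build_units(
    study: SimulatedStudy, sim, units_kind: str, validation: str, clusters: np.ndarray
) -> UnitStructure:
    phen = study.phenotype
    if units_kind == "clusters":
        return cluster_units(phen, clusters)
    if units_kind == "pairs":
        if validation == "cluster":
            return match_within_clusters(sim, phen, clusters)
        structure = match_pairs(sim, phen)
        structure, _ = validate_units(structure, sim, phen, "vicinity")
        return structure
    if units_kind == "groups":
        return match_groups(sim, phen, validation, clusters)
    raise ValueError(f"unknown unit kind {units_kind!r}")


def _parse_method(method: str) -> tuple[str, str | None, str | None]:
    if method in ("cat_naive", "lr_mds"):
        return method, None, None
    test, units_kind, validation = (method.split("_") + [None])[:3]
    return test, units_kind, validation


def analyze_study(
    study: SimulatedStudy,
    methods: Sequence[str],
    b_cycles: int,
    seed: int,
    clusters: np.ndarray | None = None,
    mds_k: int | None = None,
    snps: np.ndarray | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-SNP p-values (and lambda inputs) for each requested method.

    ``clusters`` defaults to the true stratum labels (the calibration
    reference); pass an inferred assignment to exercise the full
    pipeline.  ``snps`` restricts testing (the matching always uses the
    study's matching panel).
    """
    if clusters is None:
        clusters = study.strata
    if mds_k is None:
        mds_k = study.design.n_strata
    test_snps = snps if snps is not None else np.arange(study.genotypes.n_snps)
    panel = study.genotypes.take_snps(study.matching_snps)
    sim = ibs_matrix(panel)
    onehot = genotype_onehot(study.genotypes)[:, :, test_snps]
    phen = study.phenotype

    unit_cache: dict[tuple[str, str | None], UnitStructure] = {}
    results: dict[str, dict[str, np.ndarray]] = {}
    for mi, method in enumerate(methods):
        test, units_kind, validation = _parse_method(method)
        if method == "cat_naive":
            x_t2, _, usable = pooled_cat(onehot, phen.labels)
            stats = np.where(usable, x_t2, np.nan)
            results[method] = {
                "p": asymptotic_pvalues(stats, "chi2_1"),
                "lambda_stats": stats,
                "n_units": np.array([0]),
                "n_included": np.array([len(phen)]),
            }
            continue
        if method == "lr_mds":
            cov = mds_components(sim, mds_k)
            codes = study.genotypes.codes()[:, test_snps].astype(float)
            p = logistic_lrt_scan(codes, phen, cov)
            results[method] = {
                "p": p,
                "lambda_stats": None,
                "n_units": np.array([mds_k]),
                "n_included": np.array([len(phen)]),
            }
            continue
        key = (units_kind, validation)
        if key not in unit_cache:
            unit_cache[key] = _build_units(study, sim, units_kind, validation, clusters)
        structure = unit_cache[key]
        if test == "mcat1":
            res = permutation_null(onehot, phen, structure, 1, seed + mi, ("mcat1",))[
                "mcat1"
            ]
            # statistic is |Y_U|; asymptotic two-sided normal with variance M
            m = res["m"]
            p = asymptotic_pvalues(res["observed"], "normal", m)
            with np.errstate(invalid="ignore", divide="ignore"):
                lam_stats = np.where(m > 0, res["observed"] ** 2 / m, np.nan)
        else:
            stat_name = "mcat2" if test == "mcat2" else "cat"
            res = permutation_null(
                onehot, phen, structure, b_cycles, seed + mi, (stat_name,)
            )[stat_name]
            p = pvalues_from_null(res["observed"], res["null"])
            lam_stats = None
        results[method] = {
            "p": p,
            "lambda_stats": lam_stats,
            "n_units": np.array([structure.n_units]),
            "n_included": np.array([len(structure.matched)]),
        }
    return results


def _method_lambda(res: dict[str, np.ndarray]) -> float:
    if res["lambda_stats"] is not None:
        return inflation_factor(statistics=res["lambda_stats"])
    return inflation_factor(pvalues=res["p"])


def run_h0_experiment(
    design: SimDesign,
    methods: Sequence[str] = H0_METHODS,
    replicates: int = 10,
    b_cycles: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    use_true_strata: bool = True,
) -> pd.DataFrame:
    """Null calibration: mean +/- SE of lambda and f_p per method.

    f_p is the fraction of testable SNPs with p < alpha.
    """
    from .clustering import hungarian_cluster

    if replicates < 1:
        raise ValueError("need at least one replicate")
    rows: dict[str, list[dict[str, float]]] = {m: [] for m in methods}
    root = np.random.default_rng(seed)
    for rep in range(replicates):
        study = sample_h0_study(design, np.random.default_rng(root.integers(2**31)))
        clusters = None
        if not use_true_strata:
            panel = study.genotypes.take_snps(study.matching_snps)
            clusters = hungarian_cluster(ibs_matrix(panel)).labels
        res = analyze_study(
            study, methods, b_cycles, int(root.integers(2**31)), clusters=clusters
        )
        for m in methods:
            p = res[m]["p"]
            finite = np.isfinite(p)
            rows[m].append(
                {
                    "f_p": float((p[finite] < alpha).mean()),
                    "lambda": _method_lambda(res[m]),
                    "n_units": float(res[m]["n_units"][0]),
                    "n_included": float(res[m]["n_included"][0]),
                }
            )
    out = []
    for m in methods:
        frame = pd.DataFrame(rows[m])
        out.append(
            {
                "method": m,
                "lambda": frame["lambda"].mean(),
                "se_lambda": frame["lambda"].std(ddof=1) / np.sqrt(replicates)
                if replicates > 1
                else 0.0,
                "f_p": frame["f_p"].mean(),
                "se_f_p": frame["f_p"].std(ddof=1) / np.sqrt(replicates)
                if replicates > 1
                else 0.0,
                "n_units": frame["n_units"].mean(),
                "n_included": frame["n_included"].mean(),
            }
        )
    return pd.DataFrame(out).set_index("method")


def run_power_experiment(
    design: SimDesign,
    methods: Sequence[str],
    n_datasets: int = 300,
    b_cycles: int = 999,
    seed: int = 0,
    alphas: Sequence[float] = (0.01, 0.001, 0.0001),
    lambdas: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Power per method and nominal level over independent causal datasets.

    P-values are genomic-control corrected with the per-method lambdas
    (typically taken from :func:`run_h0_experiment` on the same
    design) before thresholding; power = fraction of datasets with
    corrected p <= alpha.  Following standard genomic-control
    practice, the correction factor is max(1, lambda): inflation is
    rescaled away, deflation is never used to boost significance.
    """
    root = np.random.default_rng(seed)
    pvals: dict[str, list[float]] = {m: [] for m in methods}
    for _ in range(n_datasets):
        study = sample_power_study(design, np.random.default_rng(root.integers(2**31)))
        res = analyze_study(
            study,
            methods,
            b_cycles,
            int(root.integers(2**31)),
            snps=np.array([study.causal_snp]),
        )
        for m in methods:
            pvals[m].append(float(res[m]["p"][0]))
    out = []
    for m in methods:
        p = np.asarray(pvals[m])
        lam = max(1.0, (lambdas or {}).get(m, 1.0))
        p_corr = gc_correct(np.clip(p[np.isfinite(p)], 1e-300, 1.0), lam)
        row = {"method": m}
        for a in alphas:
            row[f"power_{a:g}"] = float((p_corr <= a).mean())
        out.append(row)
    return pd.DataFrame(out).set_index("method")
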