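"""Model/Results facade over the matching and testing pipeline.

:class:`MatchedAssociation` is constructed from genotype data and a
case-control phenotype together with a structuring design (units:
pairs, groups or clusters; validation: cluster or vicinity; test: cat,
mcat1, mcat2 or lr_mds).  ``fit`` performs similarity computation,
clustering (when required), matching, testing and genomic control, and
returns a :class:`MatchedAssociationResults` carrying per-SNP
statistics and p-values, the unit structure, the inflation factor and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, hungarian_cluster
from .codec import PackedGenotypes, Phenotype
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
    minp_adjust,
    permutation_null,
    pvalues_from_null,
)
from .similarity import SimilarityMatrix, ibs_matrix
from .trend import genotype_onehot, pooled_cat

_TESTS = ("cat", "mcat1", "mcat2", "lr_mds")
_UNITS = ("none", "pairs", "groups", "clusters")
_VALIDATIONS = ("none", "cluster", "vicinity")


class MatchedAssociation:
    """Structured case-control association model on a SNP panel.

    Parameters
    ----------
    genotypes, phenotype
        The sample; genotypes as packed minor-allele dosages.
    test
        ``"cat"`` (trend test, pooled over the matched sample),
        ``"mcat1"``/``"mcat2"`` (matched extensions) or ``"lr_mds"``
        (logistic regression with MDS covariates).
    units
        ``"pairs"``, ``"groups"``, ``"clusters"`` or ``"none"`` (no
        structuring; the naive pooled test).
    validation
        ``"cluster"``, ``"vicinity"`` or ``"none"``.
    clusters
        Optional precomputed cluster labels (true strata or any
        external assignment); inferred by agglomerative clustering when
        required but not given.
    matching_snps
        Panel used for the similarity matrix (defaults to all SNPs).
    mds_k
        Number of MDS covariates for ``lr_mds``.
    """

    def __init__(
        self,
        genotypes: PackedGenotypes,
        phenotype: Phenotype,
        test: str = "mcat2",
        units: str = "groups",
        validation: str = "cluster",
        clusters: np.ndarray | ClusterAssignment | None = None,
        matching_snps: np.ndarray | None = None,
        mds_k: int = 10,
    ) -> None:
        if test not in _TESTS:
            raise ValueError(f"test must be one of {_TESTS}")
        if units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}")
        if validation not in _VALIDATIONS:
            raise ValueError(f"validation must be one of {_VALIDATIONS}")
        if units == "none" and test in ("mcat1", "mcat2"):
            raise ValueError("matched tests require a unit structure")
        if isinstance(clusters, ClusterAssignment):
            clusters = clusters.labels
        self.genotypes = genotypes
        self.phenotype = phenotype
        self.test = test
        self.units = units
        self.validation = validation
        self.clusters = None if clusters is None else np.asarray(clusters)
        self.matching_snps = (
            np.arange(genotypes.n_snps) if matching_snps is None else np.asarray(matching_snps)
        )
        self.mds_k = mds_k

    # -- pipeline pieces ---------------------------------------------------

    def similarity(self) -> SimilarityMatrix:
        return ibs_matrix(self.genotypes.take_snps(self.matching_snps))

    def _needs_clusters(self) -> bool:
        return self.units == "clusters" or self.validation == "cluster"

    def build_units(self, sim: SimilarityMatrix) -> UnitStructure:
        clusters = self.clusters
        if self._needs_clusters() and clusters is None:
            clusters = hungarian_cluster(sim).labels
            self.clusters = clusters
        if self.units == "clusters":
            return cluster_units(self.phenotype, clusters)
        if self.units == "pairs":
            if self.validation == "cluster":
                return match_within_clusters(sim, self.phenotype, clusters)
            structure = match_pairs(sim, self.phenotype)
            if self.validation == "vicinity":
                structure, _ = validate_units(
                    structure, sim, self.phenotype, "vicinity"
                )
            return structure
        if self.units == "groups":
            return match_groups(sim, self.phenotype, self.validation, clusters)
        # units == "none": single pseudo-structure covering nobody
        return UnitStructure(units=[], kind="group")

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        b_permutations: int = 999,
        seed: int = 0,
        snps: np.ndarray | None = None,
        minp: bool = False,
        gc: bool = False,
        pvalue_mode: str = "add-one",
    ) -> "MatchedAssociationResults":
        """Run the full pipeline and return results.

        ``minp`` adds Westfall-Young familywise-adjusted p-values
        (permutation tests only); ``gc`` genomic-control-corrects the
        p-values with the estimated inflation factor.
        """
        test_snps = np.arange(self.genotypes.n_snps) if snps is None else np.asarray(snps)
        snp_ids = [self.genotypes.snp_ids[j] for j in test_snps]
        phen = self.phenotype
        sim = self.similarity() if (self.units != "none" or self.test == "lr_mds") else None
        structure = self.build_units(sim) if self.units != "none" else None
        onehot = genotype_onehot(self.genotypes)[:, :, test_snps]

        m = np.zeros(len(test_snps), dtype=np.int64)
        null = None
        adjusted = None
        if self.test == "lr_mds":
            cov = mds_components(sim, self.mds_k)
            codes = self.genotypes.codes()[:, test_snps].astype(float)
            pvalues = logistic_lrt_scan(codes, phen, cov)
            statistics = np.full(len(test_snps), np.nan)
            lam = inflation_factor(pvalues=pvalues)
        elif self.test == "cat" and self.units == "none":
            x_t2, _, usable = pooled_cat(onehot, phen.labels)
            statistics = np.where(usable, x_t2, np.nan)
            pvalues = asymptotic_pvalues(statistics, "chi2_1")
            lam = inflation_factor(statistics=statistics)
        elif self.test == "mcat1":
            res = permutation_null(onehot, phen, structure, 1, seed, ("mcat1",))["mcat1"]
            statistics, m = res["observed"], res["m"]
            pvalues = asymptotic_pvalues(statistics, "normal", m)
            with np.errstate(invalid="ignore", divide="ignore"):
                lam = inflation_factor(
                    statistics=np.where(m > 0, statistics**2 / m, np.nan)
                )
        else:  # permutation-calibrated cat / mcat2 within units
            stat_name = "mcat2" if self.test == "mcat2" else "cat"
            res = permutation_null(
                onehot, phen, structure, b_permutations, seed, (stat_name,)
            )[stat_name]
            statistics, m, null = res["observed"], res["m"], res["null"]
            pvalues = pvalues_from_null(statistics, null, pvalue_mode)
            lam = inflation_factor(pvalues=pvalues)
            if minp:
                finite = np.isfinite(statistics)
                adjusted = np.full(len(test_snps), np.nan)
                adjusted[finite] = minp_adjust(null[:, finite], statistics[finite])
        corrected = None
        if gc:
            finite = np.isfinite(pvalues)
            corrected = np.full(len(test_snps), np.nan)
            corrected[finite] = gc_correct(
                np.clip(pvalues[finite], 1e-300, 1.0), max(lam, 1e-9)
            )
        return MatchedAssociationResults(
            model=self,
            snp_ids=snp_ids,
            statistics=statistics,
            m_units=m,
            pvalues=pvalues,
            pvalues_minp=adjusted,
            pvalues_gc=corrected,
            inflation=lam,
            structure=structure,
            b_permutations=b_permutations,
            seed=seed,
        )


@dataclass
class MatchedAssociationResults:
    """Per-SNP results of a structured association scan."""

    model: MatchedAssociation
    snp_ids: list[str]
    statistics: np.ndarray
    m_units: np.ndarray
    pvalues: np.ndarray
    pvalues_minp: np.ndarray | None
    pvalues_gc: np.ndarray | None
    inflation: float
    structure: UnitStructure | None
    b_permutations: int
    seed: int

    @property
    def n_units(self) -> int:
        return self.structure.n_units if self.structure is not None else 0

    def false_positive_rate(self, alpha: float = 0.05) -> float:
        p = self.pvalues[np.isfinite(self.pvalues)]
        return float((p < alpha).mean())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "method": self.model.test,
                "statistic": self.statistics,
                "M": self.m_units,
                "p_value": self.pvalues,
            }
        )
        if self.pvalues_minp is not None:
            frame["p_minp"] = self.pvalues_minp
        if self.pvalues_gc is not None:
            frame["p_gc"] = self.pvalues_gc
        return frame

    def summary(self) -> str:
        model = self.model
        n = len(model.phenotype)
        included = (
            len(self.structure.matched) if self.structure is not None else n
        )
        lines = [
            "Structured case-control association scan",
            "========================================",
            f"test: {model.test}   units: {model.units}   validation: {model.validation}",
            f"individuals: {n} (included: {included})   SNPs tested: {len(self.snp_ids)}",
            f"units: {self.n_units}   permutation cycles: {self.b_permutations}",
            f"inflation factor lambda: {self.inflation:.3f}",
            f"false-positive rate at 0.05: {self.false_positive_rate():.4f}",
        ]
        finite = np.isfinite(self.pvalues)
        if finite.any():
            top = int(np.nanargmin(np.where(finite, self.pvalues, np.nan)))
            lines.append(
                f"top SNP: {self.snp_ids[top]} (p = {self.pvalues[top]:.3g})"
            )
        return "\n".join(lines)
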