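"""Benchmark arm: MDS ancestry covariates and logistic-regression LRT.

Classical (Torgerson) multidimensional scaling of the IBS-derived
distance d_ij = 1 - s_ij yields per-individual coordinates whose
leading axes track ancestry; a logistic regression of case-control
status on these covariates plus the additive genotype dosage, tested
with the likelihood-ratio statistic against the covariates-only null,
is the standard principal-components comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import chi2

from .codec import MISSING, Phenotype
from .similarity import SimilarityMatrix


@dataclass
class StructureCovariates:
    """Column-centred MDS coordinates with their (nonincreasing) eigenvalues."""

    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)
    individual_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        ids = self.individual_ids or [str(i) for i in range(len(self.coordinates))]
        with open(path, "w") as fh:
            fh.write("individual_id\t" + "\t".join(f"C{j+1}" for j in range(self.k)) + "\n")
            for iid, row in zip(ids, self.coordinates):
                fh.write(iid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def mds_components(sim: SimilarityMatrix, k: int) -> StructureCovariates:
    """Top-k classical-scaling coordinates of the distance 1 - s.

    Coordinates are eigenvectors of the double-centred squared-distance
    Gram matrix scaled by sqrt(eigenvalue); negative-eigenvalue axes are
    never returned.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = sim.n
    if k >= n:
        raise ValueError("k must be smaller than the sample size")
    d = 1.0 - sim.scores
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    gram = (gram + gram.T) / 2
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:k]
    vals = vals[order]
    vecs = vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    coords = vecs * np.sqrt(pos)
    coords -= coords.mean(axis=0, keepdims=True)
    return StructureCovariates(
        coordinates=coords, eigenvalues=pos, individual_ids=list(sim.individual_ids)
    )


class SeparationError(RuntimeError):
    """The logistic fit diverged (quasi-complete separation)."""


def _logistic_loglik_irls(
    x: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> float:
    """Maximised log-likelihood of a logistic model via IRLS.

    Columns are standardised internally (the log-likelihood is
    invariant), so the divergence guard |beta| > 20 refers to
    per-standard-deviation effects; tripping it is reported as
    separation.
    """
    n, p = x.shape
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    sd[0] = 1.0  # intercept column
    x = x / sd
    beta = np.zeros(p)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        ll = float(y @ eta - np.log1p(np.exp(eta)).sum())
        if np.abs(beta).max() > 20:
            raise SeparationError("diverging coefficients")
        if abs(ll - ll_old) < tol:
            return ll
        ll_old = ll
        xtw = x.T * np.maximum(w, 1e-10)
        try:
            beta = beta + np.linalg.solve(xtw @ x, x.T @ (y - mu))
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
    return ll_old


def logistic_lrt(
    genotypes: np.ndarray,
    phen: Phenotype,
    covariates: StructureCovariates | np.ndarray | None = None,
) -> float:
    """LRT p-value for additive genotype effect given structure covariates.

    Missing genotypes are excluded for the tested SNP.  A constant
    genotype yields LRT = 0 and p = 1; a separated fit yields NaN.
    """
    g = np.asarray(genotypes, dtype=float)
    keep = g != MISSING
    g = g[keep]
    y = phen.labels[keep].astype(float)
    cov = None
    if covariates is not None:
        cov = (
            covariates.coordinates if isinstance(covariates, StructureCovariates) else covariates
        )
        cov = np.asarray(cov, dtype=float)[keep]
    n = len(g)
    x0 = np.ones((n, 1)) if cov is None else np.hstack([np.ones((n, 1)), cov])
    if np.ptp(g) == 0:
        return 1.0
    x1 = np.hstack([x0, g[:, None]])
    try:
        ll0 = _logistic_loglik_irls(x0, y)
        ll1 = _logistic_loglik_irls(x1, y)
    except SeparationError:
        return float("nan")
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    return float(chi2.sf(lrt, 1))


def logistic_lrt_scan(
    codes: np.ndarray,
    phen: Phenotype,
    covariates: StructureCovariates | np.ndarray | None = None,
) -> np.ndarray:
    """Per-SNP LRT p-values over a full (n, S) dosage matrix."""
    s = codes.shape[1]
    return np.array([logistic_lrt(codes[:, j], phen, covariates) for j in range(s)])
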