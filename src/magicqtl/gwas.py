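"""Kinship-corrected single-SNP mixed-linear-model association scan.

The model is y = mu + x_j b_j + u + e with u ~ N(0, s2_g K) and
e ~ N(0, s2_e I).  Variance components are estimated once by REML on the
null (no-SNP) model through a spectral decomposition of the kinship
matrix — the "previously determined population parameters" (P3D)
strategy — and held fixed for every SNP test, which is then a
generalized-least-squares Wald F test of the additive dosage term.
No compression (individual grouping) is applied: the scan is a standard
mixed linear model per SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core_io import MISSING, GenotypeMatrix, GwasResult

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Genome-wide relationship matrix among individuals."""

    individuals: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individuals)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape inconsistent with individual list")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


@dataclass
class NullModelFit:
    """REML fit of the intercept-only polygenic model."""

    sigma2_g: float
    sigma2_e: float
    loglik: float
    beta: np.ndarray
    # spectral cache for P3D tests: K = U diag(d) U'
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def ratio(self) -> float:
        """Polygenic-to-residual variance ratio (lambda)."""
        return self.sigma2_g / self.sigma2_e if self.sigma2_e > 0 else np.inf


def _imputed_dosages(gm: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with per-locus mean imputation of missing calls."""
    D = gm.dosages.astype(float)
    D[gm.dosages == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(D), np.nan, D), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.broadcast_to(col_mean, D.shape)[nan_mask]
    return D


def compute_kinship(gm: GenotypeMatrix, ridge_tol: float = 1e-8) -> KinshipMatrix:
    """Centered (VanRaden) genomic relationship matrix.

    K = W W' / sum_j 2 p_j (1 - p_j) with W the dosage matrix centered by
    2p per locus; monomorphic loci contribute nothing.  A small ridge is
    added to the diagonal if the smallest eigenvalue is negative.
    """
    D = _imputed_dosages(gm)
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic; kinship undefined")
    W = D[:, poly] - 2.0 * p[poly]
    denom = float(np.sum(2.0 * p[poly] * (1.0 - p[poly])))
    K = W @ W.T / denom
    w = np.linalg.eigvalsh(K)
    if w.min() < -ridge_tol:
        K = K + (abs(w.min()) + ridge_tol) * np.eye(K.shape[0])
        logger.info("added ridge %.3e to kinship for PSD", abs(w.min()) + ridge_tol)
    return KinshipMatrix(individuals=list(gm.individuals), values=K)


def fit_null(
    phenotype: np.ndarray,
    kinship: KinshipMatrix,
    X: np.ndarray | None = None,
) -> NullModelFit:
    """REML of the intercept-only mixed model via the kinship spectrum.

    One-dimensional optimization of the variance ratio on the rotated
    data; the residual variance is profiled out in closed form.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if n != len(kinship.individuals):
        raise ValueError("phenotype and kinship dimensions differ")
    if np.var(y) == 0.0:
        raise ValueError("phenotype has zero variance; null model degenerate")
    if X is None:
        X = np.ones((n, 1))

    d, U = np.linalg.eigh(kinship.values)
    d = np.clip(d, 0.0, None)
    y_rot = U.T @ y
    X_rot = U.T @ X
    p = X.shape[1]

    def reml_pieces(log_delta: float):
        """beta, residual quadratic form and restricted log-likelihood at
        delta = s2_g/s2_e, with s2_e profiled out (V = s2_e (delta K + I))."""
        v = np.exp(log_delta) * d + 1.0
        Xw = X_rot / v[:, None]
        XtHX = X_rot.T @ Xw
        beta = np.linalg.solve(XtHX, Xw.T @ y_rot)
        eta = y_rot - X_rot @ beta
        ypy = float(np.sum(eta**2 / v))
        s2 = ypy / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(s2)
            + float(np.sum(np.log(v)))
            + float(np.linalg.slogdet(np.atleast_2d(XtHX))[1])
            + (n - p)
        )
        return beta, s2, ll

    def neg_ll(log_delta: float) -> float:
        return -reml_pieces(log_delta)[2]

    # coarse grid then local refinement over log(delta)
    grid = np.linspace(-10.0, 10.0, 81)
    vals = np.array([neg_ll(g) for g in grid])
    if not np.all(np.isfinite(vals)):
        raise RuntimeError(
            "null-model REML failed; profile trace: "
            + ", ".join(f"{g:.2f}:{v:.4g}" for g, v in zip(grid, vals))
        )
    k = int(np.argmin(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    log_delta = float(res.x)
    if neg_ll(grid[k]) < res.fun:
        log_delta = float(grid[k])

    delta = np.exp(log_delta)
    beta, s2_e, ll = reml_pieces(log_delta)
    s2_g = delta * s2_e
    # near-zero ratios collapse to the OLS limit
    if delta < 1e-8:
        s2_g = 0.0
    return NullModelFit(
        sigma2_g=s2_g, sigma2_e=s2_e, loglik=ll, beta=beta, eigvals=d, eigvecs=U
    )


def scan_snps(
    phenotype: np.ndarray,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    null: NullModelFit,
    maf_threshold: float = 0.05,
) -> tuple[list[GwasResult], list]:
    """GLS Wald F test of every SNP with null-model components held fixed.

    Returns (results, filtered_loci): SNPs below the minor-allele-frequency
    threshold are reported in ``filtered_loci`` rather than silently
    omitted.  The test statistic uses n - rank(X) - 1 denominator degrees
    of freedom (intercept plus the dosage term).
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if genotypes.n_individuals != n:
        raise ValueError("phenotype and genotype dimensions differ")

    # whitening transform from the fixed null components
    v = null.sigma2_g * null.eigvals + null.sigma2_e
    w = 1.0 / np.sqrt(v)
    Ut = null.eigvecs.T
    y_t = w * (Ut @ y)
    one_t = w * (Ut @ np.ones(n))

    D = _imputed_dosages(genotypes)
    freq = D.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    results: list[GwasResult] = []
    filtered: list = []
    dof = n - 2
    for j, locus in enumerate(genotypes.loci):
        if maf[j] < maf_threshold:
            filtered.append(locus)
            continue
        x_t = w * (Ut @ D[:, j])
        X = np.column_stack([one_t, x_t])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            filtered.append(locus)
            continue
        beta = XtX_inv @ (X.T @ y_t)
        resid = y_t - X @ beta
        s2 = float(resid @ resid) / dof
        se = float(np.sqrt(s2 * XtX_inv[1, 1]))
        if se == 0.0:
            filtered.append(locus)
            continue
        fstat = (beta[1] / se) ** 2
        pval = float(stats.f.sf(fstat, 1, dof))
        results.append(
            GwasResult(
                locus=locus, effect=float(beta[1]), p=max(pval, np.nextafter(0, 1)),
                se=se, maf=float(maf[j]),
            )
        )
    if not results:
        logger.warning("all %d SNPs filtered; empty scan", genotypes.n_loci)
    return results, filtered
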