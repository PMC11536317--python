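"""Adjusted means, variance components and heritability from field trials.

Three estimators over plot-level phenotype tables from replicated
incomplete-block designs:

* :func:`estimate_blues` — genotype BLUEs across environments from a
  one-stage mixed model with genotype fixed and environment,
  replicate-within-environment and incomplete-block random.
* :func:`estimate_variance_components` — REML components Vg, Vgxe, Vres
  (all factors random), with standard errors from the information matrix.
* :func:`heritability_family_mean` — heritability on a family-mean basis,
  h² = Vg / (Vg + Vgxe/e + Vres/(e·r)), with a delta-method SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import PhenotypeTable
from .reml import RemlFit, indicator_matrix, reml_fit

logger = logging.getLogger(__name__)


@dataclass
class AdjustedMeans:
    """Per-genotype BLUEs with standard errors for one trait."""

    trait: str
    set_id: str
    table: pd.DataFrame  # columns: genotype, blue, se
    missing: list[str]  # genotypes with no usable records

    def series(self) -> pd.Series:
        return self.table.set_index("genotype")["blue"]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class VarianceComponents:
    """REML variance decomposition of one trait: Vp = Vg + Vgxe + Vres."""

    vg: float
    vgxe: float
    vres: float
    vg_se: float
    vgxe_se: float
    vres_se: float
    cov: np.ndarray | None = None  # covariance of (vg, vgxe, vres)

    @property
    def vp(self) -> float:
        return self.vg + self.vgxe + self.vres

    def significant(self, component: str) -> bool:
        """A component is declared significant when it exceeds twice its SE."""
        val, se = {
            "vg": (self.vg, self.vg_se),
            "vgxe": (self.vgxe, self.vgxe_se),
            "vres": (self.vres, self.vres_se),
        }[component]
        return val > 2 * se


@dataclass
class HeritabilityEstimate:
    """Family-mean heritability over e environments and r replicates."""

    h2: float
    se: float
    e: int
    r: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.h2)


def _design_matrices(df: pd.DataFrame):
    env = df["env"].astype(str)
    rep = env + ":" + df["rep"].astype(str)
    block = df["block"].astype(str)
    Z_env, _ = indicator_matrix(env.to_numpy())
    Z_rep, _ = indicator_matrix(rep.to_numpy())
    Z_block, _ = indicator_matrix(block.to_numpy())
    return Z_env, Z_rep, Z_block


def estimate_blues(
    phenotypes: PhenotypeTable, trait: str, set_id: str = ""
) -> AdjustedMeans:
    """Generalized-least-squares genotype means across environments.

    Genotype enters as a fixed factor (cell-means coding); environment,
    replicate-within-environment and incomplete-block-within-replicate
    are random.  Genotypes present in the table but without any usable
    record are reported in ``missing`` rather than silently dropped.
    """
    df = phenotypes.trait(trait)
    usable = df.dropna(subset=["value"])
    all_geno = sorted(df["genotype"].astype(str).unique())
    geno = usable["genotype"].astype(str).to_numpy()
    present = sorted(set(geno))
    missing = [g for g in all_geno if g not in present]
    if len(present) < 2:
        raise ValueError("need at least two genotypes with data")
    if missing:
        logger.warning("%d genotype(s) without data: %s", len(missing), missing)

    y = usable["value"].to_numpy(dtype=float)
    X, levels = indicator_matrix(geno)
    Z_env, Z_rep, Z_block = _design_matrices(usable)
    single_env = usable["env"].nunique() == 1

    # drop factors whose partition duplicates a coarser one (e.g. one rep
    # per environment, one block per replicate) to keep REML identifiable
    z_list, names = [], []
    prev_levels = 1
    for Z, name in ((Z_env, "env"), (Z_rep, "rep"), (Z_block, "block")):
        if Z.shape[1] > max(prev_levels, 1):
            z_list.append(Z)
            names.append(name)
            prev_levels = Z.shape[1]
    if not z_list:
        # complete single-environment single-rep layout: plain OLS means
        fit_beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ fit_beta
        dof = max(len(y) - X.shape[1], 1)
        s2 = float(resid @ resid) / dof
        counts = X.sum(axis=0)
        se = np.sqrt(s2 / counts)
        table = pd.DataFrame({"genotype": levels, "blue": fit_beta, "se": se})
        return AdjustedMeans(trait=trait, set_id=set_id, table=table, missing=missing)

    fit = reml_fit(y, X, z_list, names=names)
    se = np.sqrt(np.clip(np.diag(fit.beta_cov), 0.0, None))
    table = pd.DataFrame({"genotype": levels, "blue": fit.beta, "se": se})
    if missing:
        table = pd.concat(
            [table, pd.DataFrame({"genotype": missing, "blue": np.nan, "se": np.nan})],
            ignore_index=True,
        ).sort_values("genotype", ignore_index=True)
    if single_env:
        logger.info("single environment: BLUEs are within-environment adjusted means")
    return AdjustedMeans(trait=trait, set_id=set_id, table=table, missing=missing)


def estimate_variance_components(
    phenotypes: PhenotypeTable, trait: str
) -> tuple[VarianceComponents, RemlFit]:
    """REML Vg, Vgxe, Vres with all factors random.

    The model carries genotype, environment, genotype x environment,
    replicate-within-environment and block random effects; only the three
    components of the phenotypic variance on the plot scale are reported
    (design factors are nuisance).  Negative solutions are constrained
    to zero.
    """
    df = phenotypes.trait(trait).dropna(subset=["value"])
    if df["env"].nunique() < 2:
        raise ValueError("variance components need >= 2 environments")
    if df["genotype"].nunique() < 2:
        raise ValueError("variance components need >= 2 genotypes")

    y = df["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    geno = df["genotype"].astype(str).to_numpy()
    gxe = np.char.add(np.char.add(geno, "@"), df["env"].astype(str).to_numpy())
    Z_g, _ = indicator_matrix(geno)
    Z_ge, _ = indicator_matrix(gxe)
    Z_env, Z_rep, Z_block = _design_matrices(df)

    z_list = [Z_g, Z_ge, Z_env]
    names = ["vg", "vgxe", "env"]
    prev_levels = Z_env.shape[1]
    for Z, name in ((Z_rep, "rep"), (Z_block, "block")):
        if Z.shape[1] > prev_levels:
            z_list.append(Z)
            names.append(name)
            prev_levels = Z.shape[1]
    fit = reml_fit(y, X, z_list, names=names)

    idx = {n: i for i, n in enumerate(fit.names)}
    sel = [idx["vg"], idx["vgxe"], idx["residual"]]
    cov = fit.sigma2_cov[np.ix_(sel, sel)]
    vc = VarianceComponents(
        vg=fit.component("vg"),
        vgxe=fit.component("vgxe"),
        vres=fit.component("residual"),
        vg_se=fit.component_se("vg"),
        vgxe_se=fit.component_se("vgxe"),
        vres_se=fit.component_se("residual"),
        cov=cov,
    )
    return vc, fit


def heritability_family_mean(
    vc: VarianceComponents, e: int, r: int
) -> HeritabilityEstimate:
    """h² = Vg / (Vg + Vgxe/e + Vres/(e·r)) on the family-mean scale.

    ``e`` is the number of environments actually phenotyped for the trait
    and ``r`` the replicates per environment.  The SE comes from the delta
    method; component covariances are used when available, else the
    components are treated as uncorrelated.
    """
    if e < 1 or r < 1:
        raise ValueError("e and r must be >= 1")
    denom = vc.vg + vc.vgxe / e + vc.vres / (e * r)
    if denom == 0.0:
        logger.warning("all variance components are zero; heritability undefined")
        return HeritabilityEstimate(h2=float("nan"), se=float("nan"), e=e, r=r)
    h2 = vc.vg / denom
    # delta method: gradient of h2 w.r.t. (vg, vgxe, vres)
    grad = np.array(
        [
            (denom - vc.vg) / denom**2,
            -vc.vg / (e * denom**2),
            -vc.vg / (e * r * denom**2),
        ]
    )
    if vc.cov is not None:
        var = float(grad @ vc.cov @ grad)
    else:
        var = float(np.sum(grad**2 * np.array([vc.vg_se, vc.vgxe_se, vc.vres_se]) ** 2))
    return HeritabilityEstimate(h2=h2, se=float(np.sqrt(max(var, 0.0))), e=e, r=r)
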