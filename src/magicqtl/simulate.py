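"""Synthetic MAGIC population, testcross and field-trial generator.

Simulates an eight-founder multiparent advanced generation intercross
(MAGIC): fully inbred founders crossed through a balanced funnel
(2-way -> 4-way -> 8-way), then single-seed descent for ``g`` selfing
generations.  Recombination follows the Haldane model: crossovers per
chromosome per meiosis are Poisson with mean equal to the map length in
Morgans, positions uniform on the genetic map, no interference.

Testcross hybrids are produced by crossing each RIL to a homozygous
unrelated tester.  Field phenotypes come from a replicated
incomplete-block (lattice-style) design with environment, genotype x
environment, block and plot-residual effects, calibrated by default to
the variance structure of the study sets (see :mod:`magicqtl.presets`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .core_io import MISSING, GenotypeMatrix, PhenotypeTable, SnpLocus, parse_snp_id
from .presets import PRESETS, TraitPreset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class GeneticMap:
    """Physical loci with genetic (cM) positions, per chromosome."""

    loci: list[SnpLocus]
    cm: np.ndarray  # map position of each locus, aligned with loci

    def __post_init__(self) -> None:
        self.cm = np.asarray(self.cm, dtype=float)
        if len(self.loci) == 0:
            raise ValueError("empty genetic map")
        if len(self.loci) != self.cm.shape[0]:
            raise ValueError("loci/cM length mismatch")
        for c in self.chromosomes:
            idx = self._chrom_idx(c)
            if np.any(np.diff(self.cm[idx]) < 0):
                raise ValueError(f"cM positions decrease with bp on chromosome {c}")
            if self.length_cm(c) <= 0:
                raise ValueError(f"chromosome {c} has zero map length")

    @property
    def chromosomes(self) -> list[int]:
        return sorted({loc.chrom for loc in self.loci})

    def _chrom_idx(self, chrom: int) -> np.ndarray:
        return np.array([j for j, loc in enumerate(self.loci) if loc.chrom == chrom])

    def chrom_slices(self) -> dict[int, np.ndarray]:
        return {c: self._chrom_idx(c) for c in self.chromosomes}

    def length_cm(self, chrom: int) -> float:
        idx = self._chrom_idx(chrom)
        return float(self.cm[idx].max() - self.cm[idx].min())

    @classmethod
    def uniform(
        cls,
        n_chrom: int = 10,
        loci_per_chrom: int = 100,
        length_cm: float = 150.0,
        length_bp: int = 200_000_000,
    ) -> "GeneticMap":
        """Evenly spaced loci with cM proportional to bp (constant cM/Mb)."""
        loci: list[SnpLocus] = []
        cms: list[float] = []
        for c in range(1, n_chrom + 1):
            pos = np.linspace(1, length_bp, loci_per_chrom).astype(int)
            pos = np.unique(pos)
            loci.extend(SnpLocus(chrom=c, pos=int(p)) for p in pos)
            cms.extend(length_cm * (pos - 1) / max(length_bp - 1, 1))
        return cls(loci=loci, cm=np.array(cms))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class QtlEffect:
    """A causal locus: additive effect per alternate-allele copy, and a
    dominance deviation expressed by heterozygotes (relevant in hybrids)."""

    locus: SnpLocus
    additive: float
    dominance: float = 0.0


@dataclass
class TraitSpec:
    """Generative model for one trait.

    ``vg`` is the polygenic background variance among genotypes; planted
    QTLs add variance on top of it.  ``venv`` and ``vblock`` control the
    design nuisance effects (environment main effects and incomplete-block
    effects) which are absorbed by the analysis models, not reported.
    """

    name: str
    intercept: float = 0.0
    vg: float = 1.0
    vgxe: float = 0.0
    vres: float = 1.0
    venv: float | None = None  # default: vres
    vblock: float | None = None  # default: vres / 4
    qtls: list[QtlEffect] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.vg, self.vgxe, self.vres):
            if v < 0:
                raise ValueError("variance components must be >= 0")

    @property
    def venv_(self) -> float:
        return self.vres if self.venv is None else self.venv

    @property
    def vblock_(self) -> float:
        return self.vres / 4 if self.vblock is None else self.vblock

    @classmethod
    def from_preset(cls, set_id: str, trait: str, **overrides) -> "TraitSpec":
        p: TraitPreset = PRESETS[set_id][trait]
        kw = dict(name=trait, intercept=p.mean, vg=p.vg, vgxe=p.vgxe, vres=p.vres)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FieldDesign:
    """Replicated incomplete-block layout: every replicate contains all
    genotypes, partitioned at random into blocks of ``block_size``."""

    environments: list[str]
    replicates: int = 2
    block_size: int = 8

    def __post_init__(self) -> None:
        if not self.environments:
            raise ValueError("design needs at least one environment")
        if self.replicates < 1 or self.block_size < 1:
            raise ValueError("replicates and block size must be >= 1")


@dataclass
class SimulationConfig:
    """Study-level knobs for the synthetic MAGIC experiment.

    Defaults mirror the modelled study: 8 founders, 608 RILs, ~6 selfing
    generations, two genetically correlated traits.  The marker panel is
    scaled down from the real 224k-SNP panel to keep simulation tractable;
    density is configurable through the map arguments.
    """

    n_founders: int = 8
    n_rils: int = 608
    selfing_generations: int = 6
    n_chrom: int = 10
    loci_per_chrom: int = 100
    chrom_length_cm: float = 150.0
    chrom_length_bp: int = 200_000_000
    genetic_correlation: float = 0.0
    traits: list[TraitSpec] = dc_field(default_factory=list)
    design: FieldDesign | None = None
    truncate_at_zero: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_founders < 2 or (self.n_founders & (self.n_founders - 1)) != 0:
            raise ValueError("n_founders must be a power of two for a balanced funnel")
        if self.selfing_generations < 1:
            raise ValueError("need at least one selfing generation")
        if abs(self.genetic_correlation) > 1:
            raise ValueError("|genetic correlation| must be <= 1")

    def make_map(self) -> GeneticMap:
        return GeneticMap.uniform(
            self.n_chrom, self.loci_per_chrom, self.chrom_length_cm, self.chrom_length_bp
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        traits = []
        for t in raw.pop("traits", []):
            qtls = [
                QtlEffect(
                    locus=parse_snp_id(q["snp"]),
                    additive=float(q.get("additive", 0.0)),
                    dominance=float(q.get("dominance", 0.0)),
                )
                for q in t.pop("qtls", [])
            ]
            traits.append(TraitSpec(qtls=qtls, **t))
        design = raw.pop("design", None)
        if design is not None:
            design = FieldDesign(**design)
        return cls(traits=traits, design=design, **raw)


# ---------------------------------------------------------------------------
# founders and meiosis


@dataclass
class FounderSet:
    """Homozygous founder haplotypes: alleles[f, j] in {0, 1}."""

    alleles: np.ndarray
    map: GeneticMap

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]


def simulate_founders(config: SimulationConfig, gmap: GeneticMap, rng: np.random.Generator) -> FounderSet:
    """Draw distinct fully homozygous founders, polymorphic at every locus."""
    n_f = config.n_founders
    m = len(gmap.loci)
    alleles = (rng.random((n_f, m)) < 0.5).astype(np.int8)
    # guarantee polymorphism across the founder set at every locus
    mono = np.flatnonzero(alleles.sum(axis=0) % n_f == 0)
    for j in mono:
        alleles[rng.integers(n_f), j] ^= 1
    return FounderSet(alleles=alleles, map=gmap)


def _gamete(hap_a: np.ndarray, hap_b: np.ndarray, gmap: GeneticMap,
            chrom_slices: dict[int, np.ndarray], rng: np.random.Generator) -> np.ndarray:
    """One meiotic product under the Haldane (Poisson crossover) model."""
    out = np.empty_like(hap_a)
    for c, idx in chrom_slices.items():
        cm = gmap.cm[idx]
        lo, hi = float(cm.min()), float(cm.max())
        n_xo = rng.poisson((hi - lo) / 100.0)
        phase0 = int(rng.integers(2))
        if n_xo == 0:
            src = hap_a if phase0 == 0 else hap_b
            out[idx] = src[idx]
            continue
        xo = np.sort(rng.uniform(lo, hi, size=n_xo))
        seg = (np.searchsorted(xo, cm, side="right") + phase0) % 2
        out[idx] = np.where(seg == 0, hap_a[idx], hap_b[idx])
    return out


@dataclass
class MagicPopulation:
    """RIL genotypes plus the founder-origin mosaic for diagnostics."""

    genotypes: GenotypeMatrix
    origins: np.ndarray  # (n_rils, 2, n_loci) founder labels per haplotype
    founders: FounderSet

    def founder_share(self) -> np.ndarray:
        """Mean genome fraction inherited from each founder, over RILs."""
        n_f = self.founders.n_founders
        counts = np.array([(self.origins == f).mean() for f in range(n_f)])
        return counts


def simulate_magic_rils(
    founders: FounderSet, config: SimulationConfig, rng: np.random.Generator
) -> MagicPopulation:
    """Balanced-funnel MAGIC RILs by single-seed descent.

    Each RIL descends from an independent funnel over a random permutation
    of the founders, followed by ``selfing_generations`` generations of
    selfing, so residual heterozygosity halves each generation.
    """
    gmap = founders.map
    m = len(gmap.loci)
    slices = gmap.chrom_slices()
    n_f = config.n_founders
    labels = [np.full(m, f, dtype=np.int8) for f in range(n_f)]

    origins = np.empty((config.n_rils, 2, m), dtype=np.int8)
    for i in range(config.n_rils):
        order = rng.permutation(n_f)
        # funnel: pair up, recombine, repeat until a single individual remains
        generation = [(labels[order[k]], labels[order[k + 1]]) for k in range(0, n_f, 2)]
        while len(generation) > 1:
            nxt = []
            for a, b in zip(generation[::2], generation[1::2]):
                nxt.append((_gamete(*a, gmap, slices, rng), _gamete(*b, gmap, slices, rng)))
            generation = nxt
        h1, h2 = generation[0]
        for _ in range(config.selfing_generations):
            h1, h2 = (
                _gamete(h1, h2, gmap, slices, rng),
                _gamete(h1, h2, gmap, slices, rng),
            )
        origins[i, 0] = h1
        origins[i, 1] = h2

    allele = founders.alleles
    col = np.arange(m)
    dosages = (
        allele[origins[:, 0, :], col[None, :]] + allele[origins[:, 1, :], col[None, :]]
    ).astype(np.int8)
    ids = [f"RIL_{i + 1:04d}" for i in range(config.n_rils)]
    gm = GenotypeMatrix(individuals=ids, loci=list(gmap.loci), dosages=dosages)
    gm.check_ril_heterozygosity()
    return MagicPopulation(genotypes=gm, origins=origins, founders=founders)


def make_tester(gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """An unrelated homozygous tester, as a dosage vector in {0, 2}."""
    return 2 * (rng.random(len(gmap.loci)) < 0.5).astype(np.int8)


def make_testcross(
    rils: GenotypeMatrix,
    tester: np.ndarray,
    rng: np.random.Generator | None = None,
    prefix: str = "HYB",
) -> GenotypeMatrix:
    """Cross every RIL to a homozygous tester.

    Hybrid dosage = RIL gamete allele + tester allele.  Residual
    heterozygous RIL loci transmit a random allele (rng required if any
    are present).
    """
    tester = np.asarray(tester)
    if tester.shape[0] != rils.n_loci:
        raise ValueError("tester length does not match locus count")
    if np.any(~np.isin(tester, (0, 2))):
        raise ValueError("tester must be homozygous (dosages 0 or 2) at every locus")
    t_allele = (tester // 2).astype(np.int8)

    d = rils.dosages
    gamete = (d // 2).astype(np.int8)  # exact for homozygous calls
    het = d == 1
    if het.any():
        if rng is None:
            raise ValueError("rng required: RIL matrix has heterozygous calls")
        gamete[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    hyb = gamete + t_allele[None, :]
    hyb[d == MISSING] = MISSING
    ids = [f"{prefix}_{rid}" for rid in rils.individuals]
    return GenotypeMatrix(
        individuals=ids, loci=list(rils.loci), dosages=hyb, alleles=list(rils.alleles)
    )


# ---------------------------------------------------------------------------
# phenotypes


def genotypic_values(
    gm: GenotypeMatrix,
    traits: list[TraitSpec],
    genetic_correlation: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True genotypic value per individual and trait.

    Value = intercept + QTL contributions (additive per allele copy plus a
    dominance deviation for heterozygotes) + a polygenic deviate.  The
    polygenic deviates of the first two traits are drawn jointly with the
    configured genetic correlation.
    """
    n = gm.n_individuals
    sds = np.array([np.sqrt(t.vg) for t in traits])
    z = rng.standard_normal((n, len(traits)))
    if len(traits) >= 2 and genetic_correlation != 0.0:
        rho = genetic_correlation
        z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
    poly = z * sds[None, :]

    values = {}
    for k, t in enumerate(traits):
        g = np.full(n, t.intercept) + poly[:, k]
        for q in t.qtls:
            d = gm.column(q.locus).astype(float)
            d[d == MISSING] = np.nan
            contrib = q.additive * (d - 1.0) + q.dominance * (d == 1.0)
            g = g + np.nan_to_num(contrib)
        values[t.name] = g
    return pd.DataFrame(values, index=gm.individuals)


def simulate_phenotypes(
    gm: GenotypeMatrix,
    traits: list[TraitSpec],
    design: FieldDesign,
    rng: np.random.Generator,
    genetic_correlation: float = 0.0,
    truncate_at_zero: bool = False,
    set_id: str = "",
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Plot-level phenotypes under the lattice-style design.

    Returns the phenotype table and the true genotypic values used
    (handy for rank-correlation checks).  Plot value = genotypic value +
    environment effect + GxE deviation + block effect + residual;
    negative values are truncated at zero only on request (the truncation
    rate is logged, since truncation biases variance components).
    """
    n = gm.n_individuals
    if design.block_size > n:
        raise ValueError("block size exceeds number of genotypes")
    gvals = genotypic_values(gm, traits, genetic_correlation, rng)

    records = []
    n_truncated = {t.name: 0 for t in traits}
    for t in traits:
        gv = gvals[t.name].to_numpy()
        env_eff = rng.normal(0.0, np.sqrt(t.venv_), size=len(design.environments))
        gxe = rng.normal(0.0, np.sqrt(t.vgxe), size=(n, len(design.environments)))
        for e_idx, env in enumerate(design.environments):
            for rep in range(1, design.replicates + 1):
                order = rng.permutation(n)
                n_blocks = int(np.ceil(n / design.block_size))
                block_eff = rng.normal(0.0, np.sqrt(t.vblock_), size=n_blocks)
                resid = rng.normal(0.0, np.sqrt(t.vres), size=n)
                for slot, i in enumerate(order):
                    b = slot // design.block_size
                    val = (
                        gv[i]
                        + env_eff[e_idx]
                        + gxe[i, e_idx]
                        + block_eff[b]
                        + resid[i]
                    )
                    if truncate_at_zero and val < 0:
                        val = 0.0
                        n_truncated[t.name] += 1
                    records.append(
                        {
                            "genotype": gm.individuals[i],
                            "env": env,
                            "rep": rep,
                            "block": f"{env}:r{rep}:b{b + 1}",
                            "trait": t.name,
                            "value": float(val),
                        }
                    )
    for name, k in n_truncated.items():
        if k:
            logger.info("trait %s: truncated %d negative plot values at 0 (%s)",
                        name, k, set_id or "unnamed set")
    return PhenotypeTable(pd.DataFrame(records)), gvals
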