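"""Domain types and table I/O for the MAGIC QTL-validation pipeline.

SNP identifiers follow the ``S{chrom}_{pos}`` convention used throughout
maize GBS panels: the integer before the underscore is the chromosome
(1-10 in maize), the integer after it the 1-based physical position in
base pairs.  Genotypes travel as HapMap-format tables or VCF; phenotypes,
GWAS results and published-QTL lists as tab-separated tables.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing call

_SNP_ID_RE = re.compile(r"^S(\d+)_(\d+)$")

# IUPAC single-letter codes for heterozygous HapMap calls
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_IUPAC_REV = {v: tuple(sorted(k)) for k, v in _IUPAC.items()}


class SnpIdError(ValueError):
    """Raised when a SNP identifier does not match ``S{chrom}_{pos}``."""


@dataclass(frozen=True, order=True)
class SnpLocus:
    """A biallelic SNP locus addressed by chromosome and physical position."""

    chrom: int
    pos: int

    def __post_init__(self) -> None:
        if self.chrom < 1 or self.pos < 1:
            raise ValueError(
                f"chromosome and position must be >= 1, got ({self.chrom}, {self.pos})"
            )

    @property
    def id(self) -> str:
        return format_snp_id(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id


def parse_snp_id(snp_id: str) -> SnpLocus:
    """Parse ``S{chrom}_{pos}`` into a :class:`SnpLocus`.

    >>> parse_snp_id("S1_3708430")
    SnpLocus(chrom=1, pos=3708430)
    """
    m = _SNP_ID_RE.match(snp_id.strip())
    if m is None:
        raise SnpIdError(f"malformed SNP id {snp_id!r}: expected 'S<chrom>_<pos>'")
    chrom, pos = int(m.group(1)), int(m.group(2))
    if chrom < 1 or pos < 1:
        raise SnpIdError(f"malformed SNP id {snp_id!r}: chrom/pos must be >= 1")
    return SnpLocus(chrom=chrom, pos=pos)


def format_snp_id(locus: SnpLocus) -> str:
    return f"S{locus.chrom}_{locus.pos}"


def snp_distance(a: SnpLocus, b: SnpLocus) -> int | None:
    """Physical distance in bp, or ``None`` for loci on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    return abs(a.pos - b.pos)


# ---------------------------------------------------------------------------
# genotype matrix


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele dosages.

    dosages are int8 in {0, 1, 2} with -1 for missing.  Loci are kept
    strictly sorted by (chrom, pos); ``alleles`` stores (ref, alt) pairs
    so the matrix can round-trip through HapMap/VCF.
    """

    individuals: list[str]
    loci: list[SnpLocus]
    dosages: np.ndarray
    alleles: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.individuals) or m != len(self.loci):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if not self.alleles:
            self.alleles = [("A", "C")] * m
        if len(self.alleles) != m:
            raise ValueError("alleles list length must match number of loci")
        order = sorted(range(m), key=lambda j: (self.loci[j].chrom, self.loci[j].pos))
        if order != list(range(m)):
            logger.warning("loci not sorted by (chrom, pos); sorting")
            self.loci = [self.loci[j] for j in order]
            self.dosages = self.dosages[:, order]
            self.alleles = [self.alleles[j] for j in order]
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} dosage entries outside {{0,1,2,missing}}")
        self._index = {loc: j for j, loc in enumerate(self.loci)}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, locus: SnpLocus) -> int:
        try:
            return self._index[locus]
        except KeyError:
            raise KeyError(f"locus {locus.id} not present in genotype matrix") from None

    def __contains__(self, locus: SnpLocus) -> bool:
        return locus in self._index

    def column(self, locus: SnpLocus) -> np.ndarray:
        return self.dosages[:, self.locus_index(locus)]

    def het_fraction(self) -> float:
        """Fraction of heterozygous calls among non-missing calls."""
        called = self.dosages != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            return float("nan")
        return float((self.dosages == 1).sum() / n_called)

    def check_ril_heterozygosity(self, max_het: float = 0.05) -> float:
        """Report the het fraction; warn when it exceeds ``max_het``."""
        het = self.het_fraction()
        if het > max_het:
            logger.warning(
                "heterozygous call fraction %.4f exceeds RIL tolerance %.3f", het, max_het
            )
        return het

    def allele_freq(self) -> np.ndarray:
        """Per-locus alternate allele frequency over non-missing calls."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return GenotypeMatrix(
            individuals=list(ids),
            loci=list(self.loci),
            dosages=self.dosages[idx, :].copy(),
            alleles=list(self.alleles),
        )

    def subset_loci(self, loci: Sequence[SnpLocus]) -> "GenotypeMatrix":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=[self.loci[j] for j in idx],
            dosages=self.dosages[:, idx].copy(),
            alleles=[self.alleles[j] for j in idx],
        )


# ---------------------------------------------------------------------------
# HapMap / VCF genotype I/O

_HAPMAP_META = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def _genotype_code(ref: str, alt: str, dosage: int) -> str:
    if dosage == MISSING:
        return "NN"
    return {0: ref + ref, 1: ref + alt, 2: alt + alt}[dosage]


def write_hapmap(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a HapMap-format genotype table (tab separated, diploid calls)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_HAPMAP_META + list(gm.individuals)) + "\n")
        for j, loc in enumerate(gm.loci):
            ref, alt = gm.alleles[j]
            calls = [_genotype_code(ref, alt, int(d)) for d in gm.dosages[:, j]]
            row = [
                loc.id, f"{ref}/{alt}", str(loc.chrom), str(loc.pos),
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ] + calls
            fh.write("\t".join(row) + "\n")


def _decode_call(call: str, ref: str, alt: str) -> int:
    call = call.strip()
    if call in ("NN", "N", "--", "-", "./.", "."):
        return MISSING
    if len(call) == 1:
        pair = _IUPAC_REV.get(call)
        if pair is None:
            pair = (call, call)
        call = "".join(pair)
    if len(call) != 2:
        raise ValueError(f"unknown genotype call {call!r}")
    dosage = 0
    for a in call:
        if a == alt:
            dosage += 1
        elif a != ref:
            raise ValueError(f"allele {a!r} not in {{{ref},{alt}}}")
    return dosage


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty HapMap file: {path}")
    individuals = list(df.columns[len(_HAPMAP_META):])
    loci, alleles, rows = [], [], []
    n_multi = 0
    for _, rec in df.iterrows():
        allele_field = rec["alleles"].split("/")
        if len(allele_field) != 2:
            n_multi += 1
            continue
        ref, alt = allele_field
        loci.append(SnpLocus(chrom=int(rec["chrom"]), pos=int(rec["pos"])))
        alleles.append((ref, alt))
        rows.append([_decode_call(rec[ind], ref, alt) for ind in individuals])
    if n_multi:
        logger.warning("dropped %d non-biallelic HapMap records", n_multi)
    if not loci:
        raise ValueError(f"no biallelic records in HapMap file: {path}")
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci,
        dosages=np.array(rows, dtype=np.int8).T,
        alleles=alleles,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF v4.2 with GT-only genotype fields."""
    path = Path(path)
    chroms = sorted({loc.chrom for loc in gm.loci})
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=magicqtl\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals) + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, loc in enumerate(gm.loci):
            ref, alt = gm.alleles[j]
            calls = [gt_code[int(d)] for d in gm.dosages[:, j]]
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; non-biallelic records are dropped."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    individuals = list(vcf.samples)
    loci, alleles, rows = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        loci.append(SnpLocus(chrom=int(var.CHROM), pos=int(var.POS)))
        alleles.append((var.REF, var.ALT[0]))
        gts = var.genotype.array()[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        rows.append(dos)
    vcf.close()
    if n_multi:
        logger.warning("dropped %d non-biallelic VCF records", n_multi)
    if not loci:
        raise ValueError(f"no biallelic records in VCF: {path}")
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci,
        dosages=np.array(rows, dtype=np.int8).T,
        alleles=alleles,
    )


def read_genotypes(path: str | Path, format: str = "hapmap") -> GenotypeMatrix:
    """Read genotypes from ``hapmap`` or ``vcf`` format."""
    if format == "hapmap":
        return read_hapmap(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# phenotype tables

PHENOTYPE_COLUMNS = ["genotype", "env", "rep", "block", "trait", "value"]


@dataclass
class PhenotypeTable:
    """Plot-level phenotype records from replicated incomplete-block trials.

    One row per (genotype, environment, replicate, trait); the environment
    id encodes year x location x condition.  Values are non-negative in
    their trait units (tunnel length in cm; grain yield in g/plant for
    inbreds, Mg/ha for hybrids).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        dup = self.data.duplicated(subset=["genotype", "env", "rep", "trait"])
        if dup.any():
            raise ValueError(
                f"{int(dup.sum())} duplicate (genotype, env, rep, trait) records"
            )

    def trait(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == name]
        if sub.empty:
            raise KeyError(f"trait {name!r} not present")
        return sub.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def environments(self, trait: str) -> list[str]:
        return sorted(self.trait(trait)["env"].unique())

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"genotype": str, "env": str}))


# ---------------------------------------------------------------------------
# GWAS results


@dataclass(frozen=True)
class GwasResult:
    """Single-SNP association result: additive effect and p-value."""

    locus: SnpLocus
    effect: float
    p: float
    se: float = float("nan")
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value must be in (0, 1], got {self.p}")


def write_gwas_results(results: Iterable[GwasResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "snp": r.locus.id, "chrom": r.locus.chrom, "pos": r.locus.pos,
                "maf": r.maf, "effect": r.effect, "se": r.se, "p": r.p,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gwas_results(path: str | Path) -> list[GwasResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        GwasResult(
            locus=parse_snp_id(rec["snp"]), effect=float(rec["effect"]),
            p=float(rec["p"]), se=float(rec.get("se", np.nan)),
            maf=float(rec.get("maf", np.nan)),
        )
        for rec in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# published QTL lists

_QTL_CODE_RE = re.compile(r"^QTL_(\d+)_(\d+)$")


@dataclass(frozen=True)
class PublishedQtl:
    """A previously reported QTL: one code grouping >= 1 member SNPs."""

    code: str
    trait: str
    members: tuple[SnpLocus, ...]

    def __post_init__(self) -> None:
        m = _QTL_CODE_RE.match(self.code)
        if m is None:
            raise ValueError(f"malformed QTL code {self.code!r}")
        chrom = int(m.group(1))
        if int(m.group(2)) < 1:
            raise ValueError(f"QTL index must be >= 1 in {self.code!r}")
        off = [loc.id for loc in self.members if loc.chrom != chrom]
        if off:
            raise ValueError(
                f"QTL {self.code} members on wrong chromosome: {off}"
            )
        if not self.members:
            raise ValueError(f"QTL {self.code} has no member SNPs")

    @property
    def chrom(self) -> int:
        return self.members[0].chrom


def _strip_thousands(x) -> str:
    return str(x).replace(",", "").strip()


def read_published_qtls(path: str | Path, trait: str = "") -> list[PublishedQtl]:
    """Read a delimited SNP/QTL-code table and group rows into QTLs.

    The first two columns must be the SNP identifier and the QTL code;
    printed thousands separators are tolerated.  Member order within a
    QTL follows physical position; QTL order follows first appearance.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("published-QTL table needs SNP-id and QTL-code columns")
    snp_col, qtl_col = df.columns[:2]
    groups: dict[str, list[SnpLocus]] = {}
    for _, rec in df.iterrows():
        code = str(rec[qtl_col]).strip()
        locus = parse_snp_id(_strip_thousands(rec[snp_col]))
        groups.setdefault(code, []).append(locus)
    return [
        PublishedQtl(code=code, trait=trait, members=tuple(sorted(set(members))))
        for code, members in groups.items()
    ]
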