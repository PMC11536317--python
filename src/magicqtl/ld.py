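"""Pairwise linkage disequilibrium (r²) between SNPs.

The estimator is the squared Pearson correlation of dosage vectors
(composite LD).  On a fully homozygous RIL panel this coincides with the
haplotype-frequency r² = D² / (p_A p_a p_B p_b); in hybrid panels, where
phase is unknown, the composite form remains well defined.  A pair is
undefined ("No" in reports) when either locus is monomorphic among the
individuals scored at both loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, SnpLocus


@dataclass(frozen=True)
class LdValue:
    """r² for one locus pair; ``r2`` is NaN when not computable."""

    a: SnpLocus
    b: SnpLocus
    r2: float
    n: int  # individuals scored at both loci

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r2)


class LdSource(Protocol):
    """Anything that can answer an r² query for a pair of loci."""

    def ld_r2(self, a: SnpLocus, b: SnpLocus) -> LdValue: ...

    def __contains__(self, locus: SnpLocus) -> bool: ...


@dataclass
class GenotypeLd:
    """LD queries backed by a genotype matrix (pairwise-complete)."""

    genotypes: GenotypeMatrix

    def __contains__(self, locus: SnpLocus) -> bool:
        return locus in self.genotypes

    def ld_r2(self, a: SnpLocus, b: SnpLocus) -> LdValue:
        return ld_r2(self.genotypes, a, b)

    def ld_window(self, focal: SnpLocus, half_width: int) -> list[LdValue]:
        return ld_window(self.genotypes, focal, half_width)


@dataclass
class PrecomputedLd:
    """LD queries answered from a table of precomputed pair values.

    Used to re-evaluate published validation tables, where the r² values
    are given rather than recomputable from genotypes.  Lookup is
    symmetric in the pair; unknown pairs raise ``KeyError``.
    """

    values: dict[frozenset, float]

    @classmethod
    def from_pairs(cls, pairs) -> "PrecomputedLd":
        """pairs: iterable of (locus_a, locus_b, r2); r2 may be NaN."""
        vals = {}
        for a, b, r2 in pairs:
            vals[frozenset((a, b))] = float(r2)
        return cls(values=vals)

    def __contains__(self, locus: SnpLocus) -> bool:
        return any(locus in key for key in self.values)

    def ld_r2(self, a: SnpLocus, b: SnpLocus) -> LdValue:
        if a == b:
            return LdValue(a=a, b=b, r2=1.0, n=0)
        key = frozenset((a, b))
        if key not in self.values:
            raise KeyError(f"no precomputed LD for pair ({a.id}, {b.id})")
        return LdValue(a=a, b=b, r2=self.values[key], n=0)


def ld_r2(genotypes: GenotypeMatrix, a: SnpLocus, b: SnpLocus) -> LdValue:
    """Squared dosage correlation between two loci.

    Individuals missing at either locus are excluded pairwise; a
    monomorphic locus (after exclusion) makes the value undefined (NaN).
    """
    xa = genotypes.column(a).astype(float)
    xb = genotypes.column(b).astype(float)
    ok = (genotypes.column(a) != MISSING) & (genotypes.column(b) != MISSING)
    xa, xb = xa[ok], xb[ok]
    n = int(ok.sum())
    if n < 2 or np.var(xa) == 0.0 or np.var(xb) == 0.0:
        return LdValue(a=a, b=b, r2=float("nan"), n=n)
    r = np.corrcoef(xa, xb)[0, 1]
    r2 = min(float(r * r), 1.0)
    return LdValue(a=a, b=b, r2=r2, n=n)


def ld_window(
    genotypes: GenotypeMatrix, focal: SnpLocus, half_width: int
) -> list[LdValue]:
    """r² of the focal locus against every locus within ±half_width bp
    on the same chromosome (inclusive bounds), focal locus excluded."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    genotypes.locus_index(focal)  # raises if absent
    out = []
    for loc in genotypes.loci:
        if loc.chrom != focal.chrom or loc == focal:
            continue
        if abs(loc.pos - focal.pos) <= half_width:
            out.append(ld_r2(genotypes, focal, loc))
    return out


def write_ld_table(values: list[LdValue], path) -> None:
    df = pd.DataFrame(
        [
            {
                "snp_a": v.a.id, "snp_b": v.b.id, "n": v.n,
                "r2": "NA" if not v.defined else f"{v.r2:.6g}",
            }
            for v in values
        ]
    )
    df.to_csv(path, sep="\t", index=False)
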