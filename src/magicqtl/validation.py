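"""Two-criterion QTL validation against an independent GWAS.

A previously reported SNP is *validated* in a new evaluation set when

1. the same SNP is associated with the trait at p < 0.02, or
2. some SNP within ±2 Mbp is associated at p < 0.02 **and** is in
   linkage disequilibrium (r² > 0.2) with the reported SNP.

A multi-SNP QTL is validated when any of its member SNPs is.  The module
also provides the extreme-tail subset selection used to build the
validation sets, the cross-set (inbred vs hybrid) concordance summary,
and tabular report rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, GwasResult, PublishedQtl, SnpLocus
from .field_analysis import AdjustedMeans
from .ld import GenotypeLd, LdSource

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationPolicy:
    """Thresholds of the validation rule; defaults are the published ones."""

    p_threshold: float = 0.02
    window_bp: int = 2_000_000
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window must be positive")
        if not (0.0 <= self.r2_threshold < 1.0):
            raise ValueError("r2 threshold must be in [0, 1)")


class Criterion(str, Enum):
    SAME_SNP = "same_snp"
    LD_WINDOW = "ld_window"
    NONE = "none"


@dataclass
class ValidationRecord:
    """Outcome of the rule for one published SNP (or one QTL)."""

    qtl_code: str
    published: SnpLocus
    set_id: str
    trait: str
    published_p: float  # published SNP's own p in the subset GWAS
    candidate: SnpLocus | None
    candidate_p: float
    distance_bp: float  # NaN when no candidate
    r2: float  # NaN when undefined / no candidate
    criterion: Criterion
    validated: bool
    flagged: bool = False  # published SNP absent from the LD universe

    def __post_init__(self) -> None:
        assert self.validated == (self.criterion != Criterion.NONE)


def select_tails(
    blues_by_trait: dict[str, AdjustedMeans], n_target: int
) -> list[str]:
    """Union of the highest- and lowest-BLUE genotypes across traits.

    Starting from k = 1, the k most extreme genotypes at each tail of each
    trait's distribution are pooled; k grows until the union holds at
    least ``n_target`` genotypes.  If the final k overshoots, the newly
    added genotypes are kept in order of extremity (then id) until the
    target is met, so the selection is deterministic.  Ties at a cut rank
    are broken by lexicographic genotype id and logged.
    """
    tables = {t: am.table.dropna(subset=["blue"]) for t, am in blues_by_trait.items()}
    pools = [set(tab["genotype"]) for tab in tables.values()]
    pool = sorted(set.intersection(*pools))
    if n_target > len(pool):
        raise ValueError(f"n_target {n_target} exceeds pool size {len(pool)}")

    orderings: list[list[str]] = []
    for t, tab in tables.items():
        sub = tab[tab["genotype"].isin(pool)]
        asc = sub.sort_values(["blue", "genotype"], ascending=[True, True])
        desc = sub.sort_values(["blue", "genotype"], ascending=[False, True])
        dup = sub["blue"].duplicated(keep=False)
        if dup.any():
            logger.info("trait %s: %d tied BLUEs broken by genotype id", t, int(dup.sum()))
        orderings.append(list(asc["genotype"]))
        orderings.append(list(desc["genotype"]))

    selected: set[str] = set()
    for k in range(1, len(pool) + 1):
        new: list[tuple[int, int, str]] = []
        for o_idx, order in enumerate(orderings):
            g = order[k - 1]
            if g not in selected:
                new.append((k, o_idx, g))
        # keep most-extreme-first, deterministic
        new.sort(key=lambda t3: (t3[0], t3[1], t3[2]))
        for _, _, g in new:
            if g in selected:
                continue
            selected.add(g)
            if len(selected) == n_target:
                return sorted(selected)
    return sorted(selected)


def _scan_index(scan: list[GwasResult]) -> dict[SnpLocus, GwasResult]:
    return {r.locus: r for r in scan}


def validate_snp(
    published: SnpLocus,
    scan: list[GwasResult],
    ld_source: LdSource | GenotypeMatrix,
    policy: ValidationPolicy = ValidationPolicy(),
    qtl_code: str = "",
    set_id: str = "",
    trait: str = "",
) -> ValidationRecord:
    """Apply the two-criterion rule to one published SNP.

    Criterion 1 (same SNP significant) is checked first.  Otherwise the
    window SNPs with p below threshold are ranked by smallest p, then
    smallest distance, then position; the best one with r² above
    threshold validates the SNP.  When none passes the r² test, the best
    sub-threshold-p window candidate is still reported as evidence with
    ``validated=False``.  If the published SNP is absent from the LD
    universe, r² is undefined and criterion 2 cannot fire (flagged).
    """
    if isinstance(ld_source, GenotypeMatrix):
        ld_source = GenotypeLd(ld_source)
    index = _scan_index(scan)
    own = index.get(published)
    own_p = own.p if own is not None else float("nan")

    if own is not None and own.p < policy.p_threshold:
        return ValidationRecord(
            qtl_code=qtl_code, published=published, set_id=set_id, trait=trait,
            published_p=own_p, candidate=published, candidate_p=own.p,
            distance_bp=0.0, r2=float("nan"), criterion=Criterion.SAME_SNP,
            validated=True,
        )

    flagged = published not in ld_source
    window = [
        r
        for r in scan
        if r.locus != published
        and r.locus.chrom == published.chrom
        and abs(r.locus.pos - published.pos) <= policy.window_bp
        and r.p < policy.p_threshold
    ]
    window.sort(key=lambda r: (r.p, abs(r.locus.pos - published.pos), r.locus.pos))

    best = None  # best fully qualifying candidate
    fallback = window[0] if window else None  # best evidence regardless of r2
    r2_of: dict[SnpLocus, float] = {}
    if not flagged:
        for r in window:
            if r.locus not in ld_source:
                r2_of[r.locus] = float("nan")
                continue
            val = ld_source.ld_r2(published, r.locus)
            r2_of[r.locus] = val.r2
            if val.defined and val.r2 > policy.r2_threshold:
                best = r
                break

    if best is not None:
        return ValidationRecord(
            qtl_code=qtl_code, published=published, set_id=set_id, trait=trait,
            published_p=own_p, candidate=best.locus, candidate_p=best.p,
            distance_bp=float(abs(best.locus.pos - published.pos)),
            r2=r2_of[best.locus], criterion=Criterion.LD_WINDOW, validated=True,
            flagged=flagged,
        )
    if fallback is not None:
        return ValidationRecord(
            qtl_code=qtl_code, published=published, set_id=set_id, trait=trait,
            published_p=own_p, candidate=fallback.locus, candidate_p=fallback.p,
            distance_bp=float(abs(fallback.locus.pos - published.pos)),
            r2=r2_of.get(fallback.locus, float("nan")),
            criterion=Criterion.NONE, validated=False, flagged=flagged,
        )
    return ValidationRecord(
        qtl_code=qtl_code, published=published, set_id=set_id, trait=trait,
        published_p=own_p, candidate=None, candidate_p=float("nan"),
        distance_bp=float("nan"), r2=float("nan"),
        criterion=Criterion.NONE, validated=False, flagged=flagged,
    )


def validate_qtl(
    qtl: PublishedQtl,
    scan: list[GwasResult],
    ld_source: LdSource | GenotypeMatrix,
    policy: ValidationPolicy = ValidationPolicy(),
    set_id: str = "",
) -> ValidationRecord:
    """Any-member rule: a QTL validates when any member SNP validates.

    The returned record is the member outcome with the strongest
    evidence: validated records first, then smallest candidate p, then
    smallest distance.
    """
    records = [
        validate_snp(
            member, scan, ld_source, policy,
            qtl_code=qtl.code, set_id=set_id, trait=qtl.trait,
        )
        for member in qtl.members
    ]

    def sort_key(rec: ValidationRecord):
        return (
            not rec.validated,
            rec.candidate_p if np.isfinite(rec.candidate_p) else np.inf,
            rec.distance_bp if np.isfinite(rec.distance_bp) else np.inf,
            rec.published.pos,
        )

    return min(records, key=sort_key)


@dataclass
class CrossSetSummary:
    """Per-QTL concordance between the inbred and hybrid validation sets."""

    per_qtl: pd.DataFrame  # columns: qtl, trait, ivs, hvs, category
    counts: pd.DataFrame  # per trait: both / ivs_only / hvs_only / neither

    CATEGORIES = ("both", "ivs_only", "hvs_only", "neither")


def cross_set_summary(
    ivs: list[ValidationRecord], hvs: list[ValidationRecord]
) -> CrossSetSummary:
    """Classify every published QTL by where it validated.

    A QTL present in only one record list is treated as not validated in
    the missing set and flagged in the log.
    """
    ivs_by = {r.qtl_code: r for r in ivs}
    hvs_by = {r.qtl_code: r for r in hvs}
    all_codes = sorted(set(ivs_by) | set(hvs_by))
    rows = []
    for code in all_codes:
        ri, rh = ivs_by.get(code), hvs_by.get(code)
        if ri is None or rh is None:
            logger.warning("QTL %s present in only one validation set", code)
        vi = bool(ri.validated) if ri is not None else False
        vh = bool(rh.validated) if rh is not None else False
        category = {
            (True, True): "both", (True, False): "ivs_only",
            (False, True): "hvs_only", (False, False): "neither",
        }[(vi, vh)]
        trait = (ri or rh).trait
        rows.append({"qtl": code, "trait": trait, "ivs": vi, "hvs": vh,
                     "category": category})
    per_qtl = pd.DataFrame(rows)
    counts = (
        per_qtl.groupby("trait")["category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(CrossSetSummary.CATEGORIES), fill_value=0)
        .reset_index()
    )
    return CrossSetSummary(per_qtl=per_qtl, counts=counts)


def render_report(
    records: list[ValidationRecord], summary: CrossSetSummary | None = None
) -> pd.DataFrame:
    """Tabular report mirroring the published layout.

    Columns: published SNP, QTL code, its own p-value in the subset scan,
    best candidate SNP with p-value, distance (thousands separators) and
    LD r² ('Same SNP' at distance 0, 'No' when undefined); plus a
    ``validated`` flag standing in for the original colour highlighting.
    """
    rows = []
    for rec in records:
        if rec.candidate is None:
            cand = p5 = dist = r2s = ""
        else:
            cand = rec.candidate.id
            p5 = f"{rec.candidate_p:.3g}"
            dist = f"{int(rec.distance_bp):,}"
            if rec.distance_bp == 0:
                r2s = "Same SNP"
            elif not np.isfinite(rec.r2):
                r2s = "No"
            else:
                r2s = f"{rec.r2:.2f}"
        rows.append(
            {
                "published_snp": rec.published.id,
                "qtl": rec.qtl_code,
                "published_p": "" if not np.isfinite(rec.published_p) else f"{rec.published_p:.3g}",
                "candidate_snp": cand,
                "candidate_p": p5,
                "distance_bp": dist,
                "ld_r2": r2s,
                "criterion": rec.criterion.value,
                "validated": rec.validated,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "published_snp", "qtl", "published_p", "candidate_snp",
            "candidate_p", "distance_bp", "ld_r2", "criterion", "validated",
        ],
    )
    if summary is not None:
        n_flagged = int(report["validated"].sum()) if len(report) else 0
        n_summary = int(summary.per_qtl[["ivs", "hvs"]].to_numpy().sum())
        logger.info("report: %d validated rows; summary counts %d set-level validations",
                    n_flagged, n_summary)
    return report
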