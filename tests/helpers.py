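"""Shared helpers for reconstructing validation inputs from the bundled
published cross-reference tables."""

import math

from magicqtl.core_io import GwasResult, parse_snp_id
from magicqtl.ld import PrecomputedLd


def row_inputs(row):
    """Build (published locus, scan, LD source) for one cross-reference row.

    The scan holds the published SNP at its own subset p-value and, when a
    window candidate is printed, that candidate at its p-value; the LD
    source knows exactly the printed pair r² (NaN for 'No').
    """
    pub = parse_snp_id(row["published_snp"])
    scan = [GwasResult(locus=pub, effect=0.0, p=float(row["published_p"]))]
    pairs = []
    if isinstance(row["candidate_snp"], str):
        cand = parse_snp_id(row["candidate_snp"])
        if cand != pub:
            scan.append(GwasResult(locus=cand, effect=0.0, p=float(row["candidate_p"])))
            pairs.append((pub, cand, row["ld_r2"]))
    return pub, scan, PrecomputedLd.from_pairs(pairs)


def strict_rule(row, policy):
    """The validation rule restated directly on the printed cells — the
    independent oracle for the decision."""
    if row["published_p"] < policy.p_threshold:
        return True
    if not isinstance(row["candidate_snp"], str):
        return False
    return (
        row["candidate_p"] < policy.p_threshold
        and row["distance_bp"] <= policy.window_bp
        and not math.isnan(row["ld_r2"])
        and row["ld_r2"] > policy.r2_threshold
    )
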