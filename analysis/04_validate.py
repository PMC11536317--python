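"""Apply the two-criterion validation rule to the planted QTLs.

For each trait and each validation set, every planted QTL is checked
against that set's GWAS: validated if the same SNP is significant at
p < 0.02, or if a significant SNP within +/-2 Mbp is in LD (r2 > 0.2)
with it.  Writes per-set validation reports and the cross-set
concordance summary (validated in both sets / one / neither).

Run:  python analysis/04_validate.py
"""

import argparse
from pathlib import Path

import pandas as pd

from magicqtl.core_io import read_gwas_results, read_hapmap, read_published_qtls
from magicqtl.validation import (
    ValidationPolicy,
    cross_set_summary,
    render_report,
    validate_qtl,
)

TRAITS = ("tunnel_length", "grain_yield")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--p", type=float, default=0.02)
    ap.add_argument("--window", type=int, default=2_000_000)
    ap.add_argument("--r2", type=float, default=0.2)
    args = ap.parse_args()
    out = args.out_dir
    policy = ValidationPolicy(p_threshold=args.p, window_bp=args.window,
                              r2_threshold=args.r2)

    qtl_table = pd.read_csv(out / "planted_qtls.tsv", sep="\t")
    records = {s: [] for s in ("ivs", "hvs")}
    for set_id in ("ivs", "hvs"):
        gm = read_hapmap(out / f"geno_{set_id}.hmp.txt")
        for trait in TRAITS:
            sub = qtl_table[qtl_table["trait"] == trait]
            tmp = out / f"_qtls_{trait}.tsv"
            sub[["snp", "qtl"]].to_csv(tmp, sep="\t", index=False)
            qtls = read_published_qtls(tmp, trait=trait)
            tmp.unlink()
            scan = read_gwas_results(out / f"gwas_{set_id}_{trait}.tsv")
            for qtl in qtls:
                rec = validate_qtl(qtl, scan, gm, policy, set_id=set_id)
                records[set_id].append(rec)
        report = render_report(records[set_id])
        report.to_csv(out / f"validation_{set_id}.tsv", sep="\t", index=False)
        n_val = int(report["validated"].sum())
        print(f"{set_id}: {n_val}/{len(report)} planted QTLs validated")

    summary = cross_set_summary(records["ivs"], records["hvs"])
    summary.per_qtl.to_csv(out / "cross_set_per_qtl.tsv", sep="\t", index=False)
    summary.counts.to_csv(out / "cross_set_counts.tsv", sep="\t", index=False)
    print(summary.counts.to_string(index=False))


if __name__ == "__main__":
    main()
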