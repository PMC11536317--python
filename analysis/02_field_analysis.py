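"""Field-trial analysis of the validation sets: BLUEs, variance
components and family-mean heritability.

Reads the phenotype tables written by 01_simulate_study.py, estimates
genotype BLUEs across environments for every set x trait, decomposes the
phenotypic variance into Vg, Vgxe and Vres by REML, and derives
heritability on a family-mean basis with e = environments phenotyped for
the trait and r = replicates.  Writes blues_{set}_{trait}.tsv and a
variance_components.tsv summary.

Run:  python analysis/02_field_analysis.py
"""

import argparse
from pathlib import Path

import pandas as pd

from magicqtl.core_io import PhenotypeTable
from magicqtl.field_analysis import (
    estimate_blues,
    estimate_variance_components,
    heritability_family_mean,
)

TRAITS = ("tunnel_length", "grain_yield")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out_dir

    rows = []
    for set_id in ("ivs", "hvs"):
        pheno = PhenotypeTable.read(out / f"pheno_{set_id}.tsv")
        for trait in TRAITS:
            blues = estimate_blues(pheno, trait, set_id=set_id)
            blues.write(out / f"blues_{set_id}_{trait}.tsv")
            vc, fit = estimate_variance_components(pheno, trait)
            e = len(pheno.environments(trait))
            r = int(pheno.trait(trait)["rep"].max())
            h = heritability_family_mean(vc, e=e, r=r)
            rows.append({
                "set": set_id, "trait": trait,
                "vg": round(vc.vg, 1), "vg_se": round(vc.vg_se, 1),
                "vgxe": round(vc.vgxe, 1), "vgxe_se": round(vc.vgxe_se, 1),
                "vres": round(vc.vres, 1), "vres_se": round(vc.vres_se, 1),
                "vp": round(vc.vp, 1), "e": e, "r": r,
                "h2": round(h.h2, 2), "h2_se": round(h.se, 2),
                "vg_significant": vc.significant("vg"),
            })
            print(f"{set_id} {trait}: Vg={vc.vg:.0f}±{vc.vg_se:.0f} "
                  f"Vgxe={vc.vgxe:.0f}±{vc.vgxe_se:.0f} "
                  f"Vres={vc.vres:.0f}±{vc.vres_se:.0f}  h2={h.h2:.2f}±{h.se:.2f}"
                  f"  (e={e}, r={r})")
    pd.DataFrame(rows).to_csv(out / "variance_components.tsv", sep="\t", index=False)
    print(f"wrote {out / 'variance_components.tsv'}")


if __name__ == "__main__":
    main()
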