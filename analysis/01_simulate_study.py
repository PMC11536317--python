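"""Simulate the study populations: whole MAGIC, extreme subset, testcrosses.

Steps, mirroring the modelled experiment at reduced marker density:

1. simulate an 8-founder MAGIC population of RILs with planted QTLs for
   the two traits (stem-tunnel length, grain yield);
2. phenotype the whole population in two unreplicated trial years and
   compute BLUEs;
3. select the extreme-tail subset on both traits (the inbred validation
   set, IVS) and cross it to an unrelated homozygous tester (the hybrid
   validation set, HVS);
4. phenotype IVS and HVS in replicated lattice-style trials calibrated
   to the corresponding variance-component presets (tunnel length is
   only recorded in infested/natural-infestation environments).

Writes genotypes (HapMap), phenotypes (TSV), BLUEs, the planted-QTL list
and the selected id lists under --out-dir.

Run:  python analysis/01_simulate_study.py --seed 1
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from magicqtl.core_io import PhenotypeTable, write_hapmap
from magicqtl.field_analysis import estimate_blues
from magicqtl.simulate import (
    FieldDesign,
    QtlEffect,
    SimulationConfig,
    TraitSpec,
    make_testcross,
    make_tester,
    simulate_founders,
    simulate_magic_rils,
    simulate_phenotypes,
)

TRAITS = ("tunnel_length", "grain_yield")

# planted QTLs: (locus index, additive effect, dominance effect)
PLANTED = {
    "tunnel_length": [(35, -5.0, 0.0), (155, 4.0, 0.0), (310, -4.5, 1.0)],
    "grain_yield": [(80, 8.0, 2.0), (250, -7.0, 0.0), (455, 7.0, 3.0)],
}


def _phenotype_set(gm, set_id, envs, infested, reps, rho, rng, qtls):
    """Simulate both traits on one design; tunnel length is dropped in
    protected environments (no borer pressure there)."""
    traits = [TraitSpec.from_preset(set_id, t, qtls=qtls[t]) for t in TRAITS]
    design = FieldDesign(environments=envs, replicates=reps, block_size=8)
    pheno, gvals = simulate_phenotypes(
        gm, traits, design, rng, genetic_correlation=rho, set_id=set_id
    )
    df = pheno.data
    keep = (df["trait"] != "tunnel_length") | df["env"].isin(infested)
    return PhenotypeTable(df[keep].reset_index(drop=True)), gvals


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--n-rils", type=int, default=360,
                    help="whole-population size (scaled down from 608)")
    ap.add_argument("--n-ivs", type=int, default=56)
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    cfg = SimulationConfig(n_rils=args.n_rils, n_chrom=10, loci_per_chrom=60,
                           genetic_correlation=-0.2)
    gmap = cfg.make_map()
    founders = simulate_founders(cfg, gmap, rng)
    pop = simulate_magic_rils(founders, cfg, rng)
    gm = pop.genotypes
    print(f"simulated {gm.n_individuals} RILs x {gm.n_loci} SNPs; "
          f"het fraction {gm.het_fraction():.4f}")

    # the same planted QTLs drive every evaluation set
    qtl_rows = []
    whole_traits = []
    planted = {t: [QtlEffect(gm.loci[j], a, d) for j, a, d in PLANTED[t]]
               for t in TRAITS}
    for t in TRAITS:
        whole_traits.append(TraitSpec.from_preset("whole_magic", t,
                                                  qtls=planted[t]))
        for k, q in enumerate(planted[t], start=1):
            qtl_rows.append({"snp": q.locus.id,
                             "qtl": f"QTL_{q.locus.chrom}_{k}", "trait": t})
    pd.DataFrame(qtl_rows).to_csv(out / "planted_qtls.tsv", sep="\t", index=False)

    # whole-MAGIC evaluation: two unreplicated trial years
    design = FieldDesign(environments=["2014.inf", "2015.inf"], replicates=1,
                         block_size=8)
    pheno_whole, _ = simulate_phenotypes(
        gm, whole_traits, design, rng, genetic_correlation=cfg.genetic_correlation,
        set_id="whole_magic",
    )
    pheno_whole.write(out / "pheno_whole_magic.tsv")

    blues = {}
    for t in TRAITS:
        blues[t] = estimate_blues(pheno_whole, t, set_id="whole_magic")
        blues[t].write(out / f"blues_whole_magic_{t}.tsv")

    from magicqtl.validation import select_tails

    ivs_ids = select_tails(blues, args.n_ivs)
    (out / "ivs_ids.txt").write_text("\n".join(ivs_ids) + "\n")
    for t in TRAITS:
        pool = blues[t].table.set_index("genotype")["blue"]
        sel = pool.loc[ivs_ids]
        print(f"{t}: pool var {pool.var():.1f} -> subset var {sel.var():.1f}")

    ivs = gm.subset_individuals(ivs_ids)
    write_hapmap(gm, out / "geno_whole_magic.hmp.txt")
    write_hapmap(ivs, out / "geno_ivs.hmp.txt")

    tester = make_tester(gmap, rng)
    hvs = make_testcross(ivs, tester, rng)
    write_hapmap(hvs, out / "geno_hvs.hmp.txt")
    print(f"testcrossed {hvs.n_individuals} hybrids to one tester")

    # replicated lattice evaluations of the validation sets
    ivs_pheno, _ = _phenotype_set(
        ivs, "ivs",
        envs=["2017.inf", "2018.inf", "2017.ctrl", "2018.ctrl"],
        infested=["2017.inf", "2018.inf"], reps=2,
        rho=cfg.genetic_correlation, rng=rng, qtls=planted,
    )
    ivs_pheno.write(out / "pheno_ivs.tsv")
    hvs_pheno, _ = _phenotype_set(
        hvs, "hvs",
        envs=["P2017.inf", "P2018.inf", "Bar2017.nat", "PC2017.nat",
              "P2017.ctrl", "P2018.ctrl"],
        infested=["P2017.inf", "P2018.inf", "Bar2017.nat", "PC2017.nat"],
        reps=2, rho=cfg.genetic_correlation, rng=rng, qtls=planted,
    )
    hvs_pheno.write(out / "pheno_hvs.tsv")
    print(f"wrote study files under {out}")


if __name__ == "__main__":
    main()
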