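"""BLUEs, REML variance components and family-mean heritability."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from magicqtl.core_io import PhenotypeTable
from magicqtl.field_analysis import (
    VarianceComponents,
    estimate_blues,
    estimate_variance_components,
    heritability_family_mean,
)
from magicqtl.reml import reml_fit
from magicqtl.simulate import FieldDesign, TraitSpec, simulate_phenotypes


def _pheno_frame(values):
    """values: dict (genotype, env, rep) -> value, single block per rep."""
    rows = [
        {"genotype": g, "env": e, "rep": r, "block": f"{e}:{r}:b1",
         "trait": "t", "value": v}
        for (g, e, r), v in values.items()
    ]
    return PhenotypeTable(pd.DataFrame(rows))


class TestBlues:
    def test_single_env_single_rep_equals_raw_means(self):
        tab = _pheno_frame({("g1", "e1", 1): 4.0, ("g2", "e1", 1): 8.0,
                            ("g3", "e1", 1): 6.0})
        blues = estimate_blues(tab, "t")
        assert blues.table.set_index("genotype")["blue"].to_dict() == {
            "g1": 4.0, "g2": 8.0, "g3": 6.0
        }

    def test_balanced_zero_residual_equals_genotype_mean(self):
        # identical value in both environments -> BLUE is that value
        vals = {}
        for g, base in (("g1", 3.0), ("g2", 9.0)):
            for e in ("e1", "e2"):
                vals[(g, e, 1)] = base
        blues = estimate_blues(_pheno_frame(vals), "t")
        got = blues.table.set_index("genotype")["blue"]
        assert got["g1"] == pytest.approx(3.0, abs=1e-6)
        assert got["g2"] == pytest.approx(9.0, abs=1e-6)

    def test_rank_correlation_with_true_effects(self, small_pop, lattice_design,
                                                ivs_tunnel_trait):
        # at the h2=0.74 preset the attainable correlation between adjusted
        # means and true genotypic values is bounded by sqrt(h2) ~ 0.86;
        # the estimator should get close to that bound on average
        pop, _, _ = small_pop
        gm = pop.genotypes.subset_individuals(pop.genotypes.individuals[:64])
        rhos = []
        for seed in range(8):
            rng = np.random.default_rng(77 + seed)
            pheno, gvals = simulate_phenotypes(
                gm, [ivs_tunnel_trait], lattice_design, rng
            )
            blues = estimate_blues(pheno, "tunnel_length")
            merged = blues.table.set_index("genotype")["blue"].loc[gvals.index]
            rhos.append(scipy.stats.spearmanr(merged, gvals["tunnel_length"]).statistic)
        assert np.mean(rhos) > 0.75

    def test_genotype_missing_one_environment_has_larger_se(self):
        rng = np.random.default_rng(0)
        vals = {}
        for gi in range(8):
            for e in ("e1", "e2"):
                for r in (1, 2):
                    vals[(f"g{gi}", e, r)] = 10 + gi + rng.normal(0, 1)
        del vals[("g0", "e2", 1)], vals[("g0", "e2", 2)]
        blues = estimate_blues(_pheno_frame(vals), "t")
        tab = blues.table.set_index("genotype")
        assert np.isfinite(tab.loc["g0", "blue"])
        assert tab.loc["g0", "se"] > tab.loc["g1", "se"]

    def test_genotype_without_data_reported_missing(self):
        tab = _pheno_frame({("g1", "e1", 1): 4.0, ("g2", "e1", 1): 8.0})
        df = tab.data.copy()
        df = pd.concat([df, pd.DataFrame([{"genotype": "g3", "env": "e1", "rep": 1,
                                           "block": "e1:1:b1", "trait": "t",
                                           "value": np.nan}])], ignore_index=True)
        blues = estimate_blues(PhenotypeTable(df), "t")
        assert blues.missing == ["g3"]


class TestVarianceComponents:
    def test_zero_genetic_variance_estimated_nonnegative(self):
        rng = np.random.default_rng(4)
        vals = {}
        for gi in range(20):
            for e in ("e1", "e2"):
                for r in (1, 2):
                    vals[(f"g{gi:02d}", e, r)] = rng.normal(0, 1)
        vc, _ = estimate_variance_components(_pheno_frame(vals), "t")
        assert 0.0 <= vc.vg < 0.5

    def test_single_environment_rejected(self):
        tab = _pheno_frame({("g1", "e1", 1): 1.0, ("g2", "e1", 1): 2.0})
        with pytest.raises(ValueError, match="environments"):
            estimate_variance_components(tab, "t")

    def test_components_recovered_at_ivs_preset(self, small_pop, lattice_design,
                                                ivs_tunnel_trait):
        # one-seed sanity check; the multi-seed recovery experiment lives in
        # the acceptance suite
        pop, _, _ = small_pop
        gm = pop.genotypes.subset_individuals(pop.genotypes.individuals[:64])
        rng = np.random.default_rng(123)
        pheno, _ = simulate_phenotypes(gm, [ivs_tunnel_trait], lattice_design, rng)
        vc, fit = estimate_variance_components(pheno, "tunnel_length")
        for est, truth, se in [
            (vc.vg, 107, vc.vg_se), (vc.vgxe, 38, vc.vgxe_se), (vc.vres, 75, vc.vres_se),
        ]:
            assert abs(est - truth) < 3 * max(se, 1.0)

    def test_significance_flag_is_two_se_rule(self):
        vc = VarianceComponents(10, 5, 2, vg_se=4, vgxe_se=3, vres_se=1.1)
        assert vc.significant("vg")
        assert not vc.significant("vgxe")  # 5 < 2 * 3
        assert not vc.significant("vres")  # 2 < 2 * 1.1

    def test_reml_matches_lme4_on_tiny_fixture(self, tmp_path):
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript expected on PATH"
        rng = np.random.default_rng(8)
        genos = [f"g{i}" for i in range(12)]
        envs = ["e1", "e2", "e3"]
        g_eff = dict(zip(genos, rng.normal(0, 2, len(genos))))
        e_eff = dict(zip(envs, rng.normal(0, 1, len(envs))))
        rows = []
        for g in genos:
            for e in envs:
                for r in (1, 2):
                    rows.append({"g": g, "env": e,
                                 "y": 5 + g_eff[g] + e_eff[e] + rng.normal(0, 1)})
        df = pd.DataFrame(rows)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)

        from magicqtl.reml import indicator_matrix

        Zg, _ = indicator_matrix(df["g"].to_numpy())
        Ze, _ = indicator_matrix(df["env"].to_numpy())
        fit = reml_fit(df["y"].to_numpy(), np.ones((len(df), 1)), [Zg, Ze],
                       names=["g", "env"])

        script = (
            f"d <- read.csv('{csv}');"
            "suppressMessages(library(lme4));"
            "f <- lmer(y ~ 1 + (1|g) + (1|env), data=d, REML=TRUE);"
            "v <- as.data.frame(VarCorr(f));"
            "cat(v$vcov[v$grp=='g'], v$vcov[v$grp=='env'],"
            " v$vcov[v$grp=='Residual'], sep='\\n')"
        )
        out = subprocess.run([rscript, "-e", script], capture_output=True, text=True,
                             check=True)
        vg_r, venv_r, vres_r = (float(x) for x in out.stdout.split())
        assert fit.component("g") == pytest.approx(vg_r, rel=1e-3, abs=1e-5)
        assert fit.component("env") == pytest.approx(venv_r, rel=1e-3, abs=1e-4)
        assert fit.component("residual") == pytest.approx(vres_r, rel=1e-3, abs=1e-5)


class TestHeritability:
    @pytest.mark.parametrize(
        "vg, vgxe, vres, e, r, expected",
        [(107, 38, 75, 2, 2, 0.74), (21, 17, 119, 4, 2, 0.52)],
    )
    def test_published_component_sets(self, vg, vgxe, vres, e, r, expected):
        vc = VarianceComponents(vg, vgxe, vres, 0, 0, 0)
        h = heritability_family_mean(vc, e=e, r=r)
        assert round(h.h2, 2) == expected

    def test_no_noise_gives_unity(self):
        vc = VarianceComponents(10, 0, 0, 0, 0, 0)
        assert heritability_family_mean(vc, 2, 2).h2 == pytest.approx(1.0)

    def test_all_zero_components_undefined(self):
        vc = VarianceComponents(0, 0, 0, 0, 0, 0)
        h = heritability_family_mean(vc, 2, 2)
        assert not h.defined

    def test_monotone_in_environments_and_replicates(self):
        vc = VarianceComponents(50, 30, 80, 0, 0, 0)
        h = [[heritability_family_mean(vc, e, r).h2 for r in (1, 2, 4, 8)]
             for e in (1, 2, 4, 8)]
        arr = np.array(h)
        assert np.all(np.diff(arr, axis=0) >= 0)  # more environments
        assert np.all(np.diff(arr, axis=1) >= 0)  # more replicates
        assert np.all((arr >= 0) & (arr <= 1))

    def test_delta_method_se_uses_component_ses(self):
        vc = VarianceComponents(107, 38, 75, 30, 17, 12)
        h = heritability_family_mean(vc, 2, 2)
        assert 0.0 < h.se < 0.3
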