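"""Tail selection, the two-criterion validation rule, and reporting."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magicqtl import datasets
from magicqtl.core_io import GwasResult, PublishedQtl, SnpLocus, parse_snp_id
from magicqtl.field_analysis import AdjustedMeans
from magicqtl.ld import PrecomputedLd
from magicqtl.validation import (
    Criterion,
    ValidationPolicy,
    ValidationRecord,
    cross_set_summary,
    render_report,
    select_tails,
    validate_qtl,
    validate_snp,
)

from helpers import row_inputs, strict_rule

POLICY = ValidationPolicy()


def _blues(values: dict[str, float], trait="t", set_id="s") -> AdjustedMeans:
    tab = pd.DataFrame(
        {"genotype": list(values), "blue": list(values.values()), "se": 1.0}
    )
    return AdjustedMeans(trait=trait, set_id=set_id, table=tab, missing=[])


class TestSelectTails:
    def test_whole_pool_when_target_is_pool_size(self):
        b = {"t1": _blues({"a": 1, "b": 2, "c": 3}), "t2": _blues({"a": 3, "b": 1, "c": 2})}
        assert select_tails(b, 3) == ["a", "b", "c"]

    def test_constant_trait_defers_to_other_trait(self):
        vals2 = {f"g{i}": float(i) for i in range(10)}
        b = {"t1": _blues({g: 5.0 for g in vals2}), "t2": _blues(vals2)}
        sel = select_tails(b, 4)
        # extremes of t2 dominate the selection
        assert "g0" in sel and "g9" in sel and "g1" in sel and "g8" in sel

    def test_selection_increases_trait_variance(self):
        rng = np.random.default_rng(6)
        n = 400
        v1 = {f"g{i:03d}": float(x) for i, x in enumerate(rng.normal(35, 5, n))}
        v2 = {f"g{i:03d}": float(x) for i, x in enumerate(rng.normal(42, 9, n))}
        b = {"t1": _blues(v1), "t2": _blues(v2)}
        sel = set(select_tails(b, 56))
        for vals in (v1, v2):
            pool_var = np.var(list(vals.values()))
            sel_var = np.var([vals[g] for g in sel])
            assert sel_var > pool_var

    def test_target_larger_than_pool_rejected(self):
        b = {"t1": _blues({"a": 1.0, "b": 2.0})}
        with pytest.raises(ValueError):
            select_tails(b, 3)

    def test_deterministic_under_ties(self):
        vals = {f"g{i}": float(i % 3) for i in range(9)}
        b = {"t1": _blues(vals)}
        assert select_tails(b, 4) == select_tails(b, 4)


def _scan(entries):
    return [GwasResult(locus=parse_snp_id(s), effect=0.0, p=p) for s, p in entries]


class TestValidateSnp:
    def test_same_snp_criterion(self):
        # published SNP itself significant in the subset scan
        pub = parse_snp_id("S2_14798875")
        scan = _scan([("S2_14798875", 0.009)])
        rec = validate_snp(pub, scan, PrecomputedLd.from_pairs([]), POLICY)
        assert rec.validated and rec.criterion == Criterion.SAME_SNP
        assert rec.distance_bp == 0

    def test_window_candidate_with_sufficient_ld_validates(self):
        pub = parse_snp_id("S1_19252698")
        cand = parse_snp_id("S1_18200092")
        scan = _scan([("S1_19252698", 0.25), ("S1_18200092", 0.002)])
        ld = PrecomputedLd.from_pairs([(pub, cand, 0.22)])
        rec = validate_snp(pub, scan, ld, POLICY)
        assert rec.validated and rec.criterion == Criterion.LD_WINDOW
        assert rec.candidate == cand and rec.distance_bp == 1_052_606

    def test_low_ld_candidate_does_not_validate(self):
        pub = parse_snp_id("S1_290934634")
        cand = parse_snp_id("S1_290306138")
        scan = _scan([("S1_290934634", 0.60), ("S1_290306138", 0.004)])
        ld = PrecomputedLd.from_pairs([(pub, cand, 0.01)])
        rec = validate_snp(pub, scan, ld, POLICY)
        assert not rec.validated and rec.candidate == cand

    def test_candidate_beyond_window_ignored(self):
        pub = parse_snp_id("S1_199075640")
        scan = _scan([("S1_199075640", 0.95), ("S1_196201034", 0.013)])
        ld = PrecomputedLd.from_pairs(
            [(pub, parse_snp_id("S1_196201034"), 0.07)]
        )
        rec = validate_snp(pub, scan, ld, POLICY)  # distance 2,874,606 > 2 Mbp
        assert not rec.validated and rec.candidate is None

    def test_published_snp_own_p_recorded_regardless_of_outcome(self):
        pub = parse_snp_id("S3_212770896")
        scan = _scan([("S3_212770896", 0.74), ("S3_212771115", 0.004)])
        ld = PrecomputedLd.from_pairs([(pub, parse_snp_id("S3_212771115"), 0.15)])
        rec = validate_snp(pub, scan, ld, POLICY)
        assert rec.published_p == pytest.approx(0.74)
        assert not rec.validated

    def test_undefined_ld_fails_criterion_two(self):
        pub = parse_snp_id("S9_11746822")
        cand = parse_snp_id("S9_11564902")
        scan = _scan([("S9_11746822", 0.52), ("S9_11564902", 0.005)])
        ld = PrecomputedLd.from_pairs([(pub, cand, math.nan)])
        rec = validate_snp(pub, scan, ld, POLICY)
        assert not rec.validated

    def test_candidate_tie_break_smallest_p_then_distance(self):
        pub = SnpLocus(1, 1_000_000)
        c_near = SnpLocus(1, 1_100_000)
        c_far = SnpLocus(1, 1_900_000)
        scan = [
            GwasResult(locus=pub, effect=0, p=0.5),
            GwasResult(locus=c_far, effect=0, p=0.001),
            GwasResult(locus=c_near, effect=0, p=0.001),
        ]
        ld = PrecomputedLd.from_pairs([(pub, c_near, 0.9), (pub, c_far, 0.9)])
        rec = validate_snp(pub, scan, ld, POLICY)
        assert rec.candidate == c_near  # equal p, closer wins

    @pytest.mark.parametrize("trait", ["tunnel_length", "grain_yield"])
    @pytest.mark.parametrize("set_id", ["ivs", "hvs"])
    def test_reproduces_strict_rule_on_published_tables(self, trait, set_id):
        df = datasets.load_published_crossref(trait, set_id)
        for _, row in df.iterrows():
            pub, scan, ld = row_inputs(row)
            rec = validate_snp(pub, scan, ld, POLICY, set_id=set_id, trait=trait)
            assert rec.validated == strict_rule(row, POLICY), row["published_snp"]


class TestValidateQtl:
    def _qtl(self, members, code="QTL_1_1"):
        return PublishedQtl(
            code=code, trait="t", members=tuple(parse_snp_id(m) for m in members)
        )

    def test_any_member_validates_qtl(self):
        qtl = self._qtl(["S1_100", "S1_200", "S1_300"])
        scan = _scan([("S1_100", 0.8), ("S1_200", 0.01), ("S1_300", 0.9)])
        rec = validate_qtl(qtl, scan, PrecomputedLd.from_pairs([]), POLICY)
        assert rec.validated and rec.published == parse_snp_id("S1_200")

    def test_no_member_validates(self):
        qtl = self._qtl(["S1_100", "S1_200"])
        scan = _scan([("S1_100", 0.8), ("S1_200", 0.9)])
        rec = validate_qtl(qtl, scan, PrecomputedLd.from_pairs([]), POLICY)
        assert not rec.validated

    def test_shared_candidate_consolidates_to_strongest_member(self):
        members = ["S1_1000000", "S1_1000050", "S1_1000100"]
        cand = "S1_1500000"
        qtl = self._qtl(members)
        scan = _scan([(m, 0.95) for m in members] + [(cand, 0.013)])
        c = parse_snp_id(cand)
        ld = PrecomputedLd.from_pairs(
            [(parse_snp_id(m), c, 0.4) for m in members]
        )
        rec = validate_qtl(qtl, scan, ld, POLICY)
        assert rec.validated and rec.candidate == c
        # reported member is the closest one (smallest distance at equal p)
        assert rec.published == parse_snp_id("S1_1000100")


class TestMonotonicity:
    @settings(derandomize=True, max_examples=120)
    @given(
        p_cand=st.floats(1e-6, 0.5),
        dist=st.integers(1, 6_000_000),
        r2=st.floats(0, 0.99),
        wider=st.floats(1.0, 4.0),
        p_up=st.floats(1.0, 4.0),
        r2_down=st.floats(0.2, 1.0),
    )
    def test_relaxing_policy_never_invalidates(self, p_cand, dist, r2, wider, p_up, r2_down):
        pub = SnpLocus(1, 10_000_000)
        cand = SnpLocus(1, 10_000_000 + dist)
        scan = [
            GwasResult(locus=pub, effect=0, p=0.5),
            GwasResult(locus=cand, effect=0, p=p_cand),
        ]
        ld = PrecomputedLd.from_pairs([(pub, cand, r2)])
        strict = validate_snp(pub, scan, ld, POLICY)
        relaxed_policy = ValidationPolicy(
            p_threshold=min(POLICY.p_threshold * p_up, 0.99),
            window_bp=int(POLICY.window_bp * wider),
            r2_threshold=POLICY.r2_threshold * (1 / r2_down) ** -1,
        )
        relaxed = validate_snp(pub, scan, ld, relaxed_policy)
        if strict.validated:
            assert relaxed.validated


class TestSummaryAndReport:
    def _rec(self, code, validated, set_id, trait="t"):
        return ValidationRecord(
            qtl_code=code, published=SnpLocus(1, 100), set_id=set_id, trait=trait,
            published_p=0.5, candidate=SnpLocus(1, 200) if validated else None,
            candidate_p=0.01 if validated else math.nan,
            distance_bp=100.0 if validated else math.nan,
            r2=0.5 if validated else math.nan,
            criterion=Criterion.LD_WINDOW if validated else Criterion.NONE,
            validated=validated,
        )

    def test_categories(self):
        ivs = [self._rec("QTL_1_1", True, "ivs"), self._rec("QTL_1_2", True, "ivs"),
               self._rec("QTL_1_3", False, "ivs"), self._rec("QTL_1_4", False, "ivs")]
        hvs = [self._rec("QTL_1_1", True, "hvs"), self._rec("QTL_1_2", False, "hvs"),
               self._rec("QTL_1_3", True, "hvs"), self._rec("QTL_1_4", False, "hvs")]
        summary = cross_set_summary(ivs, hvs)
        cat = summary.per_qtl.set_index("qtl")["category"]
        assert cat["QTL_1_1"] == "both"
        assert cat["QTL_1_2"] == "ivs_only"
        assert cat["QTL_1_3"] == "hvs_only"
        assert cat["QTL_1_4"] == "neither"
        counts = summary.counts.set_index("trait").loc["t"]
        assert counts.sum() == 4 and counts["both"] == 1

    def test_qtl_in_one_set_only_flagged_not_validated_elsewhere(self, caplog):
        ivs = [self._rec("QTL_1_1", True, "ivs")]
        summary = cross_set_summary(ivs, [])
        assert summary.per_qtl.iloc[0]["category"] == "ivs_only"

    def test_report_formatting(self):
        recs = [self._rec("QTL_1_1", True, "ivs"),
                self._rec("QTL_1_2", False, "ivs")]
        recs[0].distance_bp = 1_052_606.0
        report = render_report(recs)
        assert report.loc[0, "distance_bp"] == "1,052,606"
        assert report.loc[0, "validated"] and not report.loc[1, "validated"]

    def test_empty_record_list_gives_header_only(self):
        report = render_report([])
        assert len(report) == 0 and "published_snp" in report.columns

    def test_same_snp_and_undefined_ld_rendering(self):
        rec = self._rec("QTL_1_1", True, "ivs")
        rec.distance_bp = 0.0
        rec.criterion = Criterion.SAME_SNP
        rec2 = self._rec("QTL_1_2", True, "ivs")
        rec2.r2 = math.nan
        report = render_report([rec, rec2])
        assert report.loc[0, "ld_r2"] == "Same SNP"
        assert report.loc[1, "ld_r2"] == "No"
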