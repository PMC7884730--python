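"""Variant filter, TMB, CIN, MATH, Lynch rule and PPA/NPA concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from hervscape import genomics


def _record(**overrides):
    base = {"sample_id": "S001", "chrom": "1", "pos": 1000, "ref": "A",
            "alt": "T", "vaf_tumor": 0.20, "vaf_normal": 0.01,
            "dp_tumor": 100, "dp_normal": 40, "ad_tumor": 20,
            "both_strands": True, "gene": "", "aa_change": "",
            "pathogenic": False}
    base.update(overrides)
    return base


@pytest.fixture()
def eight_record_table():
    """Two clean records plus one record violating each of the six rules."""
    rows = [
        _record(pos=1),                         # clean
        _record(pos=2),                         # clean
        _record(pos=3, vaf_tumor=0.04, vaf_normal=0.005, ad_tumor=5),
        _record(pos=4, dp_tumor=49),
        _record(pos=5, dp_normal=19),
        _record(pos=6, ad_tumor=4),
        _record(pos=7, vaf_tumor=0.25, vaf_normal=0.05),  # ratio 0.2
        _record(pos=8, both_strands=False),
    ]
    return pd.DataFrame(rows)


class TestFilterSomatic:
    def test_clean_record_retained(self):
        retained, rejections = genomics.filter_somatic(
            pd.DataFrame([_record()]))
        assert len(retained) == 1
        assert all(v == 0 for v in rejections.values())

    def test_eight_record_fixture(self, eight_record_table):
        retained, rejections = genomics.filter_somatic(eight_record_table)
        assert len(retained) == 2
        assert sorted(retained["pos"]) == [1, 2]
        assert rejections == {r: 1 for r in genomics.FILTER_RULES}

    @pytest.mark.parametrize("overrides,rule", [
        ({"vaf_tumor": 0.25, "vaf_normal": 0.05},
         "vaf_ratio"),                         # ratio exactly 0.2: strict <
        ({"dp_tumor": 49}, "dp_tumor"),
        ({"vaf_tumor": 0.0, "vaf_normal": 0.0, "ad_tumor": 5},
         "vaf_tumor"),                         # VAF 0 fails the VAF rule
    ])
    def test_boundaries(self, overrides, rule):
        retained, rejections = genomics.filter_somatic(
            pd.DataFrame([_record(**overrides)]))
        assert len(retained) == 0
        assert rejections[rule] == 1

    def test_idempotent(self, eight_record_table):
        once, _ = genomics.filter_somatic(eight_record_table)
        twice, rejections = genomics.filter_somatic(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in rejections.values())

    def test_malformed_vaf_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            genomics.filter_somatic(pd.DataFrame([_record(vaf_tumor=1.5)]))


class TestTmb:
    def test_values(self):
        assert genomics.compute_tmb(300, 30.0) == pytest.approx(10.0)
        assert genomics.compute_tmb(0, 30.0) == 0.0

    def test_chained_with_filter(self, eight_record_table):
        retained, _ = genomics.filter_somatic(eight_record_table)
        assert genomics.compute_tmb(len(retained), 1.0) == 2.0

    def test_zero_mb_error(self):
        with pytest.raises(ValueError):
            genomics.compute_tmb(5, 0.0)


class TestArmEvents:
    def test_strictly_exceeds_rule(self):
        deleted = genomics.arm_events(
            genomics.ArmCNProfile("17p", 100, 21, 0))
        assert deleted == {"deleted": True, "amplified": False}
        boundary = genomics.arm_events(
            genomics.ArmCNProfile("17p", 100, 20, 0))
        assert boundary == {"deleted": False, "amplified": False}
        both = genomics.arm_events(
            genomics.ArmCNProfile("8q", 100, 21, 30))
        assert both == {"deleted": True, "amplified": True}

    def test_no_genes_error(self):
        with pytest.raises(ValueError):
            genomics.arm_events(genomics.ArmCNProfile("1p", 0, 0, 0))

    def test_invariant_to_gene_order_and_splitting(self):
        rng = np.random.default_rng(0)
        calls = pd.Series(rng.choice(["del", "neutral", "amp"], 60,
                                     p=[0.3, 0.5, 0.2]),
                          index=[f"g{i}" for i in range(60)])
        arms = pd.Series(["1p"] * 30 + ["1q"] * 30, index=calls.index)
        base = genomics.count_arm_events(calls, arms)
        perm = rng.permutation(calls.index)
        assert genomics.count_arm_events(calls[perm], arms[perm]) == base
        # split into halves per arm and re-aggregate tallies
        profiles = genomics.arm_profiles_from_calls(calls, arms)
        for p in profiles:
            half = calls[arms[arms == p.arm_id].index[:15]]
            rest = calls[arms[arms == p.arm_id].index[15:]]
            merged = genomics.ArmCNProfile(
                p.arm_id, 30,
                int((half == "del").sum()) + int((rest == "del").sum()),
                int((half == "amp").sum()) + int((rest == "amp").sum()))
            assert genomics.arm_events(merged) == genomics.arm_events(p)


class TestCinBurden:
    def test_zero_events_stable(self):
        counts = pd.Series([0, 0, 3, 3, 8, 8])
        assert genomics.cin_burden(counts).iloc[0] == "stable"

    def test_tertiles_match_sort_oracle(self):
        counts = pd.Series([0] * 10 + [10] * 10 + [20] * 10)
        cats = genomics.cin_burden(counts)
        q1, q2 = np.quantile(counts, [1 / 3, 2 / 3])
        expected = ["stable" if c <= q1 else "medium" if c <= q2
                    else "high" for c in counts]
        assert cats.tolist() == expected

    def test_category_monotone_in_count(self):
        counts = pd.Series(range(12))
        cats = genomics.cin_burden(counts)
        order = {"stable": 0, "medium": 1, "high": 2}
        ranks = cats.map(order)
        assert (ranks.diff().dropna() >= 0).all()


class TestMathScore:
    def test_zero_dispersion(self):
        assert genomics.math_score([0.25, 0.25, 0.25]) == 0.0

    def test_hand_worked_value(self):
        assert genomics.math_score([0.2, 0.25, 0.3]) == \
            pytest.approx(29.652)

    def test_scale_invariance(self):
        vafs = np.array([0.1, 0.2, 0.3, 0.4])
        assert genomics.math_score(vafs * 2) == \
            pytest.approx(genomics.math_score(vafs))

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 3"):
            genomics.math_score([0.2, 0.3])
        with pytest.raises(ValueError, match="median VAF"):
            genomics.math_score([0.0, 0.0, 0.0])


class TestLynch:
    def _table(self, rows):
        cols = ["gene", "pathogenic", "vaf_tumor", "aa_change"]
        return pd.DataFrame(rows, columns=cols)

    def test_pathogenic_msh2_positive(self):
        t = self._table([("MSH2", True, 0.48, "")])
        assert genomics.classify_lynch(t) == "LS-positive"

    def test_mlh1_with_braf_v600e_is_sporadic(self):
        t = self._table([("MLH1", True, 0.50, ""),
                         ("BRAF", True, 0.30, "p.V600E")])
        assert genomics.classify_lynch(t) == "LS-negative"

    def test_msh2_immune_to_braf_override(self):
        t = self._table([("MSH2", True, 0.50, ""),
                         ("BRAF", True, 0.30, "p.V600E")])
        assert genomics.classify_lynch(t) == "LS-positive"

    def test_no_mmr_variants_negative(self):
        t = self._table([("KRAS", True, 0.40, "p.G12D")])
        assert genomics.classify_lynch(t) == "LS-negative"

    def test_somatic_vaf_outside_window_negative(self):
        t = self._table([("PMS2", True, 0.12, "")])
        assert genomics.classify_lynch(t) == "LS-negative"

    def test_missing_annotations_error(self):
        t = pd.DataFrame([{"gene": "MLH1"}])
        with pytest.raises(ValueError, match="pathogenic"):
            genomics.classify_lynch(t)


def cp_interval_oracle(x: int, n: int) -> tuple[float, float]:
    """Clopper-Pearson by direct binomial tail inversion."""
    lo = 0.0 if x == 0 else brentq(
        lambda p: binom.sf(x - 1, n, p) - 0.025, 1e-12, 1 - 1e-12)
    hi = 1.0 if x == n else brentq(
        lambda p: binom.cdf(x, n, p) - 0.025, 1e-12, 1 - 1e-12)
    return lo, hi


class TestConcordance:
    def test_thirteen_of_thirteen(self):
        ref = [True] * 13 + [False] * 100
        test = list(ref)
        out = genomics.concordance(test, ref)
        assert out.ppa == 1.0
        assert round(out.ppa_ci[0] * 100, 1) == 75.3
        assert out.ppa_ci[1] == 1.0

    def test_zero_of_thirteen_symmetry(self):
        ref = [True] * 13
        out = genomics.concordance([False] * 13, ref)
        assert out.ppa == 0.0
        assert out.ppa_ci[0] == 0.0
        assert round(out.ppa_ci[1] * 100, 1) == 24.7

    def test_half_matches_tail_inversion_oracle(self):
        ref = [True] * 10
        test = [True] * 5 + [False] * 5
        out = genomics.concordance(test, ref)
        assert out.ppa == 0.5
        lo, hi = cp_interval_oracle(5, 10)
        assert out.ppa_ci == (pytest.approx(lo), pytest.approx(hi))

    def test_npa_and_undefined(self):
        out = genomics.concordance([True, False, False],
                                   [True, False, True])
        assert out.tp == 1 and out.tn == 1 and out.fn == 1 and out.fp == 0
        assert out.npa == 1.0
        none_pos = genomics.concordance([False, False], [False, False])
        assert none_pos.ppa is None and none_pos.ppa_ci is None

    def test_coverage_at_nominal_level(self):
        """95% CP intervals cover p=0.9 in >= 95% (+/-2%) of n=13 draws."""
        rng = np.random.default_rng(0)
        draws = rng.binomial(13, 0.9, size=2000)
        covered = 0
        cache = {}
        for x in draws:
            if x not in cache:
                ref = [True] * 13
                test = [True] * x + [False] * (13 - x)
                ci = genomics.concordance(test, ref).ppa_ci
                cache[x] = ci[0] <= 0.9 <= ci[1]
            covered += cache[x]
        assert covered / 2000 >= 0.93


class TestExtractFeatures:
    def test_bundle_features(self, small_bundle):
        feats = genomics.extract_features(
            small_bundle.variants, small_bundle.cn_calls,
            small_bundle.gene_arms,
            exonic_mb=small_bundle.config.exonic_mb)
        truth = small_bundle.truth
        # Lynch rule recovers simulated truth
        ls = feats["ls_status"] == "LS-positive"
        for s, expected in truth["lynch"].items():
            assert bool(ls[s]) == expected, s
        # TMB reflects retained counts
        pass_counts = truth["variant_pass_counts"]
        for s in feats.index:
            assert feats.loc[s, "tmb"] == pytest.approx(
                pass_counts.get(s, 0) / small_bundle.config.exonic_mb)
        # arm events match truth annotations
        for s in feats.index:
            assert feats.loc[s, "cin_count"] == \
                len(truth["arm_events"].get(s, {}))
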