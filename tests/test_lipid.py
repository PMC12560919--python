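"""Fatty-acid class sums and health indices: printed cells, invariants, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    PANEL,
    oracle_ai,
    oracle_classes,
    oracle_hh,
    oracle_ti,
    random_profile,
)
from nutriscore import (
    FattyAcidProfile,
    atherogenic_index,
    cohort_lipid_quality,
    fixture_cohort,
    fixture_fatty_acid_profile,
    hypo_hyper_ratio,
    lipid_quality,
    n6_n3_ratio,
    sum_fatty_acid_classes,
    thrombogenic_index,
)
from nutriscore.lipid import FattyAcidClassSummary


@pytest.fixture(scope="module")
def male():
    return fixture_fatty_acid_profile("male")


@pytest.fixture(scope="module")
def female():
    return fixture_fatty_acid_profile("female")


@pytest.fixture(scope="module")
def overall():
    return fixture_fatty_acid_profile("overall")


class TestClassSums:
    def test_male_column_reproduces_printed_sums(self, male):
        s = sum_fatty_acid_classes(male)
        assert s.sfa == pytest.approx(49.73, abs=0.01)
        assert s.pufa == pytest.approx(4.43, abs=0.01)
        assert s.ufa == pytest.approx(41.64, abs=0.05)
        assert s.mufa == pytest.approx(37.21, abs=0.05)
        assert s.n6 == pytest.approx(6.51, abs=0.01)

    def test_female_n6_includes_trans_under_as_published(self, female):
        # printed 2.23; the hand sum 2.10 + 0.14 = 2.24 is within rounding
        assert sum_fatty_acid_classes(female, "as_published").n6 == pytest.approx(
            2.24, abs=1e-9
        )
        assert sum_fatty_acid_classes(female, "conventional").n6 == pytest.approx(
            2.10, abs=1e-9
        )

    def test_single_mufa_profile_gives_inf_ratio(self):
        with pytest.warns(UserWarning):
            s = sum_fatty_acid_classes(FattyAcidProfile({"C18:1 cis": 100.0}))
        assert s.mufa == 100.0 and s.sfa == 0.0
        assert math.isinf(s.ufa_sfa_ratio)

    def test_ufa_is_mufa_plus_pufa_by_construction(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s = sum_fatty_acid_classes(random_profile(rng))
            assert s.ufa == pytest.approx(s.mufa + s.pufa, abs=1e-12)
            assert s.ufa_sfa_ratio == pytest.approx(s.ufa / s.sfa, rel=1e-12)


class TestIndices:
    @pytest.mark.parametrize(
        "column, printed", [("male", 0.798), ("overall", 0.821)]
    )
    def test_atherogenic_index_reproduces_print(self, column, printed):
        assert atherogenic_index(
            fixture_fatty_acid_profile(column)
        ) == pytest.approx(printed, abs=0.005)

    @pytest.mark.parametrize(
        "column, printed", [("male", 2.03), ("overall", 1.54)]
    )
    def test_thrombogenic_index_reproduces_print(self, column, printed):
        assert thrombogenic_index(
            fixture_fatty_acid_profile(column)
        ) == pytest.approx(printed, abs=0.005)

    def test_hypo_hyper_male_as_published(self, male):
        hfa, h_fa, ratio = hypo_hyper_ratio(male, "as_published")
        assert hfa == pytest.approx(25.48, abs=1e-9)
        assert h_fa == pytest.approx(6.38, abs=1e-9)
        assert ratio == pytest.approx(0.250, abs=0.001)

    def test_hypo_hyper_male_conventional_uses_oleic(self, male):
        # (34.02 + 4.43) / 25.48 = 1.509
        _, h_fa, ratio = hypo_hyper_ratio(male, "conventional")
        assert h_fa == pytest.approx(38.45, abs=1e-9)
        assert ratio == pytest.approx(1.509, abs=0.001)

    def test_hypo_hyper_female(self, female):
        hfa, _, ratio = hypo_hyper_ratio(female, "as_published")
        assert hfa == pytest.approx(31.71, abs=1e-9)
        assert ratio == pytest.approx(0.142, abs=0.001)

    def test_zero_numerators(self):
        base = {a: 2.0 for a in PANEL}
        ai_zero = dict(base, **{"C12:0": 0.0, "C14:0": 0.0, "C16:0": 0.0})
        assert atherogenic_index(FattyAcidProfile(ai_zero)) == 0.0
        ti_zero = dict(base, **{"C14:0": 0.0, "C16:0": 0.0, "C18:0": 0.0})
        assert thrombogenic_index(FattyAcidProfile(ti_zero)) == 0.0

    def test_domain_errors(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ZeroDivisionError, match="unsaturated"):
                atherogenic_index(FattyAcidProfile({"C16:0": 50.0}))
            with pytest.raises(ZeroDivisionError, match="n-6"):
                thrombogenic_index(FattyAcidProfile({"C16:0": 50.0, "C18:1 cis": 10.0}))
            with pytest.raises(ZeroDivisionError, match="hypercholesterolemic"):
                hypo_hyper_ratio(FattyAcidProfile({"C18:1 cis": 50.0}))


class TestN6N3Ratio:
    def test_male_ratio_of_means(self, male):
        s = sum_fatty_acid_classes(male)
        assert n6_n3_ratio(s) == pytest.approx(6.51 / 0.44, abs=0.01)

    def test_identical_classes_give_unity(self):
        s = FattyAcidClassSummary(
            sfa=10, mufa=10, pufa=10, ufa=20, tfa=0, n3=2.5, n6=2.5,
            ufa_sfa_ratio=2.0, n6_n3_ratio=1.0,
        )
        assert n6_n3_ratio(s) == 1.0

    def test_mean_of_ratios_vs_ratio_of_means(self):
        # two records with per-record ratios 10 and 20
        p1 = FattyAcidProfile({"C18:2 cis": 10.0, "C18:3 cis n3": 1.0, "C16:0": 20.0})
        p2 = FattyAcidProfile({"C18:2 cis": 40.0, "C18:3 cis n3": 2.0, "C16:0": 20.0})
        from nutriscore import AnimalRecord, CohortTable

        cohort = CohortTable(
            [
                AnimalRecord("a", "male", fatty_acids=p1),
                AnimalRecord("b", "female", fatty_acids=p2),
            ]
        )
        with pytest.warns(UserWarning):
            assert n6_n3_ratio(cohort, "mean_of_ratios") == pytest.approx(15.0)
            assert n6_n3_ratio(cohort, "ratio_of_means") == pytest.approx(50 / 3)


class TestProperties:
    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=3.0),
            min_size=len(PANEL),
            max_size=len(PANEL),
        ),
        st.floats(min_value=0.1, max_value=2.0),
    )
    def test_degree_zero_homogeneity(self, values, k):
        """Scale-free indices are unchanged by scaling every acid by k > 0.

        The thrombogenic index is the deliberate exception: its
        denominator mixes degree-1 class sums with the dimensionless
        n3/n6 term, so it obeys an affine scaling law instead of exact
        invariance (checked separately below).
        """
        prof = FattyAcidProfile(dict(zip(PANEL, values)))
        scaled = prof.scaled(k)
        assert atherogenic_index(scaled) == pytest.approx(
            atherogenic_index(prof), rel=1e-12
        )
        assert hypo_hyper_ratio(scaled)[2] == pytest.approx(
            hypo_hyper_ratio(prof)[2], rel=1e-12
        )
        s, ss = sum_fatty_acid_classes(prof), sum_fatty_acid_classes(scaled)
        assert ss.ufa_sfa_ratio == pytest.approx(s.ufa_sfa_ratio, rel=1e-12)
        assert ss.n6_n3_ratio == pytest.approx(s.n6_n3_ratio, rel=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=3.0),
            min_size=len(PANEL),
            max_size=len(PANEL),
        ),
        st.floats(min_value=0.1, max_value=2.0),
    )
    def test_thrombogenic_index_scaling_law(self, values, k):
        """TI(k·p) = k·num / (k·(0.5·MUFA + 0.5·n6 + 3·n3) + n3/n6)."""
        prof = FattyAcidProfile(dict(zip(PANEL, values)))
        s = sum_fatty_acid_classes(prof)
        num = prof.get("C14:0") + prof.get("C16:0") + prof.get("C18:0")
        scale_part = 0.5 * s.mufa + 0.5 * s.n6 + 3.0 * s.n3
        expected = k * num / (k * scale_part + s.n3 / s.n6)
        assert thrombogenic_index(prof.scaled(k)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_monotonicity_in_myristic_and_oleic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            prof = random_profile(rng)
            bumped = FattyAcidProfile(
                dict(prof.values, **{"C14:0": prof.get("C14:0") + 1.0})
            )
            assert atherogenic_index(bumped) > atherogenic_index(prof)
            assert thrombogenic_index(bumped) > thrombogenic_index(prof)
            more_oleic = FattyAcidProfile(
                dict(prof.values, **{"C18:1 cis": prof.get("C18:1 cis") + 1.0})
            )
            assert atherogenic_index(more_oleic) < atherogenic_index(prof)

    def test_dialects_agree_without_trans_acids(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            vals = dict(zip(PANEL, rng.uniform(0.05, 3.0, len(PANEL))))
            vals["C18:1 trans"] = 0.0
            vals["C18:2 trans"] = 0.0
            prof = FattyAcidProfile(vals)
            for fn in (atherogenic_index, thrombogenic_index):
                assert fn(prof, "as_published") == pytest.approx(
                    fn(prof, "conventional"), rel=1e-12
                )
            assert hypo_hyper_ratio(prof, "as_published")[2] != pytest.approx(
                hypo_hyper_ratio(prof, "conventional")[2], rel=1e-12
            ) or vals["C18:1 cis"] == 0.0  # h/H differs unless oleic == trans == 0

    def test_oracle_equivalence_on_random_profiles(self):
        """1,000 random profiles vs the brute-force formula transcriptions."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            prof = random_profile(rng)
            v = prof.values
            for as_pub, dialect in ((True, "as_published"), (False, "conventional")):
                assert atherogenic_index(prof, dialect) == pytest.approx(
                    oracle_ai(v, as_pub), rel=1e-12
                )
                assert thrombogenic_index(prof, dialect) == pytest.approx(
                    oracle_ti(v, as_pub), rel=1e-12
                )
                assert hypo_hyper_ratio(prof, dialect)[2] == pytest.approx(
                    oracle_hh(v, as_pub), rel=1e-12
                )
            s = sum_fatty_acid_classes(prof)
            oc = oracle_classes(v)
            for name in ("sfa", "mufa", "pufa", "ufa", "tfa", "n3", "n6"):
                assert getattr(s, name) == pytest.approx(oc[name], rel=1e-12)


class TestCohortAggregation:
    def test_per_record_vs_mean_profile(self):
        cohort = fixture_cohort("fatty_acid")
        per = cohort_lipid_quality(cohort, aggregate="per_record")
        mean = cohort_lipid_quality(cohort, aggregate="mean_profile")
        # per-record averages the two sex indices
        m = lipid_quality(fixture_fatty_acid_profile("male"))
        f = lipid_quality(fixture_fatty_acid_profile("female"))
        assert per.ai == pytest.approx((m.ai + f.ai) / 2, rel=1e-12)
        assert per.ai != pytest.approx(mean.ai, rel=1e-6)
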