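import pytest
from hypothesis import given, strategies as st

from lactoteq import (
    Basis,
    BoundStrategy,
    GrowthModel,
    IntakeScenario,
    RiskThresholds,
    Units,
    compliance_check,
    daily_intake,
    default_sex_volumes,
    infant_weight_at,
)
from lactoteq.errors import DomainError


def _scenario(volume=798.0, bw=4.0, sex="female", density=1.0):
    return IntakeScenario(sex=sex, milk_volume_ml_per_day=volume,
                          body_weight_kg=bw, milk_density_g_per_ml=density)


class TestDailyIntake:
    def test_hand_case_mean_volume(self):
        res = daily_intake(0.1, _scenario())
        assert res.daily_pg_teq_per_kg == pytest.approx(19.95)
        assert res.weekly_pg_teq_per_kg == pytest.approx(139.65)
        assert res.exceeds_twi

    def test_zero_teq(self):
        res = daily_intake(0.0, _scenario())
        assert res.daily_pg_teq_per_kg == 0.0
        assert res.twi_fraction == 0.0
        assert not res.exceeds_twi

    def test_homogeneity(self):
        base = daily_intake(0.05, _scenario(volume=600, bw=4))
        double_vol = daily_intake(0.05, _scenario(volume=1200, bw=4))
        double_bw = daily_intake(0.05, _scenario(volume=600, bw=8))
        assert double_vol.daily_pg_teq_per_kg == pytest.approx(2 * base.daily_pg_teq_per_kg)
        assert double_bw.daily_pg_teq_per_kg == pytest.approx(base.daily_pg_teq_per_kg / 2)

    def test_weekly_is_seven_daily(self):
        res = daily_intake(0.033, _scenario(volume=500, bw=5.1))
        assert res.weekly_pg_teq_per_kg == pytest.approx(7 * res.daily_pg_teq_per_kg)

    def test_linear_in_teq(self):
        r1 = daily_intake(0.02, _scenario())
        r2 = daily_intake(0.04, _scenario())
        assert r2.daily_pg_teq_per_kg == pytest.approx(2 * r1.daily_pg_teq_per_kg)

    def test_twi_fraction_against_legacy(self):
        strict = daily_intake(0.001, _scenario(), RiskThresholds())
        legacy = daily_intake(0.001, _scenario(),
                              RiskThresholds(twi_pg_teq_per_kg_week=14.0))
        assert strict.twi_fraction == pytest.approx(7 * legacy.twi_fraction)

    def test_volume_outside_bounds_rejected(self):
        with pytest.raises(DomainError):
            _scenario(volume=2000)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(DomainError):
            _scenario(bw=0.0)


class TestDefaultSexVolumes:
    def test_study_values(self):
        female, male = default_sex_volumes(798.0, 76.0, 0.625)
        assert female == pytest.approx(750.5)
        assert male == pytest.approx(826.5)

    def test_zero_gap(self):
        female, male = default_sex_volumes(798.0, 0.0, 0.625)
        assert female == male == 798.0

    @given(st.floats(0, 1), st.floats(0, 200))
    def test_weighted_mean_identity(self, male_fraction, gap):
        female, male = default_sex_volumes(798.0, gap, male_fraction)
        mixed = male_fraction * male + (1 - male_fraction) * female
        assert mixed == pytest.approx(798.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(DomainError):
            default_sex_volumes(10.0, 100.0, 1.0)


class TestCompliance:
    def test_ndl_at_55_percent_of_limit(self, make_sample):
        # a sample whose indicator sum is 0.552 ng/g wet weight
        s = make_sample({153: (0.552, Basis.WET_WEIGHT, Units.NG_PER_G)})
        res = compliance_check(s, bound=BoundStrategy.LOWER)
        assert res.ndl_fraction_of_limit == pytest.approx(0.552)
        assert res.compliant_ndl

    def test_dl_teq_above_limit_flagged(self, make_sample):
        # 56.76 pg/g of PCB 126 -> TEQ 5.676 pg-TEQ/g vs limit 0.1
        s = make_sample({126: (56.76, Basis.WET_WEIGHT, Units.PG_PER_G)})
        res = compliance_check(s, bound=BoundStrategy.LOWER)
        assert res.dl_teq_ww == pytest.approx(5.676)
        assert res.dl_fraction_of_limit == pytest.approx(56.76)
        assert not res.compliant_dl

    def test_zero_sample_compliant(self, make_sample):
        s = make_sample({126: (0.0, Basis.WET_WEIGHT, Units.PG_PER_G),
                         153: (0.0, Basis.WET_WEIGHT, Units.NG_PER_G)})
        res = compliance_check(s, bound=BoundStrategy.LOWER)
        assert res.compliant_dl and res.compliant_ndl
        assert res.dl_fraction_of_limit == 0.0

    def test_exactly_at_limit_is_compliant(self, make_sample):
        s = make_sample({126: (1.0, Basis.WET_WEIGHT, Units.PG_PER_G),
                         153: (1.0, Basis.WET_WEIGHT, Units.NG_PER_G)})
        res = compliance_check(s, bound=BoundStrategy.LOWER)
        assert res.dl_fraction_of_limit == pytest.approx(1.0)
        assert res.ndl_fraction_of_limit == pytest.approx(1.0)
        assert res.compliant_dl and res.compliant_ndl

    def test_invariant_to_stored_basis(self, make_sample, composition):
        lipid_frac = composition.lipid_fraction
        wet = make_sample({153: (0.4, Basis.WET_WEIGHT, Units.NG_PER_G)})
        lipid = make_sample({153: (0.4 / lipid_frac, Basis.LIPID, Units.NG_PER_G)})
        r_wet = compliance_check(wet, bound=BoundStrategy.LOWER)
        r_lip = compliance_check(lipid, bound=BoundStrategy.LOWER)
        assert r_wet.ndl_fraction_of_limit == pytest.approx(r_lip.ndl_fraction_of_limit)


class TestInfantWeight:
    def test_birth_anchor(self):
        assert infant_weight_at(0, 3.5) == 3.5

    def test_linear_ramp_one_month(self):
        assert infant_weight_at(30, 3.0) == pytest.approx(3.6)

    def test_slower_gain_after_six_months(self):
        w7 = infant_weight_at(7 * 30, 3.0)
        w6 = infant_weight_at(6 * 30, 3.0)
        assert w7 - w6 == pytest.approx(0.4)
        assert w6 == pytest.approx(3.0 + 6 * 0.6)

    def test_monotone_nondecreasing(self):
        weights = [infant_weight_at(d, 3.2) for d in range(0, 400, 10)]
        assert weights == sorted(weights)

    def test_constant_mode(self):
        m = GrowthModel(mode="none")
        assert infant_weight_at(365, 3.2, m) == 3.2

    def test_negative_stage_rejected(self):
        with pytest.raises(DomainError):
            infant_weight_at(-1, 3.2)
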