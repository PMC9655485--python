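import math

import pytest
from hypothesis import given, settings, strategies as st

from lactoteq import (
    Basis,
    BoundStrategy,
    CensorState,
    CongenerMeasurement,
    DL_CONGENERS,
    Units,
    WHO_2005,
    compute_teq,
    congener,
    convert_basis,
    substitute_censored,
    sum_group,
)
from lactoteq.congeners import CongenerGroup, NDL_INDICATORS
from lactoteq.errors import ConfigurationError, DegenerateSampleError
from lactoteq.teq import TEFScheme


class TestTEFScheme:
    def test_default_values(self):
        expected = {77: 0.0001, 81: 0.0003, 126: 0.1, 169: 0.03}
        for n in (105, 114, 118, 123, 156, 157, 167, 189):
            expected[n] = 0.00003
        assert WHO_2005.tef == expected

    def test_missing_congener_rejected(self):
        with pytest.raises(ConfigurationError):
            TEFScheme(name="partial", tef={126: 0.1})

    def test_ndl_congener_has_no_tef(self):
        with pytest.raises(ConfigurationError):
            WHO_2005.factor(congener(153))


class TestConvertBasis:
    def test_wet_to_lipid_hand_case(self):
        # 0.5 ng/g wet at 4 % lipid -> 0.5 / 0.04 = 12.5 ng/g lipid
        assert convert_basis(0.5, Basis.WET_WEIGHT, Basis.LIPID, 4.0) == pytest.approx(12.5)

    def test_identity(self):
        assert convert_basis(3.7, Basis.WET_WEIGHT, Basis.WET_WEIGHT) == 3.7

    @given(st.floats(0, 1e6), st.floats(0.01, 100))
    def test_round_trip(self, value, lipid_pct):
        mid = convert_basis(value, Basis.WET_WEIGHT, Basis.LIPID, lipid_pct)
        back = convert_basis(mid, Basis.LIPID, Basis.WET_WEIGHT, lipid_pct)
        assert back == pytest.approx(value, rel=1e-12, abs=1e-12)

    def test_zero_lipid_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            convert_basis(1.0, Basis.WET_WEIGHT, Basis.LIPID, 0.0)


class TestSubstituteCensored:
    def _censored(self, lod=0.1, loq=0.3, state=CensorState.BELOW_LOD):
        value = lod if state is CensorState.BELOW_LOD else loq
        return CongenerMeasurement(
            congener=congener(126), value=value, basis=Basis.WET_WEIGHT,
            units=Units.PG_PER_G, censor=state, lod=lod, loq=loq,
        )

    def test_definitions(self):
        m = self._censored()
        assert substitute_censored(m, BoundStrategy.UPPER) == 0.1
        assert substitute_censored(m, BoundStrategy.MIDDLE) == 0.05
        assert substitute_censored(m, BoundStrategy.LOWER) == 0.0

    def test_below_loq_uses_loq(self):
        m = self._censored(state=CensorState.BELOW_LOQ)
        assert substitute_censored(m, BoundStrategy.UPPER) == 0.3

    def test_detected_identity(self):
        m = CongenerMeasurement(congener=congener(126), value=3.2,
                                basis=Basis.WET_WEIGHT, units=Units.PG_PER_G)
        for b in BoundStrategy:
            assert substitute_censored(m, b) == 3.2


class TestComputeTEQ:
    def test_single_pcb126_unit_sample(self, make_sample):
        s = make_sample({126: (1.0, Basis.WET_WEIGHT, Units.PG_PER_G)})
        res = compute_teq(s, basis=Basis.WET_WEIGHT, bound=BoundStrategy.LOWER)
        assert res.teq == pytest.approx(0.1)

    def test_all_12_unit_samples_return_tef(self, make_sample):
        for c in DL_CONGENERS:
            s = make_sample({c.iupac_number: (1.0, Basis.WET_WEIGHT, Units.PG_PER_G)})
            res = compute_teq(s, basis=Basis.WET_WEIGHT, bound=BoundStrategy.LOWER)
            assert res.teq == WHO_2005.tef[c.iupac_number]

    def test_weighted_sum_hand_case(self, make_sample):
        s = make_sample({
            77: (10.0, Basis.WET_WEIGHT, Units.PG_PER_G),
            126: (2.0, Basis.WET_WEIGHT, Units.PG_PER_G),
        })
        res = compute_teq(s, basis=Basis.WET_WEIGHT, bound=BoundStrategy.LOWER)
        assert res.teq == pytest.approx(10 * 0.0001 + 2 * 0.1)  # 0.201

    def test_zero_concentrations(self, make_sample):
        s = make_sample({n: (0.0, Basis.WET_WEIGHT, Units.PG_PER_G)
                         for n in (77, 81, 126, 169)})
        res = compute_teq(s, bound=BoundStrategy.LOWER)
        assert res.teq == 0.0

    def test_teq_equals_sum_of_contributions(self, make_sample):
        s = make_sample({
            126: (2.0, Basis.WET_WEIGHT, Units.PG_PER_G),
            169: (5.0, Basis.WET_WEIGHT, Units.PG_PER_G),
        })
        res = compute_teq(s, bound=BoundStrategy.LOWER)
        assert res.teq == pytest.approx(sum(res.per_congener.values()))

    def test_absent_congener_warns_under_upper_bound(self, make_sample):
        s = make_sample({126: (1.0, Basis.WET_WEIGHT, Units.PG_PER_G)})
        with pytest.warns(UserWarning, match="absent"):
            compute_teq(s, bound=BoundStrategy.UPPER)

    def test_homogeneity(self, make_sample):
        base = {77: 3.0, 126: 1.5, 169: 0.7}
        s1 = make_sample({n: (v, Basis.WET_WEIGHT, Units.PG_PER_G) for n, v in base.items()})
        s2 = make_sample({n: (v * 3, Basis.WET_WEIGHT, Units.PG_PER_G)
                          for n, v in base.items()})
        t1 = compute_teq(s1, bound=BoundStrategy.LOWER).teq
        t2 = compute_teq(s2, bound=BoundStrategy.LOWER).teq
        assert t2 == pytest.approx(3 * t1)

    def test_convert_and_teq_commute(self, make_sample):
        s = make_sample({126: (2.0, Basis.WET_WEIGHT, Units.PG_PER_G)})
        lipid_pct = s.composition.lipid_pct
        teq_ww = compute_teq(s, basis=Basis.WET_WEIGHT, bound=BoundStrategy.LOWER).teq
        teq_lipid = compute_teq(s, basis=Basis.LIPID, bound=BoundStrategy.LOWER).teq
        assert teq_lipid == pytest.approx(
            convert_basis(teq_ww, Basis.WET_WEIGHT, Basis.LIPID, lipid_pct)
        )


def _random_censored_sample(make_sample, rng):
    specs = {}
    for c in DL_CONGENERS:
        state = rng.choice(["detected", "below_loq", "below_lod"])
        lod = float(rng.uniform(0.01, 0.2))
        loq = lod * 10 / 3.3
        if state == "detected":
            specs[c.iupac_number] = (float(rng.uniform(0, 5)), Basis.WET_WEIGHT,
                                     Units.PG_PER_G, CensorState.DETECTED, lod, loq)
        elif state == "below_lod":
            specs[c.iupac_number] = (lod, Basis.WET_WEIGHT, Units.PG_PER_G,
                                     CensorState.BELOW_LOD, lod, loq)
        else:
            specs[c.iupac_number] = (loq, Basis.WET_WEIGHT, Units.PG_PER_G,
                                     CensorState.BELOW_LOQ, lod, loq)
    return make_sample(specs)


def test_bound_ordering_on_random_samples(make_sample):
    import numpy as np

    rng = np.random.default_rng(7)
    for _ in range(100):
        s = _random_censored_sample(make_sample, rng)
        lo = compute_teq(s, bound=BoundStrategy.LOWER).teq
        mid = compute_teq(s, bound=BoundStrategy.MIDDLE).teq
        up = compute_teq(s, bound=BoundStrategy.UPPER).teq
        assert lo <= mid <= up


class TestSumGroup:
    def test_six_indicators_at_one(self, make_sample):
        s = make_sample({c.iupac_number: (1.0, Basis.LIPID, Units.NG_PER_G)
                         for c in NDL_INDICATORS})
        total = sum_group(s, CongenerGroup.NDL_INDICATOR, basis=Basis.LIPID,
                          units=Units.NG_PER_G)
        assert total == pytest.approx(6.0)

    def test_linearity_over_merged_sets(self, make_sample):
        a = make_sample({28: (1.0, Basis.LIPID, Units.NG_PER_G),
                         52: (2.0, Basis.LIPID, Units.NG_PER_G)})
        b = make_sample({101: (3.0, Basis.LIPID, Units.NG_PER_G)})
        merged = make_sample({28: (1.0, Basis.LIPID, Units.NG_PER_G),
                              52: (2.0, Basis.LIPID, Units.NG_PER_G),
                              101: (3.0, Basis.LIPID, Units.NG_PER_G)})
        kw = dict(basis=Basis.LIPID, units=Units.NG_PER_G)
        assert sum_group(merged, "ndl_indicator", **kw) == pytest.approx(
            sum_group(a, "ndl_indicator", **kw) + sum_group(b, "ndl_indicator", **kw)
        )

    def test_lower_vs_upper_differ_by_sum_of_limits(self, make_sample):
        lods = {28: 0.05, 52: 0.11}
        specs = {
            n: (lod, Basis.LIPID, Units.NG_PER_G, CensorState.BELOW_LOD, lod, lod * 10 / 3.3)
            for n, lod in lods.items()
        }
        specs[153] = (4.0, Basis.LIPID, Units.NG_PER_G)
        s = make_sample(specs)
        kw = dict(basis=Basis.LIPID, units=Units.NG_PER_G)
        upper = sum_group(s, "ndl_indicator", bound=BoundStrategy.UPPER, **kw)
        lower = sum_group(s, "ndl_indicator", bound=BoundStrategy.LOWER, **kw)
        assert upper - lower == pytest.approx(sum(lods.values()))
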