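"""Mass-balance allocation, risk quotients, bands and high-risk area."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wetrisk import regional, synthgen
from wetrisk.synthgen import sample_features


def make_county(emission, wetlands_spec, seed=0):
    """Toy county: wetlands_spec is a list of (wclass, area_km2)."""
    county = pd.Series({"county_id": "C1", "emission_t": emission, "area_km2": 100.0})
    feats = sample_features(len(wetlands_spec), np.random.default_rng(seed))
    w = pd.DataFrame(
        {
            "wetland_id": [f"W{i}" for i in range(len(wetlands_spec))],
            "county_id": "C1",
            "wclass": [c for c, _ in wetlands_spec],
            "area_km2": [a for _, a in wetlands_spec],
        }
    )
    return county, pd.concat([w, feats.reset_index(drop=True)], axis=1)


def const_are(value):
    return lambda feats: np.full(len(feats), value)


class TestAllocate:
    def test_single_wetland_takes_everything(self):
        county, w = make_county(10.0, [("natural", 5.0)])
        for mode in regional.MODES:
            alloc = regional.allocate(county, w, mode)
            assert alloc.stage1["ai_t"].sum() == pytest.approx(10.0)
            assert len(alloc.stage1) == 1

    def test_im_two_stage_arithmetic(self):
        """100 t, one constructed wetland removing 70%, two natural
        wetlands sharing the 30 t surplus 15/15 under equal-mass sharing."""
        county, w = make_county(
            100.0, [("constructed", 4.0), ("natural", 2.0), ("natural", 6.0)]
        )
        alloc = regional.allocate(county, w, "IM", stage2_share="mass")
        assert alloc.stage1["ai_t"].tolist() == [100.0]
        res = regional.removal_and_surplus(alloc, w, const_are(0.7))
        stage2 = res.wetlands[res.wetlands["stage"] == 2]
        np.testing.assert_allclose(stage2["ai_t"], [15.0, 15.0])
        # area sharing splits the same 30 t in proportion 2:6
        alloc_a = regional.allocate(county, w, "IM", stage2_share="area")
        res_a = regional.removal_and_surplus(alloc_a, w, const_are(0.7))
        stage2_a = res_a.wetlands[res_a.wetlands["stage"] == 2]
        np.testing.assert_allclose(stage2_a["ai_t"], [7.5, 22.5])

    def test_im_without_constructed_equals_nm(self):
        county, w = make_county(20.0, [("natural", 2.0), ("reservoir", 8.0)])
        a_im = regional.allocate(county, w, "IM")
        a_nm = regional.allocate(county, w, "NM")
        pd.testing.assert_frame_equal(a_im.stage1, a_nm.stage1)
        assert a_im.stage2_ids == []

    def test_no_wetlands_full_surplus_with_warning(self):
        county, w = make_county(7.0, [])
        with pytest.warns(UserWarning, match="no wetlands"):
            alloc = regional.allocate(county, w.iloc[:0], "NM")
        res = regional.removal_and_surplus(alloc, w.iloc[:0], const_are(0.5))
        assert res.surplus_t == pytest.approx(7.0)
        assert res.total_removal == 0.0

    def test_unknown_mode(self):
        county, w = make_county(1.0, [("natural", 1.0)])
        with pytest.raises(ValueError):
            regional.allocate(county, w, "XX")


class TestRemovalAndSurplus:
    @pytest.mark.parametrize(
        "are,expected_surplus", [(1.0, 0.0), (0.0, 50.0)]
    )
    def test_extreme_efficiencies(self, are, expected_surplus):
        county, w = make_county(50.0, [("constructed", 1.0), ("natural", 3.0)])
        alloc = regional.allocate(county, w, "IM")
        res = regional.removal_and_surplus(alloc, w, const_are(are))
        assert res.surplus_t == pytest.approx(expected_surplus, abs=1e-9)

    def test_removal_is_input_times_efficiency(self):
        county, w = make_county(10.0, [("natural", 1.0)])
        alloc = regional.allocate(county, w, "NM")
        res = regional.removal_and_surplus(alloc, w, const_are(0.722))
        assert res.total_removal == pytest.approx(7.22)


class TestRQArithmetic:
    def test_conc_surplus_values(self):
        assert regional.conc_surplus(10.0, 1.0) == pytest.approx(0.0)
        assert regional.conc_surplus(10.0, 0.75) == pytest.approx(2.5)

    def test_conc_surplus_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            regional.conc_surplus(10.0, 1.2)

    def test_rq_total_values(self):
        assert regional.rq_total(6.0, 1, 3.0) == pytest.approx(2.0)
        assert regional.rq_total(0.0, 80, 3.0) == 0.0

    @pytest.mark.parametrize("n,pnec", [(0, 3.0), (1, 0.0), (1, -1.0)])
    def test_rq_total_rejects_bad_inputs(self, n, pnec):
        with pytest.raises(ValueError):
            regional.rq_total(1.0, n, pnec)

    @given(
        st.floats(0.0, 1e6),
        st.integers(1, 200),
        st.floats(0.1, 1e3),
        st.floats(0.1, 10.0),
    )
    def test_rq_scaling_laws(self, c, n, pnec, k):
        """Linear in concentration, inverse in type count and PNEC."""
        rq = regional.rq_total(c, n, pnec)
        assert regional.rq_total(k * c, n, pnec) == pytest.approx(k * rq, rel=1e-9)
        assert regional.rq_total(c, n, k * pnec) == pytest.approx(rq / k, rel=1e-9)


class TestRiskBands:
    @pytest.mark.parametrize(
        "rq,band",
        [
            (1.01, "high"),
            (1.00, "medium"),  # strictly greater than 1 is required for high
            (0.5, "medium"),
            (0.05, "low"),
            (0.005, "no-risk"),
            (0.0, "no-risk"),
        ],
    )
    def test_band_cut_points(self, rq, band):
        assert regional.classify_risk(rq) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            regional.classify_risk(-0.1)


class TestHRA:
    def _tables(self, bands_by_class):
        counties = pd.DataFrame(
            {"county_id": ["C1"], "area_km2": [100.0], "emission_t": [1.0]}
        )
        wetlands = pd.DataFrame(
            {
                "county_id": "C1",
                "wclass": [c for c, _ in bands_by_class],
                "band": [b for _, b in bands_by_class],
            }
        )
        return counties, wetlands

    def test_no_high_risk_gives_zero(self):
        counties, w = self._tables([("natural", "medium"), ("constructed", "low")])
        assert regional.hra(counties, w) == 0.0

    def test_high_risk_natural_counts_county_area(self):
        counties, w = self._tables([("natural", "high")])
        assert regional.hra(counties, w) == pytest.approx(100.0)

    def test_constructed_high_risk_excluded(self):
        counties, w = self._tables([("constructed", "high"), ("natural", "low")])
        assert regional.hra(counties, w) == 0.0

    def test_reservoir_counts_by_default_but_is_configurable(self):
        counties, w = self._tables([("reservoir", "high")])
        assert regional.hra(counties, w) == pytest.approx(100.0)
        assert regional.hra(counties, w, natural_classes=("natural",)) == 0.0


class TestMassConservation:
    def test_thousand_random_toy_counties(self, toy_are_fn):
        """emission == removal + surplus to 1e-9 in both modes."""
        rng = np.random.default_rng(123)
        region, inv = synthgen.gen_region(
            1000, 123, 10, mean_wetlands=3.0
        )
        for mode in regional.MODES:
            ass = regional.assess_region(region, inv, toy_are_fn, mode)
            np.testing.assert_allclose(
                ass.counties["emission_t"],
                ass.counties["removal_t"] + ass.counties["surplus_t"],
                atol=1e-9,
            )
            # per-wetland consistency: AR <= AI and both non-negative
            assert (ass.wetlands["ar_t"] <= ass.wetlands["ai_t"] + 1e-12).all()
            assert (ass.wetlands["ai_t"] >= 0).all()

    def test_vectorized_matches_per_county_path(
        self, region_and_inventory, toy_are_fn
    ):
        region, inv = region_and_inventory
        for mode in regional.MODES:
            vec = regional.assess_region(region, inv, toy_are_fn, mode)
            for cid in region.counties["county_id"].iloc[:15]:
                county = region.counties.set_index(
                    "county_id", drop=False
                ).loc[cid]
                w = region.wetlands[region.wetlands["county_id"] == cid]
                if len(w) == 0:
                    continue
                alloc = regional.allocate(county, w, mode)
                res = regional.removal_and_surplus(alloc, w, toy_are_fn)
                got = vec.counties.set_index("county_id").loc[cid]
                assert got["removal_t"] == pytest.approx(res.total_removal, abs=1e-9)
                assert got["surplus_t"] == pytest.approx(res.surplus_t, abs=1e-9)


def test_assessment_with_learned_model(study, ensemble, region_and_inventory):
    """The ensemble-backed assessment keeps mass balance and IM helps."""
    region, inv = region_and_inventory
    are_fn = regional.ensemble_are_fn(ensemble, study["transform"])
    nm = regional.assess_region(region, inv, are_fn, "NM")
    im = regional.assess_region(region, inv, are_fn, "IM")
    for ass in (nm, im):
        np.testing.assert_allclose(
            ass.counties["emission_t"],
            ass.counties["removal_t"] + ass.counties["surplus_t"],
            atol=1e-9,
        )
    assert im.total_removal >= nm.total_removal
    assert im.total_surplus <= nm.total_surplus
    assert im.hra_km2 <= nm.hra_km2
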