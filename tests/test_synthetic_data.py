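"""The survey generator: determinism, calibration, internal consistency."""

import numpy as np
import pandas as pd
import pytest

from streamn2o.errors import ValidationError
from streamn2o.gas_physics import dissolved_from_headspace
from streamn2o.stat_models import fit_saturation_model
from streamn2o.survey_processing import classify_records, percent_saturation
from streamn2o.synthetic_data import (
    GeneratorTruth,
    RegionSpec,
    default_region_specs,
    generate_strata,
    generate_survey,
)


class TestDeterminism:
    def test_same_seed_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_survey(seed=42, out_csv=a)
        generate_survey(seed=42, out_csv=b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seed_differs(self):
        f1, _ = generate_survey(seed=1)
        f2, _ = generate_survey(seed=2)
        assert not np.allclose(f1["C_obs"], f2["C_obs"])


class TestCalibration:
    def test_pooled_class_means_near_published_values(self, records):
        """Forest ~1.3 and agricultural ~1.6 ug N/L, within 20%."""
        means = records.groupby("landuse_class")["C_obs"].mean()
        assert means["forest"] == pytest.approx(1.3, rel=0.2)
        assert means["agricultural"] == pytest.approx(1.6, rel=0.2)

    def test_region_means_match_their_targets(self, survey):
        frame, truth = survey
        for region, target in truth["region_targets"].items():
            got = frame.loc[frame["region_id"] == region, "C_obs"].mean()
            assert got == pytest.approx(target, rel=0.25), region

    def test_ph_contrast_between_forest_and_agricultural_regions(self, survey):
        frame, _ = survey
        ph = frame.groupby("region_id")["pH"].mean()
        assert max(ph["KRY"], ph["SES"], ph["SRC"]) < 6.5
        assert min(ph["SCA"], ph["UPP1"], ph["UPP2"]) > 7.4

    def test_survey_shape_matches_the_design(self, survey):
        frame, _ = survey
        counts = frame.groupby("region_id").size()
        assert counts.sum() == 986
        assert counts["KRY"] == 420 and counts["SES"] == 227
        assert frame["region_id"].nunique() == 6
        assert frame["site_id"].nunique() == sum(
            s.n_sites for s in default_region_specs())

    def test_sample_moments_converge_to_spec_moments(self):
        """At n=10,000 the drawn covariates match the spec within 3 SE."""
        spec = RegionSpec(
            "BIG", "forest", n_sites=50, n_obs=10_000,
            months=tuple(range(1, 13)), order_probs=(1.0,),
            n2o_mean=1.3, tn_mean=800.0, tn_sd=400.0,
            doc_mean=20.0, doc_sd=8.0, ph_mean=6.0, ph_sd=0.5,
            temp_mean=8.0, temp_amplitude=0.0, temp_sd=1.0,
        )
        frame, _ = generate_survey([spec], seed=9)
        n = len(frame)
        assert frame["TN"].mean() == pytest.approx(
            800.0, abs=3 * 400.0 / np.sqrt(n))
        assert frame["DOC"].mean() == pytest.approx(
            20.0, abs=3 * 8.0 / np.sqrt(n))
        assert frame["pH"].mean() == pytest.approx(
            6.0, abs=3 * 0.5 / np.sqrt(n))


class TestInternalConsistency:
    def test_vial_round_trip_recovers_generated_saturation(self, survey):
        """generate -> headspace -> dissolved -> %sat closes to 1e-6."""
        frame, _ = survey
        c_obs = dissolved_from_headspace(
            frame["headspace_ppb"].to_numpy(),
            frame["equilibration_temp"].to_numpy(),
            frame["pressure"].to_numpy(),
            frame["vial_volume_ml"].to_numpy(),
            frame["water_volume_ml"].to_numpy(),
        )
        records = classify_records(frame)
        sat = percent_saturation(c_obs, records["C_eq"].to_numpy())
        assert np.allclose(sat, records["pct_sat"], rtol=1e-6)

    def test_truth_sidecar_is_sufficient_for_recovery(self, survey):
        _, truth = survey
        assert truth["truth"]["tn_slope"] == pytest.approx(0.00023)
        assert truth["truth"]["ph_slope"] == pytest.approx(-0.17)
        assert set(truth["region_effects"]) == set(truth["region_targets"])
        assert truth["seed"] == 1

    def test_null_truth_recovers_zero_slopes(self):
        seasons = dict.fromkeys(("winter", "spring", "summer", "autumn"), 1.0)
        orders = dict.fromkeys(range(1, 6), 1.0)
        truth = GeneratorTruth(
            tn_slope=0.0, ph_slope=0.0, agriculture_slope=0.0,
            wetland_slope=0.0, doc_slope=0.0, temp_slope=0.0,
            region_sd=0.0,
            season_multipliers={"forest": dict(seasons),
                                "agricultural": dict(seasons)},
            order_multipliers={"forest": dict(orders),
                               "agricultural": dict(orders)},
        )
        frame, _ = generate_survey(truth=truth, seed=13,
                                   calibrate_regions=False)
        fit = fit_saturation_model(classify_records(frame))
        coef = fit.coefficients.set_index("term")
        for term in ("TN", "pH", "DOC"):
            assert coef.loc[term, "ci_low"] <= 0.0 <= coef.loc[term, "ci_high"]


class TestSpecValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            RegionSpec("BAD", "forest", n_sites=2, n_obs=10, months=(1,),
                       order_probs=(1.0,), n2o_mean=1.0, tn_mean=500,
                       tn_sd=-1.0, doc_mean=10, doc_sd=2, ph_mean=6,
                       ph_sd=0.5, temp_mean=8, temp_amplitude=5)

    def test_order_probabilities_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            RegionSpec("BAD", "forest", n_sites=2, n_obs=10, months=(1,),
                       order_probs=(0.5, 0.2), n2o_mean=1.0, tn_mean=500,
                       tn_sd=100, doc_mean=10, doc_sd=2, ph_mean=6,
                       ph_sd=0.5, temp_mean=8, temp_amplitude=5)


class TestStrataFixture:
    def test_forest_order1_area(self, strata_frame):
        row = strata_frame[(strata_frame["order"] == 1)
                           & (strata_frame["landuse_class"] == "forest")]
        assert row["area_km2"].iloc[0] == 125.0

    def test_forest_order4_k600_mean(self, strata_frame):
        row = strata_frame[(strata_frame["order"] == 4)
                           & (strata_frame["landuse_class"] == "forest")]
        assert row["k600_mean"].iloc[0] == 10.3

    def test_shape_and_area_consistency(self, strata_frame):
        assert len(strata_frame) == 8  # 4 orders x 2 classes
        assert set(strata_frame["order"]) == {1, 2, 3, 4}
        # class areas sum to the published network totals
        assert strata_frame.loc[strata_frame["landuse_class"] == "forest",
                                "area_km2"].sum() == 511.0
        assert strata_frame.loc[
            strata_frame["landuse_class"] == "agricultural",
            "area_km2"].sum() == 144.0
        # class areas never exceed the order's total network area
        for _, row in strata_frame.iterrows():
            assert row["area_km2"] <= row["area_total_km2"]

    def test_percentile_ordering(self, strata_frame):
        assert (strata_frame["k600_p10"] <= strata_frame["k600_median"]).all()
        assert (strata_frame["k600_median"] <= strata_frame["k600_p90"]).all()

    def test_written_csv_round_trips(self, tmp_path):
        path = tmp_path / "strata.csv"
        frame = generate_strata(path)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(frame, back)
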