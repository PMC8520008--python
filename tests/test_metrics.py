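"""SQI/ISS arithmetic, categories, linearity validation and matrix assembly."""

import numpy as np
import pytest

import sqiflow
from sqiflow.cli_report import controls_from_simulation
from sqiflow.metrics import (
    CAPTION_BINS,
    TEXT_BINS,
    NoSeparationError,
    SQIMatrix,
    SingleStainControl,
    classify_sqi,
    compute_sqi_matrix,
    compute_ssm,
    iss_value,
    normalization_factor,
    percent_occupancy,
    replicate_cv,
    sqi_value,
    validate_linearity,
)

from conftest import two_fluor_config, run_pipeline, entry_map


class TestNormalizationFactor:
    def test_identity_when_separation_equals_p(self):
        assert normalization_factor(9000.0, 0.0, 9000.0) == 1.0

    def test_direct_substitution(self):
        assert normalization_factor(110_000.0, 2_000.0, 9000.0) == pytest.approx(
            9000.0 / 108_000.0
        )

    def test_no_separation_error(self):
        with pytest.raises(NoSeparationError):
            normalization_factor(500.0, 500.0)

    def test_negative_p_rejected(self):
        with pytest.raises(ValueError):
            normalization_factor(10.0, 0.0, -1.0)


class TestSQIValue:
    def test_zero_spread(self):
        assert sqi_value(1234.0, 1234.0, 0.5) == 0.0

    def test_direct_substitution(self):
        assert sqi_value(740.0, 500.0, 1.0) == 240.0

    def test_linear_in_p(self):
        nf1 = normalization_factor(10_000.0, 1_000.0, 9000.0)
        nf2 = normalization_factor(10_000.0, 1_000.0, 18_000.0)
        assert sqi_value(300.0, 100.0, nf2) == pytest.approx(
            2.0 * sqi_value(300.0, 100.0, nf1)
        )


class TestClassification:
    @pytest.mark.parametrize(
        "value,category",
        [(20.0, "Green"), (120.0, "Green"), (220.0, "Yellow"), (221.0, "Orange"),
         (300.0, "Orange"), (611.0, "Red")],
    )
    def test_default_bins(self, value, category):
        assert classify_sqi(value) == category

    def test_caption_preset(self):
        assert classify_sqi(199.0, CAPTION_BINS) == "Yellow"
        assert classify_sqi(200.0, CAPTION_BINS) == "Orange"
        assert classify_sqi(300.0, CAPTION_BINS) == "Red"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_sqi(-1.0)

    def test_monotone_in_value(self):
        order = ["Green", "Yellow", "Orange", "Red"]
        cats = [order.index(classify_sqi(v)) for v in np.linspace(0, 500, 101)]
        assert cats == sorted(cats)


class TestOccupancy:
    def test_one_percent(self):
        assert percent_occupancy(2621.44, 0.0, 262_144.0) == pytest.approx(1.0)

    def test_zero_and_full(self):
        assert percent_occupancy(5.0, 5.0, 262_144.0) == 0.0
        assert percent_occupancy(262_144.0, 0.0, 262_144.0) == 100.0

    def test_bad_range(self):
        with pytest.raises(ValueError):
            percent_occupancy(1.0, 0.0, 0.0)


class TestISS:
    def test_hand_arithmetic(self):
        assert iss_value(5.0, 3.0, 16.0) == pytest.approx(1.0)

    def test_equal_spreads_give_zero(self):
        assert iss_value(3.0, 3.0, 100.0) == 0.0
        assert iss_value(2.0, 3.0, 100.0) == 0.0  # clamped, not imaginary

    def test_bad_delta_f(self):
        with pytest.raises(ValueError):
            iss_value(5.0, 3.0, 0.0)

    @pytest.mark.parametrize("c", [0.25, 0.5, 2.0, 4.0])
    def test_scaling_algebra(self, c):
        base = iss_value(5.0, 3.0, 16.0)
        # secondary-channel scaling by c multiplies ISS by c
        assert iss_value(5.0 * c, 3.0 * c, 16.0) == pytest.approx(c * base)
        # primary-channel scaling by c multiplies ISS by 1/sqrt(c)
        assert iss_value(5.0, 3.0, 16.0 * c) == pytest.approx(base / np.sqrt(c))


class TestValidateLinearity:
    def test_mid_scale_valid(self):
        ok, reason = validate_linearity({"x_b99": 1e4, "x_b50": 5e3}, -100.0, 262_144.0)
        assert ok and reason == ""

    def test_pegged_percentile_invalid(self):
        ok, reason = validate_linearity({"x_b99": 262_144.0}, -100.0, 262_144.0)
        assert not ok and "outside linear range" in reason

    def test_reference_median_above_max_invalid(self):
        ok, reason = validate_linearity({"yst_b50": 3e5}, -100.0, 262_144.0)
        assert not ok and "yst_b50" in reason

    def test_below_noise_floor_invalid(self):
        ok, _ = validate_linearity({"x_b50": -5000.0}, -100.0, 262_144.0)
        assert not ok


@pytest.fixture(scope="module")
def small_panel():
    out = sqiflow.simulate_panel(two_fluor_config(n_events=35_000, seed=17))
    return controls_from_simulation(out, gate_kwargs={})


class TestMatrixAssembly:
    def test_zero_spillover_panel_stays_near_baseline(self):
        cfg = two_fluor_config(n_events=35_000, seed=19, spill=0.0)
        cfg.spillover["APC"]["YG670"] = 0.0
        out = sqiflow.simulate_panel(cfg)
        matrix = compute_sqi_matrix(controls_from_simulation(out))
        values = [e.value for e in matrix.entries]
        assert len(values) == 2
        # Measurement error on the autofluorescence signal keeps SQI nonzero:
        # counting error on ~30 background photons puts the floor near
        # 2.4*sqrt(30*(1+nu^2)) ~ 15 SQI units; anything deep in Green and
        # far below the dimmest true-spillover entries qualifies as baseline.
        assert all(0.0 < v < 20.0 for v in values)
        assert all(e.category == "Green" for e in matrix.entries)

    def test_secondary_rescaling_is_exact_noop(self, small_panel):
        base = compute_sqi_matrix(small_panel)
        scaled = []
        for c in small_panel:
            table = sqiflow.EventTable(
                list(c.table.channels), c.table.events.copy(), compensated=True
            )
            j = table.channel_index("R670")
            table.events[:, j] *= 3.0
            scaled.append(SingleStainControl(c.name, c.primary_channel, table))
        again = compute_sqi_matrix(scaled)
        for e in base.entries:
            e2 = again.get(e.source_fluor, e.secondary_detector)
            assert e2.value == pytest.approx(e.value, rel=1e-12)

    def test_dim_reference_scales_sqi_inversely(self):
        # two reference fluorochromes on one detector, one 5x dimmer
        cfg = sqiflow.SimConfig(
            fluorochromes=[
                sqiflow.FluorSpec("PE-Cy5", "YG670", 9000.0),
                sqiflow.FluorSpec("APC", "R670", 10_000.0),
                sqiflow.FluorSpec("AF647", "R670", 2_000.0),
            ],
            spillover={
                "PE-Cy5": {"YG670": 1.0, "R670": 0.05},
                "APC": {"R670": 1.0, "YG670": 0.002},
                "AF647": {"R670": 1.0, "YG670": 0.002},
            },
            n_events=35_000,
            seed=23,
        )
        out = sqiflow.simulate_panel(cfg)
        matrix = compute_sqi_matrix(controls_from_simulation(out))
        bright = matrix.get("PE-Cy5", "R670", reference="APC")
        dim = matrix.get("PE-Cy5", "R670", reference="AF647")
        expected = (bright.yst_b50 - bright.un_b50) / (dim.yst_b50 - dim.un_b50)
        assert dim.value / bright.value == pytest.approx(expected, rel=1e-9)
        assert dim.value / bright.value == pytest.approx(5.0, rel=0.10)

    def test_manifest_order_invariance(self, small_panel):
        fwd = compute_sqi_matrix(small_panel)
        rev = compute_sqi_matrix(list(reversed(small_panel)))
        fwd_map = {(e.source_fluor, e.secondary_detector): e.value for e in fwd.entries}
        rev_map = {(e.source_fluor, e.secondary_detector): e.value for e in rev.entries}
        assert fwd_map == rev_map

    def test_missing_reference_marked_invalid(self, small_panel):
        matrix = compute_sqi_matrix(small_panel, detectors=["YG670", "R670", "B530"])
        entry = matrix.get("PE-Cy5", "B530")
        assert not entry.valid
        assert "no reference fluorochrome" in entry.invalid_reason

    def test_sqi_nonnegative_and_category_consistent(self, small_panel):
        matrix = compute_sqi_matrix(small_panel)
        for e in matrix.entries:
            assert e.value >= 0.0
            assert e.category == classify_sqi(e.value)

    def test_merge_requires_same_p(self, small_panel):
        a = compute_sqi_matrix(small_panel, p_const=9000.0)
        b = compute_sqi_matrix(small_panel, p_const=4500.0)
        with pytest.raises(ValueError, match="different P"):
            a.merged(b)
        assert b.get("PE-Cy5", "R670").value == pytest.approx(
            a.get("PE-Cy5", "R670").value / 2.0
        )

    def test_iss_matches_brute_force_recomputation(self, small_panel):
        ssm = compute_ssm(small_panel)
        for ctrl in small_panel:
            other = "R670" if ctrl.primary_channel == "YG670" else "YG670"
            pair = ctrl.pair
            prim = ctrl.table.column(ctrl.primary_channel)
            sec = ctrl.table.column(other)
            # independent oracle: explicit medians and 1.4826*MAD
            def mad_sd(x):
                return 1.4826022185056018 * np.median(np.abs(x - np.median(x)))
            sp = mad_sd(sec[pair.stained_index])
            sn = mad_sd(sec[pair.unstained_index])
            df = np.median(prim[pair.stained_index]) - np.median(prim[pair.unstained_index])
            want = np.sqrt(max(sp**2 - sn**2, 0.0) / df)
            assert ssm.get(ctrl.name, other).value == pytest.approx(want, rel=1e-9)

    def test_replicate_cv_matches_manual_computation(self):
        mats = []
        for seed in (41, 42):
            out = sqiflow.simulate_panel(two_fluor_config(n_events=35_000, seed=seed))
            mats.append(compute_sqi_matrix(controls_from_simulation(out)))
        frame = replicate_cv(mats)
        row = frame[(frame.source_fluor == "PE-Cy5")].iloc[0]
        vals = np.array([m.get("PE-Cy5", "R670").value for m in mats])
        assert row.cv_percent == pytest.approx(100 * vals.std(ddof=1) / vals.mean())

    def test_pegged_control_flagged_invalid(self):
        cfg = two_fluor_config(n_events=35_000, seed=29)
        cfg.dynamic_range = {"YG670": 262_144.0, "R670": 7_000.0}  # spill p99 pegs
        cfg.__post_init__()
        out = sqiflow.simulate_panel(cfg)
        matrix = compute_sqi_matrix(controls_from_simulation(out))
        entry = matrix.get("PE-Cy5", "R670")
        assert not entry.valid
        assert "pegged" in entry.invalid_reason
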