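"""Variation, time-scaling, stitching, and impedance profiles."""

import numpy as np
import pytest

from gaitforge.core import DataError, DiscretizedPattern, GaitPattern, \
    InvalidSpecError, TimeSeriesGait
from gaitforge.timeseries import (
    ImpedanceRanges,
    MODE_PRESETS,
    ModePreset,
    StitchConfig,
    VariationConfig,
    apply_variation,
    build_dataset,
    impedance_profile,
    scale_to_physical,
    stitch,
    timeseries_from_pattern,
)


class _ZeroDrawRng:
    """Stub generator whose uniform draws are all zero."""

    def uniform(self, lo, hi, size=None):
        return np.zeros(size) if size else 0.0


class TestApplyVariation:
    def test_zero_draw_leaves_sketch_unchanged(self, lgw_sketch):
        out = apply_variation(lgw_sketch, VariationConfig(), rng=_ZeroDrawRng())
        assert np.allclose(out.values, lgw_sketch.values)

    def test_constant_channel_unchanged(self):
        vals = np.ones((11, 4)) * 5.0
        out = apply_variation(DiscretizedPattern(vals), VariationConfig(seed=3))
        assert np.allclose(out.values, vals)

    def test_unit_draw_shifts_by_scaled_sigma(self):
        # with r = 1 everywhere each node moves by exactly 0.4 * sigma(ch);
        # for the two-level toy channel {0, 1} population sigma follows
        # sqrt(p(1-p)), the hand value of the variation rule
        class _OnesRng:
            def uniform(self, lo, hi, size=None):
                return np.ones(size)

        vals = np.zeros((11, 4))
        vals[6:] = 1.0
        sketch = DiscretizedPattern(vals)
        sigma = np.sqrt((5 / 11) * (6 / 11))  # population sigma of the toy
        out = apply_variation(sketch, VariationConfig(scale=0.4), rng=_OnesRng())
        assert np.allclose(out.values, vals + 0.4 * sigma)

    def test_deterministic_per_seed(self, lgw_sketch):
        a = apply_variation(lgw_sketch, VariationConfig(seed=9))
        b = apply_variation(lgw_sketch, VariationConfig(seed=9))
        assert np.array_equal(a.values, b.values)


class TestTimeseriesFromPattern:
    def test_duration_sample_counts(self, lgw_normalized):
        p = lgw_normalized.drop_final_node()
        assert len(timeseries_from_pattern(p, 1.2)) == 240
        assert len(timeseries_from_pattern(p, 1.0)) == 200

    def test_one_to_one_mapping_at_1s(self, lgw_normalized):
        p = lgw_normalized.drop_final_node()
        ts = timeseries_from_pattern(p, 1.0)
        assert np.allclose(ts.gait, p.values)

    def test_constant_pattern_stays_constant(self):
        p = GaitPattern(np.full((200, 4), 0.4), units="normalized")
        ts = timeseries_from_pattern(p, 1.7)
        assert len(ts) == 340
        assert np.allclose(ts.gait, 0.4)

    def test_too_short_duration_rejected(self, lgw_normalized):
        with pytest.raises(DataError):
            timeseries_from_pattern(lgw_normalized.drop_final_node(), 0.004)


class TestStitch:
    def _series(self, n, value):
        return TimeSeriesGait(np.full((n, 4), float(value)))

    def test_length_arithmetic_single_bridge(self):
        cfg = StitchConfig(bridge_choices=(1,))
        out = stitch([self._series(240, 0.2), self._series(240, 0.8)], cfg)
        assert len(out) == 481

    def test_identical_constant_series_stay_constant(self):
        out = stitch([self._series(50, 0.3)] * 3, StitchConfig(seed=2))
        assert np.allclose(out.gait, 0.3)

    def test_bridge_values_between_endpoints(self, rng):
        a = TimeSeriesGait(rng.uniform(0, 1, (30, 4)))
        b = TimeSeriesGait(rng.uniform(0, 1, (30, 4)))
        cfg = StitchConfig(bridge_choices=(2,))
        out = stitch([a, b], cfg)
        bridge = out.gait[30:32]
        lo = np.minimum(a.gait[-1], b.gait[0])
        hi = np.maximum(a.gait[-1], b.gait[0])
        assert np.all(bridge >= lo - 1e-12) and np.all(bridge <= hi + 1e-12)

    def test_no_jump_exceeds_endpoint_gap(self, rng):
        parts = [TimeSeriesGait(np.cumsum(rng.normal(0, 0.01, (40, 4)), 0) + 0.5)
                 for _ in range(4)]
        out = stitch(parts, StitchConfig(seed=0))
        gaps = [np.abs(a.gait[-1] - b.gait[0]) for a, b in zip(parts, parts[1:])]
        max_gap = np.max(gaps)
        internal = np.abs(np.diff(out.gait, axis=0)).max()
        own = max(np.abs(np.diff(p.gait, axis=0)).max() for p in parts)
        assert internal <= max(max_gap, own) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            stitch([])

    def test_bridging_reduces_junction_discontinuity(self):
        # two flat segments at different levels: without bridging the join
        # jumps by the full gap; with bridging the largest step shrinks
        a = self._series(40, 0.2)
        b = self._series(40, 0.8)
        unbridged = stitch([a, b], StitchConfig(bridge_choices=(0,)))
        bridged = stitch([a, b], StitchConfig(bridge_choices=(2,)))
        jump = lambda ts: np.abs(np.diff(ts.gait, axis=0)).max()
        assert jump(unbridged) == pytest.approx(0.6)
        assert jump(bridged) < jump(unbridged)
        assert jump(bridged) == pytest.approx(0.2)  # gap split in thirds


class TestImpedance:
    @pytest.mark.parametrize("joint", ["knee", "ankle"])
    def test_profile_bounds_and_periodicity(self, joint):
        prof = impedance_profile(joint)
        phases = np.linspace(0, 100, 401)
        curves = prof.curves(phases)
        assert np.all(curves >= 0.0) and np.all(curves <= 1.0)
        assert np.allclose(curves[0], curves[-1], atol=1e-9)

    def test_profile_hits_knot_values(self):
        prof = impedance_profile("knee")
        phases, values = prof.stiffness_knots
        assert np.allclose(prof.curves(np.asarray(phases))[:, 0], values)

    def test_unknown_joint_rejected(self):
        with pytest.raises(InvalidSpecError):
            impedance_profile("hip")

    @pytest.mark.parametrize(
        "joint,kind,norm,expected",
        [
            ("knee", "stiffness", 0.0, 1.5),
            ("knee", "stiffness", 1.0, 5.0),
            ("knee", "stiffness", 0.5, 3.25),
            ("knee", "damping", 0.0, 0.05),
            ("knee", "damping", 1.0, 0.5),
            ("ankle", "stiffness", 0.0, 3.0),
            ("ankle", "stiffness", 1.0, 8.0),
            ("ankle", "damping", 0.0, 0.05),
            ("ankle", "damping", 1.0, 0.15),
        ],
    )
    def test_scale_to_physical_endpoints(self, joint, kind, norm, expected):
        assert scale_to_physical(norm, joint, kind) == pytest.approx(expected)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert scale_to_physical(1.5, "knee", "stiffness") == 5.0
        with pytest.warns(UserWarning):
            assert scale_to_physical(-0.2, "ankle", "damping") == 0.05


@pytest.fixture(scope="module")
def datasets(lgw_sketch):
    from gaitforge.core import interpolate_input

    preset = ModePreset("lgw", (1.0, 1.25), variations=4, datasets=3)
    return preset, build_dataset(
        preset, interpolate_input, lgw_sketch, seed=21,
        stitch_cfg=StitchConfig(seed=21),
    )


class TestBuildDataset:
    def test_counts_and_alignment(self, datasets):
        preset, series = datasets
        assert len(series) == preset.datasets
        for ts in series:
            assert ts.impedance is not None
            assert ts.impedance.shape == ts.gait.shape

    def test_durations_within_preset_bounds(self, datasets):
        preset, series = datasets
        # each dataset: variations segments + bridges of 1 or 2 samples
        lo = preset.variations * round(1.0 / 0.005)
        hi = preset.variations * round(1.25 / 0.005) + 2 * (preset.variations - 1)
        for ts in series:
            assert lo <= len(ts) <= hi

    def test_deterministic_with_same_seed(self, lgw_sketch):
        from gaitforge.core import interpolate_input

        preset = ModePreset("lgw", (1.0, 1.25), variations=2, datasets=1)
        a = build_dataset(preset, interpolate_input, lgw_sketch, seed=5,
                          stitch_cfg=StitchConfig(seed=5))
        b = build_dataset(preset, interpolate_input, lgw_sketch, seed=5,
                          stitch_cfg=StitchConfig(seed=5))
        assert np.array_equal(a[0].gait, b[0].gait)
        assert np.array_equal(a[0].impedance, b[0].impedance)

    def test_mode_presets_durations(self):
        assert MODE_PRESETS["lgw"].duration_range == (1.0, 1.25)
        assert MODE_PRESETS["sts"].duration_range == (5.0, 6.25)
        assert MODE_PRESETS["lgw"].variations == 60
        assert MODE_PRESETS["lgw"].datasets == 10
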