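"""Analytic and determinism checks on the synthetic scene generator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchcontact.errors import InvalidSpecError
from patchcontact.synthscene import (
    NeuronSpec,
    SceneSpec,
    TraceSpec,
    descent_schedule,
    make_cunet_dataset,
    render_focus_stack,
    render_neuron_stack,
    render_pipette_frame,
    simulate_resistance_trace,
)


def _local_minima_plateaus(profile):
    """Brute-force plateau-compressed strict local minima of a 1D profile."""
    vals, runs = [], []
    for v in profile:
        if not vals or v != vals[-1]:
            vals.append(v)
            runs.append(1)
        else:
            runs[-1] += 1
    minima = []
    for i in range(1, len(vals) - 1):
        if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            minima.append(vals[i])
    return minima


class TestPipetteRendering:
    def test_deterministic_under_fixed_seed(self):
        spec = SceneSpec(seed=7)
        a = render_pipette_frame(spec, 3.0)
        b = render_pipette_frame(spec, 3.0)
        assert np.array_equal(a, b)

    def test_zero_blur_limit_is_focal_independent(self):
        spec = SceneSpec(blur_per_um=0.0, noise_sd=0.0)
        frames = [render_pipette_frame(spec, z) for z in (-20.0, 0.0, 13.0)]
        assert np.array_equal(frames[0], frames[1])
        assert np.array_equal(frames[0], frames[2])

    def test_tip_column_profile_single_dark_valley(self, quiet_scene):
        """The tip column shows one grayscale valley below 80% of the
        background, flanked by two sub-background wall bands."""
        frame = render_pipette_frame(quiet_scene, quiet_scene.pipette_tip_z)
        col = frame[:, int(round(quiet_scene.pipette_tip_xy[0]))].astype(float)
        bg = quiet_scene.background_level
        minima = _local_minima_plateaus(col.tolist())
        deep = [m for m in minima if m < 0.8 * bg]
        assert len(deep) == 1
        # flanking bands: darker than background but brighter than the valley
        y = int(round(quiet_scene.pipette_tip_xy[1]))
        bands = col[[y - 4, y + 4]]
        assert np.all(bands < 0.95 * bg) and np.all(bands > deep[0])

    def test_region_right_of_tip_is_pure_background(self, quiet_scene):
        frame = render_pipette_frame(quiet_scene, quiet_scene.pipette_tip_z)
        right = frame[:, int(quiet_scene.pipette_tip_xy[0]) + 3 :]
        assert np.all(right == int(round(quiet_scene.background_level)))

    def test_degenerate_image_size_rejected(self):
        with pytest.raises(InvalidSpecError):
            SceneSpec(image_size=(16, 320))

    def test_tip_outside_bounds_rejected(self):
        with pytest.raises(InvalidSpecError):
            SceneSpec(pipette_tip_xy=(500.0, 10.0))


class TestFocusStack:
    def test_frame_count_and_monotone_z(self):
        stack = render_focus_stack(SceneSpec(), (-25.0, 25.0), 1.0)
        assert len(stack) == 51
        assert np.all(np.diff(stack.z_um) > 0)

    def test_frames_below_tip_are_identical_without_noise(self, quiet_scene):
        """Raising the focal plane below the tip changes nothing: the whole
        pipette is still beyond the plane, so there is no motion."""
        stack = render_focus_stack(quiet_scene, (-25.0, -1.0), 4.0)
        for frame in stack.frames[1:]:
            assert np.array_equal(frame, stack.frames[0])

    def test_empty_or_disordered_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            render_focus_stack(SceneSpec(), (5.0, -5.0), 1.0)
        with pytest.raises(InvalidSpecError):
            render_focus_stack(SceneSpec(), (0.0, 10.0), -1.0)


class TestNeuronStack:
    def test_ellipsoid_area_profile(self):
        """A neuron with depth semi-axis 4 um centred at z=25 is visible in
        planes 22..28 (strictly inside its extent) with the largest
        cross-section at 25, by brute-force pixel counting."""
        scene = SceneSpec(noise_sd=0.0)
        neuron = NeuronSpec(center_xy=(160.0, 160.0), center_z=25.0,
                            semi_axes=(4.0, 4.0, 4.0))
        z_list = np.arange(19.0, 32.0)
        stack = render_neuron_stack([neuron], scene, z_list)
        thresh = scene.background_level - neuron.intensity_contrast / 2
        areas = {z: int((f < thresh).sum()) for z, f in stack}
        visible = sorted(z for z, a in areas.items() if a > 0)
        assert visible == [22.0, 23.0, 24.0, 25.0, 26.0, 27.0, 28.0]
        assert max(areas, key=areas.get) == 25.0

    def test_impurity_spans_at_most_three_planes(self):
        scene = SceneSpec(noise_sd=0.0)
        imp = NeuronSpec(center_xy=(100.0, 100.0), center_z=25.0,
                         semi_axes=(3.0, 3.0, 1.4), is_impurity=True)
        stack = render_neuron_stack([imp], scene, np.arange(20.0, 31.0))
        thresh = scene.background_level - imp.intensity_contrast / 2
        visible = [z for z, f in stack if (f < thresh).sum() > 0]
        assert 0 < len(visible) <= 3

    def test_empty_spec_list_gives_pure_background(self):
        scene = SceneSpec(noise_sd=0.0)
        stack = render_neuron_stack([], scene, [1.0, 2.0])
        assert np.all(stack.frames == int(round(scene.background_level)))

    def test_default_grid_is_50_planes_at_1um(self):
        z = np.arange(1.0, 51.0)
        stack = render_neuron_stack([], SceneSpec(noise_sd=0.0), z)
        assert len(stack) == 50
        assert np.allclose(np.diff(stack.z_um), 1.0)


class TestCunetDataset:
    def test_counts_labels_and_determinism(self, train_scene):
        levels = np.arange(0.0, 11.0)
        data = make_cunet_dataset(train_scene, 2, levels, seed=5)
        assert len(data) == 22  # 11 samples per cell
        labels = [lab for _, _, lab in data[:11]]
        assert labels[0] == 0.0 and labels[-1] == 1.0
        assert np.allclose(np.diff(labels), 0.1)
        again = make_cunet_dataset(train_scene, 2, levels, seed=5)
        assert np.array_equal(data[3][0], again[3][0])
        assert np.array_equal(data[3][1], again[3][1])
        for roi, mask, _ in data[:2]:
            assert roi.shape == (128, 128) and mask.shape == (128, 128)
            assert mask.dtype == bool

    def test_out_of_range_levels_rejected(self, train_scene):
        with pytest.raises(InvalidSpecError):
            make_cunet_dataset(train_scene, 1, [12.0], seed=0)


class TestResistanceTrace:
    def test_constant_before_contact(self):
        tspec = TraceSpec(bath_resistance=5.0, contact_z=-100.0)
        descent = descent_schedule(10.0, 0.0)
        trace = simulate_resistance_trace(tspec, descent)
        assert np.all(trace.resistance == 5.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        bath=st.floats(3.0, 9.0),
        rise=st.floats(0.05, 0.4),
        plateau=st.floats(0.05, 0.45),
        regime=st.sampled_from(["plateau", "continue_rising"]),
    )
    def test_quantisation_and_monotone_rise(self, bath, rise, plateau, regime):
        tspec = TraceSpec(bath_resistance=bath, rise_per_um=rise,
                          plateau_delta_r=plateau, regime=regime, contact_z=2.0)
        trace = simulate_resistance_trace(tspec, descent_schedule(8.0, -2.0))
        grid = np.round(trace.resistance / 0.1) * 0.1
        assert np.allclose(trace.resistance, grid, atol=1e-9)
        assert np.all(np.diff(trace.resistance) >= -1e-9)
        if regime == "plateau":
            assert trace.resistance.max() - trace.bath_resistance <= plateau + 0.051

    def test_rise_below_half_mohm_at_contact_depth(self):
        """At the moment of first contact the quantised rise is < 0.5 MOhm
        for any valid spec (the declared-contact window is entered at the
        contact plane, before deeper penetration accumulates)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            tspec = TraceSpec(
                bath_resistance=round(float(rng.uniform(3, 8)), 1),
                rise_per_um=float(rng.uniform(0.1, 0.4)),
                plateau_delta_r=float(rng.uniform(0.1, 0.45)),
                regime="plateau" if seed % 2 else "continue_rising",
                contact_z=0.0,
            )
            descent = descent_schedule(5.0, -0.4, dt_s=0.25)
            trace = simulate_resistance_trace(tspec, descent)
            at_contact = trace.resistance[np.argmin(np.abs(
                np.asarray([z for _, z in descent])))]
            assert at_contact - tspec.bath_resistance < 0.5

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            TraceSpec(bath_resistance=-1.0)
        with pytest.raises(InvalidSpecError):
            TraceSpec(quantization=0.0)
        with pytest.raises(InvalidSpecError):
            simulate_resistance_trace(TraceSpec(), [(0.0, 5.0), (0.0, 4.0)])
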