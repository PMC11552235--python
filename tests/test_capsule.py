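"""Capsule volume integral, surface-layer statistics, and detectability."""

from dataclasses import replace

import numpy as np
import pytest

from sandplume.capsule import (
    ConcentrationField,
    capsule_concentration,
    detect_onset,
    detectability_map,
    field_over_grid,
    surface_layer_profile,
)
from sandplume.diffusion import point_source_free
from sandplume.params import PhysicalParams, ellipsoid_volume


class TestPhysicalParams:
    def test_nonpositive_fields_rejected(self):
        with pytest.raises(ValueError, match="c0"):
            PhysicalParams(c0=-1.0)

    def test_volume_axis_consistency_enforced_when_derived(self):
        with pytest.raises(ValueError, match="inconsistent"):
            PhysicalParams(V=1e-6, volume_from_axes=True)
        p = PhysicalParams.from_axes()
        assert p.V == pytest.approx(ellipsoid_volume(p.a_major, p.a_minor))

    def test_capsule_poking_through_surface_warns(self):
        with pytest.warns(UserWarning, match="buried"):
            PhysicalParams(depth_l=2e-3)

    def test_source_density_scales_with_configured_volume(self):
        # V = 1 mL of capsule solution spread over a ~0.33 mL ellipsoid
        p = PhysicalParams()
        assert p.total_moles == pytest.approx(p.c0 * 1e-6)
        assert p.source_density == pytest.approx(p.c0 * 1e-6 / p.geometric_volume)


class TestInitialCondition:
    def test_t0_values_inside_outside_boundary(self, consistent_params):
        p = consistent_params
        centre = (0.0, 0.0, p.depth_l)
        outside = (0.0, 0.0, p.depth_l - 5e-3)
        boundary = (0.0, 0.0, p.depth_l - p.a_minor / 2.0)
        assert capsule_concentration(p, centre, 0.0) == pytest.approx(p.c0)
        assert capsule_concentration(p, outside, 0.0) == 0.0
        assert capsule_concentration(p, boundary, 0.0) == pytest.approx(p.c0 / 2.0)

    def test_small_time_limit_recovers_initial_density(self, consistent_params):
        p = consistent_params
        c = capsule_concentration(p, (0.0, 0.0, p.depth_l), 1e-3)
        assert c == pytest.approx(p.c0, rel=0.01)
        c_out = capsule_concentration(p, (0.0, 0.0, p.depth_l - 5e-3), 1e-3)
        assert c_out <= 1e-6 * p.c0


class TestQuadrature:
    def test_far_field_matches_point_source(self, consistent_params):
        # once sqrt(4Dt) dwarfs the capsule, the ellipsoid acts as a point
        p, t = consistent_params, 2.0e6
        probe = (0.15, 0.0, p.depth_l)
        c = capsule_concentration(p, probe, t)
        pt = point_source_free(p.total_moles, (0, 0, p.depth_l), probe, p.D, t)
        assert c == pytest.approx(pt, rel=0.01)

    def test_dirichlet_bounded_by_free_everywhere_in_sand(self, capsule_params):
        p, t = capsule_params, 600.0
        x = np.linspace(-10e-3, 10e-3, 5)
        z = np.linspace(0.5e-3, 10e-3, 5)
        free = field_over_grid(p, x, x, z, [t], "free_interface")
        diri = field_over_grid(p, x, x, z, [t], "dirichlet")
        peak = free.values.max()
        assert np.all(diri.values <= free.values + 1e-9 * peak)
        assert np.all(diri.values >= -1e-9 * peak)


class TestConcentrationField:
    def test_unsorted_coordinates_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ConcentrationField(
                x=np.array([1.0, 0.0]), y=np.array([0.0]), z=np.array([0.0]),
                t=np.array([1.0]), values=np.zeros((1, 1, 1, 2)),
                scenario="free_interface",
            )

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ConcentrationField(
                x=np.array([0.0]), y=np.array([0.0]), z=np.array([0.0]),
                t=np.array([1.0]), values=np.full((1, 1, 1, 1), -1.0),
                scenario="free_interface",
            )

    def test_long_format_export(self, capsule_params):
        f = surface_layer_profile(capsule_params, [0.0, 1e-3], [0.0], [600.0])
        df = f.to_dataframe()
        assert list(df.columns) == ["scenario", "t", "x", "y", "z", "c"]
        assert len(df) == 2


class TestSurfaceLayer:
    def test_profile_peaks_above_capsule_centre(self, capsule_params):
        x = np.linspace(-12e-3, 12e-3, 7)
        f = surface_layer_profile(capsule_params, x, [0.0], [900.0])
        assert int(np.argmax(f.values[0, 0, 0])) == 3  # centre column

    def test_free_interface_dominates_dirichlet(self, capsule_params):
        x = np.linspace(-8e-3, 8e-3, 5)
        ff = surface_layer_profile(capsule_params, x, [0.0], [900.0], "free_interface")
        fd = surface_layer_profile(capsule_params, x, [0.0], [900.0], "dirichlet")
        assert np.all(fd.values <= ff.values * (1 + 1e-9) + 1e-15)

    def test_early_times_are_subthreshold(self, capsule_params):
        # burial depth far exceeds sqrt(D t): the initial transient
        x = np.linspace(-8e-3, 8e-3, 5)
        f = surface_layer_profile(capsule_params, x, [0.0], [5.0])
        assert np.all(f.values < capsule_params.c_star)

    def test_empty_grid_rejected(self, capsule_params):
        with pytest.raises(ValueError, match="empty"):
            surface_layer_profile(capsule_params, [], [0.0], [60.0])


class TestDetectability:
    def test_unreachable_threshold_reports_no_onset(self, capsule_params):
        p = replace(capsule_params, c_star=1e6, t_max=300.0)
        res = detect_onset(p, n_scan=10)
        assert not res.detected_within_t_max
        assert res.onset_time is None
        assert res.peak_surface_conc < p.c_star

    def test_detection_with_paper_parameters(self, capsule_params):
        res = detect_onset(capsule_params, n_scan=15, time_resolution=5.0)
        assert res.detected_within_t_max
        assert 0.0 < res.onset_time <= capsule_params.t_max
        assert res.peak_surface_conc >= capsule_params.c_star

    def test_single_entry_sweep_matches_detect_onset(self, capsule_params):
        kwargs = dict(n_scan=10, time_resolution=30.0)
        sweep = detectability_map(capsule_params, [capsule_params.c0],
                                  [capsule_params.depth_l], **kwargs)
        single = detect_onset(capsule_params, **kwargs)
        assert len(sweep) == 1
        assert sweep[0] == single

    def test_detected_region_monotone_in_concentration_and_depth(self, capsule_params):
        c0s = [0.03, 0.3, 3.0, 30.0]
        depths = [4e-3, 5e-3, 7e-3, 10e-3]
        res = detectability_map(capsule_params, c0s, depths,
                                n_scan=12, time_resolution=30.0)
        grid = {(c, d): r for (c, d), r in
                zip([(c, d) for c in c0s for d in depths], res)}
        for (c, d), r in grid.items():
            if r.detected_within_t_max:
                for c2 in c0s:
                    for d2 in depths:
                        if c2 >= c and d2 <= d:
                            assert grid[(c2, d2)].detected_within_t_max
        # onset non-decreasing with depth at fixed concentration
        for c in c0s:
            onsets = [grid[(c, d)].onset_time for d in depths]
            known = [o for o in onsets if o is not None]
            assert known == sorted(known)

    def test_empty_sweep_rejected(self, capsule_params):
        with pytest.raises(ValueError):
            detectability_map(capsule_params, [], [5e-3])
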