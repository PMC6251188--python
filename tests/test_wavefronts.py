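import numpy as np
import pytest

from fibwave.movie_io import RunConfig
from fibwave.phase_analysis import wrap_phase
from fibwave.singularities import DensityMap
from fibwave.wavefronts import (CLASS_NEW_EXISTING, CLASS_NEW_QUIESCENCE,
                                CLASS_PROPAGATED, WavefrontEvent, classify_wavefront,
                                detect_new_wavefronts, find_nwf_sites,
                                isophase_pixels, label_wavefronts, nwf_density_map,
                                site_cycle_lengths)


def oracle_isophase(phase, theta, band, mask):
    h, w = phase.shape
    out = np.zeros((h, w), bool)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            if not (theta - band <= phase[r, c] <= theta):
                continue
            n = 0
            for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                        and phase[rr, cc] > theta:
                    n += 1
            out[r, c] = 1 <= n <= 3
    return out


class TestIsophasePixels:
    theta = -np.pi / 2
    band = 0.5

    def test_plane_wave_band(self):
        w = 40
        phase = np.tile(np.linspace(-np.pi + 0.01, np.pi - 0.01, w), (20, 1))
        mask = np.ones((20, w), bool)
        active = isophase_pixels(phase, self.theta, self.band, mask)
        expected = oracle_isophase(phase, self.theta, self.band, mask)
        np.testing.assert_array_equal(active, expected)
        cols = np.unique(np.nonzero(active)[1])
        assert 1 <= len(cols) <= 4
        assert np.all(np.abs(phase[10, cols] - self.theta) <= self.band)

    def test_uniform_field_at_theta_inactive(self):
        phase = np.full((10, 10), self.theta)
        active = isophase_pixels(phase, self.theta, self.band)
        assert not active.any()

    def test_spiral_frame_matches_oracle(self):
        from fibwave.synthetic import analytic_spiral_movie

        pm, _, _ = analytic_spiral_movie(10.0, (32, 20), 10.0, grid=(64, 40),
                                         wavenumber=0.3)
        frame = pm.phase[5]
        active = isophase_pixels(frame, self.theta, self.band, pm.mask)
        expected = oracle_isophase(frame, self.theta, self.band, pm.mask)
        np.testing.assert_array_equal(active, expected)
        assert active.sum() > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fields_match_oracle(self, seed):
        from fibwave.synthetic import random_smooth_phase

        phase = random_smooth_phase((24, 24), sigma=2.0, seed=seed)
        mask = np.ones((24, 24), bool)
        mask[::7, ::5] = False
        np.testing.assert_array_equal(
            isophase_pixels(phase, self.theta, self.band, mask),
            oracle_isophase(phase, self.theta, self.band, mask))

    def test_theta_near_branch_cut_rejected(self):
        with pytest.raises(ValueError):
            isophase_pixels(np.zeros((5, 5)), np.pi - 0.1, 0.5)


class TestLabelWavefronts:
    def test_two_disjoint_bands(self):
        active = np.zeros((10, 10), bool)
        active[:, 2] = True
        active[:, 7] = True
        comps = label_wavefronts(active)
        assert len(comps) == 2

    def test_empty_mask(self):
        assert label_wavefronts(np.zeros((5, 5), bool)) == []

    def test_min_size_filter(self):
        active = np.zeros((10, 10), bool)
        active[0, 0] = True
        active[5, 5:8] = True
        comps = label_wavefronts(active, min_component_px=2)
        assert len(comps) == 1
        assert len(comps[0]) == 3

    def test_matches_flood_fill_oracle(self, rng):
        active = rng.random((20, 20)) < 0.3

        def flood(start, seen):
            stack = [start]
            comp = set()
            while stack:
                r, c = stack.pop()
                if (r, c) in seen or not (0 <= r < 20 and 0 <= c < 20) \
                        or not active[r, c]:
                    continue
                seen.add((r, c))
                comp.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        stack.append((r + dr, c + dc))
            return comp

        seen = set()
        expected = []
        for r, c in zip(*np.nonzero(active)):
            if (r, c) not in seen:
                expected.append(flood((int(r), int(c)), seen))
        got = label_wavefronts(active)
        assert sorted(map(sorted, got)) == sorted(map(sorted, expected))


class TestDetectNewWavefronts:
    def test_focal_onset_after_quiescence_all_new(self):
        prev = np.zeros((20, 20), bool)
        cur = np.zeros((20, 20), bool)
        cur[10, 10:13] = True
        new = detect_new_wavefronts(cur, prev, 3)
        np.testing.assert_array_equal(new, cur)

    def test_advancing_plane_wave_propagated(self):
        prev = np.zeros((20, 20), bool)
        prev[:, 5] = True
        cur = np.zeros((20, 20), bool)
        cur[:, 6] = True
        new = detect_new_wavefronts(cur, prev, 3)
        assert not new.any()

    def test_second_front_beyond_radius_is_new(self):
        prev = np.zeros((30, 30), bool)
        prev[:, 3] = True
        cur = np.zeros((30, 30), bool)
        cur[:, 4] = True       # advance of the first front
        cur[15, 25] = True     # far-away new front
        new = detect_new_wavefronts(cur, prev, 3)
        # oracle: per-pixel neighbourhood check
        for r, c in zip(*np.nonzero(cur)):
            window = prev[max(0, r - 3):r + 4, max(0, c - 3):c + 4]
            assert new[r, c] == (not window.any())
        assert new[15, 25]
        assert not new[:, 4].any()

    def test_monotone_in_radius(self, rng):
        prev = rng.random((25, 25)) < 0.1
        cur = rng.random((25, 25)) < 0.2
        sizes = [detect_new_wavefronts(cur, prev, r).sum() for r in range(1, 6)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            detect_new_wavefronts(np.zeros((5, 5), bool), np.zeros((6, 5), bool))


class TestClassifyWavefront:
    def test_new_with_existing_activity(self):
        comp = {(5, 5), (5, 6)}
        labels = np.zeros((10, 10), bool)
        labels[5, 5] = labels[5, 6] = True
        assert classify_wavefront(comp, labels, prev_frame_active_count=12) \
            == CLASS_NEW_EXISTING

    def test_new_after_quiescence(self):
        comp = {(5, 5), (5, 6)}
        labels = np.zeros((10, 10), bool)
        labels[5, 5] = labels[5, 6] = True
        assert classify_wavefront(comp, labels, prev_frame_active_count=0) \
            == CLASS_NEW_QUIESCENCE

    def test_continuation_propagated(self):
        comp = {(5, 5), (5, 6), (5, 7)}
        labels = np.zeros((10, 10), bool)  # nothing new
        assert classify_wavefront(comp, labels, 40) == CLASS_PROPAGATED

    def test_tie_counts_as_new(self):
        comp = {(5, 5), (5, 6)}
        labels = np.zeros((10, 10), bool)
        labels[5, 5] = True  # exactly half new
        assert classify_wavefront(comp, labels, 3) == CLASS_NEW_EXISTING


class TestNWFDensityAndSites:
    @staticmethod
    def _event(frame, pixel, wf_class=CLASS_NEW_QUIESCENCE):
        return WavefrontEvent(frame=frame, pixels={pixel},
                              origin=(float(pixel[0]), float(pixel[1])),
                              wf_class=wf_class, component_id=frame)

    def test_twenty_events_one_pixel(self):
        events = [self._event(i, (8, 8)) for i in range(20)]
        dm = nwf_density_map(events, (16, 16))
        assert dm.total == 20
        assert dm.counts[8, 8] == 20

    def test_no_new_events_zero_map(self):
        events = [self._event(0, (3, 3), CLASS_PROPAGATED)]
        assert nwf_density_map(events, (8, 8)).total == 0

    def test_single_cluster_one_site(self, rng):
        events = []
        for i in range(50):
            r = int(np.clip(round(rng.normal(20, 1.0)), 0, 39))
            c = int(np.clip(round(rng.normal(25, 1.0)), 0, 39))
            events.append(self._event(i * 10, (r, c)))
        dm = nwf_density_map(events, (40, 40))
        sites = find_nwf_sites(dm, events=events)
        assert len(sites) == 1
        mean_r = np.mean([e.origin[0] for e in events])
        mean_c = np.mean([e.origin[1] for e in events])
        assert np.hypot(sites[0].centroid[0] - mean_r,
                        sites[0].centroid[1] - mean_c) <= 1.5

    def test_uniform_events_no_site(self):
        rng = np.random.default_rng(0)
        events = [self._event(i, (int(rng.integers(0, 40)), int(rng.integers(0, 40))))
                  for i in range(40)]
        dm = nwf_density_map(events, (40, 40))
        assert find_nwf_sites(dm) == []

    def test_two_clusters_two_sites(self):
        events = ([self._event(i, (8, 8)) for i in range(25)]
                  + [self._event(100 + i, (30, 32)) for i in range(25)])
        dm = nwf_density_map(events, (40, 40))
        sites = find_nwf_sites(dm, events=events)
        assert len(sites) == 2

    def test_site_cycle_lengths(self):
        events = [self._event(f, (8, 8)) for f in (0, 80, 160, 240)]
        dm = nwf_density_map(events, (16, 16))
        sites = find_nwf_sites(dm, events=events)
        assert len(sites) == 1
        cls = site_cycle_lengths(sites[0], events, dt_ms=1.0)
        assert cls == [80.0, 80.0, 80.0]
        assert float(np.median(cls)) == 80.0

    def test_harmonic_cycle_lengths(self):
        events = [self._event(f, (8, 8)) for f in (0, 80, 240)]
        dm = nwf_density_map(events, (16, 16))
        sites = find_nwf_sites(dm, events=events)
        cls = site_cycle_lengths(sites[0], events)
        assert cls == [80.0, 160.0]  # second interval at twice the base CL

    def test_single_event_empty_cls(self):
        from fibwave.wavefronts import NWFSite

        events = [self._event(0, (8, 8))]
        site = NWFSite(pixels={(8, 8)}, centroid=(8.0, 8.0))
        assert site_cycle_lengths(site, events) == []

    def test_single_isolated_event_is_not_a_site(self):
        events = [self._event(0, (8, 8))]
        assert find_nwf_sites(nwf_density_map(events, (16, 16))) == []
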