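import numpy as np
import pytest

from fibwave.phase_analysis import PhaseMovie, wrap_phase
from fibwave.singularities import (PSPoint, PSTrack, count_rotations, detect_ps,
                                   detect_ps_movie, ps_density_maps, ps_rate,
                                   topological_charge, track_ps)
from fibwave.synthetic import analytic_spiral_movie, random_smooth_phase


def oracle_charge(phase):
    """Independent loop-walk implementation of the ring integral."""
    h, w = phase.shape
    ring = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
    out = np.zeros((h, w))
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            total = 0.0
            for k in range(8):
                r0, c0 = ring[k]
                r1, c1 = ring[(k + 1) % 8]
                d = phase[r + r1, c + c1] - phase[r + r0, c + c0]
                while d > np.pi:
                    d -= 2 * np.pi
                while d <= -np.pi:
                    d += 2 * np.pi
                total += d
            out[r, c] = total
    return out


def vortex(shape, core, sign=1):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return wrap_phase(sign * np.arctan2(rr - core[0], cc - core[1]))


class TestTopologicalCharge:
    def test_ccw_vortex_plus_2pi(self):
        field = vortex((33, 33), (16, 16))
        ch = topological_charge(field)
        near = ch[15:18, 15:18]
        assert near.max() == pytest.approx(2 * np.pi, abs=0.5)
        assert abs(ch[3, 3]) < 0.1

    def test_mirrored_vortex_minus_2pi(self):
        field = vortex((33, 33), (16, 16), sign=-1)
        ch = topological_charge(field)
        assert ch[15:18, 15:18].min() == pytest.approx(-2 * np.pi, abs=0.5)

    def test_boundary_zero(self, rng):
        field = wrap_phase(rng.uniform(-np.pi, np.pi, (10, 10)))
        ch = topological_charge(field)
        assert np.all(ch[0, :] == 0)
        assert np.all(ch[:, -1] == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_walk_oracle(self, seed):
        field = random_smooth_phase((24, 24), sigma=3.0, seed=seed)
        np.testing.assert_allclose(topological_charge(field), oracle_charge(field),
                                   atol=1e-9)


class TestDetectPS:
    def test_single_vortex_one_ps(self):
        field = vortex((33, 33), (16, 16))
        pts = detect_ps(field, 3.0)
        assert len(pts) == 1
        assert pts[0].chirality == 1
        assert np.hypot(pts[0].row - 16, pts[0].col - 16) <= 1.0

    def test_plane_wave_no_ps(self):
        cc = np.arange(30, dtype=float)
        field = wrap_phase(np.tile(0.4 * cc, (30, 1)))
        assert detect_ps(field, 3.0) == []

    def test_two_opposite_vortices(self):
        rr, cc = np.mgrid[0:40, 0:40].astype(float)
        z1 = (cc - 10) + 1j * (rr - 20)
        z2 = (cc - 30) + 1j * (rr - 20)
        field = wrap_phase(np.angle(z1 * np.conj(z2)))
        pts = detect_ps(field, 3.0)
        assert len(pts) == 2
        assert sum(p.chirality for p in pts) == 0
        for p in pts:
            true = (20, 10) if p.chirality == 1 else (20, 30)
            assert np.hypot(p.row - true[0], p.col - true[1]) <= 1.0

    def test_mask_excludes_region(self):
        field = vortex((33, 33), (16, 16))
        mask = np.ones((33, 33), bool)
        mask[10:23, 10:23] = False  # cut out the core
        assert detect_ps(field, 3.0, mask=mask) == []

    def test_noise_robust_after_smoothing(self):
        from fibwave.phase_analysis import smooth_phase

        hits = 0
        n = 20
        for seed in range(n):
            rng = np.random.default_rng(seed)
            field = wrap_phase(vortex((33, 33), (16, 16))
                               + rng.normal(0, 0.2, (33, 33)))
            pm = smooth_phase(PhaseMovie(field[None], np.ones((33, 33), bool)), 9)
            pts = detect_ps(pm.phase[0], 3.0)
            if len(pts) >= 1 and min(np.hypot(p.row - 16, p.col - 16)
                                     for p in pts) <= 1.0:
                hits += 1
        assert hits >= 0.95 * n


class TestTrackPS:
    @staticmethod
    def _pt(frame, r, c, chi=1):
        return PSPoint(frame=frame, row=r, col=c, chirality=chi)

    def test_stationary_ps_single_track(self):
        frames = [[self._pt(t, 10.0, 10.0)] for t in range(100)]
        tracks = track_ps(frames, 5.0, 0)
        assert len(tracks) == 1
        assert tracks[0].lifetime_frames == 100

    def test_moving_ps_followed(self):
        frames = [[self._pt(t, 10.0 + 0.5 * t, 10.0)] for t in range(40)]
        tracks = track_ps(frames, 5.0, 0)
        assert len(tracks) == 1
        steps = np.diff([p.row for p in tracks[0].points])
        np.testing.assert_allclose(steps, 0.5, atol=1e-9)

    def test_distant_ps_not_cross_linked(self):
        frames = [[self._pt(t, 5.0, 5.0), self._pt(t, 5.0, 35.0)]
                  for t in range(20)]
        tracks = track_ps(frames, 5.0, 0)
        assert len(tracks) == 2
        for tr in tracks:
            cols = {p.col for p in tr.points}
            assert len(cols) == 1  # never jumps between the two sites

    def test_chirality_gating(self):
        frames = [[self._pt(0, 10.0, 10.0, 1)], [self._pt(1, 10.0, 10.0, -1)]]
        tracks = track_ps(frames, 5.0, 0)
        assert len(tracks) == 2

    def test_gap_frames(self):
        frames = [[self._pt(0, 10.0, 10.0)], [], [self._pt(2, 10.5, 10.0)]]
        assert len(track_ps(frames, 5.0, 0)) == 2
        assert len(track_ps(frames, 5.0, 1)) == 1


class TestCountRotations:
    def test_three_rotations(self):
        pm, _, truth = analytic_spiral_movie(10.0, (32, 20), 300.0, grid=(64, 40))
        tracks = track_ps(detect_ps_movie(pm, 3.0), 5.0, 0)
        tr = max(tracks, key=lambda t: t.lifetime_frames)
        rot = count_rotations(tr, pm)
        assert rot == pytest.approx(3.0, abs=0.1)
        assert tr.is_rotor

    def test_fraction_of_rotation(self):
        pm, _, _ = analytic_spiral_movie(10.0, (32, 20), 40.0, grid=(64, 40))
        tracks = track_ps(detect_ps_movie(pm, 3.0), 5.0, 0)
        tr = max(tracks, key=lambda t: t.lifetime_frames)
        rot = count_rotations(tr, pm)
        assert rot == pytest.approx(0.4, abs=0.1)
        assert not tr.is_rotor

    def test_static_field_zero_rotations(self):
        field = vortex((33, 33), (16, 16))
        pm = PhaseMovie(np.repeat(field[None], 50, axis=0), np.ones((33, 33), bool))
        tracks = track_ps(detect_ps_movie(pm, 3.0), 5.0, 0)
        rot = count_rotations(tracks[0], pm)
        assert rot == pytest.approx(0.0, abs=0.05)


class TestDensityAndRate:
    def test_stationary_track_maps(self):
        pts = [PSPoint(frame=t, row=10.0, col=12.0, chirality=1) for t in range(100)]
        traj, init, annih = ps_density_maps([PSTrack(points=pts)], (20, 20))
        assert traj.counts[10, 12] == 100
        assert traj.total == 100
        assert init.counts[10, 12] == 1
        assert annih.counts[10, 12] == 1

    def test_no_tracks_zero_maps(self):
        traj, init, annih = ps_density_maps([], (8, 8))
        assert traj.total == init.total == annih.total == 0

    def test_meandering_rotor_mass_on_path(self):
        n = 200
        ang = 2 * np.pi * np.arange(n) / 100.0
        core = np.stack([32 + 5 * np.sin(ang), 20 + 5 * np.cos(ang)], axis=1)
        pm, _, truth = analytic_spiral_movie(10.0, core, float(n), grid=(64, 40))
        tracks = track_ps(detect_ps_movie(pm, 3.0), 5.0, 0)
        traj, _, _ = ps_density_maps(tracks, (64, 40))
        rr, cc = np.nonzero(traj.counts)
        counts = traj.counts[rr, cc]
        d = np.array([min(np.hypot(r - tr[0], c - tr[1]) for tr in core)
                      for r, c in zip(rr, cc)])
        assert counts[d <= 3].sum() / counts.sum() >= 0.90

    def test_rate_definitional(self):
        # one PS in every frame over 1 cm^2 and dt 1 ms -> rate 1
        pts = [PSPoint(frame=t, row=5.0, col=5.0, chirality=1) for t in range(50)]
        tr = PSTrack(points=pts, rotations=2.0)
        mask = np.ones((10, 10), bool)  # 10x10 px at 1 mm pitch = 1 cm^2
        rates = ps_rate([tr], mask, 50.0, pitch_mm=1.0, dt_ms=1.0)
        assert rates["long"] == pytest.approx(1.0)
        assert rates["short"] == 0.0
        assert rates["all"] == pytest.approx(1.0)

    def test_rate_no_ps(self):
        mask = np.ones((10, 10), bool)
        rates = ps_rate([], mask, 50.0, pitch_mm=1.0)
        assert rates["all"] == 0.0

    def test_rate_zero_area(self):
        with pytest.raises(ValueError):
            ps_rate([], np.zeros((5, 5), bool), 10.0, pitch_mm=1.0)

    def test_rate_matches_hand_count(self):
        # two rotors coexisting for 30 of 60 frames
        a = PSTrack(points=[PSPoint(frame=t, row=2.0, col=2.0, chirality=1)
                            for t in range(60)], rotations=3.0)
        b = PSTrack(points=[PSPoint(frame=t, row=8.0, col=8.0, chirality=-1)
                            for t in range(30)], rotations=2.0)
        mask = np.ones((10, 10), bool)
        rates = ps_rate([a, b], mask, 60.0, pitch_mm=1.0, dt_ms=1.0)
        assert rates["long"] == pytest.approx((60 + 30) / 60 / 1.0)


class TestChiralityBalance:
    @pytest.mark.parametrize("seed", range(5))
    def test_net_chirality_zero_for_boundary_uniform_fields(self, seed):
        # build a field from vortex pairs; boundary-far fields wind to zero
        rng = np.random.default_rng(seed)
        rr, cc = np.mgrid[0:48, 0:48].astype(float)
        z = np.ones((48, 48), complex)
        for _ in range(2):
            r1, c1 = rng.uniform(15, 33, 2)
            r2, c2 = rng.uniform(15, 33, 2)
            if np.hypot(r1 - r2, c1 - c2) < 8:
                c2 += 10
            z *= ((cc - c1) + 1j * (rr - r1)) * np.conj((cc - c2) + 1j * (rr - r2))
        pts = detect_ps(wrap_phase(np.angle(z)), 3.0)
        assert sum(p.chirality for p in pts) == 0
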