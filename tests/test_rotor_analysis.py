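"""Phase-mapping, PS-detection and tracking tests on constructed fields."""

import numpy as np
import pytest

from atrialdt import rotor_analysis as ra
from atrialdt.ep_simulator import Recording


def _recording_from(frames, dt_ms=5.0, spacing=0.3):
    return Recording(
        frames=np.asarray(frames, dtype=np.float32),
        frame_interval_ms=dt_ms,
        t0_ms=0.0,
        spacing=spacing,
    )


def _phase_field_from(phases, dt_ms=5.0, spacing=0.3):
    ph = np.asarray(phases, dtype=np.float32)
    return ra.PhaseField(
        phase=ph,
        defined=np.ones(ph.shape[1:], dtype=bool),
        frame_interval_ms=dt_ms,
        t0_ms=0.0,
        tau_ms=50.0,
        spacing=spacing,
    )


class TestComputePhase:
    def test_sinusoid_advances_2pi_per_period(self):
        period_ms = 250.0
        dt = 5.0
        t = np.arange(0, 4000.0, dt)
        sig = 0.5 + 0.5 * np.sin(2 * np.pi * t / period_ms)
        frames = np.tile(sig[:, None, None], (1, 4, 4))
        rec = _recording_from(frames)
        pf = ra.compute_phase(rec, tau_ms=period_ms / 4)
        ph = np.unwrap(pf.phase[:, 2, 2].astype(float))
        cycles = (ph[-1] - ph[0]) / (2 * np.pi)
        expected = (len(ph) - 1) * dt / period_ms
        assert cycles == pytest.approx(expected, abs=0.15)

    def test_resting_node_flagged_undefined(self):
        frames = np.zeros((200, 6, 6), dtype=np.float32)
        frames[:, :3, :] = np.random.default_rng(0).random((200, 3, 6)).astype(np.float32)
        pf = ra.compute_phase(_recording_from(frames), tau_ms=25.0)
        assert not pf.defined[5, 5]
        assert pf.defined[0, 0]


class TestPSDetection:
    def test_single_pinwheel(self):
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        ph = np.arctan2(yy - 20.2, xx - 19.8)
        pos, charge = ra.detect_phase_singularities(ph, spacing=1.0)
        assert len(charge) == 1
        assert charge[0] == 1
        assert np.hypot(pos[0][0] - 19.8, pos[0][1] - 20.2) <= 1.0

    def test_planar_ramp_no_ps(self):
        yy, xx = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        ph = ((0.3 * xx + 0.1 * yy + np.pi) % (2 * np.pi)) - np.pi
        _, charge = ra.detect_phase_singularities(ph)
        assert len(charge) == 0

    def test_figure_of_eight_net_zero(self):
        yy, xx = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        ph = np.arctan2(yy - 30.4, xx - 15.5) - np.arctan2(yy - 30.4, xx - 45.5)
        ph = ((ph + np.pi) % (2 * np.pi)) - np.pi
        pos, charge = ra.detect_phase_singularities(ph, spacing=1.0)
        assert len(charge) == 2
        assert sorted(charge) == [-1, 1]
        assert charge.sum() == 0

    def test_matches_brute_force_winding(self):
        """Plaquette detector equals brute-force winding sums on random
        smooth phase fields (oracle equivalence, 100 fields)."""
        rng = np.random.default_rng(17)
        from scipy.ndimage import gaussian_filter

        for _ in range(100):
            a = gaussian_filter(rng.standard_normal((24, 24)), 2.0)
            b = gaussian_filter(rng.standard_normal((24, 24)), 2.0)
            ph = np.arctan2(a, b)
            pos, charge = ra.detect_phase_singularities(ph, spacing=1.0)
            found = {(tuple(p), int(c)) for p, c in zip(pos, charge)}
            brute = set()
            for i in range(23):
                for j in range(23):
                    loop = [ph[i, j], ph[i, j + 1], ph[i + 1, j + 1], ph[i + 1, j]]
                    w = 0.0
                    for k in range(4):
                        d = loop[(k + 1) % 4] - loop[k]
                        w += (d + np.pi) % (2 * np.pi) - np.pi
                    q = int(round(w / (2 * np.pi)))
                    if q != 0:
                        brute.add(((j + 0.5, i + 0.5), q))
            assert found == brute

    def test_charge_conservation_frame_to_frame(self):
        """Net topological charge changes only by pair creation/annihilation
        or boundary crossing: for an interior-confined drifting pinwheel the
        net charge is constant."""
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        charges = []
        for t in range(30):
            # increments chosen so the singular point never lands exactly on
            # a lattice node or edge (degenerate wrap)
            cx, cy = 15.3 + 0.19 * t, 20.4 + 0.17 * t
            ph = np.arctan2(yy - cy, xx - cx) + 0.2 * t
            ph = ((ph + np.pi) % (2 * np.pi)) - np.pi
            _, ch = ra.detect_phase_singularities(ph)
            charges.append(ch.sum())
        assert len(set(charges)) == 1


class TestTracking:
    def _pinwheel_frames(self, centers):
        yy, xx = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        out = []
        for (cx, cy) in centers:
            ph = np.arctan2(yy - cy, xx - cx)
            out.append(ph)
        return np.asarray(out)

    def test_stationary_ps_single_track(self):
        frames = self._pinwheel_frames([(20.3, 20.6)] * 100)
        pf = _phase_field_from(frames, spacing=1.0)
        tracks = ra.track_singularities(pf, gate_mm=2.0)
        assert len(tracks) == 1
        assert len(tracks[0].points) == 100

    def test_distant_ps_never_merged(self):
        yy, xx = np.meshgrid(np.arange(60), np.arange(80), indexing="ij")
        ph = np.arctan2(yy - 30.4, xx - 20.5) - np.arctan2(yy - 30.4, xx - 60.5)
        ph = ((ph + np.pi) % (2 * np.pi)) - np.pi
        frames = np.tile(ph[None], (50, 1, 1))
        pf = _phase_field_from(frames, spacing=1.0)
        tracks = ra.track_singularities(pf)
        assert len(tracks) == 2
        assert {t.charge for t in tracks} == {-1, 1}

    def test_annihilation_ends_both_tracks(self):
        yy, xx = np.meshgrid(np.arange(60), np.arange(80), indexing="ij")
        frames = []
        n_alive = 40
        for t in range(60):
            if t < n_alive:
                sep = max(20 - t, 1)
                ph = np.arctan2(yy - 30.4, xx - (40.2 - sep / 2)) - np.arctan2(
                    yy - 30.4, xx - (40.2 + sep / 2)
                )
            else:
                ph = 0.1 * xx  # wave with no singularities
            frames.append(((ph + np.pi) % (2 * np.pi)) - np.pi)
        pf = _phase_field_from(np.asarray(frames), spacing=1.0)
        tracks = [t for t in ra.track_singularities(pf, gate_mm=3.0) if len(t.points) > 5]
        assert len(tracks) == 2
        ends = {t.times_ms[-1] for t in tracks}
        assert len(ends) == 1  # both end at the annihilation frame
        assert sorted(t.charge for t in tracks) == [-1, 1]


class TestRotorExtraction:
    def _track(self, duration_s, drift_mm=0.0, n=None):
        n = n or int(duration_s * 200) + 1
        t = np.linspace(0, duration_s * 1000, n)
        x = np.linspace(0, drift_mm, n)
        tr = ra.PSTrack(charge=1)
        tr.times_ms = list(t)
        tr.points = [(xi, 10.0) for xi in x]
        return tr

    def test_short_track_excluded(self):
        assert ra.extract_rotors([self._track(4.0)]) == []

    def test_stationary_rotor(self):
        evs = ra.extract_rotors([self._track(6.0)])
        assert len(evs) == 1
        assert evs[0].meander_extent_mm == 0.0
        assert not evs[0].wide_meander
        assert evs[0].lifetime_s == pytest.approx(6.0)

    def test_wide_meander_flag_and_axis(self):
        evs = ra.extract_rotors([self._track(6.0, drift_mm=18.0)])
        assert evs[0].wide_meander
        assert evs[0].meander_extent_mm == pytest.approx(18.0)
        assert evs[0].principal_axis_rad == pytest.approx(0.0, abs=0.05)


class TestDominantFrequency:
    def test_synthetic_sinusoid(self):
        t = np.arange(0, 4000.0, 5.0)
        sig = np.sin(2 * np.pi * 3.6 * t / 1000.0)
        frames = np.tile(sig[:, None, None], (1, 4, 4)).astype(np.float32)
        rec = _recording_from(frames)
        f = ra.dominant_frequency(rec, np.ones((4, 4), dtype=bool))
        assert f == pytest.approx(3.6, abs=0.13)

    def test_paced_cycle_length(self):
        t = np.arange(0, 4000.0, 5.0)
        sig = ((t % 250.0) < 60.0).astype(float)  # 4 Hz pulse train
        frames = np.tile(sig[:, None, None], (1, 4, 4)).astype(np.float32)
        f = ra.dominant_frequency(_recording_from(frames), np.ones((4, 4), bool))
        assert f == pytest.approx(4.0, abs=0.13)

    def test_flat_signal_flagged(self):
        frames = np.zeros((800, 4, 4), dtype=np.float32)
        with pytest.raises(ValueError):
            ra.dominant_frequency(_recording_from(frames), np.ones((4, 4), bool))


class TestMatching:
    def _event(self, x, y):
        return ra.RotorEvent(
            trajectory=np.array([[x, y]]),
            times_ms=np.array([0.0]),
            chirality=1,
            birth_s=0.0,
            death_s=6.0,
            centroid=(x, y),
            meander_extent_mm=0.0,
            principal_axis_rad=0.0,
            wide_meander=False,
        )

    def test_identity_matching(self):
        evs = [self._event(10, 10), self._event(30, 30)]
        pairs, emergent = ra.match_rotor_locations(evs, evs)
        assert sorted(pairs) == [(0, 0), (1, 1)]
        assert emergent == []

    def test_distant_centroid_emergent(self):
        a = [self._event(10, 10)]
        b = [self._event(22, 10)]  # 12 mm away, radius 6
        pairs, emergent = ra.match_rotor_locations(a, b)
        assert pairs == []
        assert emergent == [0]

    def test_jittered_complete_matching(self):
        rng = np.random.default_rng(9)
        a = [self._event(10, 10), self._event(30, 12), self._event(18, 35)]
        b = [
            self._event(c[0] + rng.uniform(-2, 2), c[1] + rng.uniform(-2, 2))
            for c in [(30, 12), (18, 35), (10, 10)]
        ]
        pairs, emergent = ra.match_rotor_locations(a, b)
        assert len(pairs) == 3
        assert emergent == []
        mapping = dict(pairs)
        assert mapping[0] == 2 and mapping[1] == 0 and mapping[2] == 1
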