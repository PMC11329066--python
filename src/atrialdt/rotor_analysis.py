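"""Phase mapping, phase-singularity tracking and rotor summarization.

A rotor is operationally a phase singularity (PS) — a lattice point where
the activation phase winds by ±2π — whose trajectory persists for more
than 5 s. Phase is computed per node by time-delay embedding; PS points are
detected as ±2π winding of the wrapped phase difference around 2x2
plaquettes; trajectories come from greedy nearest-neighbour linking with a
displacement gate and short gap closing. Rotor location is the trajectory
centroid; widely meandering rotors (extent > 12 mm) are flagged so the
lesion becomes a covering ellipse along the meander axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .ep_simulator import Recording

__all__ = [
    "PhaseField",
    "PSPoint",
    "PSTrack",
    "RotorEvent",
    "compute_phase",
    "detect_phase_singularities",
    "track_singularities",
    "extract_rotors",
    "dominant_frequency",
    "match_rotor_locations",
    "analyze_recording",
]

PERSISTENCE_S = 5.0
WIDE_MEANDER_MM = 12.0
MATCH_RADIUS_MM = 6.0


@dataclass
class PhaseField:
    """Per-node activation phase in (-pi, pi] with an undefined-node mask."""

    phase: np.ndarray  # (T, ny, nx) radians
    defined: np.ndarray  # (ny, nx) bool: nodes with enough signal excursion
    frame_interval_ms: float
    t0_ms: float
    tau_ms: float
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)


def compute_phase(
    rec: Recording,
    tau_ms: float | None = None,
    min_excursion: float = 0.05,
) -> PhaseField:
    """Phase via time-delay embedding.

    phase(t) = atan2(V(t - tau) - Vbar, V(t) - Vbar) per node, with the
    node mean Vbar taken over a sliding 1-s window. Nodes whose signal
    excursion never exceeds ``min_excursion`` (resting tissue, lesions)
    are flagged undefined and excluded from PS detection. The embedding
    delay must stay within the action-potential pulse width for the
    embedded trajectory to encircle the node mean; the default (50 ms,
    about 40% of the calibrated model's action-potential duration) does.
    """
    if tau_ms is None:
        tau_ms = 50.0
    lag = int(round(tau_ms / rec.frame_interval_ms))
    v = rec.frames.astype(np.float32)
    if v.shape[0] <= lag:
        raise ValueError("recording shorter than the embedding delay")
    win = max(int(round(1000.0 / rec.frame_interval_ms)), 1)
    vbar = uniform_filter1d(v, size=win, axis=0, mode="nearest")
    a = v[lag:] - vbar[lag:]
    b = v[:-lag] - vbar[lag:]
    phase = np.arctan2(b, a).astype(np.float32)
    excursion = v.max(axis=0) - v.min(axis=0)
    defined = excursion > min_excursion
    phase[:, ~defined] = 0.0
    return PhaseField(
        phase=phase,
        defined=defined,
        frame_interval_ms=rec.frame_interval_ms,
        t0_ms=rec.t0_ms + lag * rec.frame_interval_ms,
        tau_ms=tau_ms,
        spacing=rec.spacing,
        origin=rec.origin,
    )


def _wrap(x: np.ndarray) -> np.ndarray:
    return (x + np.pi) % (2 * np.pi) - np.pi


def detect_phase_singularities(
    phase_frame: np.ndarray,
    defined: np.ndarray | None = None,
    spacing: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """PS positions (mm) and topological charges (+-1) in one phase frame.

    The winding number of the wrapped phase difference is accumulated
    counterclockwise around every 2x2 plaquette; a sum of +-2pi marks a
    singularity at the plaquette centre. Plaquettes touching undefined
    nodes are skipped.
    """
    p = phase_frame
    # counterclockwise around plaquette (i,j)->(i,j+1)->(i+1,j+1)->(i+1,j)
    d1 = _wrap(p[:-1, 1:] - p[:-1, :-1])
    d2 = _wrap(p[1:, 1:] - p[:-1, 1:])
    d3 = _wrap(p[1:, :-1] - p[1:, 1:])
    d4 = _wrap(p[:-1, :-1] - p[1:, :-1])
    winding = d1 + d2 + d3 + d4
    charge = np.rint(winding / (2 * np.pi)).astype(int)
    if defined is not None:
        ok = defined[:-1, :-1] & defined[:-1, 1:] & defined[1:, :-1] & defined[1:, 1:]
        charge = np.where(ok, charge, 0)
    ii, jj = np.nonzero(charge != 0)
    pos = np.column_stack([
        origin[0] + (jj + 0.5) * spacing,
        origin[1] + (ii + 0.5) * spacing,
    ])
    return pos, charge[ii, jj]


@dataclass
class PSPoint:
    t_ms: float
    xy: tuple[float, float]
    charge: int


@dataclass
class PSTrack:
    charge: int
    times_ms: list[float] = field(default_factory=list)
    points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def lifetime_s(self) -> float:
        if len(self.times_ms) < 2:
            return 0.0
        return (self.times_ms[-1] - self.times_ms[0]) / 1000.0


def track_singularities(
    field: PhaseField,
    gate_mm: float = 2.0,
    gap_ms: float = 20.0,
) -> list[PSTrack]:
    """Link per-frame PS detections into trajectories.

    Greedy nearest-neighbour assignment per frame within a displacement
    gate (same charge only); tracks unmatched for longer than ``gap_ms``
    are closed. Charge is conserved along a track by construction.
    """
    if field.frame_interval_ms > 10.0:
        raise ValueError("frame interval must be <= 10 ms for tracking")
    open_tracks: list[PSTrack] = []
    closed: list[PSTrack] = []
    for f in range(field.phase.shape[0]):
        t = field.t0_ms + f * field.frame_interval_ms
        pos, charges = detect_phase_singularities(
            field.phase[f], field.defined, field.spacing, field.origin
        )
        unmatched = list(range(len(charges)))
        # match open tracks to detections (greedy by distance)
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = np.array(tr.points[-1])
            for di in unmatched:
                if charges[di] != tr.charge:
                    continue
                d = float(np.hypot(*(pos[di] - last)))
                if d <= gate_mm:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t, used_d = set(), set()
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            open_tracks[ti].times_ms.append(t)
            open_tracks[ti].points.append(tuple(pos[di]))
        for di in unmatched:
            if di not in used_d:
                tr = PSTrack(charge=int(charges[di]))
                tr.times_ms.append(t)
                tr.points.append(tuple(pos[di]))
                open_tracks.append(tr)
        still_open = []
        for tr in open_tracks:
            if t - tr.times_ms[-1] > gap_ms:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
    closed.extend(open_tracks)
    return closed


@dataclass
class RotorEvent:
    """A persistent phase-singularity trajectory (lifetime > 5 s)."""

    trajectory: np.ndarray  # (n, 2) positions, mm
    times_ms: np.ndarray
    chirality: int
    birth_s: float
    death_s: float
    centroid: tuple[float, float]
    meander_extent_mm: float
    principal_axis_rad: float
    wide_meander: bool
    region: int | None = None

    @property
    def lifetime_s(self) -> float:
        return self.death_s - self.birth_s

    def to_dict(self) -> dict:
        return {
            "centroid": list(self.centroid),
            "chirality": self.chirality,
            "birth_s": self.birth_s,
            "death_s": self.death_s,
            "lifetime_s": self.lifetime_s,
            "meander_extent_mm": self.meander_extent_mm,
            "principal_axis_rad": self.principal_axis_rad,
            "wide_meander": self.wide_meander,
            "region": self.region,
            "trajectory": [list(p) for p in self.trajectory],
        }


def _meander_extent(points: np.ndarray) -> float:
    """Max pairwise trajectory distance (on a subsample for long tracks)."""
    if points.shape[0] > 400:
        idx = np.linspace(0, points.shape[0] - 1, 400).astype(int)
        points = points[idx]
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def extract_rotors(
    tracks: list[PSTrack],
    persistence_s: float = PERSISTENCE_S,
    region_label_field: np.ndarray | None = None,
    spacing: float | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> list[RotorEvent]:
    """Keep tracks persisting beyond the threshold and summarize them."""
    events = []
    for tr in tracks:
        if tr.lifetime_s <= persistence_s:
            continue
        pts = np.asarray(tr.points)
        centroid = tuple(map(float, pts.mean(axis=0)))
        extent = _meander_extent(pts)
        if pts.shape[0] >= 2 and extent > 0:
            centered = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = float(np.arctan2(vt[0, 1], vt[0, 0])) % np.pi
        else:
            axis = 0.0
        region = None
        if region_label_field is not None and spacing is not None:
            j = int(round((centroid[0] - origin[0]) / spacing))
            i = int(round((centroid[1] - origin[1]) / spacing))
            ny, nx = region_label_field.shape
            region = int(region_label_field[min(max(i, 0), ny - 1), min(max(j, 0), nx - 1)])
        events.append(
            RotorEvent(
                trajectory=pts,
                times_ms=np.asarray(tr.times_ms),
                chirality=tr.charge,
                birth_s=tr.times_ms[0] / 1000.0,
                death_s=tr.times_ms[-1] / 1000.0,
                centroid=centroid,
                meander_extent_mm=extent,
                principal_axis_rad=axis,
                wide_meander=extent > WIDE_MEANDER_MM,
                region=region,
            )
        )
    return events


def dominant_frequency(
    rec: Recording,
    probe_mask: np.ndarray,
    window_s: float = 3.0,
    resolution_hz: float = 0.25,
    band_hz: tuple[float, float] = (1.0, 15.0),
) -> float:
    """Peak spectral frequency of the mean probe signal over the final window.

    Zero-padded FFT to the requested resolution; searches the given band.
    Raises if the recording is too short or no peak rises above the noise
    floor (flat signal).
    """
    fs = 1000.0 / rec.frame_interval_ms
    n_need = int(window_s * fs)
    if rec.frames.shape[0] < n_need:
        raise ValueError("need >= 3 s of signal for dominant frequency")
    sig = rec.frames[-n_need:, probe_mask].mean(axis=1).astype(float)
    sig = sig - sig.mean()
    if np.ptp(sig) < 1e-6:
        raise ValueError("flat probe signal: dominant frequency undefined")
    n_fft = int(2 ** np.ceil(np.log2(fs / resolution_hz)))
    spec = np.abs(np.fft.rfft(sig * np.hanning(sig.size), n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return float(freqs[sel][np.argmax(spec[sel])])


def match_rotor_locations(
    events_a: list[RotorEvent],
    events_b: list[RotorEvent],
    radius_mm: float = MATCH_RADIUS_MM,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Greedy mutual-nearest centroid matching within a radius.

    Returns (pairs, emergent): ``pairs`` are (index_a, index_b) matches;
    ``emergent`` are indices in ``events_b`` with no counterpart in
    ``events_a`` (rotors at genuinely new locations).
    """
    if not events_a or not events_b:
        return [], list(range(len(events_b)))
    ca = np.array([e.centroid for e in events_a])
    cb = np.array([e.centroid for e in events_b])
    d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
    pairs = []
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for ia, ib in order:
        if d[ia, ib] > radius_mm:
            break
        if ia in used_a or ib in used_b:
            continue
        # mutual-nearest among unused
        pairs.append((int(ia), int(ib)))
        used_a.add(int(ia))
        used_b.add(int(ib))
    emergent = [i for i in range(len(events_b)) if i not in used_b]
    return pairs, emergent


def export_trajectories_vtk(events: list[RotorEvent], path) -> None:
    """Write rotor trajectories as VTK polylines for overlay rendering."""
    from ._vtk import write_polylines

    write_polylines(path, [e.trajectory for e in events])


def analyze_recording(
    rec: Recording,
    tau_ms: float | None = None,
    persistence_s: float = PERSISTENCE_S,
    region_label_field: np.ndarray | None = None,
) -> list[RotorEvent]:
    """Recording -> persistent rotors (phase, PS detection, tracking, filter)."""
    if rec.frames.shape[0] < 3:
        return []
    field_ = compute_phase(rec, tau_ms=tau_ms)
    tracks = track_singularities(field_)
    return extract_rotors(
        tracks,
        persistence_s=persistence_s,
        region_label_field=region_label_field,
        spacing=rec.spacing,
        origin=rec.origin,
    )
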