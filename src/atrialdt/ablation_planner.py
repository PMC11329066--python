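"""Virtual ablation planning: lesion-minimizing guided search.

Rotor-attracting locations are classified by probing the inducibility
oracle: a location whose rotor becomes non-inducible after ablating other
rotor locations is contingent (LCR) and can be spared; a location whose
rotor persists regardless is independent (LIR) and must itself be ablated.
The guided search ablates LIRs first, re-tests, classifies any emergent
rotors, and repeats until the substrate cannot sustain rotors from any
pacing site. The all-at-once comparator ablates every rotor location
without discerning types. Around each executed lesion, iatrogenic
atrial tachycardia (iAT) — macro-reentry circulating around the scar —
is screened for and, when present, eliminated by a connecting line to the
nearest non-conductive barrier.

Oracles are memoized; the scripted oracle answers from an exhaustive
dependency table (exact planner testing), the simulator oracle runs the
full pacing sweep per query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import ep_simulator as ep
from .rotor_analysis import (
    MATCH_RADIUS_MM,
    RotorEvent,
    analyze_recording,
    compute_phase,
    dominant_frequency,
)
from .synthetic_substrate import DependencyScript

__all__ = [
    "Lesion",
    "AblationPlan",
    "InducibilityOracle",
    "ScriptOracle",
    "SimulatorOracle",
    "OracleConsistencyError",
    "lesion_for_rotor",
    "script_oracle",
    "simulator_oracle",
    "classify_rotors",
    "guided_search",
    "all_at_once",
    "detect_iat",
    "classify_lesion_reentry",
    "connecting_line",
    "exhaustive_minimal_sets",
    "IATResult",
]

LESION_DIAMETER_MM = 12.0
PVI_BAND_WIDTH_MM = 7.5
CONNECTING_LINE_WIDTH_MM = 7.5
IAT_CONTOUR_OFFSET_MM = 2.0
IAT_MIN_CYCLES = 3


class OracleConsistencyError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Lesion geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lesion:
    """Ablation lesion: disc, covering ellipse, line or band.

    Discs default to 12 mm diameter; ellipses to a 12-mm minor axis with
    the major axis along the rotor meander; PVI-style bands are 7.5 mm wide.
    """

    shape: str  # disc | ellipse | line | band
    center: tuple[float, float] = (0.0, 0.0)  # mm
    diameter: float = LESION_DIAMETER_MM
    axes: tuple[float, float] = (LESION_DIAMETER_MM, LESION_DIAMETER_MM)  # (major, minor)
    orientation: float = 0.0  # rad
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None
    width: float = PVI_BAND_WIDTH_MM

    def to_mask(self, shape, spacing, origin=(0.0, 0.0)) -> np.ndarray:
        ny, nx = shape
        x = origin[0] + np.arange(nx) * spacing
        y = origin[1] + np.arange(ny) * spacing
        xx, yy = np.meshgrid(x, y)
        if self.shape == "disc":
            r2 = (xx - self.center[0]) ** 2 + (yy - self.center[1]) ** 2
            return r2 <= (self.diameter / 2.0) ** 2
        if self.shape == "ellipse":
            dx, dy = xx - self.center[0], yy - self.center[1]
            c, s = np.cos(self.orientation), np.sin(self.orientation)
            u = c * dx + s * dy
            v = -s * dx + c * dy
            return (u / (self.axes[0] / 2)) ** 2 + (v / (self.axes[1] / 2)) ** 2 <= 1.0
        if self.shape in ("line", "band"):
            if self.endpoints is None:
                raise ValueError("line/band lesion requires endpoints")
            (x1, y1), (x2, y2) = self.endpoints
            px, py = xx - x1, yy - y1
            ex, ey = x2 - x1, y2 - y1
            ll = ex * ex + ey * ey
            if ll == 0:
                d2 = px * px + py * py
            else:
                t = np.clip((px * ex + py * ey) / ll, 0.0, 1.0)
                d2 = (px - t * ex) ** 2 + (py - t * ey) ** 2
            return d2 <= (self.width / 2.0) ** 2
        raise ValueError(f"unknown lesion shape {self.shape!r}")


def lesion_for_rotor(event) -> Lesion:
    """Lesion covering one rotor location.

    Stationary / small-meander rotors get a 12-mm disc at the trajectory
    centroid; widely meandering rotors (> 12 mm extent) get a covering
    ellipse: 12-mm minor axis, major axis = meander extent + 6 mm margin,
    oriented along the meander principal axis. Accepts a RotorEvent or any
    object with ``location`` (e.g. a scripted RotorInfo).
    """
    if isinstance(event, RotorEvent):
        center = event.centroid
        if event.wide_meander:
            return Lesion(
                shape="ellipse",
                center=center,
                axes=(event.meander_extent_mm + 6.0, LESION_DIAMETER_MM),
                orientation=event.principal_axis_rad,
            )
        return Lesion(shape="disc", center=center)
    return Lesion(shape="disc", center=tuple(event.location))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

class InducibilityOracle:
    """Memoized inducibility-query contract.

    ``query(ablated_ids)`` returns the frozenset of rotor ids induced on
    the substrate after ablating the given rotor locations. Implementations
    expose ``rotor_info(rid)`` for lesion geometry / tie-break metadata.
    """

    def __init__(self) -> None:
        self._memo: dict[frozenset, frozenset] = {}
        self.query_log: list[dict] = []

    def query(self, ablated) -> frozenset:
        key = frozenset(ablated)
        if key not in self._memo:
            result = self._evaluate(key)
            self._memo[key] = result
            self.query_log.append({"ablated": sorted(key), "induced": sorted(result)})
        return self._memo[key]

    @property
    def n_queries(self) -> int:
        return len(self._memo)

    def _evaluate(self, key: frozenset) -> frozenset:  # pragma: no cover - abstract
        raise NotImplementedError

    def rotor_info(self, rid):
        raise NotImplementedError

    def is_emergent(self, rid) -> bool:
        raise NotImplementedError


class ScriptOracle(InducibilityOracle):
    """Oracle answering from an exhaustive DependencyScript table."""

    def __init__(self, script: DependencyScript):
        super().__init__()
        script.validate()
        self.script = script

    def _evaluate(self, key: frozenset) -> frozenset:
        return self.script.induce(key)

    def rotor_info(self, rid):
        return self.script.rotors[rid]

    def is_emergent(self, rid) -> bool:
        return self.script.rotors[rid].emergent


def script_oracle(script: DependencyScript) -> ScriptOracle:
    return ScriptOracle(script)


class SimulatorOracle(InducibilityOracle):
    """Oracle backed by the monodomain simulator.

    Each query applies the 12-mm lesions for the ablated rotor ids, runs
    the burst-pacing sweep over every protocol site, extracts persistent
    rotors, and matches their centroids against the rotor registry
    (6-mm radius); unmatched centroids are registered as emergent ids.
    """

    def __init__(
        self,
        tissue: ep.TissueModel,
        protocol: ep.PacingProtocol,
        match_radius_mm: float = MATCH_RADIUS_MM,
        persistence_s: float = 5.0,
    ):
        super().__init__()
        if not protocol.sites:
            raise ValueError("protocol must carry a site list")
        self.tissue = tissue
        self.protocol = protocol
        self.match_radius = match_radius_mm
        self.persistence_s = persistence_s
        self.registry: dict[str, RotorEvent] = {}
        self._native_ids: set[str] | None = None
        self._counter = 0

    def rotor_info(self, rid):
        return self.registry[rid]

    def is_emergent(self, rid) -> bool:
        if self._native_ids is None:
            raise RuntimeError("query the native substrate first")
        return rid not in self._native_ids

    def _sweep(self, tissue: ep.TissueModel) -> list[RotorEvent]:
        events: list[RotorEvent] = []
        for site in self.protocol.sites:
            if not tissue.conductive[site]:
                continue  # site swallowed by a lesion: nothing to pace
            rec = ep.run_pacing(tissue, self.protocol, site=site)
            for ev in analyze_recording(rec, persistence_s=self.persistence_s):
                # dedupe locations already seen in this sweep
                if all(
                    np.hypot(ev.centroid[0] - e.centroid[0], ev.centroid[1] - e.centroid[1])
                    > self.match_radius
                    for e in events
                ):
                    events.append(ev)
        return events

    def _evaluate(self, key: frozenset) -> frozenset:
        lesions = [lesion_for_rotor(self.registry[rid]) for rid in key]
        tissue = ep.apply_lesions(self.tissue, lesions) if lesions else self.tissue
        events = self._sweep(tissue)
        ids = set()
        for ev in events:
            match = None
            best = self.match_radius
            for rid, reg in self.registry.items():
                d = float(np.hypot(ev.centroid[0] - reg.centroid[0],
                                   ev.centroid[1] - reg.centroid[1]))
                if d <= best:
                    match, best = rid, d
            if match is None:
                self._counter += 1
                match = f"L{self._counter}"
                self.registry[match] = ev
            ids.add(match)
        if self._native_ids is None and not key:
            self._native_ids = set(ids)
        return frozenset(ids)


def simulator_oracle(tissue: ep.TissueModel, protocol: ep.PacingProtocol) -> SimulatorOracle:
    return SimulatorOracle(tissue, protocol)


# ---------------------------------------------------------------------------
# Classification and search
# ---------------------------------------------------------------------------

def classify_rotors(
    oracle: InducibilityOracle,
    base: frozenset = frozenset(),
) -> tuple[dict[str, str], dict[str, str]]:
    """Classify current rotors as LIR/LCR by guided probing.

    Single-lesion probes of every other rotor come first; if no probe
    suppresses any rotor (mutual independence at the single-lesion level),
    probing escalates to pairs, mirroring how the worked patient cases were
    adjudicated. Returns (classification, emergent_provenance): emergent
    rotors uncovered during probes map to the probe set that triggered them.
    """
    current = sorted(oracle.query(base))
    suppressed = {r: False for r in current}
    emergent_prov: dict[str, str] = {}

    def _probe(subset: tuple) -> None:
        res = oracle.query(base | set(subset))
        for r in current:
            if r not in subset and r not in res:
                suppressed[r] = True
        for rid in res:
            if rid not in current and rid not in base:
                emergent_prov.setdefault(rid, f"probe {sorted(set(subset))}")

    for r in current:
        _probe((r,))
    if len(current) > 2 and not any(suppressed.values()):
        for pair in combinations(current, 2):
            _probe(pair)

    classification = {r: ("LCR" if suppressed[r] else "LIR") for r in current}
    return classification, emergent_prov


@dataclass
class AblationPlan:
    """Ordered lesion set with classification and iAT annotations."""

    strategy: str
    lesion_ids: list[str] = field(default_factory=list)
    lesions: list[Lesion] = field(default_factory=list)
    classification: dict[str, str] = field(default_factory=dict)
    iat_annotations: dict[str, str] = field(default_factory=dict)
    connecting_lines: list[dict] = field(default_factory=list)
    final_inducible: bool = True
    query_log: list[dict] = field(default_factory=list)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    def to_json(self, path) -> None:
        obj = {
            "strategy": self.strategy,
            "lesion_ids": self.lesion_ids,
            "classification": self.classification,
            "iat_annotations": self.iat_annotations,
            "connecting_lines": self.connecting_lines,
            "final_inducible": self.final_inducible,
            "query_log": self.query_log,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _annotate_iat(oracle: InducibilityOracle, plan: AblationPlan) -> None:
    """Fill iAT annotations for ablated locations from oracle metadata."""
    for rid in plan.lesion_ids:
        info = oracle.rotor_info(rid)
        if not hasattr(info, "iat_flag"):
            plan.iat_annotations[rid] = "untested"  # needs detect_iat
        elif getattr(info, "barrier_contact", False):
            plan.iat_annotations[rid] = "barrier-contact"
        elif info.iat_flag:
            plan.iat_annotations[rid] = "iat"
        else:
            plan.iat_annotations[rid] = "no-iat"


def _fd_of(oracle: InducibilityOracle, rid: str) -> float:
    fd = getattr(oracle.rotor_info(rid), "fd", None)
    return -np.inf if fd is None else float(fd)


def guided_search(
    oracle: InducibilityOracle,
    tiebreak: str = "fd",
    max_iterations: int = 64,
) -> AblationPlan:
    """Lesion-minimizing guided search.

    Loop: classify the current rotors, ablate all LIRs; when rotors remain
    but none is independent (mutual contingency), ablate a single LCR
    chosen by the tie-break (highest regional fibrosis density, then lowest
    id); re-test; stop at non-inducibility. Terminates on every consistent
    oracle since each iteration ablates at least one rotor from a finite
    universe; a suppressed rotor reappearing raises OracleConsistencyError.
    """
    plan = AblationPlan(strategy="lesion-minimizing")
    base: frozenset = frozenset()
    emergent_seen: dict[str, str] = {}
    for _ in range(max_iterations):
        current = oracle.query(base)
        # contract check: a rotor absent (while unablated) from a probed
        # subset of the executed set must stay absent in the superset
        for s_prev, induced_prev in oracle._memo.items():
            if s_prev < base:
                reappeared = {
                    r for r in current if r not in s_prev and r not in induced_prev
                    and not oracle.is_emergent(r)
                }
                if reappeared:
                    raise OracleConsistencyError(
                        f"suppressed rotors reappeared: {sorted(reappeared)}"
                    )
        if not current:
            plan.final_inducible = False
            break
        cls, emergent_prov = classify_rotors(oracle, base)
        emergent_seen.update(emergent_prov)
        for rid, label in cls.items():
            tag = f"emergent-{label}" if oracle.is_emergent(rid) else label
            plan.classification.setdefault(rid, tag)
        lirs = sorted(r for r, c in cls.items() if c == "LIR")
        if lirs:
            targets = lirs
        else:
            if tiebreak == "fd":
                # highest regional FD; ties resolve to lowest id
                best = max(_fd_of(oracle, r) for r in cls)
                targets = [sorted(r for r in cls if _fd_of(oracle, r) == best)[0]]
            else:
                targets = [sorted(cls)[0]]
        for rid in targets:
            plan.lesion_ids.append(rid)
            info = oracle.rotor_info(rid)
            plan.lesions.append(lesion_for_rotor(info))
        base = base | set(targets)
    else:
        raise OracleConsistencyError("guided search did not terminate")
    plan.final_inducible = bool(oracle.query(base))
    # emergent rotors uncovered during probes that the final plan never
    # needed to ablate are contingent on the executed lesion set
    for rid in emergent_seen:
        plan.classification.setdefault(rid, "emergent-LCR")
    _annotate_iat(oracle, plan)
    plan.query_log = list(oracle.query_log)
    return plan


def all_at_once(oracle: InducibilityOracle, max_iterations: int = 64) -> AblationPlan:
    """Comparator strategy: ablate every rotor location, types undiscerned.

    All rotors induced on the native substrate are ablated simultaneously;
    the inducibility test is repeated and any emergent rotors are ablated
    too, until non-inducibility.
    """
    plan = AblationPlan(strategy="all-at-once")
    base: frozenset = frozenset()
    for _ in range(max_iterations):
        current = oracle.query(base)
        if not current:
            plan.final_inducible = False
            break
        for rid in sorted(current):
            tag = "emergent" if oracle.is_emergent(rid) else "rotor"
            plan.classification.setdefault(rid, tag)
            plan.lesion_ids.append(rid)
            plan.lesions.append(lesion_for_rotor(oracle.rotor_info(rid)))
        base = base | current
    else:
        raise OracleConsistencyError("all-at-once did not terminate")
    plan.final_inducible = bool(oracle.query(base))
    _annotate_iat(oracle, plan)
    plan.query_log = list(oracle.query_log)
    return plan


# ---------------------------------------------------------------------------
# iAT detection and connecting lines
# ---------------------------------------------------------------------------

@dataclass
class IATResult:
    verdict: str  # "iat" | "no-iat" | "barrier-contact"
    n_cycles: float = 0.0
    cycle_length_ms: float | None = None
    sustained_s: float = 0.0


def _contour_points(lesion: Lesion, offset_mm: float, spacing: float):
    """Ordered sample points on a closed contour outside the lesion boundary."""
    if lesion.shape == "disc":
        r = lesion.diameter / 2.0 + offset_mm
        n = max(int(np.ceil(2 * np.pi * r / spacing)), 16)
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([
            lesion.center[0] + r * np.cos(th),
            lesion.center[1] + r * np.sin(th),
        ])
    if lesion.shape == "ellipse":
        a = lesion.axes[0] / 2.0 + offset_mm
        b = lesion.axes[1] / 2.0 + offset_mm
        n = max(int(np.ceil(np.pi * (a + b) / spacing)), 16)
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        c, s = np.cos(lesion.orientation), np.sin(lesion.orientation)
        u, v = a * np.cos(th), b * np.sin(th)
        return np.column_stack([
            lesion.center[0] + c * u - s * v,
            lesion.center[1] + s * u + c * v,
        ])
    raise ValueError("iAT contour requires a disc or ellipse lesion")


def classify_lesion_reentry(
    rec: "ep.Recording",
    lesion: Lesion,
    contour_offset_mm: float = IAT_CONTOUR_OFFSET_MM,
    min_cycles: int = IAT_MIN_CYCLES,
    persistence_s: float = 5.0,
    tau_ms: float | None = None,
) -> IATResult:
    """Classify a recording as lesion macro-reentry (iAT) or not.

    iAT requires the activation phase sampled on the closed contour
    ``contour_offset_mm`` outside the lesion boundary to advance with a net
    winding of +-2pi per cycle over a contiguous span longer than
    ``persistence_s`` covering at least ``min_cycles`` cycles, with no
    sustained phase singularity in bulk tissue away from the lesion.
    """
    if rec.frames.shape[0] < 3:
        return IATResult(verdict="no-iat")
    lesion_r = lesion.diameter / 2.0 if lesion.shape == "disc" else lesion.axes[0] / 2.0
    contour = _contour_points(lesion, contour_offset_mm, rec.spacing)
    ny, nx = rec.frames.shape[1:]
    cells = np.array([
        (
            min(max(int(round((p[1] - rec.origin[1]) / rec.spacing)), 0), ny - 1),
            min(max(int(round((p[0] - rec.origin[0]) / rec.spacing)), 0), nx - 1),
        )
        for p in contour
    ])
    field_ = compute_phase(rec, tau_ms=tau_ms)
    ph = field_.phase[:, cells[:, 0], cells[:, 1]]
    d = np.diff(np.concatenate([ph, ph[:, :1]], axis=1), axis=1)
    d = (d + np.pi) % (2 * np.pi) - np.pi
    winding = np.rint(d.sum(axis=1) / (2 * np.pi)).astype(int)
    # longest contiguous span of consistent-sign +-1 winding
    span_frames = run = 0
    prev = 0
    for w in winding:
        if abs(w) >= 1 and (prev == 0 or np.sign(w) == np.sign(prev)):
            run += 1
            span_frames = max(span_frames, run)
        elif abs(w) >= 1:
            run = 1
        else:
            run = 0
        prev = w
    sustained_s = span_frames * field_.frame_interval_ms / 1000.0
    if sustained_s <= persistence_s:
        return IATResult(verdict="no-iat", sustained_s=float(sustained_s))
    probe = np.zeros(rec.frames.shape[1:], dtype=bool)
    probe[cells[:, 0], cells[:, 1]] = True
    try:
        freq = dominant_frequency(rec, probe)
    except ValueError:
        return IATResult(verdict="no-iat", sustained_s=float(sustained_s))
    cl_ms = 1000.0 / freq
    n_cycles = sustained_s * 1000.0 / cl_ms
    if n_cycles < min_cycles:
        return IATResult(verdict="no-iat", sustained_s=float(sustained_s),
                         n_cycles=float(n_cycles), cycle_length_ms=float(cl_ms))
    bulk = [
        evn for evn in analyze_recording(rec, tau_ms=tau_ms, persistence_s=persistence_s)
        if np.hypot(evn.centroid[0] - lesion.center[0],
                    evn.centroid[1] - lesion.center[1]) > lesion_r + 6.0
    ]
    if bulk:
        return IATResult(verdict="no-iat", sustained_s=float(sustained_s),
                         n_cycles=float(n_cycles), cycle_length_ms=float(cl_ms))
    return IATResult(
        verdict="iat",
        n_cycles=float(n_cycles),
        cycle_length_ms=float(cl_ms),
        sustained_s=float(sustained_s),
    )


def detect_iat(
    tissue: ep.TissueModel,
    lesion: Lesion,
    protocol: ep.PacingProtocol | None = None,
    contour_offset_mm: float = IAT_CONTOUR_OFFSET_MM,
    min_cycles: int = IAT_MIN_CYCLES,
    persistence_s: float = 5.0,
) -> IATResult:
    """Screen a single rotor lesion on the native substrate for iAT.

    Barrier contact (the lesion boundary touching a non-conductive barrier)
    excludes iAT outright. Otherwise the pacing protocol is run from sites
    around the lesion and each recording is classified by
    ``classify_lesion_reentry`` (contour winding of +-2pi per cycle for
    at least 3 cycles, persisting beyond 5 s, no bulk rotor).
    """
    mask = lesion.to_mask(tissue.shape, tissue.spacing, tissue.origin)
    from scipy.ndimage import binary_dilation

    touches = binary_dilation(mask) & (tissue.classes == ep.BARRIER)
    if touches.any():
        return IATResult(verdict="barrier-contact")

    lesioned = ep.apply_lesions(tissue, [mask])
    if protocol is None:
        protocol = ep.PacingProtocol()
    sites = protocol.sites or [
        lesioned.cell_at(tuple(p))
        for p in _contour_points(lesion, contour_offset_mm + 4.0, 12.0)
    ]
    best = IATResult(verdict="no-iat")
    for site in sites:
        if not lesioned.conductive[site]:
            continue
        rec = ep.run_pacing(lesioned, protocol, site=site)
        res = classify_lesion_reentry(
            rec, lesion,
            contour_offset_mm=contour_offset_mm,
            min_cycles=min_cycles,
            persistence_s=persistence_s,
        )
        if res.verdict == "iat":
            return res
        if res.sustained_s > best.sustained_s:
            best = res
    return best


def connecting_line(
    lesion: Lesion,
    tissue: ep.TissueModel,
    width_mm: float = CONNECTING_LINE_WIDTH_MM,
) -> tuple[Lesion, float]:
    """Straight ablation line from the lesion boundary to the nearest barrier.

    The distance is Euclidean boundary-to-boundary; a lesion already
    touching the barrier yields a zero-length line. Raises when the domain
    has no barrier.
    """
    barrier = tissue.classes == ep.BARRIER
    if not barrier.any():
        raise ValueError("no non-conductive barrier in the domain")
    mask = lesion.to_mask(tissue.shape, tissue.spacing, tissue.origin)
    from scipy.ndimage import binary_dilation

    boundary = binary_dilation(mask) & ~mask
    bi = np.argwhere(boundary)
    ki = np.argwhere(barrier)
    from scipy.spatial import cKDTree

    tree = cKDTree(ki)
    dists, idx = tree.query(bi)
    best = int(np.argmin(dists))
    p_lesion = bi[best]
    p_barrier = ki[idx[best]]
    dist_mm = float(dists[best] * tissue.spacing)
    p1 = tissue.xy_of(tuple(p_lesion))
    p2 = tissue.xy_of(tuple(p_barrier))
    line = Lesion(shape="line", endpoints=(p1, p2), width=width_mm)
    return line, dist_mm


# ---------------------------------------------------------------------------
# Brute-force verifier
# ---------------------------------------------------------------------------

def exhaustive_minimal_sets(script: DependencyScript) -> tuple[set, list[frozenset]]:
    """Essential rotors and all minimal sufficient ablation subsets.

    A subset is sufficient when its iterated closure (ablate, re-query,
    ablate any emergent rotors that appear, repeat) reaches non-
    inducibility. Essential rotors are those present in every minimal
    sufficient subset. Brute force over all subsets; refuses above
    8 rotors.
    """
    ids = script.rotor_ids
    if len(ids) > 8 + 2:
        raise ValueError("too many rotors for exhaustive enumeration")

    def closure(s: frozenset) -> tuple[bool, frozenset]:
        cur = s
        for _ in range(len(ids) + 1):
            induced = script.induce(cur)
            emergent = {r for r in induced if script.rotors[r].emergent}
            new = emergent - cur
            if new:
                cur = cur | new
                continue
            return (len(induced) == 0), cur
        return False, cur

    sufficient = []
    for size in range(len(ids) + 1):
        for s in combinations(ids, size):
            ok, _ = closure(frozenset(s))
            if ok:
                sufficient.append(frozenset(s))
    minimal = [s for s in sufficient if not any(t < s for t in sufficient)]
    if minimal:
        essential = set.intersection(*(set(s) for s in minimal))
    else:
        essential = set()
    return essential, minimal
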