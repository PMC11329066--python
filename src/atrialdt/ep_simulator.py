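"""Monodomain reaction-diffusion solver on fibrotic 2D tissue sheets.

The membrane is a two-variable phenomenological excitable model
(Aliev-Panfilov kinetics: a fast activation variable and a slow recovery
variable) with one parameter set per tissue class. Fibrotic remodeling is
represented by documented parameter scalings (reduced excitability, slower
recovery) calibrated so the emergent propagation properties match the
atrial digital-twin operating point: longitudinal conduction velocity
43.39 cm/s in non-fibrotic and 20 cm/s in fibrotic tissue, conductivity
anisotropy 5:1 and 8:1 respectively, and a reentrant rotor frequency near
3.6 Hz.

Numerics: explicit forward-Euler diffusion with operator-split reaction on
a regular lattice (default spacing 0.3 mm), face-based heterogeneous
anisotropic fluxes (harmonic face conductivities, zero across lesion,
barrier and domain boundaries, i.e. no-flux), CFL-checked timestep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .synthetic_substrate import FibrosisMap

__all__ = [
    "MembraneParams",
    "TissueModel",
    "PacingProtocol",
    "Recording",
    "Stimulus",
    "SolverError",
    "CalibrationError",
    "PropagationFailure",
    "NORMAL",
    "FIBROTIC",
    "LESION",
    "BARRIER",
    "build_tissue",
    "build_slab",
    "apply_lesions",
    "measure_planar_cv",
    "calibrate_conductivity",
    "calibrate_rotor_frequency",
    "select_pacing_sites",
    "run_pacing",
    "iterate_pacing",
    "induce_rotor_s1s2",
    "fibrotic_reference_sheet",
    "Simulation",
    "measure_stim_threshold",
]

# tissue classes
NORMAL, FIBROTIC, LESION, BARRIER = 0, 1, 2, 3

V_REST_MV = -80.0  # mapping of the dimensionless potential to mV
V_AMP_MV = 100.0
ACTIVATION_THRESHOLD = 0.5  # dimensionless V defining local activation


class SolverError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


class PropagationFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class MembraneParams:
    """Aliev-Panfilov membrane parameters for one tissue class.

    ``gain`` is the excitability gain k, ``threshold`` the activation
    threshold a, ``eps0``/``mu1``/``mu2`` the recovery kinetics, and
    ``time_scale_ms`` the physical duration of one model time unit.
    ``remodeling`` documents the parameter-scaling analogs of fibrotic
    ionic remodeling applied relative to the non-fibrotic set.
    """

    gain: float = 8.0
    threshold: float = 0.15
    eps0: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    time_scale_ms: float = 12.0
    remodeling: dict = field(default_factory=dict, compare=False)


# Fibrotic remodeling analogs: excitability reduced (threshold raised, the
# analog of reduced sodium-channel availability) and recovery slowed
# (the analog of the action-potential prolongation accompanying reduced
# I_CaL / I_K1 in the remodeled fibrotic myocardium). At matched
# conductivity the fibrotic set conducts more slowly and repolarizes later.
DEFAULT_NORMAL_PARAMS = MembraneParams(eps0=0.006, time_scale_ms=6.0)
DEFAULT_FIBROTIC_PARAMS = MembraneParams(
    threshold=0.19,
    eps0=0.0004,
    time_scale_ms=6.0,
    remodeling={"threshold_scale": 0.19 / 0.15, "eps0_scale": 0.0004 / 0.006},
)

# Longitudinal conductivity defaults (mm^2/ms): the values produced by
# calibrate_conductivity for the default membrane sets at the CV targets
# (43.39 cm/s non-fibrotic, 20 cm/s fibrotic); regenerable at run time.
DEFAULT_D_LONG = {NORMAL: 0.599, FIBROTIC: 0.161}
DEFAULT_ANISOTROPY = {NORMAL: 5.0, FIBROTIC: 8.0}


@dataclass
class TissueModel:
    """Simulatable 2D tissue: geometry, classes, conductivity, membrane."""

    classes: np.ndarray  # (ny, nx) uint8 in {NORMAL, FIBROTIC, LESION, BARRIER}
    spacing: float = 0.3  # mm
    origin: tuple[float, float] = (0.0, 0.0)
    fiber_angle: np.ndarray | None = None  # radians, per cell
    membrane: dict = field(default_factory=lambda: {
        NORMAL: DEFAULT_NORMAL_PARAMS, FIBROTIC: DEFAULT_FIBROTIC_PARAMS,
    })
    d_long: dict = field(default_factory=lambda: dict(DEFAULT_D_LONG))
    anisotropy: dict = field(default_factory=lambda: dict(DEFAULT_ANISOTROPY))
    region_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.fiber_angle is None:
            self.fiber_angle = np.zeros(self.classes.shape)
        self.d_long.setdefault(LESION, 0.0)
        self.d_long.setdefault(BARRIER, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]

    @property
    def conductive(self) -> np.ndarray:
        return self.classes < LESION

    def extent_mm(self) -> tuple[float, float]:
        ny, nx = self.classes.shape
        return nx * self.spacing, ny * self.spacing

    def cell_at(self, xy_mm: tuple[float, float]) -> tuple[int, int]:
        j = int(round((xy_mm[0] - self.origin[0]) / self.spacing))
        i = int(round((xy_mm[1] - self.origin[1]) / self.spacing))
        ny, nx = self.classes.shape
        return min(max(i, 0), ny - 1), min(max(j, 0), nx - 1)

    def xy_of(self, ij: tuple[int, int]) -> tuple[float, float]:
        return (
            self.origin[0] + ij[1] * self.spacing,
            self.origin[1] + ij[0] * self.spacing,
        )

    def tensors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell conductivity tensor components (Dxx, Dyy, Dxy)."""
        dl = np.zeros(self.classes.shape)
        ratio = np.ones(self.classes.shape)
        for cls, d in self.d_long.items():
            dl[self.classes == cls] = d
        for cls, r in self.anisotropy.items():
            ratio[self.classes == cls] = r
        dt_ = dl / ratio
        th = self.fiber_angle
        c, s = np.cos(th), np.sin(th)
        dxx = dl * c * c + dt_ * s * s
        dyy = dl * s * s + dt_ * c * c
        dxy = (dl - dt_) * c * s
        nc = ~self.conductive
        dxx[nc] = dyy[nc] = dxy[nc] = 0.0
        return dxx, dyy, dxy

    def to_vtk(self, path) -> None:
        """Write class, fiber angle and conductivity fields as legacy VTK."""
        from ._vtk import write_structured_scalars

        dxx, dyy, _ = self.tensors()
        write_structured_scalars(
            path,
            {
                "tissue_class": self.classes.astype(float),
                "fiber_angle_rad": np.asarray(self.fiber_angle, dtype=float),
                "conductivity_xx": dxx,
                "conductivity_yy": dyy,
            },
            self.spacing,
            self.origin,
        )

    def membrane_fields(self) -> tuple[np.ndarray, ...]:
        """Per-cell membrane parameter arrays (gain, a, eps0, mu1, mu2, invT)."""
        shape = self.classes.shape
        arrs = [np.zeros(shape) for _ in range(6)]
        ref = self.membrane.get(NORMAL, DEFAULT_NORMAL_PARAMS)
        for cls in (NORMAL, FIBROTIC, LESION, BARRIER):
            sel = self.classes == cls
            if not sel.any():
                continue
            p = self.membrane.get(cls, ref)
            vals = (p.gain, p.threshold, p.eps0, p.mu1, p.mu2, 1.0 / p.time_scale_ms)
            for a, v in zip(arrs, vals):
                a[sel] = v
        return tuple(arrs)


def build_tissue(
    fmap: FibrosisMap,
    fiber_field: np.ndarray | None = None,
    barriers: np.ndarray | None = None,
    membrane: dict | None = None,
    d_long: dict | None = None,
    anisotropy: dict | None = None,
    region_labels: np.ndarray | None = None,
) -> TissueModel:
    """Assemble a tissue model from a fibrosis map.

    Fibrotic cells take the fibrotic membrane/conductivity class; barrier
    cells (e.g. a PVI band or a valve) are non-conductive. A missing fiber
    field defaults to uniform 0 rad with a warning.
    """
    classes = np.where(fmap.labels > 0, FIBROTIC, NORMAL).astype(np.uint8)
    if barriers is not None:
        classes[np.asarray(barriers, dtype=bool)] = BARRIER
    if fiber_field is None:
        warnings.warn("no fiber field supplied; defaulting to uniform 0 rad", stacklevel=2)
    return TissueModel(
        classes=classes,
        spacing=fmap.spacing,
        origin=fmap.origin,
        fiber_angle=fiber_field,
        membrane=membrane or {NORMAL: DEFAULT_NORMAL_PARAMS, FIBROTIC: DEFAULT_FIBROTIC_PARAMS},
        d_long=dict(d_long or DEFAULT_D_LONG),
        anisotropy=dict(anisotropy or DEFAULT_ANISOTROPY),
        region_labels=region_labels,
    )


def build_slab(
    width_mm: float = 60.0,
    height_mm: float = 15.0,
    spacing: float = 0.3,
    tissue_class: int = NORMAL,
    membrane: MembraneParams | None = None,
    d_long: float | None = None,
    anisotropy: float | None = None,
    fiber_angle_rad: float = 0.0,
) -> TissueModel:
    """Homogeneous rectangular slab for planar-propagation tests."""
    ny = int(round(height_mm / spacing))
    nx = int(round(width_mm / spacing))
    classes = np.full((ny, nx), tissue_class, dtype=np.uint8)
    mem = {tissue_class: membrane or (
        DEFAULT_FIBROTIC_PARAMS if tissue_class == FIBROTIC else DEFAULT_NORMAL_PARAMS)}
    dl = {tissue_class: DEFAULT_D_LONG.get(tissue_class, 0.3) if d_long is None else d_long}
    ani = {tissue_class: DEFAULT_ANISOTROPY.get(tissue_class, 5.0) if anisotropy is None else anisotropy}
    return TissueModel(
        classes=classes,
        spacing=spacing,
        fiber_angle=np.full((ny, nx), fiber_angle_rad),
        membrane=mem,
        d_long=dl,
        anisotropy=ani,
    )


def apply_lesions(tissue: TissueModel, lesions) -> TissueModel:
    """Return a copy with lesion cells reclassified as non-conductive scar.

    ``lesions`` is an iterable of boolean masks or objects exposing
    ``to_mask(shape, spacing, origin)``. Idempotent: re-applying the same
    lesion yields an identical model. Barrier cells stay barriers.
    """
    classes = tissue.classes.copy()
    for lesion in lesions:
        if hasattr(lesion, "to_mask"):
            mask = lesion.to_mask(tissue.shape, tissue.spacing, tissue.origin)
        else:
            mask = np.asarray(lesion, dtype=bool)
        classes[mask & (classes != BARRIER)] = LESION
    out = replace(tissue, classes=classes)
    return out


# ---------------------------------------------------------------------------
# Core stepping kernel
# ---------------------------------------------------------------------------

@njit(cache=False, fastmath=True)
def _step_kernel(V, W, gain, a, eps0, mu1, mu2, invT,
                 fxx, fyy, dxy, cond,
                 stim, dt, inv_dx2, n_steps,
                 probe_i, probe_j, probe_act, step0):
    ny, nx = V.shape
    Vn = np.empty_like(V)
    for s in range(n_steps):
        for i in range(ny):
            for j in range(nx):
                if not cond[i, j]:
                    Vn[i, j] = V[i, j]
                    continue
                v = V[i, j]
                w = W[i, j]
                # face fluxes (zero across non-conductive faces / boundary)
                lap = 0.0
                if j + 1 < nx:
                    lap += fxx[i, j] * (V[i, j + 1] - v)
                if j > 0:
                    lap -= fxx[i, j - 1] * (v - V[i, j - 1])
                if i + 1 < ny:
                    lap += fyy[i, j] * (V[i + 1, j] - v)
                if i > 0:
                    lap -= fyy[i - 1, j] * (v - V[i - 1, j])
                # cross-fiber term (centered; dxy pre-zeroed near obstacles)
                if dxy[i, j] != 0.0 and 0 < i < ny - 1 and 0 < j < nx - 1:
                    dVdy_xp = V[i + 1, j + 1] - V[i - 1, j + 1]
                    dVdy_xm = V[i + 1, j - 1] - V[i - 1, j - 1]
                    dVdx_yp = V[i + 1, j + 1] - V[i + 1, j - 1]
                    dVdx_ym = V[i - 1, j + 1] - V[i - 1, j - 1]
                    lap += 0.25 * dxy[i, j] * (dVdy_xp - dVdy_xm + dVdx_yp - dVdx_ym)
                k = gain[i, j]
                rate = invT[i, j]
                dv = -k * v * (v - a[i, j]) * (v - 1.0) - v * w
                eps = eps0[i, j] + mu1[i, j] * w / (v + mu2[i, j])
                dw = eps * (-w - k * v * (v - a[i, j] - 1.0))
                Vn[i, j] = v + dt * (lap * inv_dx2 + rate * (dv + stim[i, j]))
                W[i, j] = w + dt * rate * dw
        V, Vn = Vn, V
        # probe activation times with sub-step linear interpolation
        for p in range(probe_i.shape[0]):
            if probe_act[p] < 0.0:
                vc = V[probe_i[p], probe_j[p]]
                if vc >= 0.5:
                    vp = Vn[probe_i[p], probe_j[p]]  # previous value
                    frac = (0.5 - vp) / (vc - vp) if vc > vp else 1.0
                    probe_act[p] = step0 + s + frac
    return V, W


class Simulation:
    """Stateful monodomain simulation on a tissue model.

    Advances in 1-ms blocks (stimuli snap to this grid), optionally
    recording dimensionless-voltage frames at a fixed interval.
    """

    BLOCK_MS = 1.0

    def __init__(self, tissue: TissueModel, dt_ms: float | None = None):
        self.tissue = tissue
        ny, nx = tissue.shape
        self.V = np.zeros((ny, nx))
        self.W = np.zeros((ny, nx))
        self.t_ms = 0.0
        dxx, dyy, dxy = tissue.tensors()
        dx2 = tissue.spacing**2
        # harmonic face conductivities (0 if either side non-conductive)
        def _face(d, axis):
            a = d[:, :-1] if axis == 1 else d[:-1, :]
            b = d[:, 1:] if axis == 1 else d[1:, :]
            s = a + b
            out = np.zeros_like(a)
            ok = (a > 0) & (b > 0)
            out[ok] = 2.0 * a[ok] * b[ok] / s[ok]
            return out

        fxx = np.zeros((ny, nx))
        fyy = np.zeros((ny, nx))
        fxx[:, :-1] = _face(dxx, 1)
        fyy[:-1, :] = _face(dyy, 0)
        cond = tissue.conductive
        # zero the cross term next to any non-conductive cell or boundary
        pad = np.pad(cond, 1, constant_values=False)
        interior_ok = np.ones((ny, nx), dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                interior_ok &= pad[1 + di : 1 + di + ny, 1 + dj : 1 + dj + nx]
        dxy = np.where(interior_ok, dxy, 0.0)
        self._fxx, self._fyy, self._dxy = fxx, fyy, dxy
        self._cond = cond
        self._mem = tissue.membrane_fields()
        # CFL bound for the explicit anisotropic 5/9-point stencil
        dmax = float((dxx + dyy + 2 * np.abs(dxy)).max())
        cfl = 0.8 * dx2 / (2.0 * dmax) if dmax > 0 else np.inf
        # reaction stability: fastest upstroke rate ~ gain / time scale
        react = 0.25 / max(
            p.gain / p.time_scale_ms for p in tissue.membrane.values()
        )
        self.dt_ms = dt_ms if dt_ms is not None else min(cfl, react, 0.2)
        if self.dt_ms > cfl:
            raise SolverError(
                f"timestep {self.dt_ms} ms violates the diffusion CFL bound {cfl:.4f} ms"
            )
        self._inv_dx2 = 1.0 / dx2
        self._steps_per_block = max(int(np.ceil(self.BLOCK_MS / self.dt_ms)), 1)
        self._dt_eff = self.BLOCK_MS / self._steps_per_block
        self._no_probe = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
        self.stim_log: list[dict] = []

    def advance(
        self,
        duration_ms: float,
        stims: list["Stimulus"] | None = None,
        record_every_ms: float | None = None,
        probes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
        stop_when_quiet_after_ms: float | None = None,
    ) -> list[np.ndarray]:
        """Advance the state, returning recorded frames (possibly empty).

        ``stims`` are absolute-time rectangular pulses. If
        ``stop_when_quiet_after_ms`` is given, the run terminates early once
        all activity has died out after that absolute time.
        """
        stims = stims or []
        frames: list[np.ndarray] = []
        n_blocks = int(round(duration_ms / self.BLOCK_MS))
        record_every = None
        if record_every_ms is not None:
            record_every = max(int(round(record_every_ms / self.BLOCK_MS)), 1)
        pi, pj, pact = probes if probes is not None else self._no_probe
        zero_stim = np.zeros(self.tissue.shape)
        for b in range(n_blocks):
            t0 = self.t_ms
            active = [s for s in stims if s.t_on_ms < t0 + self.BLOCK_MS and t0 < s.t_on_ms + s.duration_ms]
            if active:
                cur = zero_stim.copy()
                for s in active:
                    cur[s.mask] += s.amplitude
                    if s.t_on_ms >= t0:
                        self.stim_log.append(
                            {"t_ms": s.t_on_ms, "duration_ms": s.duration_ms,
                             "amplitude": s.amplitude, "n_cells": int(s.mask.sum())}
                        )
            else:
                cur = zero_stim
            step0 = self.t_ms / self._dt_eff
            self.V, self.W = _step_kernel(
                self.V, self.W, *self._mem,
                self._fxx, self._fyy, self._dxy, self._cond,
                cur, self._dt_eff, self._inv_dx2, self._steps_per_block,
                pi, pj, pact, step0,
            )
            self.t_ms = t0 + self.BLOCK_MS
            vmax = float(np.max(np.abs(self.V)))
            if not np.isfinite(vmax) or vmax > 5.0:
                raise SolverError(f"numerical blow-up at t={self.t_ms:.1f} ms")
            if record_every is not None and (b + 1) % record_every == 0:
                frames.append(self.V.astype(np.float32))
            if (
                stop_when_quiet_after_ms is not None
                and self.t_ms > stop_when_quiet_after_ms
                and b % 20 == 0
                and float(self.V.max()) < 0.05
            ):
                break
        return frames


@dataclass
class Stimulus:
    """Rectangular current pulse applied to a cell mask (absolute time)."""

    t_on_ms: float
    duration_ms: float
    mask: np.ndarray
    amplitude: float


@dataclass
class Recording:
    """Voltage snapshots at a fixed sampling interval over the lattice."""

    frames: np.ndarray  # (T, ny, nx) dimensionless V, float32
    frame_interval_ms: float
    t0_ms: float
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    stim_log: list = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] * self.frame_interval_ms / 1000.0

    def voltage_mv(self) -> np.ndarray:
        return V_REST_MV + V_AMP_MV * self.frames

    def save(self, prefix) -> None:
        """Array container (.npy) plus a JSON sidecar header."""
        import json

        np.save(f"{prefix}.npy", self.frames)
        header = {
            "frame_interval_ms": self.frame_interval_ms,
            "t0_ms": self.t0_ms,
            "spacing_mm": self.spacing,
            "origin_mm": list(self.origin),
            "shape": list(self.frames.shape),
            "stim_log": self.stim_log,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(header, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "Recording":
        import json

        with open(f"{prefix}.json") as fh:
            header = json.load(fh)
        return cls(
            frames=np.load(f"{prefix}.npy"),
            frame_interval_ms=header["frame_interval_ms"],
            t0_ms=header["t0_ms"],
            spacing=header["spacing_mm"],
            origin=tuple(header["origin_mm"]),
            stim_log=header.get("stim_log", []),
        )


# ---------------------------------------------------------------------------
# Measurement and calibration
# ---------------------------------------------------------------------------

def _disc_mask(shape, spacing, center_ij, radius_mm) -> np.ndarray:
    ny, nx = shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    r2 = ((ii - center_ij[0]) ** 2 + (jj - center_ij[1]) ** 2) * spacing**2
    return r2 <= radius_mm**2


_THRESHOLD_CACHE: dict = {}


def measure_stim_threshold(params: MembraneParams, spacing: float = 0.3,
                           d_long: float | None = None) -> float:
    """Diastolic stimulus threshold (model current units) for a 2-ms pulse.

    Bisection on a small isotropic patch: the smallest amplitude whose
    2-ms, 1.5-mm-radius pulse elicits a propagated response.
    """
    key = (params.gain, params.threshold, params.eps0, params.time_scale_ms,
           spacing, d_long)
    if key in _THRESHOLD_CACHE:
        return _THRESHOLD_CACHE[key]
    n = int(round(9.0 / spacing))
    classes = np.zeros((n, n), dtype=np.uint8)
    tissue = TissueModel(
        classes=classes, spacing=spacing,
        membrane={NORMAL: params},
        d_long={NORMAL: DEFAULT_D_LONG[NORMAL] if d_long is None else d_long},
        anisotropy={NORMAL: 1.0},
    )
    mask = _disc_mask((n, n), spacing, (n // 2, n // 2), 1.5)
    corner = (2, 2)

    def excites(amp: float) -> bool:
        sim = Simulation(tissue)
        sim.advance(60.0, stims=[Stimulus(1.0, 2.0, mask, amp)])
        return bool(sim.V[corner] > ACTIVATION_THRESHOLD or sim.V.max() > 0.8)

    lo, hi = 0.0, 2.0
    for _ in range(20):
        if excites(hi):
            break
        hi *= 2.0
    else:
        raise CalibrationError("no stimulus amplitude elicited a response")
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        if excites(mid):
            hi = mid
        else:
            lo = mid
    _THRESHOLD_CACHE[key] = hi
    return hi


def measure_planar_cv(
    tissue: TissueModel,
    direction: str = "x",
    stim_amplitude: float | None = None,
) -> float:
    """Planar conduction velocity (cm/s) along ``direction`` on a slab.

    A plane-wave stimulus is applied at one edge; CV is computed from the
    activation-time difference between two sensing sites >= 20 mm apart on
    the centerline, excluding 5-mm margins at both ends.
    """
    if direction not in ("x", "y"):
        raise ValueError("direction must be 'x' or 'y'")
    ny, nx = tissue.shape
    wx, wy = tissue.extent_mm()
    length = wx if direction == "x" else wy
    if length < 30.0:
        raise ValueError("slab too short: need >= 30 mm along the propagation axis")
    margin = 5.0
    x1 = margin + 2.0
    x2 = length - margin - 2.0
    if x2 - x1 < 20.0:
        x1, x2 = margin, length - margin
    spacing = tissue.spacing
    if direction == "x":
        p1 = (ny // 2, int(round(x1 / spacing)))
        p2 = (ny // 2, int(round(x2 / spacing)))
        edge = np.zeros((ny, nx), dtype=bool)
        edge[:, : max(int(round(1.2 / spacing)), 2)] = True
    else:
        p1 = (int(round(x1 / spacing)), nx // 2)
        p2 = (int(round(x2 / spacing)), nx // 2)
        edge = np.zeros((ny, nx), dtype=bool)
        edge[: max(int(round(1.2 / spacing)), 2), :] = True

    params = next(iter(tissue.membrane.values()))
    amp = stim_amplitude if stim_amplitude is not None else 2.0 * measure_stim_threshold(params)
    sim = Simulation(tissue)
    pi = np.array([p1[0], p2[0]], dtype=np.int64)
    pj = np.array([p1[1], p2[1]], dtype=np.int64)
    pact = np.full(2, -1.0)
    # generous window: slowest plausible CV ~ 5 cm/s
    t_max = 20.0 + length / 0.05
    n_chunks = int(np.ceil(t_max / 50.0))
    for _ in range(n_chunks):
        sim.advance(50.0, stims=[Stimulus(1.0, 2.0, edge, amp)],
                    probes=(pi, pj, pact))
        if pact.min() >= 0:
            break
    if pact.min() < 0:
        raise PropagationFailure(
            f"wavefront failed to traverse the slab (activations: {pact})"
        )
    dt_act = (pact[1] - pact[0]) * sim._dt_eff
    if dt_act <= 0:
        raise PropagationFailure("non-positive activation delay between probes")
    dist_mm = (x2 - x1)
    return float(dist_mm / dt_act * 100.0)  # mm/ms -> cm/s


def calibrate_conductivity(
    membrane: MembraneParams,
    target_cv_cm_s: float,
    anisotropy: float = 1.0,
    tolerance: float = 0.02,
    tissue_class: int = NORMAL,
    spacing: float = 0.3,
    d_init: float | None = None,
    max_iter: int = 30,
) -> float:
    """Longitudinal conductivity giving the target planar CV (bisection-free
    secant iteration using the sqrt-D diffusion scaling law; deterministic).
    """
    if not target_cv_cm_s > 0:
        raise ValueError("target CV must be positive")
    d = d_init if d_init is not None else DEFAULT_D_LONG.get(tissue_class, 0.3)
    history = []
    for _ in range(max_iter):
        slab = build_slab(
            tissue_class=tissue_class, membrane=membrane, d_long=d,
            anisotropy=anisotropy, spacing=spacing,
        )
        amp = 2.0 * measure_stim_threshold(membrane, spacing=spacing)
        cv = measure_planar_cv(slab, "x", stim_amplitude=amp)
        history.append((d, cv))
        if abs(cv - target_cv_cm_s) <= tolerance * target_cv_cm_s:
            return d
        d = d * (target_cv_cm_s / cv) ** 2
    raise CalibrationError(
        f"conductivity calibration did not converge; trace: {history}"
    )


def select_pacing_sites(tissue: TissueModel, n: int = 40, seed: int = 0) -> list[tuple[int, int]]:
    """Distributed pacing sites by greedy farthest-point sampling.

    Deterministic under ``seed`` (which picks the initial site among
    conductive cells); subsequent sites maximize the minimum distance to
    the already-selected set, ties broken by lattice order.
    """
    cond = tissue.conductive
    coords = np.argwhere(cond)
    if n > coords.shape[0]:
        raise ValueError("requested more sites than conductive cells")
    # subsample candidates on a coarse grid for tractability
    stride = max(int(round(1.5 / tissue.spacing)), 1)
    cand = coords[(coords[:, 0] % stride == 0) & (coords[:, 1] % stride == 0)]
    if cand.shape[0] < n:
        cand = coords
    rng = np.random.default_rng(seed)
    first = int(rng.integers(cand.shape[0]))
    chosen = [first]
    d2 = np.sum((cand - cand[first]) ** 2, axis=1).astype(float)
    for _ in range(n - 1):
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((cand - cand[nxt]) ** 2, axis=1))
    return [tuple(map(int, cand[c])) for c in chosen]


@dataclass
class PacingProtocol:
    """Incremental burst pacing protocol.

    Trains of ``train_beats`` stimuli at each cycle length in
    ``cycle_lengths_ms`` (strictly decreasing), stimulus amplitude expressed
    as a multiple of the diastolic threshold, followed by an observation
    window of ``observe_s`` seconds.
    """

    sites: list[tuple[int, int]] | None = None
    train_beats: int = 10
    cycle_lengths_ms: tuple[float, ...] = (300.0, 280.0, 260.0, 240.0, 220.0, 200.0)
    stim_amplitude_factor: float = 2.0
    stim_duration_ms: float = 2.0
    stim_radius_mm: float = 1.5
    observe_s: float = 6.0
    frame_interval_ms: float = 5.0

    def __post_init__(self) -> None:
        cls = self.cycle_lengths_ms
        if any(b <= a for a, b in zip(cls[1:], cls[:-1])) and len(cls) > 1:
            pass
        if len(cls) > 1 and any(b >= a for a, b in zip(cls, cls[1:])):
            raise ValueError("cycle lengths must be strictly decreasing")
        if self.observe_s < 6.0:
            raise ValueError("observation window must be >= 6 s")

    @property
    def pacing_duration_ms(self) -> float:
        return sum(cl * self.train_beats for cl in self.cycle_lengths_ms)


def run_pacing(
    tissue: TissueModel,
    protocol: PacingProtocol,
    site: tuple[int, int] | None = None,
    record_pacing: bool = False,
) -> Recording:
    """Burst-pace from one site and record the observation window.

    By default only the post-pacing observation window is recorded (that is
    where rotor persistence is judged); the stimulus log covers the whole
    run. Terminates early if all activity dies out during observation.
    """
    if site is None:
        if not protocol.sites or len(protocol.sites) != 1:
            raise ValueError("pass site= or a protocol with exactly one site")
        site = protocol.sites[0]
    params = next(iter(tissue.membrane.values()))
    amp = protocol.stim_amplitude_factor * measure_stim_threshold(params, tissue.spacing)
    mask = _disc_mask(tissue.shape, tissue.spacing, site, protocol.stim_radius_mm)
    if not (mask & tissue.conductive).any():
        raise ValueError("pacing site lies entirely on non-conductive tissue")
    mask &= tissue.conductive

    stims = []
    t = 1.0
    for cl in protocol.cycle_lengths_ms:
        for _ in range(protocol.train_beats):
            stims.append(Stimulus(t, protocol.stim_duration_ms, mask, amp))
            t += cl
    pacing_end = t
    sim = Simulation(tissue)
    frames = []
    if record_pacing:
        frames += sim.advance(pacing_end, stims=stims,
                              record_every_ms=protocol.frame_interval_ms)
        t0 = 0.0
    else:
        sim.advance(pacing_end, stims=stims)
        t0 = pacing_end
    frames += sim.advance(
        protocol.observe_s * 1000.0,
        record_every_ms=protocol.frame_interval_ms,
        stop_when_quiet_after_ms=pacing_end + 50.0,
    )
    arr = np.stack(frames) if frames else np.zeros((0,) + tissue.shape, np.float32)
    return Recording(
        frames=arr,
        frame_interval_ms=protocol.frame_interval_ms,
        t0_ms=t0,
        spacing=tissue.spacing,
        origin=tissue.origin,
        stim_log=sim.stim_log,
    )


def iterate_pacing(tissue: TissueModel, protocol: PacingProtocol):
    """Yield (site, Recording) over the protocol's site list."""
    if not protocol.sites:
        raise ValueError("protocol has no sites")
    for site in protocol.sites:
        yield site, run_pacing(tissue, protocol, site=site)


# ---------------------------------------------------------------------------
# Rotor induction and frequency calibration
# ---------------------------------------------------------------------------

def induce_rotor_s1s2(
    tissue: TissueModel,
    duration_s: float = 8.0,
    s2_offsets_ms: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, -15.0),
    frame_interval_ms: float = 5.0,
    check_after_s: float = 2.0,
) -> Recording:
    """Reference cross-field S1-S2 rotor induction.

    S1 is a plane wave from the left edge; S2 a half-field stimulus covering
    the lower half, timed into the repolarization tail of S1 (the base
    timing is measured from the sheet center's recovery, then scanned over
    ``s2_offsets_ms`` until persistent rotational activity survives the
    check time). Deterministic.
    """
    ny, nx = tissue.shape
    params = next(iter(tissue.membrane.values()))
    amp = 2.0 * measure_stim_threshold(params, tissue.spacing)
    edge = np.zeros((ny, nx), dtype=bool)
    edge[:, : max(int(round(1.2 / tissue.spacing)), 2)] = True
    lower = np.zeros((ny, nx), dtype=bool)
    lower[: ny // 2, :] = True

    # measure the center recovery time under S1 alone
    sim = Simulation(tissue)
    center = (ny // 2, nx // 2)
    sim.advance(1.0)
    t_rec = None
    activated = False
    for _ in range(1200):
        sim.advance(1.0, stims=[Stimulus(1.0, 2.0, edge, amp)])
        v = sim.V[center]
        if not activated and v > ACTIVATION_THRESHOLD:
            activated = True
        elif activated and v < 0.1:
            t_rec = sim.t_ms
            break
    if t_rec is None:
        raise CalibrationError("S1 wave never activated/recovered the sheet center")

    last_err: str = ""
    for off in s2_offsets_ms:
        s2_t = t_rec + off
        sim = Simulation(tissue)
        stims = [Stimulus(1.0, 2.0, edge, amp), Stimulus(s2_t, 2.0, lower, amp)]
        frames = sim.advance(check_after_s * 1000.0, stims=stims,
                             record_every_ms=frame_interval_ms)
        if float(sim.V.max()) < 0.05:
            last_err = f"S2 at {s2_t:.0f} ms: activity extinguished"
            continue
        frames += sim.advance((duration_s - check_after_s) * 1000.0,
                              record_every_ms=frame_interval_ms,
                              stop_when_quiet_after_ms=s2_t + 100.0)
        rec = Recording(
            frames=np.stack(frames), frame_interval_ms=frame_interval_ms,
            t0_ms=0.0, spacing=tissue.spacing, origin=tissue.origin,
            stim_log=sim.stim_log,
        )
        if rec.duration_s >= duration_s - 0.5 and float(rec.frames[-1].max()) > 0.3:
            return rec
        last_err = f"S2 at {s2_t:.0f} ms: activity not sustained"
    raise CalibrationError(f"no S2 timing induced a sustained rotor ({last_err})")


def fibrotic_reference_sheet(size_mm: float = 50.0, spacing: float = 0.3,
                             membrane: MembraneParams | None = None,
                             d_long: float | None = None) -> TissueModel:
    """Homogeneous fibrotic-parameter sheet used for rotor calibration."""
    n = int(round(size_mm / spacing))
    classes = np.full((n, n), FIBROTIC, dtype=np.uint8)
    return TissueModel(
        classes=classes, spacing=spacing,
        membrane={FIBROTIC: membrane or DEFAULT_FIBROTIC_PARAMS},
        d_long={FIBROTIC: DEFAULT_D_LONG[FIBROTIC] if d_long is None else d_long},
        anisotropy={FIBROTIC: DEFAULT_ANISOTROPY[FIBROTIC]},
    )


def calibrate_rotor_frequency(
    membrane: MembraneParams | None = None,
    target_hz: float = 3.6,
    tolerance_hz: float = 0.4,
    sheet_size_mm: float = 50.0,
    duration_s: float = 8.0,
    d_long: float | None = None,
    max_iter: int = 5,
) -> tuple[MembraneParams, float, float]:
    """Adjust the membrane time constant so the rotor spins at the target.

    The rotation period of the reference S1-S2 rotor scales almost exactly
    with the model's kinetic time constant (the recovery dynamics set the
    cycle), so a secant search on ``time_scale_ms`` is monotone and
    converges in one or two evaluations. Conductivity is co-scaled
    proportionally to the time constant, which holds the planar conduction
    velocity fixed while the rotation frequency moves. Returns the
    calibrated parameters, the co-scaled longitudinal conductivity
    (mm^2/ms) and the measured dominant frequency.
    """
    from .rotor_analysis import dominant_frequency

    params = membrane or DEFAULT_FIBROTIC_PARAMS
    d_ref = DEFAULT_D_LONG[FIBROTIC] if d_long is None else d_long
    t_ref = params.time_scale_ms

    def measure(p: MembraneParams) -> float:
        d = d_ref * p.time_scale_ms / t_ref  # keeps CV = c * sqrt(D/T) fixed
        sheet = fibrotic_reference_sheet(sheet_size_mm, membrane=p, d_long=d)
        rec = induce_rotor_s1s2(sheet, duration_s=duration_s)
        n = sheet.shape[0]
        probe = _disc_mask(sheet.shape, sheet.spacing, (n // 2, n // 2), 10.0)
        return dominant_frequency(rec, probe)

    t_scale = params.time_scale_ms
    f = measure(params)
    history = [(t_scale, f)]
    for _ in range(max_iter):
        if abs(f - target_hz) <= tolerance_hz:
            p = replace(params, time_scale_ms=t_scale)
            return p, d_ref * t_scale / t_ref, f
        t1, f1 = history[-1]
        if len(history) >= 2 and history[-2][1] != f1:
            t0, f0 = history[-2]
            t_scale = t1 + (target_hz - f1) * (t1 - t0) / (f1 - f0)
        else:
            t_scale = t1 * f1 / target_hz  # period ~ time constant
        params2 = replace(params, time_scale_ms=float(t_scale))
        f = measure(params2)
        history.append((float(t_scale), f))
        params = params2
    raise CalibrationError(f"rotor-frequency calibration failed; trace: {history}")
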