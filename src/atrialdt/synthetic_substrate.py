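"""Synthetic substrate generators.

Everything the desk-scale pipeline consumes is generated here with known
ground truth: binary fibrosis fields on a regular 2D lattice, 3D LGE
intensity phantoms with wall/blood/aorta masks, bipolar electrogram sets
with scripted fractionation, and scripted rotor-dependency fixtures that
encode inducibility outcomes under ablation sets (including the three
worked patient examples).

Conventions
-----------
* Lattices are row-major ``(ny, nx)`` arrays; index ``(i, j)`` maps to the
  physical point ``(x, y) = origin + spacing * (j, i)`` in millimetres.
* All generators are deterministic under ``seed`` (bit-identical output).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FibrosisMap",
    "PhantomGeometry",
    "TissueIntensities",
    "LGEPhantom",
    "EGMPoint",
    "EGMSet",
    "RotorInfo",
    "DependencyScript",
    "generate_fibrosis_field",
    "generate_lge_phantom",
    "generate_egm_set",
    "builtin_patient_fixture",
    "generate_random_dependency",
]


# ---------------------------------------------------------------------------
# Fibrosis maps
# ---------------------------------------------------------------------------

@dataclass
class FibrosisMap:
    """Binary fibrotic/non-fibrotic label field on a regular 2D lattice.

    Parameters
    ----------
    labels
        ``(ny, nx)`` array with values in {0, 1}; 1 marks fibrotic tissue.
    spacing
        Lattice step in mm (default 0.3, the target mesh edge length).
    origin
        Physical coordinates of lattice index (0, 0), mm.
    intensity
        Optional continuous LGE-derived intensity on the same lattice.
    """

    labels: np.ndarray
    spacing: float = 0.3
    origin: tuple[float, float] = (0.0, 0.0)
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def burden(self) -> float:
        """Global fibrosis burden: 100 * fibrotic cells / all cells."""
        return 100.0 * float(np.count_nonzero(self.labels)) / self.labels.size

    def extent_mm(self) -> tuple[float, float]:
        """Physical (width, height) of the sheet in mm."""
        ny, nx = self.labels.shape
        return nx * self.spacing, ny * self.spacing

    # -- I/O ----------------------------------------------------------------

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.spacing, self.spacing, 1.0, 1.0])
        affine[0, 3], affine[1, 3] = self.origin
        img = nib.Nifti1Image(self.labels.T[:, :, None].astype(np.uint8), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "FibrosisMap":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.squeeze(np.asarray(img.dataobj)).T
        spacing = float(img.affine[0, 0])
        origin = (float(img.affine[0, 3]), float(img.affine[1, 3]))
        return cls(labels=(data > 0).astype(np.uint8), spacing=spacing, origin=origin)

    def to_csv(self, path) -> None:
        np.savetxt(str(path), self.labels, fmt="%d", delimiter=",")


def _grf(shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized Gaussian random field with correlation length sigma_cells."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _top_k_mask(score: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k highest-scoring cells (deterministic ties)."""
    flat = score.ravel()
    order = np.argsort(flat, kind="stable")[::-1]
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(score.shape)


def _grow_connected(score: np.ndarray, k: int, start: tuple[int, int]) -> np.ndarray:
    """Region-grow a connected component of k cells minimizing score.

    Dijkstra-style frontier growth from ``start``: repeatedly absorb the
    frontier cell with the lowest score. Guarantees 4-connectivity.
    """
    ny, nx = score.shape
    selected = np.zeros((ny, nx), dtype=bool)
    in_heap = np.zeros((ny, nx), dtype=bool)
    heap: list[tuple[float, int, int]] = [(float(score[start]), start[0], start[1])]
    in_heap[start] = True
    while heap and selected.sum() < k:
        _, i, j = heapq.heappop(heap)
        if selected[i, j]:
            continue
        selected[i, j] = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ii, jj = i + di, j + dj
            if 0 <= ii < ny and 0 <= jj < nx and not in_heap[ii, jj]:
                in_heap[ii, jj] = True
                heapq.heappush(heap, (float(score[ii, jj]), ii, jj))
    return selected


def generate_fibrosis_field(
    shape: tuple[int, int],
    spacing: float = 0.3,
    burden_target: float = 20.0,
    correlation_length: float = 2.0,
    pattern: str = "diffuse",
    seed: int = 0,
) -> FibrosisMap:
    """Generate a binary fibrosis field with a controlled burden and texture.

    Patterns
    --------
    ``diffuse``
        Thresholded Gaussian random field: scattered patchy fibrosis.
    ``compact``
        A single connected fibrosis island with a GRF-roughened boundary.
    ``interdigitated_border``
        A dense-fibrosis side grading into healthy tissue through an
        interdigitated border zone (two-phase gradient + GRF perturbation).

    The achieved burden matches ``burden_target`` up to quantization
    (one lattice cell); the same seed reproduces the field bit-identically.
    """
    if not (np.isfinite(burden_target) and 0.0 <= burden_target <= 100.0):
        raise ValueError("burden_target must be a finite percentage in [0, 100]")
    if not np.isfinite(correlation_length) or correlation_length < spacing:
        raise ValueError("correlation_length must be finite and >= spacing")
    ny, nx = shape
    n = ny * nx
    k = int(round(burden_target / 100.0 * n))
    if k == 0:
        return FibrosisMap(np.zeros(shape, dtype=np.uint8), spacing=spacing)
    if k == n:
        return FibrosisMap(np.ones(shape, dtype=np.uint8), spacing=spacing)

    rng = np.random.default_rng(seed)
    sigma = correlation_length / spacing
    g = _grf(shape, sigma, rng)

    if pattern == "diffuse":
        mask = _top_k_mask(g, k)
    elif pattern == "compact":
        ci, cj = ny // 2, nx // 2
        ii, jj = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        r = np.hypot(ii - ci, jj - cj)
        # multiplicative boundary roughening; growth keeps it one component
        score = r * (1.0 + 0.25 * g)
        mask = _grow_connected(score, k, (ci, cj))
    elif pattern == "interdigitated_border":
        jj = np.arange(nx)[None, :] * np.ones((ny, 1))
        ramp = jj / max(nx - 1, 1)
        mask = _top_k_mask(ramp + 0.35 * g, k)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    return FibrosisMap(mask.astype(np.uint8), spacing=spacing)


# ---------------------------------------------------------------------------
# LGE phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomGeometry:
    """Nested-shell phantom: spherical blood pool + atrial wall shell, and a
    separate cylindrical aorta wall along z in one corner of the volume."""

    shape: tuple[int, int, int] = (48, 48, 48)  # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (1.25, 1.25, 1.25)
    blood_radius: float = 15.0  # mm
    wall_thickness: float = 3.0  # mm
    aorta_center_frac: tuple[float, float] = (0.15, 0.15)  # (y, x) fraction
    aorta_inner_radius: float = 5.0  # mm
    aorta_thickness: float = 2.0  # mm


@dataclass
class TissueIntensities:
    """Per-tissue intensity distributions in arbitrary scanner units."""

    blood_mean: float = 100.0
    blood_sd: float = 8.0
    wall_mean: float = 80.0
    wall_sd: float = 8.0
    fibrotic_mean: float = 150.0
    fibrotic_sd: float = 10.0
    aorta_mean: float = 100.0
    aorta_sd: float = 8.0


@dataclass
class LGEPhantom:
    """Synthetic 3D LGE scan with tissue masks and fibrosis ground truth."""

    intensity: np.ndarray
    wall_mask: np.ndarray
    blood_mask: np.ndarray
    aorta_mask: np.ndarray
    truth_labels: np.ndarray  # binary, defined on wall voxels only
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        masks = [self.wall_mask, self.blood_mask, self.aorta_mask]
        for a, b in combinations(range(3), 2):
            if np.any(masks[a] & masks[b]):
                raise ValueError("tissue masks must be pairwise disjoint")
        if np.any(self.truth_labels & ~self.wall_mask):
            raise ValueError("truth_labels must lie inside the wall mask")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and non-negative")

    @property
    def truth_burden(self) -> float:
        """Fibrosis burden (%) of the ground-truth labels on wall voxels."""
        return 100.0 * float(self.truth_labels.sum()) / float(self.wall_mask.sum())

    def to_nifti(self, prefix) -> None:
        import nibabel as nib

        affine = np.diag(list(self.voxel_size[::-1]) + [1.0])
        for name, arr in (
            ("intensity", self.intensity),
            ("wall", self.wall_mask),
            ("blood", self.blood_mask),
            ("aorta", self.aorta_mask),
            ("truth", self.truth_labels),
        ):
            img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32).T, affine)
            nib.save(img, f"{prefix}_{name}.nii.gz")


def generate_lge_phantom(
    geometry: PhantomGeometry | None = None,
    intensities: TissueIntensities | None = None,
    fibrosis: FibrosisMap | None = None,
    gain: float = 1.0,
    seed: int = 0,
) -> LGEPhantom:
    """Build a 3D LGE phantom with known fibrosis truth on the wall.

    The 2D fibrosis map is projected onto the spherical wall shell via
    spherical coordinates (longitude -> map x, colatitude -> map y), so the
    phantom's truth burden tracks the map burden. The aorta wall is modelled
    as entirely fibrous tissue with its own intensity distribution.
    """
    geo = geometry or PhantomGeometry()
    ints = intensities or TissueIntensities()
    if not gain > 0:
        raise ValueError("gain must be positive")
    if not ints.fibrotic_mean > ints.wall_mean:
        raise ValueError("fibrotic mean must exceed non-fibrotic wall mean")

    nz, ny, nx = geo.shape
    dz, dy, dx = geo.voxel_size
    zz, yy, xx = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    cz, cy, cx = (nz - 1) * dz / 2, (ny - 1) * dy / 2, (nx - 1) * dx / 2
    # keep the atrium clear of the aorta corner
    cx += 0.15 * nx * dx
    cy += 0.15 * ny * dy
    r = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    blood = r <= geo.blood_radius
    wall = (r > geo.blood_radius) & (r <= geo.blood_radius + geo.wall_thickness)

    ay = geo.aorta_center_frac[0] * (ny - 1) * dy
    ax = geo.aorta_center_frac[1] * (nx - 1) * dx
    rho = np.sqrt((yy - ay) ** 2 + (xx - ax) ** 2)
    aorta = (rho > geo.aorta_inner_radius) & (
        rho <= geo.aorta_inner_radius + geo.aorta_thickness
    )
    aorta &= ~(blood | wall)

    truth = np.zeros(geo.shape, dtype=bool)
    if fibrosis is not None:
        wz, wy, wx = np.nonzero(wall)
        vz, vy, vx = wz * dz - cz, wy * dy - cy, wx * dx - cx
        phi = np.arctan2(vy, vx)  # longitude in (-pi, pi]
        theta = np.arccos(np.clip(vz / np.maximum(r[wall], 1e-9), -1, 1))
        mny, mnx = fibrosis.shape
        j = np.minimum(((phi + np.pi) / (2 * np.pi) * mnx).astype(int), mnx - 1)
        i = np.minimum((theta / np.pi * mny).astype(int), mny - 1)
        truth[wz, wy, wx] = fibrosis.labels[i, j] > 0

    rng = np.random.default_rng(seed)
    base = np.zeros(geo.shape, dtype=np.float64)
    noise = rng.standard_normal(geo.shape)
    base[blood] = ints.blood_mean + ints.blood_sd * noise[blood]
    base[wall & ~truth] = ints.wall_mean + ints.wall_sd * noise[wall & ~truth]
    base[truth] = ints.fibrotic_mean + ints.fibrotic_sd * noise[truth]
    base[aorta] = ints.aorta_mean + ints.aorta_sd * noise[aorta]
    intensity = gain * np.maximum(base, 0.0)

    return LGEPhantom(
        intensity=intensity,
        wall_mask=wall,
        blood_mask=blood,
        aorta_mask=aorta,
        truth_labels=truth & wall,
        voxel_size=geo.voxel_size,
    )


# ---------------------------------------------------------------------------
# Electrogram sets
# ---------------------------------------------------------------------------

@dataclass
class EGMPoint:
    position: tuple[float, float]  # mm
    trace: np.ndarray  # bipolar voltage, mV
    quality_flag: str = "good"  # "good" | "poor"
    truth_times: np.ndarray | None = None  # scheduled deflection times, ms
    truth_amplitude: float | None = None  # scheduled peak-to-peak, mV


@dataclass
class EGMSet:
    """A set of sampled bipolar electrograms with fractionation ground truth."""

    points: list[EGMPoint]
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        lengths = {len(p.trace) for p in self.points}
        if len(lengths) > 1:
            raise ValueError("all traces must have the same length")

    @property
    def times_ms(self) -> np.ndarray:
        n = len(self.points[0].trace) if self.points else 0
        return np.arange(n) * 1000.0 / self.sampling_rate

    def to_csv(self, path) -> None:
        import pandas as pd

        t = self.times_ms
        rows = []
        for pid, p in enumerate(self.points):
            for ti, v in zip(t, p.trace):
                rows.append((pid, ti, v))
        pd.DataFrame(rows, columns=["point_id", "t_ms", "mV"]).to_csv(path, index=False)

    def metadata_json(self, path) -> None:
        meta = {
            "sampling_rate_hz": self.sampling_rate,
            "n_points": len(self.points),
            "points": [
                {
                    "point_id": i,
                    "position_mm": list(p.position),
                    "quality_flag": p.quality_flag,
                    "truth_times_ms": None if p.truth_times is None else list(map(float, p.truth_times)),
                    "truth_amplitude_mv": p.truth_amplitude,
                }
                for i, p in enumerate(self.points)
            ],
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)


def _biphasic_wavelet(t_ms: np.ndarray, t0: float, pp_amplitude: float, sd: float = 0.45) -> np.ndarray:
    """Antisymmetric (derivative-of-Gaussian) deflection, peak-to-peak scaled."""
    u = (t_ms - t0) / sd
    w = -u * np.exp(-0.5 * u * u)
    # extrema of u*exp(-u^2/2) are at u=+-1 with value exp(-0.5)
    return pp_amplitude / (2.0 * np.exp(-0.5)) * w


def generate_egm_set(
    activation_times: Sequence[float],
    fractionation_spec: Sequence[tuple[int, float]] | None = None,
    amplitudes: Sequence[float] | float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 2000.0,
    positions: Sequence[tuple[float, float]] | None = None,
    duration_ms: float | None = None,
    quality_flags: Sequence[str] | None = None,
) -> EGMSet:
    """Generate bipolar electrograms with scripted fractionation.

    Each point gets a primary biphasic deflection at its activation time;
    ``fractionation_spec[i] = (n_extra, spacing_ms)`` injects ``n_extra``
    additional deflections at the given spacing (the clinically fractionated
    regime uses 2-8 ms). Ground truth (times and peak-to-peak amplitude) is
    stored on each point.
    """
    if sampling_rate < 1000.0:
        raise ValueError("sampling rate must be >= 1 kHz")
    n_pts = len(activation_times)
    amps = np.broadcast_to(np.atleast_1d(np.asarray(amplitudes, dtype=float)), (n_pts,))
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive")
    spec = fractionation_spec or [(0, 0.0)] * n_pts
    dt_ms = 1000.0 / sampling_rate
    for n_extra, spacing in spec:
        if n_extra > 0 and spacing < dt_ms:
            raise ValueError("deflection spacing below one sample period")

    if duration_ms is None:
        duration_ms = max(
            at + n_extra * spacing for at, (n_extra, spacing) in zip(activation_times, spec)
        ) + 50.0
    t = np.arange(int(round(duration_ms / dt_ms))) * dt_ms
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = [(float(i), 0.0) for i in range(n_pts)]
    flags = quality_flags or ["good"] * n_pts

    points = []
    for i, (t0, (n_extra, spacing)) in enumerate(zip(activation_times, spec)):
        truth = t0 + spacing * np.arange(n_extra + 1)
        trace = np.zeros_like(t)
        for tk in truth:
            trace += _biphasic_wavelet(t, tk, amps[i])
        if noise_sd > 0:
            trace = trace + noise_sd * rng.standard_normal(t.shape)
        points.append(
            EGMPoint(
                position=tuple(positions[i]),
                trace=trace,
                quality_flag=flags[i],
                truth_times=truth,
                truth_amplitude=float(amps[i]),
            )
        )
    return EGMSet(points=points, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# Rotor-dependency scripts
# ---------------------------------------------------------------------------

@dataclass
class RotorInfo:
    """Nominal description of one rotor-attracting location."""

    rotor_id: str
    location: tuple[float, float] = (0.0, 0.0)  # mm
    region: int = 1  # 1..12 atrial region label
    emergent: bool = False
    barrier_contact: bool = False
    iat_flag: bool = False
    fd: float | None = None  # regional fibrosis density, % (tie-break key)


@dataclass
class DependencyScript:
    """Scripted inducibility oracle.

    ``induce_table`` maps every ablation subset (frozenset of rotor ids,
    over native and emergent ids) to the frozenset of rotor ids induced on
    the resulting substrate. Tables are exhaustive over all subsets so the
    planner can be tested exactly.
    """

    rotors: dict[str, RotorInfo]
    induce_table: dict[frozenset, frozenset]
    metadata: dict = field(default_factory=dict)

    @property
    def rotor_ids(self) -> list[str]:
        return sorted(self.rotors)

    @property
    def native_ids(self) -> list[str]:
        return sorted(r for r, info in self.rotors.items() if not info.emergent)

    def induce(self, ablated: Iterable[str]) -> frozenset:
        key = frozenset(ablated)
        unknown = key - set(self.rotors)
        if unknown:
            raise KeyError(f"unknown rotor ids {sorted(unknown)}")
        if key not in self.induce_table:
            raise KeyError(f"fixture incomplete: no entry for {sorted(key)}")
        return self.induce_table[key]

    def validate(self) -> None:
        """Check self-exclusion and monotone suppression/persistence."""
        ids = set(self.rotors)
        for size in range(len(ids) + 1):
            for s in combinations(sorted(ids), size):
                if frozenset(s) not in self.induce_table:
                    raise ValueError(f"induce_table missing subset {s}")
        for s, induced in self.induce_table.items():
            if induced & s:
                raise ValueError(f"induce({sorted(s)}) contains ablated rotor")
        subsets = sorted(self.induce_table, key=len)
        for s in subsets:
            for s2 in subsets:
                if s < s2:
                    for r in self.native_ids:
                        if r not in s and r not in self.induce_table[s] and r not in s2:
                            if r in self.induce_table[s2]:
                                raise ValueError(
                                    f"suppressed rotor {r} reappears: "
                                    f"{sorted(s)} -> {sorted(s2)}"
                                )

    # -- I/O ----------------------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "rotors": {
                rid: {
                    "location": list(info.location),
                    "region": info.region,
                    "emergent": info.emergent,
                    "barrier_contact": info.barrier_contact,
                    "iat_flag": info.iat_flag,
                    "fd": info.fd,
                }
                for rid, info in self.rotors.items()
            },
            "induce_table": [
                {"ablated": sorted(s), "induced": sorted(v)}
                for s, v in sorted(self.induce_table.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
            ],
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DependencyScript":
        with open(path) as fh:
            obj = json.load(fh)
        rotors = {
            rid: RotorInfo(
                rotor_id=rid,
                location=tuple(d["location"]),
                region=d["region"],
                emergent=d["emergent"],
                barrier_contact=d["barrier_contact"],
                iat_flag=d["iat_flag"],
                fd=d["fd"],
            )
            for rid, d in obj["rotors"].items()
        }
        table = {
            frozenset(e["ablated"]): frozenset(e["induced"]) for e in obj["induce_table"]
        }
        return cls(rotors=rotors, induce_table=table, metadata=obj.get("metadata", {}))


def _powerset(ids: Sequence[str]):
    return chain.from_iterable(combinations(ids, n) for n in range(len(ids) + 1))


def _complete_table(
    explicit: Mapping[frozenset, frozenset],
    native: Sequence[str],
    emergent: Sequence[str],
) -> dict[frozenset, frozenset]:
    """Complete a partial inducibility table under monotone suppression.

    Native rotors are induced unless some explicit entry at a subset of the
    query shows them suppressed (absent while not ablated). Emergent rotors
    are induced only if an explicit entry at a subset shows them appearing
    and no explicit entry between that trigger and the query shows them
    suppressed.
    """
    all_ids = list(native) + list(emergent)
    table: dict[frozenset, frozenset] = {}
    for subset in _powerset(all_ids):
        s = frozenset(subset)
        if s in explicit:
            table[s] = frozenset(explicit[s])
            continue
        induced = set()
        for r in native:
            if r in s:
                continue
            suppressed = any(
                s2 <= s and r not in s2 and r not in i2 for s2, i2 in explicit.items()
            )
            if not suppressed:
                induced.add(r)
        for e in emergent:
            if e in s:
                continue
            triggers = [s2 for s2, i2 in explicit.items() if s2 <= s and e in i2]
            if not triggers:
                continue
            # suppression between trigger and query wins over the trigger
            active = any(
                not any(
                    s2 < s3 and s3 <= s and e not in s3 and e not in i3
                    for s3, i3 in explicit.items()
                )
                for s2 in triggers
            )
            if active:
                induced.add(e)
        table[s] = frozenset(induced)
    return table


def builtin_patient_fixture(patient_id: int) -> DependencyScript:
    """Scripted rotor-dependency fixtures for the three worked patient cases.

    The explicit subsets encode the reported inducibility responses; all
    other subsets are completed by the monotone-suppression convention
    (a suppressed rotor stays suppressed in supersets) — flagged in
    ``metadata['completion']``.

    * Patient 1: three native rotors; A and C are independent (LIR), B is
      contingent on C; ablating {A, C} renders the substrate non-inducible.
      A's lesion touches a non-conductive barrier (no iAT possible); C's
      lesion produces iAT.
    * Patient 2: three native rotors, pairwise single ablations have no
      effect; ablating {B, C} uncovers an emergent rotor D; ablating {A, C}
      achieves non-inducibility. All three native lesions produce iAT.
    * Patient 3: two mutually contingent rotors; ablating either one alone
      suffices. No iAT.
    """
    f = frozenset
    if patient_id == 1:
        native, emergent = ["A", "B", "C"], []
        explicit = {
            f(): f("ABC"),
            f("A"): f("BC"),
            f("B"): f("AC"),
            f("C"): f("A"),
            f("AC"): f(),
        }
        info = {
            "A": RotorInfo("A", (10.0, 10.0), region=12, barrier_contact=True, iat_flag=False, fd=70.0),
            "B": RotorInfo("B", (30.0, 15.0), region=2, iat_flag=False, fd=55.0),
            "C": RotorInfo("C", (20.0, 35.0), region=6, iat_flag=True, fd=65.0),
        }
    elif patient_id == 2:
        native, emergent = ["A", "B", "C"], ["D"]
        explicit = {
            f(): f("ABC"),
            f("A"): f("BC"),
            f("B"): f("AC"),
            f("C"): f("AB"),
            f("AB"): f("C"),
            f("BC"): f("AD"),
            f("AC"): f(),
            f("ABC"): f("D"),
            f("ABCD"): f(),
        }
        info = {
            "A": RotorInfo("A", (12.0, 12.0), region=1, iat_flag=True, fd=68.0),
            "B": RotorInfo("B", (35.0, 12.0), region=3, iat_flag=True, fd=50.0),
            "C": RotorInfo("C", (22.0, 35.0), region=7, iat_flag=True, fd=66.0),
            "D": RotorInfo("D", (40.0, 30.0), region=9, emergent=True, fd=48.0),
        }
    elif patient_id == 3:
        native, emergent = ["A", "B"], []
        explicit = {
            f(): f("AB"),
            f("A"): f(),
            f("B"): f(),
        }
        info = {
            "A": RotorInfo("A", (15.0, 20.0), region=10, iat_flag=False, fd=62.0),
            "B": RotorInfo("B", (35.0, 25.0), region=11, iat_flag=False, fd=58.0),
        }
    else:
        raise KeyError(f"no builtin fixture for patient id {patient_id!r}")

    table = _complete_table(explicit, native, emergent)
    script = DependencyScript(
        rotors=info,
        induce_table=table,
        metadata={
            "patient": patient_id,
            "completion": "monotone-suppression convention for unreported subsets",
        },
    )
    script.validate()
    return script


def generate_random_dependency(
    n_rotors: int,
    p_contingent: float = 0.4,
    p_emergent: float = 0.2,
    seed: int = 0,
) -> DependencyScript:
    """Random dependency script for property-testing the planner.

    Construction guarantees monotone suppression: a contingent native rotor
    r carries a suppressor set K_r (ablating any member suppresses r);
    emergent rotors carry a trigger set T_e (appearing once all of T_e is
    ablated) and are never themselves contingent.
    """
    if n_rotors > 8:
        raise ValueError("n_rotors > 8: exhaustive table too large")
    if n_rotors < 1:
        raise ValueError("need at least one rotor")
    if not (0.0 <= p_contingent <= 1.0 and 0.0 <= p_emergent <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    native = [f"R{i+1}" for i in range(n_rotors)]
    suppressors: dict[str, frozenset] = {}
    for r in native:
        others = [x for x in native if x != r]
        if others and rng.random() < p_contingent:
            size = int(rng.integers(1, min(2, len(others)) + 1))
            suppressors[r] = frozenset(rng.choice(others, size=size, replace=False))
        else:
            suppressors[r] = frozenset()

    n_emergent = min(int(rng.binomial(n_rotors, p_emergent)), 2)
    emergent = [f"E{i+1}" for i in range(n_emergent)]
    triggers: dict[str, frozenset] = {}
    for e in emergent:
        size = int(rng.integers(1, min(2, n_rotors) + 1))
        triggers[e] = frozenset(rng.choice(native, size=size, replace=False))

    table: dict[frozenset, frozenset] = {}
    for subset in _powerset(native + emergent):
        s = frozenset(subset)
        induced = {r for r in native if r not in s and not (suppressors[r] & s)}
        induced |= {e for e in emergent if e not in s and triggers[e] <= s}
        table[s] = frozenset(induced)

    rotors = {}
    for i, r in enumerate(native):
        rotors[r] = RotorInfo(
            r,
            location=(float(10 * (i + 1)), float(10 * (i + 1))),
            region=int(rng.integers(1, 13)),
            iat_flag=bool(rng.random() < 0.5),
            fd=float(np.round(rng.uniform(20, 80), 1)),
        )
    for i, e in enumerate(emergent):
        rotors[e] = RotorInfo(
            e,
            location=(float(5 * (i + 1)), 45.0),
            region=int(rng.integers(1, 13)),
            emergent=True,
            fd=float(np.round(rng.uniform(20, 80), 1)),
        )
    script = DependencyScript(
        rotors=rotors,
        induce_table=table,
        metadata={"seed": seed, "p_contingent": p_contingent, "p_emergent": p_emergent},
    )
    return script
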