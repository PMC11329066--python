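"""Fibrosis density (FD) and fibrosis entropy (FE) substrate metrics.

FD over a region footprint is the percentage of fibrotic lattice elements
inside the footprint. FE is the local structural disorganization of the
fibrosis pattern: the binary Shannon entropy (bits) of the fibrotic
occupancy fraction within a 2.5-mm-radius kernel (the LGE-MRI resolution),
so FE vanishes on homogeneous tissue (all-fibrotic or all-healthy), is
maximal (1 bit) at 50% local occupancy, and is high at interdigitated
fibrosis border zones while low inside compact fibrosis islands.

Region footprints at rotor locations default to the ablation-lesion
footprint: a 12-mm-diameter disc, or the meander-covering ellipse for
widely meandering rotors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic_substrate import FibrosisMap

__all__ = [
    "disc_footprint",
    "ellipse_footprint",
    "fibrosis_density",
    "fibrosis_entropy_map",
    "regional_fe",
    "assign_region",
    "SubstrateMetrics",
]

DEFAULT_KERNEL_RADIUS_MM = 2.5


def disc_footprint(
    fmap: FibrosisMap, center_mm: tuple[float, float], diameter_mm: float = 12.0
) -> np.ndarray:
    """Boolean lattice mask of a Euclidean disc (center and diameter in mm)."""
    ny, nx = fmap.shape
    x = fmap.origin[0] + np.arange(nx) * fmap.spacing
    y = fmap.origin[1] + np.arange(ny) * fmap.spacing
    xx, yy = np.meshgrid(x, y)
    r2 = (xx - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
    return r2 <= (diameter_mm / 2.0) ** 2


def ellipse_footprint(
    fmap: FibrosisMap,
    center_mm: tuple[float, float],
    major_mm: float,
    minor_mm: float = 12.0,
    orientation_rad: float = 0.0,
) -> np.ndarray:
    """Boolean mask of a rotated ellipse (axes are full diameters, mm)."""
    ny, nx = fmap.shape
    x = fmap.origin[0] + np.arange(nx) * fmap.spacing
    y = fmap.origin[1] + np.arange(ny) * fmap.spacing
    xx, yy = np.meshgrid(x, y)
    dx, dy = xx - center_mm[0], yy - center_mm[1]
    c, s = np.cos(orientation_rad), np.sin(orientation_rad)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / (major_mm / 2.0)) ** 2 + (v / (minor_mm / 2.0)) ** 2 <= 1.0


def fibrosis_density(fmap: FibrosisMap, footprint: np.ndarray) -> float:
    """FD (%): fibrotic element fraction within the footprint."""
    footprint = np.asarray(footprint, dtype=bool)
    n = int(footprint.sum())
    if n == 0:
        raise ValueError("region footprint does not overlap the tissue")
    return 100.0 * float(fmap.labels[footprint].sum()) / n


def _binary_entropy_bits(q: np.ndarray) -> np.ndarray:
    q = np.clip(q, 0.0, 1.0)
    out = np.zeros_like(q, dtype=float)
    inner = (q > 0) & (q < 1)
    qi = q[inner]
    out[inner] = -qi * np.log2(qi) - (1 - qi) * np.log2(1 - qi)
    return out


def fibrosis_entropy_map(
    fmap: FibrosisMap,
    kernel_radius_mm: float = DEFAULT_KERNEL_RADIUS_MM,
    scale: float = 1.0,
) -> np.ndarray:
    """FE field: binary entropy (bits) of kernel fibrotic occupancy.

    The kernel is a Euclidean disc of ``kernel_radius_mm`` in-plane. At the
    sheet edges occupancy is computed over the in-domain part of the kernel.
    ``scale`` is an output scale factor (default 1.0, entropy in bits).
    """
    if kernel_radius_mm < fmap.spacing:
        raise ValueError("kernel radius must be >= lattice spacing")
    r_cells = int(np.floor(kernel_radius_mm / fmap.spacing))
    ii, jj = np.meshgrid(
        np.arange(-r_cells, r_cells + 1), np.arange(-r_cells, r_cells + 1), indexing="ij"
    )
    kernel = (ii**2 + jj**2) * fmap.spacing**2 <= kernel_radius_mm**2
    kernel = kernel.astype(float)
    lab = fmap.labels.astype(float)
    hits = ndimage.convolve(lab, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(lab), kernel, mode="constant", cval=0.0)
    q = hits / counts
    return scale * _binary_entropy_bits(q)


def regional_fe(fe_map: np.ndarray, footprint: np.ndarray) -> float:
    """Regional FE: arithmetic mean of FE values within the footprint."""
    footprint = np.asarray(footprint, dtype=bool)
    if not footprint.any():
        raise ValueError("empty region footprint")
    return float(fe_map[footprint].mean())


def assign_region(footprint: np.ndarray, region_label_field: np.ndarray) -> int:
    """Majority region label (1..12) under the footprint; ties -> lowest id.

    Cells labelled 0 are unlabelled and ignored; an entirely unlabelled
    footprint raises.
    """
    footprint = np.asarray(footprint, dtype=bool)
    labels = np.asarray(region_label_field)[footprint]
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("footprint contains no labelled cells")
    vals, counts = np.unique(labels, return_counts=True)
    # np.unique sorts ascending, argmax takes the first maximum -> lowest id wins ties
    return int(vals[np.argmax(counts)])


@dataclass
class SubstrateMetrics:
    """FD/FE maps plus per-location values for one substrate."""

    fd_map: np.ndarray | None
    fe_map: np.ndarray
    kernel_radius_mm: float

    @classmethod
    def from_map(
        cls, fmap: FibrosisMap, kernel_radius_mm: float = DEFAULT_KERNEL_RADIUS_MM
    ) -> "SubstrateMetrics":
        fe = fibrosis_entropy_map(fmap, kernel_radius_mm)
        # FD map shares the FE kernel: local fibrotic percentage
        r_cells = int(np.floor(kernel_radius_mm / fmap.spacing))
        ii, jj = np.meshgrid(
            np.arange(-r_cells, r_cells + 1), np.arange(-r_cells, r_cells + 1), indexing="ij"
        )
        kernel = ((ii**2 + jj**2) * fmap.spacing**2 <= kernel_radius_mm**2).astype(float)
        lab = fmap.labels.astype(float)
        hits = ndimage.convolve(lab, kernel, mode="constant", cval=0.0)
        counts = ndimage.convolve(np.ones_like(lab), kernel, mode="constant", cval=0.0)
        return cls(fd_map=100.0 * hits / counts, fe_map=fe, kernel_radius_mm=kernel_radius_mm)

    def to_vtk(self, path, spacing: float, origin=(0.0, 0.0)) -> None:
        """Write the FD and FE maps as a legacy-ASCII VTK scalar dataset."""
        from ._vtk import write_structured_scalars

        fields = {"fe": self.fe_map}
        if self.fd_map is not None:
            fields["fd"] = self.fd_map
        write_structured_scalars(path, fields, spacing, origin)

    def to_csv(self, prefix) -> None:
        np.savetxt(f"{prefix}_fd.csv", self.fd_map, delimiter=",", fmt="%.4f")
        np.savetxt(f"{prefix}_fe.csv", self.fe_map, delimiter=",", fmt="%.6f")
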