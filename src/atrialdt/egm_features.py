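"""Bipolar electrogram features: voltage statistics and FAAM/ICL fractionation.

Fractionated atrial electrograms show trains of closely spaced deflections.
Following the clinical FAAM definition, deflections with amplitudes from
0.1 mV up to the atrium-wide maximum and inter-deflection intervals in
(0, 10] ms constitute fractionated segments; the interval confidence level
(ICL) counts those short intervals per mapping point, and the ICL
percentage expresses a location's ICL relative to the atrium-wide maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic_substrate import EGMPoint, EGMSet

__all__ = [
    "PointFeature",
    "detect_deflections",
    "icl_count",
    "icl_percentage",
    "bipolar_voltage_stats",
    "point_features",
]

FAAM_AMP_MIN_MV = 0.1
ICL_WINDOW_MS = 10.0
DEFAULT_REFRACTORY_MS = 1.0
DEFAULT_FOOTPRINT_RADIUS_MM = 6.0  # lesion-footprint radius around a rotor centroid


@dataclass
class PointFeature:
    """Per-mapping-point electrogram feature summary."""

    position: tuple[float, float]
    voltage_pp: float  # peak-to-peak bipolar voltage, mV
    deflection_times: np.ndarray  # ms
    icl_count: int
    quality_flag: str = "good"


def detect_deflections(
    trace: np.ndarray,
    sampling_rate: float,
    amp_min: float = FAAM_AMP_MIN_MV,
    amp_max: float | None = None,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> np.ndarray:
    """Deflection times (ms) from a bipolar trace.

    Local extrema of either polarity with absolute amplitude in
    ``[amp_min, amp_max]`` are detected; extrema closer than the refractory
    period are merged keeping the largest, so the two lobes of one biphasic
    deflection count once.
    """
    if sampling_rate < 1000.0:
        raise ValueError("trace must be sampled at >= 1 kHz")
    v = np.asarray(trace, dtype=float)
    dt_ms = 1000.0 / sampling_rate
    hi = np.inf if amp_max is None else amp_max
    pk_pos, _ = find_peaks(v)
    pk_neg, _ = find_peaks(-v)
    idx = np.sort(np.concatenate([pk_pos, pk_neg]))
    amp = np.abs(v[idx])
    keep = (amp >= amp_min) & (amp <= hi)
    idx, amp = idx[keep], amp[keep]
    if idx.size == 0:
        return np.empty(0)

    # refractory merge: extrema within the refractory period (inclusive:
    # intervals must exceed it to count separately) collapse to the
    # largest-amplitude one, so a biphasic pair counts once
    merged_t = []
    cluster = [0]
    for i in range(1, idx.size):
        if (idx[i] - idx[cluster[-1]]) * dt_ms <= refractory_ms:
            cluster.append(i)
        else:
            best = cluster[int(np.argmax(amp[cluster]))]
            merged_t.append(idx[best] * dt_ms)
            cluster = [i]
    best = cluster[int(np.argmax(amp[cluster]))]
    merged_t.append(idx[best] * dt_ms)
    return np.asarray(merged_t)


def icl_count(deflection_times: np.ndarray, interval_window_ms: float = ICL_WINDOW_MS) -> int:
    """Count consecutive-deflection intervals with 0 < dt <= window.

    Zero-length intervals are double-detection artifacts and excluded.
    """
    t = np.sort(np.asarray(deflection_times, dtype=float))
    if t.size < 2:
        return 0
    dt = np.diff(t)
    return int(np.count_nonzero((dt > 0) & (dt <= interval_window_ms)))


def point_features(
    egms: EGMSet,
    amp_min: float = FAAM_AMP_MIN_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> list[PointFeature]:
    """Compute features for every mapping point of an electrogram set.

    Points flagged poor quality are excluded from fractionation analysis
    (deflections empty, ICL 0) but retain their voltage measurement; the
    atrium-wide amplitude ceiling is the largest peak-to-peak voltage over
    good-quality points.
    """
    amp_max = max(
        (float(np.ptp(p.trace)) for p in egms.points if p.quality_flag == "good"),
        default=np.inf,
    )
    feats = []
    for p in egms.points:
        vpp = float(np.ptp(p.trace))
        if p.quality_flag != "good":
            feats.append(PointFeature(p.position, vpp, np.empty(0), 0, p.quality_flag))
            continue
        times = detect_deflections(
            p.trace, egms.sampling_rate, amp_min=amp_min, amp_max=amp_max,
            refractory_ms=refractory_ms,
        )
        feats.append(PointFeature(p.position, vpp, times, icl_count(times), "good"))
    return feats


def _in_footprint(
    feats: list[PointFeature],
    center_mm: tuple[float, float],
    radius_mm: float,
) -> list[PointFeature]:
    out = []
    for f in feats:
        d = np.hypot(f.position[0] - center_mm[0], f.position[1] - center_mm[1])
        if d <= radius_mm:
            out.append(f)
    return out


def icl_percentage(
    feats: list[PointFeature],
    location_centers: dict[str, tuple[float, float]],
    radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
    statistic: str = "max",
) -> dict[str, float]:
    """ICL% per location: location ICL relative to the atrium-wide maximum.

    The location ICL is the maximum point-wise ICL count within the
    location footprint (configurable to the mean). Undefined when no point
    in the whole map has a positive count.
    """
    counts = [f.icl_count for f in feats if f.quality_flag == "good"]
    atrium_max = max(counts, default=0)
    if atrium_max == 0:
        raise ValueError("atrium-wide maximum ICL is zero: ICL percentage undefined")
    out = {}
    for loc, center in location_centers.items():
        local = [f.icl_count for f in _in_footprint(feats, center, radius_mm)
                 if f.quality_flag == "good"]
        if not local:
            out[loc] = 0.0
            continue
        stat = max(local) if statistic == "max" else float(np.mean(local))
        out[loc] = 100.0 * stat / atrium_max
    return out


def bipolar_voltage_stats(
    feats: list[PointFeature],
    center_mm: tuple[float, float],
    radius_mm: float = DEFAULT_FOOTPRINT_RADIUS_MM,
) -> tuple[float, float]:
    """(max, mean) peak-to-peak bipolar voltage over points in a footprint."""
    local = _in_footprint(feats, center_mm, radius_mm)
    if not local:
        raise ValueError("no mapping points within the location footprint")
    v = np.array([f.voltage_pp for f in local])
    return float(v.max()), float(v.mean())
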