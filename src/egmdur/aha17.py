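"""AHA 17-segment transform and per-segment substrate summaries.

The left ventricle is divided into the standard 17 segments (6 basal, 6 mid,
4 apical, apex cap) by a deterministic geometric rule anchored on three user
landmarks (apex, base center, septal direction):

* long-axis coordinate ``t`` runs from 0 at the base center to 1 at the apex;
  ``t < 1/3`` is basal, ``1/3 <= t < 2/3`` mid, ``2/3 <= t < 0.85`` apical and
  ``t >= 0.85`` the apex cap (segment 17);
* the circumferential angle ``phi`` is measured from the septal direction in
  the short-axis plane, counterclockwise viewed from the apex. Sector
  *centers* align with the anatomical labels: basal/mid boundaries sit at
  phi = -30, 30, 90, ... deg (six 60-degree sectors, ids 2,1,6,5,4,3 and
  8,7,12,11,10,9 in increasing phi) and apical boundaries at -45, 45, 135,
  225 deg (ids 14, 13, 16, 15). All intervals are half-open on the lower
  bound, so every point gets exactly one segment.

Per segment, the summary carries the arithmetic mean EGM duration (degenerate
points excluded), mean bipolar voltage, the voltage class of that mean
(healthy > 1.0 mV, border zone 0.2-1.0 mV inclusive, dense scar < 0.2 mV),
whether any ablation lesion falls in the segment, and the abnormality flag
(segment mean duration strictly greater than the cutoff).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConsistencyError, ParameterError
from .model import ElectroanatomicMap, Landmarks

logger = logging.getLogger(__name__)

HEALTHY_VOLTAGE_MV = 1.0   # > 1.0 mV: healthy myocardium
DENSE_SCAR_VOLTAGE_MV = 0.2  # < 0.2 mV: dense scar; [0.2, 1.0] border zone

# Segment ids of the 60-degree basal sectors in increasing phi, starting at
# the sector centred on the septal direction.
_BASAL_ORDER = np.array([2, 1, 6, 5, 4, 3])
_APICAL_ORDER = np.array([14, 13, 16, 15])

SEGMENT_NAMES = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}

# Neighbor table (angular/radial overlap) used e.g. for border-zone halos.
SEGMENT_NEIGHBORS = {
    1: {2, 6, 7}, 2: {1, 3, 8}, 3: {2, 4, 9}, 4: {3, 5, 10}, 5: {4, 6, 11},
    6: {5, 1, 12},
    7: {8, 12, 1, 13}, 8: {7, 9, 2, 14}, 9: {8, 10, 3, 14, 15},
    10: {9, 11, 4, 15, 16}, 11: {10, 12, 5, 16}, 12: {11, 7, 6, 13, 16},
    13: {14, 16, 7, 12, 17}, 14: {13, 15, 8, 9, 17},
    15: {14, 16, 9, 10, 17}, 16: {15, 13, 10, 11, 12, 17},
    17: {13, 14, 15, 16},
}


@dataclass(frozen=True)
class SegmentSummary:
    segment: int
    n_points: int
    mean_duration_ms: float
    mean_voltage_mv: float
    voltage_class: str
    ablated: bool
    abnormal: bool


def classify_voltage(mean_voltage_mv: float) -> str:
    """Voltage class: healthy (> 1.0 mV), border (0.2-1.0 mV), dense (< 0.2 mV)."""
    if mean_voltage_mv < 0:
        raise ParameterError("voltage must be >= 0")
    if mean_voltage_mv > HEALTHY_VOLTAGE_MV:
        return "healthy"
    if mean_voltage_mv >= DENSE_SCAR_VOLTAGE_MV:
        return "border"
    return "dense"


def _frame(landmarks: Landmarks) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axis = landmarks.long_axis_unit()
    septal = landmarks.septal_direction - np.dot(landmarks.septal_direction, axis) * axis
    e1 = septal / np.linalg.norm(septal)
    e2 = np.cross(axis, e1)  # phi increases counterclockwise viewed from apex
    return axis, e1, e2


def assign_segments(
    positions: np.ndarray,
    landmarks: Landmarks,
    axis_guard_mm: float = 30.0,
) -> np.ndarray:
    """Segment id (1-17) for each row of ``positions`` (mm).

    Points whose long-axis coordinate lies more than ``axis_guard_mm`` beyond
    the apex-base extent trigger an out-of-chamber warning and are assigned to
    the nearest ring.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    axis, e1, e2 = _frame(landmarks)
    rel = positions - landmarks.base_center
    length = landmarks.long_axis_length_mm()
    t = rel @ axis / length

    overshoot_mm = np.maximum(-t, t - 1.0) * length
    n_outside = int(np.sum(overshoot_mm > axis_guard_mm))
    if n_outside:
        warnings.warn(
            f"{n_outside} position(s) lie > {axis_guard_mm} mm beyond the "
            "landmark long-axis extent; assigned to the nearest ring",
            stacklevel=2,
        )
    t = np.clip(t, 0.0, 1.0)

    phi = np.degrees(np.arctan2(rel @ e2, rel @ e1)) % 360.0
    sector6 = _BASAL_ORDER[(np.floor(((phi + 30.0) % 360.0) / 60.0)).astype(int)]
    sector4 = _APICAL_ORDER[(np.floor(((phi + 45.0) % 360.0) / 90.0)).astype(int)]

    seg = np.full(len(positions), 17, dtype=int)
    basal = t < 1.0 / 3.0
    mid = (t >= 1.0 / 3.0) & (t < 2.0 / 3.0)
    apical = (t >= 2.0 / 3.0) & (t < 0.85)
    seg[basal] = sector6[basal]
    seg[mid] = sector6[mid] + 6
    seg[apical] = sector4[apical]
    return seg


def assign_segment(position, landmarks: Landmarks, axis_guard_mm: float = 30.0) -> int:
    """Segment id (1-17) for a single 3-D position in mm."""
    return int(assign_segments(np.asarray(position, dtype=float)[None, :], landmarks, axis_guard_mm)[0])


def summarize_segments(
    emap: ElectroanatomicMap,
    durations: pd.DataFrame,
    cutoff_ms: float = 70.0,
    lesion_radius_mm: float = 0.0,
) -> pd.DataFrame:
    """Per-segment substrate summary (always 17 rows).

    ``durations`` must be the per-point result table of
    :func:`egmdur.duration.map_durations` covering exactly this map's points.
    Degenerate points are excluded from the duration mean (their count is
    logged); voltages of all points contribute to the voltage mean. A segment
    is ablated if a lesion center falls in it, or — when ``lesion_radius_mm``
    > 0 — if any map point of the segment lies within that radius of a lesion
    (lesions treated as spheres). Empty segments get voltage_class ``empty``
    and make no abnormal/ablated claims.
    """
    ids = emap.point_ids()
    dur = durations.set_index("point_id")
    if set(map(str, dur.index)) != set(map(str, ids)) or len(dur) != len(ids):
        raise ConsistencyError("durations table does not cover exactly the map's points")
    dur = dur.loc[ids]

    seg_of_point = assign_segments(emap.positions(), emap.landmarks)
    voltage = emap.voltages()
    duration_ms = dur["duration_ms"].to_numpy(dtype=float)
    degenerate = dur["degenerate"].to_numpy(dtype=bool)
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("excluding %d degenerate point(s) from segment duration means", n_degenerate)

    lesion_segments: set[int] = set()
    lesions = emap.lesion_positions()
    if len(lesions):
        lesion_segments.update(assign_segments(lesions, emap.landmarks).tolist())
        if lesion_radius_mm > 0 and emap.n_points:
            tree = cKDTree(emap.positions())
            for hit in tree.query_ball_point(lesions, r=lesion_radius_mm):
                lesion_segments.update(seg_of_point[hit].tolist())

    rows = []
    for seg in range(1, 18):
        in_seg = seg_of_point == seg
        n = int(in_seg.sum())
        if n == 0:
            rows.append((seg, 0, np.nan, np.nan, "empty", False, False))
            continue
        valid = in_seg & ~degenerate
        mean_dur = float(duration_ms[valid].mean()) if valid.any() else np.nan
        mean_volt = float(voltage[in_seg].mean())
        rows.append(
            (
                seg, n, mean_dur, mean_volt,
                classify_voltage(mean_volt),
                seg in lesion_segments,
                bool(np.isfinite(mean_dur) and mean_dur > cutoff_ms),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["segment", "n_points", "mean_duration_ms", "mean_voltage_mv",
                 "voltage_class", "ablated", "abnormal"],
    )
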