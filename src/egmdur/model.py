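"""Domain types for electroanatomic maps and bipolar electrograms.

The central objects are :class:`EgmTrace` (one bipolar electrogram sampled
uniformly, by default at 1 kHz so one sample is one millisecond),
:class:`MapPoint` (a mapped endocardial site: 3-D position in mm, peak-to-peak
bipolar voltage in mV, and its trace) and :class:`ElectroanatomicMap` (one
patient's map with optional triangulated surface, anatomical landmarks needed
for 17-segment assignment, and annotated ablation lesions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import FormatError, ParameterError

DEFAULT_SAMPLING_RATE_HZ = 1000.0


def _as_point3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ParameterError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} must be finite")
    return arr


@dataclass
class EgmTrace:
    """A single bipolar electrogram tied to a mapping point.

    Parameters
    ----------
    point_id : str
        Identifier of the mapping point the trace belongs to.
    samples : ndarray of float
        Voltage samples in mV. Must be non-empty and finite.
    sampling_rate_hz : float
        Samples per second; 1000 Hz by default (1 ms per sample).
    """

    point_id: str
    samples: np.ndarray
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("trace samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("trace samples must be finite")
        if not self.sampling_rate_hz > 0:
            raise ParameterError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        """Total trace length in milliseconds."""
        return self.n_samples * 1000.0 / self.sampling_rate_hz

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz


@dataclass
class MapPoint:
    """One acquired mapping point: position, bipolar amplitude and EGM."""

    point_id: str
    position: np.ndarray
    bipolar_voltage_mv: float
    trace: EgmTrace
    projection_distance_mm: float | None = None

    def __post_init__(self) -> None:
        self.position = _as_point3(self.position, "position")
        if self.bipolar_voltage_mv < 0:
            raise ParameterError("bipolar_voltage_mv must be >= 0")
        if self.projection_distance_mm is not None:
            if np.isnan(self.projection_distance_mm):
                self.projection_distance_mm = None
            elif self.projection_distance_mm < 0:
                raise ParameterError("projection_distance_mm must be >= 0")


@dataclass
class Landmarks:
    """Anatomical landmarks anchoring the 17-segment transform.

    The long axis runs from ``base_center`` (center of the mitral annulus
    plane) to ``apex``; ``septal_direction`` points toward the septum in the
    short-axis plane. All anatomy is derived from these three inputs, never
    from the coordinate axes, because export orientations vary by system.
    """

    apex: np.ndarray
    base_center: np.ndarray
    septal_direction: np.ndarray

    def __post_init__(self) -> None:
        self.apex = _as_point3(self.apex, "apex")
        self.base_center = _as_point3(self.base_center, "base_center")
        self.septal_direction = _as_point3(self.septal_direction, "septal_direction")
        if np.allclose(self.apex, self.base_center):
            raise ParameterError("apex and base_center must differ")
        axis = self.long_axis_unit()
        septal_perp = self.septal_direction - np.dot(self.septal_direction, axis) * axis
        if np.linalg.norm(septal_perp) < 1e-9:
            raise ParameterError(
                "septal_direction is parallel to the long axis; it must have a "
                "component in the short-axis plane"
            )

    def long_axis_unit(self) -> np.ndarray:
        """Unit vector from base_center toward apex."""
        axis = self.apex - self.base_center
        return axis / np.linalg.norm(axis)

    def long_axis_length_mm(self) -> float:
        return float(np.linalg.norm(self.apex - self.base_center))


@dataclass
class AblationLesion:
    """Site of radiofrequency energy delivery (annotated during the case)."""

    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = _as_point3(self.position, "position")


@dataclass
class Mesh:
    """Triangulated endocardial surface: vertices in mm, 0-based face triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("mesh vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("mesh faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise FormatError("mesh face indices must refer to existing vertices")


@dataclass
class ElectroanatomicMap:
    """One patient's electroanatomic map."""

    patient_id: str
    points: list[MapPoint]
    landmarks: Landmarks
    mesh: Mesh | None = None
    lesions: list[AblationLesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.point_id for p in self.points]
        if len(set(ids)) != len(ids):
            raise FormatError("point_ids must be unique within a map")
        lengths = {p.trace.n_samples for p in self.points}
        if len(lengths) > 1:
            raise FormatError("all traces in a map must have the same length")
        rates = {p.trace.sampling_rate_hz for p in self.points}
        if len(rates) > 1:
            raise FormatError("all traces in a map must share one sampling rate")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def sampling_rate_hz(self) -> float:
        if not self.points:
            return DEFAULT_SAMPLING_RATE_HZ
        return self.points[0].trace.sampling_rate_hz

    def point_ids(self) -> list[str]:
        return [p.point_id for p in self.points]

    def positions(self) -> np.ndarray:
        """(n_points, 3) array of point positions in mm."""
        if not self.points:
            return np.zeros((0, 3))
        return np.stack([p.position for p in self.points])

    def voltages(self) -> np.ndarray:
        return np.array([p.bipolar_voltage_mv for p in self.points], dtype=float)

    def trace_matrix(self) -> np.ndarray:
        """(n_points, n_samples) matrix of EGM samples in mV (map order)."""
        if not self.points:
            return np.zeros((0, 0))
        return np.stack([p.trace.samples for p in self.points])

    def lesion_positions(self) -> np.ndarray:
        if not self.lesions:
            return np.zeros((0, 3))
        return np.stack([l.position for l in self.lesions])


def make_traces(
    matrix: np.ndarray,
    point_ids: Sequence[str],
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> list[EgmTrace]:
    """Build one :class:`EgmTrace` per row of a sample matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != len(point_ids):
        raise FormatError("matrix rows and point_ids must correspond")
    return [
        EgmTrace(point_id=str(pid), samples=row, sampling_rate_hz=sampling_rate_hz)
        for pid, row in zip(point_ids, matrix)
    ]
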