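"""Reading and writing the EAMX electroanatomic-map interchange format.

Commercial mapping systems export maps in proprietary containers, so this
package defines a small, open, text-based schema ("EAMX", version 1) with two
interchangeable realizations that readers auto-detect:

* a **directory layout** — ``header.json`` plus CSV tables ``points.csv``,
  ``egms.csv`` and optionally ``mesh_vertices.csv`` / ``mesh_faces.csv`` /
  ``lesions.csv``;
* a **single JSON container** (a ``.json`` file holding the same blocks).

Numeric values are serialized with shortest round-trip ``repr`` so that
``read_map(write_map(m))`` reproduces every numeric field bit-exactly.

The header carries ``patient_id``, ``sampling_rate_hz``, ``n_samples`` and the
landmarks; the per-point EGM window length is free and recorded in the header,
since exports differ in how much signal they keep around each beat.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .model import (
    AblationLesion,
    ElectroanatomicMap,
    EgmTrace,
    Landmarks,
    MapPoint,
    Mesh,
)

logger = logging.getLogger(__name__)

EAMX_VERSION = "1.0"

_POINT_COLUMNS = ["point_id", "x_mm", "y_mm", "z_mm", "bipolar_voltage_mv", "projection_distance_mm"]


def _header_dict(emap: ElectroanatomicMap, n_samples: int) -> dict:
    return {
        "eamx_version": EAMX_VERSION,
        "patient_id": emap.patient_id,
        "sampling_rate_hz": emap.sampling_rate_hz,
        "n_samples": n_samples,
        "landmarks": {
            "apex": emap.landmarks.apex.tolist(),
            "base_center": emap.landmarks.base_center.tolist(),
            "septal_direction": emap.landmarks.septal_direction.tolist(),
        },
    }


def _points_frame(emap: ElectroanatomicMap) -> pd.DataFrame:
    rows = []
    for p in emap.points:
        rows.append(
            {
                "point_id": p.point_id,
                "x_mm": p.position[0],
                "y_mm": p.position[1],
                "z_mm": p.position[2],
                "bipolar_voltage_mv": p.bipolar_voltage_mv,
                "projection_distance_mm": np.nan
                if p.projection_distance_mm is None
                else p.projection_distance_mm,
            }
        )
    return pd.DataFrame(rows, columns=_POINT_COLUMNS)


def write_map(emap: ElectroanatomicMap, path: str | Path) -> None:
    """Write a map to ``path``.

    A path ending in ``.json`` produces the single-file JSON container;
    anything else is treated as a directory (created if missing) and written
    in the CSV+JSON layout.
    """
    path = Path(path)
    n_samples = emap.points[0].trace.n_samples if emap.points else 0
    header = _header_dict(emap, n_samples)
    points = _points_frame(emap)
    egm = emap.trace_matrix()

    if path.suffix == ".json":
        blob = dict(header)
        blob["points"] = points.to_dict(orient="list")
        blob["egm_mv"] = [row.tolist() for row in egm]
        if emap.mesh is not None:
            blob["mesh_vertices_mm"] = emap.mesh.vertices.tolist()
            blob["mesh_faces"] = emap.mesh.faces.tolist()
        blob["lesions_mm"] = emap.lesion_positions().tolist()
        tmp = json.dumps(blob, allow_nan=True)
        path.write_text(tmp)
        return

    path.mkdir(parents=True, exist_ok=True)
    (path / "header.json").write_text(json.dumps(header, indent=1))
    points.to_csv(path / "points.csv", index=False, float_format="%.17g")
    egm_df = pd.DataFrame(egm, columns=[f"s{i}" for i in range(n_samples)])
    egm_df.insert(0, "point_id", points["point_id"])
    egm_df.to_csv(path / "egms.csv", index=False, float_format="%.17g")
    if emap.mesh is not None:
        pd.DataFrame(emap.mesh.vertices, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path / "mesh_vertices.csv", index=False, float_format="%.17g"
        )
        pd.DataFrame(emap.mesh.faces, columns=["v0", "v1", "v2"]).to_csv(
            path / "mesh_faces.csv", index=False
        )
    if emap.lesions:
        pd.DataFrame(emap.lesion_positions(), columns=["x_mm", "y_mm", "z_mm"]).to_csv(
            path / "lesions.csv", index=False, float_format="%.17g"
        )


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required field '{key}' in {where}")
    return mapping[key]


def _landmarks_from_header(header: dict) -> Landmarks:
    lm = _require(header, "landmarks", "header")
    return Landmarks(
        apex=_require(lm, "apex", "landmarks"),
        base_center=_require(lm, "base_center", "landmarks"),
        septal_direction=_require(lm, "septal_direction", "landmarks"),
    )


def _build_map(
    header: dict,
    points: pd.DataFrame,
    egm: np.ndarray,
    mesh_vertices: np.ndarray | None,
    mesh_faces: np.ndarray | None,
    lesions: np.ndarray,
    max_projection_mm: float | None,
) -> ElectroanatomicMap:
    patient_id = str(_require(header, "patient_id", "header"))
    rate = float(_require(header, "sampling_rate_hz", "header"))
    n_samples = int(_require(header, "n_samples", "header"))

    for col in _POINT_COLUMNS[:-1]:  # projection_distance_mm is optional
        if col not in points.columns:
            raise SchemaError(f"missing required column '{col}' in points table")
    if "projection_distance_mm" not in points.columns:
        points = points.assign(projection_distance_mm=np.nan)

    if egm.ndim != 2 or egm.shape[0] != len(points):
        raise FormatError(
            f"EGM matrix has {egm.shape[0] if egm.ndim == 2 else 'malformed'} rows "
            f"for {len(points)} points"
        )
    if egm.shape[1] != n_samples:
        raise FormatError(
            f"EGM trace length {egm.shape[1]} disagrees with header n_samples {n_samples}"
        )

    map_points: list[MapPoint] = []
    n_dropped = 0
    for row, samples in zip(points.itertuples(index=False), egm):
        proj = None if pd.isna(row.projection_distance_mm) else float(row.projection_distance_mm)
        if max_projection_mm is not None and proj is not None and proj > max_projection_mm:
            n_dropped += 1
            continue
        trace = EgmTrace(point_id=str(row.point_id), samples=samples, sampling_rate_hz=rate)
        map_points.append(
            MapPoint(
                point_id=str(row.point_id),
                position=(row.x_mm, row.y_mm, row.z_mm),
                bipolar_voltage_mv=float(row.bipolar_voltage_mv),
                trace=trace,
                projection_distance_mm=proj,
            )
        )
    if n_dropped:
        logger.info(
            "dropped %d/%d points with projection distance > %.3g mm",
            n_dropped, len(points), max_projection_mm,
        )

    mesh = None
    if mesh_vertices is not None and mesh_faces is not None:
        mesh = Mesh(vertices=mesh_vertices, faces=mesh_faces)

    return ElectroanatomicMap(
        patient_id=patient_id,
        points=map_points,
        landmarks=_landmarks_from_header(header),
        mesh=mesh,
        lesions=[AblationLesion(position=p) for p in lesions],
    )


def read_map(path: str | Path, max_projection_mm: float | None = None) -> ElectroanatomicMap:
    """Read an EAMX map (directory layout or single JSON container).

    Points whose electrode-to-surface projection distance exceeds
    ``max_projection_mm`` are dropped (mapping systems use ~3 mm); points with
    no recorded projection distance are retained — only what is measurable is
    filtered. The number of dropped points is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if path.is_file():
        blob = json.loads(path.read_text())
        points = pd.DataFrame(_require(blob, "points", "container"))
        egm = np.asarray(_require(blob, "egm_mv", "container"), dtype=float)
        if egm.size == 0:
            egm = egm.reshape(len(points), int(blob.get("n_samples", 0)))
        mesh_v = blob.get("mesh_vertices_mm")
        mesh_f = blob.get("mesh_faces")
        lesions = np.asarray(blob.get("lesions_mm", []), dtype=float).reshape(-1, 3)
        return _build_map(
            blob,
            points,
            egm,
            None if mesh_v is None else np.asarray(mesh_v, dtype=float),
            None if mesh_f is None else np.asarray(mesh_f, dtype=int),
            lesions,
            max_projection_mm,
        )

    header_path = path / "header.json"
    if not header_path.exists():
        raise SchemaError(f"missing required file 'header.json' in {path}")
    header = json.loads(header_path.read_text())
    points_path = path / "points.csv"
    if not points_path.exists():
        raise SchemaError(f"missing required file 'points.csv' in {path}")
    points = pd.read_csv(points_path, float_precision="round_trip")
    egms_path = path / "egms.csv"
    if not egms_path.exists():
        raise SchemaError(f"missing required file 'egms.csv' in {path}")
    egm_df = pd.read_csv(egms_path, float_precision="round_trip")
    egm = egm_df.drop(columns=["point_id"], errors="ignore").to_numpy(dtype=float)

    mesh_v = mesh_f = None
    if (path / "mesh_vertices.csv").exists() and (path / "mesh_faces.csv").exists():
        mesh_v = pd.read_csv(path / "mesh_vertices.csv", float_precision="round_trip").to_numpy(dtype=float)
        mesh_f = pd.read_csv(path / "mesh_faces.csv").to_numpy(dtype=int)
    lesions = np.zeros((0, 3))
    if (path / "lesions.csv").exists():
        lesions = pd.read_csv(path / "lesions.csv", float_precision="round_trip").to_numpy(dtype=float).reshape(-1, 3)

    return _build_map(header, points, egm, mesh_v, mesh_f, lesions, max_projection_mm)
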