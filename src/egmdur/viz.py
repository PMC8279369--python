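"""Bull's-eye polar plots, 3-D map coloring and the end-to-end pipeline.

The bull's-eye follows the conventional orientation (septum left, anterior
up) with the basal ring outermost and the apex at the center. Duration maps
use a two-band scale split at the cutoff; voltage maps use the three
voltage-class bands. 3-D coloring paints each mesh vertex with the value of
the nearest mapping point within a fill threshold (5 mm by default, matching
common mapping-system display defaults); the threshold is display-only and
never feeds statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless backend; all output goes to files
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import cm, colors
from matplotlib.patches import Circle, Wedge
from scipy.spatial import cKDTree

from .aha17 import summarize_segments
from .duration import DurationParams, map_durations
from .errors import CapabilityError, ParameterError
from .filtering import FilterSpec
from .io import read_map
from .model import ElectroanatomicMap
from .stats import (
    chi_square,
    contingency,
    diagnostic_odds_ratio,
    sensitivity_specificity,
)

logger = logging.getLogger(__name__)

# Bull's-eye ring radii: apex cap, apical, mid, basal (outermost).
_RING_RADII = (0.25, 0.5, 0.75, 1.0)
# Segment ids per ring in increasing anatomical angle phi (phi=0 at septum).
_RING_SEGMENTS = {
    "basal": (2, 1, 6, 5, 4, 3),
    "mid": (8, 7, 12, 11, 10, 9),
    "apical": (14, 13, 16, 15),
}


@dataclass(frozen=True)
class PolarPlotData:
    """Exactly 17 per-segment values plus per-segment ablation markers."""

    values: np.ndarray
    ablated: np.ndarray
    vmin: float
    vmax: float
    label: str = ""
    cutoff: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "ablated", np.asarray(self.ablated, dtype=bool))
        if self.values.shape != (17,) or self.ablated.shape != (17,):
            raise ParameterError("polar plot needs exactly 17 values and 17 flags")
        if not (np.isfinite(self.vmin) and np.isfinite(self.vmax) and self.vmin < self.vmax):
            raise ParameterError("color bounds must be finite with vmin < vmax")


def _segment_patch_angles() -> dict[int, tuple[float, float, float, float]]:
    """(r_in, r_out, theta1_deg, theta2_deg) per segment in display coords.

    Display angle psi = 180 - phi puts the septum (phi=0) on the left and the
    anterior wall (phi=90) at the top.
    """
    out: dict[int, tuple[float, float, float, float]] = {}
    ring_bounds = {"apical": (0.25, 0.5), "mid": (0.5, 0.75), "basal": (0.75, 1.0)}
    for ring, segs in _RING_SEGMENTS.items():
        r_in, r_out = ring_bounds[ring]
        step = 360.0 / len(segs)
        start = -step / 2.0  # sector centers at phi = 0, step, 2*step, ...
        for k, seg in enumerate(segs):
            phi1 = start + k * step
            phi2 = phi1 + step
            psi1, psi2 = 180.0 - phi2, 180.0 - phi1  # reversed orientation
            out[seg] = (r_in, r_out, psi1, psi2)
    return out


def _segment_center_xy(seg: int) -> tuple[float, float]:
    if seg == 17:
        return 0.0, 0.0
    r_in, r_out, psi1, psi2 = _segment_patch_angles()[seg]
    r = 0.5 * (r_in + r_out)
    psi = np.radians(0.5 * (psi1 + psi2))
    return r * np.cos(psi), r * np.sin(psi)


def polar_plot(data: PolarPlotData, out: str | Path, cmap: str = "turbo") -> None:
    """Render a 17-segment bull's-eye to ``out`` (format from the suffix)."""
    norm = colors.Normalize(vmin=data.vmin, vmax=data.vmax)
    mapper = cm.ScalarMappable(norm=norm, cmap=cmap)

    fig, ax = plt.subplots(figsize=(6, 6))
    angles = _segment_patch_angles()
    for seg in range(1, 17):
        r_in, r_out, psi1, psi2 = angles[seg]
        face = mapper.to_rgba(data.values[seg - 1]) if np.isfinite(data.values[seg - 1]) else (0.85, 0.85, 0.85, 1.0)
        ax.add_patch(
            Wedge((0, 0), r_out, psi1, psi2, width=r_out - r_in,
                  facecolor=face, edgecolor="black", linewidth=1.0)
        )
    face17 = mapper.to_rgba(data.values[16]) if np.isfinite(data.values[16]) else (0.85, 0.85, 0.85, 1.0)
    ax.add_patch(Circle((0, 0), _RING_RADII[0], facecolor=face17, edgecolor="black", linewidth=1.0))

    for seg in range(1, 18):
        x, y = _segment_center_xy(seg)
        ax.text(x, y + 0.045, str(seg), ha="center", va="center", fontsize=9, color="black")
        if data.ablated[seg - 1]:
            ax.plot(x, y - 0.045, marker="o", markersize=7, color="white",
                    markeredgecolor="black", zorder=5)

    cbar = fig.colorbar(mapper, ax=ax, shrink=0.75)
    if data.label:
        cbar.set_label(data.label)
    if data.cutoff is not None and data.vmin < data.cutoff < data.vmax:
        cbar.ax.axhline(data.cutoff, color="black", linewidth=1.5, linestyle="--")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)


def polar_data_from_summary(
    summary: pd.DataFrame, column: str, vmin: float, vmax: float,
    label: str = "", cutoff: float | None = None,
) -> PolarPlotData:
    values = summary.sort_values("segment")[column].to_numpy(dtype=float)
    ablated = summary.sort_values("segment")["ablated"].to_numpy(dtype=bool)
    return PolarPlotData(values=values, ablated=ablated, vmin=vmin, vmax=vmax,
                         label=label, cutoff=cutoff)


def nearest_point_colors(
    emap: ElectroanatomicMap,
    values: np.ndarray,
    fill_threshold_mm: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex value from the nearest map point within the fill threshold.

    Returns (vertex_values, colored_mask); vertices with no point within the
    threshold are masked (rendered uncolored).
    """
    if emap.mesh is None:
        raise CapabilityError("map has no mesh; use the polar plot output instead")
    values = np.asarray(values, dtype=float)
    tree = cKDTree(emap.positions())
    dist, idx = tree.query(emap.mesh.vertices)
    colored = dist <= fill_threshold_mm
    vertex_values = np.where(colored, values[idx], np.nan)
    return vertex_values, colored


def color_map_3d(
    emap: ElectroanatomicMap,
    values: np.ndarray,
    out: str | Path,
    fill_threshold_mm: float = 5.0,
    cmap: str = "turbo",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Export the mesh as an ASCII PLY with per-vertex colors.

    Uncolored vertices (no mapping point within the threshold) are gray.
    """
    vertex_values, colored = nearest_point_colors(emap, values, fill_threshold_mm)
    finite = vertex_values[colored]
    if vmin is None:
        vmin = float(np.nanmin(finite)) if finite.size else 0.0
    if vmax is None:
        vmax = float(np.nanmax(finite)) if finite.size else 1.0
    if vmax <= vmin:
        vmax = vmin + 1.0
    mapper = cm.ScalarMappable(norm=colors.Normalize(vmin=vmin, vmax=vmax), cmap=cmap)
    rgba = mapper.to_rgba(np.where(colored, vertex_values, vmin))
    rgb = (rgba[:, :3] * 255).astype(int)
    rgb[~colored] = 160  # gray for unfilled vertices

    mesh = emap.mesh
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property float x", "property float y", "property float z",
        "property uchar red", "property uchar green", "property uchar blue",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, c in zip(mesh.vertices, rgb):
        lines.append(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f} {c[0]} {c[1]} {c[2]}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(out).write_text("\n".join(lines) + "\n")


def run_pipeline(
    inputs: Sequence[str | Path | ElectroanatomicMap],
    params: DurationParams = DurationParams(),
    filter_spec: FilterSpec | None = FilterSpec(),
    out_dir: str | Path = "egmdur_out",
    lesion_radius_mm: float = 0.0,
    make_plots: bool = True,
    make_3d: bool = False,
    max_projection_mm: float | None = None,
) -> dict:
    """End-to-end cohort analysis: durations, segments, statistics, plots.

    ``inputs`` may mix EAMX paths and in-memory maps. Per-patient failures are
    isolated and reported; the cohort statistics pool whatever succeeded. The
    machine-readable report is written to ``out_dir/report.json`` and
    returned. Output is independent of input ordering (patients are processed
    and reported keyed by patient_id).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    patients: dict[str, dict] = {}
    summaries = []
    failures: dict[str, str] = {}
    for item in inputs:
        name = None
        try:
            if isinstance(item, ElectroanatomicMap):
                emap = item
            else:
                name = str(item)
                emap = read_map(item, max_projection_mm=max_projection_mm)
            name = emap.patient_id
            durations = map_durations(emap, params, filter_spec)
            summary = summarize_segments(
                emap, durations, cutoff_ms=params.duration_cutoff_ms,
                lesion_radius_mm=lesion_radius_mm,
            )
            durations.to_csv(out_dir / f"{name}_durations.csv", index=False)
            summary.to_csv(out_dir / f"{name}_segments.csv", index=False)
            if make_plots:
                dur_data = polar_data_from_summary(
                    summary, "mean_duration_ms", vmin=0.0,
                    vmax=max(2 * params.duration_cutoff_ms,
                             float(np.nanmax(summary["mean_duration_ms"])) + 1.0),
                    label="mean EGM duration (ms)", cutoff=params.duration_cutoff_ms,
                )
                polar_plot(dur_data, out_dir / f"{name}_duration_polar.png")
                volt_data = polar_data_from_summary(
                    summary, "mean_voltage_mv", vmin=0.0,
                    vmax=max(2.0, float(np.nanmax(summary["mean_voltage_mv"])) + 0.1),
                    label="mean bipolar voltage (mV)",
                )
                polar_plot(volt_data, out_dir / f"{name}_voltage_polar.png")
            if make_3d and emap.mesh is not None:
                order = {pid: k for k, pid in enumerate(durations["point_id"])}
                vals = durations["duration_ms"].to_numpy()[
                    [order[pid] for pid in emap.point_ids()]
                ]
                color_map_3d(emap, vals, out_dir / f"{name}_duration.ply")
            summaries.append(summary)
            patients[name] = {
                "n_points": emap.n_points,
                "n_degenerate": int(durations["degenerate"].sum()),
                "segments": summary.to_dict(orient="records"),
            }
        except Exception as exc:  # isolate per-patient failures
            failures[name or repr(item)] = str(exc)
            logger.error("patient input %s failed: %s", name or item, exc)

    report: dict = {
        "params": {
            "sd_window_ms": params.sd_window_ms,
            "sd_threshold_frac": params.sd_threshold_frac,
            "duration_cutoff_ms": params.duration_cutoff_ms,
        },
        "patients": dict(sorted(patients.items())),
        "failures": failures,
    }
    if summaries:
        table = contingency(summaries)
        dor = diagnostic_odds_ratio(table)
        sens, spec_ = sensitivity_specificity(table)
        chi2, chi2_p = chi_square(table)
        report["cohort"] = {
            "contingency": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
            "dor": dor.dor, "dor_ci_low": dor.ci_low, "dor_ci_high": dor.ci_high,
            "dor_corrected": dor.corrected, "dor_p_value": dor.p_value,
            "sensitivity": sens, "specificity": spec_,
            "chi_square": chi2, "chi_square_p": chi2_p,
        }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
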