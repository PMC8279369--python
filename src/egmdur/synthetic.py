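"""Synthetic left-ventricular maps with scar architecture and class-specific EGMs.

Clinical electroanatomic exports are proprietary, so every downstream module
is exercised on synthetic cohorts built here. A patient is a truncated
ellipsoidal LV endocardial shell (~80 mm long axis, ~25 mm short-axis radius)
with points sampled uniformly on the surface. Dense-scar segments are drawn
per patient (location frequencies follow the typical inferior-basal
predominance of ischemic scar); optionally their neighbors form a border-zone
halo; all remaining segments are healthy.

Electrogram archetypes are sums of Gaussian-enveloped sinusoids (Gabor
wavelets, per-component center frequency 80-200 Hz so the morphology survives
the 30-250 Hz bandpass):

* healthy (> 1.0 mV): 1-2 short sharp components, true duration < 50 ms;
* border zone (0.2-1.0 mV): >= 3 staggered components (fractionation) with a
  dominant early deflection and progressively smaller late components (late
  potentials are low-amplitude), true duration 75-150 ms;
* dense scar (< 0.2 mV): low-amplitude prolonged activity, 80-185 ms.

Two features make the cohort resemble clinical data rather than a toy with
perfectly separated classes: durations carry a per-segment random effect
(slow conduction is spatially correlated, and healthy-voltage segments
adjacent to the scar region have mildly prolonged durations), and the
ablation lesion set correlates imperfectly with the substrate — most lesions
fall in scar/halo segments, some spill into the adjacent healthy segments and
a few land at remote bystander sites.

Ground-truth duration is defined generator-side, independent of the detector:
the support of the noise-free composite above 1% of its peak, rescaled so the
support spans exactly the requested duration and sits centred in the trace.
White noise with 0.01 mV RMS emulates the low noise floor of mini-electrode
basket acquisitions. Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aha17 import SEGMENT_NEIGHBORS, assign_segments
from .errors import ParameterError
from .model import (
    AblationLesion,
    ElectroanatomicMap,
    EgmTrace,
    Landmarks,
    MapPoint,
    Mesh,
)

# Ellipsoid semi-axes (mm): short-axis radius and long semi-axis; the shell is
# truncated at 80% of the long semi-axis above center (base plane), giving an
# apex-to-base length of ~81 mm and a basal ring radius of ~15 mm.
SHORT_AXIS_MM = 25.0
LONG_SEMI_AXIS_MM = 45.0
BASE_TRUNCATION = 0.8

# Scar-region location frequencies (region -> weight), matching the typical
# distribution in ischemic VT cohorts: inferior-basal scar predominates.
SCAR_REGIONS: tuple[tuple[frozenset[int], float], ...] = (
    (frozenset({17}), 2 / 16),        # apical
    (frozenset({2, 8}), 1 / 16),      # anteroseptal
    (frozenset({3, 9}), 3 / 16),      # inferoseptal
    (frozenset({4}), 6 / 16),         # inferior basal
    (frozenset({5, 11}), 2 / 16),     # inferolateral
    (frozenset({6, 12}), 2 / 16),     # anterolateral
)

_CLASS_BANDS = {
    # class: (duration_lo, duration_hi, amp_lo, amp_hi, n_comp_lo, n_comp_hi)
    "healthy": (24.0, 48.0, 1.2, 3.0, 1, 2),
    "border": (75.0, 150.0, 0.22, 0.95, 3, 6),
    "dense": (80.0, 185.0, 0.03, 0.18, 2, 5),
}

# Per-segment duration random effects (ms): activity duration is spatially
# correlated, so points within one segment share a segment-level center with
# a small per-point jitter. "Elevated" healthy segments border the scar/halo
# region, where conduction is already slowed despite healthy voltage.
_SEGMENT_DURATION_EFFECTS = {
    # role: (center_lo, center_hi, point_jitter)
    "dense": (90.0, 175.0, 10.0),
    "border": (80.0, 145.0, 5.0),
    "healthy_elevated": (30.0, 42.0, 3.0),
    "healthy": (24.0, 38.0, 3.0),
}


@dataclass(frozen=True)
class EgmMorphology:
    """Archetype of one synthetic EGM (generator ground truth)."""

    egm_class: str
    true_duration_ms: float
    amplitude_mv: float
    n_components: int

    def __post_init__(self) -> None:
        if self.egm_class not in _CLASS_BANDS:
            raise ParameterError(f"unknown EGM class '{self.egm_class}'")
        if self.true_duration_ms <= 0 or self.amplitude_mv <= 0 or self.n_components < 1:
            raise ParameterError("morphology fields must be positive")


def random_morphology(egm_class: str, rng: np.random.Generator) -> EgmMorphology:
    """Draw a morphology within the class band."""
    if egm_class not in _CLASS_BANDS:
        raise ParameterError(f"unknown EGM class '{egm_class}'")
    d_lo, d_hi, a_lo, a_hi, n_lo, n_hi = _CLASS_BANDS[egm_class]
    return EgmMorphology(
        egm_class=egm_class,
        true_duration_ms=float(rng.uniform(d_lo, d_hi)),
        amplitude_mv=float(rng.uniform(a_lo, a_hi)),
        n_components=int(rng.integers(n_lo, n_hi + 1)),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate a 16-patient high-density mapping cohort with 2000
    points per map (clinical maps reach ~8000), a 0.01 mV noise floor, one
    scar region per patient with a border-zone halo, and ablation lesions
    placed in scar and halo segments.
    """

    n_patients: int = 16
    points_per_map: int = 2000
    scar_segments: tuple[int, ...] | None = None  # None: drawn per patient
    border_halo: bool = True
    noise_mv: float = 0.01
    ablate_on: str = "scar_and_border"  # or "scar_only"
    n_lesions: int = 8
    lesion_spillover_frac: float = 0.2
    lesion_remote_frac: float = 0.1
    trace_ms: float = 400.0
    sampling_rate_hz: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.points_per_map < 17:
            raise ParameterError("points_per_map must be >= 17")
        if self.noise_mv < 0:
            raise ParameterError("noise_mv must be >= 0")
        if not 0 <= self.lesion_spillover_frac <= 1:
            raise ParameterError("lesion_spillover_frac must be in [0, 1]")
        if not 0 <= self.lesion_remote_frac <= 1 - self.lesion_spillover_frac:
            raise ParameterError("lesion_remote_frac must be in [0, 1 - lesion_spillover_frac]")
        if self.ablate_on not in ("scar_and_border", "scar_only"):
            raise ParameterError("ablate_on must be 'scar_and_border' or 'scar_only'")
        if self.scar_segments is not None:
            segs = tuple(int(s) for s in self.scar_segments)
            if not segs and self.ablate_on == "scar_only":
                raise ParameterError("scar_segments empty with ablate_on='scar_only'")
            if any(not 1 <= s <= 17 for s in segs):
                raise ParameterError("scar segment ids must be in 1..17")
            object.__setattr__(self, "scar_segments", segs)


def generate_geometry(
    seed: int | None = None,
    n_rings: int = 24,
    n_around: int = 32,
) -> tuple[Mesh, Landmarks]:
    """Truncated-ellipsoid LV endocardial shell and consistent landmarks.

    The construction is deterministic; ``seed`` is accepted for interface
    symmetry with the other generators but does not alter the geometry.
    """
    a, c = SHORT_AXIS_MM, LONG_SEMI_AXIS_MM
    theta0 = np.arccos(-BASE_TRUNCATION)  # polar angle of the base ring
    # rings from near-apex (small theta) to base (theta0)
    thetas = theta0 * np.arange(1, n_rings + 1) / n_rings
    phis = 2 * np.pi * np.arange(n_around) / n_around

    vertices = [np.array([0.0, 0.0, -c])]  # apex pole
    for th in thetas:
        ring = np.stack(
            [a * np.sin(th) * np.cos(phis), a * np.sin(th) * np.sin(phis),
             np.full(n_around, -c * np.cos(th))],
            axis=1,
        )
        vertices.extend(ring)
    vertices = np.asarray(np.vstack(vertices), dtype=float)

    faces = []
    for j in range(n_around):  # apex fan
        faces.append((0, 1 + j, 1 + (j + 1) % n_around))
    for i in range(n_rings - 1):  # quad strips
        base0 = 1 + i * n_around
        base1 = base0 + n_around
        for j in range(n_around):
            jn = (j + 1) % n_around
            faces.append((base0 + j, base1 + j, base1 + jn))
            faces.append((base0 + j, base1 + jn, base0 + jn))
    mesh = Mesh(vertices=vertices, faces=np.asarray(faces, dtype=int))

    landmarks = Landmarks(
        apex=np.array([0.0, 0.0, -c]),
        base_center=np.array([0.0, 0.0, c * BASE_TRUNCATION]),
        septal_direction=np.array([1.0, 0.0, 0.0]),
    )
    return mesh, landmarks


def sample_surface(mesh: Mesh, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform (area-weighted) random points on a triangulated surface."""
    v = mesh.vertices
    tri = v[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    face_idx = rng.choice(len(areas), size=n, p=areas / areas.sum())
    u = rng.random(n)
    w = rng.random(n)
    flip = u + w > 1.0
    u[flip] = 1.0 - u[flip]
    w[flip] = 1.0 - w[flip]
    t = tri[face_idx]
    return t[:, 0] + u[:, None] * (t[:, 1] - t[:, 0]) + w[:, None] * (t[:, 2] - t[:, 0])


def _gabor_sum(t_ms, centers_ms, sigmas_ms, freqs_hz, amps, phases):
    """Sum of Gaussian-enveloped sinusoids evaluated at times ``t_ms``."""
    out = np.zeros_like(t_ms, dtype=float)
    for mu, sg, f, a, ph in zip(centers_ms, sigmas_ms, freqs_hz, amps, phases):
        out += a * np.exp(-0.5 * ((t_ms - mu) / sg) ** 2) * np.sin(
            2 * np.pi * f * (t_ms - mu) / 1000.0 + ph
        )
    return out


def generate_egm(
    morphology: EgmMorphology,
    sampling_rate_hz: float = 1000.0,
    trace_ms: float = 400.0,
    noise_mv: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> tuple[EgmTrace, float, float]:
    """One synthetic EGM plus its ground-truth (onset_ms, offset_ms).

    The composite wavelet is rescaled in time so that its support above 1% of
    peak spans exactly ``morphology.true_duration_ms``, centred in the trace,
    then scaled so the sampled peak-to-peak amplitude equals
    ``morphology.amplitude_mv``, and finally white noise of RMS ``noise_mv``
    is added.
    """
    rng = np.random.default_rng(rng)
    d = morphology.true_duration_ms
    if trace_ms < d + 100.0:
        raise ParameterError(
            f"trace_ms={trace_ms} too short for true duration {d} ms (+100 ms margin)"
        )
    n = morphology.n_components
    if n == 1:
        centers = np.array([0.5 * d])
    else:
        centers = np.linspace(0.15 * d, 0.85 * d, n) + rng.uniform(-0.04 * d, 0.04 * d, n)
    sigmas = np.minimum(d * rng.uniform(0.06, 0.10, n), 14.0)
    freqs = rng.uniform(80.0, 200.0, n)
    if morphology.egm_class == "healthy":
        amps = rng.uniform(0.6, 1.0, n)
    else:
        # scarred tissue: a dominant early deflection followed by progressively
        # smaller late components (late potentials / LAVA are low-amplitude)
        decay = rng.uniform(0.6, 0.8)
        amps = decay ** np.arange(n) * rng.uniform(0.85, 1.15, n)
        amps[0] = 1.0
        amps = np.maximum(amps, 0.12)
    phases = rng.uniform(0.0, 2 * np.pi, n)

    fine = np.arange(-0.6 * d, 1.6 * d, 0.2)
    g = _gabor_sum(fine, centers, sigmas, freqs, amps, phases)
    peak = np.max(np.abs(g))
    above = np.abs(g) >= 0.01 * peak
    t0, t1 = fine[above][0], fine[above][-1]

    onset_ms = (trace_ms - d) / 2.0
    offset_ms = onset_ms + d
    n_samples = int(round(trace_ms * sampling_rate_hz / 1000.0))
    t = np.arange(n_samples) * 1000.0 / sampling_rate_hz
    # affine time map: [onset, offset] in trace time -> [t0, t1] in wavelet time
    tau = t0 + (t - onset_ms) * (t1 - t0) / d
    s = _gabor_sum(tau, centers, sigmas, freqs, amps, phases)
    p2p = s.max() - s.min()
    s *= morphology.amplitude_mv / p2p
    if noise_mv > 0:
        s = s + rng.normal(0.0, noise_mv, n_samples)
    trace = EgmTrace(point_id="synthetic", samples=s, sampling_rate_hz=sampling_rate_hz)
    return trace, onset_ms, offset_ms


def _draw_scar_segments(rng: np.random.Generator) -> tuple[int, ...]:
    weights = np.array([w for _, w in SCAR_REGIONS])
    idx = rng.choice(len(SCAR_REGIONS), p=weights / weights.sum())
    return tuple(sorted(SCAR_REGIONS[idx][0]))


def _halo(scar: set[int]) -> set[int]:
    halo: set[int] = set()
    for seg in scar:
        halo |= SEGMENT_NEIGHBORS[seg]
    return halo - scar


def _segment_roles(scar: set[int], halo: set[int]) -> dict[int, str]:
    """Role of every segment: dense scar, border halo, elevated healthy
    (adjacent to the scar/halo region, where conduction is already slowed
    despite healthy voltage), or remote healthy."""
    adjacent: set[int] = set()
    for seg in scar | halo:
        adjacent |= SEGMENT_NEIGHBORS[seg]
    adjacent -= scar | halo
    roles = {}
    for seg in range(1, 18):
        if seg in scar:
            roles[seg] = "dense"
        elif seg in halo:
            roles[seg] = "border"
        elif seg in adjacent:
            roles[seg] = "healthy_elevated"
        else:
            roles[seg] = "healthy"
    return roles


def generate_patient(
    spec: CohortSpec, patient_index: int, rng: np.random.Generator
) -> tuple[ElectroanatomicMap, pd.DataFrame]:
    """One synthetic patient map and its per-point ground-truth table."""
    mesh, landmarks = generate_geometry()
    positions = sample_surface(mesh, spec.points_per_map, rng)
    segments = assign_segments(positions, landmarks)

    scar = set(spec.scar_segments) if spec.scar_segments is not None else set(
        _draw_scar_segments(rng)
    )
    halo = _halo(scar) if spec.border_halo else set()
    roles = _segment_roles(scar, halo)

    # per-segment duration centers (spatially correlated slow conduction)
    seg_duration_center = {}
    for seg in range(1, 18):
        lo, hi, _ = _SEGMENT_DURATION_EFFECTS[roles[seg]]
        seg_duration_center[seg] = float(rng.uniform(lo, hi))

    points: list[MapPoint] = []
    truth_rows = []
    for i, (pos, seg) in enumerate(zip(positions, segments)):
        role = roles[seg]
        cls = role if role in ("dense", "border") else "healthy"
        jitter = _SEGMENT_DURATION_EFFECTS[role][2]
        d_lo, d_hi, a_lo, a_hi, n_lo, n_hi = _CLASS_BANDS[cls]
        d = float(np.clip(seg_duration_center[seg] + rng.uniform(-jitter, jitter),
                          d_lo if cls != "healthy" else 1.0, d_hi))
        morph = EgmMorphology(
            egm_class=cls,
            true_duration_ms=d,
            amplitude_mv=float(rng.uniform(a_lo, a_hi)),
            n_components=int(rng.integers(n_lo, n_hi + 1)),
        )
        trace, onset, offset = generate_egm(
            morph, spec.sampling_rate_hz, spec.trace_ms, spec.noise_mv, rng
        )
        pid = f"p{i:05d}"
        points.append(
            MapPoint(
                point_id=pid,
                position=pos,
                bipolar_voltage_mv=morph.amplitude_mv,
                trace=EgmTrace(pid, trace.samples, spec.sampling_rate_hz),
            )
        )
        truth_rows.append(
            (pid, int(seg), cls, morph.true_duration_ms, onset, offset,
             morph.amplitude_mv, morph.n_components)
        )

    # Ablation: most lesions inside the rule segments (scar, optionally halo).
    # A fraction spills into the adjacent healthy segments (clinical lesion
    # sets extend beyond the low-voltage region) and a smaller fraction lands
    # at remote healthy sites (bystander or exit-site ablation), so ablation
    # and prolonged duration correlate imperfectly, as in real cohorts.
    eligible = scar | halo if spec.ablate_on == "scar_and_border" else scar
    adjacent = {s for s, r in roles.items() if r == "healthy_elevated"}
    remote = {s for s, r in roles.items() if r == "healthy"}
    eligible_idx = np.flatnonzero(np.isin(segments, sorted(eligible)))
    adjacent_idx = np.flatnonzero(np.isin(segments, sorted(adjacent)))
    remote_idx = np.flatnonzero(np.isin(segments, sorted(remote)))
    lesions: list[AblationLesion] = []
    for _ in range(spec.n_lesions):
        u = rng.random()
        if u < spec.lesion_spillover_frac and len(adjacent_idx):
            pool = adjacent_idx
        elif u < spec.lesion_spillover_frac + spec.lesion_remote_frac and len(remote_idx):
            pool = remote_idx
        else:
            pool = eligible_idx
        if not len(pool):
            continue
        lesions.append(AblationLesion(position=positions[rng.choice(pool)]))

    emap = ElectroanatomicMap(
        patient_id=f"synth{patient_index:02d}",
        points=points,
        landmarks=landmarks,
        mesh=mesh,
        lesions=lesions,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["point_id", "segment", "egm_class", "true_duration_ms",
                 "true_onset_ms", "true_offset_ms", "amplitude_mv", "n_components"],
    )
    return emap, truth


def generate_cohort(
    spec: CohortSpec, return_truth: bool = False
) -> list[ElectroanatomicMap] | tuple[list[ElectroanatomicMap], list[pd.DataFrame]]:
    """Generate the full cohort, reproducibly from ``spec.seed``."""
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    maps, truths = [], []
    for i, child in enumerate(children):
        emap, truth = generate_patient(spec, i, np.random.default_rng(child))
        maps.append(emap)
        truths.append(truth)
    return (maps, truths) if return_truth else maps
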