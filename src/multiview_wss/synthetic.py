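"""Procedural AAA-like geometries and an analytic pseudo-CFD oracle.

Real studies of aneurysm hemodynamics pair patient/sculpted geometries with
transient CFD; neither is re-runnable in a test suite. This module stands in
for both ends: a seeded parametric generator sweeps a circular cross-section
along a (gently bent) centerline with a smooth sac-shaped radius bump, and a
Poiseuille-like law (wall shear ∝ flow / r³) modulated by a pulsatile
waveform produces per-vertex WSS vector time series whose time average is
smooth, positive, lower inside the sac, and anti-correlated with surface
curvature — the qualitative structure the surrogate must learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .mesh import TriMesh, ScalarField, mean_curvature, save_mesh

__all__ = [
    "AortaParams",
    "FlowWaveform",
    "WSSSeries",
    "default_waveform",
    "generate_aorta",
    "pseudo_cfd_wss",
    "tawss",
    "build_dataset",
    "realize_geometry",
    "save_manifest",
    "load_manifest",
    "write_wss_series",
    "read_wss_series",
]


class ParameterError(ValueError):
    """Geometry parameters describe a self-intersecting or invalid shape."""


@dataclass(frozen=True)
class AortaParams:
    """Parameters of one synthetic AAA-like geometry.

    The sac radius is ``base_radius * (1 + bulge_factor)``; the default
    ``bulge_factor=0.8`` corresponds to a dilatation of 80% of the normal
    vessel diameter, past the 50% threshold that defines an aneurysm.
    Lengths in mm.
    """

    centerline_length: float = 120.0
    base_radius: float = 10.0
    bulge_factor: float = 0.8
    bulge_center: float = 0.5
    bulge_width: float = 30.0
    centerline_curvature: float = 0.08
    radius_noise: float = 0.01
    axial_resolution: int = 80
    circumferential_resolution: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ParameterError("base_radius must be positive")
        if self.bulge_factor < 0:
            raise ParameterError("bulge_factor must be >= 0")
        if not 0 < self.bulge_center < 1:
            raise ParameterError("bulge_center must lie in (0, 1)")
        if self.axial_resolution < 8 or self.circumferential_resolution < 8:
            raise ParameterError("resolutions must be >= 8")
        if self.bulge_width > self.centerline_length:
            raise ParameterError("bulge_width exceeds centerline_length "
                                 "(self-intersecting sac)")


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic inlet velocity over one cardiac cycle (times s, values m/s)."""

    times: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        if len(t) < 10:
            raise ValueError("waveform needs at least 10 samples per cycle")
        if t.shape != v.shape or not np.all(np.diff(t) > 0):
            raise ValueError("waveform times must be strictly increasing")
        if abs(v[0] - v[-1]) > 1e-12:
            raise ValueError("waveform must be periodic (first == last value)")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def at(self, t: np.ndarray) -> np.ndarray:
        """Velocity at arbitrary times, wrapping periodically."""
        tt = (np.asarray(t, dtype=float) - self.times[0]) % self.period + self.times[0]
        return np.interp(tt, self.times, self.velocities)

    def mean(self) -> float:
        return float(np.trapezoid(self.velocities, self.times) / self.period)

    def scaled(self, c: float) -> "FlowWaveform":
        return FlowWaveform(self.times.copy(), self.velocities * c)


def default_waveform(period: float = 1.0, n: int = 64,
                     v_diastole: float = 0.1, v_peak: float = 0.6) -> FlowWaveform:
    """Two-phase systolic/diastolic template with the peak at 30% of the cycle.

    Diastolic baseline plus a smooth systolic bump supported on
    [0.05, 0.55] of the cycle (sin² window, maximum at 0.30). This is a
    qualitative stand-in for a literature aortic inlet waveform.
    """
    tau = np.linspace(0.0, 1.0, n)
    v = np.full(n, v_diastole)
    win = (tau >= 0.05) & (tau <= 0.55)
    v[win] += (v_peak - v_diastole) * np.sin(np.pi * (tau[win] - 0.05) / 0.5) ** 2
    v[-1] = v[0]
    return FlowWaveform(tau * period, v)


# Reference velocity for the shear law: the time-mean of the default
# template. With the default waveform the straight-tube TAWSS equals tau0
# exactly, and scaling the waveform scales the stress linearly (tau ∝ Q).
_V_REF = default_waveform().mean()


@dataclass
class WSSSeries:
    """Per-vertex WSS vectors (Pa) over time: values[step, vertex, xyz]."""

    values: np.ndarray
    dt: float
    cycle_period: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must have shape (n_steps, n_vertices, 3)")
        if self.dt <= 0 or self.cycle_period <= 0:
            raise ValueError("dt and cycle_period must be positive")
        n_cycles = self.n_steps * self.dt / self.cycle_period
        if n_cycles < 1 - 1e-9 or abs(n_cycles - round(n_cycles)) > 1e-6:
            raise ValueError("series must cover an integer number >= 1 of cycles")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.cycle_period / self.dt))

    @property
    def n_cycles(self) -> int:
        return self.n_steps // self.steps_per_cycle


# ---------------------------------------------------------------------------
# Geometry generation
# ---------------------------------------------------------------------------

def _bump(t: np.ndarray, center: float, width_frac: float) -> np.ndarray:
    """Smooth unit bump in arclength fraction; sigma = width/2 in mm."""
    return np.exp(-0.5 * ((t - center) / (width_frac / 2.0)) ** 2)


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent + rotation-minimizing normal/binormal along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.zeros_like(tangents)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = ref - np.dot(ref, tangents[0]) * tangents[0]
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(points)):
        # double-reflection step for a rotation-minimizing frame
        v1 = points[i] - points[i - 1]
        c1 = np.dot(v1, v1)
        if c1 < 1e-18:
            normals[i] = normals[i - 1]
            continue
        nL = normals[i - 1] - (2.0 / c1) * np.dot(v1, normals[i - 1]) * v1
        tL = tangents[i - 1] - (2.0 / c1) * np.dot(v1, tangents[i - 1]) * v1
        v2 = tangents[i] - tL
        c2 = np.dot(v2, v2)
        n = nL if c2 < 1e-18 else nL - (2.0 / c2) * np.dot(v2, nL) * v2
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def generate_aorta(params: AortaParams) -> TriMesh:
    """Watertight tube-with-sac mesh, deterministic in ``params.seed``.

    The seed perturbs the centerline bend direction, a small off-axis sac
    displacement, and a smooth axial radius noise; the nominal radius
    profile is ``base_radius * (1 + bulge_factor * G(s))`` with G a Gaussian
    bump at ``bulge_center``.

    The mesh carries metadata used by the pseudo-CFD oracle: per-vertex
    arclength fraction, local tube radius, and axial tangent direction.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    A, C = p.axial_resolution, p.circumferential_resolution
    t = np.linspace(0.0, 1.0, A)
    L = p.centerline_length

    # centerline: mostly along +z with a planar bend in a seeded direction
    phi = rng.uniform(0, 2 * np.pi)
    bend = p.centerline_curvature * L * np.sin(np.pi * t)
    centers = np.column_stack([
        bend * np.cos(phi),
        bend * np.sin(phi),
        t * L,
    ])
    # seeded off-axis sac displacement (asymmetric aneurysm)
    G = _bump(t, p.bulge_center, p.bulge_width / L)
    asym_dir = rng.uniform(0, 2 * np.pi)
    asym_amp = rng.uniform(0.0, 0.3) * p.base_radius * p.bulge_factor
    centers[:, 0] += asym_amp * G * np.cos(asym_dir)
    centers[:, 1] += asym_amp * G * np.sin(asym_dir)

    # smooth axial radius noise: a few low-order Fourier modes
    noise = np.zeros(A)
    for k in range(2, 6):
        noise += rng.normal(0, 1) * np.sin(np.pi * k * t) / k
    radius = p.base_radius * (1.0 + p.bulge_factor * G) * (1.0 + p.radius_noise * noise)
    if np.any(radius <= 0):
        raise ParameterError("radius profile is non-positive")

    tangents, normals, binormals = _parallel_transport_frames(centers)
    theta = np.linspace(0, 2 * np.pi, C, endpoint=False)
    ring_dirs = (np.cos(theta)[None, :, None] * normals[:, None, :]
                 + np.sin(theta)[None, :, None] * binormals[:, None, :])
    verts = centers[:, None, :] + radius[:, None, None] * ring_dirs
    verts = verts.reshape(A * C, 3)

    faces = []
    for a in range(A - 1):
        for c in range(C):
            c2 = (c + 1) % C
            i00, i01 = a * C + c, a * C + c2
            i10, i11 = (a + 1) * C + c, (a + 1) * C + c2
            faces.append([i00, i10, i11])
            faces.append([i00, i11, i01])
    # end caps as fans around center vertices
    v0 = len(verts)
    v1 = v0 + 1
    verts = np.vstack([verts, centers[0], centers[-1]])
    for c in range(C):
        c2 = (c + 1) % C
        faces.append([v0, c2, c])
        faces.append([v1, (A - 1) * C + c, (A - 1) * C + c2])
    faces = np.asarray(faces, dtype=np.int64)

    mesh = TriMesh(verts, faces)
    tm = mesh.to_trimesh()
    if tm.volume < 0:  # enforce outward orientation
        faces = faces[:, [0, 2, 1]]
        mesh = TriMesh(verts, faces)

    arclength = np.concatenate([np.repeat(t, C), [0.0, 1.0]])
    local_radius = np.concatenate([np.repeat(radius, C), [radius[0], radius[-1]]])
    axial = np.vstack([np.repeat(tangents, C, axis=0), tangents[0], tangents[-1]])
    mesh.metadata.update({
        "generator": "synthetic_aorta",
        "params": asdict(p),
        "arclength_frac": arclength,
        "local_radius": local_radius,
        "axial_tangent": axial,
    })
    return mesh


# ---------------------------------------------------------------------------
# Pseudo-CFD oracle
# ---------------------------------------------------------------------------

def pseudo_cfd_wss(
    mesh: TriMesh,
    params: AortaParams,
    waveform: FlowWaveform | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    tau0: float = 1.5,
    dt: float = 0.01,
    n_cycles: int = 3,
) -> WSSSeries:
    """Analytic WSS time series from a Poiseuille-like shear law.

    The instantaneous magnitude at a vertex with local tube radius r is
    ``tau0 * (base_radius / r)^3 * w(t) / v_ref`` — the r^-3 dependence of
    fully developed laminar pipe flow at fixed flow rate, modulated by the
    inlet waveform (v_ref is the default template's time mean, so the
    straight-tube TAWSS under the default waveform equals ``tau0``). Vectors
    point along the local axial tangent; optional zero-mean Gaussian noise
    (Pa, seeded) is added along that direction.

    The sac therefore sees low WSS (large r) exactly where curvature is
    extreme, reproducing the qualitative low-WSS-in-the-sac pattern of
    transient CFD on aneurysms at a tiny fraction of the cost.
    """
    if waveform is None:
        waveform = default_waveform()
    r = mesh.metadata.get("local_radius")
    axial = mesh.metadata.get("axial_tangent")
    if r is None or axial is None:
        r, axial = _estimate_tube_geometry(mesh)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("local radius must be positive everywhere")

    n_steps = int(round(n_cycles * waveform.period / dt))
    times = np.arange(n_steps) * dt
    w = waveform.at(times)
    spatial = tau0 * (params.base_radius / r) ** 3  # (n_vertices,)
    mag = spatial[None, :] * (w[:, None] / _V_REF)  # (n_steps, n_vertices)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mag = mag + rng.normal(0.0, noise_sd, size=mag.shape)
    values = mag[:, :, None].astype(np.float32) * np.asarray(axial, np.float32)[None, :, :]
    return WSSSeries(values, dt=dt, cycle_period=waveform.period)


def _estimate_tube_geometry(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Fallback radius/tangent for meshes without generator metadata.

    Uses the principal axis as a straight centerline approximation: adequate
    for near-tubular shapes, documented as crude for anything else.
    """
    v = mesh.vertices - mesh.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(v, full_matrices=False)
    axis = vt[0]
    proj = v @ axis
    radial = v - proj[:, None] * axis
    r = np.linalg.norm(radial, axis=1)
    r = np.maximum(r, 1e-6)
    tangent = np.tile(axis, (mesh.n_vertices, 1))
    return r, tangent


def tawss(series: WSSSeries, cycle_index: int) -> ScalarField:
    """Time-averaged WSS magnitude (Pa) over one selected cardiac cycle.

    ``cycle_index`` is 1-based; the mean is the arithmetic mean of the
    per-step Euclidean norms of the WSS vectors within that cycle (rectangle
    rule over T = cycle_period). Selecting the last of several simulated
    cycles discards initial-transient effects.
    """
    spc = series.steps_per_cycle
    if cycle_index < 1:
        raise IndexError("cycle_index is 1-based")
    start, stop = (cycle_index - 1) * spc, cycle_index * spc
    if stop > series.n_steps:
        raise IndexError(
            f"cycle {cycle_index} needs steps [{start}, {stop}) but the "
            f"series has {series.n_steps}")
    mags = np.linalg.norm(series.values[start:stop].astype(np.float64), axis=2)
    mean = mags.mean(axis=0)
    return ScalarField("tawss", mean, units="Pa",
                       meta={"cycle_index": cycle_index, "steps_averaged": spc})


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "base_radius": (8.0, 12.0),
    "bulge_factor": (0.5, 1.2),
    "bulge_center": (0.35, 0.65),
    "bulge_width": (22.0, 40.0),
    "centerline_curvature": (0.02, 0.14),
}


def build_dataset(
    n_base: int,
    variants_per_base: int,
    params_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[dict]:
    """Manifest of ``n_base * (1 + variants_per_base)`` synthetic geometries.

    Each base geometry is sampled uniformly from ``params_ranges``; its
    variants jitter every ranged parameter by up to ±10% of the range span
    (clipped to the range). All members of a family share a family id —
    the unit of leakage-free train/test splitting. Deterministic in ``seed``.
    """
    if n_base < 1 or variants_per_base < 0:
        raise ValueError("need n_base >= 1 and variants_per_base >= 0")
    ranges = dict(DEFAULT_PARAM_RANGES if params_ranges is None else params_ranges)
    rng = np.random.default_rng(seed)
    manifest: list[dict] = []
    for b in range(n_base):
        family = f"fam{b:03d}"
        base = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        members = [base]
        for _ in range(variants_per_base):
            jit = {}
            for k, (lo, hi) in ranges.items():
                span = hi - lo
                jit[k] = float(np.clip(base[k] + rng.uniform(-0.1, 0.1) * span, lo, hi))
            members.append(jit)
        for g, sampled in enumerate(members):
            gseed = int((seed * 100003 + b * 1009 + g) % (2**31))
            manifest.append({
                "id": f"{family}-g{g:03d}",
                "family": family,
                "real": False,
                "split_eligible": True,
                "params": {**sampled, "seed": gseed},
                "paths": {},
            })
    return manifest


def realize_geometry(
    record: dict,
    waveform: FlowWaveform | None = None,
    noise_sd: float = 0.0,
    tau0: float = 1.5,
    with_curvature: bool = True,
    out_dir: str | Path | None = None,
) -> TriMesh:
    """Generate the mesh for one manifest record and attach TAWSS (+curvature).

    The TAWSS field comes from the pseudo-CFD oracle run for three cardiac
    cycles at dt = 0.01 s, averaging the third cycle. If ``out_dir`` is
    given, the mesh is written as VTK polydata and the path recorded.
    """
    params = AortaParams(**{k: v for k, v in record["params"].items()})
    mesh = generate_aorta(params)
    mesh.metadata["id"] = record["id"]
    series = pseudo_cfd_wss(mesh, params, waveform, noise_sd=noise_sd,
                            seed=params.seed + 1, tau0=tau0)
    mesh.attach(tawss(series, cycle_index=series.n_cycles))
    if with_curvature:
        mesh.attach(mean_curvature(mesh))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{record['id']}.vtk"
        save_mesh(mesh, path, format="vtk")
        record["paths"]["mesh"] = str(path)
    return mesh


def save_manifest(manifest: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in manifest:
            fh.write(json.dumps(rec) + "\n")


def load_manifest(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_wss_series(series: WSSSeries, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("values", data=series.values)
        ds.attrs["dt"] = series.dt
        ds.attrs["cycle_period"] = series.cycle_period


def read_wss_series(path: str | Path) -> WSSSeries:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["values"]
        return WSSSeries(ds[...], dt=float(ds.attrs["dt"]),
                         cycle_period=float(ds.attrs["cycle_period"]))
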