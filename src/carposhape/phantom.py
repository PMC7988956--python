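"""Synthetic scaphoid-like phantom specimens with known ground truth.

Real carpal-bone populations for this kind of pipeline come from cadaver
HR-pQCT scans that cannot be redistributed, so every stage here is exercised
on an analytic phantom family instead: a two-lobed, waisted solid of
revolution (lobes of independent radii joined through a circular waist),
flattened on the dorsal side and bent about the waist.  The family has
independent generative modes — length, lobe radii, waist radius, axial waist
position, dorsal width, bend angle — which downstream shape models should
recover, and a three-zone concentric density structure (dense periphery,
intermediate shell with four angular/axial subregions, low-density core)
whose generating means downstream density models should recover.

Because the surface is analytic, homologous landmarks, segment polylines and
region boundary loops are placed exactly, and every specimen records the
latent parameters that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._mesh import SurfaceDistance, axial_angular_coords, grid_points_inside
from .imaging import DensityVolume, LabeledMesh
from .landmarks import LandmarkSet, Segment

__all__ = [
    "PhantomParams",
    "ZoneProfile",
    "PhantomSpecimen",
    "generate_phantom_mesh",
    "generate_phantom_volume",
    "generate_population",
    "DEFAULT_PARAM_MEANS",
    "DEFAULT_PARAM_SDS",
]

# parameter-space region boundaries (axial fraction t, angle theta about the
# long axis; theta = 0 medial, pi/2 dorsal, pi lateral, -pi/2 volar)
T_RADIUS = 0.20          # proximal cap: articular surface for the radius
T_TRAPEZOID = 0.82       # distal cap: articular surface for trapezium/trapezoid
T_LUNATE = (0.24, 0.46)  # medial patch, proximal half
T_CAPITATE = (0.52, 0.78)  # medial patch, distal half
MEDIAL_HALF_ANGLE = np.pi / 3.0
T_DORSAL = (0.22, 0.80)  # axial span of the dorsal rough strip


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters of one phantom specimen (mm / degrees)."""

    length: float = 27.0
    proximal_radius: float = 6.5
    distal_radius: float = 7.5
    waist_radius: float = 5.2
    waist_axial_position: float = 0.5
    dorsal_width: float = 6.5
    bend_angle: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("length", "proximal_radius", "distal_radius", "waist_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"invariant violated: {name} must be > 0 "
                                 f"(got {getattr(self, name)})")
        if not 0 < self.waist_axial_position < 1:
            raise ValueError("invariant violated: waist_axial_position must lie "
                             f"in (0, 1) (got {self.waist_axial_position})")
        if not self.waist_radius < min(self.proximal_radius, self.distal_radius):
            raise ValueError(
                "invariant violated: waist_radius must be smaller than both lobe "
                f"radii (waist {self.waist_radius} vs lobes "
                f"{self.proximal_radius}, {self.distal_radius})")
        if not self.dorsal_width > 0:
            raise ValueError("invariant violated: dorsal_width must be > 0")


@dataclass(frozen=True)
class ZoneProfile:
    """Concentric density-zone structure (mg HA/cm^3 and mm).

    Default zone means are the population values reported for the scaphoid:
    a dense cortical/subchondral periphery near 550 mg HA/cm^3, an
    intermediate trabecular shell near 350-390 with four subregions (medial,
    proximal pole, distal pole, lateral), and a low-density centre near 226.
    """

    peripheral_mean: float = 549.4
    intermediate_means: tuple[float, float, float, float] = (376.2, 379.0, 346.5, 389.1)
    centre_mean: float = 225.6
    noise_sd: float = 60.0
    peripheral_thickness: float = 1.0
    intermediate_thickness: float = 2.0

    def validate(self) -> None:
        if not (self.peripheral_thickness > 0 and self.intermediate_thickness > 0):
            raise ValueError("invariant violated: zone thicknesses must be > 0")
        if not all(self.peripheral_mean > m > self.centre_mean
                   for m in self.intermediate_means):
            raise ValueError(
                "invariant violated: zone means must be ordered "
                "peripheral > each intermediate > centre")

    @property
    def centre_start_depth(self) -> float:
        return self.peripheral_thickness + self.intermediate_thickness


# ---------------------------------------------------------------------------
# analytic surface


def _profile_radius(p: PhantomParams, t: np.ndarray) -> np.ndarray:
    """Radius of the unflattened solid of revolution at axial fraction t."""
    t = np.asarray(t, dtype=float)
    w = p.waist_axial_position
    r = np.empty_like(t)

    s = np.clip(t / w, 0.0, 1.0)
    cap = s <= 0.5
    # proximal lobe: quarter-ellipse rise 0 -> Rp, then cos^2 fall Rp -> Rw
    r_prox = np.where(
        cap,
        p.proximal_radius * np.sqrt(np.clip(1.0 - ((0.5 - s) / 0.5) ** 2, 0.0, 1.0)),
        p.waist_radius + (p.proximal_radius - p.waist_radius)
        * np.cos(0.5 * np.pi * (s - 0.5) / 0.5) ** 2,
    )
    s2 = np.clip((t - w) / (1.0 - w), 0.0, 1.0)
    cap2 = s2 >= 0.5
    r_dist = np.where(
        cap2,
        p.distal_radius * np.sqrt(np.clip(1.0 - ((s2 - 0.5) / 0.5) ** 2, 0.0, 1.0)),
        p.waist_radius + (p.distal_radius - p.waist_radius)
        * np.sin(0.5 * np.pi * s2 / 0.5) ** 2,
    )
    np.copyto(r, np.where(t <= w, r_prox, r_dist))
    return r


def surface_point(p: PhantomParams, t, theta) -> np.ndarray:
    """Exact surface point(s) at parameter (t, theta), flattening and bending
    applied.  Broadcasts over t and theta."""
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    t, theta = np.broadcast_arrays(t, theta)
    r = _profile_radius(p, t)
    x = t * p.length
    y = np.minimum(r * np.sin(theta), 0.5 * p.dorsal_width)
    z = r * np.cos(theta)
    return _apply_bend(p, np.stack([x, y, z], axis=-1))


def _apply_bend(p: PhantomParams, pts: np.ndarray) -> np.ndarray:
    """Progressive bend about the z-axis through the waist point."""
    if p.bend_angle == 0:
        return pts
    out = np.array(pts, dtype=float)
    xw = p.waist_axial_position * p.length
    dx = out[..., 0] - xw
    frac = np.clip(dx / (p.length - xw), 0.0, None)
    phi = np.deg2rad(p.bend_angle) * frac
    c, s = np.cos(phi), np.sin(phi)
    x_new = xw + c * dx - s * out[..., 1]
    y_new = s * dx + c * out[..., 1]
    out[..., 0] = x_new
    out[..., 1] = y_new
    return out


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


def _region_of(p: PhantomParams, t: float, theta: float) -> str:
    if t < T_RADIUS:
        return "cartilage_radius"
    if t > T_TRAPEZOID:
        return "cartilage_trapezium_trapezoid"
    if abs(_wrap_angle(theta)) < MEDIAL_HALF_ANGLE:
        if T_LUNATE[0] < t < T_LUNATE[1]:
            return "cartilage_lunate"
        if T_CAPITATE[0] < t < T_CAPITATE[1]:
            return "cartilage_capitate"
    if (T_DORSAL[0] < t < T_DORSAL[1] and np.sin(theta) > 0
            and _profile_radius(p, np.asarray(t)) * np.sin(theta)
            >= 0.5 * p.dorsal_width):
        return "dorsal"
    return "bone"


def _phantom_landmarks(p: PhantomParams, seg_points: int = 9,
                       loop_points: int = 24) -> LandmarkSet:
    def sp(t, th):
        return surface_point(p, t, th).reshape(3)

    w = p.waist_axial_position
    compass = {"dorsal": np.pi / 2, "volar": -np.pi / 2, "medial": 0.0,
               "lateral": np.pi}
    homologous = {"proximal_pole": sp(0.0, 0.0), "distal_pole": sp(1.0, 0.0)}
    for name, th in compass.items():
        homologous[f"waist_{name}"] = sp(w, th)
        homologous[f"radius_margin_{name}"] = sp(T_RADIUS, th)
        homologous[f"trapezoid_margin_{name}"] = sp(T_TRAPEZOID, th)

    segments = []
    t_int = np.linspace(T_RADIUS, T_TRAPEZOID, seg_points + 2)[1:-1]
    for name, th in compass.items():
        segments.append(Segment(
            f"crest_{name}", f"radius_margin_{name}", f"trapezoid_margin_{name}",
            surface_point(p, t_int, th)))

    # half-step phase offset keeps loop samples clear of the compass-angle
    # homologous landmarks (TPS controls must not duplicate)
    thetas = 2 * np.pi * (np.arange(loop_points) + 0.5) / loop_points
    regions = {
        "cartilage_radius": surface_point(p, T_RADIUS, thetas),
        "cartilage_trapezium_trapezoid": surface_point(p, T_TRAPEZOID, thetas),
    }
    for name, (t0, t1) in (("cartilage_lunate", T_LUNATE),
                           ("cartilage_capitate", T_CAPITATE)):
        n_edge = loop_points // 4
        ts = np.linspace(t0, t1, n_edge)
        ths = np.linspace(-MEDIAL_HALF_ANGLE, MEDIAL_HALF_ANGLE, n_edge)
        loop = np.vstack([
            surface_point(p, ts, -MEDIAL_HALF_ANGLE),
            surface_point(p, t1, ths),
            surface_point(p, ts[::-1], MEDIAL_HALF_ANGLE),
            surface_point(p, t0, ths[::-1]),
        ])
        regions[name] = loop
    # dorsal strip boundary: theta where flattening begins, at each axial station
    ts = np.linspace(*T_DORSAL, loop_points // 2)
    rr = _profile_radius(p, ts)
    th_edge = np.arcsin(np.clip(0.5 * p.dorsal_width / rr, 0.0, 1.0))
    front = surface_point(p, ts, th_edge)
    back = surface_point(p, ts[::-1], np.pi - th_edge[::-1])
    regions["dorsal"] = np.vstack([front, back])
    return LandmarkSet(homologous, segments, regions)


# ---------------------------------------------------------------------------
# mesh generation


def generate_phantom_mesh(params: PhantomParams, n_subdiv: int = 16,
                          n_rings: int | None = None,
                          ring_size: int | None = None,
                          ) -> tuple[LabeledMesh, LandmarkSet, dict]:
    """Triangulate one phantom and place its landmarks analytically.

    The mesh is a UV-style triangulation: two pole vertices plus ``n_rings``
    rings of ``ring_size`` vertices (defaults 2*n_subdiv and 4*n_subdiv), so
    V = 2 + n_rings*ring_size and T = 2*n_rings*ring_size = 2V - 4 — a
    closed genus-zero surface.  Returns (mesh, landmarks, generative record).
    """
    params.validate()
    if n_subdiv < 2:
        raise ValueError("n_subdiv must be >= 2")
    n = n_rings if n_rings is not None else 2 * n_subdiv
    m = ring_size if ring_size is not None else 4 * n_subdiv

    t_rings = np.arange(1, n + 1) / (n + 1)
    thetas = 2 * np.pi * np.arange(m) / m
    tt = np.repeat(t_rings, m)
    th = np.tile(thetas, n)
    ring_pts = surface_point(params, tt, th)
    pole0 = surface_point(params, 0.0, 0.0).reshape(1, 3)
    pole1 = surface_point(params, 1.0, 0.0).reshape(1, 3)
    vertices = np.vstack([pole0, ring_pts, pole1])
    t_vert = np.concatenate([[0.0], tt, [1.0]])
    th_vert = np.concatenate([[np.nan], th, [np.nan]])

    idx = lambda i, j: 1 + i * m + (j % m)  # noqa: E731
    tris = []
    for j in range(m):
        tris.append([0, idx(0, j + 1), idx(0, j)])
    for i in range(n - 1):
        for j in range(m):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            tris.append([a, b, d])
            tris.append([a, d, c])
    last = 1 + n * m
    for j in range(m):
        tris.append([last, idx(n - 1, j), idx(n - 1, j + 1)])
    triangles = np.asarray(tris, dtype=np.int64)

    # per-triangle region from the parameter-space centroid
    t_tri = np.nanmean(t_vert[triangles], axis=1)
    sin_m = np.nanmean(np.sin(th_vert[triangles]), axis=1)
    cos_m = np.nanmean(np.cos(th_vert[triangles]), axis=1)
    th_tri = np.arctan2(sin_m, cos_m)
    labels = np.asarray(
        [_region_of(params, t_tri[k], th_tri[k]) for k in range(len(triangles))],
        dtype=object)

    mesh = LabeledMesh(vertices, triangles, labels)
    if mesh.volume() < 0:
        mesh = LabeledMesh(vertices, triangles[:, ::-1], labels)
    record = {"params": asdict(params), "n_rings": n, "ring_size": m,
              "proximal_pole_vertex": 0, "distal_pole_vertex": last}
    return mesh, _phantom_landmarks(params), record


# ---------------------------------------------------------------------------
# density volume generation


def zone_label_for_depth(depth: np.ndarray, axial_frac: np.ndarray,
                         angle: np.ndarray, peripheral_depth: float,
                         centre_start_depth: float) -> np.ndarray:
    """Shared zone rule: depth bands, outer axial thirds, angular halves.

    Returns integer labels: 0 peripheral, 1 intermediate-medial, 2
    intermediate-proximal, 3 intermediate-distal, 4 intermediate-lateral,
    5 centre.  Medial is the half-space with |angle| < pi/2 (angle measured
    from the medial reference direction).
    """
    lab = np.full(depth.shape, 5, dtype=np.int8)
    inter = (depth > peripheral_depth) & (depth < centre_start_depth)
    lab[inter & (axial_frac < 1 / 3)] = 2
    lab[inter & (axial_frac > 2 / 3)] = 3
    mid = inter & (axial_frac >= 1 / 3) & (axial_frac <= 2 / 3)
    lab[mid & (np.abs(angle) < np.pi / 2)] = 1
    lab[mid & (np.abs(angle) >= np.pi / 2)] = 4
    lab[depth <= peripheral_depth] = 0
    return lab


def generate_phantom_volume(mesh: LabeledMesh, zones: ZoneProfile = ZoneProfile(),
                            voxel_size: float = 0.3, seed: int = 0,
                            units: str = "vBMD",
                            calibration: tuple[float, float] = (0.75, 0.0),
                            ) -> DensityVolume:
    """Rasterize a phantom mesh into a concentric-zone density volume.

    Voxels outside the closed mesh are 0.  Inside, the voxel's depth (exact
    distance to the surface mesh) selects the zone; the value is drawn from
    Normal(zone mean, noise_sd) and clamped at 0.  With ``units='HU'`` the
    stored values are back-converted through the attached linear calibration
    so the HU -> vBMD path can be exercised end to end.
    """
    zones.validate()
    if not voxel_size > 0:
        raise ValueError("voxel_size must be positive")
    if voxel_size > zones.peripheral_thickness:
        warnings.warn(
            f"voxel size {voxel_size} mm exceeds the peripheral-zone thickness "
            f"{zones.peripheral_thickness} mm; zones will be unresolvable",
            stacklevel=2)

    lo = mesh.vertices.min(axis=0) - 2 * voxel_size
    hi = mesh.vertices.max(axis=0) + 2 * voxel_size
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel_size)) + 1 for a in range(3))
    inside = grid_points_inside(mesh.vertices, mesh.triangles, lo, voxel_size, shape)

    ijk = np.argwhere(inside)
    pts = lo + voxel_size * ijk
    depth, _, _ = SurfaceDistance(mesh.vertices, mesh.triangles).query(pts)

    axis_origin, long_axis, ref_dir = _oriented_axes(mesh.vertices)
    proj = (mesh.vertices - axis_origin) @ long_axis
    frac, angle = axial_angular_coords(pts, axis_origin, long_axis, ref_dir,
                                       (proj.min(), proj.max()))
    lab = zone_label_for_depth(depth, frac, angle, zones.peripheral_thickness,
                               zones.centre_start_depth)
    means = np.array([zones.peripheral_mean, *zones.intermediate_means,
                      zones.centre_mean])
    rng = np.random.default_rng(seed)
    vals = means[lab]
    if zones.noise_sd > 0:
        vals = vals + rng.normal(0.0, zones.noise_sd, size=vals.shape)
    vals = np.maximum(vals, 0.0)

    values = np.zeros(shape, dtype=float)
    values[tuple(ijk.T)] = vals
    slope, intercept = calibration
    if units.lower() == "hu":
        values = (values - intercept) / slope
        return DensityVolume(values, voxel_size, lo, "HU", calibration)
    return DensityVolume(values, voxel_size, lo, "vBMD", calibration)


def _oriented_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centroid, long axis, medial reference direction) for a vertex cloud.

    The long axis is the first principal axis oriented toward +x; the medial
    reference is global +z orthogonalized against it.  The generator and the
    zone segmentation share this convention so phantom ground truth and its
    recovery agree on subregion naming.
    """
    from ._mesh import principal_axes
    c, axes = principal_axes(points)
    long_axis = axes[0] if axes[0] @ np.array([1.0, 0.0, 0.0]) >= 0 else -axes[0]
    ref = np.array([0.0, 0.0, 1.0])
    ref = ref - (ref @ long_axis) * long_axis
    return c, long_axis, ref / np.linalg.norm(ref)


# ---------------------------------------------------------------------------
# population generation

DEFAULT_PARAM_MEANS = {
    "length": 27.0, "proximal_radius": 6.5, "distal_radius": 7.5,
    "waist_radius": 5.2, "waist_axial_position": 0.5, "dorsal_width": 6.5,
    "bend_angle": 20.0,
}
DEFAULT_PARAM_SDS = {
    "length": 2.5, "proximal_radius": 0.5, "distal_radius": 0.5,
    "waist_radius": 0.35, "waist_axial_position": 0.04, "dorsal_width": 0.8,
    "bend_angle": 4.0,
}


@dataclass
class PhantomSpecimen:
    specimen_id: str
    params: PhantomParams
    mesh: LabeledMesh
    landmarks: LandmarkSet
    record: dict = field(default_factory=dict)
    volume: DensityVolume | None = None


def generate_population(n: int, mode_sds: dict | None = None, seed: int = 0,
                        n_subdiv: int = 16, means: dict | None = None,
                        zones: ZoneProfile | None = None,
                        voxel_size: float = 0.3, units: str = "vBMD",
                        ) -> tuple[list[PhantomSpecimen], pd.DataFrame]:
    """Draw a phantom population from independent normals over the parameters.

    Returns the specimens plus the latent parameter table (one row per
    specimen) for recovery experiments.  Pass a ZoneProfile to also generate
    per-specimen density volumes.  Fully reproducible from ``seed``.
    """
    if n < 3:
        raise ValueError("need n >= 3 specimens (PCA needs at least 3 shapes)")
    mu = {**DEFAULT_PARAM_MEANS, **(means or {})}
    sd = {**DEFAULT_PARAM_SDS, **(mode_sds or {})}
    unknown = set(sd) - set(DEFAULT_PARAM_MEANS)
    if unknown:
        raise ValueError(f"unknown phantom parameters: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    names = list(DEFAULT_PARAM_MEANS)
    rows, specimens = [], []
    for i in range(n):
        for _ in range(200):
            draw = {k: rng.normal(mu[k], sd[k]) if sd[k] > 0 else mu[k]
                    for k in names}
            p = PhantomParams(**draw, seed=int(rng.integers(2**31)))
            try:
                p.validate()
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw valid phantom parameters; "
                               "check means/SDs against the invariants")
        mesh, lms, record = generate_phantom_mesh(p, n_subdiv=n_subdiv)
        spec = PhantomSpecimen(f"phantom_{i:03d}", p, mesh, lms, record)
        if zones is not None:
            spec.volume = generate_phantom_volume(
                mesh, zones, voxel_size=voxel_size, seed=p.seed, units=units)
        specimens.append(spec)
        rows.append({"specimen_id": spec.specimen_id, **{k: draw[k] for k in names}})
    return specimens, pd.DataFrame(rows).set_index("specimen_id")
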