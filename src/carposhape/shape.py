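"""Statistical surface model: non-scaling GPA, PCA of form, morphometrics.

Corresponded meshes are superimposed by a generalized Procrustes fit that
removes translation and rotation only — centroid sizes are preserved
exactly, so the subsequent PCA captures joint size-and-shape ("form")
variation.  The PCA eigenmodes synthesize shapes at any +-k*SD along a
mode, and the morphometric routines measure the descriptors reported for
carpal bones: length along the long axis, the two orthogonal diameters of
the minimal waist cross-section, the width of the dorsal rough surface, and
per-region surface areas.

Conventions: eigenmode signs are fixed by requiring a nonnegative projection
of the displacement field on the mean's long axis (second axis if the first
projection is ~0); sample covariance divides by N - 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from sklearn.base import BaseEstimator, TransformerMixin

from ._mesh import cross_section_points, is_closed, principal_axes, triangle_areas
from .correspond import HomologousMeshSet
from .imaging import LabeledMesh

__all__ = [
    "GeneralizedProcrustes",
    "ShapePCA",
    "Morphometrics",
    "procrustes_align",
    "fit_pca",
    "synthesize_shape",
    "centroid_size",
    "measure",
    "population_stats",
]


def centroid_size(vertices: np.ndarray) -> float:
    """Root-sum-of-squares distance of the configuration from its centroid."""
    v = np.asarray(vertices, dtype=float)
    return float(np.linalg.norm(v - v.mean(axis=0)))


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections excluded) minimizing |shape R - target|."""
    h = shape.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Non-scaling generalized Procrustes superimposition.

    Iteratively centres every shape, rotates it optimally onto the current
    mean (rotation constrained to det +1 so anatomical chirality is never
    mirrored) and recomputes the mean, until the mean moves less than
    ``tol`` (mm, RMS per vertex) or ``max_iter`` is reached.  No scaling is
    applied anywhere: centroid sizes are preserved exactly.
    """

    def __init__(self, tol: float = 1e-7, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None) -> "GeneralizedProcrustes":
        shapes = _as_shape_stack(X)
        n = len(shapes)
        if n < 2:
            raise ValueError("need at least 2 shapes to superimpose")
        centred = shapes - shapes.mean(axis=1, keepdims=True)
        # initial reference: the raw average, so an already-aligned set is a
        # fixed point (re-alignment is the identity); fall back to the first
        # shape when raw orientations cancel the average out
        mean = centred.mean(axis=0)
        if centroid_size(mean) < 1e-3 * centroid_size(centred[0]):
            mean = centred[0].copy()
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n):
                centred[i] = centred[i] @ _optimal_rotation(centred[i], mean)
            new_mean = centred.mean(axis=0)
            shift = np.sqrt(np.mean((new_mean - mean) ** 2))
            mean = new_mean
            if shift < self.tol:
                break
        self.aligned_ = centred
        self.mean_ = mean - mean.mean(axis=0)
        self.n_iter_ = n_iter
        return self

    def transform(self, X) -> np.ndarray:
        """Align further shapes to the fitted mean (centre + rotate only)."""
        shapes = _as_shape_stack(X)
        out = shapes - shapes.mean(axis=1, keepdims=True)
        for i in range(len(out)):
            out[i] = out[i] @ _optimal_rotation(out[i], self.mean_)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).aligned_


def _as_shape_stack(X) -> np.ndarray:
    if isinstance(X, HomologousMeshSet):
        return np.array(X.vertices, dtype=float)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected shapes as (N, V, 3) or a HomologousMeshSet")
    return arr.copy()


def procrustes_align(shapes) -> tuple[np.ndarray, np.ndarray, "GeneralizedProcrustes"]:
    """Functional wrapper: (aligned (N,V,3), mean (V,3), fitted aligner)."""
    gpa = GeneralizedProcrustes().fit(shapes)
    return gpa.aligned_, gpa.mean_, gpa


class ShapePCA(TransformerMixin, BaseEstimator):
    """PCA form model over aligned homologous vertex configurations.

    Attributes (after fit)
    ----------------------
    mean_vertices_ : (V, 3) mean shape.
    components_ : (M, V, 3) orthonormal displacement fields, sorted by
        decreasing variance, signs fixed by the long-axis convention.
    variances_ : (M,) per-mode variance (mm^2, divisor N - 1).
    variance_fractions_ : (M,) fractions of total variance (sum 1).
    scores_ : (N, M) per-specimen mode scores (mm).
    degenerate_ : True when the training set has zero total variance.
    """

    def __init__(self, n_modes: int | None = None):
        self.n_modes = n_modes

    def fit(self, X, y=None, triangles: np.ndarray | None = None,
            labels: np.ndarray | None = None) -> "ShapePCA":
        if isinstance(X, HomologousMeshSet):
            triangles = X.triangles if triangles is None else triangles
            labels = X.labels if labels is None else labels
        shapes = _as_shape_stack(X)
        n, v, _ = shapes.shape
        if n < 3:
            raise ValueError("PCA needs at least 3 shapes")
        self.triangles_ = triangles
        self.labels_ = labels
        self.mean_vertices_ = shapes.mean(axis=0)
        flat = (shapes - self.mean_vertices_).reshape(n, 3 * v)

        max_modes = min(n - 1, 3 * v)
        requested = max_modes if self.n_modes is None else self.n_modes
        if requested > max_modes:
            warnings.warn(f"only {max_modes} modes available from {n} shapes; "
                          f"truncating the requested {requested}", stacklevel=2)
            requested = max_modes

        u, s, vt = np.linalg.svd(flat, full_matrices=False)
        variances = s[:max_modes] ** 2 / (n - 1)
        total = variances.sum()
        self.degenerate_ = bool(total <= 1e-12 * max(1.0, v))
        if self.degenerate_:
            warnings.warn("degenerate model: all training shapes identical "
                          "(zero total variance)", stacklevel=2)
            self.components_ = np.zeros((0, v, 3))
            self.variances_ = np.zeros(0)
            self.variance_fractions_ = np.zeros(0)
            self.scores_ = np.zeros((n, 0))
            return self

        keep = min(requested, int((s[:max_modes] > 1e-10 * s[0]).sum()))
        comps = vt[:keep]
        scores = u[:, :keep] * s[:keep]
        # sign convention: the positive direction of each mode extends the
        # shape along the mean's long axis (axial position-weighted
        # projection of the displacement field; second axis when ~0)
        c, axes = principal_axes(self.mean_vertices_)
        rel = self.mean_vertices_ - c
        for k in range(keep):
            fld = comps[k].reshape(v, 3)
            p = float((fld @ axes[0]) @ (rel @ axes[0]))
            if abs(p) < 1e-9:
                p = float((fld @ axes[1]) @ (rel @ axes[1]))
            if p < 0:
                comps[k] = -comps[k]
                scores[:, k] = -scores[:, k]
        self.components_ = comps.reshape(keep, v, 3)
        self.variances_ = variances[:keep]
        self.variance_fractions_ = variances[:max_modes] / total
        self.scores_ = scores
        return self

    def transform(self, X) -> np.ndarray:
        shapes = _as_shape_stack(X)
        flat = (shapes - self.mean_vertices_).reshape(len(shapes), -1)
        return flat @ self.components_.reshape(len(self.components_), -1).T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        sc = np.atleast_2d(np.asarray(scores, dtype=float))
        flat = sc @ self.components_.reshape(len(self.components_), -1)
        return self.mean_vertices_ + flat.reshape(len(sc), -1, 3)

    def synthesize(self, mode: int, k_sd: float) -> LabeledMesh | np.ndarray:
        """Mean + k_sd standard deviations along one mode."""
        if mode >= len(self.components_):
            raise ValueError(f"mode {mode} not in model "
                             f"({len(self.components_)} modes)")
        verts = (self.mean_vertices_
                 + k_sd * np.sqrt(self.variances_[mode]) * self.components_[mode])
        if self.triangles_ is not None:
            return LabeledMesh(verts, self.triangles_, self.labels_)
        return verts

    def mean_mesh(self) -> LabeledMesh:
        if self.triangles_ is None:
            raise ValueError("no triangulation attached")
        return LabeledMesh(self.mean_vertices_, self.triangles_, self.labels_)


def fit_pca(aligned, n_modes: int | None = None, **kw) -> ShapePCA:
    return ShapePCA(n_modes=n_modes).fit(aligned, **kw)


def synthesize_shape(model: ShapePCA, mode: int, k_sd: float):
    return model.synthesize(mode, k_sd)


# ---------------------------------------------------------------------------
# morphometrics


@dataclass
class Morphometrics:
    length: float                       # mm along the long axis
    waist_diameters: tuple[float, float]  # mm, ascending, at the minimal section
    waist_area: float                   # mm^2 (convex section area)
    dorsal_width: float                 # mm (nan when no dorsal strip labelled)
    region_areas: dict[str, float] = field(default_factory=dict)
    total_area: float = 0.0

    def as_dict(self) -> dict[str, float]:
        out = {"length": self.length,
               "waist_diameter_1": self.waist_diameters[0],
               "waist_diameter_2": self.waist_diameters[1],
               "waist_area": self.waist_area,
               "dorsal_width": self.dorsal_width,
               "total_area": self.total_area}
        out.update({f"area_{k}": v for k, v in self.region_areas.items()})
        return out


def _section_metrics(pts: np.ndarray, axis: np.ndarray) -> tuple[float, float, float]:
    """(area, d_max, d_perp) of a planar section point cloud."""
    u = np.array([0.0, 0.0, 1.0])
    if abs(axis @ u) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    u = u - (u @ axis) * axis
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    p2 = np.column_stack([pts @ u, pts @ w])
    if len(p2) < 3:
        return 0.0, 0.0, 0.0
    hull = ConvexHull(p2)
    hp = p2[hull.vertices]
    diff = hp[:, None, :] - hp[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(d2.argmax(), d2.shape)
    d_max = float(np.sqrt(d2[i, j]))
    e = (hp[j] - hp[i]) / d_max if d_max > 0 else np.array([1.0, 0.0])
    perp = np.array([-e[1], e[0]])
    proj = hp @ perp
    return float(hull.volume), d_max, float(proj.max() - proj.min())


def measure(mesh: LabeledMesh, axis: np.ndarray | None = None,
            waist_band: float = 0.6, n_stations: int = 100,
            dorsal_label: str = "dorsal", n_dorsal_bins: int = 20,
            ) -> Morphometrics:
    """Morphometric descriptors of one closed mesh.

    Length is the extent along the long axis (default: first principal axis
    of the vertex cloud).  The waist is the minimal-area cross-section over
    ``n_stations`` stations spanning the central ``waist_band`` fraction of
    the length; its two diameters are the maximal in-plane extent and the
    extent perpendicular to it (returned ascending).  The dorsal width is
    the mean cross-sectional chord of the ``dorsal_label`` triangle strip.
    """
    if not is_closed(mesh.triangles):
        raise ValueError("morphometrics require a closed mesh")
    c, axes = principal_axes(mesh.vertices)
    a = axes[0] if axis is None else np.asarray(axis, float) / np.linalg.norm(axis)
    proj = (mesh.vertices - c) @ a
    length = float(proj.max() - proj.min())

    lo = proj.min() + (0.5 - waist_band / 2) * length
    hi = proj.min() + (0.5 + waist_band / 2) * length
    best = (np.inf, 0.0, 0.0)
    for s in np.linspace(lo, hi, n_stations):
        pts = cross_section_points(mesh.vertices, mesh.triangles, c + s * a, a)
        if len(pts) < 3:
            continue
        area, d1, d2 = _section_metrics(pts - (c + s * a), a)
        if 0 < area < best[0]:
            best = (area, d1, d2)
    waist_area = best[0] if np.isfinite(best[0]) else 0.0
    waist_diameters = tuple(sorted((best[1], best[2])))

    region_areas = mesh.region_areas()
    total_area = mesh.area()

    dorsal_width = float("nan")
    strip = mesh.labels.astype(str) == dorsal_label
    if strip.any():
        vid = np.unique(mesh.triangles[strip])
        sp = mesh.vertices[vid]
        sproj = (sp - c) @ a
        bins = np.linspace(sproj.min(), sproj.max(), n_dorsal_bins + 1)
        widths = []
        for b0, b1 in zip(bins[:-1], bins[1:]):
            sel = sp[(sproj >= b0) & (sproj <= b1)]
            if len(sel) < 2:
                continue
            in_plane = sel - np.outer((sel - c) @ a, a)
            d = np.linalg.norm(in_plane[:, None] - in_plane[None, :], axis=2)
            widths.append(d.max())
        if widths:
            dorsal_width = float(np.mean(widths))

    return Morphometrics(length, waist_diameters, waist_area, dorsal_width,
                         region_areas, total_area)


def population_stats(values: pd.DataFrame | dict) -> pd.DataFrame:
    """Per-descriptor mean, sample SD (N-1), min, max plus the formatted
    ``mean +- SD (min-max)`` column used in descriptive anatomy tables."""
    df = pd.DataFrame(values)
    if len(df) < 2:
        raise ValueError("need at least 2 specimens for population statistics")
    out = pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1),
        "min": df.min(),
        "max": df.max(),
    })
    out["formatted"] = [
        f"{m:.1f} ± {s:.1f} ({lo:.1f}–{hi:.1f})"
        for m, s, lo, hi in zip(out["mean"], out["sd"], out["min"], out["max"])
    ]
    return out
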