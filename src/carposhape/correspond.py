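"""Vertex-wise anatomical correspondence across a specimen population.

One representative specimen is chosen as the reference; its mesh is warped
to every other specimen by a thin-plate spline fitted on the full landmark
sets (homologous points, equidistant segment landmarks and region boundary
loops), and the warped vertices are attached to the target surface by
nearest-point projection.  The result is a population of meshes sharing one
triangulation with vertex-wise homology, onto which the reference's
cartilage-region labels transfer directly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from ._mesh import SurfaceDistance, is_closed, triangle_areas
from .imaging import LabeledMesh
from .landmarks import LandmarkSet, Segment
from .tps import ThinPlateSpline

__all__ = [
    "resample_segments",
    "resample_polyline",
    "choose_reference",
    "establish_homology",
    "transfer_cartilage_regions",
    "HomologousMeshSet",
]


def resample_polyline(points: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    """Resample a piecewise-linear polyline at equal arc-length spacing.

    Open polylines keep both endpoints exactly and return ``n`` points
    total; closed loops keep the first point and return ``n`` points with
    the wrap-around segment included.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-length polyline cannot be resampled")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = (np.linspace(0.0, total, n, endpoint=True) if not closed
         else np.linspace(0.0, total, n, endpoint=False))
    out = np.column_stack([np.interp(s, cum, pts[:, a]) for a in range(3)])
    if not closed:
        out[0], out[-1] = pts[0], pts[-1]
    return out


def resample_segments(landmarks: LandmarkSet, points_per_segment: int,
                      points_per_loop: int | None = None) -> LandmarkSet:
    """Recompute segment landmarks as equidistant samples.

    Every segment polyline (flanking homologous landmark, interior points,
    flanking homologous landmark) is replaced by ``points_per_segment``
    points at equal arc-length spacing, endpoints preserved exactly; the
    interior points are stored back on the segment.  Region boundary loops
    are likewise resampled to ``points_per_loop`` points when given, so all
    specimens end up with identical landmark counts.
    """
    if points_per_segment < 2:
        raise ValueError("points_per_segment must be >= 2")
    segments = []
    for s in landmarks.segments:
        poly = s.polyline(landmarks.homologous)
        res = resample_polyline(poly, points_per_segment)
        segments.append(Segment(s.name, s.start, s.end, res[1:-1]))
    regions = landmarks.regions
    if points_per_loop is not None:
        regions = {k: resample_polyline(v, points_per_loop, closed=True)
                   for k, v in regions.items()}
    return LandmarkSet(dict(landmarks.homologous), segments, dict(regions))


def _landmark_signature(lms: LandmarkSet) -> tuple:
    return (tuple(sorted(lms.homologous)),
            tuple((s.name, len(np.asarray(s.points).reshape(-1, 3)))
                  for s in sorted(lms.segments, key=lambda s: s.name)),
            tuple((k, len(np.asarray(v).reshape(-1, 3)))
                  for k, v in sorted(lms.regions.items())))


def choose_reference(landmark_sets: list[LandmarkSet]) -> int:
    """Index of the most representative specimen: the one minimizing the
    summed pairwise (non-scaling) Procrustes distance of its landmark set
    to all others."""
    clouds = [ls.all_points() for ls in landmark_sets]
    n = len(clouds)
    if n == 0:
        raise ValueError("no landmark sets given")
    centered = [c - c.mean(axis=0) for c in clouds]
    cost = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            r, _ = orthogonal_procrustes(centered[i], centered[j])
            d = np.linalg.norm(centered[i] @ r - centered[j])
            cost[i] += d
            cost[j] += d
    return int(cost.argmin())


@dataclass
class HomologousMeshSet:
    """N surface meshes sharing one triangulation with vertex-wise homology."""

    vertices: np.ndarray          # (N, V, 3) mm, per-specimen
    triangles: np.ndarray         # (T, 3) shared
    labels: np.ndarray            # (T,) shared region labels
    specimen_ids: list[str]
    reference_id: str
    residuals: np.ndarray = field(default=None)  # (N,) mean projection residual
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 3 or self.vertices.shape[2] != 3:
            raise ValueError("vertices must be (N, V, 3)")
        if self.residuals is None:
            self.residuals = np.zeros(len(self.vertices))
        if len(self.triangles) != 2 * self.vertices.shape[1] - 4:
            warnings.warn("triangulation is not closed genus-0 "
                          "(T != 2V - 4)", stacklevel=2)

    @property
    def n_specimens(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[1]

    def mesh(self, i: int) -> LabeledMesh:
        return LabeledMesh(self.vertices[i], self.triangles, self.labels)

    def triangulation_hash(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.triangles).tobytes()).hexdigest()[:16]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, sid in enumerate(self.specimen_ids):
            self.mesh(i).save_ply(directory / f"{sid}.ply")
        manifest = {
            "specimen_ids": self.specimen_ids,
            "reference_id": self.reference_id,
            "triangulation_sha256": self.triangulation_hash(),
            "mean_projection_residual_mm": self.residuals.round(9).tolist(),
            "flagged": self.flagged,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "HomologousMeshSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        meshes = [LabeledMesh.load_ply(directory / f"{sid}.ply")
                  for sid in manifest["specimen_ids"]]
        return cls(np.stack([m.vertices for m in meshes]),
                   meshes[0].triangles, meshes[0].labels,
                   manifest["specimen_ids"], manifest["reference_id"],
                   np.asarray(manifest["mean_projection_residual_mm"]),
                   manifest.get("flagged", []))


def establish_homology(reference: tuple[LabeledMesh, LandmarkSet],
                       targets: list[tuple[LabeledMesh, LandmarkSet]],
                       specimen_ids: list[str] | None = None,
                       reference_id: str = "reference",
                       regularization: float = 0.0,
                       residual_tol_factor: float = 0.5,
                       project: bool = True) -> HomologousMeshSet:
    """Warp the reference mesh to every target and project onto its surface.

    For each target a TPS is fitted from the reference's full landmark set
    to the target's; the reference vertices are warped and then attached to
    the target surface by nearest-point projection (ties broken toward the
    lowest face index via the candidate ordering).  Specimens whose mean
    projection residual exceeds ``residual_tol_factor`` times the target's
    mean edge length are flagged, not dropped.
    """
    ref_mesh, ref_lms = reference
    if not is_closed(ref_mesh.triangles):
        raise ValueError("reference mesh must be closed")
    sig = _landmark_signature(ref_lms)
    src = ref_lms.all_points()

    ids = specimen_ids or [f"specimen_{i:03d}" for i in range(len(targets))]
    out = np.empty((len(targets), ref_mesh.n_vertices, 3))
    residuals = np.zeros(len(targets))
    flagged: list[str] = []
    for i, (mesh, lms) in enumerate(targets):
        if _landmark_signature(lms) != sig:
            raise ValueError(
                f"landmark set of {ids[i]} does not match the reference "
                "(names/counts differ); resample segments first")
        tps = ThinPlateSpline(regularization=regularization).fit(
            src, lms.all_points())
        warped = tps.transform(ref_mesh.vertices)
        if project:
            dist, proj, _ = SurfaceDistance(mesh.vertices, mesh.triangles).query(warped)
            residuals[i] = float(dist.mean())
            out[i] = proj
        else:
            out[i] = warped
        edge = mesh.vertices[mesh.triangles]
        mean_edge = float(np.linalg.norm(
            edge[:, [1, 2, 0]] - edge, axis=2).mean())
        if project and residuals[i] > residual_tol_factor * mean_edge:
            flagged.append(ids[i])
            warnings.warn(
                f"{ids[i]}: mean projection residual {residuals[i]:.3g} mm "
                f"exceeds {residual_tol_factor} x mean edge length "
                f"{mean_edge:.3g} mm", stacklevel=2)
    return HomologousMeshSet(out, ref_mesh.triangles, ref_mesh.labels,
                             ids, reference_id, residuals, flagged)


def transfer_cartilage_regions(reference_labels: np.ndarray,
                               homology: HomologousMeshSet,
                               ) -> tuple[HomologousMeshSet, pd.DataFrame]:
    """Attach the reference's per-triangle labels and compute per-specimen
    region areas from each specimen's own vertex geometry."""
    labels = np.asarray(reference_labels, dtype=object)
    if len(labels) != len(homology.triangles):
        raise ValueError("one label per shared triangle required")
    if any(l is None or str(l) == "" for l in labels):
        raise ValueError("unlabeled triangles in the reference labelling")
    homology.labels = labels
    rows = []
    names = sorted(set(labels.astype(str)))
    for i, sid in enumerate(homology.specimen_ids):
        areas = triangle_areas(homology.vertices[i], homology.triangles)
        row = {"specimen_id": sid}
        for name in names:
            row[name] = float(areas[labels.astype(str) == name].sum())
        row["total"] = float(areas.sum())
        rows.append(row)
    return homology, pd.DataFrame(rows).set_index("specimen_id")
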