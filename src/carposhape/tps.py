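"""3D thin-plate-spline (biharmonic) landmark registration.

The TPS is the interpolating spatial map minimizing bending energy subject
to carrying each control point to its target.  In 3D the radial kernel is
U(r) = r.  With regularization lambda > 0 the interpolation constraint is
relaxed to the standard smoothed system (K + lambda*I); lambda = 0 gives
exact interpolation.  The affine part is recovered exactly for affine
source->target maps (kernel weights vanish), so rigid motions are
reproduced without distortion.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["ThinPlateSpline", "fit_tps", "apply_tps"]


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r between every row of a and every row of b."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


class ThinPlateSpline(TransformerMixin, BaseEstimator):
    """Interpolating (or regularized) 3D thin-plate-spline transform.

    Parameters
    ----------
    regularization : float, default 0.0
        Smoothing weight lambda >= 0. Zero requests exact interpolation of
        the control points.

    Attributes
    ----------
    control_source_ : (k, 3) control points in the source frame.
    control_target_ : (k, 3) their images.
    weights_ : (k, 3) kernel weights; rows sum to ~0 with zero first moments.
    affine_ : (4, 3) affine part; row 0 is the translation, rows 1:4 the
        linear map (applied as ``[1, x, y, z] @ affine_``).
    """

    def __init__(self, regularization: float = 0.0):
        self.regularization = regularization

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThinPlateSpline":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3 or X.shape != y.shape:
            raise ValueError("source and target must both be (k, 3)")
        k = len(X)
        if k < 4:
            raise ValueError(f"need at least 4 control points, got {k}")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

        K = _kernel(X, X)
        off = K[~np.eye(k, dtype=bool)]
        if off.min() < 1e-12:
            raise ValueError("duplicated control points (zero pairwise distance)")
        sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        if sv[2] < 1e-9 * max(sv[0], 1.0):
            raise ValueError(
                "control points are coplanar: singular values "
                f"{sv.round(12).tolist()} leave the affine part underdetermined")

        P = np.hstack([np.ones((k, 1)), X])
        A = np.zeros((k + 4, k + 4))
        A[:k, :k] = K + self.regularization * np.eye(k)
        A[:k, k:] = P
        A[k:, :k] = P.T
        rhs = np.zeros((k + 4, 3))
        rhs[:k] = y
        sol = np.linalg.solve(A, rhs)
        self.weights_ = sol[:k]
        self.affine_ = sol[k:]
        self.control_source_ = X
        self.control_target_ = y
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        pts = np.asarray(X, dtype=float)
        squeeze = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = np.empty_like(pts)
        chunk = max(1, int(2e7 // max(len(self.control_source_), 1)))
        for lo in range(0, len(pts), chunk):
            p = pts[lo:lo + chunk]
            aff = np.hstack([np.ones((len(p), 1)), p]) @ self.affine_
            out[lo:lo + chunk] = aff + _kernel(p, self.control_source_) @ self.weights_
        return out[0] if squeeze else out

    def bending_weight_norm(self) -> float:
        """Frobenius norm of the kernel weights; zero for pure affine maps."""
        return float(np.linalg.norm(self.weights_))


def fit_tps(source: np.ndarray, target: np.ndarray,
            regularization: float = 0.0) -> ThinPlateSpline:
    return ThinPlateSpline(regularization=regularization).fit(source, target)


def apply_tps(transform: ThinPlateSpline, points: np.ndarray) -> np.ndarray:
    return transform.transform(points)
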