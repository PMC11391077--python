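"""Thin-plate spline surfaces for spatial interpolation of corrections.

The surface ``f(x) = a0 + a1*lon + a2*lat + sum_i w_i * phi(|x - x_i|)``
with kernel ``phi(r) = r^2 log r`` minimises residual sum of squares plus
``lambda`` times the bending energy.  The coefficients solve the
augmented symmetric system::

    [ K + lambda*I   P ] [w]   [y]
    [ P^T            0 ] [a] = [0]

where ``K_ij = phi(|x_i - x_j|)`` and ``P = [1, lon, lat]``.  The side
conditions ``P^T w = 0`` make the bending energy finite; with
``lambda = 0`` the surface interpolates the anchors exactly and
reproduces any affine field with ``w = 0``.  When no ``lambda`` is
supplied it is chosen by generalized cross-validation (GCV) over a log
grid, mirroring the "default settings" behaviour of standard TPS
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CorrectionSurface", "fit_tps", "tps_kernel"]


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """phi(r) = r^2 log r, with phi(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def _design(anchors: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    n = anchors.shape[0]
    d = np.linalg.norm(anchors[:, None, :] - anchors[None, :, :], axis=-1)
    K = tps_kernel(d)
    P = np.column_stack([np.ones(n), anchors])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    return A, K


@dataclass
class CorrectionSurface:
    """A fitted thin-plate spline for one variable's corrections.

    Attributes hold the anchor coordinates (lon, lat in degrees), the
    radial weights ``w`` and affine coefficients ``(a0, a1, a2)``, and
    the smoothing parameter used for the fit.
    """

    variable: str
    anchors: np.ndarray  # (n, 2) lon/lat
    values: np.ndarray  # (n,) anchor corrections in transformed units
    weights: np.ndarray  # (n,)
    affine: np.ndarray  # (3,) a0, a1, a2
    lam: float
    gcv_score: float | None = None

    def __call__(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        pts = np.stack([lon.ravel(), lat.ravel()], axis=-1)
        d = np.linalg.norm(pts[:, None, :] - self.anchors[None, :, :], axis=-1)
        vals = tps_kernel(d) @ self.weights
        vals += self.affine[0] + self.affine[1] * pts[:, 0] + self.affine[2] * pts[:, 1]
        return vals.reshape(lon.shape)

    def bending_energy(self) -> float:
        d = np.linalg.norm(self.anchors[:, None, :] - self.anchors[None, :, :], axis=-1)
        return float(self.weights @ tps_kernel(d) @ self.weights)


def _solve(anchors: np.ndarray, values: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    n = anchors.shape[0]
    A, _ = _design(anchors, lam)
    rhs = np.concatenate([values, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "thin-plate spline system is singular; anchors may be collinear or duplicated"
        ) from exc
    return sol[:n], sol[n:]


def _gcv(anchors: np.ndarray, values: np.ndarray, lam: float) -> float:
    """Generalized cross-validation score for one lambda."""
    n = anchors.shape[0]
    A, K = _design(anchors, lam)
    P = np.column_stack([np.ones(n), anchors])
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.inf
    # Influence matrix: y_hat = (K, P) @ sol-blocks @ [y; 0]
    B = np.hstack([K, P]) @ Ainv[:, :n]
    resid = values - B @ values
    denom = n - np.trace(B)
    if denom <= 1e-9:
        return np.inf
    return float(n * (resid @ resid) / denom**2)


def fit_tps(
    anchors: np.ndarray,
    values: np.ndarray,
    lam: float | None = 0.0,
    variable: str = "",
    lam_grid: np.ndarray | None = None,
) -> CorrectionSurface:
    """Fit a thin-plate spline surface through anchor corrections.

    Parameters
    ----------
    anchors:
        (n, 2) array of (lon, lat) coordinates; needs >= 3 non-collinear
        distinct points.
    values:
        (n,) anchor values (transformed-space corrections).
    lam:
        Smoothing parameter; 0 interpolates exactly, ``None`` selects by
        generalized cross-validation over ``lam_grid``.
    """
    anchors = np.asarray(anchors, dtype=float)
    values = np.asarray(values, dtype=float)
    if anchors.ndim != 2 or anchors.shape[1] != 2:
        raise ValueError("anchors must be an (n, 2) array of lon/lat")
    n = anchors.shape[0]
    if n < 3:
        raise ValueError("thin-plate spline needs at least 3 anchors")
    if values.shape != (n,):
        raise ValueError("values must be a length-n vector")
    uniq = np.unique(anchors, axis=0)
    if uniq.shape[0] < n:
        raise ValueError("duplicate anchor coordinates; merge them before fitting")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), anchors])) < 3:
        raise np.linalg.LinAlgError("anchors are collinear; spline affine part is rank-deficient")

    gcv_score = None
    if lam is None:
        if lam_grid is None:
            lam_grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e3, 23)])
        scores = [_gcv(anchors, values, l) for l in lam_grid]
        best = int(np.argmin(scores))
        lam = float(lam_grid[best])
        gcv_score = float(scores[best])
    w, a = _solve(anchors, values, float(lam))
    return CorrectionSurface(
        variable=variable,
        anchors=anchors,
        values=values,
        weights=w,
        affine=a,
        lam=float(lam),
        gcv_score=gcv_score,
    )
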