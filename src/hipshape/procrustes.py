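"""Generalized Procrustes analysis for 2D landmark configurations.

Translation is removed by centring on the centroid, size by rescaling to
unit centroid size (the root summed squared deviation from the centroid —
the standard size measure of geometric morphometrics), and rotation by the
orthogonal Procrustes solution.  Reflections are never permitted: shapes
from the contralateral side must be mirrored explicitly by the caller
(``mirror_x``) before alignment.

The iterative mean-shape estimate follows the classic scheme: initialise
with the first normalized configuration, rotate every configuration onto
the current mean, re-average, renormalize, and repeat to convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkConfiguration

__all__ = [
    "AlignedShape",
    "MeanShape",
    "centroid",
    "centroid_size",
    "normalize",
    "optimal_rotation",
    "rotation_angle",
    "gpa",
    "point_to_point",
    "point_to_point_batch",
    "mirror_x",
]


@dataclass(frozen=True)
class AlignedShape:
    """A configuration after removal of translation, scale and rotation.

    ``coords`` is the flattened vector ``(x1, y1, ..., xk, yk)``, centred,
    at unit centroid size, rotated into the mean's frame.
    """

    image_id: str
    coords: np.ndarray
    residual_to_mean: float

    @property
    def points(self) -> np.ndarray:
        return self.coords.reshape(-1, 2)


@dataclass(frozen=True)
class MeanShape:
    """GPA mean shape (unit centroid size, centred at the origin)."""

    coords: np.ndarray
    n_contributing: int
    gpa_iterations: int
    converged: bool
    ss_history: tuple[float, ...] = ()
    """Total Procrustes sum of squares after each iteration
    (non-increasing for a well-behaved fit)."""

    @property
    def points(self) -> np.ndarray:
        return self.coords.reshape(-1, 2)


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, LandmarkConfiguration):
        return obj.points
    if isinstance(obj, (AlignedShape, MeanShape)):
        return obj.points
    pts = np.asarray(obj, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(-1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected a (k, 2) point set, got {pts.shape}")
    return pts


def centroid(points) -> np.ndarray:
    """Arithmetic mean of the landmark coordinates."""
    pts = _as_points(points)
    if pts.shape[0] == 0:
        raise ValueError("centroid of an empty point set is undefined")
    return pts.mean(axis=0)


def centroid_size(points) -> float:
    """Root summed squared distance of the landmarks from their centroid."""
    pts = _as_points(points)
    if pts.shape[0] < 2:
        raise ValueError("centroid size needs at least two points")
    size = float(np.linalg.norm(pts - pts.mean(axis=0)))
    if size == 0.0:
        raise ValueError("all points coincide: centroid size is zero")
    return size


def normalize(points) -> np.ndarray:
    """Centre on the centroid and scale to unit centroid size."""
    pts = _as_points(points)
    centred = pts - pts.mean(axis=0)
    size = np.linalg.norm(centred)
    if size == 0.0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centred / size


def optimal_rotation(A, B) -> np.ndarray:
    """Proper rotation ``R`` minimizing ``||A @ R - B||_F``.

    ``A`` and ``B`` are centred ``(k, 2)`` point sets.  The solution is the
    orthogonal Procrustes rotation from the SVD of the cross-covariance
    ``A.T @ B``, with the sign of the smallest singular value corrected so
    the determinant is +1 (reflection suppressed).
    """
    A = _as_points(A)
    B = _as_points(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    H = A.T @ B
    if not np.any(H):
        raise ValueError("degenerate (zero) cross-covariance")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:
        raise ValueError("rank-deficient cross-covariance")
    R = U @ np.diag([1.0, d]) @ Vt
    return R


def rotation_angle(R: np.ndarray) -> float:
    """Angle (radians) by which ``points @ R`` rotates a point set.

    Uses the row-vector convention of :func:`optimal_rotation`;
    positive angles are counter-clockwise in a y-up frame.
    """
    return float(np.arctan2(R[0, 1], R[0, 0]))


def mirror_x(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a configuration about a vertical axis (left/right flip)."""
    pts = config.points.copy()
    pts[:, 0] = -pts[:, 0]
    from dataclasses import replace
    return replace(config, points=pts)


def gpa(
    configs,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[MeanShape, list[AlignedShape]]:
    """Generalized Procrustes analysis.

    Parameters
    ----------
    configs:
        Landmark configurations (or raw point sets) on a common template.
    tol:
        Convergence threshold on the Euclidean displacement of the mean
        between successive iterations.
    max_iter:
        Iteration cap; exceeding it emits a warning and sets
        ``converged=False`` rather than raising.

    Returns
    -------
    (MeanShape, list of AlignedShape)
        The mean has unit centroid size and zero centroid; each aligned
        shape carries its Procrustes residual (distance to the mean).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    ids = [c.image_id if isinstance(c, LandmarkConfiguration) else str(i)
           for i, c in enumerate(configs)]
    normalized = [normalize(c) for c in configs]
    k = normalized[0].shape[0]
    if any(p.shape[0] != k for p in normalized):
        raise ValueError("configurations differ in point count")

    mean = normalized[0].copy()
    converged = False
    iterations = 0
    ss_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        rotated = [p @ optimal_rotation(p, mean) for p in normalized]
        new_mean = normalize(np.mean(rotated, axis=0))
        ss_history.append(float(sum(
            np.sum((r - new_mean) ** 2) for r in rotated)))
        shift = float(np.linalg.norm(new_mean - mean))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iter} iterations",
            RuntimeWarning, stacklevel=2)

    aligned = []
    for image_id, p in zip(ids, normalized):
        rot = p @ optimal_rotation(p, mean)
        aligned.append(AlignedShape(
            image_id=image_id,
            coords=rot.reshape(-1),
            residual_to_mean=float(np.linalg.norm(rot - mean)),
        ))
    mean_shape = MeanShape(
        coords=mean.reshape(-1),
        n_contributing=len(configs),
        gpa_iterations=iterations,
        converged=converged,
        ss_history=tuple(ss_history),
    )
    return mean_shape, aligned


ACCURACY_MEDIAN_CUTOFF_PX = 3.0
"""Median point-to-point difference (pixels) at or below which a marking
session is conventionally considered accurate."""


def point_to_point(configA, configB) -> dict:
    """Per-point Euclidean distances between two markings of one image.

    Operates on raw pixel coordinates (not Procrustes-aligned), so the
    summary is in pixels and directly comparable with image size.
    """
    A = _as_points(configA)
    B = _as_points(configB)
    if A.shape != B.shape:
        raise ValueError(f"template mismatch: {A.shape} vs {B.shape}")
    d = np.linalg.norm(A - B, axis=1)
    return {
        "distances": d,
        "mean": float(d.mean()),
        "median": float(np.median(d)),
        "accurate": bool(np.median(d) <= ACCURACY_MEDIAN_CUTOFF_PX),
    }


def point_to_point_batch(configsA, configsB) -> dict:
    """Average per-image mean point-to-point distance across images."""
    if len(configsA) != len(configsB):
        raise ValueError("image sets differ in length")
    per_image = [point_to_point(a, b)["mean"]
                 for a, b in zip(configsA, configsB)]
    return {
        "per_image_means": np.asarray(per_image),
        "mean": float(np.mean(per_image)),
        "median": float(np.median(per_image)),
    }
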