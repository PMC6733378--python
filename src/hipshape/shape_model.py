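"""Point-distribution shape model: PCA modes of Procrustes-aligned landmarks.

``build_ssm`` eigen-decomposes the sample covariance (divisor n−1) of the
aligned coordinate vectors.  Each principal component is a *shape mode*;
an individual's mode score is their signed distance from the mean shape
along that mode, expressed in standard deviations of the training
population, so training scores have mean 0 and SD 1 per mode.

A fitted model can be frozen and applied as a *reference model* to shapes
from a different population: :func:`project` normalizes a new
configuration, rotates it onto the stored mean, and scores it with the
stored eigenvectors and score SDs without refitting anything.  Scores of
an external population therefore need not have mean 0 or SD 1 — their
departure from (0, 1) is exactly what makes populations comparable on a
common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landmark_io import LandmarkConfiguration
from .procrustes import AlignedShape, normalize, optimal_rotation

__all__ = [
    "ShapeModel",
    "ModeScores",
    "build_ssm",
    "score_training",
    "project",
    "reconstruct",
    "variance_explained",
    "truncate",
]


@dataclass(frozen=True)
class ShapeModel:
    """Frozen mean + orthonormal modes of a landmark population.

    Attributes
    ----------
    mean:
        Length-2k mean shape vector (unit centroid size, centred).
    eigenvectors:
        ``(M, 2k)`` orthonormal mode directions, descending eigenvalue.
    eigenvalues:
        Variance of the training shapes along each mode.
    score_sds:
        Per-mode SD of the raw training projections; the standardization
        divisor.  Equals ``sqrt(eigenvalue)`` up to numerical precision.
    variance_fraction:
        Per-mode share of the model's total variance (sums to 1).
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    score_sds: np.ndarray
    variance_fraction: np.ndarray
    n_training: int
    template_id: str = ""

    def __post_init__(self) -> None:
        for name in ("mean", "eigenvalues", "score_sds",
                     "variance_fraction"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        ev = np.asarray(self.eigenvectors, dtype=float)
        if ev.ndim != 2:
            ev = ev.reshape(-1, self.mean.size)
        object.__setattr__(self, "eigenvectors", ev)
        if ev.shape[1] != self.mean.size:
            raise ValueError("eigenvector length does not match mean")
        M = ev.shape[0]
        if not (self.eigenvalues.size == self.score_sds.size
                == self.variance_fraction.size == M):
            raise ValueError("per-mode field lengths disagree")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in descending order")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_points(self) -> int:
        return self.mean.size // 2

    @property
    def mean_points(self) -> np.ndarray:
        return self.mean.reshape(-1, 2)


@dataclass(frozen=True)
class ModeScores:
    """Standardized mode scores for one image (SD units)."""

    image_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError(f"non-finite score for image {self.image_id!r}")
        object.__setattr__(self, "scores", s)


def _coords_matrix(aligned: list[AlignedShape]) -> np.ndarray:
    X = np.vstack([a.coords for a in aligned])
    return X


def build_ssm(
    aligned: list[AlignedShape],
    eig_rtol: float = 1e-9,
    template_id: str = "",
) -> ShapeModel:
    """Fit the PCA shape model to Procrustes-aligned shapes.

    Parameters
    ----------
    aligned:
        Output of :func:`hipshape.procrustes.gpa`; at least two shapes.
    eig_rtol:
        Modes whose eigenvalue falls below ``eig_rtol`` times the leading
        eigenvalue are discarded as numerically null (after full GPA the
        four similarity-transform degrees of freedom leave near-zero
        directions).  Pass 0 to keep every mode with positive eigenvalue.

    Notes
    -----
    The eigenvector sign convention is deterministic: the largest-magnitude
    entry of each mode is made positive, so saved models and scores are
    reproducible across runs and platforms.
    """
    if len(aligned) < 2:
        raise ValueError("need at least two shapes to build a model")
    X = _coords_matrix(aligned)
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    lam, vec = np.linalg.eigh(cov)
    lam, vec = lam[::-1], vec[:, ::-1].T  # descending; rows are modes
    total = float(np.sum(np.clip(lam, 0.0, None)))
    if total <= 0.0:
        raise ValueError("zero total variance: all shapes identical")
    keep = lam > max(eig_rtol * lam[0], 0.0)
    lam, vec = lam[keep], vec[keep]
    # deterministic sign: largest-magnitude entry of each mode positive
    flip = np.sign(vec[np.arange(len(lam)), np.argmax(np.abs(vec), axis=1)])
    vec = vec * flip[:, None]
    raw = Xc @ vec.T
    score_sds = raw.std(axis=0, ddof=1)
    return ShapeModel(
        mean=mean,
        eigenvectors=vec,
        eigenvalues=lam,
        score_sds=score_sds,
        variance_fraction=lam / lam.sum(),
        n_training=X.shape[0],
        template_id=template_id,
    )


def score_training(
    model: ShapeModel, aligned: list[AlignedShape]
) -> list[ModeScores]:
    """Standardized scores of the shapes the model was trained on.

    Across the training set each mode's scores have mean 0 and unit SD.
    """
    out = []
    for a in aligned:
        if a.coords.size != model.mean.size:
            raise ValueError(
                f"image {a.image_id!r}: dimension {a.coords.size} does not "
                f"match model ({model.mean.size})")
        raw = model.eigenvectors @ (a.coords - model.mean)
        out.append(ModeScores(a.image_id, raw / model.score_sds))
    return out


def project(
    model: ShapeModel, config: LandmarkConfiguration | np.ndarray
) -> ModeScores:
    """Score a new configuration against a frozen reference model.

    The configuration is normalized (centred, unit centroid size), rotated
    onto the model mean by the orthogonal Procrustes solution, and its
    deviation from the mean is projected onto the saved eigenvectors and
    divided by the saved training SDs.  The model is never modified.
    """
    image_id = (config.image_id
                if isinstance(config, LandmarkConfiguration) else "")
    pts = (config.points if isinstance(config, LandmarkConfiguration)
           else np.asarray(config, dtype=float).reshape(-1, 2))
    if pts.shape[0] != model.n_points:
        raise ValueError(
            f"image {image_id!r} has {pts.shape[0]} points; model expects "
            f"{model.n_points}")
    norm = normalize(pts)
    rot = norm @ optimal_rotation(norm, model.mean_points)
    raw = model.eigenvectors @ (rot.reshape(-1) - model.mean)
    return ModeScores(image_id, raw / model.score_sds)


def project_population(
    model: ShapeModel, configs: list[LandmarkConfiguration]
) -> list[ModeScores]:
    """Project every configuration of a population (model untouched)."""
    return [project(model, c) for c in configs]


def reconstruct(model: ShapeModel, mode_index: int, k_sd: float) -> np.ndarray:
    """Shape at ``k_sd`` standard deviations along one mode.

    Returns the ``(k, 2)`` point set ``mean + k_sd * sd_m * e_m``, the
    representation conventionally drawn as the ±2 SD outlines of a mode.
    """
    if not 0 <= mode_index < model.n_modes:
        raise IndexError(
            f"mode {mode_index} out of range [0, {model.n_modes})")
    shape = model.mean + k_sd * model.score_sds[mode_index] \
        * model.eigenvectors[mode_index]
    return shape.reshape(-1, 2)


def variance_explained(model: ShapeModel, n_modes: int) -> float:
    """Cumulative variance fraction captured by the leading modes."""
    if not 0 <= n_modes <= model.n_modes:
        raise ValueError(
            f"n_modes must be in [0, {model.n_modes}], got {n_modes}")
    return float(model.variance_fraction[:n_modes].sum())


def truncate(model: ShapeModel, n_modes: int) -> ShapeModel:
    """Restrict the model to its leading modes.

    Variance fractions are kept as fitted (not renormalized), so
    ``variance_explained`` of the truncated model still refers to the
    full training variance.
    """
    if not 1 <= n_modes <= model.n_modes:
        raise ValueError(
            f"n_modes must be in [1, {model.n_modes}], got {n_modes}")
    return replace(
        model,
        eigenvectors=model.eigenvectors[:n_modes],
        eigenvalues=model.eigenvalues[:n_modes],
        score_sds=model.score_sds[:n_modes],
        variance_fraction=model.variance_fraction[:n_modes],
    )
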