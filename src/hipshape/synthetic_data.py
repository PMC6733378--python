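"""Synthetic femur-like landmark populations with known ground truth.

Real proximal-femur DXA landmark data sit behind managed access, so every
downstream stage (alignment, model building, projection, reliability,
effective-test counting) is exercised on simulated populations whose true
mean shape, true modes of variation and true scores are known exactly.

The generative model is the one a point-distribution model assumes:

.. math::

    x_i = T_i\\Bigl(\\bar{x} + \\sum_m s_{im}\\,\\sigma_m e_m\\Bigr)
          + \\varepsilon_i

with standard-normal true scores :math:`s_{im}`, orthonormal displacement
modes :math:`e_m`, a random similarity transform :math:`T_i` (rotation,
scale, translation — the nuisance Procrustes removes) and i.i.d. Gaussian
per-coordinate marking noise :math:`\\varepsilon_i`.

The 58-point base template is a parametric schematic of a proximal femur
outline (arcs and line segments, not traced from any image): femoral-head
arc, neck, greater- and lesser-trochanter bumps, medial and lateral shaft
segments, and a detached two-segment acetabular-eyebrow polyline, laid out
in a nominal 250 x 180 pixel frame using the raster convention
(x rightward, y downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkConfiguration, ShapeTemplate

__all__ = [
    "GroundTruthModel",
    "SyntheticPopulationSpec",
    "make_base_template",
    "make_ground_truth",
    "simulate_population",
    "simulate_remarking",
    "simulate_correlated_scores",
    "KEY_POINT_LABELS",
    "DEFAULT_EXCLUDED_INDICES",
]

# Anatomical descriptions of the key landmarks of the 58-point markup.
KEY_POINT_LABELS: dict[int, str] = {
    2: "Medial femoral shaft meets inferior lesser trochanter",
    4: "Medial femoral shaft meets superior lesser trochanter",
    9: "Lateral inferior curvature of femoral head at femoral neck",
    10: "Medial inferior curvature of the femoral head",
    23: "Superior lateral femoral head curvature",
    25: "Inferior lateral femoral head at the superior femoral neck",
    29: "Inferior greater trochanter slope at superior femoral neck",
    31: "Medial superior greater trochanter",
    38: "Inferior lateral greater trochanter",
    43: "Lateral femoral shaft",
    46: "Inferior lesser trochanter",
    51: "Acetabular eyebrow medial end",
    56: "Acetabular eyebrow lateral end",
}

# Markup points dropped before modelling: high placement variability at
# the acetabular overhang and the distal shaft ends.
DEFAULT_EXCLUDED_INDICES = frozenset({0, 1, 44, 45, 57})

# Point 46 often coincides with point 2 depending on patient positioning.
_ALIASES = {46: 2}


@dataclass(frozen=True)
class GroundTruthModel:
    """Known population model behind a simulated landmark data set."""

    base_shape: np.ndarray            # (k, 2), pixel units
    true_modes: np.ndarray            # (n_modes, 2k), orthonormal rows
    true_mode_sds: np.ndarray         # (n_modes,), pixel units

    def __post_init__(self) -> None:
        base = np.asarray(self.base_shape, dtype=float)
        modes = np.asarray(self.true_modes, dtype=float)
        sds = np.asarray(self.true_mode_sds, dtype=float)
        if modes.ndim != 2 or modes.shape[1] != 2 * base.shape[0]:
            raise ValueError("true_modes must be (n_modes, 2k)")
        if sds.shape != (modes.shape[0],):
            raise ValueError("one SD per mode required")
        G = modes @ modes.T
        if not np.allclose(G, np.eye(modes.shape[0]), atol=1e-8):
            raise ValueError("true modes are not orthonormal")
        if modes.shape[0] > 2 * base.shape[0] - 4:
            raise ValueError(
                "at most 2k-4 modes are identifiable after removing "
                "the similarity transform")
        object.__setattr__(self, "base_shape", base)
        object.__setattr__(self, "true_modes", modes)
        object.__setattr__(self, "true_mode_sds", sds)

    @property
    def n_modes(self) -> int:
        return self.true_modes.shape[0]


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Sampling conditions for one simulated marking session.

    Defaults emulate plausible DXA positioning variation: rotation within
    ±15 degrees, isotropic scale 0.9–1.1, translation within ±20 px, and
    1 px per-coordinate marking noise.
    """

    n_images: int
    rotation_range: float = np.deg2rad(15.0)     # radians, symmetric
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range: float = 20.0              # pixels, symmetric
    marking_noise_sd: float = 1.0                # pixels per coordinate
    seed: int = 0
    template: ShapeTemplate | None = None
    aspect_ratio: float = 1.0   # optional anisotropic pixel-spacing factor

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ValueError("n_images must be at least 2")
        if self.marking_noise_sd < 0:
            raise ValueError("marking_noise_sd must be non-negative")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range bounds must be positive and ordered")
        if self.rotation_range < 0 or self.translation_range < 0:
            raise ValueError("nuisance ranges must be non-negative")


# ---------------------------------------------------------------------------
# base template

def _arc(centre, radius, deg_from, deg_to, n) -> np.ndarray:
    """n points on a circular arc; angles in degrees, y-up frame."""
    th = np.deg2rad(np.linspace(deg_from, deg_to, n))
    return np.column_stack([centre[0] + radius * np.cos(th),
                            centre[1] + radius * np.sin(th)])


def _segment(p, q, n, endpoint=False) -> np.ndarray:
    """n points from p toward q (excluding q unless endpoint)."""
    t = np.linspace(0.0, 1.0, n, endpoint=endpoint)[:, None]
    return np.asarray(p) + t * (np.asarray(q) - np.asarray(p))


def _femur_outline_58() -> np.ndarray:
    """Schematic 58-point proximal femur, y-up design frame."""
    head_c, head_r = np.array([90.0, 120.0]), 30.0
    rows: list[np.ndarray] = []
    # 0-4: medial shaft bottom, up to and over the lesser trochanter
    rows.append(np.array([[135.0, 0.0], [135.0, 12.0]]))     # 0, 1 (excluded)
    rows.append(np.array([[136.0, 24.0]]))                   # 2
    rows.append(np.array([[127.0, 32.0]]))                   # 3 (apex)
    rows.append(np.array([[136.0, 40.0]]))                   # 4
    # 5-8: medial neck rising toward the head
    rows.append(_segment([136.0, 48.0], [113.0, 90.0], 4))   # 5-8
    # 9: neck-head junction (inferior)
    rows.append(np.array([[110.0, 94.0]]))
    # 10-24: femoral head arc, swept away from the neck over the top
    rows.append(_arc(head_c, head_r, -70.0, -330.0, 15))     # 10-24
    # 25: head meets superior neck
    rows.append(np.array([[119.0, 133.0]]))
    # 26-28: superior neck toward the greater trochanter
    rows.append(_segment([126.0, 128.0], [150.0, 106.0], 3, endpoint=True))
    # 29-31: trochanteric slope up to its medial superior corner
    rows.append(np.array([[158.0, 101.0], [168.0, 103.0], [178.0, 105.0]]))
    # 32-37: over the greater trochanter and down its lateral face
    rows.append(np.array([[185.0, 108.0], [192.0, 104.0], [196.0, 96.0],
                          [197.0, 88.0], [196.0, 78.0], [194.0, 68.0]]))
    # 38: inferior lateral greater trochanter
    rows.append(np.array([[192.0, 60.0]]))
    # 39-43: lateral shaft descending
    rows.append(np.array([[190.0, 48.0], [188.0, 36.0], [187.0, 24.0],
                          [186.0, 14.0], [186.0, 8.0]]))
    # 44-45: distal lateral shaft (excluded)
    rows.append(np.array([[186.0, 2.0], [178.0, 0.0]]))
    # 46: inferior lesser trochanter (often coincides with point 2)
    rows.append(np.array([[139.0, 21.0]]))
    # 47-50: distal medial shaft back toward the start
    rows.append(np.array([[138.0, 14.0], [137.0, 8.0], [136.0, 3.0],
                          [136.0, 0.0]]))
    # 51-56: detached acetabular eyebrow above the head (medial->lateral)
    rows.append(_arc(head_c, 48.0, 150.0, 55.0, 6))
    # 57: stray point past the eyebrow's lateral end (excluded)
    rows.append(np.array([[125.0, 165.0]]))
    pts = np.vstack(rows)
    assert pts.shape == (58, 2)
    pts[:, 1] = 180.0 - pts[:, 1]   # flip to raster convention (y down)
    return pts


def _generic_outline(n_points: int) -> np.ndarray:
    """Smooth femur-ish closed outline for non-standard point counts."""
    t = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    r = 60.0 + 18.0 * np.cos(2 * t) + 8.0 * np.sin(3 * t)
    pts = np.column_stack([125.0 + r * np.cos(t), 90.0 + 0.9 * r * np.sin(t)])
    return pts


def make_base_template(
    n_points: int = 58,
) -> tuple[ShapeTemplate, np.ndarray]:
    """Build the landmark template and its schematic base point set.

    ``n_points=58`` yields the standard markup: 58 labelled points of
    which five ({0, 1, 44, 45, 57}) are excluded, leaving the 53-point
    model.  Any other even count >= 12 yields an unlabelled femur-ish
    closed outline with an empty exclusion set.
    """
    if n_points % 2 != 0 or n_points < 12:
        raise ValueError(
            f"invalid template size {n_points}: need an even count >= 12")
    if n_points == 58:
        template = ShapeTemplate(
            template_id="femur58",
            n_points_markup=58,
            labels=dict(KEY_POINT_LABELS),
            excluded_indices=DEFAULT_EXCLUDED_INDICES,
            aliases=dict(_ALIASES),
        )
        return template, _femur_outline_58()
    template = ShapeTemplate(
        template_id=f"outline{n_points}",
        n_points_markup=n_points,
    )
    return template, _generic_outline(n_points)


# ---------------------------------------------------------------------------
# ground-truth modes

def _similarity_tangent_basis(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity-transform directions at a shape.

    Rows span translation (x, y), infinitesimal rotation and scaling of
    the centred shape — the 4 degrees of freedom Procrustes removes.
    """
    k = base.shape[0]
    centred = base - base.mean(axis=0)
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    scale = centred.reshape(-1)
    rot = np.column_stack([-centred[:, 1], centred[:, 0]]).reshape(-1)
    B = np.vstack([tx, ty, scale, rot])
    Q, _ = np.linalg.qr(B.T)
    return Q.T


def make_ground_truth(
    base_shape: np.ndarray,
    n_modes: int,
    mode_sds,
    seed: int = 0,
    n_harmonics: int = 5,
) -> GroundTruthModel:
    """Plant smooth orthonormal modes of variation on a base shape.

    Each mode starts as a random low-frequency displacement field (a
    short Fourier series over the point index, coefficient SD decaying as
    1/harmonic), mimicking the smoothness of principal modes of real
    outlines.  The fields are projected off the similarity-transform
    tangent space — a planted mode must be genuine *shape* variation,
    invisible to none of the downstream pipeline — then orthonormalized.
    """
    base = np.asarray(base_shape, dtype=float)
    k = base.shape[0]
    if not 0 <= n_modes <= 2 * k - 4:
        raise ValueError(f"n_modes must be in [0, {2 * k - 4}]")
    mode_sds = np.broadcast_to(np.asarray(mode_sds, dtype=float),
                               (n_modes,)).copy()
    rng = np.random.default_rng(seed)
    t = np.arange(k) / k
    fields = np.empty((n_modes, 2 * k))
    for m in range(n_modes):
        disp = np.zeros((k, 2))
        for h in range(1, n_harmonics + 1):
            amp = 1.0 / h
            for axis in range(2):
                a, b = rng.normal(0.0, amp, size=2)
                disp[:, axis] += (a * np.cos(2 * np.pi * h * t)
                                  + b * np.sin(2 * np.pi * h * t))
        fields[m] = disp.reshape(-1)
    sim = _similarity_tangent_basis(base)
    fields -= (fields @ sim.T) @ sim
    Q, R = np.linalg.qr(fields.T)
    if n_modes and np.min(np.abs(np.diag(R))) < 1e-10:
        raise ValueError("degenerate random fields; use another seed")
    modes = (Q[:, :n_modes] * np.sign(np.diag(R))[:n_modes]).T
    return GroundTruthModel(base, modes, mode_sds)


# ---------------------------------------------------------------------------
# population simulation

def _similarity(points: np.ndarray, angle: float, scale: float,
                shift: np.ndarray) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[c, -s], [s, c]])
    return scale * points @ R.T + shift


def simulate_population(
    gt: GroundTruthModel,
    spec: SyntheticPopulationSpec,
) -> tuple[list[LandmarkConfiguration], np.ndarray]:
    """Draw one marked landmark population from the generative model.

    Returns the configurations and the ``(n_images, n_modes)`` matrix of
    true standard-normal scores, for parameter-recovery tests.
    Bit-reproducible from ``spec.seed``.
    """
    k = gt.base_shape.shape[0]
    if spec.template is not None and spec.template.n_points_markup != k:
        raise ValueError(
            f"template expects {spec.template.n_points_markup} points, "
            f"ground truth has {k}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_images
    scores = rng.standard_normal((n, gt.n_modes))
    angles = rng.uniform(-spec.rotation_range, spec.rotation_range, n)
    scales = rng.uniform(*spec.scale_range, n)
    shifts = rng.uniform(-spec.translation_range, spec.translation_range,
                         (n, 2))
    noise = (rng.normal(0.0, spec.marking_noise_sd, (n, k, 2))
             if spec.marking_noise_sd > 0 else np.zeros((n, k, 2)))
    template_id = spec.template.template_id if spec.template else ""
    width = len(str(n - 1))
    configs = []
    for i in range(n):
        disp = (scores[i] * gt.true_mode_sds) @ gt.true_modes
        shape = gt.base_shape + disp.reshape(k, 2)
        shape = shape * np.array([spec.aspect_ratio, 1.0])
        shape = _similarity(shape, angles[i], scales[i], shifts[i])
        configs.append(LandmarkConfiguration(
            image_id=f"img{i:0{width}d}",
            points=shape + noise[i],
            template_id=template_id,
        ))
    return configs, scores


def simulate_remarking(
    population: list[LandmarkConfiguration],
    noise_sd: float,
    seed: int = 0,
) -> list[LandmarkConfiguration]:
    """Emulate a second marking session of the same images.

    Each configuration is copied with fresh i.i.d. per-coordinate
    Gaussian noise of scale ``noise_sd`` pixels.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    from dataclasses import replace
    out = []
    for cfg in population:
        noise = (rng.normal(0.0, noise_sd, cfg.points.shape)
                 if noise_sd > 0 else 0.0)
        out.append(replace(cfg, points=cfg.points + noise))
    return out


def simulate_correlated_scores(
    R: np.ndarray, n: int, seed: int = 0
) -> np.ndarray:
    """Draw ``n`` i.i.d. zero-mean score vectors with correlation ``R``.

    Independent standard normals are linearly transformed with the
    symmetric square root of ``R``, so the population correlation is
    exactly ``R`` and the sample correlation converges to it.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("R must have unit diagonal")
    lam, V = np.linalg.eigh(R)
    if lam.min() < -1e-10:
        raise ValueError(
            f"R is not positive semi-definite: eigenvalue {lam.min():.3e}")
    L = V * np.sqrt(np.clip(lam, 0.0, None))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, R.shape[0]))
    return Z @ L.T
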