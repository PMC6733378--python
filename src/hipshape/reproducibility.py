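"""Repeatability of landmark placement and of mode scores.

Two complementary views of marking reliability:

* **point-to-point repeatability** — per-landmark Euclidean distance in
  raw pixels between two markings of the same image (the units in which
  placement error is judged against image size; a median of <= 3 px per
  image is the conventional accuracy cut-off);
* **per-mode intraclass correlation** — agreement of standardized mode
  scores between two sessions or two markers, one ICC per mode.

The ICC variant is the two-way random-effects, absolute-agreement,
single-measurement coefficient ICC(2,1) — the conservative standard for
test–retest of continuous scores.  A consistency-type variant ICC(3,1)
is available for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration
from .procrustes import ACCURACY_MEDIAN_CUTOFF_PX, point_to_point
from .shape_model import ModeScores

__all__ = [
    "ReliabilityReport",
    "repeatability_summary",
    "icc",
    "icc_per_mode",
    "scores_frame",
    "ICC_FLAG_THRESHOLD",
]

ICC_FLAG_THRESHOLD = 0.70
"""Modes with ICC below this are flagged as poorly reproduced."""


@dataclass(frozen=True)
class ReliabilityReport:
    """Summary of a two-session (or two-marker) reliability study."""

    n_images: int
    mean_point_to_point: float
    median_point_to_point: float
    per_image_means: np.ndarray = field(repr=False)
    inaccurate_images: tuple[str, ...] = ()
    icc_per_mode: tuple[tuple[str, float], ...] = ()
    mean_icc: float | None = None
    low_icc_modes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "mean_point_to_point_px": self.mean_point_to_point,
            "median_point_to_point_px": self.median_point_to_point,
            "accuracy_cutoff_px": ACCURACY_MEDIAN_CUTOFF_PX,
            "inaccurate_images": list(self.inaccurate_images),
            "icc_per_mode": {m: v for m, v in self.icc_per_mode},
            "mean_icc": self.mean_icc,
            "low_icc_modes": list(self.low_icc_modes),
        }


def _by_id(configs) -> dict[str, LandmarkConfiguration]:
    return {c.image_id: c for c in configs}


def repeatability_summary(setA, setB) -> ReliabilityReport:
    """Point-to-point repeatability between two matched marking sessions.

    Distances are computed per image on raw pixel coordinates; the report
    carries the per-image mean distances, their overall mean and median,
    and the images whose median distance exceeds the accuracy cut-off.
    """
    a, b = _by_id(setA), _by_id(setB)
    missing = sorted(set(a) ^ set(b))
    if missing:
        raise ValueError(f"unmatched image ids between sessions: {missing}")
    ids = sorted(a)
    per_image, flagged = [], []
    for image_id in ids:
        res = point_to_point(a[image_id], b[image_id])
        per_image.append(res["mean"])
        if not res["accurate"]:
            flagged.append(image_id)
    per_image = np.asarray(per_image)
    return ReliabilityReport(
        n_images=len(ids),
        mean_point_to_point=float(per_image.mean()),
        median_point_to_point=float(np.median(per_image)),
        per_image_means=per_image,
        inaccurate_images=tuple(flagged),
    )


def icc(ratings, kind: str = "agreement") -> float:
    """Intraclass correlation of a complete subjects x raters matrix.

    ``kind='agreement'`` gives ICC(2,1) from the two-way random-effects
    ANOVA mean squares:

        (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    where MS_R, MS_C, MS_E are the subject, rater and error mean squares.
    ``kind='consistency'`` gives ICC(3,1), which ignores systematic
    rater offsets.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 subjects "
                         "and >= 2 raters")
    if not np.all(np.isfinite(Y)):
        raise ValueError("ratings matrix contains non-finite values")
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    resid = Y - row_means[:, None] - col_means[None, :] + grand
    ss_err = np.sum(resid ** 2)
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))

    if ss_rows == 0.0:
        warnings.warn("zero between-subject variance: ICC is degenerate",
                      RuntimeWarning, stacklevel=2)
    if kind == "agreement":
        denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    elif kind == "consistency":
        denom = ms_rows + (k - 1) * ms_err
    else:
        raise ValueError(f"unknown ICC kind {kind!r}")
    if denom == 0.0:
        warnings.warn("constant ratings matrix: ICC undefined, returning nan",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float((ms_rows - ms_err) / denom)


def scores_frame(scores: list[ModeScores]) -> pd.DataFrame:
    """Scores table: one row per image, columns ``hsm1..hsmM``."""
    if not scores:
        return pd.DataFrame()
    M = scores[0].scores.size
    data = {s.image_id: s.scores for s in scores}
    df = pd.DataFrame.from_dict(
        data, orient="index",
        columns=[f"hsm{m + 1}" for m in range(M)])
    df.index.name = "image_id"
    return df.sort_index()


def icc_per_mode(
    scoresA, scoresB, kind: str = "agreement"
) -> tuple[list[tuple[str, float]], float, list[str]]:
    """Per-mode ICC between two score tables over the same images.

    Accepts DataFrames (images in rows, modes in columns) or lists of
    :class:`~hipshape.shape_model.ModeScores`.  Returns the per-mode ICCs,
    their arithmetic mean and the modes flagged below the 0.70 threshold.
    """
    A = scoresA if isinstance(scoresA, pd.DataFrame) else scores_frame(scoresA)
    B = scoresB if isinstance(scoresB, pd.DataFrame) else scores_frame(scoresB)
    if list(A.columns) != list(B.columns):
        raise ValueError("score tables have different mode columns")
    missing = sorted(set(A.index) ^ set(B.index))
    if missing:
        raise ValueError(f"unmatched image ids between tables: {missing}")
    B = B.loc[A.index]
    out = []
    for col in A.columns:
        out.append((str(col),
                    icc(np.column_stack([A[col], B[col]]), kind=kind)))
    mean_icc = float(np.mean([v for _, v in out]))
    low = [m for m, v in out if v < ICC_FLAG_THRESHOLD]
    return out, mean_icc, low


def reliability_study(
    setA, setB, model=None, kind: str = "agreement"
) -> ReliabilityReport:
    """Full reliability report: distances plus (optionally) score ICCs.

    When a shape model is given, both sessions are scored against it —
    the same frozen model, so ICC reflects marking noise only — and the
    per-mode ICCs are appended to the distance summary.
    """
    report = repeatability_summary(setA, setB)
    if model is None:
        return report
    from dataclasses import replace

    from .shape_model import project
    sA = [project(model, c) for c in sorted(setA, key=lambda c: c.image_id)]
    sB = [project(model, c) for c in sorted(setB, key=lambda c: c.image_id)]
    per_mode, mean_icc, low = icc_per_mode(sA, sB, kind=kind)
    return replace(report, icc_per_mode=tuple(per_mode),
                   mean_icc=mean_icc, low_icc_modes=tuple(low))
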