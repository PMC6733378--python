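"""Landmark, template and shape-model file I/O plus exclusion-ledger accounting.

The on-disk formats are deliberately plain text:

* **points CSV** — long format, one row per landmark, columns
  ``image_id, point_index, x, y``.  Long format makes partial or corrupted
  files detectable (a missing point is a missing row, not a silently
  shifted column) and is robust to template changes.
* **model file** — a self-describing key–value + matrix-block text format
  (see :func:`write_model_file`) that round-trips a fitted shape model
  losslessly at ``repr`` precision.

Point indices are 0-based throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ShapeTemplate",
    "LandmarkConfiguration",
    "ExclusionLedger",
    "read_points_csv",
    "write_points_csv",
    "apply_template_exclusions",
    "ledger_apply",
    "write_model_file",
    "read_model_file",
]

MODEL_FORMAT_VERSION = 1


class MalformedFileError(ValueError):
    """A landmark or model file violates its documented format."""


@dataclass(frozen=True)
class ShapeTemplate:
    """Roster of landmark points for one markup protocol.

    Parameters
    ----------
    template_id:
        Short identifier written into point files.
    n_points_markup:
        Number of points placed on each image.
    labels:
        Anatomical descriptions for key points, ``index -> text``.
    excluded_indices:
        Points placed during markup but dropped before modelling
        (e.g. unreliable acetabular-overhang points).
    aliases:
        Metadata only: points that can map onto one another depending on
        patient positioning (no coordinates are ever merged).
    """

    template_id: str
    n_points_markup: int
    labels: dict[int, str] = field(default_factory=dict)
    excluded_indices: frozenset[int] = frozenset()
    aliases: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_points_markup < 1:
            raise ValueError("template must have at least one point")
        bad = [i for i in self.excluded_indices
               if not 0 <= i < self.n_points_markup]
        if bad:
            raise ValueError(f"excluded indices out of range: {sorted(bad)}")
        bad = [i for i in self.labels if not 0 <= i < self.n_points_markup]
        if bad:
            raise ValueError(f"labelled indices out of range: {sorted(bad)}")
        object.__setattr__(self, "excluded_indices",
                           frozenset(self.excluded_indices))

    @property
    def n_points_model(self) -> int:
        """Points retained in the final model."""
        return self.n_points_markup - len(self.excluded_indices)

    @property
    def retained_indices(self) -> np.ndarray:
        """Sorted indices that survive exclusion, original order preserved."""
        return np.array(
            [i for i in range(self.n_points_markup)
             if i not in self.excluded_indices],
            dtype=int,
        )


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One image's ordered 2D point set, in pixel coordinates."""

    image_id: str
    points: np.ndarray  # (k, 2) float array
    template_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(
                f"points must be (k, 2), got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError(
                f"non-finite coordinate in image {self.image_id!r}")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def flattened(self) -> np.ndarray:
        """Coordinates as ``(x1, y1, ..., xk, yk)``."""
        return self.points.reshape(-1)


@dataclass(frozen=True)
class ExclusionLedger:
    """Stage-by-stage accounting of images removed before modelling."""

    initial_count: int
    stage_names: tuple[str, ...]
    counts_removed: tuple[int, ...]

    @property
    def final_count(self) -> int:
        return self.initial_count - sum(self.counts_removed)

    def running_counts(self) -> list[int]:
        out, n = [], self.initial_count
        for r in self.counts_removed:
            n -= r
            out.append(n)
        return out

    def report(self) -> str:
        """Human-readable table of the exclusion cascade."""
        width = max([len("Images available")]
                    + [len(s) for s in self.stage_names])
        lines = [f"{'Images available':<{width}}  {self.initial_count:>7,}"]
        for name, removed, left in zip(
                self.stage_names, self.counts_removed, self.running_counts()):
            lines.append(f"{name:<{width}}  -{removed:>6,}  ({left:,} left)")
        lines.append(f"{'Final':<{width}}  {self.final_count:>7,}")
        return "\n".join(lines)


def ledger_apply(
    initial_count: int,
    stages: list[tuple[str, int]] | tuple[tuple[str, int], ...] = (),
) -> ExclusionLedger:
    """Apply an ordered cascade of exclusion stages to an image count.

    Each stage removes a non-negative number of images; the running total
    must never go negative.
    """
    if initial_count < 0:
        raise ValueError("initial count must be non-negative")
    names, removed = [], []
    running = initial_count
    for name, n in stages:
        if n < 0:
            raise ValueError(f"stage {name!r} removes a negative count")
        running -= n
        if running < 0:
            raise ValueError(
                f"stage {name!r} drives the running total below zero "
                f"({running})")
        names.append(str(name))
        removed.append(int(n))
    return ExclusionLedger(int(initial_count), tuple(names), tuple(removed))


# ---------------------------------------------------------------------------
# points CSV

_POINTS_COLUMNS = ["image_id", "point_index", "x", "y"]


def read_points_csv(
    path, template: ShapeTemplate | None = None
) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a long-format points CSV.

    Rows may appear in any order; points are sorted by ``point_index``
    within each image.  When ``template`` is given the point count of
    every image is checked strictly against ``template.n_points_markup``.
    """
    try:
        df = pd.read_csv(path, dtype={"image_id": str},
                         float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise MalformedFileError(f"cannot parse points file {path}: {exc}")
    missing = [c for c in _POINTS_COLUMNS if c not in df.columns]
    if missing:
        raise MalformedFileError(
            f"points file {path} lacks columns {missing}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: one for the header, one for 0- vs 1-based line numbers
            line = int(bad.idxmax()) + 2
            raise MalformedFileError(
                f"non-numeric {col!r} value at line {line} of {path}")
    df["point_index"] = df["point_index"].astype(int)
    df[["x", "y"]] = df[["x", "y"]].astype(float)

    configs: list[LandmarkConfiguration] = []
    template_id = template.template_id if template is not None else ""
    for image_id, grp in df.groupby("image_id", sort=True):
        idx = grp["point_index"].to_numpy()
        dup = pd.Series(idx).duplicated()
        if dup.any():
            raise MalformedFileError(
                f"image {image_id!r}: duplicate point index "
                f"{int(idx[dup.to_numpy()][0])}")
        expected = (template.n_points_markup if template is not None
                    else int(idx.max()) + 1)
        present = set(idx.tolist())
        absent = sorted(set(range(expected)) - present)
        if absent or len(idx) != expected:
            extra = sorted(present - set(range(expected)))
            detail = (f"missing indices {absent}" if absent
                      else f"unexpected indices {extra}")
            raise MalformedFileError(
                f"image {image_id!r}: expected {expected} points, "
                f"got {len(idx)} ({detail})")
        grp = grp.sort_values("point_index")
        configs.append(LandmarkConfiguration(
            image_id=str(image_id),
            points=grp[["x", "y"]].to_numpy(),
            template_id=template_id,
        ))
    return configs


def write_points_csv(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as a long-format points CSV.

    Row order is deterministic (image_id, then point_index) and
    coordinates are written with 17 significant digits so a
    write→read round trip is bit-exact.
    """
    frames = []
    for cfg in sorted(configs, key=lambda c: c.image_id):
        frames.append(pd.DataFrame({
            "image_id": cfg.image_id,
            "point_index": np.arange(cfg.n_points),
            "x": cfg.points[:, 0],
            "y": cfg.points[:, 1],
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=_POINTS_COLUMNS)
    out.to_csv(path, index=False, float_format="%.17g")


def apply_template_exclusions(
    config: LandmarkConfiguration, template: ShapeTemplate
) -> LandmarkConfiguration:
    """Drop a template's excluded points from a full markup configuration.

    The configuration must still hold the full markup point count; a
    configuration that was already reduced is rejected rather than
    silently re-indexed.
    """
    if config.n_points != template.n_points_markup:
        raise ValueError(
            f"image {config.image_id!r} has {config.n_points} points; "
            f"template {template.template_id!r} expects "
            f"{template.n_points_markup} (already reduced?)")
    return replace(config, points=config.points[template.retained_indices])


# ---------------------------------------------------------------------------
# model file

def _write_matrix(fh: io.TextIOBase, name: str, arr: np.ndarray) -> None:
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    fh.write(f"@{name} {arr.shape[0]} {arr.shape[1]}\n")
    for row in arr:
        fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def write_model_file(model, path) -> None:
    """Serialise a fitted shape model to a self-describing text file.

    Layout: a ``format_version`` line, scalar ``key value`` lines, then
    ``@name rows cols`` matrix blocks with one whitespace-separated row
    per line.  Floats are written with ``repr`` so the round trip is
    lossless.
    """
    with open(path, "w") as fh:
        fh.write(f"format_version {MODEL_FORMAT_VERSION}\n")
        fh.write(f"template_id {model.template_id or '-'}\n")
        fh.write(f"n_points {model.n_points}\n")
        fh.write(f"n_modes {model.n_modes}\n")
        fh.write(f"n_training {model.n_training}\n")
        _write_matrix(fh, "mean", model.mean[None, :])
        _write_matrix(fh, "eigenvectors", model.eigenvectors)
        _write_matrix(fh, "eigenvalues", model.eigenvalues[None, :])
        _write_matrix(fh, "score_sds", model.score_sds[None, :])
        _write_matrix(fh, "variance_fraction",
                      model.variance_fraction[None, :])


def read_model_file(path):
    """Read a shape model written by :func:`write_model_file`."""
    from .shape_model import ShapeModel  # deferred: avoids import cycle

    scalars: dict[str, str] = {}
    matrices: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith("@"):
            try:
                name, nrow, ncol = line[1:].split()
                nrow, ncol = int(nrow), int(ncol)
                block = lines[i:i + nrow]
                if len(block) < nrow:
                    raise ValueError("truncated matrix block")
                mat = np.array([[float(v) for v in row.split()]
                                for row in block]).reshape(nrow, ncol)
                if mat.shape != (nrow, ncol):
                    raise ValueError("matrix block shape mismatch")
            except ValueError as exc:
                raise MalformedFileError(
                    f"model file {path}: bad matrix block {line!r} ({exc})")
            matrices[name] = mat
            i += nrow
        else:
            key, _, value = line.partition(" ")
            scalars[key] = value.strip()

    version = scalars.get("format_version")
    if version != str(MODEL_FORMAT_VERSION):
        raise MalformedFileError(
            f"model file {path}: unsupported format_version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})")
    required = ["mean", "eigenvectors", "eigenvalues", "score_sds",
                "variance_fraction"]
    missing = [k for k in required if k not in matrices]
    if missing:
        raise MalformedFileError(
            f"model file {path}: missing blocks {missing}")

    n_modes = int(scalars.get("n_modes", matrices["eigenvectors"].shape[0]))
    eigenvectors = matrices["eigenvectors"]
    if n_modes == 0:
        eigenvectors = eigenvectors.reshape(0, matrices["mean"].size)
    template_id = scalars.get("template_id", "-")
    return ShapeModel(
        mean=matrices["mean"].ravel(),
        eigenvectors=eigenvectors,
        eigenvalues=matrices["eigenvalues"].ravel()[:n_modes],
        score_sds=matrices["score_sds"].ravel()[:n_modes],
        variance_fraction=matrices["variance_fraction"].ravel()[:n_modes],
        n_training=int(scalars.get("n_training", 0)),
        template_id="" if template_id == "-" else template_id,
    )
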