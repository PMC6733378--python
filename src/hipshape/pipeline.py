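"""End-to-end workflow: ingest -> exclude -> align -> model/project -> report.

``run_pipeline`` composes the library stages into the standard study
workflow.  With no reference model it builds a shape model on the input
population and reports training scores (per-mode mean 0, SD 1 by
construction).  With a frozen reference model it projects every image
onto the saved eigenvectors without touching the model, so projected
means and SDs are free to drift from (0, 1) — the quantity of interest
when comparing populations.

Every run is reproducible from (config, seed): artifact row order and
float formatting are deterministic.  Exclusion accounting is a
first-class output: the summary carries a ledger whose final count always
equals the number of score rows emitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import landmark_io, procrustes, shape_model
from .effective_tests import correlation_matrix, nyholt_veff
from .landmark_io import LandmarkConfiguration, ShapeTemplate
from .reproducibility import scores_frame
from .synthetic_data import make_base_template

log = logging.getLogger("hipshape.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "summarize_scores"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    points_path: str
    output_dir: str
    template_points: int = 58
    mirror: str = "none"               # none | all
    n_modes_retained: int = 10
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100
    reference_model_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modes_retained < 1:
            raise ValueError("n_modes_retained must be >= 1")
        if self.mirror not in ("none", "all"):
            raise ValueError("mirror must be 'none' or 'all'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def summarize_scores(scores) -> dict:
    """Per-mode mean/SD table plus correlation and effective-test summary.

    ``scores`` is a DataFrame (images x modes) or a list of
    :class:`~hipshape.shape_model.ModeScores`.
    """
    df = scores if isinstance(scores, pd.DataFrame) else scores_frame(scores)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 score rows to summarize")
    table = pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1),
    })
    out = {
        "n_images": int(df.shape[0]),
        "n_modes": int(df.shape[1]),
        "per_mode": {
            str(m): {"mean": float(r["mean"]), "sd": float(r["sd"])}
            for m, r in table.iterrows()
        },
    }
    if df.shape[1] >= 2 and (df.std(ddof=1) > 0).all():
        R = correlation_matrix(df)
        res = nyholt_veff(R.to_numpy())
        out["correlation"] = {
            "matrix": R.round(4).to_dict(),
            "n_unique_offdiagonal": df.shape[1] * (df.shape[1] - 1) // 2,
        }
        out["effective_tests"] = {
            "veff_nyholt": res.veff_nyholt,
            "veff_rounded": res.veff_rounded,
            "meff_liji": res.meff_liji,
            "loss_fraction": res.loss_fraction,
        }
    return out


def _load_template(n_points: int) -> ShapeTemplate:
    template, _ = make_base_template(n_points)
    return template


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the summary dict it also writes.

    Artifacts in ``config.output_dir``: ``aligned.csv`` (Procrustes
    coordinates), ``model.txt`` (when a model is built), ``scores.csv``,
    ``ledger.txt`` and ``summary.json``.  On any stage failure the
    partially written artifacts are removed and the error re-raised with
    the stage name.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    stage = "setup"
    try:
        stage = "ingest"
        template = _load_template(config.template_points)
        configs = landmark_io.read_points_csv(config.points_path, template)
        log.info("ingest: %d images of %d points", len(configs),
                 template.n_points_markup)

        stage = "exclusions"
        ledger = landmark_io.ledger_apply(
            len(configs),
            [("Template point exclusions applied per image", 0)],
        )
        reduced = [landmark_io.apply_template_exclusions(c, template)
                   for c in configs]
        log.info("exclusions: %d points -> %d per image",
                 template.n_points_markup, template.n_points_model)

        stage = "mirror"
        if config.mirror == "all":
            reduced = [procrustes.mirror_x(c) for c in reduced]

        stage = "align"
        mean, aligned = procrustes.gpa(
            reduced, tol=config.gpa_tol, max_iter=config.gpa_max_iter)
        log.info("align: GPA converged=%s in %d iterations",
                 mean.converged, mean.gpa_iterations)
        aligned_configs = [
            LandmarkConfiguration(a.image_id, a.points, template.template_id)
            for a in aligned
        ]
        aligned_path = outdir / "aligned.csv"
        landmark_io.write_points_csv(aligned_configs, aligned_path)
        created.append(aligned_path)

        summary: dict = {
            "mode": "reference-projection" if config.reference_model_path
                    else "own-reference",
            "n_images": len(configs),
            "gpa": {"iterations": mean.gpa_iterations,
                    "converged": mean.converged},
            "ledger": {
                "initial": ledger.initial_count,
                "stages": [
                    {"name": n, "removed": r}
                    for n, r in zip(ledger.stage_names,
                                    ledger.counts_removed)
                ],
                "final": ledger.final_count,
            },
        }

        if config.reference_model_path:
            stage = "project"
            model = landmark_io.read_model_file(config.reference_model_path)
            scores = [shape_model.project(model, c) for c in reduced]
        else:
            stage = "build"
            model = shape_model.build_ssm(
                aligned, template_id=template.template_id)
            n_keep = min(config.n_modes_retained, model.n_modes)
            summary["variance_explained_retained"] = \
                shape_model.variance_explained(model, n_keep)
            summary["total_variance_fraction"] = float(
                model.variance_fraction.sum())
            model = shape_model.truncate(model, n_keep)
            model_path = outdir / "model.txt"
            landmark_io.write_model_file(model, model_path)
            created.append(model_path)
            scores = shape_model.score_training(model, aligned)

        stage = "report"
        df = scores_frame(scores)
        scores_path = outdir / "scores.csv"
        df.to_csv(scores_path, float_format="%.17g")
        created.append(scores_path)
        summary["scores"] = summarize_scores(df)
        assert summary["scores"]["n_images"] == ledger.final_count

        ledger_path = outdir / "ledger.txt"
        ledger_path.write_text(ledger.report() + "\n")
        created.append(ledger_path)
        summary_path = outdir / "summary.json"
        summary_path.write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
        created.append(summary_path)
        return summary
    except Exception as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") \
            from exc
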