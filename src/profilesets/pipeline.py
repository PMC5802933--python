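"""End-to-end batch workflow: read, merge, score, segment, summarize, write.

This is the library behind the command-line interface.  A
:class:`RunConfig` captures every input-panel control of the analysis
(feature files + labels + directions, the three sample roles, change-point
settings, display cutoff) and :func:`run` executes the workflow and writes
all result artifacts as CSV/JSON/text into the output directory.  Runs
are deterministic given the inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import decomposition as decomp
from . import diagnostics
from .changepoint import ChangePointSettings, Segmentation, detect_changepoints
from .gene_sets import assign_groups, results_table
from .io import (
    AnalysisInput,
    InputValidationError,
    OmicsFeatureMatrix,
    ProfileSpec,
    SampleRoles,
    merge_features,
    read_feature_table,
)
from .scoring import GROUP, STATISTIC, profile_statistics

logger = logging.getLogger("profilesets")


class StageError(RuntimeError):
    """A pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class FeatureInput:
    """One feature file with its data-type label and profile direction."""

    path: str
    label: str
    direction: str


@dataclass(frozen=True)
class RunConfig:
    """Batch equivalent of the tool's seven input-panel controls."""

    features: tuple[FeatureInput, ...]
    reference: str
    comparison1: str
    comparison2: str
    cpt_type: str = "both"
    cpt_method: str = "BinSeg"
    penalty: float | None = None
    max_cpts: int = 20
    up_to: int = 1
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not 1 <= len(self.features) <= 3:
            raise InputValidationError(
                f"expected 1-3 --features entries, got {len(self.features)}"
            )
        if self.up_to < 1:
            raise InputValidationError(
                f"up_to must be >= 1, got {self.up_to}"
            )

    def changepoint_settings(self) -> ChangePointSettings:
        return ChangePointSettings(
            change_type=self.cpt_type,
            method=self.cpt_method,
            penalty=self.penalty,
            max_cpts=self.max_cpts,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "features": [
                f"{f.path}:{f.label}:{f.direction}" for f in self.features
            ],
            "reference": self.reference,
            "comparison1": self.comparison1,
            "comparison2": self.comparison2,
            "cpt_type": self.cpt_type,
            "cpt_method": self.cpt_method,
            "penalty": self.penalty,
            "max_cpts": self.max_cpts,
            "up_to": self.up_to,
            "out_dir": str(self.out_dir),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            features=tuple(
                parse_feature_arg(entry) for entry in doc["features"]
            ),
            reference=doc["reference"],
            comparison1=doc["comparison1"],
            comparison2=doc["comparison2"],
            cpt_type=doc.get("cpt_type", "both"),
            cpt_method=doc.get("cpt_method", "BinSeg"),
            penalty=doc.get("penalty"),
            max_cpts=doc.get("max_cpts", 20),
            up_to=doc.get("up_to", 1),
            out_dir=doc.get("out_dir", "results"),
        )


def parse_feature_arg(entry: str) -> FeatureInput:
    """Parse a PATH:LABEL:DIRECTION feature argument."""
    parts = entry.rsplit(":", 2)
    if len(parts) != 3:
        raise InputValidationError(
            f"feature argument must be PATH:LABEL:DIRECTION, got {entry!r}"
        )
    return FeatureInput(path=parts[0], label=parts[1], direction=parts[2])


@dataclass
class RunResult:
    """In-memory results of one pipeline run."""

    analysis_input: AnalysisInput
    scores: pd.DataFrame  # ascending, with group column
    segmentation: Segmentation
    table: pd.DataFrame  # descending, filtered to up_to
    slope_summary: pd.DataFrame
    distribution_summary: pd.DataFrame
    decomposition: pd.DataFrame
    effective_up_to: int
    out_dir: Path


def _stage(stage: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (InputValidationError, ValueError) as exc:
            raise StageError(stage, str(exc)) from exc

    return wrap


def run(config: RunConfig) -> RunResult:
    """Execute the full workflow and write artifacts to config.out_dir."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrices: list[OmicsFeatureMatrix] = []
    for feat in config.features:
        matrices.append(
            _stage("input")(read_feature_table, feat.path, feat.label)
        )
    roles = _stage("input")(
        SampleRoles, config.reference, config.comparison1, config.comparison2
    )
    profile = _stage("input")(
        ProfileSpec, tuple(f.direction for f in config.features)
    )
    analysis_input = _stage("merge")(merge_features, matrices, roles, profile)

    scores = _stage("scoring")(profile_statistics, analysis_input)
    settings = _stage("changepoint")(config.changepoint_settings)
    seg = _stage("changepoint")(
        detect_changepoints, scores[STATISTIC].to_numpy(), settings
    )
    groups = _stage("gene-sets")(assign_groups, scores, seg)
    # the display cutoff cannot exceed the number of detected groups
    up_to = min(config.up_to, seg.n_segments)
    table = _stage("gene-sets")(results_table, scores, groups, up_to)

    slopes = _stage("diagnostics")(diagnostics.slope_table, analysis_input, groups)
    slope_summary = _stage("diagnostics")(diagnostics.group_slopes, slopes)
    dist_summary = _stage("diagnostics")(
        diagnostics.group_distribution_summary, analysis_input, groups, up_to
    )
    decomposition = _stage("decomposition")(
        decomp.decomposition_table, analysis_input, scores, list(table.index)
    )

    _write_artifacts(
        config, analysis_input, scores, groups, seg, table,
        slope_summary, dist_summary, decomposition, up_to, out_dir,
    )
    scores_with_groups = scores.copy()
    scores_with_groups[GROUP] = groups
    return RunResult(
        analysis_input=analysis_input,
        scores=scores_with_groups,
        segmentation=seg,
        table=table,
        slope_summary=slope_summary,
        distribution_summary=dist_summary,
        decomposition=decomposition,
        effective_up_to=up_to,
        out_dir=out_dir,
    )


def _write_artifacts(
    config, analysis_input, scores, groups, seg, table,
    slope_summary, dist_summary, decomposition, up_to, out_dir,
) -> None:
    roles = analysis_input.roles
    lines = ["# Input summary"]
    for feat, cfg in zip(analysis_input.features, config.features):
        lines += [
            f"feature: {feat.feature_label}",
            f"  file: {cfg.path}",
            f"  genes (rows) after merge: {len(feat.data)}",
            f"  samples (columns): {len(feat.sample_ids)}",
            f"  zero-variance rows dropped: {feat.n_dropped_zero_variance}",
        ]
    lines += [
        f"merged genes: {analysis_input.n_genes}",
        f"reference sample: {roles.reference}",
        f"comparison samples: {roles.comparison1}, {roles.comparison2}",
        f"profile: "
        + ", ".join(
            f"{lbl}={d}"
            for lbl, d in zip(
                analysis_input.feature_labels,
                analysis_input.profile.directions,
            )
        ),
    ]
    (out_dir / "input_summary.txt").write_text("\n".join(lines) + "\n")

    table.rename_axis(index="row_id").to_csv(out_dir / "results_table.csv")

    group_sizes = groups.value_counts().sort_index()
    seg_doc = {
        "method": config.cpt_method,
        "change_type": config.cpt_type,
        "penalty": config.changepoint_settings().resolve_penalty(
            seg.series_length
        ),
        "series_length": seg.series_length,
        "cpt_indices": list(seg.cpt_indices),
        "n_groups": seg.n_segments,
        "group_sizes": {int(g): int(s) for g, s in group_sizes.items()},
        "total_cost": seg.total_cost,
        "display_up_to": up_to,
    }
    (out_dir / "segmentation.json").write_text(
        json.dumps(seg_doc, indent=2) + "\n"
    )

    slope_summary.to_csv(out_dir / "slope_summary.csv")
    dist_summary.to_csv(out_dir / "distribution_summary.csv", index=False)
    decomposition.to_csv(out_dir / "decomposition.csv", index=False)
    config.to_yaml(out_dir / "config.yaml")
    logger.info(
        "wrote results for %d gene(s) in groups <= %d to %s",
        len(table), up_to, out_dir,
    )
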