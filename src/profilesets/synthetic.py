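"""Seeded multi-omics fixtures with a planted profile-satisfying gene set.

Backgrounds are i.i.d. Normal(0, noise_sd) per feature; for the planted
genes the reference sample is shifted by +effect_size * noise_sd in "up"
features and -effect_size * noise_sd in "down" features, simultaneously
in every feature.  Comparison samples are exchangeable background draws
and features are generated independently (the analysis treats features
independently, so fixtures do too).  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MIN_GENES,
    InputValidationError,
    OmicsFeatureMatrix,
    ProfileSpec,
    SampleRoles,
)

#: sample names used in generated fixtures (first = reference)
SAMPLE_NAMES = ("S1", "S2", "S3")
DEFAULT_FEATURE_LABELS = ("expression", "variant", "methylation")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-signal fixture.

    effect_size is the reference-sample shift for planted genes in units
    of noise_sd; 0 makes planted genes indistinguishable from background.
    """

    n_genes: int = 200
    n_planted: int = 10
    n_features: int = 2
    directions: tuple[str, ...] = ("up", "up")
    effect_size: float = 6.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < MIN_GENES:
            raise InputValidationError(
                f"n_genes must be >= {MIN_GENES}, got {self.n_genes}"
            )
        if not 1 <= self.n_planted < self.n_genes:
            raise InputValidationError(
                f"n_planted must be in 1..{self.n_genes - 1}, "
                f"got {self.n_planted}"
            )
        if not 1 <= self.n_features <= 3:
            raise InputValidationError(
                f"n_features must be 1-3, got {self.n_features}"
            )
        if len(self.directions) != self.n_features:
            raise InputValidationError(
                f"{self.n_features} feature(s) but "
                f"{len(self.directions)} direction(s)"
            )
        ProfileSpec(tuple(self.directions))  # validates entries
        if self.effect_size < 0:
            raise InputValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise InputValidationError("noise_sd must be > 0")

    @property
    def profile(self) -> ProfileSpec:
        return ProfileSpec(tuple(self.directions))


def generate(
    spec: SyntheticSpec,
) -> tuple[list[OmicsFeatureMatrix], SampleRoles, list[str]]:
    """Generate feature matrices, sample roles and the planted row IDs."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]
    planted_idx = np.sort(
        rng.choice(spec.n_genes, size=spec.n_planted, replace=False)
    )
    planted = [gene_ids[i] for i in planted_idx]
    features = []
    for f in range(spec.n_features):
        values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, 3))
        shift = spec.effect_size * spec.noise_sd
        if spec.directions[f] == "down":
            shift = -shift
        values[planted_idx, 0] += shift  # column 0 = reference sample
        df = pd.DataFrame(
            values,
            index=pd.Index(gene_ids, name="gene"),
            columns=list(SAMPLE_NAMES),
        )
        features.append(
            OmicsFeatureMatrix.from_dataframe(df, DEFAULT_FEATURE_LABELS[f])
        )
    roles = SampleRoles(*SAMPLE_NAMES)
    return features, roles, planted


def write_fixture(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[list[Path], Path]:
    """Write the fixture as tab-delimited files plus a JSON metadata sidecar.

    Returns the per-feature file paths and the metadata path.  The files
    round-trip through :func:`profilesets.io.read_feature_table`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features, roles, planted = generate(spec)
    paths = []
    for feat in features:
        p = out_dir / f"{feat.feature_label}.tsv"
        feat.to_tsv(p, id_column="gene")
        paths.append(p)
    meta = {
        "spec": asdict(spec),
        "sample_roles": {
            "reference": roles.reference,
            "comparison1": roles.comparison1,
            "comparison2": roles.comparison2,
        },
        "planted_row_ids": planted,
        "files": [str(p.name) for p in paths],
    }
    meta_path = out_dir / "fixture_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return paths, meta_path
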