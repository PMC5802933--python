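"""Reading, validation and merging of tab-delimited omics feature matrices.

Each input file is one molecular data type ("feature"): rows are gene /
probe / variant identifiers (first column), columns are samples.  Values
are assumed to be pre-processed and normalized upstream; this module only
validates structure and merges 1-3 matrices on their shared row identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("profilesets")

MIN_GENES = 10
MIN_SAMPLES = 3

#: tokens treated as missing values; missing values are a hard error
NA_TOKENS = frozenset({"", "NA", "N/A", "NAN", "NULL", "NONE", "."})

DIRECTIONS = ("up", "down")


class InputValidationError(ValueError):
    """Raised when an input matrix or configuration violates the contract."""


@dataclass(frozen=True)
class OmicsFeatureMatrix:
    """One validated data type: row IDs x sample values.

    ``data`` is a float DataFrame whose index holds unique row identifiers
    and whose columns hold unique sample identifiers.  Rows with zero
    variance across all samples have already been removed;
    ``n_dropped_zero_variance`` records how many.
    """

    feature_label: str
    data: pd.DataFrame
    n_dropped_zero_variance: int = 0

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def value_range(self) -> float:
        """Global max - min over the whole matrix (used by slope scaling)."""
        v = self.data.to_numpy()
        return float(v.max() - v.min())

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_label: str
    ) -> "OmicsFeatureMatrix":
        """Validate a numeric DataFrame (index = row IDs) and build a matrix."""
        return _validate(df, feature_label)

    def to_tsv(self, path: str | Path, id_column: str = "ID") -> None:
        out = self.data.copy()
        out.index.name = id_column
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class SampleRoles:
    """The three sample roles: one reference and two comparison samples."""

    reference: str
    comparison1: str
    comparison2: str

    def __post_init__(self) -> None:
        names = (self.reference, self.comparison1, self.comparison2)
        if len(set(names)) != 3:
            raise InputValidationError(
                f"reference/comparison1/comparison2 must be three distinct "
                f"samples, got {names}"
            )

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.reference, self.comparison1, self.comparison2)


@dataclass(frozen=True)
class ProfileSpec:
    """Desired direction of change ('up' or 'down') per feature."""

    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.directions) <= 3:
            raise InputValidationError(
                f"a profile needs 1-3 directions, got {len(self.directions)}"
            )
        for d in self.directions:
            if d not in DIRECTIONS:
                raise InputValidationError(
                    f"profile direction must be 'up' or 'down', got {d!r}"
                )


@dataclass(frozen=True)
class AnalysisInput:
    """1-3 feature matrices restricted to a shared, identically ordered row set."""

    features: tuple[OmicsFeatureMatrix, ...]
    roles: SampleRoles
    profile: ProfileSpec

    @property
    def row_ids(self) -> list[str]:
        return self.features[0].row_ids

    @property
    def n_genes(self) -> int:
        return len(self.features[0].data)

    @property
    def feature_labels(self) -> list[str]:
        return [f.feature_label for f in self.features]


def _validate(df: pd.DataFrame, feature_label: str) -> OmicsFeatureMatrix:
    """Shared validation: uniqueness, zero-variance filter, minimum sizes."""
    dup_rows = df.index[df.index.duplicated()]
    if len(dup_rows):
        raise InputValidationError(
            f"feature {feature_label!r}: duplicated row ID {dup_rows[0]!r} "
            f"(no duplicated rows are allowed)"
        )
    dup_cols = df.columns[df.columns.duplicated()]
    if len(dup_cols):
        raise InputValidationError(
            f"feature {feature_label!r}: duplicated sample column "
            f"{dup_cols[0]!r} (no duplicated columns are allowed)"
        )
    if df.shape[1] < MIN_SAMPLES:
        raise InputValidationError(
            f"feature {feature_label!r}: {df.shape[1]} sample columns; the "
            f"analysis requires a minimum of at least {MIN_GENES} genes and "
            f"{_words(MIN_SAMPLES)} samples"
        )
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise InputValidationError(
            f"feature {feature_label!r}: non-finite value at row "
            f"{df.index[bad[0]]!r}, column {df.columns[bad[1]]!r}"
        )
    constant = values.max(axis=1) == values.min(axis=1)
    n_dropped = int(constant.sum())
    if n_dropped:
        logger.info(
            "feature %r: excluded %d row(s) with zero variance across all samples",
            feature_label,
            n_dropped,
        )
        df = df.loc[~constant]
    if len(df) < MIN_GENES:
        raise InputValidationError(
            f"feature {feature_label!r}: {len(df)} rows after filtering; the "
            f"analysis requires a minimum of at least {MIN_GENES} genes and "
            f"{_words(MIN_SAMPLES)} samples"
        )
    return OmicsFeatureMatrix(
        feature_label=feature_label,
        data=df.astype(float),
        n_dropped_zero_variance=n_dropped,
    )


def _words(n: int) -> str:
    return {3: "three"}.get(n, str(n))


def _parse_cell(token: str, row_id: str, column: str, label: str) -> float:
    token = token.strip()
    if token.upper() in NA_TOKENS:
        raise InputValidationError(
            f"feature {label!r}: missing value at row {row_id!r}, "
            f"column {column!r} (missing values are not supported)"
        )
    try:
        return float(token)
    except ValueError:
        raise InputValidationError(
            f"feature {label!r}: non-numeric value {token!r} at row "
            f"{row_id!r}, column {column!r}"
        ) from None


def read_feature_table(path: str | Path, feature_label: str) -> OmicsFeatureMatrix:
    """Read one tab-delimited matrix (header row mandatory, first column = ID).

    Zero-variance rows are removed and the drop count recorded on the
    returned matrix.  Row and sample order are preserved from the file.

    Raises
    ------
    InputValidationError
        On duplicated row IDs or sample columns, non-numeric or missing
        cells (with coordinates), fewer than 10 surviving rows, or fewer
        than 3 samples.
    """
    path = Path(path)
    if not path.exists():
        raise InputValidationError(f"input file not found: {path}")
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        header_line = fh.readline().rstrip("\r\n")
        if not header_line:
            raise InputValidationError(f"{path}: empty file or missing header")
        header = [h.strip() for h in header_line.split("\t")]
        samples = header[1:]
        seen: set[str] = set()
        for s in samples:
            if s in seen:
                raise InputValidationError(
                    f"feature {feature_label!r}: duplicated sample column "
                    f"{s!r} (no duplicated columns are allowed)"
                )
            seen.add(s)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise InputValidationError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"found {len(cells)}"
                )
            rid = cells[0].strip()
            row_ids.append(rid)
            rows.append(
                [
                    _parse_cell(tok, rid, samples[j], feature_label)
                    for j, tok in enumerate(cells[1:])
                ]
            )
    df = pd.DataFrame(rows, index=pd.Index(row_ids, name=header[0]), columns=samples)
    matrix = _validate(df, feature_label)
    logger.info(
        "feature %r: read %d rows x %d samples from %s (%d zero-variance row(s) dropped)",
        feature_label,
        len(matrix.data),
        len(matrix.sample_ids),
        path,
        matrix.n_dropped_zero_variance,
    )
    return matrix


def merge_features(
    matrices: Sequence[OmicsFeatureMatrix],
    roles: SampleRoles,
    profile: ProfileSpec,
) -> AnalysisInput:
    """Inner-join 1-3 feature matrices on their row IDs.

    The merged row set is the intersection of all row-ID sets, ordered by
    the first matrix's row order; every matrix is subset to that set.  Row
    counts of the inputs may differ (inner-join semantics).
    """
    if not 1 <= len(matrices) <= 3:
        raise InputValidationError(
            f"expected 1-3 feature matrices, got {len(matrices)}"
        )
    if len(profile.directions) != len(matrices):
        raise InputValidationError(
            f"profile has {len(profile.directions)} directions but "
            f"{len(matrices)} feature matrices were supplied"
        )
    labels = [m.feature_label for m in matrices]
    if len(set(labels)) != len(labels):
        raise InputValidationError(
            f"feature labels must be unique, got {labels}"
        )
    for m in matrices:
        for sample in roles.as_tuple():
            if sample not in m.data.columns:
                raise InputValidationError(
                    f"sample {sample!r} not found in feature "
                    f"{m.feature_label!r}"
                )
    common = matrices[0].data.index
    for m in matrices[1:]:
        common = common[common.isin(m.data.index)]
    if len(common) == 0:
        raise InputValidationError(
            "no common row IDs across the input matrices (empty intersection)"
        )
    if len(common) < MIN_GENES:
        raise InputValidationError(
            f"only {len(common)} common row IDs across the input matrices; "
            f"the analysis requires a minimum of at least {MIN_GENES} genes"
        )
    merged = tuple(
        OmicsFeatureMatrix(
            feature_label=m.feature_label,
            data=m.data.loc[common],
            n_dropped_zero_variance=m.n_dropped_zero_variance,
        )
        for m in matrices
    )
    logger.info("merged %d feature(s) on %d common row IDs", len(merged), len(common))
    return AnalysisInput(features=merged, roles=roles, profile=profile)
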