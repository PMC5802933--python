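"""Per-gene directional scores and the combined profile statistic.

For each feature, a gene's raw support for the requested direction is the
mean difference between the reference sample and the two comparison
samples (negated for a "down" profile).  Raw differences are then
standardized to rank proportions -- rank(d) / G with average ties -- so
features measured on different platforms and scales contribute
comparably.  The profile statistic is the sum of the per-feature rank
proportions; it lies in (0, F] for F features and genes are sorted
ascending by it.

This statistic is a deliberate canonicalization chosen so that (a) the
series is ascending-sortable for change-point segmentation, (b) scores
are nonnegative so between-feature percent contributions are
well-defined, and (c) the ranking is invariant to monotone rescaling of
any single feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import AnalysisInput, OmicsFeatureMatrix, SampleRoles

#: results-table column holding the combined statistic
STATISTIC = "profile_statistic"
RANK = "rank"
GROUP = "change_point_group"


def directional_difference(
    x_ref: float, x_c1: float, x_c2: float, direction: str
) -> float:
    """Mean reference-minus-comparison difference, signed by direction.

    Larger values always mean more support for the requested direction:
    ``mean(x_ref - x_c1, x_ref - x_c2)`` for "up", its negation for "down".
    """
    d = ((x_ref - x_c1) + (x_ref - x_c2)) / 2.0
    return d if direction == "up" else -d


def feature_differences(
    feature: OmicsFeatureMatrix, roles: SampleRoles, direction: str
) -> pd.Series:
    """Vectorized directional differences for every gene in one feature."""
    ref = feature.data[roles.reference].to_numpy()
    c1 = feature.data[roles.comparison1].to_numpy()
    c2 = feature.data[roles.comparison2].to_numpy()
    d = ((ref - c1) + (ref - c2)) / 2.0
    if direction == "down":
        d = -d
    return pd.Series(d, index=feature.data.index, name=feature.feature_label)


def per_feature_scores(
    feature: OmicsFeatureMatrix, roles: SampleRoles, direction: str
) -> pd.Series:
    """Rank-proportion scores in (0, 1]: rank(d)/G with average ties."""
    d = feature_differences(feature, roles, direction)
    scores = rankdata(d.to_numpy(), method="average") / len(d)
    return pd.Series(scores, index=d.index, name=feature.feature_label)


def profile_statistics(analysis_input: AnalysisInput) -> pd.DataFrame:
    """Score every gene and sort ascending by the combined profile statistic.

    Returns a DataFrame indexed by row ID with one score column per
    feature (named by its label), a ``profile_statistic`` column equal to
    the row sum of the scores, and a 1-based ``rank`` column (1 = smallest
    statistic).  Ties in the statistic are broken by lexicographic row ID
    so results tables are bit-reproducible.
    """
    cols = {
        f.feature_label: per_feature_scores(f, analysis_input.roles, direction)
        for f, direction in zip(
            analysis_input.features, analysis_input.profile.directions
        )
    }
    table = pd.DataFrame(cols)
    table[STATISTIC] = table.sum(axis=1)
    # stable two-key sort: lexicographic row ID first, then statistic,
    # so equal statistics come out in ID order
    table = table.sort_index(kind="mergesort").sort_values(
        STATISTIC, kind="mergesort"
    )
    table[RANK] = np.arange(1, len(table) + 1)
    return table
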