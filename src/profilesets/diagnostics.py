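"""Slope and distribution diagnostics behind the change-point choice.

The slope of a gene within one feature is the mean comparison-minus-
reference difference normalized by the feature's global value range:

    slope = ((c1 - ref) + (c2 - ref)) / (2 * range)

Genes satisfying an "up" profile (reference above both comparisons) get
negative ("small") slopes; genes satisfying a "down" profile get positive
("large") slopes.  Range normalization makes slopes comparable across
features on different scales.  Averaging slopes within each change-point
group gives the per-group summary used to judge how many groups genuinely
support the profile.  The distribution summaries are plain five-number
summaries (linear-interpolation quartiles) of the raw input values per
feature and sample role, restricted to the top groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AnalysisInput
from .scoring import GROUP


def gene_slope(
    x_ref: float, x_c1: float, x_c2: float, feature_range: float
) -> float:
    """Range-normalized mean comparison-minus-reference difference."""
    if feature_range <= 0:
        raise ValueError(
            f"feature_range must be positive, got {feature_range}"
        )
    return ((x_c1 - x_ref) + (x_c2 - x_ref)) / (2.0 * feature_range)


def slope_table(
    analysis_input: AnalysisInput, assignments: pd.Series
) -> pd.DataFrame:
    """Per-gene slopes, one column per feature, plus the group label."""
    roles = analysis_input.roles
    cols = {}
    for feat in analysis_input.features:
        rng = feat.value_range
        if rng <= 0:
            raise ValueError(
                f"feature {feat.feature_label!r} has zero value range"
            )
        ref = feat.data[roles.reference]
        c1 = feat.data[roles.comparison1]
        c2 = feat.data[roles.comparison2]
        cols[feat.feature_label] = ((c1 - ref) + (c2 - ref)) / (2.0 * rng)
    table = pd.DataFrame(cols)
    table[GROUP] = assignments
    return table.loc[assignments.index]


def group_slopes(slopes: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean slope per change-point group and feature."""
    return (
        slopes.groupby(GROUP).mean().sort_index().rename_axis(index=GROUP)
    )


def group_distribution_summary(
    analysis_input: AnalysisInput, assignments: pd.Series, up_to: int
) -> pd.DataFrame:
    """Five-number summaries per feature x sample role for the top groups.

    Returns a DataFrame with columns feature_label, sample_role, min, q1,
    median, q3, max computed over the raw input values of genes in groups
    1..up_to.  Quartiles use linear interpolation.
    """
    n_groups = int(assignments.max())
    if not 1 <= up_to <= n_groups:
        raise ValueError(
            f"up_to must be in 1..{n_groups}, got {up_to}"
        )
    keep = assignments.index[assignments <= up_to]
    roles = analysis_input.roles
    role_names = ("reference", "comparison1", "comparison2")
    rows = []
    for feat in analysis_input.features:
        sub = feat.data.loc[keep]
        for role_name, sample in zip(role_names, roles.as_tuple()):
            v = sub[sample].to_numpy()
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "feature_label": feat.feature_label,
                    "sample_role": role_name,
                    "sample_id": sample,
                    "min": float(v.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(v.max()),
                }
            )
    return pd.DataFrame(rows)
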