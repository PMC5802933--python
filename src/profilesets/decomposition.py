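"""Percent-contribution breakdowns for selected genes.

Two decompositions explain WHY a gene was selected:

* between-sample: within one feature, each of the three samples'
  percentage of the summed total across samples.  A variant present only
  in the reference sample decomposes as (100, 0, 0).  Because negative
  values (log-ratios, copy-number log2) break the "percent of summed
  total" notion, all three values are first shifted by -min(0, min(values))
  so contributions are nonnegative; if the shifted values sum to zero the
  triple is undefined rather than an error.
* between-feature: each feature's rank-proportion score as a percentage
  of the gene's combined profile statistic, showing which data type
  drives the gene's selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AnalysisInput


SAMPLE_ROLE_NAMES = ("reference", "comparison1", "comparison2")


def between_sample_contributions(
    x_ref: float, x_c1: float, x_c2: float
) -> np.ndarray | None:
    """Percent of the summed total contributed by each sample (one feature).

    Values are min-shifted to be nonnegative first.  Returns a length-3
    array summing to 100, or None when the shifted values sum to zero
    (the decomposition is undefined, e.g. three equal negative values).
    """
    x = np.array([x_ref, x_c1, x_c2], dtype=float)
    x = x - min(0.0, float(x.min()))
    total = float(x.sum())
    if total == 0.0:
        return None
    return 100.0 * x / total


def between_feature_contributions(scores: np.ndarray) -> np.ndarray:
    """Each feature's percentage of the combined profile statistic."""
    scores = np.asarray(scores, dtype=float)
    total = float(scores.sum())
    if total <= 0.0:
        # cannot occur for rank-proportion scores (minimum 1/G per feature)
        raise ValueError(
            "profile statistic must be positive to decompose by feature"
        )
    return 100.0 * scores / total


def decomposition_table(
    analysis_input: AnalysisInput,
    results: pd.DataFrame,
    row_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format percent contributions for the given genes.

    One row per (gene, feature, component): components are the three
    sample roles (between-sample percentages within that feature) plus
    "feature" (that feature's percentage of the profile statistic).
    Undefined between-sample triples are emitted as NaN with
    ``undefined=True``.
    """
    if row_ids is None:
        row_ids = list(results.index)
    labels = analysis_input.feature_labels
    roles = analysis_input.roles.as_tuple()
    rows = []
    for rid in row_ids:
        feature_pcts = between_feature_contributions(
            results.loc[rid, labels].to_numpy()
        )
        for feat, fpct in zip(analysis_input.features, feature_pcts):
            vals = feat.data.loc[rid, list(roles)].to_numpy(dtype=float)
            pcts = between_sample_contributions(*vals)
            undefined = pcts is None
            if undefined:
                pcts = np.full(3, np.nan)
            for role_name, pct in zip(SAMPLE_ROLE_NAMES, pcts):
                rows.append(
                    {
                        "row_id": rid,
                        "feature_label": feat.feature_label,
                        "component": role_name,
                        "pct": float(pct),
                        "undefined": undefined,
                    }
                )
            rows.append(
                {
                    "row_id": rid,
                    "feature_label": feat.feature_label,
                    "component": "feature",
                    "pct": float(fpct),
                    "undefined": False,
                }
            )
    return pd.DataFrame(
        rows, columns=["row_id", "feature_label", "component", "pct", "undefined"]
    )
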