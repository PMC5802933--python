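"""Numbered gene sets from a segmentation of the ranked statistic series.

Change points are detected on the ascending-sorted profile statistics;
group numbering then counts from the TOP of the sorted series: group 1 is
the segment with the largest statistics (most support for the profile),
group 2 the next one down, and so on.  With zero change points every gene
is group 1.  A change-point index marks the last position of its segment,
so the boundary gene belongs to the lower group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .changepoint import Segmentation
from .scoring import GROUP


def assign_groups(results: pd.DataFrame, seg: Segmentation) -> pd.Series:
    """Map each gene of an ascending-sorted results table to its group.

    Parameters
    ----------
    results : DataFrame sorted ascending by ``profile_statistic``
        (as returned by :func:`profilesets.scoring.profile_statistics`).
    seg : Segmentation of the same series.

    Returns
    -------
    pandas.Series of positive integers indexed like ``results``;
    group labels are contiguous 1..S with 1 = top segment.
    """
    n = len(results)
    if seg.series_length != n:
        raise ValueError(
            f"segmentation covers {seg.series_length} positions but the "
            f"results table has {n} genes"
        )
    n_seg = seg.n_segments
    groups = np.empty(n, dtype=int)
    for j, (start, end) in enumerate(seg.segment_bounds(), start=1):
        # bottom segment j=1 -> highest group number; top segment -> group 1
        groups[start - 1 : end] = n_seg - j + 1
    return pd.Series(groups, index=results.index, name=GROUP)


def results_table(
    results: pd.DataFrame, assignments: pd.Series, display_up_to: int
) -> pd.DataFrame:
    """Final table: descending by statistic, restricted to top groups.

    ``display_up_to`` keeps groups 1..display_up_to (the web-style "up to"
    cutoff); passing the total number of groups keeps every gene.
    """
    if display_up_to < 1:
        raise ValueError(f"display_up_to must be >= 1, got {display_up_to}")
    table = results.copy()
    table[GROUP] = assignments
    table = table[table[GROUP] <= display_up_to]
    # reverse the ascending order; ascending ties are already ID-sorted
    return table.iloc[::-1]
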