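"""Quantile normalization of probe intensities.

Arrays belonging to the same experimental group (by default the three
replicate wells of one treatment condition) are forced onto a common
intensity distribution: every sample's sorted value vector is replaced by
the mean sorted vector of its group, preserving within-sample rank order.
Tied values receive the mean of the reference values at their ranks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .containers import ProbeIntensityMatrix


def _normalize_group(x: np.ndarray) -> np.ndarray:
    """Quantile-normalize the columns of one group (probes x samples)."""
    n, m = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        normed = np.empty(n, dtype=float)
        normed[order] = ref
        # ties: average the reference values assigned across each run of
        # equal input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        if boundaries.size < n:
            means = np.add.reduceat(ref, boundaries) / np.diff(np.r_[boundaries, n])
            normed[order] = np.repeat(means, np.diff(np.r_[boundaries, n]))
        out[:, j] = normed
    return out


def quantile_normalize(
    matrix: ProbeIntensityMatrix,
    grouping: str | Sequence[Iterable[str]] = "condition",
) -> ProbeIntensityMatrix:
    """Quantile-normalize samples within experimental groups.

    Parameters
    ----------
    matrix
        Probe intensities with design.
    grouping
        ``"condition"`` (default) normalizes each treatment group's
        replicate arrays against one another; ``"global"`` normalizes all
        samples together; otherwise an explicit partition of sample ids.

    Returns
    -------
    ProbeIntensityMatrix
        New matrix; within each group every sample has an identical
        sorted value vector.

    Raises
    ------
    ValueError
        If any group contains fewer than two samples (there is nothing to
        normalize a single array against).
    """
    if grouping == "condition":
        groups: list[list[str]] = list(matrix.condition_groups().values())
    elif grouping == "global":
        groups = [list(matrix.sample_ids)]
    else:
        groups = [list(g) for g in grouping]
        flat = [s for g in groups for s in g]
        if sorted(flat) != sorted(matrix.sample_ids):
            raise ValueError("grouping must partition the sample ids exactly")

    values = matrix.values.copy()
    for group in groups:
        if len(group) < 2:
            raise ValueError(f"group {group} has fewer than 2 samples")
        values[group] = _normalize_group(matrix.values[group].to_numpy(dtype=float))
    return matrix.with_values(values)
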