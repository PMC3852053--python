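"""Probe-level differential expression versus vehicle.

Each probe is tested with an equal-variance two-sample two-tailed t test
on log2 intensities (three treated versus three vehicle wells), p values
are Benjamini-Hochberg adjusted across all probes of the contrast, and
fold change is reported on the linear scale in the signed convention:
+r for r-fold induction, -r for r-fold repression, so +-4 denotes
four-fold either way and a tie is +1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ProbeIntensityMatrix

PROBE_STAT_COLUMNS = (
    "probe_id",
    "transcript_id",
    "mean_treated",
    "mean_vehicle",
    "signed_fold",
    "t",
    "p",
    "p_bh",
    "degenerate",
)


def signed_fold_change(mean_treated: float, mean_vehicle: float) -> float:
    """Signed fold change of treated over vehicle means (linear scale).

    Returns ``+r`` where ``r = mean_treated / mean_vehicle`` if ``r >= 1``
    and ``-1/r`` otherwise, so the magnitude is always >= 1 and the sign
    is the regulation direction (ties count as +1).
    """
    if mean_treated <= 0 or mean_vehicle <= 0:
        raise ValueError("means must be strictly positive")
    r = mean_treated / mean_vehicle
    return r if r >= 1 else -1.0 / r


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def probe_level_stats(
    matrix: ProbeIntensityMatrix,
    annotation: pd.DataFrame,
    treated: str,
    control: str = "vehicle",
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-probe fold change and significance of ``treated`` vs ``control``.

    Parameters
    ----------
    matrix
        Normalized probe intensities.
    annotation
        DataFrame with columns ``probe_id`` and ``transcript_id``.
    treated, control
        Condition labels from the design; each needs >= 2 replicates.
    log_scale
        Run the t test on log2 intensities (default); fold changes are
        always computed from linear-scale means.

    Returns
    -------
    DataFrame with one row per probe: ``probe_id``, ``transcript_id``,
    group means, ``signed_fold``, ``t``, ``p``, ``p_bh`` (BH across all
    probes of this contrast) and a ``degenerate`` flag for zero
    pooled-variance probes.
    """
    t_cols = matrix.samples_for(treated)
    c_cols = matrix.samples_for(control)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("each condition needs at least 2 replicates")

    lin_t = matrix.values[t_cols].to_numpy(dtype=float)
    lin_c = matrix.values[c_cols].to_numpy(dtype=float)
    a = np.log2(lin_t) if log_scale else lin_t
    b = np.log2(lin_c) if log_scale else lin_c

    with warnings.catch_warnings():
        # near-constant probes trip scipy's catastrophic-cancellation
        # warning; the degenerate branch below handles them explicitly
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    t_stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    # zero pooled variance: equal means -> no evidence (p = 1),
    # unequal means -> flagged degenerate certainty (p = 0)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same = zero_var & np.isclose(mean_a, mean_b)
    diff = zero_var & ~np.isclose(mean_a, mean_b)
    t_stat[same], p[same] = 0.0, 1.0
    t_stat[diff] = np.where(mean_a[diff] > mean_b[diff], np.inf, -np.inf)
    p[diff] = 0.0
    degenerate = diff  # equal-constant probes are unremarkable, not flagged

    mean_treated = lin_t.mean(axis=1)
    mean_vehicle = lin_c.mean(axis=1)
    folds = np.array(
        [signed_fold_change(mt, mv) for mt, mv in zip(mean_treated, mean_vehicle)]
    )

    annot = annotation.set_index("probe_id")["transcript_id"]
    out = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "transcript_id": matrix.probe_ids.map(annot),
            "mean_treated": mean_treated,
            "mean_vehicle": mean_vehicle,
            "signed_fold": folds,
            "t": t_stat,
            "p": p,
            "p_bh": adjust_bh(p),
            "degenerate": degenerate,
        }
    )
    if out["transcript_id"].isna().any():
        bad = out.loc[out["transcript_id"].isna(), "probe_id"].tolist()[:5]
        raise ValueError(f"probes without transcript annotation, e.g. {bad}")
    return out.reset_index(drop=True)
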