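"""Collapse probe-level signals to transcript-level regulation.

Illumina Sentrix-6 arrays interrogate most transcripts with one probe but
many with two or three. Transcript-level regulation is derived from the
significant probes of each transcript under three concordance rules:

i.   all significant probes agree in direction -> average their signed
     fold changes;
ii.  the probes disagree with no clear majority (including 1-vs-1)
     -> discard the transcript;
iii. exactly one probe of three or more disagrees -> take the mean of the
     majority probes.

Significance is decided per probe first (BH-adjusted p <= alpha); a
transcript none of whose probes is significant is reported as
``not_significant`` and carries no fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STATUS_CONCORDANT = "retained_concordant"
STATUS_MAJORITY = "retained_majority"
STATUS_DISCORDANT = "discarded_discordant"
STATUS_NOT_SIG = "not_significant"

RETAINED = (STATUS_CONCORDANT, STATUS_MAJORITY)


def is_retained(status: pd.Series | str) -> pd.Series | bool:
    if isinstance(status, str):
        return status in RETAINED
    return status.isin(RETAINED)


def _collapse_folds(folds: np.ndarray) -> tuple[float | None, str]:
    """Apply rules i-iii to the signed folds of one transcript's significant probes."""
    signs = np.where(folds >= 0, 1, -1)
    if len(folds) == 0:
        return None, STATUS_NOT_SIG
    if (signs == signs[0]).all():
        return float(folds.mean()), STATUS_CONCORDANT
    n_pos = int((signs > 0).sum())
    n_min = min(n_pos, len(folds) - n_pos)
    if n_min == 1 and len(folds) >= 3:
        majority_sign = 1 if n_pos > len(folds) - n_pos else -1
        return float(folds[signs == majority_sign].mean()), STATUS_MAJORITY
    return None, STATUS_DISCORDANT


def collapse_probes(probe_stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Collapse per-probe statistics into per-transcript regulation calls.

    Parameters
    ----------
    probe_stats
        Output of :func:`csfarray.differential.probe_level_stats`
        (columns ``probe_id``, ``transcript_id``, ``signed_fold``,
        ``p_bh`` are required).
    alpha
        BH-adjusted significance cutoff applied per probe, in (0, 1].

    Returns
    -------
    DataFrame with one row per transcript: ``transcript_id``,
    ``signed_fold`` (NaN unless retained), ``status``, ``n_probes``
    (total probes for that transcript) and ``contributing_probe_ids``
    (the probes averaged into the fold, empty tuple otherwise).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    required = {"probe_id", "transcript_id", "signed_fold", "p_bh"}
    if not required <= set(probe_stats.columns):
        raise ValueError(f"probe_stats lacks columns {sorted(required - set(probe_stats.columns))}")
    if probe_stats["probe_id"].duplicated().any():
        dupes = probe_stats.loc[probe_stats["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe ids, e.g. {dupes}")
    if probe_stats["transcript_id"].isna().any():
        raise ValueError("probe references unknown transcript (NaN transcript_id)")

    rows = []
    for transcript_id, grp in probe_stats.groupby("transcript_id", sort=True):
        grp = grp.sort_values("probe_id", kind="mergesort")  # row order must not matter
        sig = grp[grp["p_bh"] <= alpha]
        fold, status = _collapse_folds(sig["signed_fold"].to_numpy(dtype=float))
        if status in RETAINED:
            if status == STATUS_CONCORDANT:
                contributing = tuple(sig["probe_id"])
            else:
                signs = np.sign(sig["signed_fold"].to_numpy())
                signs[signs == 0] = 1
                majority = 1 if (signs > 0).sum() > (signs < 0).sum() else -1
                contributing = tuple(sig.loc[signs == majority, "probe_id"])
        else:
            contributing = ()
        rows.append(
            {
                "transcript_id": transcript_id,
                "signed_fold": np.nan if fold is None else fold,
                "status": status,
                "n_probes": len(grp),
                "contributing_probe_ids": contributing,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "signed_fold", "status", "n_probes", "contributing_probe_ids"],
    )
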