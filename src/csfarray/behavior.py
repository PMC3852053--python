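"""Statistics for nociceptive behavioral readouts.

Von Frey mechanical sensitivity is expressed as the percentage of paw
withdrawals over 5 filament stimulations (so values are multiples of
20%); Hargreaves thermal sensitivity is the paw-withdrawal latency in
seconds with a 15 s heat cutoff, treated as an observed value. Repeated
measurements across timepoints within the same animals are analyzed with
a one-way repeated-measures ANOVA followed by Fisher's LSD post-hoc
comparisons (unadjusted pairwise t tests on the ANOVA error mean square).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

HARGREAVES_CUTOFF_S = 15.0
N_STIMULATIONS = 5


def response_frequency(responses: Sequence[int]) -> float:
    """Percent withdrawal responses over the 5 von Frey stimulations."""
    if len(responses) != N_STIMULATIONS:
        raise ValueError(f"expected exactly {N_STIMULATIONS} trials")
    if any(r not in (0, 1) for r in responses):
        raise ValueError("trials must be coded 0 (no response) / 1 (withdrawal)")
    return 100.0 * sum(responses) / N_STIMULATIONS


@dataclass(frozen=True)
class RMAnovaResult:
    """One-way repeated-measures ANOVA summary (LSD reuses ms_error/df_error)."""

    F: float
    df_factor: int
    df_error: int
    p: float
    ms_error: float
    n_subjects: int
    level_means: pd.Series


def _balanced_wide(
    data: pd.DataFrame, value: str, within: str, subject: str
) -> pd.DataFrame:
    wide = data.pivot_table(index=subject, columns=within, values=value, aggfunc="mean")
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(f"unbalanced design; subjects missing levels: {incomplete}")
    counts = data.groupby([subject, within]).size()
    if (counts > 1).any():
        raise ValueError("duplicate measurements per (subject, level) cell")
    return wide


def rm_anova(
    data: pd.DataFrame,
    value: str = "value",
    within: str = "timepoint",
    subject: str = "animal_id",
) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with the subject effect removed.

    Requires a balanced complete design (every subject measured at every
    level of the within factor). In a two-level design the F statistic
    equals the squared paired t statistic. When all values are identical
    across levels F = 0 and p = 1.
    """
    wide = _balanced_wide(data, value, within, subject)
    x = wide.to_numpy(dtype=float)
    n, t = x.shape
    if n < 2 or t < 2:
        raise ValueError("need >= 2 subjects and >= 2 within-factor levels")
    grand = x.mean()
    ss_subject = t * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_factor = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = max(ss_total - ss_subject - ss_factor, 0.0)
    df_factor, df_error = t - 1, (n - 1) * (t - 1)
    ms_factor, ms_error = ss_factor / df_factor, ss_error / df_error
    if ms_error == 0.0:
        f = 0.0 if ms_factor == 0.0 else np.inf
        p = 1.0 if ms_factor == 0.0 else 0.0
    else:
        f = ms_factor / ms_error
        p = float(stats.f.sf(f, df_factor, df_error))
    return RMAnovaResult(
        F=float(f),
        df_factor=df_factor,
        df_error=df_error,
        p=p,
        ms_error=float(ms_error),
        n_subjects=n,
        level_means=wide.mean(axis=0),
    )


def fisher_lsd(
    data: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]] | None = None,
    value: str = "value",
    within: str = "timepoint",
    subject: str = "animal_id",
) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons between within-factor levels.

    Each pair is an unadjusted two-sided t test of the level means using
    the repeated-measures error mean square and its degrees of freedom
    (no multiplicity correction — LSD's defining property). With
    ``comparisons=None`` all level pairs are tested.
    """
    res = rm_anova(data, value=value, within=within, subject=subject)
    means = res.level_means
    if comparisons is None:
        levels = list(means.index)
        comparisons = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    rows = []
    for a, b in comparisons:
        for lvl in (a, b):
            if lvl not in means.index:
                raise KeyError(f"level {lvl!r} absent from factor {within!r}")
        diff = means[a] - means[b]
        se = np.sqrt(res.ms_error * 2.0 / res.n_subjects)
        if se == 0.0:
            t_stat = 0.0 if diff == 0 else np.sign(diff) * np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            t_stat = diff / se
            p = float(2.0 * stats.t.sf(abs(t_stat), res.df_error))
        rows.append({"level_a": a, "level_b": b, "mean_diff": float(diff), "t": float(t_stat), "p": p})
    return pd.DataFrame(rows, columns=["level_a", "level_b", "mean_diff", "t", "p"])


def fisher_lsd_between_groups(
    data: pd.DataFrame,
    timepoint: str,
    comparisons: Sequence[tuple[str, str]] | None = None,
    value: str = "value",
    within: str = "timepoint",
    group: str = "group",
) -> pd.DataFrame:
    """LSD contrasts between treatment groups at one timepoint.

    Between-animal comparisons (e.g. inhibitor versus vehicle at a given
    hour) use the pooled within-group error mean square of a one-way
    ANOVA across groups at that timepoint, again without multiplicity
    correction.
    """
    at_t = data[data[within] == timepoint]
    if at_t.empty:
        raise KeyError(f"timepoint {timepoint!r} absent")
    cells = {g: sub[value].to_numpy(dtype=float) for g, sub in at_t.groupby(group)}
    if len(cells) < 2:
        raise ValueError("need >= 2 groups")
    df_error = sum(len(v) - 1 for v in cells.values())
    ss_error = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    ms_error = ss_error / df_error
    if comparisons is None:
        names = sorted(cells)
        comparisons = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in comparisons:
        for g in (a, b):
            if g not in cells:
                raise KeyError(f"group {g!r} absent at timepoint {timepoint!r}")
        diff = cells[a].mean() - cells[b].mean()
        se = np.sqrt(ms_error * (1.0 / len(cells[a]) + 1.0 / len(cells[b])))
        if se == 0.0:
            t_stat = 0.0 if diff == 0 else np.sign(diff) * np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            t_stat = diff / se
            p = float(2.0 * stats.t.sf(abs(t_stat), df_error))
        rows.append({"group_a": a, "group_b": b, "mean_diff": float(diff), "t": float(t_stat), "p": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "t", "p"])
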