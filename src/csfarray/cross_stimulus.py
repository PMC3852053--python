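"""Cross-stimulus classification of regulated transcripts.

After probe collapse, each stimulus (GMCSF, GCSF) yields a list of
retained transcripts with signed fold changes. Transcripts are
partitioned by their joint behavior: commonly up, commonly down,
reciprocally regulated (opposite directions), or regulated by exactly one
stimulus. A stringency filter keeps only transcripts at or beyond a fold
threshold (|signed fold| >= 4 is the cutoff used ahead of network
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .aggregation import is_retained


@dataclass(frozen=True)
class RegulationClasses:
    """Disjoint partition of the transcripts retained in >=1 stimulus."""

    common_up: frozenset
    common_down: frozenset
    reciprocal: frozenset
    gm_only: frozenset
    gcsf_only: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in self.class_names()}

    @staticmethod
    def class_names() -> tuple[str, ...]:
        return ("common_up", "common_down", "reciprocal", "gm_only", "gcsf_only")

    def all_transcripts(self) -> frozenset:
        out: frozenset = frozenset()
        for name in self.class_names():
            out |= getattr(self, name)
        return out

    def membership_table(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "regulation_class": name}
            for name in self.class_names()
            for t in sorted(getattr(self, name))
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "regulation_class"])


def _retained_folds(stats: pd.DataFrame, label: str) -> pd.Series:
    if stats["transcript_id"].duplicated().any():
        dupes = stats.loc[stats["transcript_id"].duplicated(), "transcript_id"].tolist()[:5]
        raise ValueError(f"{label}: transcript appears more than once, e.g. {dupes}")
    kept = stats[is_retained(stats["status"])] if "status" in stats.columns else stats
    return kept.set_index("transcript_id")["signed_fold"]


def classify_regulation(
    gm: pd.DataFrame,
    gc: pd.DataFrame,
    min_fold: float | None = None,
) -> RegulationClasses:
    """Partition retained transcripts by their joint GMCSF/GCSF regulation.

    Parameters
    ----------
    gm, gc
        Collapsed transcript tables (columns ``transcript_id``,
        ``signed_fold`` and optionally ``status``) for the GMCSF and
        GCSF contrasts, produced with the same alpha.
    min_fold
        Optionally require |signed fold| >= ``min_fold`` in a stimulus
        before a transcript counts as regulated there (the two-fold
        variant of the classification).
    """
    fg = _retained_folds(gm, "gm")
    fc = _retained_folds(gc, "gc")
    if min_fold is not None:
        if min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        fg = fg[fg.abs() >= min_fold]
        fc = fc[fc.abs() >= min_fold]

    both = fg.index.intersection(fc.index)
    sg, sc = fg.loc[both] > 0, fc.loc[both] > 0
    return RegulationClasses(
        common_up=frozenset(both[sg & sc]),
        common_down=frozenset(both[~sg & ~sc]),
        reciprocal=frozenset(both[sg ^ sc]),
        gm_only=frozenset(fg.index.difference(fc.index)),
        gcsf_only=frozenset(fc.index.difference(fg.index)),
    )


def filter_by_fold(stats: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep retained transcripts with |signed fold| at or beyond ``threshold``.

    The threshold is inclusive: "at least 4-fold" keeps |fold| >= 4.
    """
    if threshold < 1:
        raise ValueError("fold threshold must be >= 1")
    kept = stats[is_retained(stats["status"])] if "status" in stats.columns else stats
    return kept[kept["signed_fold"].abs() >= threshold].copy()


def load_regulated_list(path: str | Path, stimulus: str | None = None) -> pd.DataFrame:
    """Load a significantly-regulated transcript list from a TSV export.

    Expects columns ``transcript_id`` and ``signed_fold``; if a
    ``stimulus`` column is present the table may hold both stimuli and
    ``stimulus`` selects one. Rows are treated as retained transcripts.
    """
    table = pd.read_csv(path, sep="\t")
    if stimulus is not None and "stimulus" in table.columns:
        table = table[table["stimulus"] == stimulus]
    if not {"transcript_id", "signed_fold"} <= set(table.columns):
        raise ValueError("list needs columns transcript_id, signed_fold")
    out = table[["transcript_id", "signed_fold"]].copy()
    out["status"] = "retained_concordant"
    return out.reset_index(drop=True)
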