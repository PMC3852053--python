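"""End-to-end array pipeline: normalize -> test -> collapse -> classify."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aggregation import collapse_probes
from .containers import ProbeIntensityMatrix
from .cross_stimulus import RegulationClasses, classify_regulation
from .differential import probe_level_stats
from .normalization import quantile_normalize


@dataclass
class PipelineResult:
    normalized: ProbeIntensityMatrix
    gm_probe_stats: pd.DataFrame
    gc_probe_stats: pd.DataFrame
    gm_transcripts: pd.DataFrame
    gc_transcripts: pd.DataFrame
    classes: RegulationClasses


def run_array_pipeline(
    matrix: ProbeIntensityMatrix,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    grouping: str = "condition",
    min_fold: float | None = None,
    treated: tuple[str, str] = ("GMCSF", "GCSF"),
    control: str = "vehicle",
) -> PipelineResult:
    """Run the full array analysis for the two stimulus-vs-vehicle contrasts.

    Quantile-normalizes within experimental groups, computes probe-level
    t statistics and BH-adjusted p values per contrast, collapses probes
    to transcript-level regulation at ``alpha``, and classifies the
    retained transcripts across stimuli (optionally requiring
    |fold| >= ``min_fold``).
    """
    norm = quantile_normalize(matrix, grouping)
    gm_stats = probe_level_stats(norm, annotation, treated[0], control)
    gc_stats = probe_level_stats(norm, annotation, treated[1], control)
    gm = collapse_probes(gm_stats, alpha)
    gc = collapse_probes(gc_stats, alpha)
    classes = classify_regulation(gm, gc, min_fold=min_fold)
    return PipelineResult(norm, gm_stats, gc_stats, gm, gc, classes)
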