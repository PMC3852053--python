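"""Core in-memory containers for the expression pipeline.

The probe-level intensity matrix is the single input every array stage
consumes: probes in rows, samples in columns, with a design table mapping
each sample to its treatment condition (vehicle / GMCSF / GCSF) and
replicate number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("vehicle", "GMCSF", "GCSF")


@dataclass
class ProbeIntensityMatrix:
    """Probe x sample fluorescence intensities with the experimental design.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per sample id. All
        intensities must be strictly positive (arbitrary fluorescence
        units, linear scale). Rows containing missing values are dropped
        on construction with a logged count.
    design
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``. Every sample column of ``values`` must appear.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    n_dropped: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.design.index):
            missing = set(self.values.columns) - set(self.design.index)
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        for col in ("condition", "replicate"):
            if col not in self.design.columns:
                raise ValueError(f"design table lacks required column {col!r}")
        na_rows = self.values.isna().any(axis=1)
        if na_rows.any():
            self.n_dropped = int(na_rows.sum())
            logger.info("dropping %d probe rows with missing values", self.n_dropped)
            self.values = self.values.loc[~na_rows]
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("intensities must be strictly positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in design order."""
        hits = [s for s in self.sample_ids if self.design.loc[s, "condition"] == condition]
        if not hits:
            raise KeyError(f"no samples for condition {condition!r}")
        return hits

    def condition_groups(self) -> dict[str, list[str]]:
        """Partition of the samples by condition."""
        groups: dict[str, list[str]] = {}
        for s in self.sample_ids:
            groups.setdefault(str(self.design.loc[s, "condition"]), []).append(s)
        return groups

    def with_values(self, values: pd.DataFrame) -> "ProbeIntensityMatrix":
        """New matrix sharing this design."""
        return ProbeIntensityMatrix(values, self.design)

    # ---- I/O -------------------------------------------------------------

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, design_path: str | Path) -> "ProbeIntensityMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(values, design)

    def to_tsv(self, matrix_path: str | Path, design_path: str | Path | None = None) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 2-column probe->transcript annotation TSV."""
    annot = pd.read_csv(path, sep="\t")
    if not {"probe_id", "transcript_id"} <= set(annot.columns):
        raise ValueError("annotation needs columns probe_id, transcript_id")
    return annot[["probe_id", "transcript_id"]]


def make_design(n_replicates: int = 3, conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Standard design: each condition measured in ``n_replicates`` wells."""
    rows = [
        {"sample_id": f"{c}_{r}", "condition": c, "replicate": r}
        for c in conditions
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def as_linear_intensities(log2_values: np.ndarray) -> np.ndarray:
    """Convert log2 intensities back to the linear fluorescence scale."""
    return np.exp2(log2_values)
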