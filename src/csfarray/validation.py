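"""Fold-change quantification for the validation platforms.

TaqMan qPCR fold changes use the ddCt method against a reference gene
(Gapdh by default); NanoString nCounter fold changes are expressed as the
arithmetic average of the per-housekeeping-gene fold changes over the
five internal controls (Cltc, Gapdh, Gusb, Hprt, Tubb5). Concordance
scores the agreement of validated regulation directions with the array
predictions.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HOUSEKEEPING_GENES = ("Cltc", "Gapdh", "Gusb", "Hprt", "Tubb5")

TREATED, CONTROL = "treated", "control"


def _check_table(table: pd.DataFrame, value_col: str) -> None:
    required = {"gene", "group", value_col}
    if not required <= set(table.columns):
        raise ValueError(f"table lacks columns {sorted(required - set(table.columns))}")
    groups = set(table["group"])
    if not {TREATED, CONTROL} <= groups:
        raise ValueError(f"table must contain groups {TREATED!r} and {CONTROL!r}")


def _group_mean(table: pd.DataFrame, gene: str, group: str, value_col: str) -> float:
    rows = table[(table["gene"] == gene) & (table["group"] == group)]
    if rows.empty:
        raise KeyError(f"no {value_col} rows for gene {gene!r} in group {group!r}")
    return float(rows[value_col].mean())


def ddct_fold_change(ct: pd.DataFrame, target: str, reference: str = "Gapdh") -> float:
    """Relative expression fold change by the ddCt method.

    dCt(group) = mean Ct(target, group) - mean Ct(reference, group);
    ddCt = dCt(treated) - dCt(control); fold = 2^-ddCt.

    ``ct`` is long-format with columns ``gene``, ``group``
    (treated/control) and ``ct`` (threshold cycles); replicate wells are
    averaged within each (gene, group) cell.
    """
    _check_table(ct, "ct")
    d_treated = _group_mean(ct, target, TREATED, "ct") - _group_mean(ct, reference, TREATED, "ct")
    d_control = _group_mean(ct, target, CONTROL, "ct") - _group_mean(ct, reference, CONTROL, "ct")
    return float(2.0 ** -(d_treated - d_control))


def ncounter_fold_change(
    counts: pd.DataFrame,
    target: str,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
    method: str = "per_gene_mean",
) -> float:
    """Housekeeping-normalized nCounter fold change of ``target``.

    With ``method="per_gene_mean"`` (default) the target count is
    referenced to each housekeeping gene separately —
    fold_h = (target/h ratio in treated) / (target/h ratio in control),
    with the target/h ratio formed per sample and averaged within each
    group — and the arithmetic mean of the five per-gene folds is
    returned. ``method="hk_mean"`` instead normalizes each sample's
    target count by that sample's mean housekeeping count before forming
    the single ratio. Both are invariant to rescaling all counts of any
    one sample (lane effects).
    """
    _check_table(counts, "count")
    if not housekeeping:
        raise ValueError("need at least one housekeeping gene")
    if (counts["count"] <= 0).any():
        raise ValueError("counts must be strictly positive")

    def group_ratios(group: str) -> np.ndarray:
        sub = counts[counts["group"] == group]
        wide = sub.pivot_table(index="sample", columns="gene", values="count")
        needed = [target, *housekeeping]
        missing = [g for g in needed if g not in wide.columns or wide[g].isna().any()]
        if missing:
            raise KeyError(f"genes missing from group {group!r} samples: {missing}")
        if method == "per_gene_mean":
            # per-sample target/housekeeping ratios, averaged over samples
            return np.array([(wide[target] / wide[h]).mean() for h in housekeeping])
        if method == "hk_mean":
            return np.array([(wide[target] / wide[list(housekeeping)].mean(axis=1)).mean()])
        raise ValueError(f"unknown method {method!r}")

    return float((group_ratios(TREATED) / group_ratios(CONTROL)).mean())


def concordance(
    predicted: Mapping[str, float] | Iterable[tuple[str, float]],
    validated: Mapping[str, float] | Iterable[tuple[str, float]],
) -> float:
    """Fraction of shared genes whose regulation directions agree.

    Directions are the signs of the supplied values (signed folds or
    +-1 flags). Genes present in only one list are ignored; the gene sets
    must overlap.
    """
    pred = dict(predicted)
    val = dict(validated)
    shared = set(pred) & set(val)
    if not shared:
        raise ValueError("predicted and validated gene sets do not overlap")
    agree = sum(1 for g in shared if np.sign(pred[g]) == np.sign(val[g]))
    return agree / len(shared)
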