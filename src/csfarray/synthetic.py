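"""Synthetic data generators with planted ground truth.

The study design being emulated: adult DRG neuron cultures treated with
vehicle, GMCSF or GCSF in triplicate wells, profiled on arrays carrying
~46k probes against ~30k transcripts (1-3 probes per transcript), then
validated by TaqMan qPCR, NanoString nCounter counts, and von Frey /
Hargreaves behavioral readouts in groups of 6 mice. Each generator
plants a known effect structure so every downstream stage can be tested
for recovery without external data.

Intensity model: each transcript draws a log2 baseline shared by its
probes; each probe adds a fixed offset; treatment adds a signed log2
effect according to the transcript's regulation class; i.i.d. Gaussian
log2 noise sits on top. Effects are therefore multiplicative on the
linear fluorescence scale and apply to treated conditions only. A
discordant probe is planted by flipping the effect sign on exactly one
probe of a multi-probe transcript, exercising the collapse rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ProbeIntensityMatrix, make_design
from .validation import HOUSEKEEPING_GENES

REGULATION_CLASSES = ("common_up", "common_down", "reciprocal", "gm_only", "gcsf_only", "null")

# class mix implied by the published cross-stimulus breakdown of the
# 30723 arrayed transcripts (union of regulated sets = 19142)
DEFAULT_CLASS_PROPORTIONS = {
    "common_up": 3898 / 30723,
    "common_down": 9254 / 30723,
    "reciprocal": 421 / 30723,
    "gm_only": 2260 / 30723,
    "gcsf_only": 3309 / 30723,
    "null": 11581 / 30723,
}


@dataclass
class SimulationConfig:
    """Conditions of the simulated profiling experiment.

    Defaults mirror the emulated study: 30723 transcripts probed by
    ~46k probes (1-3 each), 3 conditions x 3 replicate wells, and the
    class mix implied by the published regulation counts. Baseline and
    noise scales are typical BeadArray log2 values; the study's raw
    distributional parameters are unpublished.
    """

    n_transcripts: int = 30723
    probes_per_transcript_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.40, 3: 0.05}
    )
    n_replicates: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    probe_offset_log2_sd: float = 0.3
    noise_log2_sd: float = 0.25
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_fold_range: tuple[float, float] = (2.0, 8.0)
    discordant_probe_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.n_replicates < 1:
            raise ValueError("counts must be positive")
        w = dict(self.probes_per_transcript_weights)
        if set(w) - {1, 2, 3} or not np.isclose(sum(w.values()), 1.0):
            raise ValueError("probe weights must be a probability vector over {1,2,3}")
        p = dict(self.class_proportions)
        if set(p) != set(REGULATION_CLASSES):
            raise ValueError(f"class_proportions must cover exactly {REGULATION_CLASSES}")
        if not np.isclose(sum(p.values()), 1.0) or min(p.values()) < 0:
            raise ValueError("class_proportions must be probabilities summing to 1")
        lo, hi = self.effect_fold_range
        if not 1.0 < lo <= hi:
            raise ValueError("effect_fold_range minimum must exceed 1")
        if self.baseline_log2_sd <= 0 or self.probe_offset_log2_sd < 0 or self.noise_log2_sd < 0:
            raise ValueError("standard deviations must be positive (noise may be 0)")
        if not 0 <= self.discordant_probe_rate <= 1:
            raise ValueError("discordant_probe_rate must be a probability")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated experiment.

    ``table`` has one row per transcript: regulation class and the true
    signed fold change under each stimulus (+1 where unaffected).
    ``probe_flips`` marks the probes whose effect sign was flipped to
    plant discordance.
    """

    table: pd.DataFrame
    probe_flips: pd.DataFrame

    def members(self, regulation_class: str) -> frozenset:
        if regulation_class not in REGULATION_CLASSES:
            raise KeyError(regulation_class)
        sel = self.table["regulation_class"] == regulation_class
        return frozenset(self.table.loc[sel, "transcript_id"])

    def fold(self, stimulus: str) -> pd.Series:
        col = {"GMCSF": "fold_gm", "GCSF": "fold_gc"}[stimulus]
        return self.table.set_index("transcript_id")[col]


def _signed_log2_effects(
    rng: np.random.Generator, classes: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-transcript signed log2 effects for (GMCSF, GCSF)."""
    n = len(classes)
    mag_gm = np.log2(rng.uniform(lo, hi, size=n))
    mag_gc = np.log2(rng.uniform(lo, hi, size=n))
    sign_gm = np.zeros(n)
    sign_gc = np.zeros(n)
    flip = rng.random(n) < 0.5  # orientation of reciprocal / specific effects
    for i, klass in enumerate(classes):
        if klass == "common_up":
            sign_gm[i] = sign_gc[i] = 1
        elif klass == "common_down":
            sign_gm[i] = sign_gc[i] = -1
        elif klass == "reciprocal":
            sign_gm[i], sign_gc[i] = (1, -1) if flip[i] else (-1, 1)
        elif klass == "gm_only":
            sign_gm[i] = 1 if flip[i] else -1
        elif klass == "gcsf_only":
            sign_gc[i] = 1 if flip[i] else -1
    return sign_gm * mag_gm, sign_gc * mag_gc


def _signed_fold(log2_effect: np.ndarray) -> np.ndarray:
    """Signed fold convention: +2^|e| up, -2^|e| down, +1 unaffected."""
    fold = np.exp2(np.abs(log2_effect))
    return np.where(log2_effect >= 0, fold, -fold)


def simulate_expression_experiment(
    config: SimulationConfig,
) -> tuple[ProbeIntensityMatrix, pd.DataFrame, PlantedTruth]:
    """Simulate a probe-level profiling experiment with planted effects.

    Returns the probe intensity matrix (strictly positive, linear
    scale), the probe->transcript annotation, and the planted truth.
    The same config and seed always produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts
    transcript_ids = np.array([f"T{i:06d}" for i in range(1, n + 1)])

    weights = config.probes_per_transcript_weights
    n_probes_per = rng.choice([1, 2, 3], size=n, p=[weights.get(i, 0.0) for i in (1, 2, 3)])
    classes = rng.choice(
        REGULATION_CLASSES,
        size=n,
        p=[config.class_proportions[c] for c in REGULATION_CLASSES],
    )
    lo, hi = config.effect_fold_range
    eff_gm, eff_gc = _signed_log2_effects(rng, classes, lo, hi)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)

    tr_idx = np.repeat(np.arange(n), n_probes_per)
    probe_rank = np.concatenate([np.arange(k) for k in n_probes_per])
    probe_ids = np.array(
        [f"P{t + 1:06d}_{r + 1}" for t, r in zip(tr_idx, probe_rank)]
    )
    offsets = rng.normal(0.0, config.probe_offset_log2_sd, size=len(probe_ids))

    # plant discordance: flip the effect sign of exactly one probe on a
    # fraction of multi-probe transcripts that carry an effect
    has_effect = (eff_gm != 0) | (eff_gc != 0)
    eligible = np.flatnonzero((n_probes_per >= 2) & has_effect)
    chosen = eligible[rng.random(len(eligible)) < config.discordant_probe_rate]
    flipped_probe = np.zeros(len(probe_ids), dtype=bool)
    first_probe_of = np.r_[0, np.cumsum(n_probes_per)[:-1]]
    for t in chosen:
        flipped_probe[first_probe_of[t] + rng.integers(n_probes_per[t])] = True
    probe_sign = np.where(flipped_probe, -1.0, 1.0)

    probe_eff_gm = eff_gm[tr_idx] * probe_sign
    probe_eff_gc = eff_gc[tr_idx] * probe_sign

    design = make_design(config.n_replicates)
    columns = {}
    for sample_id, row in design.iterrows():
        eff = {"vehicle": 0.0, "GMCSF": probe_eff_gm, "GCSF": probe_eff_gc}[row["condition"]]
        log2_values = (
            baseline[tr_idx]
            + offsets
            + eff
            + rng.normal(0.0, config.noise_log2_sd, size=len(probe_ids))
        )
        columns[sample_id] = np.exp2(log2_values)
    values = pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id"))

    annotation = pd.DataFrame(
        {"probe_id": probe_ids, "transcript_id": transcript_ids[tr_idx]}
    )
    truth = PlantedTruth(
        table=pd.DataFrame(
            {
                "transcript_id": transcript_ids,
                "regulation_class": classes,
                "fold_gm": _signed_fold(eff_gm),
                "fold_gc": _signed_fold(eff_gc),
                "n_probes": n_probes_per,
            }
        ),
        probe_flips=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "transcript_id": transcript_ids[tr_idx],
                "flipped": flipped_probe,
            }
        ),
    )
    return ProbeIntensityMatrix(values, design), annotation, truth


# ---------------------------------------------------------------------------
# validation-platform generators


def simulate_qpcr(
    true_folds: Mapping[str, float],
    reps: int = 3,
    ct_sd: float = 0.2,
    reference: str = "Gapdh",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a TaqMan Ct table for target genes with known fold changes.

    A gene with true fold f has its treated-group Ct lowered by log2(f);
    the reference gene is unaffected by treatment. Gaussian Ct noise of
    ``ct_sd`` cycles is added per well.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be positive (linear-scale ratios)")
    rng = np.random.default_rng(seed)
    folds = {reference: 1.0, **dict(true_folds)}
    rows = []
    for gene, fold in folds.items():
        base = rng.uniform(18.0, 26.0)
        for group, shift in (("control", 0.0), ("treated", -np.log2(fold))):
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"{group}_{r}",
                        "group": group,
                        "replicate": r,
                        "ct": base + shift + rng.normal(0.0, ct_sd),
                    }
                )
    return pd.DataFrame(rows)


def simulate_ncounter(
    true_folds: Mapping[str, float],
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
    reps: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an nCounter count table with treatment-independent housekeeping.

    Counts are multiplicatively noisy (log-normal, coefficient of
    variation ``noise_cv``); treated-group counts of a target gene are
    scaled by its true fold. Housekeeping counts have fold 1.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true folds must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    folds = {**{h: 1.0 for h in housekeeping}, **dict(true_folds)}
    rows = []
    for gene, fold in folds.items():
        base = rng.uniform(500.0, 5000.0)
        for group, scale in (("control", 1.0), ("treated", fold)):
            for r in range(1, reps + 1):
                noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"{group}_{r}",
                        "group": group,
                        "replicate": r,
                        "count": base * scale * noise,
                    }
                )
    return pd.DataFrame(rows)


def simulate_behavior(
    groups: Sequence[str] = ("vehicle", "GMCSF"),
    timepoints: Sequence[str] = ("0h", "4h", "8h"),
    n_animals: int = 6,
    modality: str = "vonfrey",
    effects: Mapping[tuple[str, str], float] | None = None,
    baseline: float | None = None,
    latency_sd: float = 1.5,
    cutoff_s: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a von Frey or Hargreaves behavioral dataset.

    Von Frey values are percent responses over 5 stimulations (binomial,
    so multiples of 20); Hargreaves values are withdrawal latencies in
    seconds, censored at the 15 s cutoff. ``effects`` maps
    (group, timepoint) to an additive shift: a response-probability
    delta for von Frey (positive = hypersensitive), a latency delta in
    seconds for Hargreaves (negative = hypersensitive).
    """
    if modality not in ("vonfrey", "hargreaves"):
        raise ValueError("modality must be 'vonfrey' or 'hargreaves'")
    rng = np.random.default_rng(seed)
    effects = dict(effects or {})
    if baseline is None:
        baseline = 0.2 if modality == "vonfrey" else 8.0
    rows = []
    for group in groups:
        for a in range(1, n_animals + 1):
            animal = f"{group}_a{a}"
            for tp in timepoints:
                shift = effects.get((group, tp), 0.0)
                if modality == "vonfrey":
                    p = float(np.clip(baseline + shift, 0.0, 1.0))
                    value = 100.0 * rng.binomial(5, p) / 5.0
                else:
                    raw = rng.normal(baseline + shift, latency_sd)
                    value = float(np.clip(raw, 0.1, cutoff_s))
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "timepoint": tp,
                        "modality": modality,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def simulate_interaction_db(
    n_genes: int,
    edge_density: float,
    planted_hub_ids: Sequence[str] = (),
    hub_min_degree: int = 10,
    seed: int = 0,
    prefix: str = "G",
):
    """Random undirected interaction database with optional planted hubs.

    Background edges are Erdos-Renyi with probability ``edge_density``;
    each planted hub id is wired to random partners until its degree
    reaches ``hub_min_degree``. No self-loops or duplicate edges.
    """
    import networkx as nx

    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be a probability")
    rng = np.random.default_rng(seed)
    genes = [f"{prefix}{i:05d}" for i in range(1, n_genes + 1)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if edge_density > 0:
        iu, ju = np.triu_indices(n_genes, k=1)
        hit = rng.random(len(iu)) < edge_density
        g.add_edges_from((genes[i], genes[j]) for i, j in zip(iu[hit], ju[hit]))
    for hub in planted_hub_ids:
        if hub not in g:
            g.add_node(hub)
        others = [x for x in genes if x != hub]
        while g.degree(hub) < min(hub_min_degree, len(others)):
            g.add_edge(hub, others[rng.integers(len(others))])
    return g


# ---------------------------------------------------------------------------
# published-summary stand-in

GM_TOTAL, GC_TOTAL = 15833, 16882
COMMON_UP, COMMON_DOWN, RECIPROCAL = 3898, 9254, 421
GM_ONLY = GM_TOTAL - COMMON_UP - COMMON_DOWN - RECIPROCAL  # 2260
GC_ONLY = GC_TOTAL - COMMON_UP - COMMON_DOWN - RECIPROCAL  # 3309
GM_FOLD4, GC_FOLD4 = 661, 611


def table_s1_standin(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic stand-in for the published significant-transcript lists.

    The real supplementary table of significantly regulated transcripts
    (2-fold cutoff, BH-adjusted p < 0.05) is not deposited as data; this
    generator fabricates GMCSF and GCSF lists whose joint structure
    matches the published summary counts — 15833 / 16882 regulated
    transcripts, of which 3898 commonly up, 9254 commonly down, 421
    reciprocal, and 661 / 611 at the four-fold stringency filter — with
    random fold magnitudes and shuffled order. It is a labelled synthetic
    reference for exercising the classification stage at published
    scale, not the study's data.
    """
    rng = np.random.default_rng(seed)
    ids = iter(f"T{i:06d}" for i in range(1, GM_TOTAL + GC_ONLY + 1))

    def take(k: int) -> list[str]:
        return [next(ids) for _ in range(k)]

    gm_rows: list[tuple[str, int]] = []  # (transcript, sign)
    gc_rows: list[tuple[str, int]] = []
    for t in take(COMMON_UP):
        gm_rows.append((t, 1))
        gc_rows.append((t, 1))
    for t in take(COMMON_DOWN):
        gm_rows.append((t, -1))
        gc_rows.append((t, -1))
    for i, t in enumerate(take(RECIPROCAL)):
        gm_rows.append((t, 1 if i % 2 else -1))
        gc_rows.append((t, -1 if i % 2 else 1))
    for t in take(GM_ONLY):
        gm_rows.append((t, 1 if rng.random() < 0.5 else -1))
    for t in take(GC_ONLY):
        gc_rows.append((t, 1 if rng.random() < 0.5 else -1))

    def finish(rows: list[tuple[str, int]], n_strong: int) -> pd.DataFrame:
        n = len(rows)
        mags = rng.uniform(2.0, 3.9, size=n)  # 2-fold cutoff of the source lists
        strong = rng.choice(n, size=n_strong, replace=False)
        mags[strong] = rng.uniform(4.0, 40.0, size=n_strong)
        table = pd.DataFrame(
            {
                "transcript_id": [t for t, _ in rows],
                "signed_fold": [s for _, s in rows] * np.round(mags, 3),
                "status": "retained_concordant",
            }
        )
        return table.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    return finish(gm_rows, GM_FOLD4), finish(gc_rows, GC_FOLD4)
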