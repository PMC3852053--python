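import numpy as np
import pandas as pd
import pytest

from csfarray import (
    concordance,
    ddct_fold_change,
    ncounter_fold_change,
    simulate_ncounter,
    simulate_qpcr,
)


def ct_table(rows):
    return pd.DataFrame(rows, columns=["gene", "group", "replicate", "ct"])


def count_table(rows):
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "count"])


class TestDdctFoldChange:
    def test_two_cycle_shift_is_fourfold(self):
        ct = ct_table(
            [("tgt", "treated", 1, 20.0), ("tgt", "control", 1, 22.0),
             ("ref", "treated", 1, 15.0), ("ref", "control", 1, 15.0)]
        )
        assert ddct_fold_change(ct, "tgt", "ref") == pytest.approx(4.0)

    def test_target_equal_to_reference_is_unity(self):
        ct = ct_table(
            [("ref", "treated", 1, 18.0), ("ref", "control", 1, 21.0)]
        )
        assert ddct_fold_change(ct, "ref", "ref") == pytest.approx(1.0)

    def test_replicates_are_averaged_before_ddct(self):
        rows = [("tgt", "treated", r, c) for r, c in enumerate([20.1, 19.9, 20.0])]
        rows += [("tgt", "control", r, c) for r, c in enumerate([21.9, 22.1, 22.0])]
        rows += [("ref", g, r, 15.0) for g in ("treated", "control") for r in range(3)]
        assert ddct_fold_change(ct_table(rows), "tgt", "ref") == pytest.approx(4.0, rel=1e-9)

    def test_plate_shift_invariance(self, rng):
        rows = [
            (g, grp, r, float(rng.uniform(14, 30)))
            for g in ("tgt", "ref")
            for grp in ("treated", "control")
            for r in range(3)
        ]
        ct = ct_table(rows)
        base = ddct_fold_change(ct, "tgt", "ref")
        shifted = ct.copy()
        shifted.loc[shifted["group"] == "treated", "ct"] += 1.7  # plate offset
        assert ddct_fold_change(shifted, "tgt", "ref") == pytest.approx(base, rel=1e-9)

    def test_missing_gene_or_group_is_error(self):
        ct = ct_table([("tgt", "treated", 1, 20.0), ("tgt", "control", 1, 21.0)])
        with pytest.raises(KeyError):
            ddct_fold_change(ct, "tgt", "ref")


HK = ("h1", "h2", "h3", "h4", "h5")


def flat_hk_counts(target_fold, hk_folds=(1.0,) * 5):
    rows = []
    for gene, fold in [("tgt", target_fold)] + list(zip(HK, hk_folds)):
        for grp, scale in (("control", 1.0), ("treated", fold)):
            rows.append((gene, f"{grp}_1", grp, 100.0 * scale))
    return count_table(rows)


class TestNcounterFoldChange:
    def test_doubling_target_with_flat_housekeeping(self):
        counts = flat_hk_counts(2.0)
        assert ncounter_fold_change(counts, "tgt", HK) == pytest.approx(2.0)

    def test_flat_target_is_unity(self):
        assert ncounter_fold_change(flat_hk_counts(1.0), "tgt", HK) == pytest.approx(1.0)

    def test_arithmetic_mean_over_housekeeping_folds(self):
        # per-housekeeping folds {2,2,2,2,1} -> mean 1.8
        counts = flat_hk_counts(2.0, hk_folds=(1, 1, 1, 1, 2))
        assert ncounter_fold_change(counts, "tgt", HK) == pytest.approx(1.8)

    def test_lane_scaling_invariance(self, rng):
        counts = simulate_ncounter({"tgt": 3.0}, housekeeping=HK, noise_cv=0.2, seed=4)
        base = ncounter_fold_change(counts, "tgt", HK)
        scaled = counts.copy()
        scaled.loc[scaled["sample"] == "treated_2", "count"] *= 7.5
        assert ncounter_fold_change(scaled, "tgt", HK) == pytest.approx(base, rel=1e-9)

    def test_alternative_hk_mean_method(self):
        counts = flat_hk_counts(2.0)
        assert ncounter_fold_change(counts, "tgt", HK, method="hk_mean") == pytest.approx(2.0)

    def test_nonpositive_counts_rejected(self):
        bad = flat_hk_counts(2.0)
        bad.loc[0, "count"] = 0.0
        with pytest.raises(ValueError):
            ncounter_fold_change(bad, "tgt", HK)


class TestConcordance:
    def test_identical_and_opposite_lists(self):
        pred = {f"g{i}": (-1) ** i * 2.0 for i in range(10)}
        assert concordance(pred, pred) == 1.0
        flipped = {g: -v for g, v in pred.items()}
        assert concordance(pred, flipped) == 0.0

    def test_partial_agreement_fraction(self):
        # 78 of 100 validated genes regulated in the predicted direction
        pred = {f"g{i}": 1.0 for i in range(100)}
        val = {f"g{i}": (1.0 if i < 78 else -1.0) for i in range(100)}
        assert concordance(pred, val) == pytest.approx(0.78)

    def test_only_shared_genes_scored(self):
        assert concordance({"a": 1, "b": 1, "x": 1}, {"a": 1, "b": -1, "y": 1}) == 0.5

    def test_disjoint_sets_rejected(self):
        with pytest.raises(ValueError):
            concordance({"a": 1}, {"b": 1})


class TestSimulatedRecovery:
    def test_qpcr_zero_noise_shifts_ct_exactly(self):
        ct = simulate_qpcr({"tgt": 4.0}, reps=3, ct_sd=0.0, seed=1)
        tgt = ct[ct["gene"] == "tgt"].groupby("group")["ct"].mean()
        ref = ct[ct["gene"] == "Gapdh"].groupby("group")["ct"].mean()
        assert tgt["control"] - tgt["treated"] == pytest.approx(2.0)
        assert ref["control"] == pytest.approx(ref["treated"])
        assert ddct_fold_change(ct, "tgt") == pytest.approx(4.0)

    def test_qpcr_unit_fold_estimates_unity(self):
        ct = simulate_qpcr({"tgt": 1.0}, ct_sd=0.05, seed=2)
        assert ddct_fold_change(ct, "tgt") == pytest.approx(1.0, rel=0.15)

    def test_qpcr_monte_carlo_recovery_within_5_percent(self):
        est = [
            ddct_fold_change(simulate_qpcr({"tgt": 4.0}, ct_sd=0.1, seed=s), "tgt")
            for s in range(300)
        ]
        assert np.mean(est) == pytest.approx(4.0, rel=0.05)

    def test_ncounter_zero_noise_recovers_fold_exactly(self):
        counts = simulate_ncounter({"tgt": 2.0}, noise_cv=0.0, seed=3)
        assert ncounter_fold_change(counts, "tgt") == pytest.approx(2.0, rel=1e-12)

    def test_ncounter_monte_carlo_recovery_within_5_percent(self):
        est = [
            ncounter_fold_change(
                simulate_ncounter({"tgt": 2.0}, noise_cv=0.05, seed=s), "tgt"
            )
            for s in range(300)
        ]
        assert np.mean(est) == pytest.approx(2.0, rel=0.05)

    def test_invalid_folds_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr({"tgt": 0.0})
        with pytest.raises(ValueError):
            simulate_ncounter({"tgt": -2.0})
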