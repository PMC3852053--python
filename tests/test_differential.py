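import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfarray import ProbeIntensityMatrix, adjust_bh, probe_level_stats, signed_fold_change


def two_group_matrix(rows_treated, rows_control):
    """Matrix whose log2 intensities are the given per-probe replicate values."""
    t = np.exp2(np.atleast_2d(rows_treated))
    c = np.exp2(np.atleast_2d(rows_control))
    values = pd.DataFrame(
        np.hstack([t, c]),
        index=[f"p{i}" for i in range(t.shape[0])],
        columns=[f"T{j}" for j in range(t.shape[1])] + [f"C{j}" for j in range(c.shape[1])],
    )
    design = pd.DataFrame(
        {
            "condition": {f"T{j}": "GMCSF" for j in range(t.shape[1])}
            | {f"C{j}": "vehicle" for j in range(c.shape[1])},
            "replicate": {s: 1 for s in values.columns},
        }
    )
    annot = pd.DataFrame({"probe_id": values.index, "transcript_id": values.index})
    return ProbeIntensityMatrix(values, design), annot


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "treated,vehicle,expected",
        [(200, 100, 2.0), (100, 200, -2.0), (100, 100, 1.0), (800, 100, 8.0)],
    )
    def test_stated_convention(self, treated, vehicle, expected):
        assert signed_fold_change(treated, vehicle) == pytest.approx(expected)

    @pytest.mark.parametrize("treated,vehicle", [(0, 1), (1, 0), (-2, 3)])
    def test_nonpositive_means_rejected(self, treated, vehicle):
        with pytest.raises(ValueError):
            signed_fold_change(treated, vehicle)

    @given(
        a=st.floats(min_value=1e-3, max_value=1e6),
        b=st.floats(min_value=1e-3, max_value=1e6),
    )
    def test_magnitude_at_least_one_and_antisymmetric(self, a, b):
        f, g = signed_fold_change(a, b), signed_fold_change(b, a)
        assert abs(f) >= 1 and abs(g) >= 1
        assert abs(f) == pytest.approx(abs(g), rel=1e-9)
        if a != b:
            assert np.sign(f) == -np.sign(g) == np.sign(a - b)


class TestProbeLevelStats:
    def test_textbook_equal_variance_t(self):
        # log2 replicates {1,2,3} vs {4,5,6}: pooled variance 1,
        # se = sqrt(2/3), t = -3/se = -3.674, p = 0.0214 at 4 df
        m, annot = two_group_matrix([[1, 2, 3]], [[4, 5, 6]])
        out = probe_level_stats(m, annot, "GMCSF", "vehicle")
        assert out.loc[0, "t"] == pytest.approx(-3.6742346, abs=1e-6)
        assert out.loc[0, "p"] == pytest.approx(0.0214, abs=5e-4)
        assert not out.loc[0, "degenerate"]

    def test_identical_groups_give_p_one(self):
        m, annot = two_group_matrix([[5, 6, 7]], [[5, 6, 7]])
        out = probe_level_stats(m, annot, "GMCSF", "vehicle")
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0
        assert out.loc[0, "signed_fold"] == pytest.approx(1.0)

    def test_zero_variance_cases(self):
        m, annot = two_group_matrix([[3, 3, 3], [3, 3, 3]], [[3, 3, 3], [5, 5, 5]])
        out = probe_level_stats(m, annot, "GMCSF", "vehicle")
        equal, diff = out.iloc[0], out.iloc[1]
        assert (equal["t"], equal["p"], bool(equal["degenerate"])) == (0.0, 1.0, False)
        assert diff["p"] == 0.0 and np.isinf(diff["t"]) and bool(diff["degenerate"])

    def test_fold_is_on_linear_means_and_bh_spans_call(self):
        m, annot = two_group_matrix(
            [[3, 3, 3], [1, 2, 3]], [[1, 1, 1], [1.1, 2.1, 3.1]]
        )
        out = probe_level_stats(m, annot, "GMCSF", "vehicle")
        assert out.loc[0, "signed_fold"] == pytest.approx(4.0)
        assert (out["p_bh"] >= out["p"] - 1e-15).all()

    def test_single_replicate_condition_rejected(self):
        m, annot = two_group_matrix([[1]], [[2]])
        with pytest.raises(ValueError, match="2 replicates"):
            probe_level_stats(m, annot, "GMCSF", "vehicle")

    def test_null_false_positive_rate_calibrated(self, rng):
        n = 4000
        log2 = rng.normal(8.0, 0.4, size=(n, 6))
        m, annot = two_group_matrix(log2[:, :3], log2[:, 3:])
        out = probe_level_stats(m, annot, "GMCSF", "vehicle")
        rate = (out["p"] <= 0.05).mean()
        mc_sd = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 3 * mc_sd


class TestAdjustBH:
    def test_hand_examples(self):
        assert adjust_bh([0.03]) == pytest.approx([0.03])
        assert adjust_bh([0.01] * 4) == pytest.approx([0.01] * 4)
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [0.5, np.nan]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_bh(bad)

    @staticmethod
    def brute_force_step_up(p):
        """Direct evaluation of adj_i = min_{j: p_j >= p_i} (p_j * m / rank_j)."""
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = min(running, 1.0)
        return adj

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_definition(self, p):
        assert adjust_bh(p) == pytest.approx(self.brute_force_step_up(np.array(p)))

    def test_monotone_in_raw_p(self, rng):
        p = rng.uniform(size=500)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
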