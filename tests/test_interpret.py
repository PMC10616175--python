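"""Interpretation analyses: erasure, preservation curves, quartered signs,
summed weights, High/Low tables."""

import numpy as np
import pandas as pd
import pytest

from alwx import alw as alw_mod
from alwx import interpret as interp
from alwx import lrp
from alwx import synthetic as syn


def _kernel_from_weights(W_start, W_end, freq_axis=None):
    return alw_mod.ALWKernel(
        W_start=np.asarray(W_start, dtype=float),
        W_end=np.asarray(W_end, dtype=float),
        tau=np.asarray(W_start).shape[1],
        classes=np.arange(np.asarray(W_start).shape[2]),
        D_used=1,
        ratio_stabilizer=1e-9,
        freq_axis_hz=freq_axis,
    )


class TestQuarterSigns:
    def _k(self, start_seq, end_seq):
        ws = np.array(start_seq, dtype=float).reshape(1, -1, 1)
        we = np.array(end_seq, dtype=float).reshape(1, -1, 1)
        return _kernel_from_weights(ws, we)

    def test_all_positive_is_pppp(self):
        assert interp.quarter_signs(self._k([1, 2, 3], [0.5, 1, 2]), 0, 0) == "PPPP"

    def test_hand_derived_flip_strings(self):
        assert interp.quarter_signs(self._k([1, 1, -1, -1], [-1, -1, -1, -1]), 0, 0) == "PNNN"
        assert interp.quarter_signs(self._k([-1, 1, -1, 1], [1, -1, 1, -1]), 0, 0) == "NPPN"

    def test_no_flip_duplicates_first_sign(self):
        assert interp.quarter_signs(self._k([-1, -2], [3, 4]), 0, 0) == "NNPP"

    def test_zeros_inherit_previous_nonzero_sign(self):
        assert interp.quarter_signs(self._k([1, 0, 0, -1], [0, 0, 2, 2]), 0, 0) == "PNPP"

    def test_all_zero_window_reported_undefined(self):
        assert interp.quarter_signs(self._k([0, 0, 0], [1, 1, 1]), 0, 0) == "UUPP"

    def test_later_flips_ignored(self):
        # only the first flip defines the quarter boundary
        assert interp.quarter_signs(self._k([1, -1, 1, -1, 1], [1, 1, 1, 1, 1]), 0, 0) == "PNPP"

    def test_tau_one_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            interp.quarter_signs(self._k([1], [1]), 0, 0)

    def test_format_is_four_letters(self, trained):
        s = interp.quarter_signs(trained["aclf"].kernel_, 10, 1)
        assert len(s) == 4 and set(s) <= {"P", "N", "U"}

    def test_sign_table_covers_all_features(self, trained):
        tab = interp.sign_table(trained["aclf"].kernel_, class_names=["ET", "N", "PD"])
        assert len(tab) == 105
        assert list(tab.columns) == ["part", "freq_hz", "ET", "N", "PD"]


class TestSummedWeights:
    def test_single_class_normalizes_to_unit(self):
        k = _kernel_from_weights(np.full((2, 3, 1), 0.5), np.full((2, 3, 1), 0.5))
        s = interp.summed_weights(k)
        assert np.allclose(s["normalized_weight"], 1.0)

    def test_max_abs_normalization_oracle(self):
        ws = np.zeros((1, 1, 3))
        we = np.zeros((1, 1, 3))
        ws[0, 0] = [2.0, -4.0, 1.0]
        s = interp.summed_weights(_kernel_from_weights(ws, we))
        np.testing.assert_allclose(s["normalized_weight"], [0.5, -1.0, 0.25])

    def test_all_zero_feature_guarded(self):
        k = _kernel_from_weights(np.zeros((1, 2, 3)), np.zeros((1, 2, 3)))
        s = interp.summed_weights(k)
        assert np.all(s["normalized_weight"] == 0.0)

    def test_sums_cover_both_windows(self):
        ws = np.full((1, 2, 1), 1.0)
        we = np.full((1, 2, 1), 2.0)
        s = interp.summed_weights(_kernel_from_weights(ws, we))
        assert s["summed_weight"].iloc[0] == pytest.approx(2 + 4)


class TestFeatureTable:
    def _summary(self, sums):
        rows = []
        for ci, cname in enumerate(["N", "PD", "ET"]):
            rows.append(
                {"part": "L", "freq_hz": 3.1, "feature_index": 0, "class": cname,
                 "summed_weight": sums[ci], "normalized_weight": 0.0}
            )
        return pd.DataFrame(rows)

    def test_unique_positive_gets_asterisk(self):
        tab = interp.feature_table(self._summary([1.0, -2.0, -0.5]))
        assert tab.iloc[0]["N"] == "High*"
        assert tab.iloc[0]["PD"] == "Low" and tab.iloc[0]["ET"] == "Low"

    def test_all_positive_no_asterisk(self):
        tab = interp.feature_table(self._summary([1.0, 2.0, 3.0]))
        assert all(tab.iloc[0][c] == "High" for c in ["N", "PD", "ET"])

    def test_depends_only_on_signs(self):
        a = interp.feature_table(self._summary([1.0, -2.0, -0.5]))
        scaled = self._summary([1.0, -2.0, -0.5])
        scaled["summed_weight"] *= 37.0
        b = interp.feature_table(scaled)
        pd.testing.assert_frame_equal(a, b)


class TestPlateauDetect:
    def test_step_curve(self):
        curve = pd.DataFrame({"k": [0, 5, 10, 20], "accuracy": [0.33, 0.9, 0.9, 0.9]})
        assert interp.plateau_detect(curve, tolerance=0.02) == 5

    def test_strictly_increasing_with_zero_tolerance(self):
        curve = pd.DataFrame({"k": [0, 5, 10], "accuracy": [0.2, 0.5, 0.9]})
        assert interp.plateau_detect(curve, tolerance=0.0) == 10

    def test_noisy_flat_curve_scan_oracle(self):
        ks = list(range(0, 60, 10))
        accs = [0.3, 0.88, 0.9, 0.89, 0.91, 0.9]
        curve = pd.DataFrame({"k": ks, "accuracy": accs})
        full = accs[-1]
        expected = next(k for k, a in zip(ks, accs) if a >= full - 0.02)
        assert interp.plateau_detect(curve, tolerance=0.02) == expected


class TestErasurePrimitives:
    def test_fraction_zero_is_identity(self):
        X = np.random.default_rng(0).random((3, 4, 2))
        out = interp.erase_by_relevance(X, X.copy(), "positive", 0.0)
        np.testing.assert_array_equal(out, X)

    def test_fraction_one_zeroes_everything(self):
        rng = np.random.default_rng(1)
        X = rng.random((3, 4, 2))
        for strategy in interp.ERASURE_STRATEGIES:
            out = interp.erase_by_relevance(X, rng.standard_normal(X.shape), strategy, 1.0, rng)
            assert np.all(out == 0)

    def test_positive_strategy_zeroes_largest_relevance_first(self):
        X = np.ones((1, 2, 2))
        rel = np.array([[[4.0, 1.0], [3.0, 2.0]]])
        out = interp.erase_by_relevance(X, rel, "positive", 0.5)  # zero top 2 of 4
        np.testing.assert_array_equal(out[0], [[0.0, 1.0], [0.0, 1.0]])

    def test_negative_strategy_zeroes_most_negative_first(self):
        X = np.ones((1, 2, 2))
        rel = np.array([[[-4.0, 1.0], [-3.0, 2.0]]])
        out = interp.erase_by_relevance(X, rel, "negative", 0.5)
        np.testing.assert_array_equal(out[0], [[0.0, 1.0], [0.0, 1.0]])

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            interp.erase_by_relevance(np.ones((1, 2, 2)), np.ones((1, 2, 2)), "best", 0.5)

    def test_preserve_edges_boundaries(self):
        X = np.arange(24, dtype=float).reshape(1, 6, 4)
        assert np.all(interp.preserve_edges(X, 0) == 0)
        np.testing.assert_array_equal(interp.preserve_edges(X, 3), X)
        with pytest.raises(ValueError, match="exceeds"):
            interp.preserve_edges(X, 4)


class TestOnTrainedModel:
    def test_erasure_baseline_and_convergence(self, trained):
        s = trained["split"]
        Xt, yt = trained["X"][s.test_ids], trained["y"][s.test_ids]
        df = interp.erasure_analysis(trained["clf"], Xt, yt, fractions=[0.0, 1.0], seed=0)
        base = df[df["fraction"] == 0.0]["accuracy"]
        assert base.nunique() == 1  # identical baseline for all strategies
        final = df[df["fraction"] == 1.0]["accuracy"]
        assert final.nunique() == 1  # all strategies converge on all-zero inputs

    def test_single_top_entry_erasure_never_raises_predicted_score(self, trained):
        s = trained["split"]
        Xt = trained["X"][s.test_ids]
        clf = trained["clf"]
        probs = clf.predict_proba(Xt)
        preds = probs.argmax(1)
        rel = interp._predicted_class_relevance(clf, Xt, lrp.LRPConfig())
        Xz = Xt.copy().reshape(len(Xt), -1)
        flat = rel.reshape(len(Xt), -1)
        top = flat.argmax(axis=1)
        Xz[np.arange(len(Xt)), top] = 0.0
        probs2 = clf.predict_proba(Xz.reshape(Xt.shape))
        before = probs[np.arange(len(Xt)), preds]
        after = probs2[np.arange(len(Xt)), preds]
        # saturated probabilities (~1 - 1e-4) can wiggle by ~1e-5 through the
        # recurrence; anything beyond that would signal unfaithful relevance
        assert np.all(after <= before + 1e-4)

    def test_timestep_preservation_curve_shape(self, trained):
        s = trained["split"]
        Xt, yt = trained["X"][s.test_ids], trained["y"][s.test_ids]
        T = Xt.shape[1]
        curve = interp.timestep_preservation_curve(
            trained["clf"], Xt, yt, [0, 5, 10, 20, 40, T // 2]
        )
        accs = dict(zip(curve["k"], curve["accuracy"]))
        assert accs[0] == pytest.approx(1 / 3, abs=1e-9)  # all-zero inputs, balanced test
        baseline = accs[T // 2]
        k_star = interp.plateau_detect(curve, tolerance=0.02)
        assert k_star is not None and k_star < T // 2  # plateau before full preservation
        assert accs[k_star] >= baseline - 0.02
        with pytest.raises(ValueError, match="exceeds"):
            interp.timestep_preservation_curve(trained["clf"], Xt, yt, [T])

    def test_relevance_heatmap_export(self, tmp_path, trained):
        s = trained["split"]
        rt = lrp.relevance(trained["clf"], trained["X"][s.test_ids][0], 0)
        out = tmp_path / "heat.png"
        interp.relevance_heatmap(rt.R, trained["freq_axis"], out)
        assert out.stat().st_size > 0

    def test_planted_feature_recovery(self, trained):
        summary = interp.summed_weights(
            trained["aclf"].kernel_, class_names=list(trained["clf"].classes_)
        )
        rec = syn.planted_recovery(summary, trained["freq_axis"])
        assert rec >= 0.8
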