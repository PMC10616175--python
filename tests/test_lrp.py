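"""Relevance propagation: stabilized linear rule, BN folding, LSTM rule,
conservation, directionality."""

import numpy as np
import pytest

from alwx import lrp
from alwx import network as net
from conftest import make_random_bilstm


def eq1_reference(R_out, z_in, z_out, W, b, delta, eps):
    """Direct double-loop evaluation of the stabilized linear rule."""
    Ni, Nj = W.shape
    R_in = np.zeros(Ni)
    for i in range(Ni):
        for j in range(Nj):
            s = 1.0 if z_out[j] >= 0 else -1.0
            R_in[i] += (
                (W[i, j] * z_in[i] + (delta * b[j] + eps * s) / Ni)
                / (z_out[j] + eps * s)
                * R_out[j]
            )
    return R_in


class TestLinearRule:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_formula_on_random_small_layers(self, seed):
        rng = np.random.default_rng(seed)
        Ni, Nj = rng.integers(1, 6, 2)
        W = rng.standard_normal((Ni, Nj))
        b = rng.standard_normal(Nj)
        z_in = rng.standard_normal(Ni)
        z_out = z_in @ W + b
        R_out = rng.standard_normal(Nj)
        delta = float(rng.choice([0.0, 0.5]))
        got = lrp.lrp_linear(R_out, z_in, z_out, W, b, delta=delta, epsilon=0.001)[0]
        want = eq1_reference(R_out, z_in, z_out, W, b, delta, 0.001)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_identity_layer_conserves(self):
        # 1x1 layer, w=1, b=0, z=2, R=2: (2 + 0.001)/(2.001) * 2 = 2
        out = lrp.lrp_linear([2.0], [2.0], [2.0], np.array([[1.0]]), np.array([0.0]))
        assert out[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_conservation_in_clean_limit(self):
        rng = np.random.default_rng(1)
        W = rng.standard_normal((4, 3))
        z_in = rng.standard_normal(4)
        z_out = z_in @ W
        R_out = rng.standard_normal(3)
        R_in = lrp.lrp_linear(R_out, z_in, z_out, W, None, delta=0.0, epsilon=1e-12)
        assert R_in.sum() == pytest.approx(R_out.sum(), rel=1e-9)

    def test_zero_preactivation_uses_positive_sign(self):
        out = lrp.lrp_linear([1.0], [0.0], [0.0], np.array([[1.0]]), np.array([0.0]))
        assert np.isfinite(out).all()
        assert out[0, 0] == pytest.approx(1.0)  # share term: (eps/1)/(eps) * 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lrp.lrp_linear([1.0, 2.0], [1.0], [1.0], np.array([[1.0]]))


class TestBatchNormRule:
    def test_identity_bn_passes_relevance_through(self):
        R = np.array([[1.0, -2.0, 0.5]])
        z = np.array([[0.3, -0.7, 2.0]])
        out = lrp.lrp_batchnorm(R, z, np.ones(3), np.zeros(3), np.zeros(3), np.ones(3))
        np.testing.assert_allclose(out, R, rtol=1e-2)

    def test_pure_scaling_preserves_per_feature_relevance(self):
        R = np.array([[1.5, -0.5]])
        z = np.array([[2.0, 1.0]])
        out = lrp.lrp_batchnorm(
            R, z, np.array([3.0, 0.2]), np.zeros(2), np.zeros(2), np.ones(2),
            eps_bn=0.0, config=lrp.LRPConfig(epsilon=1e-12),
        )
        np.testing.assert_allclose(out, R, rtol=1e-9)

    def test_generic_bn_matches_folded_linear_rule_per_feature(self):
        rng = np.random.default_rng(3)
        gamma, beta = rng.standard_normal(4), rng.standard_normal(4)
        mean, var = rng.standard_normal(4), rng.random(4) + 0.5
        z_in = rng.standard_normal(4)
        R_out = rng.standard_normal(4)
        got = lrp.lrp_batchnorm(R_out, z_in, gamma, beta, mean, var, eps_bn=1e-5)[0]
        scale, shift = lrp.fold_batchnorm(gamma, beta, mean, var, 1e-5)
        for k in range(4):  # each feature is its own fan-in-1 affine layer
            want = lrp.lrp_linear(
                [R_out[k]], [z_in[k]], [z_in[k] * scale[k] + shift[k]],
                np.array([[scale[k]]]), np.array([shift[k]]), fan_in=1,
            )[0, 0]
            assert got[k] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            lrp.fold_batchnorm(np.ones(2), np.zeros(2), np.zeros(2), np.array([1.0, 0.0]))


def _direction_trace(clf, X, direction="f"):
    p = clf.params_
    if direction == "b":
        X = X[:, ::-1]
    return net._lstm_forward(X, p[f"Wx_{direction}"], p[f"Wh_{direction}"],
                             p[f"b_{direction}"], clf.config_.hidden_units)


class TestLSTMRule:
    def test_closed_forget_gate_sends_relevance_to_final_candidate(self):
        clf = make_random_bilstm(input_size=3, hidden_units=1, seed=2, zero_bias=True)
        clf.params_["b_f"][1:2] = -60.0  # forget gate ~ 0
        clf.params_["Wh_f"][:] = 0.0  # no recurrent path into the gates/candidate
        X = np.random.default_rng(0).standard_normal((2, 5, 3))
        trace = _direction_trace(clf, X)
        R_x, _ = lrp.lrp_lstm_cell(
            trace, np.ones((2, 1)), clf.params_["Wx_f"], clf.params_["Wh_f"],
            clf.params_["b_f"], lrp.LRPConfig(epsilon=1e-9),
        )
        total = np.abs(R_x).sum()
        assert np.abs(R_x[:, -1]).sum() / total > 1 - 1e-6  # all at the last step

    def test_closed_input_gate_gives_inputs_zero_relevance(self):
        clf = make_random_bilstm(input_size=3, hidden_units=1, seed=4, zero_bias=True)
        clf.params_["b_f"][0:1] = -60.0  # input gate ~ 0
        clf.params_["b_f"][1:2] = 60.0  # forget gate ~ 1
        clf.params_["Wh_f"][:] = 0.0
        X = np.random.default_rng(1).standard_normal((1, 4, 3))
        trace = _direction_trace(clf, X)
        # charge the cell chain: c constant at 1 (consistent with f=1, i=0)
        trace["cs"][:] = 1.0
        R_x, R_c0 = lrp.lrp_lstm_cell(
            trace, np.ones((1, 1)), clf.params_["Wx_f"], clf.params_["Wh_f"],
            clf.params_["b_f"],
        )
        assert np.abs(R_x).sum() < 0.01  # inputs get (almost) nothing
        assert R_c0[0, 0] == pytest.approx(1.0, abs=1e-2)  # relevance rode the chain

    def test_matches_independent_scalar_unrolling(self):
        """Signal-takes-all rule re-derived with explicit scalar loops."""
        clf = make_random_bilstm(input_size=2, hidden_units=1, seed=6)
        p = clf.params_
        rng = np.random.default_rng(7)
        X = rng.standard_normal((1, 3, 2))
        trace = _direction_trace(clf, X)
        eps = 0.001
        R_last = np.array([[0.8]])
        got, _ = lrp.lrp_lstm_cell(trace, R_last, p["Wx_f"], p["Wh_f"], p["b_f"],
                                   lrp.LRPConfig(epsilon=eps))

        Wg, Ug, bg = p["Wx_f"][:, 2:3], p["Wh_f"][:, 2:3], p["b_f"][2:3]
        cs, hs, gates = trace["cs"][0], trace["hs"][0], trace["gates"][0]
        Rc = 0.8
        want = np.zeros((3, 2))
        for t in (2, 1, 0):
            i_g, f_g = gates[t, 0], gates[t, 1]
            c_prev, c_t = cs[t, 0], cs[t + 1, 0]
            g = gates[t, 2]
            sgn = 1.0 if c_t >= 0 else -1.0
            denom = c_t + eps * sgn
            R_carry = (f_g * c_prev + eps * sgn / 2) / denom * Rc
            R_cand = (i_g * g + eps * sgn / 2) / denom * Rc
            a_g = X[0, t] @ Wg + hs[t] @ Ug + bg
            sgn_a = 1.0 if a_g[0] >= 0 else -1.0
            den_a = a_g[0] + eps * sgn_a
            Ni = 3  # two inputs + one recurrent
            R_h = 0.0
            for k in range(2):
                want[t, k] = (Wg[k, 0] * X[0, t, k] + eps * sgn_a / Ni) / den_a * R_cand
            R_h = (Ug[0, 0] * hs[t, 0] + eps * sgn_a / Ni) / den_a * R_cand
            Rc = R_carry + (R_h if t > 0 else 0.0)
        np.testing.assert_allclose(got[0], want, atol=1e-12)


@pytest.fixture(scope="module")
def directional_setup():
    clf = make_random_bilstm(input_size=5, hidden_units=4, seed=8)
    X = np.random.default_rng(9).standard_normal((3, 30, 5))
    cache = net.forward(clf.params_, X, clf.config_, train=False,
                        bn_state=clf.bn_state_)
    return clf, cache


class TestBiLSTMDirectionality:

    def test_forward_only_seeding_concentrates_late(self, directional_setup):
        clf, cache = directional_setup
        R_sum = np.zeros((3, 8))
        R_sum[:, :4] = 1.0
        R, _ = lrp.lrp_bilstm(clf.params_, cache, R_sum, 4)
        prof = np.abs(R).mean(axis=(0, 2))
        assert prof[-5:].mean() > 10 * prof[:5].mean()

    def test_backward_only_seeding_concentrates_early(self, directional_setup):
        clf, cache = directional_setup
        R_sum = np.zeros((3, 8))
        R_sum[:, 4:] = 1.0
        R, _ = lrp.lrp_bilstm(clf.params_, cache, R_sum, 4)
        prof = np.abs(R).mean(axis=(0, 2))
        assert prof[:5].mean() > 10 * prof[-5:].mean()

    def test_zero_seed_gives_zero_relevance(self, directional_setup):
        clf, cache = directional_setup
        R, _ = lrp.lrp_bilstm(clf.params_, cache, np.zeros((3, 8)), 4)
        assert np.allclose(R, 0.0)


class TestRelevanceEndToEnd:
    def test_seeded_relevance_is_softmax_probability(self):
        clf = make_random_bilstm(seed=10, bn=True)
        X = np.random.default_rng(11).standard_normal((4, 12, 6))
        rt = lrp.relevance(clf, X, target_class=1)
        cache = net.forward(clf.params_, X, clf.config_, train=False, bn_state=clf.bn_state_)
        np.testing.assert_allclose(rt.seeded_score, cache["probs"][:, 1], atol=1e-12)

    def test_conservation_bias_free_clean_limit(self):
        """Sum of input relevance equals the seeded score for a bias-free
        network as the stabilizer vanishes (relative error <= 1e-6)."""
        clf = make_random_bilstm(input_size=6, hidden_units=4, seed=12, zero_bias=True)
        X = np.random.default_rng(13).standard_normal((3, 10, 6))
        rt = lrp.relevance(clf, X, 0, lrp.LRPConfig(epsilon=1e-12, seed="logit"))
        seeded = rt.layer_sums["seeded"]
        assert abs(rt.layer_sums["input_total"] - seeded) / abs(seeded) <= 1e-6

    def test_invalid_class_rejected(self):
        clf = make_random_bilstm(seed=14)
        with pytest.raises(ValueError, match="target_class"):
            lrp.relevance(clf, np.zeros((1, 5, 6)), 7)

    def test_leakage_grows_with_epsilon(self):
        clf = make_random_bilstm(seed=15, bn=True)
        X = np.random.default_rng(16).standard_normal((1, 12, 6))
        leaks = []
        for eps in (1e-6, 1e-3, 1e-1):
            rt = lrp.relevance(clf, X, 0, lrp.LRPConfig(epsilon=eps))
            rep = lrp.conservation_report(rt)
            leaks.append(abs(rep.set_index("layer").loc["input_total", "leakage"]))
        assert leaks[2] > leaks[0]

    def test_conservation_report_layout(self):
        clf = make_random_bilstm(seed=17, bn=True)
        rt = lrp.relevance(clf, np.random.default_rng(18).standard_normal((2, 8, 6)), 2)
        rep = lrp.conservation_report(rt)
        assert list(rep["layer"]) == ["seeded", "after_fc", "after_bn", "input_total"]
        assert rep["leakage"].iloc[0] == 0.0
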