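"""Cell- and network-level checks against independent scalar oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorsep.model import gru_cell_step, network_forward
from tremorsep.model.gru import (
    GRUCellParams,
    NetworkParams,
    init_params,
    stack_backward,
    stack_forward,
)


def oracle_cell_step(x, h_prev, p, activation="relu"):
    """Independent scalar-loop evaluation of the gated recurrence."""
    H, D = p.U_r.shape
    h_new = [0.0] * H
    for i in range(H):
        ar = sum(p.U_r[i][d] * x[d] for d in range(D))
        ar += sum(p.W_r[i][j] * h_prev[j] for j in range(H)) + p.b_r[i]
        az = sum(p.U_z[i][d] * x[d] for d in range(D))
        az += sum(p.W_z[i][j] * h_prev[j] for j in range(H)) + p.b_z[i]
        r_i = 1.0 / (1.0 + math.exp(-ar))
        z_i = 1.0 / (1.0 + math.exp(-az))
        # the reset gate of every unit scales the previous state feeding W
        pre = sum(p.U[i][d] * x[d] for d in range(D)) + p.b_h[i]
        for j in range(H):
            rj_a = sum(p.U_r[j][d] * x[d] for d in range(D))
            rj_a += sum(p.W_r[j][k] * h_prev[k] for k in range(H)) + p.b_r[j]
            r_j = 1.0 / (1.0 + math.exp(-rj_a))
            pre += p.W[i][j] * (r_j * h_prev[j])
        cand = max(pre, 0.0) if activation == "relu" else math.tanh(pre)
        h_new[i] = (1.0 - z_i) * h_prev[i] + z_i * cand
    return np.array(h_new)


def random_cell(rng, H, D):
    return GRUCellParams(
        U_r=rng.standard_normal((H, D)),
        U_z=rng.standard_normal((H, D)),
        U=rng.standard_normal((H, D)),
        W_r=rng.standard_normal((H, H)),
        W_z=rng.standard_normal((H, H)),
        W=rng.standard_normal((H, H)),
        b_r=rng.standard_normal(H),
        b_z=rng.standard_normal(H),
        b_h=rng.standard_normal(H),
    )


class TestCellStep:
    def test_matches_scalar_oracle(self, rng):
        for _ in range(200):
            H = int(rng.integers(1, 5))
            D = int(rng.integers(1, 5))
            p = random_cell(rng, H, D)
            x = rng.standard_normal(D)
            h = rng.standard_normal(H)
            np.testing.assert_allclose(
                gru_cell_step(x, h, p), oracle_cell_step(x, h, p), atol=1e-6
            )

    def test_zero_weights_halve_state(self, rng):
        H = 3
        zero = GRUCellParams(*[np.zeros((H, 1))] * 3, *[np.zeros((H, H))] * 3)
        h = rng.standard_normal(H)
        # r = z = sigmoid(0) = 0.5 and the candidate is relu(0) = 0
        np.testing.assert_allclose(gru_cell_step([1.0], h, zero), 0.5 * h, atol=1e-12)

    def test_update_gate_saturation_selects_candidate(self):
        H = 2
        p = GRUCellParams(
            U_r=np.zeros((H, 1)),
            U_z=np.full((H, 1), 50.0),  # z -> 1
            U=np.ones((H, 1)),
            W_r=np.zeros((H, H)),
            W_z=np.zeros((H, H)),
            W=np.zeros((H, H)),
        )
        h = np.array([5.0, -3.0])
        out = gru_cell_step([2.0], h, p)
        np.testing.assert_allclose(out, [2.0, 2.0], atol=1e-8)  # h -> relu(U x)

    def test_frozen_update_gate_freezes_state(self):
        H = 2
        p = GRUCellParams(
            U_r=np.zeros((H, 1)),
            U_z=np.zeros((H, 1)),
            U=np.ones((H, 1)),
            W_r=np.zeros((H, H)),
            W_z=np.zeros((H, H)),
            W=np.zeros((H, H)),
            b_z=np.full(H, -50.0),  # z -> 0
        )
        h = np.array([1.5, -0.5])
        for _ in range(5):
            h_next = gru_cell_step([0.7], h, p)
            np.testing.assert_allclose(h_next, h, atol=1e-12)
            h = h_next

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_gate_ranges_and_candidate_sign(self, seed):
        """Gates live strictly inside (0, 1); the ReLU candidate keeps every
        state component's update bounded between h_prev and a nonnegative
        candidate."""
        rng = np.random.default_rng(seed)
        p = random_cell(rng, 3, 2)
        x = rng.standard_normal(2) * 5
        h = np.zeros(3)
        r = 1 / (1 + np.exp(-(p.U_r @ x + p.W_r @ h + p.b_r)))
        z = 1 / (1 + np.exp(-(p.U_z @ x + p.W_z @ h + p.b_z)))
        assert np.all((r > 0) & (r < 1)) and np.all((z > 0) & (z < 1))
        cand = np.maximum(p.U @ x + p.W @ (r * h) + p.b_h, 0.0)
        assert np.all(cand >= 0)
        np.testing.assert_allclose(
            gru_cell_step(x, h, p), (1 - z) * h + z * cand, atol=1e-10
        )


class TestNetworkForward:
    def test_output_lengths(self, rng):
        p = init_params(2, 4, rng, dtype=np.float64)
        out = network_forward(rng.uniform(0, 1, 37), p)
        assert len(out.forward_estimate) == 37
        assert len(out.backward_estimate) == 37

    def test_engine_matches_cell_iteration(self, rng):
        """The batched engine agrees with naive per-step cell iteration for
        both paths (H=4, T=10, L=2)."""
        p = init_params(2, 4, rng, dtype=np.float64)
        x = rng.uniform(0, 1, 10)
        out = network_forward(x, p)

        def run_path(cells, seq, V, c):
            h = [np.zeros(4), np.zeros(4)]
            ys = []
            for s in seq:
                inp = np.array([s])
                for k, cell in enumerate(cells):
                    h[k] = gru_cell_step(inp, h[k], cell)
                    inp = h[k]
                ys.append(float(V @ h[-1] + c[0]))
            return np.array(ys)

        fwd = run_path([l[0] for l in p.layers], x, p.V_f, p.c_f)
        bwd = run_path([l[1] for l in p.layers], x[::-1], p.V_b, p.c_b)[::-1]
        np.testing.assert_allclose(out.forward_estimate, fwd, atol=1e-10)
        np.testing.assert_allclose(out.backward_estimate, bwd, atol=1e-10)

    def test_hand_unrolled_scalar_network(self):
        """L=1, H=1, T=3 with hand-set weights matches explicit unrolling of
        the recurrence plus affine head."""
        w = dict(ur=0.3, uz=-0.2, u=0.8, wr=0.5, wz=0.4, wh=-0.6, v=1.2, c=0.1)
        cell = GRUCellParams(
            U_r=[[w["ur"]]], U_z=[[w["uz"]]], U=[[w["u"]]],
            W_r=[[w["wr"]]], W_z=[[w["wz"]]], W=[[w["wh"]]],
        )
        params = NetworkParams(
            layers=[(cell, cell)], V_f=[w["v"]], c_f=[w["c"]],
            V_b=[w["v"]], c_b=[w["c"]],
        )
        x = [0.5, -0.25, 1.0]

        def sig(a):
            return 1.0 / (1.0 + math.exp(-a))

        def step(xt, h):
            r = sig(w["ur"] * xt + w["wr"] * h)
            z = sig(w["uz"] * xt + w["wz"] * h)
            cand = max(w["u"] * xt + w["wh"] * (r * h), 0.0)
            return (1 - z) * h + z * cand

        h = 0.0
        expected_f = []
        for xt in x:
            h = step(xt, h)
            expected_f.append(w["v"] * h + w["c"])
        h = 0.0
        expected_b = []
        for xt in reversed(x):
            h = step(xt, h)
            expected_b.append(w["v"] * h + w["c"])
        expected_b = expected_b[::-1]

        out = network_forward(np.array(x), params)
        np.testing.assert_allclose(out.forward_estimate, expected_f, atol=1e-10)
        np.testing.assert_allclose(out.backward_estimate, expected_b, atol=1e-10)

    def test_forward_causality_under_perturbation(self, rng):
        p = init_params(2, 6, rng, dtype=np.float64)
        x = rng.uniform(0, 1, 30)
        base = network_forward(x, p)
        t0 = 17
        x2 = x.copy()
        x2[t0] += 0.5
        pert = network_forward(x2, p)
        np.testing.assert_array_equal(
            base.forward_estimate[:t0], pert.forward_estimate[:t0]
        )
        assert np.any(base.forward_estimate[t0:] != pert.forward_estimate[t0:])
        # the backward path is anticausal: indices after t0 are untouched
        np.testing.assert_array_equal(
            base.backward_estimate[t0 + 1 :], pert.backward_estimate[t0 + 1 :]
        )

    def test_path_independence(self, rng):
        """Zeroing every backward-path weight leaves the forward estimate
        bit-identical (no mixing between the two paths)."""
        p = init_params(2, 4, rng, dtype=np.float64)
        x = rng.uniform(0, 1, 20)
        base = network_forward(x, p)
        stripped = p.copy()
        for _, bwd in stripped.layers:
            for arr in bwd.arrays():
                arr[...] = 0.0
        stripped.V_b[...] = 0.0
        stripped.c_b[...] = 0.0
        out = network_forward(x, stripped)
        np.testing.assert_array_equal(out.forward_estimate, base.forward_estimate)
        assert np.any(out.backward_estimate != base.backward_estimate)

    def test_non_finite_input_rejected(self, rng):
        p = init_params(1, 2, rng, dtype=np.float64)
        x = np.ones(10)
        x[4] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            network_forward(x, p)


class TestBackprop:
    @pytest.mark.parametrize("activation", ["relu", "tanh"])
    def test_gradients_match_finite_differences(self, activation):
        rng = np.random.default_rng(1)
        p = init_params(2, 3, rng, activation=activation, dtype=np.float64)
        X = rng.uniform(0, 1, (2, 6))
        Y = rng.uniform(0, 1, (2, 6))

        def loss_grads(params):
            yf, yb, cache = stack_forward(X, params, need_cache=True)
            n = Y.size
            loss = 0.5 * (np.mean((yf - Y) ** 2) + np.mean((yb - Y) ** 2))
            return loss, stack_backward(params, cache, (yf - Y) / n, (yb - Y) / n)

        _, grads = loss_grads(p)
        arrays = p.arrays()
        eps = 1e-6
        for ai, a in enumerate(arrays):
            it = np.nditer(a, flags=["multi_index"])
            for _ in range(min(a.size, 4)):
                idx = it.multi_index
                orig = a[idx]
                a[idx] = orig + eps
                lp, _ = loss_grads(p)
                a[idx] = orig - eps
                lm, _ = loss_grads(p)
                a[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(numeric) + abs(grads[ai][idx]))
                assert abs(numeric - grads[ai][idx]) / denom < 1e-4
                it.iternext()

    def test_shape_validation(self, rng):
        with pytest.raises(ValueError):
            GRUCellParams(
                U_r=np.zeros((2, 1)), U_z=np.zeros((3, 1)), U=np.zeros((2, 1)),
                W_r=np.zeros((2, 2)), W_z=np.zeros((2, 2)), W=np.zeros((2, 2)),
            )
        with pytest.raises(ValueError):
            init_params(0, 4, rng)
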