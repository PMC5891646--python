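"""KAARMA core: forward recursion, gradients, quantization, training."""

import numpy as np
import pytest

from kaarma.network import KaarmaNetwork, TrainConfig


def make_random_model(rng, m=4, n_s=3, n_u=2, a_s=1.3, a_u=0.7, **kw):
    net = KaarmaNetwork(state_dim=n_s, output_dim=1, a_s=a_s, a_u=a_u, **kw)
    net._ensure_initialized()
    for _ in range(m):
        net.quantize_insert(rng.normal(size=n_s), rng.normal(size=n_u),
                            rng.normal(size=n_s), epsilon=0.0)
    return net


class TestForward:
    def test_zero_coefficients_give_zero_states(self, rng):
        net = make_random_model(rng)
        net._A[: net._m] = 0.0
        traj, y_f = net.forward(rng.normal(size=(4, 2)))
        assert np.all(traj == 0) and y_f == 0

    def test_empty_model_is_the_zero_map(self):
        net = KaarmaNetwork(state_dim=2)
        traj, y_f = net.forward(np.ones((3, 2)))
        assert np.all(traj == 0) and y_f == 0

    def test_two_step_hand_recursion(self):
        # one center (0, u*), A = [1], a_s = 1, input kernel ~ 1, s0 = 0
        net = KaarmaNetwork(state_dim=1, a_s=1.0, a_u=1e-14, s0_scale=0.0)
        net._ensure_initialized()
        net.quantize_insert([0.0], [0.0], [1.0], epsilon=0.0)
        traj, y_f = net.forward(np.zeros((2, 1)))
        assert traj[0, 0] == pytest.approx(1.0)
        assert traj[1, 0] == pytest.approx(np.exp(-1.0))
        assert y_f[0] == pytest.approx(np.exp(-1.0))

    def test_state_bounded_by_coefficient_column_sums(self, rng):
        for _ in range(10):
            net = make_random_model(rng, m=int(rng.integers(1, 6)))
            traj, _ = net.forward(rng.normal(size=(5, 2)))
            bound = np.abs(net.A_).sum(axis=0)
            assert np.all(np.abs(traj) <= bound + 1e-12)

    def test_divergence_guard_aborts_with_diagnostic(self, rng):
        net = make_random_model(rng, m=1, a_s=1e-12, a_u=1e-12)
        net._A[0] = 1e7
        with pytest.raises(RuntimeError, match="diverged"):
            net.forward(np.zeros((2, 2)))


class TestStateJacobian:
    def test_zero_coefficients_give_zero_jacobian(self, rng):
        net = make_random_model(rng)
        net._A[: net._m] = 0.0
        G = net.state_jacobian(rng.normal(size=3), rng.normal(size=2))
        assert np.all(G == 0)

    def test_hand_value_at_second_step(self):
        net = KaarmaNetwork(state_dim=1, a_s=1.0, a_u=1e-14, s0_scale=0.0)
        net._ensure_initialized()
        net.quantize_insert([0.0], [0.0], [1.0], epsilon=0.0)
        G = net.state_jacobian([1.0], [0.0])
        assert G[0, 0] == pytest.approx(-2 * np.exp(-1.0), rel=1e-9)

    def test_matches_central_differences(self, rng):
        h = 1e-6
        for _ in range(5):
            net = make_random_model(rng, m=int(rng.integers(1, 6)),
                                    n_s=int(rng.integers(1, 4)))
            n_s = net.state_dim
            s = rng.normal(size=n_s)
            u = rng.normal(size=2)
            G = net.state_jacobian(s, u)
            Gfd = np.zeros_like(G)
            for q in range(n_s):
                sp, sm = s.copy(), s.copy()
                sp[q] += h
                sm[q] -= h
                u_flat = net._flatten_input(u)
                kp = net._state_kernel(sp) * net._input_kernel_flat(u_flat)
                km = net._state_kernel(sm) * net._input_kernel_flat(u_flat)
                Gfd[:, q] = (net.A_.T @ kp - net.A_.T @ km) / (2 * h)
            assert np.abs(G - Gfd).max() <= 1e-5


class TestCoefficientJacobian:
    def test_matches_central_differences(self, rng):
        h = 1e-6
        for _ in range(5):
            n_s = int(rng.integers(1, 4))
            m = int(rng.integers(1, 6))
            f = int(rng.integers(1, 7))
            net = make_random_model(rng, m=m, n_s=n_s)
            seq = rng.normal(size=(f, 2))
            J = net.output_coefficient_jacobian(seq)
            Jfd = np.zeros_like(J)
            for j in range(m):
                for k in range(n_s):
                    net._A[j, k] += h
                    _, yp = net.forward(seq)
                    net._A[j, k] -= 2 * h
                    _, ym = net.forward(seq)
                    net._A[j, k] += h
                    Jfd[j, k] = (yp - ym) / (2 * h)
            scale = max(np.abs(Jfd).max(), 1e-8)
            assert np.abs(J - Jfd).max() / scale <= 1e-4


class TestQuantizeInsert:
    def test_identical_candidate_merges_at_any_epsilon(self, rng):
        net = make_random_model(rng, m=1)
        s = net.centers_states_[0].copy()
        u = net.centers_inputs_[0].copy()
        assert net.quantize_insert(s, u, np.ones(3), epsilon=0.0) == "merged"
        assert net.dictionary_size_ == 1

    def test_distinct_candidate_appends_at_epsilon_zero(self, rng):
        net = make_random_model(rng, m=1)
        out = net.quantize_insert(rng.normal(size=3) + 10.0,
                                  rng.normal(size=2), np.ones(3), epsilon=0.0)
        assert out == "appended" and net.dictionary_size_ == 2

    def test_worked_merge_example(self):
        # centers at states {0, 1} with identical inputs; candidate 0.9
        net = KaarmaNetwork(state_dim=1, epsilon=0.25)
        net._ensure_initialized()
        net.quantize_insert([0.0], [0.5], [1.0], epsilon=0.0)
        net.quantize_insert([1.0], [0.5], [2.0], epsilon=0.0)
        out = net.quantize_insert([0.9], [0.5], [0.25])
        assert out == "merged"
        assert net.dictionary_size_ == 2
        assert net.A_[1, 0] == pytest.approx(2.25)  # merged into center 1

    def test_tie_breaks_to_lowest_index(self):
        net = KaarmaNetwork(state_dim=1, epsilon=1.0)
        net._ensure_initialized()
        net.quantize_insert([-1.0], [0.0], [1.0], epsilon=0.0)
        net.quantize_insert([1.0], [0.0], [1.0], epsilon=0.0)
        net.quantize_insert([0.0], [0.0], [5.0])  # equidistant
        assert net.A_[0, 0] == pytest.approx(6.0)
        assert net.A_[1, 0] == pytest.approx(1.0)

    def test_huge_epsilon_keeps_dictionary_at_one(self, rng):
        net = KaarmaNetwork(state_dim=2, epsilon=1e12, eta=0.01)
        for _ in range(5):
            net.train_sequence(rng.normal(size=(4, 2)), [1.0])
        assert net.dictionary_size_ == 1

    def test_epsilon_zero_grows_by_f_per_distinct_sequence(self, rng):
        net = KaarmaNetwork(state_dim=2, epsilon=0.0, eta=0.05)
        f = 4
        for _ in range(6):
            net.train_sequence(rng.normal(size=(f, 2)), [1.0])
        expected = 6 * f - net.stats_["merged_zero_distance"]
        assert net.dictionary_size_ == expected


class TestTraining:
    def test_zero_error_leaves_coefficients_unchanged(self, rng):
        net = make_random_model(rng, m=3)
        seq = rng.normal(size=(3, 2))
        _, y_f = net.forward(seq)
        A_before = net.A_.copy()
        net.train_sequence(seq, y_f)  # target equals current output
        m = len(A_before)
        assert np.allclose(net.A_[:m], A_before)
        assert np.all(net.A_[m:] == 0)

    def test_single_step_bootstrap_example(self):
        # empty model, f = 1, d = +1: one center (s0, u1), coefficient eta
        net = KaarmaNetwork(state_dim=1, eta=0.1, epsilon=0.25, s0_scale=0.0)
        err = net.train_sequence(np.array([[0.5]]), [1.0])
        assert err == pytest.approx(1.0)
        assert net.dictionary_size_ == 1
        np.testing.assert_allclose(net.centers_states_[0], net.s0_)
        assert net.A_[0, 0] == pytest.approx(0.1)

    def test_small_step_updates_do_not_increase_error(self, rng):
        improved = 0
        trials = 100
        for _ in range(trials):
            net = make_random_model(rng, m=int(rng.integers(1, 5)),
                                    eta=1e-3, epsilon=0.0)
            seq = rng.normal(size=(int(rng.integers(1, 6)), 2))
            d = float(rng.choice([-1.0, 1.0]))
            _, y0 = net.forward(seq)
            e0 = (d - y0[0]) ** 2
            net.train_sequence(seq, [d])
            _, y1 = net.forward(seq)
            e1 = (d - y1[0]) ** 2
            improved += e1 <= e0 + 1e-12
        assert improved >= 0.95 * trials

    def test_learning_curve_non_increasing_in_the_median(self, rng):
        # median per-epoch loss over 10 seeds on a fixed small task
        curves = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = [r.normal(size=(4, 2)) for _ in range(20)]
            y = [1.0 if x.sum() > 0 else -1.0 for x in X]
            net = KaarmaNetwork(state_dim=3, a_s=1.0, a_u=0.5, eta=0.05,
                                epsilon=0.01, epochs=5)
            net.fit(X, y)
            curves.append(net.training_loss_)
        med = np.median(np.asarray(curves), axis=0)
        assert np.all(np.diff(med) <= 1e-9)

    def test_target_dimension_checked(self, rng):
        net = KaarmaNetwork(state_dim=3, output_dim=1)
        with pytest.raises(ValueError):
            net.train_sequence(rng.normal(size=(2, 2)), [1.0, -1.0])

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(eta=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epsilon=-0.1)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestSerialization:
    def test_round_trip_reproduces_predictions_exactly(self, rng, tmp_path):
        net = KaarmaNetwork(state_dim=3, a_s=1.0, a_u=0.5, eta=0.1,
                            epsilon=0.01)
        X = [rng.normal(size=(4, 2)) for _ in range(10)]
        net.fit(X, [1.0 if x.sum() > 0 else -1.0 for x in X])
        path = tmp_path / "model.json"
        net.save(path)
        back = KaarmaNetwork.load(path)
        test = [rng.normal(size=(5, 2)) for _ in range(5)]
        np.testing.assert_array_equal(net.decision_function(test),
                                      back.decision_function(test))

    def test_spike_model_round_trip(self, rng, tmp_path):
        net = KaarmaNetwork(input_kind="spike", state_dim=3,
                            frame_duration=0.025, epsilon=0.1)
        seqs = [np.sort(rng.uniform(0, 0.0249, size=(3, 2, 4)), axis=-1)
                for _ in range(4)]
        net.fit(seqs, [1.0, -1.0, 1.0, -1.0])
        path = tmp_path / "spike_model.json"
        net.save(path)
        back = KaarmaNetwork.load(path)
        np.testing.assert_array_equal(net.decision_function(seqs),
                                      back.decision_function(seqs))

    def test_unknown_container_rejected(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            KaarmaNetwork.load(path)
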