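"""The severity network: initialization, forward pass, AARE loss, training,
banding, and the disorder variant."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from audass.levels import SeverityBand
from audass.matrix import Window
from audass.network import (
    AARE_EPS,
    BAND_MIDPOINTS,
    DISORDER_HIDDEN_SIZES,
    FFNNParams,
    HIDDEN_SIZES,
    N_INPUT,
    TrainingConfig,
    _forward_batch,
    _gradients,
    aare,
    band_output,
    encode_bands,
    encode_disorder_targets,
    forward,
    nguyen_widrow_init,
    predict_disorders,
    train,
)
from audass.synth import generate_window_dataset


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _loop_forward(params, x):
    """Independent scalar-loop oracle for the forward pass."""
    h1 = []
    for j in range(params.weights[0].shape[1]):
        acc = 0.0
        for i in range(len(x)):
            acc += x[i] * params.weights[0][i, j]
        h1.append(np.tanh(acc))
    h2 = []
    for j in range(params.weights[1].shape[1]):
        acc = 0.0
        for i in range(len(h1)):
            acc += h1[i] * params.weights[1][i, j]
        h2.append(_sigmoid(acc))
    out = []
    for j in range(params.weights[2].shape[1]):
        acc = params.output_bias[j]
        for i in range(len(h2)):
            acc += h2[i] * params.weights[2][i, j]
        out.append(_sigmoid(acc))
    return np.array(out)


class TestNguyenWidrow:
    def test_row_norms_follow_scaling_rule(self):
        p = nguyen_widrow_init((N_INPUT, *HIDDEN_SIZES, 3), seed=4)
        for w, (n_in, h) in zip(p.weights,
                                [(930, 75), (75, 65), (65, 3)]):
            expected = 0.7 * h ** (1.0 / n_in)
            assert np.allclose(np.linalg.norm(w, axis=0), expected)

    def test_same_seed_identical_parameters(self):
        a = nguyen_widrow_init(seed=9)
        b = nguyen_widrow_init(seed=9)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_hidden_biases_are_zero(self):
        p = nguyen_widrow_init(seed=0)
        b1, b2 = p.hidden_biases
        assert not b1.any() and not b2.any()
        assert not p.output_bias.any()

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nguyen_widrow_init((930, 0, 65, 3), seed=0)


class TestForward:
    def test_zero_weights_give_one_half(self, toy_sizes):
        p = FFNNParams(
            weights=[np.zeros((a, b))
                     for a, b in zip(toy_sizes[:-1], toy_sizes[1:])],
            output_bias=np.zeros(toy_sizes[-1]),
        )
        assert np.allclose(forward(p, np.ones(toy_sizes[0])), 0.5)

    def test_matches_scalar_loop_oracle(self, toy_sizes, rng):
        p = nguyen_widrow_init(toy_sizes, seed=3)
        for _ in range(5):
            x = rng.normal(size=toy_sizes[0])
            assert np.allclose(forward(p, x), _loop_forward(p, x),
                               rtol=0, atol=1e-12)

    @given(st.integers(0, 10_000))
    def test_outputs_bounded_in_unit_interval(self, seed):
        p = nguyen_widrow_init((4, 2, 2, 3), seed=seed)
        x = np.random.default_rng(seed).normal(size=4) * 5
        y = forward(p, x)
        assert np.all((y > 0) & (y < 1))

    def test_dimension_mismatch_rejected(self):
        p = nguyen_widrow_init(seed=0)
        with pytest.raises(ValueError, match="930"):
            forward(p, np.zeros(929))

    def test_purity_same_input_same_output(self):
        p = nguyen_widrow_init(seed=1)
        x = np.linspace(0, 0.9, 930)
        assert np.array_equal(forward(p, x), forward(p, x))


class TestAARE:
    def test_zero_when_prediction_equals_target(self):
        assert aare(np.array([0.3, 0.7]), np.array([0.3, 0.7])) == 0.0

    def test_single_pair_hand_value(self):
        # desired 0.6, estimated 0.5 -> |0.6-0.5|/0.5 = 0.2
        assert aare(np.array([0.5]), np.array([0.6])) == pytest.approx(0.2)

    def test_mean_of_two_symmetric_pairs(self):
        pred = np.array([0.5, 0.5])
        des = np.array([0.4, 0.6])
        assert aare(pred, des) == pytest.approx(0.2)

    def test_small_denominator_clamped(self):
        # estimated 0.01 clamps to eps=0.05
        v = aare(np.array([0.01]), np.array([0.06]))
        assert v == pytest.approx(abs(0.06 - 0.01) / AARE_EPS)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aare(np.zeros(3), np.zeros(4))


class TestGradients:
    def test_analytic_matches_central_finite_differences(self, toy_sizes):
        rng = np.random.default_rng(12)
        p = nguyen_widrow_init(toy_sizes, seed=12)
        X = rng.normal(size=(6, toy_sizes[0]))
        T = rng.uniform(0.2, 0.9, size=(6, toy_sizes[-1]))
        Y = _forward_batch(p, X)[2]
        # keep clear of the |.| kink and the eps clamp
        assert np.all(np.abs(T - Y) > 1e-3) and np.all(Y > AARE_EPS + 1e-3)

        grads, gb = _gradients(p, X, T)
        h = 1e-6

        def loss():
            return aare(_forward_batch(p, X)[2], T)

        for w, g in zip(p.weights, grads):
            idx = [(0, 0), (w.shape[0] - 1, w.shape[1] - 1), (0, w.shape[1] - 1)]
            for i, j in idx:
                orig = w[i, j]
                w[i, j] = orig + h
                up = loss()
                w[i, j] = orig - h
                dn = loss()
                w[i, j] = orig
                fd = (up - dn) / (2 * h)
                assert abs(fd - g[i, j]) <= 1e-6 * max(1.0, abs(fd))
        for j in range(len(p.output_bias)):
            orig = p.output_bias[j]
            p.output_bias[j] = orig + h
            up = loss()
            p.output_bias[j] = orig - h
            dn = loss()
            p.output_bias[j] = orig
            fd = (up - dn) / (2 * h)
            assert abs(fd - gb[j]) <= 1e-6 * max(1.0, abs(fd))


class TestTraining:
    def test_loss_decreases_on_noiseless_windows(self):
        windows, targets, _ = generate_window_dataset(40, seed=5)
        cfg = TrainingConfig(max_epochs=200, seed=5)
        _, hist = train(windows, targets, cfg)
        assert hist.train_aare[-1] <= hist.train_aare[0]
        assert hist.stop_reason in ("error-target", "epoch-cap")

    def test_training_curve_is_bit_reproducible(self):
        windows, targets, _ = generate_window_dataset(30, seed=2)
        cfg = TrainingConfig(max_epochs=60, seed=3)
        p1, h1 = train(windows, targets, cfg)
        p2, h2 = train(windows, targets, cfg)
        assert h1.train_aare == h2.train_aare
        for a, b in zip(p1.weights, p2.weights):
            assert np.array_equal(a, b)

    def test_validation_history_tracked(self):
        windows, targets, _ = generate_window_dataset(30, seed=2)
        _, hist = train(windows, targets,
                        TrainingConfig(max_epochs=20, seed=1))
        assert len(hist.val_aare) == len(hist.train_aare)

    def test_per_sample_mode_runs_and_descends(self):
        windows, targets, _ = generate_window_dataset(20, seed=8)
        _, hist = train(windows, targets,
                        TrainingConfig(max_epochs=30, mode="per_sample",
                                       seed=8))
        assert hist.train_aare[-1] <= hist.train_aare[0]

    def test_targets_outside_unit_interval_rejected(self):
        windows, targets, _ = generate_window_dataset(5, seed=1)
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            train(windows, targets * 0.0, TrainingConfig(max_epochs=5))

    def test_hyperparameter_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(momentum=1.0)
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0)


class TestBandOutput:
    @pytest.mark.parametrize(
        "activation,band",
        [
            (0.0, SeverityBand.NORMAL),
            (0.149, SeverityBand.NORMAL),
            (0.15, SeverityBand.MILD),
            (0.3, SeverityBand.MODERATE),
            (0.45, SeverityBand.MODERATE),
            (0.6, SeverityBand.SEVERE),
            (0.8, SeverityBand.SEVERE),
            (0.801, SeverityBand.EXTREMELY_SEVERE),
            (0.85, SeverityBand.EXTREMELY_SEVERE),
            (1.0, SeverityBand.EXTREMELY_SEVERE),
        ],
    )
    def test_threshold_partition(self, activation, band):
        assert band_output(activation) == band

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            band_output(bad)

    def test_midpoints_band_back_to_their_band(self):
        for band, mid in BAND_MIDPOINTS.items():
            assert band_output(mid) == band

    def test_encode_bands_produces_midpoints(self):
        t = encode_bands([SeverityBand.NORMAL, SeverityBand.MODERATE,
                          SeverityBand.EXTREMELY_SEVERE])
        assert t.tolist() == [0.075, 0.45, 0.9]


class TestDisorderVariant:
    def test_zero_weight_net_resolves_ties_to_zero(self):
        sizes = (N_INPUT, *DISORDER_HIDDEN_SIZES, 3)
        p = FFNNParams(
            weights=[np.zeros((a, b)) for a, b in zip(sizes[:-1], sizes[1:])],
            output_bias=np.zeros(3),
        )
        w = Window(values=np.zeros((31, 30)))
        flags = predict_disorders(p, w)
        assert flags == {"MDD": 0, "GAD": 0, "PTSD": 0}

    def test_wrong_hidden_sizes_rejected(self):
        p = nguyen_widrow_init(seed=0)  # 75/65 variant
        with pytest.raises(ValueError, match="30, 25"):
            predict_disorders(p, Window(values=np.zeros((31, 30))))

    def test_flags_are_binary(self):
        sizes = (N_INPUT, *DISORDER_HIDDEN_SIZES, 3)
        p = nguyen_widrow_init(sizes, seed=6)
        w = Window(values=np.full((31, 30), 0.9))
        flags = predict_disorders(p, w)
        assert set(flags) == {"MDD", "GAD", "PTSD"}
        assert all(v in (0, 1) for v in flags.values())

    def test_disorder_target_encoding_straddles_threshold(self):
        t = encode_disorder_targets([[1, 0, 0]])
        assert t.tolist() == [[0.9, 0.1, 0.1]]

    def test_recovers_disorder_signature_after_training(self):
        # windows with the depression signature rows high <-> MDD positive
        rng = np.random.default_rng(0)
        from audass.synth import deterministic_window
        from audass.levels import SCALES

        windows, flags = [], []
        for i in range(60):
            mdd = i % 2 == 0
            bands = {
                s: (SeverityBand.EXTREMELY_SEVERE
                    if (mdd and s == "depression") else SeverityBand.NORMAL)
                for s in SCALES
            }
            windows.append(deterministic_window(bands))
            flags.append([int(mdd), 0, 0])
        targets = encode_disorder_targets(flags)
        sizes = (N_INPUT, *DISORDER_HIDDEN_SIZES, 3)
        params, _ = train(
            windows, targets,
            TrainingConfig(max_epochs=2000, seed=1, validation_fraction=0.0),
            layer_sizes=sizes,
        )
        pos = predict_disorders(params, windows[0])
        neg = predict_disorders(params, windows[1])
        assert pos["MDD"] == 1
        assert neg["MDD"] == 0
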