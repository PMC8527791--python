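"""Architecture construction, the dilated convolution op and the ensemble rule."""

import numpy as np
import pandas as pd
import pytest

from leafspec.models import (
    CNNConfig,
    CNNModel,
    ConvLayerSpec,
    EnsembleModel,
    PredictorModel,
    build_model,
    dilated_conv1d,
    ensemble_predict,
    load_model,
    match_plsr_range,
    receptive_field,
    save_model,
)
from leafspec.spectra import TRAIT_NAMES, SpectrumSet
from leafspec import nn


from tests_support_brute_conv import brute_force_conv


class TestDilatedConv1d:
    def test_zero_weights_give_zero_output(self):
        spec = ConvLayerSpec(out_channels=2, kernel_size=3, dilation=2)
        x = np.random.default_rng(0).random((2, 10))
        y = dilated_conv1d(x, spec, np.zeros((2, 2, 3)), np.zeros(2))
        np.testing.assert_array_equal(y, np.zeros((2, 10)))

    def test_centre_spike_identity_filter(self):
        spec = ConvLayerSpec(out_channels=1, kernel_size=5, dilation=1,
                             activation="identity")
        x = np.arange(1.0, 9.0)[None, :]
        W = np.zeros((1, 1, 5))
        W[0, 0, 2] = 1.0
        y = dilated_conv1d(x, spec, W, np.zeros(1))
        np.testing.assert_allclose(y, x)

    def test_matches_brute_force_difference_filter(self):
        spec = ConvLayerSpec(out_channels=1, kernel_size=3, dilation=2,
                             activation="identity")
        x = np.arange(1.0, 9.0)[None, :]
        W = np.array([[[1.0, 0.0, -1.0]]])
        y = dilated_conv1d(x, spec, W, np.zeros(1))
        np.testing.assert_allclose(y, brute_force_conv(x, W, np.zeros(1), 2))

    @pytest.mark.parametrize("case", range(20))
    def test_matches_brute_force_random_instances(self, case):
        rng = np.random.default_rng(case)
        C_in, C_out = rng.integers(1, 4, 2)
        k = int(rng.choice([1, 3, 5]))
        d = int(rng.integers(1, 4))
        L = int(rng.integers(k * d, 20))
        spec = ConvLayerSpec(out_channels=int(C_out), kernel_size=k, dilation=d,
                             activation="relu")
        x = rng.standard_normal((C_in, L))
        W = rng.standard_normal((C_out, C_in, k))
        B = rng.standard_normal(C_out)
        y = dilated_conv1d(x, spec, W, B)
        np.testing.assert_allclose(y, brute_force_conv(x, W, B, d, "relu"),
                                   atol=1e-6)

    def test_channel_mismatch_rejected(self):
        spec = ConvLayerSpec(out_channels=1, kernel_size=3)
        with pytest.raises(ValueError):
            dilated_conv1d(np.ones((2, 5)), spec, np.ones((1, 3, 3)), np.zeros(1))


class TestReceptiveField:
    def test_two_layer_worked_example(self):
        assert receptive_field((5, 5), (1, 2)) == 13

    def test_single_layer(self):
        assert receptive_field([5], [1]) == 5

    def test_default_stack_matches_recurrence_oracle(self):
        rf = 1
        for k, d in zip([5] * 4, [2] * 4):
            rf += (k - 1) * d
        assert receptive_field([5] * 4, [2] * 4) == rf

    def test_validation(self):
        with pytest.raises(ValueError):
            receptive_field([], [])
        with pytest.raises(ValueError):
            receptive_field([5, 5], [1])
        with pytest.raises(ValueError):
            receptive_field([5], [1], [2])


class TestBuildModel:
    def test_default_multi_task_layer_sequence(self):
        model = build_model("cnn-multi", seed=0)
        types = [type(l).__name__ for l in model.net.layers]
        assert types == (
            ["AvgPool1d"]
            + ["Conv1d", "BatchNorm1d", "ReLU"] * 4
            + ["Flatten"]
            + ["Linear", "ReLU", "Dropout"] * 2
            + ["Linear"]
        )
        convs = [l for l in model.net.layers if isinstance(l, nn.Conv1d)]
        assert [c.params["W"].shape[0] for c in convs] == [75, 150, 225, 300]
        assert all(c.dilation == 2 and c.params["W"].shape[2] == 5 for c in convs)
        assert model.net.layers[-1].params["W"].shape == (200, 10)

    def test_single_task_differs_only_in_output_size(self):
        multi = build_model("cnn-multi", seed=0)
        single = build_model("cnn-single", trait_names=("LMA",), seed=0)
        m_types = [type(l).__name__ for l in multi.net.layers]
        s_types = [type(l).__name__ for l in single.net.layers]
        assert m_types == s_types
        assert single.net.layers[-1].params["W"].shape == (200, 1)

    def test_parameter_count_matches_hand_summed_oracle(self):
        model = build_model("cnn-multi", seed=0)
        pooled = 200
        count = 0
        c_in = 1
        for c_out in (75, 150, 225, 300):
            count += 5 * c_in * c_out + c_out  # conv kernel + bias
            count += 2 * c_out                # batch-norm gamma + beta
            c_in = c_out
        width = 300 * pooled
        for fc in (800, 200):
            count += width * fc + fc
            width = fc
        count += 200 * 10 + 10
        assert model.net.parameter_count() == count

    def test_lstm_architecture(self):
        model = build_model("lstm", trait_names=("J",), seed=0)
        enc = [l for l in model.net.layers if isinstance(l, nn.LSTMEncoder)][0]
        assert enc.hidden_size == 100 and enc.num_layers == 2 and enc.bidirectional
        assert model.net.layers[-3].params["W"].shape == (200, 200)
        assert model.net.layers[-1].params["W"].shape == (200, 1)

    def test_mlp_reuses_pooled_head_without_convs(self):
        model = build_model("mlp", seed=0)
        types = [type(l).__name__ for l in model.net.layers]
        assert "Conv1d" not in types
        assert types[:2] == ["AvgPool1d", "Flatten"]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_model("transformer")

    def test_forward_deterministic_in_eval_mode(self):
        model = build_model("mlp", config=CNNConfig(
            conv_layers=(), fc_sizes=(16, 8), n_outputs=10), seed=0)
        X = np.random.default_rng(0).random((3, 2000)).astype(np.float32)
        a = model.forward(X, training=False)
        b = model.forward(X, training=False)
        np.testing.assert_array_equal(a, b)


class _StubModel(PredictorModel):
    kind = "stub"

    def __init__(self, constant, trait_names=TRAIT_NAMES):
        super().__init__(trait_names)
        self.constant = constant

    def predict_values(self, X):
        return np.full((X.shape[0], len(self.trait_names)), self.constant)

    def config_dict(self):
        return {"kind": "stub", "traits": list(self.trait_names),
                "config": {"constant": self.constant}}


class TestEnsemble:
    def _spectra(self, n=2):
        wl = np.arange(400, 2400)
        return SpectrumSet(wl, np.full((n, wl.size), 0.5),
                           [f"o{i}" for i in range(n)])

    def test_mean_of_stub_members(self):
        preds = ensemble_predict([_StubModel(10.0), _StubModel(20.0)],
                                 self._spectra())
        np.testing.assert_allclose(preds.to_numpy(), 15.0)

    def test_identical_members_equal_single(self):
        s = self._spectra()
        one = _StubModel(7.0).predict(s)
        ens = ensemble_predict([_StubModel(7.0)] * 3, s)
        pd.testing.assert_frame_equal(one, ens)

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([])

    def test_member_missing_trait_rejected(self):
        with pytest.raises(ValueError, match="gs"):
            EnsembleModel([_StubModel(1.0, trait_names=("LMA",))])


class TestMatchPlsrRange:
    def _coverage(self, lo, hi):
        wl = np.arange(lo, hi)
        return SpectrumSet(wl, np.full((1, wl.size), 0.5), ["x"])

    @pytest.mark.parametrize("hi,expected", [
        (951, (400, 900)),    # covers 400..950: [400,1000) not fully contained
        (2400, (400, 2400)),
        (1651, (400, 1000)),  # covers 400..1650: largest fully contained
        (940, (400, 900)),
        (1000, (400, 1000)),
    ])
    def test_largest_contained_range(self, hi, expected):
        assert match_plsr_range(self._coverage(400, hi)) == expected

    def test_narrow_coverage_rejected(self):
        with pytest.raises(ValueError):
            match_plsr_range(self._coverage(400, 850))


class TestPersistence:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        cfg = CNNConfig(conv_layers=(ConvLayerSpec(4), ConvLayerSpec(6)),
                        fc_sizes=(16, 8), n_outputs=10)
        model = CNNModel(cfg, seed=0)
        from leafspec.models import TargetScaler

        model.scaler = TargetScaler(np.zeros(10), np.ones(10))
        X = np.random.default_rng(0).random((2, 2000))
        expected = model.predict_values(X)
        path = tmp_path / "model.bin"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_allclose(back.predict_values(X), expected)

    def test_tampered_archive_rejected(self, tmp_path):
        import pickle

        model = _StubModel(1.0)
        path = tmp_path / "model.bin"
        save_model(model, path)
        payload = pickle.load(open(path, "rb"))
        payload["config"]["config"]["constant"] = 2.0
        pickle.dump(payload, open(path, "wb"))
        with pytest.raises(ValueError, match="hash"):
            load_model(path)
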