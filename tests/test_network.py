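import numpy as np
import pytest

from acpnet import network as net
from acpnet.autodiff import Tensor
from acpnet.encoding import batch_encode
from acpnet.synthetic import separable_fixture
from conftest import naive_conv, naive_lstm_step, small_config


# ---------------------------------------------------------------------------
# reference operations
# ---------------------------------------------------------------------------


def test_conv_branch_zero_input():
    kernels = np.random.default_rng(0).normal(size=(4, 3, 3))
    out = net.conv_branch(np.zeros((6, 5)), kernels)
    np.testing.assert_array_equal(out, 0)
    assert out.shape == (4 * 4 * 3,)


def test_conv_branch_ones_kernel_counts_ones():
    patch = np.array([[1.0, 0, 1], [0, 1, 0], [1, 1, 0]])
    out = net.conv_branch(patch, np.ones((1, 3, 3)))
    np.testing.assert_allclose(out, [patch.sum()])


def test_conv_branch_matches_naive_oracle(rng):
    for _ in range(20):
        L = int(rng.integers(5, 12))
        F = int(rng.integers(5, 21))
        k = int(rng.choice([3, 5]))
        X = rng.normal(size=(L, F))
        kernels = rng.normal(size=(int(rng.integers(1, 6)), k, k))
        np.testing.assert_allclose(net.conv_branch(X, kernels), naive_conv(X, kernels), atol=1e-5)


def test_conv_branch_input_smaller_than_kernel():
    with pytest.raises(ValueError):
        net.conv_branch(np.zeros((4, 4)), np.zeros((1, 5, 5)))


def test_lstm_step_zero_weights():
    rng = np.random.default_rng(0)
    p = net.LSTMParams.initialize(3, 4, rng)
    for f in vars(p):
        if f != "peephole":
            setattr(p, f, np.zeros_like(getattr(p, f)))
    h, c = net.lstm_step(np.zeros(4), np.zeros(3), np.zeros(3), p)
    np.testing.assert_array_equal(c, 0)
    np.testing.assert_array_equal(h, 0)  # gates 0.5 but tanh(0)=0


def test_lstm_memory_carry():
    rng = np.random.default_rng(1)
    p = net.LSTMParams.initialize(3, 4, rng)
    # force f-gate to 1 and i-gate to 0 via huge biases
    p.b_f = np.full(3, 50.0)
    p.b_i = np.full(3, -50.0)
    p.w_cf = np.zeros_like(p.w_cf)
    p.w_ci = np.zeros_like(p.w_ci)
    c_prev = np.array([0.3, -0.2, 0.9])
    _, c_t = net.lstm_step(np.zeros(4), np.zeros(3), c_prev, p)
    np.testing.assert_allclose(c_t, c_prev, atol=1e-12)


@pytest.mark.parametrize("peephole", [True, False])
def test_lstm_step_matches_scalar_oracle(peephole, rng):
    for _ in range(20):
        units, dim = int(rng.integers(1, 6)), int(rng.integers(1, 8))
        p = net.LSTMParams.initialize(units, dim, rng, peephole=peephole)
        x, h, c = rng.normal(size=dim), rng.normal(size=units), rng.normal(size=units)
        got_h, got_c = net.lstm_step(x, h, c, p)
        want_h, want_c = naive_lstm_step(x, h, c, p)
        np.testing.assert_allclose(got_h, want_h, atol=1e-7)
        np.testing.assert_allclose(got_c, want_c, atol=1e-7)


def test_lstm_encode_base_case_and_oracle(rng):
    p = net.LSTMParams.initialize(4, 20, rng)
    x = rng.normal(size=(1, 20))
    want, _ = net.lstm_step(x[0], np.zeros(4), np.zeros(4), p)
    np.testing.assert_allclose(net.lstm_encode(x, np.ones(1), p), want)
    for _ in range(10):
        L = int(rng.integers(1, 12))
        X = rng.normal(size=(L, 20))
        h, c = np.zeros(4), np.zeros(4)
        for t in range(L):
            h, c = net.lstm_step(X[t], h, c, p)
        np.testing.assert_allclose(net.lstm_encode(X, np.ones(L), p), h, atol=1e-6)


def test_lstm_encode_padding_invariant(rng):
    p = net.LSTMParams.initialize(5, 20, rng)
    X = rng.normal(size=(6, 20))
    base = net.lstm_encode(X, np.ones(6), p)
    padded = np.vstack([X, np.zeros((4, 20))])
    mask = np.r_[np.ones(6), np.zeros(4)]
    np.testing.assert_array_equal(net.lstm_encode(padded, mask, p), base)
    with pytest.raises(ValueError):
        net.lstm_encode(X, np.zeros(6), p)


def test_binary_cross_entropy_values():
    assert net.binary_cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-6)
    assert net.binary_cross_entropy(1, 0.5) == pytest.approx(np.log(2))
    assert net.binary_cross_entropy(0, 0.5) == pytest.approx(np.log(2))
    clipped = net.binary_cross_entropy(1, 0.0)
    assert np.isfinite(clipped) and clipped == pytest.approx(-np.log(net.BCE_EPS))


# ---------------------------------------------------------------------------
# trainable model: structure, equivalences, contracts
# ---------------------------------------------------------------------------


def _tiny_batch(n=12, seed=0, lengths=(8, 14)):
    return batch_encode(separable_fixture(n, seed=seed, length_range=lengths))


def test_model_conv_layer_matches_reference(rng):
    cfg = small_config(use_lstm=False, use_attention=False, dropout_rate=0.0)
    batch = _tiny_batch()
    model = net.build_model(cfg, batch.max_len)
    w = model.params["conv_seq_w"].data
    kernels = w.reshape(-1, cfg.seq_conv.kernel, cfg.seq_conv.kernel)
    out = model._conv_forward(Tensor(batch.seq_onehot), model.params["conv_seq_w"],
                              model._seq_conv_idx)
    for i in range(3):
        np.testing.assert_allclose(out.data[i], net.conv_branch(batch.seq_onehot[i], kernels),
                                   atol=1e-10)


def test_model_lstm_layer_matches_reference():
    cfg = small_config(use_cnn=False, use_attention=False, dropout_rate=0.0)
    batch = _tiny_batch()
    model = net.build_model(cfg, batch.max_len)
    p = net.LSTMParams(
        **{
            f"w_x{g}": model.params[f"lstm_seq_wx{g}"].data for g in "ifco"
        } | {
            f"w_h{g}": model.params[f"lstm_seq_wh{g}"].data for g in "ifco"
        } | {
            f"b_{g}": model.params[f"lstm_seq_b{g}"].data for g in "ifco"
        } | {
            f"w_c{g}": model.params[f"lstm_seq_wc{g}"].data for g in "ifo"
        },
        peephole=True,
    )
    out = model._lstm_forward(Tensor(batch.seq_onehot), batch.mask, "lstm_seq",
                              cfg.seq_lstm_units)
    for i in range(batch.n):
        want = net.lstm_encode(batch.seq_onehot[i], batch.mask[i], p)
        np.testing.assert_allclose(out.data[i], want, atol=1e-9)


def test_branch_pruning_strictly_reduces_parameters():
    batch = _tiny_batch()
    full = net.build_model(small_config(), batch.max_len).n_parameters
    for toggle in ("use_cnn", "use_lstm", "use_attention", "use_structure"):
        pruned = net.build_model(small_config(**{toggle: False}), batch.max_len).n_parameters
        assert pruned < full, toggle


def test_all_branches_off_rejected():
    with pytest.raises(ValueError):
        small_config(use_cnn=False, use_lstm=False, use_attention=False)


def test_structure_unavailable_downgrades():
    batch = _tiny_batch()
    model = net.build_model(small_config(), batch.max_len, structure_available=False)
    assert not model.config.use_structure
    assert "conv_struct_w" not in model.params


def test_cascade_fusion_builds_and_runs():
    batch = _tiny_batch()
    cfg = small_config(attention_fusion="cascade", dropout_rate=0.0)
    model = net.build_model(cfg, batch.max_len)
    probs, _ = model.forward(batch.seq_onehot, batch.struct_feats, batch.mask)
    assert probs.data.shape == (batch.n,)
    assert np.all((probs.data > 0) & (probs.data < 1))


def test_untrained_zeroed_head_predicts_half():
    batch = _tiny_batch()
    model = net.build_model(small_config(), batch.max_len)
    model.params["dense2_w"].data[:] = 0
    model.params["dense2_b"].data[:] = 0
    probs, _ = model.forward(batch.seq_onehot, batch.struct_feats, batch.mask)
    np.testing.assert_allclose(probs.data, 0.5)


def test_predict_proba_duplicate_record_same_score():
    batch = _tiny_batch()
    cfg = small_config(max_epochs=2, val_fraction=0.0)
    model = net.build_model(cfg, batch.max_len)
    fitted = net.train(model, batch, cfg)
    idx = np.array([0, 3, 0])
    scores = net.predict_proba(fitted, batch.subset(idx))
    assert scores[0] == scores[2]


def test_training_deterministic_same_seed():
    batch = _tiny_batch(n=16)
    cfg = small_config(max_epochs=3, seed=11)
    runs = []
    for _ in range(2):
        model = net.build_model(cfg, batch.max_len)
        runs.append(net.train(model, batch, cfg))
    assert runs[0].history == runs[1].history
    for k in runs[0].weights:
        np.testing.assert_array_equal(runs[0].weights[k], runs[1].weights[k])


def test_training_loss_decreases_on_separable_fixture():
    batch = _tiny_batch(n=24, seed=5)
    cfg = small_config(max_epochs=8, val_fraction=0.0, dropout_rate=0.0)
    fitted = net.train(net.build_model(cfg, batch.max_len), batch, cfg)
    losses = [h["train_loss"] for h in fitted.history]
    assert losses[-1] < losses[0]


def test_early_stopping_patience_zero():
    batch = _tiny_batch(n=16)
    # learning rate 0: validation loss can never improve after epoch 1
    cfg = small_config(max_epochs=50, learning_rate=0.0, early_stopping_patience=0,
                       val_fraction=0.25)
    fitted = net.train(net.build_model(cfg, batch.max_len), batch, cfg)
    assert len(fitted.history) == 2  # baseline epoch + first non-improvement


def test_padding_never_changes_predictions():
    ds = separable_fixture(10, seed=2, length_range=(8, 14))
    batch = batch_encode(ds)
    cfg = small_config(max_epochs=2, val_fraction=0.0)
    fitted = net.train(net.build_model(cfg, batch.max_len), batch, cfg)
    base = net.predict_proba(fitted, batch)
    padded = batch_encode(ds, max_len=batch.max_len + 7)
    np.testing.assert_allclose(net.predict_proba(fitted, padded), base, atol=1e-6)


def test_predict_rejects_real_residues_beyond_fitted_length():
    ds_long = separable_fixture(6, seed=3, length_range=(20, 25))
    ds_short = separable_fixture(6, seed=3, length_range=(8, 10))
    short_batch = batch_encode(ds_short)
    cfg = small_config(max_epochs=1, val_fraction=0.0)
    fitted = net.train(net.build_model(cfg, short_batch.max_len), short_batch, cfg)
    with pytest.raises(ValueError):
        net.predict_proba(fitted, batch_encode(ds_long))


def test_dropout_inactive_at_inference():
    batch = _tiny_batch()
    cfg = small_config(max_epochs=2, dropout_rate=0.45, val_fraction=0.0)
    fitted = net.train(net.build_model(cfg, batch.max_len), batch, cfg)
    p1 = net.predict_proba(fitted, batch)
    p2 = net.predict_proba(fitted, batch)
    np.testing.assert_array_equal(p1, p2)


def test_checkpoint_round_trip(tmp_path):
    batch = _tiny_batch()
    cfg = small_config(max_epochs=2)
    fitted = net.train(net.build_model(cfg, batch.max_len), batch, cfg)
    fitted.save(tmp_path / "ckpt")
    loaded = net.TrainedModel.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(net.predict_proba(loaded, batch), net.predict_proba(fitted, batch))
    assert loaded.config.to_dict() == fitted.config.to_dict()


def test_divergence_raises():
    batch = _tiny_batch()
    cfg = small_config(max_epochs=3, val_fraction=0.0)
    model = net.build_model(cfg, batch.max_len)
    model.params["dense1_w"].data[:] = np.inf  # poisoned weights -> non-finite loss
    with np.errstate(over="ignore", invalid="ignore"):
        with pytest.raises(net.TrainingDivergedError):
            net.train(model, batch, cfg)
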