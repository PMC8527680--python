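import numpy as np
import pytest

from acpnet import attention as att
from acpnet.autodiff import Tensor
from acpnet.network import ACPModel
from conftest import naive_multi_head, naive_scores, small_config


def test_scaled_scores_examples():
    Z = np.zeros((3, 4))
    np.testing.assert_array_equal(att.scaled_scores(Z, Z, 4), np.zeros((3, 3)))
    Q = np.array([[1.0, 0, 0, 0]])
    K = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
    np.testing.assert_allclose(att.scaled_scores(Q, K, 4), [[0.5, 0.0]])
    with pytest.raises(ValueError):
        att.scaled_scores(np.zeros((2, 3)), np.zeros((2, 4)), 4)


def test_scaled_scores_matches_loop_oracle(rng):
    for _ in range(20):
        n, d = rng.integers(1, 8, size=2)
        Q, K = rng.normal(size=(n, d)), rng.normal(size=(n, d))
        np.testing.assert_allclose(att.scaled_scores(Q, K, 20), naive_scores(Q, K, 20), atol=1e-9)


def test_attention_weights_examples():
    np.testing.assert_allclose(att.attention_weights(np.array([0.0, 0.0])), [0.5, 0.5])
    w = att.attention_weights(np.array([5.0, 100.0]), mask=np.array([1.0, 0.0]))
    np.testing.assert_allclose(w, [1.0, 0.0])
    with pytest.raises(ValueError):
        att.attention_weights(np.zeros(3), mask=np.zeros(3))


def test_attention_weights_rows_sum_to_one(rng):
    for _ in range(50):
        n = int(rng.integers(2, 9))
        scores = rng.normal(scale=5, size=(n, n))
        mask = (rng.random(n) < 0.7).astype(float)
        if not mask.any():
            mask[0] = 1.0
        w = att.attention_weights(scores, mask)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
        assert w[:, mask == 0].max(initial=0.0) < 1e-6


def test_single_head_identity_and_zero():
    S = np.array([[0.3, -1.2, 0.5]])
    eye = np.eye(3)
    out, w = att.single_head(S, eye, eye, eye, d_w=3)
    np.testing.assert_allclose(out, S)  # softmax over one key is 1
    np.testing.assert_allclose(w, [[1.0]])
    out, _ = att.single_head(np.zeros((4, 3)), eye, eye, eye, d_w=3)
    np.testing.assert_array_equal(out, 0)


def test_multi_head_identity_composition():
    S = np.random.default_rng(0).normal(size=(1, 4))
    params = att.AttentionParams(h=1, d_w=4, w_q=np.eye(4)[None], w_k=np.eye(4)[None],
                                 w_v=np.eye(4)[None], w_m=np.eye(4))
    out = att.multi_head_self_attention(S, params)
    np.testing.assert_allclose(out.enhanced, S, atol=1e-12)


@pytest.mark.parametrize("h", [1, 2, 4])
def test_multi_head_matches_scalar_oracle(h, rng):
    for trial in range(10):
        n = int(rng.integers(2, 10))
        S = rng.normal(size=(n, 20))
        mask = np.ones(n)
        mask[rng.random(n) < 0.3] = 0.0
        if not mask.any():
            mask[0] = 1.0
        params = att.AttentionParams.initialize(h=h, d_w=20, seed=int(rng.integers(1 << 30)))
        got = att.multi_head_self_attention(S, params, mask)
        want_enh, want_w = naive_multi_head(S, params, mask)
        np.testing.assert_allclose(got.enhanced, want_enh, atol=1e-6)
        np.testing.assert_allclose(got.weights, want_w, atol=1e-6)


def test_multi_head_output_shape_h2():
    S = np.random.default_rng(1).normal(size=(7, 20))
    params = att.AttentionParams.initialize(h=2, d_w=20, seed=0)
    assert params.d_head == 10
    out = att.multi_head_self_attention(S, params)
    assert out.enhanced.shape == (7, 20)
    assert out.weights.shape == (2, 7, 7)


def test_permutation_equivariance(rng):
    n = 8
    S = rng.normal(size=(n, 20))
    params = att.AttentionParams.initialize(h=2, d_w=20, seed=3)
    perm = rng.permutation(n)
    out = att.multi_head_self_attention(S, params).enhanced
    out_perm = att.multi_head_self_attention(S[perm], params).enhanced
    np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)


def test_d_w_not_divisible_rejected():
    with pytest.raises(ValueError):
        att.AttentionParams.initialize(h=3, d_w=20, seed=0)


def test_head_disagreement_penalty_cases(rng):
    a = rng.normal(size=(4, 5))
    assert att.head_disagreement_penalty([a, a.copy()]) == pytest.approx(1.0)
    x = np.zeros((2, 2))
    y = np.zeros((2, 2))
    x[0, 0] = 1.0
    y[1, 1] = 1.0
    assert att.head_disagreement_penalty([x, y]) == pytest.approx(0.0)
    assert att.head_disagreement_penalty([a]) == 0.0
    assert att.head_disagreement_penalty([np.zeros((3, 3)), np.ones((3, 3))]) == 0.0


def test_network_attention_layer_matches_functional(rng):
    """The differentiable attention inside the model equals the numpy module."""
    cfg = small_config(use_cnn=False, use_lstm=False, dropout_rate=0.0)
    model = ACPModel(cfg, max_len=9)
    params = model.attention_params()
    for _ in range(5):
        n = 3
        seq = rng.normal(size=(n, 9, 20))
        mask = np.ones((n, 9))
        mask[0, 6:] = 0
        mask[2, 4:] = 0
        enhanced, _ = model._attention_forward(Tensor(seq), mask)
        for i in range(n):
            want = att.multi_head_self_attention(seq[i], params, mask[i]).enhanced
            np.testing.assert_allclose(enhanced.data[i], want, atol=1e-8)


def test_trained_attention_localizes_enriched_residues():
    """After training on compositionally tilted data, positives' enriched
    residues receive more attention mass than the uniform 1/L baseline
    (aggregated over 3 seeded runs)."""
    import acpnet as ap
    from acpnet.encoding import one_hot_encode
    from acpnet.synthetic import POS_ENRICHED

    ratios = []
    for seed in (1, 2, 3):
        ds = ap.generate_dataset(ap.SyntheticSpec(n_pos=60, n_neg=60, effect=2.0,
                                                  seed=seed, length_range=(10, 30)))
        batch = ap.batch_encode(ds)
        cfg = small_config(max_epochs=12, seed=seed)
        fitted = ap.train(ap.build_model(cfg, batch.max_len), batch, cfg)
        params = fitted.rebuild().attention_params()
        for rec in ds.records:
            if rec.label != 1:
                continue
            L = len(rec.sequence)
            onehot, mask = one_hot_encode(rec.sequence, L)
            w = att.multi_head_self_attention(onehot, params, mask).weights
            share = w.mean(axis=0).sum(axis=0) / L  # received mass share per residue
            flag = np.array([aa in POS_ENRICHED for aa in rec.sequence])
            if flag.any():
                ratios.append(share[flag].mean() * L)  # 1.0 = uniform baseline
    assert np.mean(ratios) > 1.0


def test_export_weights_tsv(tmp_path, rng):
    S = rng.normal(size=(4, 20))
    params = att.AttentionParams.initialize(h=2, d_w=20, seed=1)
    out = att.multi_head_self_attention(S, params)
    path = tmp_path / "weights.tsv"
    att.export_attention_weights(["pep1"], [out.weights], [4], path)
    rows = path.read_text().strip().splitlines()
    assert rows[0].split("\t") == ["id", "head", "query_position", "key_position", "weight"]
    assert len(rows) == 1 + 2 * 4 * 4
    # each (head, query) group sums to 1
    import collections

    sums = collections.defaultdict(float)
    for line in rows[1:]:
        pid, head, q, k, w = line.split("\t")
        sums[(head, q)] += float(w)
    assert all(abs(s - 1.0) < 1e-6 for s in sums.values())
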