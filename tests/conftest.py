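import numpy as np
import pytest

from acpnet.network import ModelConfig


def small_config(**overrides) -> ModelConfig:
    """A narrow but architecturally complete configuration for fast tests.

    All five branches (sequence/structure CNN, sequence/structure LSTM,
    attention skip) are present; only widths and epoch counts are reduced.
    """
    base = dict(
        seq_conv={"n_kernels": 8, "kernel": 5},
        struct_conv={"n_kernels": 4, "kernel": 3},
        seq_lstm_units=8,
        struct_lstm_units=4,
        heads=2,
        dense_hidden=16,
        dropout_rate=0.45,
        learning_rate=3e-3,
        max_epochs=10,
        batch_size=32,
        early_stopping_patience=3,
        val_fraction=0.1,
        seed=0,
    )
    base.update(overrides)
    return ModelConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent scalar-loop oracles (kept free of the library's vector paths)
# ---------------------------------------------------------------------------


def naive_scores(Q, K, d_w):
    n, d = Q.shape
    m = K.shape[0]
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for r in range(d):
                s += Q[i, r] * K[j, r]
            out[i, j] = s / np.sqrt(d_w)
    return out


def naive_softmax_masked(row, mask):
    valid = [j for j in range(len(row)) if mask[j] > 0]
    mx = max(row[j] for j in valid)
    e = np.zeros(len(row))
    for j in valid:
        e[j] = np.exp(row[j] - mx)
    return e / e.sum()


def naive_multi_head(S, params, mask):
    """Pure-loop reference for multi-head self-attention (enhanced, weights)."""
    n = S.shape[0]
    heads, weight_stack = [], []
    for i in range(params.h):
        Q = naive_matmul(S, params.w_q[i].T)
        K = naive_matmul(S, params.w_k[i].T)
        V = naive_matmul(S, params.w_v[i].T)
        scores = naive_scores(Q, K, params.d_w)
        W = np.zeros((n, n))
        for q in range(n):
            if mask[q] > 0:
                W[q] = naive_softmax_masked(scores[q], mask)
            else:
                valid = mask > 0
                W[q] = valid / valid.sum()
        head = naive_matmul(W, V)
        weight_stack.append(W * mask[:, None])
        heads.append(head)
    concat = np.concatenate(heads, axis=1)
    enhanced = naive_matmul(concat, params.w_m.T) * mask[:, None]
    return enhanced, np.stack(weight_stack)


def naive_matmul(A, B):
    n, k = A.shape
    k2, m = B.shape
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for r in range(k):
                s += A[i, r] * B[r, j]
            out[i, j] = s
    return out


def naive_conv(X, kernels):
    """Quadruple-loop valid 2-D convolution + ReLU, flattened patch-major."""
    n_k, kh, kw = kernels.shape
    L, F = X.shape
    out_h, out_w = L - kh + 1, F - kw + 1
    feats = np.zeros((out_h * out_w, n_k))
    p = 0
    for i in range(out_h):
        for j in range(out_w):
            for kk in range(n_k):
                s = 0.0
                for a in range(kh):
                    for b in range(kw):
                        s += kernels[kk, a, b] * X[i + a, j + b]
                feats[p, kk] = max(s, 0.0)
            p += 1
    return feats.ravel()


def naive_lstm_step(x, h, c, p):
    """Per-element scalar reference of the peephole recurrence."""
    U = p.units

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    def lin(W_x, W_h, W_c, b, c_ref):
        pre = np.zeros(U)
        for u in range(U):
            s = b[u]
            for m in range(len(x)):
                s += W_x[u, m] * x[m]
            for m in range(U):
                s += W_h[u, m] * h[m]
            if W_c is not None and p.peephole:
                for m in range(U):
                    s += W_c[u, m] * c_ref[m]
            pre[u] = s
        return pre

    i_t = sig(lin(p.w_xi, p.w_hi, p.w_ci, p.b_i, c))
    f_t = sig(lin(p.w_xf, p.w_hf, p.w_cf, p.b_f, c))
    c_t = f_t * c + i_t * np.tanh(lin(p.w_xc, p.w_hc, None, p.b_c, c))
    o_t = sig(lin(p.w_xo, p.w_ho, p.w_co, p.b_o, c_t))
    return o_t * np.tanh(c_t), c_t
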