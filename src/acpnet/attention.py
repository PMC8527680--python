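"""Multi-head scaled dot-product self-attention over one-hot peptide encodings.

The sequence representation S (n residues x d_w features, d_w = 20 for raw
one-hot input) attends to itself: per head i, Query/Key/Value are the linear
projections S @ W_q[i].T etc. with W in R^{(d_w/h) x d_w}; similarity scores
are (Q K^T)/sqrt(d_w), softmax-normalized per query over *valid* (unpadded)
key positions, and applied to V.  Head outputs are concatenated back to width
d_w and mixed by the square output matrix W_m, yielding the enhanced
representation S' in R^{n x d_w}.

No positional encoding is used, so the map is permutation-equivariant over
valid positions.  The scaling denominator uses the full model width d_w (not
the per-head width); this is configurable at call sites that need otherwise.

This module is the plain-numpy reference used for weight export and for
cross-checking the differentiable layer in :mod:`acpnet.network`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import glorot_uniform

#: Additive pre-softmax surrogate for -inf at masked key positions.
MASK_NEG = 1e9


@dataclass
class AttentionParams:
    """Learnable parameters for h-head self-attention at model width d_w.

    w_q, w_k, w_v each stack h matrices of shape (d_w/h, d_w); w_m is
    (d_w, d_w).  head_reg_weight scales the inter-head disagreement penalty
    added to the training loss (0 disables it).
    """

    h: int
    d_w: int
    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_m: np.ndarray
    head_reg_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.d_w % self.h != 0:
            raise ValueError(f"d_w={self.d_w} not divisible by h={self.h}")
        d_head = self.d_w // self.h
        for name, w in (("w_q", self.w_q), ("w_k", self.w_k), ("w_v", self.w_v)):
            w = np.asarray(w, dtype=float)
            if w.shape != (self.h, d_head, self.d_w):
                raise ValueError(f"{name} must have shape {(self.h, d_head, self.d_w)}, got {w.shape}")
            if not np.all(np.isfinite(w)):
                raise ValueError(f"{name} contains non-finite values")
        if np.asarray(self.w_m).shape != (self.d_w, self.d_w):
            raise ValueError(f"w_m must be ({self.d_w}, {self.d_w})")

    @property
    def d_head(self) -> int:
        return self.d_w // self.h

    @classmethod
    def initialize(cls, h: int = 2, d_w: int = 20, seed: int = 0, head_reg_weight: float = 0.0):
        """Seeded Glorot-uniform initialization; each head gets its own draw."""
        rng = np.random.default_rng(seed)
        d_head = d_w // h
        w_q = np.stack([glorot_uniform(rng, (d_head, d_w)) for _ in range(h)])
        w_k = np.stack([glorot_uniform(rng, (d_head, d_w)) for _ in range(h)])
        w_v = np.stack([glorot_uniform(rng, (d_head, d_w)) for _ in range(h)])
        w_m = glorot_uniform(rng, (d_w, d_w))
        return cls(h=h, d_w=d_w, w_q=w_q, w_k=w_k, w_v=w_v, w_m=w_m, head_reg_weight=head_reg_weight)


@dataclass
class AttentionOutput:
    """Enhanced representation S' (n x d_w) plus per-head attention weights (h x n x n)."""

    enhanced: np.ndarray
    weights: np.ndarray


def scaled_scores(Q: np.ndarray, K: np.ndarray, d_w: int) -> np.ndarray:
    """Similarity scores (Q K^T) / sqrt(d_w)."""
    Q = np.asarray(Q, dtype=float)
    K = np.asarray(K, dtype=float)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"Q and K feature widths differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if d_w <= 0:
        raise ValueError("d_w must be positive")
    return (Q @ K.T) / np.sqrt(float(d_w))


def attention_weights(scores: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Row-wise softmax of scores over valid key positions.

    Masked key columns receive (numerically) zero mass via an additive
    large-negative surrogate before the softmax.  Rows belonging to masked
    *query* positions are defined as uniform over the valid keys (callers zero
    them downstream).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[-1]
    if mask is None:
        mask = np.ones(n)
    mask = np.asarray(mask, dtype=float)
    if not mask.any():
        raise ValueError("all positions masked: attention undefined")
    shifted = scores - MASK_NEG * (1.0 - mask)
    shifted = shifted - shifted.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    w = e / e.sum(axis=-1, keepdims=True)
    # self-attention case (square weights): masked-query rows -> uniform over valid keys
    valid = mask > 0
    if w.ndim == 2 and w.shape[0] == mask.shape[0]:
        w[~valid] = valid / valid.sum()
    return w


def single_head(
    S: np.ndarray,
    w_q: np.ndarray,
    w_k: np.ndarray,
    w_v: np.ndarray,
    mask: np.ndarray | None = None,
    d_w: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One attention head: returns (head output n x d_head, weights n x n)."""
    S = np.asarray(S, dtype=float)
    if d_w is None:
        d_w = S.shape[-1]
    Q = S @ w_q.T
    K = S @ w_k.T
    V = S @ w_v.T
    w = attention_weights(scaled_scores(Q, K, d_w), mask)
    return w @ V, w


def multi_head_self_attention(
    S: np.ndarray,
    params: AttentionParams,
    mask: np.ndarray | None = None,
) -> AttentionOutput:
    """Full multi-head self-attention: concatenated heads mixed by W_m.

    W_m is applied per position to the concatenated head vector (the output
    matrix left-multiplies each column vector, i.e. enhanced = concat @ W_m.T),
    keeping the output width d_w.  Masked query rows of S' are zeroed.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.shape[1] != params.d_w:
        raise ValueError(f"S width {S.shape[1]} != params.d_w {params.d_w}")
    if mask is None:
        mask = np.ones(n)
    mask = np.asarray(mask, dtype=float)

    outs, weights = [], []
    for i in range(params.h):
        head, w = single_head(S, params.w_q[i], params.w_k[i], params.w_v[i], mask, params.d_w)
        outs.append(head)
        weights.append(w * mask[:, None])  # zero mass emitted by masked queries
    concat = np.concatenate(outs, axis=1)
    enhanced = concat @ params.w_m.T
    enhanced = enhanced * mask[:, None]
    return AttentionOutput(enhanced=enhanced, weights=np.stack(weights))


def head_disagreement_penalty(head_outputs: list[np.ndarray]) -> float:
    """Mean pairwise cosine similarity of flattened head outputs.

    Encourages heads to span different subspaces when added to the loss.
    Returns 0 for a single head or when any pair involves an all-zero head.
    """
    if len(head_outputs) < 2:
        return 0.0
    flats = [np.asarray(h, dtype=float).ravel() for h in head_outputs]
    sims = []
    for i in range(len(flats)):
        for j in range(i + 1, len(flats)):
            ni, nj = np.linalg.norm(flats[i]), np.linalg.norm(flats[j])
            sims.append(0.0 if ni == 0 or nj == 0 else float(flats[i] @ flats[j] / (ni * nj)))
    return float(np.mean(sims))


def export_attention_weights(
    ids: list[str],
    weight_stacks: list[np.ndarray],
    lengths: list[int],
    path: str | Path,
) -> None:
    """Write per-peptide attention weights as TSV for residue-importance plots.

    Columns: id, head, query_position, key_position, weight (positions
    1-based, valid residues only).  Each (id, head, query) row group sums to 1.
    """
    with open(path, "w") as fh:
        fh.write("id\thead\tquery_position\tkey_position\tweight\n")
        for pid, weights, L in zip(ids, weight_stacks, lengths):
            for head in range(weights.shape[0]):
                for q in range(L):
                    for k in range(L):
                        fh.write(f"{pid}\t{head + 1}\t{q + 1}\t{k + 1}\t{weights[head, q, k]:.8g}\n")
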