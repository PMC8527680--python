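"""The peptide classifier: parallel CNN+LSTM branches with an attention skip.

Architecture
------------
Two parallel CNN+LSTM composite branch pairs extract features from the one-hot
sequence plane (L x 20) and the secondary-structure plane (L x 3) separately,
so the two information sources do not cross-talk before fusion:

* sequence CNN: 300 kernels of 5x5, 'valid' 2-D convolution, ReLU, no pooling
  (peptides are short; pooling would discard local detail), flattened;
* structure CNN: 150 kernels of 3x3, same treatment;
* sequence LSTM: 45 units; structure LSTM: 20 units (peephole gates, last
  valid hidden state);
* multi-head self-attention over the one-hot sequence, fused by *skip
  connection*: the enhanced representation S' is flattened and concatenated
  directly with the four branch outputs (``attention_fusion='cascade'``
  instead feeds S' through the sequence CNN/LSTM branches).

The concatenated features pass through a dense ReLU layer, dropout (rate
0.45, training only) and a single sigmoid unit.  Training minimizes binary
cross-entropy with Adam, optional inter-head disagreement regularization,
and early stopping on validation loss.

Convolutions carry no bias term, so zero padding rows contribute exactly
nothing to any feature — together with key masking in attention and masked
state updates in the LSTM this makes predictions invariant to appended
padding.

The module exposes both plain-numpy reference operations (``conv_branch``,
``lstm_step``, ``lstm_encode``, ``binary_cross_entropy``) and the trainable
autodiff model built from the same arithmetic.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .attention import MASK_NEG, AttentionParams
from .autodiff import Adam, Tensor, concat, glorot_uniform
from .encoding import EncodedBatch

logger = logging.getLogger(__name__)

BCE_EPS = 1e-7
CHECKPOINT_VERSION = 1


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ConvSpec:
    n_kernels: int
    kernel: int


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference architecture: 300/150 convolution kernels of
    size 5x5/3x3 for the sequence/structure branches, 45/20 LSTM units, 2
    attention heads, dropout 0.45, Adam, early stopping on validation loss.
    """

    seq_conv: ConvSpec = field(default_factory=lambda: ConvSpec(300, 5))
    struct_conv: ConvSpec = field(default_factory=lambda: ConvSpec(150, 3))
    seq_lstm_units: int = 45
    struct_lstm_units: int = 20
    heads: int = 2
    head_reg_weight: float = 0.0
    dropout_rate: float = 0.45
    dense_hidden: int = 64
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    max_epochs: int = 200
    batch_size: int = 32
    early_stopping_patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    use_cnn: bool = True
    use_lstm: bool = True
    use_attention: bool = True
    use_structure: bool = True
    attention_fusion: str = "skip"  # or "cascade"
    peephole: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.seq_conv, dict):
            self.seq_conv = ConvSpec(**self.seq_conv)
        if isinstance(self.struct_conv, dict):
            self.struct_conv = ConvSpec(**self.struct_conv)
        if isinstance(self.betas, list):
            self.betas = tuple(self.betas)
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.attention_fusion not in ("skip", "cascade"):
            raise ValueError("attention_fusion must be 'skip' or 'cascade'")
        for name in ("seq_lstm_units", "struct_lstm_units", "heads", "dense_hidden",
                     "max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.use_cnn or self.use_lstm or self.use_attention):
            raise ValueError("all branches toggled off: nothing to train")
        if 20 % self.heads != 0:
            raise ValueError(f"model width 20 not divisible by heads={self.heads}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["betas"] = list(self.betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# plain-numpy reference operations
# ---------------------------------------------------------------------------


def conv_branch(X: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Single-channel 2-D 'valid' convolution + ReLU, flattened to one vector.

    ``X`` is an (L, F) plane, ``kernels`` an (n_k, k, k) stack.  Output length
    is (L-k+1) * (F-k+1) * n_k, ordered (patch-major, kernel-minor) to match
    the trainable layer's flattening.
    """
    X = np.asarray(X, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    n_k, kh, kw = kernels.shape
    L, F = X.shape
    if L < kh or F < kw:
        raise ValueError(f"input {X.shape} smaller than kernel {kh}x{kw}")
    out_h, out_w = L - kh + 1, F - kw + 1
    feats = np.empty((out_h * out_w, n_k))
    flat_k = kernels.reshape(n_k, -1)
    p = 0
    for i in range(out_h):
        for j in range(out_w):
            patch = X[i : i + kh, j : j + kw].ravel()
            feats[p] = flat_k @ patch
            p += 1
    return np.maximum(feats, 0.0).ravel()


@dataclass
class LSTMParams:
    """Peephole LSTM weights for gates i (input), f (forget), o (output) and
    the cell candidate c.  Peephole matrices act on the cell state: W_ci and
    W_cf see c_{t-1}, W_co sees the freshly updated c_t."""

    w_xi: np.ndarray
    w_hi: np.ndarray
    w_ci: np.ndarray
    b_i: np.ndarray
    w_xf: np.ndarray
    w_hf: np.ndarray
    w_cf: np.ndarray
    b_f: np.ndarray
    w_xc: np.ndarray
    w_hc: np.ndarray
    b_c: np.ndarray
    w_xo: np.ndarray
    w_ho: np.ndarray
    w_co: np.ndarray
    b_o: np.ndarray
    peephole: bool = True

    @property
    def units(self) -> int:
        return self.w_xi.shape[0]

    @classmethod
    def initialize(cls, units: int, input_dim: int, rng: np.random.Generator,
                   peephole: bool = True) -> "LSTMParams":
        def wx():
            return glorot_uniform(rng, (units, input_dim))

        def wh():
            return glorot_uniform(rng, (units, units))

        return cls(
            w_xi=wx(), w_hi=wh(), w_ci=wh(), b_i=np.zeros(units),
            w_xf=wx(), w_hf=wh(), w_cf=wh(), b_f=np.zeros(units),
            w_xc=wx(), w_hc=wh(), b_c=np.zeros(units),
            w_xo=wx(), w_ho=wh(), w_co=wh(), b_o=np.zeros(units),
            peephole=peephole,
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMParams
) -> tuple[np.ndarray, np.ndarray]:
    """One recurrence step of the (peephole) LSTM; returns (h_t, c_t)."""
    p = params
    peep = 1.0 if p.peephole else 0.0
    i_t = _sigmoid(p.w_xi @ x_t + p.w_hi @ h_prev + peep * (p.w_ci @ c_prev) + p.b_i)
    f_t = _sigmoid(p.w_xf @ x_t + p.w_hf @ h_prev + peep * (p.w_cf @ c_prev) + p.b_f)
    c_t = f_t * c_prev + i_t * np.tanh(p.w_xc @ x_t + p.w_hc @ h_prev + p.b_c)
    o_t = _sigmoid(p.w_xo @ x_t + p.w_ho @ h_prev + peep * (p.w_co @ c_t) + p.b_o)
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


def lstm_encode(X: np.ndarray, mask: np.ndarray, params: LSTMParams) -> np.ndarray:
    """Left-to-right recurrence over valid timesteps; returns the last valid h.

    Masked (padding) timesteps leave the state untouched, so appending padding
    never changes the result.
    """
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if not mask.any():
        raise ValueError("lstm_encode needs at least one valid timestep")
    h = np.zeros(params.units)
    c = np.zeros(params.units)
    for t in range(X.shape[0]):
        if mask[t] > 0:
            h, c = lstm_step(X[t], h, c, params)
    return h


def binary_cross_entropy(t, p) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    t = np.asarray(t, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), BCE_EPS, 1.0 - BCE_EPS)
    return float(np.mean(-((1.0 - t) * np.log(1.0 - p) + t * np.log(p))))


# ---------------------------------------------------------------------------
# trainable model (autodiff)
# ---------------------------------------------------------------------------


def _conv_patch_indices(L: int, F: int, k: int) -> np.ndarray:
    """Flat im2col gather indices: (n_patches, k*k) into a flattened (L*F) plane."""
    out_h, out_w = L - k + 1, F - k + 1
    idx = np.empty((out_h * out_w, k * k), dtype=np.intp)
    p = 0
    for i in range(out_h):
        for j in range(out_w):
            rows = (np.arange(i, i + k)[:, None] * F) + np.arange(j, j + k)[None, :]
            idx[p] = rows.ravel()
            p += 1
    return idx


class ACPModel:
    """Untrained/trainable classifier; parameters live in ``self.params``."""

    def __init__(self, config: ModelConfig, max_len: int, structure_available: bool = True):
        if config.use_structure and not structure_available:
            logger.warning("structure branches requested but no profiles available; disabling them")
            config = copy.deepcopy(config)
            config.use_structure = False
        self.config = config
        self.max_len = int(max_len)
        if config.use_cnn and self.max_len < config.seq_conv.kernel:
            raise ValueError(
                f"max_len {max_len} smaller than sequence kernel {config.seq_conv.kernel}"
            )
        self.d_w = 20
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        self._init_params(rng)

    # -- parameters -------------------------------------------------------

    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        L = self.max_len
        feat_dim = 0

        if cfg.use_attention:
            d_head = self.d_w // cfg.heads
            for i in range(cfg.heads):
                self._add(f"att_wq{i}", glorot_uniform(rng, (d_head, self.d_w)))
                self._add(f"att_wk{i}", glorot_uniform(rng, (d_head, self.d_w)))
                self._add(f"att_wv{i}", glorot_uniform(rng, (d_head, self.d_w)))
            self._add("att_wm", glorot_uniform(rng, (self.d_w, self.d_w)))
            if cfg.attention_fusion == "skip":
                feat_dim += L * self.d_w

        if cfg.use_cnn:
            k = cfg.seq_conv.kernel
            self._add("conv_seq_w", glorot_uniform(rng, (cfg.seq_conv.n_kernels, k * k)))
            self._seq_conv_idx = _conv_patch_indices(L, self.d_w, k)
            feat_dim += self._seq_conv_idx.shape[0] * cfg.seq_conv.n_kernels
            if cfg.use_structure:
                k2 = cfg.struct_conv.kernel
                self._add("conv_struct_w", glorot_uniform(rng, (cfg.struct_conv.n_kernels, k2 * k2)))
                self._struct_conv_idx = _conv_patch_indices(L, 3, k2)
                feat_dim += self._struct_conv_idx.shape[0] * cfg.struct_conv.n_kernels

        if cfg.use_lstm:
            self._init_lstm("lstm_seq", cfg.seq_lstm_units, self.d_w, rng)
            feat_dim += cfg.seq_lstm_units
            if cfg.use_structure:
                self._init_lstm("lstm_struct", cfg.struct_lstm_units, 3, rng)
                feat_dim += cfg.struct_lstm_units

        if feat_dim == 0:
            raise ValueError("all branches toggled off: empty feature vector")
        self.feature_dim = feat_dim
        self._add("dense1_w", glorot_uniform(rng, (cfg.dense_hidden, feat_dim)))
        self._add("dense1_b", np.zeros(cfg.dense_hidden))
        self._add("dense2_w", glorot_uniform(rng, (1, cfg.dense_hidden)))
        self._add("dense2_b", np.zeros(1))

    def _init_lstm(self, prefix: str, units: int, input_dim: int, rng: np.random.Generator) -> None:
        for gate in ("i", "f", "c", "o"):
            self._add(f"{prefix}_wx{gate}", glorot_uniform(rng, (units, input_dim)))
            self._add(f"{prefix}_wh{gate}", glorot_uniform(rng, (units, units)))
            self._add(f"{prefix}_b{gate}", np.zeros(units))
        if self.config.peephole:
            for gate in ("i", "f", "o"):
                self._add(f"{prefix}_wc{gate}", glorot_uniform(rng, (units, units)))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()

    def attention_params(self) -> AttentionParams:
        """Export the current attention weights as an :class:`AttentionParams`."""
        cfg = self.config
        if not cfg.use_attention:
            raise ValueError("model has no attention branch")
        return AttentionParams(
            h=cfg.heads,
            d_w=self.d_w,
            w_q=np.stack([self.params[f"att_wq{i}"].data for i in range(cfg.heads)]),
            w_k=np.stack([self.params[f"att_wk{i}"].data for i in range(cfg.heads)]),
            w_v=np.stack([self.params[f"att_wv{i}"].data for i in range(cfg.heads)]),
            w_m=self.params["att_wm"].data,
            head_reg_weight=cfg.head_reg_weight,
        )

    # -- forward ----------------------------------------------------------

    def _attention_forward(self, seq: Tensor, mask: np.ndarray) -> tuple[Tensor, list[Tensor]]:
        """Batched masked multi-head self-attention; returns (S', head outputs)."""
        cfg = self.config
        n, L = mask.shape
        key_bias = Tensor((mask[:, None, :] - 1.0) * MASK_NEG)  # (N, 1, L)
        qmask = Tensor(mask[:, :, None])  # (N, L, 1)
        scale = 1.0 / np.sqrt(float(self.d_w))
        heads = []
        for i in range(cfg.heads):
            q = seq.matmul(self.params[f"att_wq{i}"].swapaxes(0, 1))
            k = seq.matmul(self.params[f"att_wk{i}"].swapaxes(0, 1))
            v = seq.matmul(self.params[f"att_wv{i}"].swapaxes(0, 1))
            scores = q.matmul(k.swapaxes(-1, -2)) * scale + key_bias
            w = scores.softmax_last() * qmask  # zero rows for masked queries
            heads.append(w.matmul(v))
        out = concat(heads, axis=-1).matmul(self.params["att_wm"].swapaxes(0, 1)) * qmask
        return out, heads

    def _conv_forward(self, x: Tensor, weight: Tensor, idx: np.ndarray) -> Tensor:
        """im2col 'valid' convolution (no bias) + ReLU, flattened per record."""
        n = x.shape[0]
        col = x.reshape(n, -1).take_last_axis(idx)  # (N, n_patches, k*k)
        out = col.matmul(weight.swapaxes(0, 1)).relu()  # (N, n_patches, n_k)
        return out.reshape(n, -1)

    def _lstm_forward(self, x: Tensor, mask: np.ndarray, prefix: str, units: int) -> Tensor:
        cfg = self.config
        n, L = mask.shape
        p = {k: self.params[k] for k in self.params if k.startswith(prefix)}
        h = Tensor(np.zeros((n, units)))
        c = Tensor(np.zeros((n, units)))
        constant_input = not x.requires_grad
        for t in range(L):
            if not mask[:, t].any():
                break  # post-padding: nothing valid beyond this point
            if constant_input:
                x_t = Tensor(x.data[:, t, :])
            else:
                x_t = x[:, t, :]
            m_t = Tensor(mask[:, t : t + 1])

            def gate(g, with_c=None):
                pre = x_t.matmul(p[f"{prefix}_wx{g}"].swapaxes(0, 1)) + h.matmul(
                    p[f"{prefix}_wh{g}"].swapaxes(0, 1)
                ) + p[f"{prefix}_b{g}"]
                if cfg.peephole and with_c is not None:
                    pre = pre + with_c.matmul(p[f"{prefix}_wc{g}"].swapaxes(0, 1))
                return pre

            i_t = gate("i", with_c=c).sigmoid()
            f_t = gate("f", with_c=c).sigmoid()
            c_new = f_t * c + i_t * gate("c").tanh()
            o_t = gate("o", with_c=c_new).sigmoid()
            h_new = o_t * c_new.tanh()
            h = h_new * m_t + h * (1.0 - m_t)
            c = c_new * m_t + c * (1.0 - m_t)
        return h

    def forward(
        self,
        seq: np.ndarray,
        struct: np.ndarray,
        mask: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, list[Tensor]]:
        """Compute sigmoid probabilities; returns (probs (N,), attention head outputs)."""
        cfg = self.config
        n = seq.shape[0]
        seq_t = Tensor(seq)
        blocks: list[Tensor] = []
        head_outputs: list[Tensor] = []

        seq_branch_input: Tensor = seq_t
        if cfg.use_attention:
            enhanced, head_outputs = self._attention_forward(seq_t, mask)
            if cfg.attention_fusion == "cascade":
                seq_branch_input = enhanced

        if cfg.use_cnn:
            blocks.append(self._conv_forward(seq_branch_input, self.params["conv_seq_w"],
                                             self._seq_conv_idx))
            if cfg.use_structure:
                blocks.append(self._conv_forward(Tensor(struct), self.params["conv_struct_w"],
                                                 self._struct_conv_idx))
        if cfg.use_lstm:
            blocks.append(self._lstm_forward(seq_branch_input, mask, "lstm_seq",
                                             cfg.seq_lstm_units))
            if cfg.use_structure:
                blocks.append(self._lstm_forward(Tensor(struct), mask, "lstm_struct",
                                                 cfg.struct_lstm_units))
        if cfg.use_attention and cfg.attention_fusion == "skip":
            blocks.append(enhanced.reshape(n, -1))

        feats = concat(blocks, axis=-1) if len(blocks) > 1 else blocks[0]
        hidden = (feats.matmul(self.params["dense1_w"].swapaxes(0, 1))
                  + self.params["dense1_b"]).relu()
        if training and cfg.dropout_rate > 0:
            if dropout_rng is None:
                raise ValueError("training forward requires a dropout rng")
            keep = 1.0 - cfg.dropout_rate
            drop_mask = (dropout_rng.random(hidden.shape) < keep) / keep
            hidden = hidden * Tensor(drop_mask)
        logit = hidden.matmul(self.params["dense2_w"].swapaxes(0, 1)) + self.params["dense2_b"]
        probs = logit.sigmoid().reshape(n)
        return probs, head_outputs


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted network: configuration, weights, per-epoch history."""

    config: ModelConfig
    weights: dict[str, np.ndarray]
    history: list[dict]
    fitted_max_len: int
    structure_available: bool

    def rebuild(self) -> ACPModel:
        model = ACPModel(self.config, self.fitted_max_len, self.structure_available)
        model.set_weights(self.weights)
        return model

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": CHECKPOINT_VERSION,
            "config": self.config.to_dict(),
            "fitted_max_len": self.fitted_max_len,
            "structure_available": self.structure_available,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(directory / "weights.npz", **self.weights)
        with open(directory / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
            )
            writer.writeheader()
            for row in self.history:
                writer.writerow(row)

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        if meta.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        with np.load(directory / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        history = []
        hist_path = directory / "history.csv"
        if hist_path.exists():
            with open(hist_path) as fh:
                for row in csv.DictReader(fh):
                    history.append({k: (int(v) if k == "epoch" else float(v))
                                    for k, v in row.items() if v != ""})
        return cls(
            config=ModelConfig.from_dict(meta["config"]),
            weights=weights,
            history=history,
            fitted_max_len=int(meta["fitted_max_len"]),
            structure_available=bool(meta["structure_available"]),
        )


def build_model(config: ModelConfig, max_len: int, structure_available: bool = True) -> ACPModel:
    """Assemble an untrained model for inputs padded to ``max_len``."""
    return ACPModel(config, max_len, structure_available)


def _loss_tensor(probs: Tensor, labels: np.ndarray, head_outputs: list[Tensor],
                 head_reg_weight: float) -> Tensor:
    t = Tensor(labels)
    p = probs.clip(BCE_EPS, 1.0 - BCE_EPS)
    loss = -((1.0 - t) * (1.0 - p).log() + t * p.log())
    loss = loss.mean()
    if head_reg_weight > 0 and len(head_outputs) >= 2:
        n = len(head_outputs)
        sims = []
        flats = [h.reshape(-1) for h in head_outputs]
        for i in range(n):
            for j in range(i + 1, n):
                dot = (flats[i] * flats[j]).sum()
                ni = ((flats[i] * flats[i]).sum() + 1e-12) ** 0.5
                nj = ((flats[j] * flats[j]).sum() + 1e-12) ** 0.5
                sims.append(dot / (ni * nj))
        penalty = sims[0]
        for s in sims[1:]:
            penalty = penalty + s
        loss = loss + (head_reg_weight / len(sims)) * penalty
    return loss


def _eval_on(model: ACPModel, seq, struct, mask, labels) -> tuple[float, float]:
    probs, _ = model.forward(seq, struct, mask, training=False)
    loss = binary_cross_entropy(labels, probs.data)
    acc = float(np.mean((probs.data >= 0.5) == (labels >= 0.5)))
    return loss, acc


def _stratified_validation_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; val gets ceil(fraction * class size), capped
    so at least one training record per class remains."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = rng.permutation(members)
        n_val = min(int(np.ceil(val_fraction * len(members))), len(members) - 1)
        val_idx.extend(members[:n_val])
        train_idx.extend(members[n_val:])
    return np.sort(np.array(train_idx, dtype=int)), np.sort(np.array(val_idx, dtype=int))


def train(model: ACPModel, batch: EncodedBatch, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the model on an encoded labeled batch.

    A stratified ``val_fraction`` of the batch is held out for early stopping
    on validation loss (patience epochs, best weights restored); with
    ``val_fraction=0`` training runs for ``max_epochs``.  Fully seeded and
    deterministic: the same seed reproduces identical weights and history.
    """
    cfg = config or model.config
    if batch.labels is None:
        raise ValueError("training requires labels")
    if batch.max_len != model.max_len:
        raise ValueError(f"batch max_len {batch.max_len} != model max_len {model.max_len}")

    rng = np.random.default_rng(cfg.seed + 1)
    labels = batch.labels
    n = batch.n
    use_val = cfg.val_fraction > 0 and all(
        np.sum(labels == c) >= 2 for c in np.unique(labels)
    ) and len(np.unique(labels)) == 2
    if use_val:
        train_idx, val_idx = _stratified_validation_split(labels, cfg.val_fraction, rng)
    else:
        train_idx, val_idx = np.arange(n), np.array([], dtype=int)

    tr = batch.subset(train_idx)
    va = batch.subset(val_idx) if len(val_idx) else None

    opt = Adam(model.params, lr=cfg.learning_rate, betas=cfg.betas)
    history: list[dict] = []
    best_val = np.inf
    best_weights = model.get_weights()
    patience_left = cfg.early_stopping_patience

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(tr.n)
        epoch_losses = []
        for start in range(0, tr.n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            probs, head_outs = model.forward(
                tr.seq_onehot[sel], tr.struct_feats[sel], tr.mask[sel],
                training=True, dropout_rng=rng,
            )
            loss = _loss_tensor(probs, tr.labels[sel], head_outs, cfg.head_reg_weight)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (batch starting {start}); "
                    f"last finite epoch losses: {epoch_losses[-3:]}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        train_loss, train_acc = _eval_on(model, tr.seq_onehot, tr.struct_feats, tr.mask, tr.labels)
        row = {"epoch": epoch, "train_loss": train_loss, "train_acc": train_acc,
               "val_loss": "", "val_acc": ""}
        if va is not None:
            val_loss, val_acc = _eval_on(model, va.seq_onehot, va.struct_feats, va.mask, va.labels)
            row["val_loss"], row["val_acc"] = val_loss, val_acc
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = model.get_weights()
                patience_left = cfg.early_stopping_patience
            else:
                if patience_left <= 0:
                    history.append(row)
                    break
                patience_left -= 1
        history.append(row)

    if va is not None:
        model.set_weights(best_weights)
    return TrainedModel(
        config=cfg,
        weights=model.get_weights(),
        history=history,
        fitted_max_len=model.max_len,
        structure_available=model.config.use_structure,
    )


def _align_batch(batch: EncodedBatch, fitted_max_len: int) -> EncodedBatch:
    """Re-pad or (safely) trim a batch to the model's fitted length."""
    L = batch.max_len
    if L == fitted_max_len:
        return batch
    if L < fitted_max_len:
        pad = fitted_max_len - L
        return EncodedBatch(
            seq_onehot=np.pad(batch.seq_onehot, ((0, 0), (0, pad), (0, 0))),
            struct_feats=np.pad(batch.struct_feats, ((0, 0), (0, pad), (0, 0))),
            mask=np.pad(batch.mask, ((0, 0), (0, pad))),
            labels=batch.labels, lengths=batch.lengths, ids=batch.ids,
            has_structure=batch.has_structure,
        )
    if batch.mask[:, fitted_max_len:].any():
        raise ValueError(
            f"batch contains residues beyond the model's fitted length {fitted_max_len}"
        )
    return EncodedBatch(
        seq_onehot=batch.seq_onehot[:, :fitted_max_len],
        struct_feats=batch.struct_feats[:, :fitted_max_len],
        mask=batch.mask[:, :fitted_max_len],
        labels=batch.labels, lengths=batch.lengths, ids=batch.ids,
        has_structure=batch.has_structure,
    )


def predict_proba(model: TrainedModel | ACPModel, batch: EncodedBatch) -> np.ndarray:
    """Sigmoid probabilities for a batch (dropout inactive; deterministic).

    Batches padded shorter or longer than the fitted length are re-aligned;
    extra padding never changes predictions because padded positions carry no
    signal in any branch.
    """
    net = model.rebuild() if isinstance(model, TrainedModel) else model
    aligned = _align_batch(batch, net.max_len)
    probs, _ = net.forward(aligned.seq_onehot, aligned.struct_feats, aligned.mask, training=False)
    return probs.data.copy()
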