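"""The y-ion intensity network.

Architecture: the one-hot peptide sequence runs through a bidirectional
gated-recurrent (GRU) encoder followed by a scaled dot-product
self-attention over the encoder states; the four scalar features (CE,
charge, length, proline count) run through fully connected layers; the
4 x 12 sliding-window matrix runs through three convolution layers.  The
dense and convolutional outputs are concatenated, projected, and merged
with the attended encoder states by matrix multiplication; the merged
sequence is decoded by a second GRU (initialised from the encoder's final
hidden state), passed through a second dot-product attention, and mapped
by linear layers onto the 42 fragment-intensity slots (y1..y14 at charge
1..3).  The output layer is linear — targets include the -1 fill for
infeasible slots, so no squashing activation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d, stack
from .encoding import MAX_LENGTH, N_SLOTS, EncodedSample
from .speclib import MAX_FRAGMENT_CHARGE, MAX_ORDINAL


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; every width the network uses is here."""

    hidden_size: int = 128
    fcn_hidden: tuple[int, ...] = (32, 32)
    cnn_channels: tuple[int, ...] = (16, 32, 64)
    cnn_kernel: int = 3
    merge_dim: int = 32
    head_hidden: int = 64
    dropout: float = 0.1
    output_dim: int = N_SLOTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim != N_SLOTS:
            raise ValueError(f"output_dim must be {N_SLOTS}, got {self.output_dim}")
        if self.hidden_size <= 0:
            raise ValueError("hidden_size must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.cnn_channels) != 3:
            raise ValueError("exactly three convolution layers are used")


def compact_config(seed: int = 0) -> "ModelConfig":
    """Desk-scale configuration: hidden size 32 with widened heads.

    This is the configuration used throughout the simulated-corpus
    experiments; it trains in minutes on one CPU while retaining enough
    head capacity to resolve the 42 slots.
    """
    return ModelConfig(
        hidden_size=32,
        fcn_hidden=(64, 64),
        cnn_channels=(8, 16, 16),
        merge_dim=64,
        head_hidden=128,
        dropout=0.0,
        seed=seed,
    )


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Tensor(rng.normal(0.0, scale, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]


class GRUCell:
    """Standard gated recurrent unit: update/reset gates + candidate state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        scale = np.sqrt(1.0 / n_hidden)
        def mat(a, b):
            return Tensor(rng.uniform(-scale, scale, (a, b)), requires_grad=True)
        self.wi = mat(n_in, 3 * n_hidden)   # input -> [z, r, n]
        self.wh = mat(n_hidden, 3 * n_hidden)
        self.bi = Tensor(np.zeros(3 * n_hidden), requires_grad=True)
        self.bh = Tensor(np.zeros(3 * n_hidden), requires_grad=True)

    def project_inputs(self, x_seq: Tensor) -> Tensor:
        """Input-gate projections for every timestep at once: (B,L,3H)."""
        return x_seq @ self.wi + self.bi

    def step(self, gi: Tensor, h: Tensor) -> Tensor:
        """One recurrence step from a precomputed input projection (B,3H)."""
        H = self.n_hidden
        gh = h @ self.wh + self.bh
        z = (gi[:, 0:H] + gh[:, 0:H]).sigmoid()
        r = (gi[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gi[:, 2 * H :] + r * gh[:, 2 * H :]).tanh()
        return (1.0 - z) * n + z * h

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        return self.step(x @ self.wi + self.bi, h)

    def parameters(self) -> list[Tensor]:
        return [self.wi, self.wh, self.bi, self.bh]


def attention(queries: Tensor, keys: Tensor, values: Tensor, mask: np.ndarray | None = None) -> Tensor:
    """Scaled dot-product attention over the key axis.

    queries (B,Lq,D), keys/values (B,Lk,D); ``mask`` is a boolean (B,Lk)
    array marking valid key positions (padded positions are excluded from
    the softmax).  Returns the (B,Lq,D) context.
    """
    d = queries.shape[-1]
    if keys.shape[-1] != d:
        raise ValueError(f"query/key dim mismatch: {d} vs {keys.shape[-1]}")
    scores = (queries @ keys.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))  # (B,Lq,Lk)
    if mask is not None:
        bias = np.where(mask[:, None, :], 0.0, -1e9)
        scores = scores + Tensor(bias)
    return scores.softmax(axis=-1) @ values


class IntensityPredictor:
    """The full recurrent/convolutional/dense intensity network."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.hidden_size

        self.enc_fwd = GRUCell(20, H, rng)
        self.enc_bwd = GRUCell(20, H, rng)

        fcn_dims = [4, *config.fcn_hidden]
        self.fcn = [Linear(a, b, rng) for a, b in zip(fcn_dims, fcn_dims[1:])]

        chans = [1, *config.cnn_channels]
        k = config.cnn_kernel
        scale = np.sqrt(2.0 / (k * k * max(chans)))
        self.cnn_kernels = [
            Tensor(rng.normal(0.0, scale, (o, c, k, k)), requires_grad=True)
            for c, o in zip(chans, chans[1:])
        ]
        self.cnn_biases = [
            Tensor(np.zeros(o), requires_grad=True) for o in chans[1:]
        ]
        cnn_flat = config.cnn_channels[-1] * 4 * 12
        self.cnn_proj = Linear(cnn_flat, config.fcn_hidden[-1], rng)

        feat_dim = 2 * config.fcn_hidden[-1]  # FCN output + projected CNN output
        self.merge = Linear(feat_dim, 2 * H * config.merge_dim, rng)
        self.dec_init = Linear(2 * H, H, rng)
        self.decoder = GRUCell(config.merge_dim, H, rng)
        # second attention: one learned query per y-ion ordinal (y1..y14);
        # keys carry a one-hot positional code so a query can address a
        # position directly as well as by content.  Queries start focused on
        # the two residues flanking their own cleavage site (positions k-1
        # and k counted from the C-terminus) — the physically relevant
        # context — and remain fully trainable.
        q0 = rng.normal(0.0, 1.0 / np.sqrt(H), (MAX_ORDINAL, H + MAX_LENGTH))
        d_attn = np.sqrt(H + MAX_LENGTH)
        for k in range(1, MAX_ORDINAL + 1):
            q0[k - 1, H + k - 1] += 4.0 * d_attn
            if k < MAX_LENGTH:
                q0[k - 1, H + k] += 4.0 * d_attn
        self.slot_queries = Tensor(q0, requires_grad=True)
        self.head1 = Linear(2 * H, config.head_hidden, rng)
        self.head2 = Linear(config.head_hidden, MAX_FRAGMENT_CHARGE, rng)

        self._drop_rng = np.random.default_rng(config.seed + 1)
        self.training = False

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        params += self.enc_fwd.parameters() + self.enc_bwd.parameters()
        for layer in self.fcn:
            params += layer.parameters()
        params += self.cnn_kernels + self.cnn_biases + self.cnn_proj.parameters()
        params += self.merge.parameters() + self.dec_init.parameters()
        params += self.decoder.parameters()
        params += [self.slot_queries]
        params += self.head1.parameters() + self.head2.parameters()
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.copy()

    # -- forward -----------------------------------------------------------

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0:
            return x
        keep = (self._drop_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    def forward(self, batch: list[EncodedSample]) -> Tensor:
        if not batch:
            raise ValueError("empty batch")
        B = len(batch)
        H = self.config.hidden_size
        onehot = np.stack([s.onehot for s in batch])        # (B, Lmax, 20)
        # the recurrent paths consume the sequence C-terminus first, so that
        # position t is the t-th residue of the y-ion ladder (y-ion ordinals
        # count from the C-terminus); padding stays at the tail
        for i, s in enumerate(batch):
            L = len(s.sequence)
            onehot[i, :L] = onehot[i, :L][::-1]
        feats = np.stack([s.features for s in batch])       # (B, 4)
        windows = np.stack([s.windows for s in batch])[:, None, :, :]  # (B,1,4,12)
        lengths = np.array([len(s.sequence) for s in batch])
        pos_mask = np.arange(MAX_LENGTH)[None, :] < lengths[:, None]   # (B, Lmax)

        # (i) bidirectional recurrent encoder over the one-hot sequence
        x = Tensor(onehot)
        h_f = Tensor(np.zeros((B, H)))
        h_b = Tensor(np.zeros((B, H)))
        gi_f = self.enc_fwd.project_inputs(x)
        gi_b = self.enc_bwd.project_inputs(x)
        fwd_states, bwd_states = [], [None] * MAX_LENGTH
        for t in range(MAX_LENGTH):
            h_f = self.enc_fwd.step(gi_f[:, t, :], h_f)
            fwd_states.append(h_f)
        for t in reversed(range(MAX_LENGTH)):
            h_b = self.enc_bwd.step(gi_b[:, t, :], h_b)
            bwd_states[t] = h_b
        enc = concat(
            [stack(fwd_states, axis=1), stack(bwd_states, axis=1)], axis=-1
        )  # (B, Lmax, 2H)
        # residual keeps per-position identity alongside the attended mix;
        # positional one-hots let scores depend on position as well as content
        pos_code = Tensor(np.broadcast_to(np.eye(MAX_LENGTH), (B, MAX_LENGTH, MAX_LENGTH)))
        enc_pos = concat([enc, pos_code], axis=-1)
        attended = enc + attention(enc_pos, enc_pos, enc, mask=pos_mask)
        attended = self._dropout(attended)

        # (ii) dense path for the scalar features
        f = Tensor(feats)
        for layer in self.fcn:
            f = layer(f).relu()

        # (iii) convolutional path for the window matrix
        c = Tensor(windows)
        for kern, bias in zip(self.cnn_kernels, self.cnn_biases):
            c = conv2d(c, kern, bias, padding=self.config.cnn_kernel // 2).relu()
        c = self.cnn_proj(c.reshape(B, -1)).relu()

        # merge: attended encoder states (B,Lmax,2H) x projected features
        v = concat([f, c], axis=-1)                              # (B, 2F)
        proj = self.merge(v).reshape(B, 2 * H, self.config.merge_dim)
        merged = attended @ proj                                  # (B, Lmax, merge_dim)

        # decoder GRU initialised from the encoder's final hidden state
        h_d = self.dec_init(concat([h_f, bwd_states[0]], axis=-1)).tanh()
        gi_d = self.decoder.project_inputs(merged)
        dec_states = []
        for t in range(MAX_LENGTH):
            h_d = self.decoder.step(gi_d[:, t, :], h_d)
            dec_states.append(h_d)
        dec = stack(dec_states, axis=1)                          # (B, Lmax, H)

        # second attention: each y-ion ordinal owns a learned query over the
        # decoded sequence; its context plus the final decoder state feed a
        # per-ordinal head emitting the three charge slots
        queries = self.slot_queries.reshape(1, MAX_ORDINAL, H + MAX_LENGTH)
        keys = concat([dec, pos_code], axis=-1)                  # (B, Lmax, H+Lmax)
        context = attention(queries, keys, dec, mask=pos_mask)   # (B, 14, H)
        context = self._dropout(context)
        global_state = stack([h_d] * MAX_ORDINAL, axis=1)        # (B, 14, H)
        out = self.head1(concat([context, global_state], axis=-1)).relu()
        return self.head2(out).reshape(B, self.config.output_dim)  # (B, 42)

    def predict(self, samples: list[EncodedSample], batch_size: int = 256) -> np.ndarray:
        """Forward in evaluation mode, returning a plain (n, 42) array."""
        was_training, self.training = self.training, False
        try:
            chunks = [
                self.forward(samples[i : i + batch_size]).data
                for i in range(0, len(samples), batch_size)
            ]
        finally:
            self.training = was_training
        return np.concatenate(chunks, axis=0)


def build_model(config: ModelConfig) -> IntensityPredictor:
    """Construct the predictor; parameters are deterministic in config.seed."""
    return IntensityPredictor(config)


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

def loss_mse(
    prediction: Tensor,
    target: np.ndarray,
    mask: np.ndarray | None = None,
    mask_infeasible: bool = False,
) -> Tensor:
    """Mean squared error over the 42 slots (reduction "mean").

    By default every slot participates, including the -1 fill of infeasible
    slots — the network is trained to reproduce the fill.  With
    ``mask_infeasible`` the mean runs over feasible slots only.
    """
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch: {prediction.shape} vs {target.shape}")
    diff = prediction - Tensor(target)
    if mask_infeasible:
        if mask is None:
            raise ValueError("mask_infeasible requires the feasibility mask")
        m = np.asarray(mask, dtype=float)
        return ((diff ** 2.0) * Tensor(m)).sum() * (1.0 / m.sum())
    return (diff ** 2.0).mean(axis=None)


def loss_topk_weighted(
    prediction: Tensor,
    target: np.ndarray,
    mask: np.ndarray,
    k: int = 3,
    weight: float = 1.0,
) -> Tensor:
    """MSE plus a weighted MSE over each sample's k highest-target slots.

    The extra term concentrates training on the intense transitions used
    for SRM/MRM selection.  ``k`` is clipped per sample when a peptide has
    fewer feasible slots than k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    target = np.asarray(target, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    base = loss_mse(prediction, target)
    if weight == 0.0:
        return base
    rows, cols = [], []
    for i in range(target.shape[0]):
        feasible = np.flatnonzero(mask[i])
        kk = min(k, feasible.size)
        top = feasible[np.argsort(-target[i, feasible], kind="stable")[:kk]]
        rows.extend([i] * kk)
        cols.extend(top.tolist())
    idx = (np.array(rows), np.array(cols))
    diff = prediction[idx] - Tensor(target[idx])
    return base + weight * (diff ** 2.0).mean(axis=None)


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(predictor: IntensityPredictor, path: str) -> None:
    """Serialize config + parameters; loading reproduces forward bit-exactly."""
    cfg = predictor.config
    arrays = {f"p{i:03d}": a for i, a in enumerate(predictor.state_arrays())}
    np.savez(
        path,
        hidden_size=cfg.hidden_size,
        fcn_hidden=np.array(cfg.fcn_hidden),
        cnn_channels=np.array(cfg.cnn_channels),
        cnn_kernel=cfg.cnn_kernel,
        merge_dim=cfg.merge_dim,
        head_hidden=cfg.head_hidden,
        dropout=cfg.dropout,
        seed=cfg.seed,
        n_params=len(arrays),
        **arrays,
    )


def load_checkpoint(path: str) -> IntensityPredictor:
    with np.load(path) as data:
        config = ModelConfig(
            hidden_size=int(data["hidden_size"]),
            fcn_hidden=tuple(int(x) for x in data["fcn_hidden"]),
            cnn_channels=tuple(int(x) for x in data["cnn_channels"]),
            cnn_kernel=int(data["cnn_kernel"]),
            merge_dim=int(data["merge_dim"]),
            head_hidden=int(data["head_hidden"]),
            dropout=float(data["dropout"]),
            seed=int(data["seed"]),
        )
        predictor = build_model(config)
        arrays = [data[f"p{i:03d}"] for i in range(int(data["n_params"]))]
    predictor.load_state_arrays(arrays)
    return predictor
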