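"""The hybrid motor-imagery decoder.

Pipeline: spatiotemporal convolution (temporal filters then a depthwise
spatial filter collapsing the electrode axis) -> three-branch separable
convolution at kernel scales 8/16/32 samples -> multi-head self-attention
over the pooled feature sequence -> depth-wise feature fusion of the
multi-scale and attention features -> three shared-weight sliding windows
through a dilated-causal TCN -> two linear heads whose logits are summed
(decision fusion) and passed through softmax.

Every stage's output extent follows the layer contract: with input
(C, T) the fused sequence entering the TCN has length T // 64 and depth
2 x F2, and the TCN receptive field 1 + 2(Kt-1)(2^L - 1) must exceed the
window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError
from .nn import Tensor

ABLATABLE_BLOCKS = ("msc", "msa", "tcn", "feature_fusion", "decision_fusion", "mff")


def receptive_field_size(kt: int, n_blocks: int) -> int:
    """Receptive field of a stack of residual blocks of two dilated causal
    convolutions each, dilation doubling per block: 1 + 2(Kt-1)(2^L - 1)."""
    if kt < 1 or n_blocks < 1:
        raise ConfigurationError(f"Kt and L must be >= 1, got Kt={kt}, L={n_blocks}")
    return 1 + 2 * (kt - 1) * (2**n_blocks - 1)


@dataclass
class ModelConfig:
    """Architecture hyperparameters. F2 = D x F1 is derived."""

    C: int
    T: int
    Nc: int
    F1: int = 32
    D: int = 2
    temporal_kernel: int = 16
    pool_width: int = 8
    msc_kernels: tuple = (8, 16, 32)
    heads: int = 8
    attn_dropout: float = 0.3
    conv_dropout: float = 0.5
    Kt: int = 4
    L: int = 2
    tcn_dropout: float = 0.5
    n_windows: int = 3
    fc_max_norm: float = 0.25
    tcn_max_norm: float = 0.5
    msa_residual: bool = False
    decision_fusion_mode: str = "sum"  # or "concat_linear"

    @property
    def F2(self) -> int:
        return self.D * self.F1

    @property
    def seq_len(self) -> int:
        """Length of the feature sequence after both pooling stages."""
        return self.T // self.pool_width // self.pool_width

    @property
    def window_len(self) -> int:
        return self.seq_len - (self.n_windows - 1)

    def validate(self):
        if self.F2 % 4:
            raise ConfigurationError(f"F2 = {self.F2} must be divisible by 4")
        if self.F2 % self.heads:
            raise ConfigurationError(
                f"F2 = {self.F2} must be divisible by heads = {self.heads}"
            )
        if self.seq_len < self.n_windows:
            raise ConfigurationError(
                f"T = {self.T} leaves only {self.seq_len} pooled steps for "
                f"{self.n_windows} windows"
            )
        rfs = receptive_field_size(self.Kt, self.L)
        if rfs <= self.window_len:
            raise ConfigurationError(
                f"receptive field 1 + 2(Kt-1)(2^L - 1) = {rfs} must exceed the "
                f"TCN window length {self.window_len}"
            )
        if self.decision_fusion_mode not in ("sum", "concat_linear"):
            raise ConfigurationError(
                f"unknown decision_fusion_mode {self.decision_fusion_mode!r}"
            )


@dataclass
class FeatureMap:
    """Intermediate activation with explicit (depth, spatial, time) extents."""

    values: np.ndarray
    depth: int
    spatial: int
    time: int


def _trace(trace, name, shape):
    if trace is not None:
        trace[name] = tuple(shape)


class SpatioTemporalConv(nn.Module):
    """Temporal filters shared across electrodes, then a depthwise spatial
    filter over the full channel axis (collapsing it), BN/ELU, width-8
    average pooling and dropout."""

    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        self.cfg = cfg
        self.temporal = nn.ConvTime(1, cfg.F1, cfg.temporal_kernel, rng, padding="same")
        self.bn1 = nn.BatchNorm(cfg.F1)
        # depthwise spatial filter: D output maps per temporal filter
        c = cfg.C
        self.spatial = Tensor(
            nn.glorot_uniform(rng, (cfg.F1, cfg.D, c), c, c * cfg.D), requires_grad=True
        )
        self.bn2 = nn.BatchNorm(cfg.F2)
        self.drop = nn.Dropout(cfg.conv_dropout, drop_rng)

    def __call__(self, x: Tensor, trace=None) -> Tensor:
        n, c, t = x.shape
        cfg = self.cfg
        h = self.temporal(x.reshape(n * c, 1, t))
        h = h.reshape(n, c, cfg.F1, t).transpose(0, 2, 1, 3)  # (N, F1, C, T)
        _trace(trace, "Temporal CNN", (cfg.F1, c, t))
        h = self.bn1(h)
        h = nn.einsum2("nfct,fdc->nfdt", h, self.spatial).reshape(n, cfg.F2, t)
        _trace(trace, "Spatial CNN", (cfg.F2, 1, t))
        h = self.bn2(h).elu()
        h = nn.avg_pool_time(h, cfg.pool_width)
        _trace(trace, "Pool1", (cfg.F2, 1, h.shape[-1]))
        return self.drop(h)


class MultiBranchSeparableConv(nn.Module):
    """Three depthwise-separable branches at kernel scales (8, 16, 32) with
    filter counts (F2/4, F2/4, F2/2), concatenated on the depth axis."""

    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        self.cfg = cfg
        f2 = cfg.F2
        nb = len(cfg.msc_kernels)
        if nb == 3:
            filters = (f2 // 4, f2 // 4, f2 // 2)
        else:  # non-standard branch counts: equal split, remainder to the last
            base = f2 // nb
            filters = tuple([base] * (nb - 1) + [f2 - base * (nb - 1)])
        self.depthwise, self.pointwise, self.branch_bn = [], [], []
        for kern, fout in zip(cfg.msc_kernels, filters):
            self.depthwise.append(
                nn.ConvTime(f2, f2, kern, rng, padding="same", groups=f2)
            )
            self.pointwise.append(nn.ConvTime(f2, fout, 1, rng))
            self.branch_bn.append(nn.BatchNorm(fout))
        self.bn3 = nn.BatchNorm(f2)
        self.drop = nn.Dropout(cfg.conv_dropout, drop_rng)

    def __call__(self, x: Tensor, trace=None) -> Tensor:
        if x.shape[1] != self.cfg.F2:
            raise ShapeError(f"expected input depth {self.cfg.F2}, got {x.shape[1]}")
        outs = []
        for dw, pw, bn in zip(self.depthwise, self.pointwise, self.branch_bn):
            outs.append(bn(pw(dw(x))).elu())
        h = nn.concat(outs, axis=1)
        _trace(trace, "MSC", (h.shape[1], 1, h.shape[2]))
        h = self.bn3(h).elu()
        _trace(trace, "BN3", (h.shape[1], 1, h.shape[2]))
        h = nn.avg_pool_time(h, self.cfg.pool_width)
        _trace(trace, "Pool2", (h.shape[1], 1, h.shape[2]))
        return self.drop(h)


class MultiHeadSelfAttention(nn.Module):
    """Pre-layer-norm multi-head scaled dot-product self-attention with an
    output projection and ELU; sequence length and embedding unchanged.

    The most recent pre-dropout attention weights are kept on
    `last_attention` (batch, heads, query, key) for inspection.
    """

    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        self.cfg = cfg
        f2 = cfg.F2
        self.ln = nn.LayerNorm(f2)
        self.wq = Tensor(nn.glorot_uniform(rng, (f2, f2), f2, f2), requires_grad=True)
        self.wk = Tensor(nn.glorot_uniform(rng, (f2, f2), f2, f2), requires_grad=True)
        self.wv = Tensor(nn.glorot_uniform(rng, (f2, f2), f2, f2), requires_grad=True)
        self.wo = Tensor(nn.glorot_uniform(rng, (f2, f2), f2, f2), requires_grad=True)
        self.drop = nn.Dropout(cfg.attn_dropout, drop_rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor, trace=None) -> Tensor:
        n, length, f2 = x.shape
        if length == 0:
            raise ShapeError("attention over an empty sequence")
        m = self.cfg.heads
        dh = f2 // m
        y = self.ln(x)

        def heads(t: Tensor) -> Tensor:
            return t.reshape(n, length, m, dh).transpose(0, 2, 1, 3)

        q, k, v = heads(y @ self.wq), heads(y @ self.wk), heads(y @ self.wv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = nn.softmax(scores, axis=-1)
        self.last_attention = att.data.copy()
        z = self.drop(att) @ v
        z = z.transpose(0, 2, 1, 3).reshape(n, length, f2)
        out = (z @ self.wo).elu()
        if self.cfg.msa_residual:
            out = out + x
        _trace(trace, "MSA", (f2, length))
        return out


class ResidualTCNBlock(nn.Module):
    """Two dilated causal convolutions, each BN/ELU/dropout, plus a residual
    connection (identity when depths match, pointwise otherwise)."""

    def __init__(self, in_depth: int, depth: int, kt: int, dilation: int,
                 rng, drop_rng, p_drop: float):
        super().__init__()
        self.conv1 = nn.ConvTime(in_depth, depth, kt, rng, "causal", dilation)
        self.bn1 = nn.BatchNorm(depth)
        self.conv2 = nn.ConvTime(depth, depth, kt, rng, "causal", dilation)
        self.bn2 = nn.BatchNorm(depth)
        self.drop1 = nn.Dropout(p_drop, drop_rng)
        self.drop2 = nn.Dropout(p_drop, drop_rng)
        self.project = None
        if in_depth != depth:
            self.project = nn.ConvTime(in_depth, depth, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop1(self.bn1(self.conv1(x)).elu())
        h = self.drop2(self.bn2(self.conv2(h)).elu())
        res = x if self.project is None else self.project(x)
        return res + h


class TemporalConvNet(nn.Module):
    """L residual blocks with dilation 2^(i-1) in block i; returns the final
    time step's feature vector."""

    def __init__(self, depth: int, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        self.depth = depth
        self.blocks = [
            ResidualTCNBlock(depth, depth, cfg.Kt, 2**i, rng, drop_rng, cfg.tcn_dropout)
            for i in range(cfg.L)
        ]
        self.rfs = receptive_field_size(cfg.Kt, cfg.L)

    def __call__(self, x: Tensor) -> Tensor:
        if self.rfs <= x.shape[-1]:
            raise ConfigurationError(
                f"receptive field {self.rfs} must exceed sequence length "
                f"{x.shape[-1]} (1 + 2(Kt-1)(2^L - 1))"
            )
        for block in self.blocks:
            x = block(x)
        return x[:, :, -1]


def feature_fusion(msc_seq: Tensor, msa_seq: Tensor) -> Tensor:
    """Depth-axis concatenation of (N, len, F2) sequences, MSC features first."""
    if msc_seq.shape[1] != msa_seq.shape[1]:
        raise ShapeError(
            f"time extents differ: {msc_seq.shape[1]} vs {msa_seq.shape[1]}"
        )
    return nn.concat([msc_seq, msa_seq], axis=2)


def decision_fusion(logits_a: Tensor, logits_b: Tensor) -> Tensor:
    """Element-wise logit sum; softmax downstream yields the fused probability."""
    if logits_a.shape != logits_b.shape:
        raise ShapeError(f"logit shapes differ: {logits_a.shape} vs {logits_b.shape}")
    return logits_a + logits_b


class MultiScaleAttentionTCN(nn.Module):
    """The full decoder. `removed_block` switches off one block for ablation:
    msc (branch convolutions bypassed), msa (MSC features fused with
    themselves), tcn (MSC head only), feature_fusion (TCN sees attention
    output only), decision_fusion (TCN head only), or mff (both fusions)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, removed_block: str | None = None):
        super().__init__()
        cfg.validate()
        if removed_block not in (None, "none") and removed_block not in ABLATABLE_BLOCKS:
            raise ConfigurationError(
                f"unknown ablation block {removed_block!r}; choose from "
                f"{ABLATABLE_BLOCKS}"
            )
        self.cfg = cfg
        self.removed_block = None if removed_block == "none" else removed_block
        rb = self.removed_block
        self.use_msc = rb != "msc"
        self.use_msa = rb != "msa"
        self.use_tcn = rb != "tcn"
        self.use_feature_fusion = rb not in ("feature_fusion", "mff")
        self.use_decision_fusion = rb not in ("decision_fusion", "mff") and self.use_tcn

        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.drop_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        drop_rng = self.drop_rng

        self.sc = SpatioTemporalConv(cfg, rng, drop_rng)
        if self.use_msc:
            self.msc = MultiBranchSeparableConv(cfg, rng, drop_rng)
        else:
            self.msc_drop = nn.Dropout(cfg.conv_dropout, drop_rng)
        if self.use_msa:
            self.msa = MultiHeadSelfAttention(cfg, rng, drop_rng)

        f2, seq = cfg.F2, cfg.seq_len
        self.use_fc1 = self.use_decision_fusion or not self.use_tcn
        if self.use_fc1:
            self.fc1 = nn.Linear(f2 * seq, cfg.Nc, rng, bias_init=0.0)
        if self.use_tcn:
            tcn_depth = 2 * f2 if self.use_feature_fusion else f2
            self.tcn = TemporalConvNet(tcn_depth, cfg, rng, drop_rng)
            self.fc2 = nn.Linear(tcn_depth * cfg.n_windows, cfg.Nc, rng, bias_init=0.0)
        if self.use_decision_fusion and cfg.decision_fusion_mode == "concat_linear":
            self.fuse = nn.Linear(2 * cfg.Nc, cfg.Nc, rng, bias_init=0.0)

    # -- constraints ----------------------------------------------------------
    def max_norm_constraints(self):
        cons = []
        if self.use_fc1:
            cons.append(nn.MaxNormConstraint(self.fc1.weight, self.cfg.fc_max_norm, (0,)))
        if self.use_tcn:
            cons.append(nn.MaxNormConstraint(self.fc2.weight, self.cfg.fc_max_norm, (0,)))
            for block in self.tcn.blocks:
                for conv in (block.conv1, block.conv2):
                    cons.append(
                        nn.MaxNormConstraint(conv.weight, self.cfg.tcn_max_norm, (1, 2))
                    )
        return cons

    # -- forward --------------------------------------------------------------
    def _windowed_tcn(self, fused_seq: Tensor, trace=None) -> Tensor:
        """Shared-weight TCN over n_windows overlapping sliding windows of the
        (N, len, depth) fused sequence; last-step vectors concatenated."""
        n, length, depth = fused_seq.shape
        nw = self.cfg.n_windows
        if length < nw:
            raise ShapeError(f"sequence length {length} shorter than {nw} windows")
        seq = fused_seq.transpose(0, 2, 1)  # (N, depth, len)
        wlen = length - (nw - 1)
        outs = [self.tcn(seq[:, :, i : i + wlen]) for i in range(nw)]
        out = nn.concat(outs, axis=1)
        _trace(trace, "TCN", (out.shape[1],))
        return out

    def __call__(self, x, trace=None) -> Tensor:
        """Forward pass; returns fused pre-softmax logits (N, Nc)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.C or x.shape[2] != cfg.T:
            raise ShapeError(
                f"expected input (N, {cfg.C}, {cfg.T}), got {x.shape}"
            )
        h = self.sc(x, trace)  # (N, F2, T//8)
        if self.use_msc:
            m = self.msc(h, trace)  # (N, F2, T//64)
        else:
            m = self.msc_drop(nn.avg_pool_time(h, cfg.pool_width))
            _trace(trace, "Pool2", (m.shape[1], 1, m.shape[2]))
        n, f2, seq = m.shape

        flat1 = m.reshape(n, f2 * seq)
        _trace(trace, "Flatten1", (f2 * seq,))
        self._embed_parts = [flat1.data]
        logits1 = self.fc1(flat1) if self.use_fc1 else None
        if logits1 is not None:
            _trace(trace, "FC1", (cfg.Nc,))

        if not self.use_tcn:
            _trace(trace, "Softmax", (cfg.Nc,))
            return logits1

        seq_msc = m.transpose(0, 2, 1)  # (N, seq, F2)
        att = self.msa(seq_msc, trace) if self.use_msa else seq_msc
        if self.use_feature_fusion:
            fused = feature_fusion(seq_msc, att)
        else:
            fused = att
        _trace(trace, "Concatenate1", (fused.shape[2], fused.shape[1]))
        tcn_out = self._windowed_tcn(fused, trace)
        self._embed_parts.append(tcn_out.data)
        _trace(trace, "Flatten2", (tcn_out.shape[1],))
        logits2 = self.fc2(tcn_out)
        _trace(trace, "FC2", (cfg.Nc,))

        if not self.use_decision_fusion:
            _trace(trace, "Softmax", (cfg.Nc,))
            return logits2
        if cfg.decision_fusion_mode == "concat_linear":
            logits = self.fuse(nn.concat([logits1, logits2], axis=1))
        else:
            logits = decision_fusion(logits1, logits2)
        _trace(trace, "Concatenate2", (cfg.Nc,))
        _trace(trace, "Softmax", (cfg.Nc,))
        return logits

    def predict_proba(self, x) -> np.ndarray:
        """Class probabilities in eval mode (deterministic)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                probs = nn.softmax(self(x), axis=1).data
        finally:
            self.train(was_training)
        return probs

    def embeddings(self, x) -> np.ndarray:
        """Penultimate feature vector per trial: the concatenated inputs of
        the two linear heads (pre-decision-fusion)."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                self(x)
                parts = self._embed_parts
        finally:
            self.train(was_training)
        return np.concatenate(parts, axis=1)


def count_parameters(model: nn.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def shape_trace(cfg: ModelConfig, removed_block: str | None = None) -> dict:
    """Run a dummy forward pass and record every stage's output extents in
    (depth, spatial, time) semantics, plus the TCN receptive field and input
    sequence length."""
    model = MultiScaleAttentionTCN(cfg, seed=0, removed_block=removed_block).eval()
    trace: dict = {}
    with nn.no_grad():
        model(np.zeros((1, cfg.C, cfg.T), dtype=np.float32), trace)
    trace["RFS"] = receptive_field_size(cfg.Kt, cfg.L)
    trace["TCN input length"] = cfg.seq_len
    return trace


def save_checkpoint(model: MultiScaleAttentionTCN, path) -> None:
    """Serialize weights plus the embedded config into one .npz archive."""
    import dataclasses
    import json

    meta = {
        "config": dataclasses.asdict(model.cfg),
        "removed_block": model.removed_block,
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> MultiScaleAttentionTCN:
    import json

    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["msc_kernels"] = tuple(cfg_dict["msc_kernels"])
    cfg = ModelConfig(**cfg_dict)
    model = MultiScaleAttentionTCN(cfg, removed_block=meta["removed_block"])
    model.load_state_dict(state)
    return model


def expected_table(cfg: ModelConfig) -> dict:
    """The layer contract evaluated symbolically from the configuration."""
    t, f1, f2, c, nc = cfg.T, cfg.F1, cfg.F2, cfg.C, cfg.Nc
    t8 = t // cfg.pool_width
    t64 = t8 // cfg.pool_width
    return {
        "Temporal CNN": (f1, c, t),
        "Spatial CNN": (f2, 1, t),
        "Pool1": (f2, 1, t8),
        "MSC": (f2, 1, t8),
        "BN3": (f2, 1, t8),
        "Pool2": (f2, 1, t64),
        "Flatten1": (f2 * t64,),
        "FC1": (nc,),
        "MSA": (f2, t64),
        "Concatenate1": (2 * f2, t64),
        "TCN": (2 * f2 * cfg.n_windows,),
        "Flatten2": (2 * f2 * cfg.n_windows,),
        "FC2": (nc,),
        "Concatenate2": (nc,),
        "Softmax": (nc,),
        "RFS": receptive_field_size(cfg.Kt, cfg.L),
        "TCN input length": t64,
    }
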