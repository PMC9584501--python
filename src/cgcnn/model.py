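"""The dual-branch attention-modulated Chebyshev graph convolution network.

Each enabled branch (spatial-temporal and spatial-spectral) runs

    pairwise spatial attention (row-L2-normalized)
      -> attention-modulated Chebyshev graph convolution (ReLU)
      -> pairwise temporal/spectral attention
      -> width-5 temporal/spectral convolution (ReLU)
      -> global spatial then global temporal/spectral aggregation (ReLU)
      -> shortcut projection of the branch input added to the aggregate

and the branch features are concatenated and passed through one fully
connected softmax head.  All parameters live in a flat ``{name: ndarray}``
dict; the forward pass is built on :mod:`cgcnn.autodiff`, so gradients for
training come from the same tape the tests verify by finite differences.

The ablation toggles reproduce the published variants: single branches,
plain dual branch (no attention, no aggregation), dual branch plus
aggregation, and the full model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .montage import SpectralOperators

__all__ = [
    "ModelConfig",
    "CGCNN",
    "pairwise_attention",
    "l2_normalize_rows",
    "attn_graph_conv",
    "temporal_spectral_conv",
    "global_aggregate",
]

VARIANTS = {
    "spatial_temporal": dict(use_ss_branch=False, use_attention=False,
                             use_global_aggregation=False),
    "spatial_spectral": dict(use_st_branch=False, use_attention=False,
                             use_global_aggregation=False),
    "dual_branch": dict(use_attention=False, use_global_aggregation=False),
    "add_aggregation": dict(use_attention=False, use_global_aggregation=True),
    "full": dict(use_attention=True, use_global_aggregation=True),
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters and ablation toggles."""

    n_nodes: int
    n_classes: int
    T: int = 100
    F: int = 100
    cheb_order: int = 3
    c1: int = 64
    c2: int = 64
    kernel_t: int = 5
    in_channels: int = 1
    use_st_branch: bool = True
    use_ss_branch: bool = True
    use_attention: bool = True
    use_global_aggregation: bool = True
    use_shortcut: bool = True
    attention_norm: str = "row"  # "row" or "global"
    seed: int = 0

    def __post_init__(self):
        if not (self.use_st_branch or self.use_ss_branch):
            raise ValueError("at least one branch must be enabled")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name, L in (("T", self.T), ("F", self.F)):
            if L < self.kernel_t:
                raise ValueError(
                    f"{name}={L} is shorter than the temporal kernel ({self.kernel_t})"
                )
        if self.attention_norm not in ("row", "global"):
            raise ValueError(f"unknown attention_norm {self.attention_norm!r}")

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "ModelConfig":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
        merged = {**VARIANTS[variant], **kwargs}
        return cls(**merged)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# functional pieces (operate on autodiff Tensors with a leading batch axis)
# ---------------------------------------------------------------------------

def _pairwise_attention_t(x: Tensor, W1, b1, W2, b2, mode: str) -> Tensor:
    """Raw pairwise attention from a (B, N, L, C) input.

    Left factor tanh(x W1 + b1) is (B, N, L); right factor tanh(W2 x + b2)
    is (B, L, N).  Spatial mode contracts over L to give (B, N, N);
    temporal/spectral mode contracts over N to give (B, L, L).
    """
    u = ad.tanh(ad.matmul(x, W1) + b1)                       # (B, N, L)
    v = ad.tanh(ad.matmul(x, W2).transpose((0, 2, 1)) + b2)  # (B, L, N)
    if mode == "spatial":
        return ad.matmul(u, v)
    return ad.matmul(v, u)


def _normalize_attention_t(a: Tensor, norm: str) -> Tensor:
    if norm == "row":
        return ad.l2_normalize(a, axis=-1)
    # global: divide the whole matrix by its Frobenius norm
    flat = a.reshape(a.shape[0], -1)
    return ad.l2_normalize(flat, axis=-1).reshape(a.shape)


def _graph_conv_t(x: Tensor, cheb_basis: np.ndarray, a_s, theta: Tensor,
                  activation: bool = True) -> Tensor:
    """sum_k (T_k(L~) (*) a'_s) x theta_k, optionally ReLU-activated.

    x : (B, N, L, C); a_s : (B, N, N) Tensor or None (no modulation);
    theta : (K+1, C, C1).
    """
    B, N, L, C = x.shape
    C1 = theta.shape[-1]
    x_flat = x.reshape(B, N, L * C)
    out = None
    for k in range(cheb_basis.shape[0]):
        Tk = Tensor(cheb_basis[k])
        M = Tk * a_s if a_s is not None else Tk
        h = ad.matmul(M, x_flat)                       # (B, N, L*C)
        h = h.reshape(B * N * L, C)
        term = ad.matmul(h, theta[k])                  # (B*N*L, C1)
        out = term if out is None else out + term
    out = out.reshape(B, N, L, C1)
    return ad.relu(out) if activation else out


def _temporal_conv_t(x1: Tensor, a_t, W: Tensor, b: Tensor) -> Tensor:
    """ReLU(Conv_(1,k)(x1 . a'_t) + b) with valid padding.

    x1 : (B, N, L, C1); a_t : (B, L, L) Tensor or None (identity);
    W : (k, C1, C2).  Output (B, N, L-k+1, C2).
    """
    B, N, L, C1 = x1.shape
    k, _, C2 = W.shape
    if L < k:
        raise ValueError(f"sequence length {L} shorter than kernel {k}")
    if a_t is not None:
        xt = x1.transpose((0, 1, 3, 2)).reshape(B, N * C1, L)
        xt = ad.matmul(xt, a_t)                        # contract time axis
        x1 = xt.reshape(B, N, C1, L).transpose((0, 1, 3, 2))
    L2 = L - k + 1
    out = None
    for d in range(k):
        sl = x1[:, :, d:d + L2, :].reshape(B * N * L2, C1)
        term = ad.matmul(sl, W[d])
        out = term if out is None else out + term
    out = out.reshape(B, N, L2, C2) + b
    return ad.relu(out)


def _global_aggregate_t(x2: Tensor, W3, b3, W4, b4):
    """Collapse nodes with a (N,1)-kernel conv, then time with a (1,L2) one."""
    B, N, L2, C2 = x2.shape
    flat = x2.transpose((0, 2, 1, 3)).reshape(B, L2, N * C2)
    x3 = ad.relu(ad.matmul(flat, W3) + b3)             # (B, L2, C2)
    x4 = ad.relu(ad.matmul(x3.reshape(B, L2 * C2), W4) + b4)  # (B, C2)
    return x3, x4


# ---------------------------------------------------------------------------
# public single-sample wrappers (numpy in, numpy out)
# ---------------------------------------------------------------------------

def pairwise_attention(x: np.ndarray, params: dict, mode: str) -> np.ndarray:
    """Raw (un-normalized) attention matrix for one (N, L, C) input.

    ``params`` must contain W1 (C,), b1 (N, L), W2 (C,), b2 (L, N).
    Spatial mode returns (N, N); temporal/spectral mode returns (L, L).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("input must be (N, L, C)")
    C = x.shape[2]
    for key in ("W1", "W2"):
        if np.asarray(params[key]).shape != (C,):
            raise ValueError(f"{key} must have shape ({C},)")
    out = _pairwise_attention_t(
        Tensor(x[None]), Tensor(params["W1"]), Tensor(params["b1"]),
        Tensor(params["W2"]), Tensor(params["b2"]),
        "spatial" if mode == "spatial" else "temporal",
    )
    return out.data[0]


def l2_normalize_rows(a: np.ndarray) -> np.ndarray:
    """Divide each row by its L2 norm; all-zero rows are returned unchanged."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("attention matrix must be finite")
    norm = np.sqrt((a ** 2).sum(axis=-1, keepdims=True))
    return a / np.where(norm > 0, norm, 1.0)


def attn_graph_conv(x: np.ndarray, ops: SpectralOperators, a_prime: np.ndarray,
                    theta: np.ndarray, activation: bool = True) -> np.ndarray:
    """Attention-modulated Chebyshev graph convolution of one (N, L, C) input."""
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != ops.cheb_order + 1:
        raise ValueError(
            f"theta provides {theta.shape[0]} coefficient matrices but the "
            f"operator stack has order K={ops.cheb_order}"
        )
    a_t = Tensor(np.asarray(a_prime, dtype=float)[None]) if a_prime is not None else None
    out = _graph_conv_t(Tensor(x[None]), ops.cheb_basis, a_t, Tensor(theta),
                        activation=activation)
    return out.data[0]


def temporal_spectral_conv(x1: np.ndarray, a_prime: np.ndarray, W: np.ndarray,
                           b: np.ndarray) -> np.ndarray:
    """Attention-contracted width-k convolution of one (N, L, C1) input."""
    a_t = Tensor(np.asarray(a_prime, dtype=float)[None]) if a_prime is not None else None
    out = _temporal_conv_t(Tensor(np.asarray(x1, dtype=float)[None]), a_t,
                           Tensor(np.asarray(W)), Tensor(np.asarray(b)))
    return out.data[0]


def global_aggregate(x2: np.ndarray, W3: np.ndarray, b3: np.ndarray,
                     W4: np.ndarray, b4: np.ndarray):
    """Global aggregation of one (N, L2, C2) input; returns (x3, x4).

    x3 has shape (1, L2, C2) and x4 has shape (1, 1, C2).
    """
    x3, x4 = _global_aggregate_t(
        Tensor(np.asarray(x2, dtype=float)[None]),
        Tensor(np.asarray(W3)), Tensor(np.asarray(b3)),
        Tensor(np.asarray(W4)), Tensor(np.asarray(b4)),
    )
    return x3.data, x4.data[:, None, :]


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _glorot(rng, *shape, fan_in=None, fan_out=None):
    fan_in = fan_in if fan_in is not None else shape[0]
    fan_out = fan_out if fan_out is not None else shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class CGCNN:
    """Dual-branch attention graph convolution classifier.

    Parameters are a flat dict of numpy arrays; :meth:`forward_logits`
    rebuilds the autodiff tape on every call.
    """

    def __init__(self, config: ModelConfig, ops: SpectralOperators):
        if ops.n_nodes != config.n_nodes:
            raise ValueError("operator stack and config disagree on node count")
        if ops.cheb_order != config.cheb_order:
            raise ValueError("operator stack and config disagree on Chebyshev order")
        self.config = config
        self.ops = ops
        self.params = self._init_params()

    # -- parameters -----------------------------------------------------------
    def _branch_lengths(self):
        cfg = self.config
        out = {}
        if cfg.use_st_branch:
            out["st"] = cfg.T
        if cfg.use_ss_branch:
            out["ss"] = cfg.F
        return out

    def _init_params(self) -> dict:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        N, K = cfg.n_nodes, cfg.cheb_order
        C, C1, C2, kt = cfg.in_channels, cfg.c1, cfg.c2, cfg.kernel_t
        p = {}
        for b, L in self._branch_lengths().items():
            L2 = L - kt + 1
            if cfg.use_attention:
                p[f"{b}.att_s.W1"] = _glorot(rng, C, fan_in=C, fan_out=1)
                p[f"{b}.att_s.W2"] = _glorot(rng, C, fan_in=C, fan_out=1)
                p[f"{b}.att_s.b1"] = np.zeros((N, L))
                p[f"{b}.att_s.b2"] = np.zeros((L, N))
            p[f"{b}.theta"] = np.stack(
                [_glorot(rng, C, C1) for _ in range(K + 1)]
            ) / (K + 1)
            if cfg.use_attention:
                p[f"{b}.att_t.W1"] = _glorot(rng, C1, fan_in=C1, fan_out=1)
                p[f"{b}.att_t.W2"] = _glorot(rng, C1, fan_in=C1, fan_out=1)
                p[f"{b}.att_t.b1"] = np.zeros((N, L))
                p[f"{b}.att_t.b2"] = np.zeros((L, N))
            p[f"{b}.conv.W"] = _glorot(rng, kt, C1, C2, fan_in=kt * C1, fan_out=C2)
            p[f"{b}.conv.b"] = np.zeros(C2)
            if cfg.use_global_aggregation:
                p[f"{b}.agg.W3"] = _glorot(rng, N * C2, C2)
                p[f"{b}.agg.b3"] = np.zeros(C2)
                p[f"{b}.agg.W4"] = _glorot(rng, L2 * C2, C2)
                p[f"{b}.agg.b4"] = np.zeros(C2)
            if cfg.use_shortcut:
                p[f"{b}.sc.W"] = _glorot(rng, C, C2)
                p[f"{b}.sc.b"] = np.zeros(C2)
        n_branches = len(self._branch_lengths())
        p["fc.W"] = _glorot(rng, n_branches * C2, cfg.n_classes)
        p["fc.b"] = np.zeros(cfg.n_classes)
        return p

    # -- forward --------------------------------------------------------------
    def _branch(self, prefix: str, x: Tensor, p: dict) -> Tensor:
        cfg = self.config
        if cfg.use_attention:
            a_s = _pairwise_attention_t(
                x, p[f"{prefix}.att_s.W1"], p[f"{prefix}.att_s.b1"],
                p[f"{prefix}.att_s.W2"], p[f"{prefix}.att_s.b2"], "spatial")
            a_s = _normalize_attention_t(a_s, cfg.attention_norm)
        else:
            a_s = None
        x1 = _graph_conv_t(x, self.ops.cheb_basis, a_s, p[f"{prefix}.theta"])
        if cfg.use_attention:
            a_t = _pairwise_attention_t(
                x1, p[f"{prefix}.att_t.W1"], p[f"{prefix}.att_t.b1"],
                p[f"{prefix}.att_t.W2"], p[f"{prefix}.att_t.b2"], "temporal")
            a_t = _normalize_attention_t(a_t, cfg.attention_norm)
        else:
            a_t = None
        x2 = _temporal_conv_t(x1, a_t, p[f"{prefix}.conv.W"], p[f"{prefix}.conv.b"])
        if cfg.use_global_aggregation:
            _, feat = _global_aggregate_t(
                x2, p[f"{prefix}.agg.W3"], p[f"{prefix}.agg.b3"],
                p[f"{prefix}.agg.W4"], p[f"{prefix}.agg.b4"])
        else:
            feat = x2.mean(axis=(1, 2))
        if cfg.use_shortcut:
            res = ad.matmul(x.mean(axis=(1, 2)), p[f"{prefix}.sc.W"])
            feat = feat + res + p[f"{prefix}.sc.b"]
        return feat

    def forward_logits(self, x_st=None, x_ss=None, params: dict = None) -> Tensor:
        """Class logits for batched inputs (B, N, L, C); returns (B, n_classes)."""
        cfg = self.config
        raw = params if params is not None else self.params
        p = {k: (v if isinstance(v, Tensor) else Tensor(v, requires_grad=True))
             for k, v in raw.items()}
        self._tensors = p  # exposed for the optimizer to harvest gradients
        feats = []
        if cfg.use_st_branch:
            if x_st is None:
                raise ValueError("spatial-temporal branch enabled but x_st missing")
            feats.append(self._branch("st", _as_input(x_st), p))
        elif x_st is not None:
            warnings.warn("x_st supplied but the spatial-temporal branch is disabled")
        if cfg.use_ss_branch:
            if x_ss is None:
                raise ValueError("spatial-spectral branch enabled but x_ss missing")
            feats.append(self._branch("ss", _as_input(x_ss), p))
        elif x_ss is not None:
            warnings.warn("x_ss supplied but the spatial-spectral branch is disabled")
        fused = feats[0] if len(feats) == 1 else ad.concat(feats, axis=1)
        return ad.matmul(fused, p["fc.W"]) + p["fc.b"]

    def predict_proba(self, x_st=None, x_ss=None) -> np.ndarray:
        logits = self.forward_logits(x_st, x_ss)
        return ad.softmax(logits.data, axis=-1)

    def predict(self, x_st=None, x_ss=None) -> np.ndarray:
        return self.predict_proba(x_st, x_ss).argmax(axis=-1)


def _as_input(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:  # single sample (N, L, C)
        x = x[None]
    if x.ndim != 4:
        raise ValueError("branch input must be (B, N, L, C)")
    return Tensor(x)
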