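"""Graph attention autoencoder over the population graph.

Encoder: stacked multi-head graph attention (GAT) layers. For head k,

    e_ij = LeakyReLU(a_k^T [W_k h_i || W_k h_j])
    alpha_ij = softmax_j(e_ij)  over the inclusive neighborhood of i
    h_i' = || _k  sum_j alpha_ij W_k h_j

with self-loops inserted inside the layer so every node attends to itself.
Inside the encoder each layer is ordered attention -> LayerNorm -> ELU, and a
final fully connected map projects to the latent embedding z_i = W_mu h_i + b_mu.

Decoder: an MLP (LayerNorm + LeakyReLU between hidden layers) reconstructs
node features, and an inner-product decoder sigmoid(Z Z^T) reconstructs the
adjacency. The loss is

    L = mean_i ||x_i - xhat_i||^2  +  lambda * BCE(A, Ahat)   (BCE over all N^2 cells)

trained full-batch with Adam. The whole model runs on the package's own
float64 autodiff engine: parameters are plain numpy arrays, training is
bit-reproducible given a seed, and no GPU or minibatching is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, concat

__all__ = [
    "EncoderConfig",
    "DecoderConfig",
    "TrainConfig",
    "GatLayerParams",
    "GaaeModel",
    "LossReport",
    "gat_layer_forward",
    "encode",
    "decode_features",
    "decode_structure",
    "compute_loss",
    "init_model",
    "train",
]

_LN_EPS = 1e-5
_BCE_EPS = 1e-7


@dataclass
class EncoderConfig:
    layer_dims: tuple = (256, 128, 64, 32)   # concatenated output dim per layer
    heads: tuple = (4, 4, 1, 1)
    latent_dim: int = 16
    attention_negative_slope: float = 0.2
    final_activation: bool = True            # LayerNorm+ELU after the last layer

    def __post_init__(self):
        if len(self.layer_dims) != len(self.heads):
            raise ValueError("layer_dims and heads must have equal length")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        for d, h in zip(self.layer_dims, self.heads):
            if d % h:
                raise ValueError(f"layer dim {d} not divisible by {h} heads")


@dataclass
class DecoderConfig:
    hidden_dims: tuple = (32, 64, 128)
    negative_slope: float = 0.01


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 500
    lambda_struct: float = 0.3   # the study's selected balancing coefficient
    seed: int = 0
    standardize_features: bool = True

    def __post_init__(self):
        if self.lambda_struct < 0:
            raise ValueError("lambda_struct must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class GatLayerParams:
    """Per-head projection W, attention vector split as (a_src, a_dst), and
    the post-aggregation LayerNorm gain/bias."""

    w: list          # heads x Tensor(in_dim, head_dim)
    a_src: list      # heads x Tensor(head_dim, 1)
    a_dst: list
    ln_gain: Tensor  # (1, out_dim)
    ln_bias: Tensor

    def tensors(self):
        return [*self.w, *self.a_src, *self.a_dst, self.ln_gain, self.ln_bias]


@dataclass
class GaaeModel:
    encoder: EncoderConfig
    decoder: DecoderConfig
    layers: list                 # list[GatLayerParams]
    w_mu: Tensor
    b_mu: Tensor
    dec_hidden: list             # list[(W, b, ln_gain, ln_bias)]
    dec_out: tuple               # (W, b)
    feature_mean: np.ndarray | None = None  # standardization used at train time
    feature_sd: np.ndarray | None = None
    attention_: list = field(default_factory=list)  # per layer: list of N x N per head

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in self.layers:
            ps += layer.tensors()
        ps += [self.w_mu, self.b_mu]
        for w, b, g, bb in self.dec_hidden:
            ps += [w, b, g, bb]
        ps += list(self.dec_out)
        return ps


@dataclass
class LossReport:
    l_recon: float
    l_struct: float
    l_total: float
    history: list = field(default_factory=list)  # per-epoch (l_recon, l_struct, l_total)


# ---------------------------------------------------------------------------
# forward pieces
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    m = x.mean(axis=1, keepdims=True)
    centered = x - m
    v = (centered**2).mean(axis=1, keepdims=True)
    return centered / ((v + _LN_EPS) ** 0.5) * gain + bias


def gat_layer_forward(
    h,
    adjacency: np.ndarray,
    layer_params: GatLayerParams,
    negative_slope: float = 0.2,
    activation: str | None = "elu",
    return_attention: bool = False,
):
    """One multi-head attention layer on the inclusive neighborhood.

    `h` may be a numpy array or a Tensor; output is a Tensor of width
    heads * head_dim. With activation="elu" the aggregation is passed through
    ELU (the standalone layer contract); the encoder instead requests the raw
    aggregation and applies LayerNorm + ELU itself.
    """
    h = h if isinstance(h, Tensor) else Tensor(h)
    n = adjacency.shape[0]
    if h.shape[0] != n:
        raise ValueError("feature row count does not match adjacency size")
    mask = (np.asarray(adjacency) > 0).astype(float)
    np.fill_diagonal(mask, 1.0)  # self-loops: inclusive neighborhood

    outs, alphas = [], []
    for wk, ak_s, ak_d in zip(layer_params.w, layer_params.a_src, layer_params.a_dst):
        hw = h @ wk                                   # N x d
        f = hw @ ak_s                                 # N x 1
        g = hw @ ak_d
        e = (f + g.T).leaky_relu(negative_slope)      # N x N, e_ij = LReLU(f_i + g_j)
        e = e * mask + (-1e4) * (1.0 - mask)          # exclude non-neighbors
        shift = e.data.max(axis=1, keepdims=True)     # detached, softmax-stable
        ex = (e - shift).exp() * mask
        alpha = ex / ex.sum(axis=1, keepdims=True)
        outs.append(alpha @ hw)
        alphas.append(alpha)
    out = outs[0] if len(outs) == 1 else concat(outs, axis=1)
    if activation == "elu":
        out = out.elu()
    if return_attention:
        return out, [a.data for a in alphas]
    return out


def encode(x, adjacency, model: GaaeModel, return_attention: bool = False):
    """Latent embedding Z = W_mu h^(L) + b_mu after all attention layers."""
    h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(h.data)):
        raise ValueError("non-finite input features")
    n_layers = len(model.layers)
    all_alphas = []
    for li, layer in enumerate(model.layers):
        agg, alphas = gat_layer_forward(
            h, adjacency, layer,
            negative_slope=model.encoder.attention_negative_slope,
            activation=None, return_attention=True,
        )
        all_alphas.append(alphas)
        last = li == n_layers - 1
        if not last or model.encoder.final_activation:
            h = _layer_norm(agg, layer.ln_gain, layer.ln_bias).elu()
        else:
            h = agg
    z = h @ model.w_mu + model.b_mu
    if return_attention:
        return z, all_alphas
    return z


def decode_features(z, model: GaaeModel) -> Tensor:
    h = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
    for w, b, g, bb in model.dec_hidden:
        h = _layer_norm(h @ w + b, g, bb).leaky_relu(model.decoder.negative_slope)
    w, b = model.dec_out
    return h @ w + b


def decode_structure(z) -> Tensor:
    """Inner-product decoder: Ahat = sigmoid(Z Z^T)."""
    z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=float))
    return (z @ z.T).sigmoid()


def compute_loss(x, x_hat, adjacency, a_hat, lambda_struct: float) -> LossReport:
    """Feature MSE (summed over features, averaged over nodes) plus
    lambda * BCE over all N^2 adjacency cells (predictions clamped away
    from {0,1}). Accepts numpy arrays; returns scalar floats."""
    l_recon, l_struct, l_total = _loss_tensors(
        Tensor._wrap(x), Tensor._wrap(x_hat), np.asarray(adjacency, dtype=float),
        Tensor._wrap(a_hat), lambda_struct,
    )
    return LossReport(float(l_recon.data), float(l_struct.data), float(l_total.data))


def _loss_tensors(x: Tensor, x_hat: Tensor, adjacency: np.ndarray,
                  a_hat: Tensor, lambda_struct: float):
    if lambda_struct < 0:
        raise ValueError("lambda_struct must be >= 0")
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes differ")
    n = x.shape[0]
    l_recon = ((x_hat - x) ** 2).sum() * (1.0 / n)
    p = a_hat.clip(_BCE_EPS, 1.0 - _BCE_EPS)
    a = adjacency
    bce = -(a * p.log() + (1.0 - a) * (1.0 - p).log()).sum() * (1.0 / (n * n))
    l_total = l_recon + lambda_struct * bce
    return l_recon, bce, l_total


# ---------------------------------------------------------------------------
# initialization and training
# ---------------------------------------------------------------------------

def _glorot(rng, fan_in, fan_out, shape=None) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, (fan_in, fan_out) if shape is None else shape),
                  requires_grad=True)


def init_model(n_features: int, enc: EncoderConfig, dec: DecoderConfig,
               seed: int = 0) -> GaaeModel:
    """Glorot-uniform weights and attention vectors, zero biases, unit
    LayerNorm gains; seeded."""
    rng = np.random.default_rng(seed)
    layers = []
    in_dim = n_features
    for dim, heads in zip(enc.layer_dims, enc.heads):
        hd = dim // heads
        layers.append(GatLayerParams(
            w=[_glorot(rng, in_dim, hd) for _ in range(heads)],
            a_src=[_glorot(rng, 2 * hd, 1, shape=(hd, 1)) for _ in range(heads)],
            a_dst=[_glorot(rng, 2 * hd, 1, shape=(hd, 1)) for _ in range(heads)],
            ln_gain=Tensor(np.ones((1, dim)), requires_grad=True),
            ln_bias=Tensor(np.zeros((1, dim)), requires_grad=True),
        ))
        in_dim = dim
    w_mu = _glorot(rng, in_dim, enc.latent_dim)
    b_mu = Tensor(np.zeros((1, enc.latent_dim)), requires_grad=True)

    dec_hidden = []
    d_in = enc.latent_dim
    for d_out in dec.hidden_dims:
        dec_hidden.append((
            _glorot(rng, d_in, d_out),
            Tensor(np.zeros((1, d_out)), requires_grad=True),
            Tensor(np.ones((1, d_out)), requires_grad=True),
            Tensor(np.zeros((1, d_out)), requires_grad=True),
        ))
        d_in = d_out
    dec_out = (_glorot(rng, d_in, n_features),
               Tensor(np.zeros((1, n_features)), requires_grad=True))
    return GaaeModel(encoder=enc, decoder=dec, layers=layers,
                     w_mu=w_mu, b_mu=b_mu, dec_hidden=dec_hidden, dec_out=dec_out)


def train(graph, enc: EncoderConfig | None = None, dec: DecoderConfig | None = None,
          cfg: TrainConfig | None = None):
    """Full-batch training; returns (model, Z, LossReport-with-history).

    The returned embeddings and attention coefficients come from a final
    evaluation pass with the post-training parameters.
    """
    enc = enc or EncoderConfig()
    dec = dec or DecoderConfig()
    cfg = cfg or TrainConfig()
    if graph.n_edges == 0:
        raise ValueError("population graph has no edges; refusing to train")

    x_raw = np.asarray(graph.node_features, dtype=float)
    if cfg.standardize_features:
        mean = x_raw.mean(axis=0)
        sd = x_raw.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x_raw - mean) / sd
    else:
        mean, sd = None, None
        x = x_raw
    adjacency = np.asarray(graph.adjacency, dtype=float)

    model = init_model(x.shape[1], enc, dec, seed=cfg.seed)
    model.feature_mean, model.feature_sd = mean, sd
    opt = Adam(model.parameters(), lr=cfg.learning_rate)

    history = []
    xt = Tensor(x)
    for epoch in range(cfg.epochs):
        z = encode(xt, adjacency, model)
        x_hat = decode_features(z, model)
        a_hat = decode_structure(z)
        l_recon, l_struct, l_total = _loss_tensors(xt, x_hat, adjacency, a_hat,
                                                   cfg.lambda_struct)
        if not np.isfinite(l_total.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        history.append((float(l_recon.data), float(l_struct.data), float(l_total.data)))
        opt.zero_grad()
        l_total.backward()
        opt.step()

    # final evaluation pass with trained parameters
    z, alphas = encode(xt, adjacency, model, return_attention=True)
    x_hat = decode_features(z, model)
    a_hat = decode_structure(z)
    l_recon, l_struct, l_total = _loss_tensors(xt, x_hat, adjacency, a_hat,
                                               cfg.lambda_struct)
    model.attention_ = alphas
    report = LossReport(float(l_recon.data), float(l_struct.data),
                        float(l_total.data), history=history)
    return model, z.data.copy(), report


def attention_edge_table(model: GaaeModel, graph, layer: int = -1) -> "np.ndarray":
    """Head-averaged final-layer attention on the graph's edges, as an array
    of (i, j, alpha_ij) rows for both edge directions."""
    import pandas as pd

    if not model.attention_:
        raise ValueError("model carries no attention coefficients; train first")
    heads = model.attention_[layer]
    alpha = np.mean(heads, axis=0)
    rows = []
    for i, j in graph.edge_list:
        rows.append((int(i), int(j), float(alpha[i, j])))
        rows.append((int(j), int(i), float(alpha[j, i])))
    return pd.DataFrame(rows, columns=["i", "j", "alpha"])
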