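"""Stacked denoising autoencoder (SDA) feature extractor.

Architecture, fixed by default: 12 -> 40 -> 8 -> 40 -> 12 with ReLU
activations throughout. The encoder compresses each normalized 12-D IMU
frame to an 8-D code; the decoder reconstructs the frame. Denoising comes
from dropout (rate 0.2) applied after each 40-D expansion activation during
training only — stochastic corruption of the internal representation, the
classic denoising mechanism. Training minimizes the mean squared
reconstruction error over the batch,

    L = (1/N) * sum_i || x_i - x_hat_i ||^2 ,

end to end with a single Adam optimizer. After training the per-frame
reconstruction (decoder output, 12-D) is the feature handed to the
classifier; the 8-D bottleneck code can be used instead via an option.

The decoder's output activation is ReLU by default (matching the encoder/
decoder symmetry); a linear output is available for inputs with negative
support where exact reconstruction matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, check_finite, relu
from .preprocess import WindowSet

__all__ = ["SdaParams", "encode", "decode", "reconstruction_loss", "pretrain", "extract_features"]

LAYER_SIZES = (12, 40, 8, 40, 12)


@dataclass
class SdaParams:
    """Weights of the 12->40->8->40->12 autoencoder.

    Encoder: W1/b1 (12->40) then Wb/bb (40->8). Decoder: Wd/bd (8->40) then
    W2/b2 (40->12). ``dropout_p`` is active only in training mode;
    ``output_activation`` is "relu" or "linear".
    """

    W1: np.ndarray
    b1: np.ndarray
    Wb: np.ndarray
    bb: np.ndarray
    Wd: np.ndarray
    bd: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    dropout_p: float = 0.2
    output_activation: str = "relu"

    def __post_init__(self):
        shapes = {
            "W1": (12, 40), "b1": (40,), "Wb": (40, 8), "bb": (8,),
            "Wd": (8, 40), "bd": (40,), "W2": (40, 12), "b2": (12,),
        }
        for name, shape in shapes.items():
            arr = np.ascontiguousarray(getattr(self, name), dtype=np.float32)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.output_activation not in ("relu", "linear"):
            raise ValueError("output_activation must be 'relu' or 'linear'")

    @classmethod
    def init(cls, seed: int = 0, dropout_p: float = 0.2, output_activation: str = "relu") -> "SdaParams":
        """Fan-in-scaled uniform random initialization with a recorded seed."""
        rng = np.random.default_rng(seed)

        def w(din, dout):
            k = 1.0 / np.sqrt(din)
            return rng.uniform(-k, k, size=(din, dout)).astype(np.float32)

        return cls(
            W1=w(12, 40), b1=np.zeros(40, np.float32),
            Wb=w(40, 8), bb=np.zeros(8, np.float32),
            Wd=w(8, 40), bd=np.zeros(40, np.float32),
            W2=w(40, 12), b2=np.zeros(12, np.float32),
            dropout_p=dropout_p, output_activation=output_activation,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("W1", "b1", "Wb", "bb", "Wd", "bd", "W2", "b2")}


def _dropout_mask(rng, shape, p):
    # inverted dropout: scale kept units by 1/(1-p) so eval needs no rescaling
    return (rng.random(shape) >= p).astype(np.float32) / np.float32(1.0 - p)


def encode(x: np.ndarray, params: SdaParams, training: bool = False, rng=None) -> np.ndarray:
    """Map 12-D frames to the 8-D code h = relu(Wb.relu(W1 x + b1) + bb)."""
    x = np.asarray(x, dtype=np.float32)
    single = x.ndim == 1
    xb = x.reshape(1, -1) if single else x
    if xb.shape[-1] != 12:
        raise ValueError(f"expected 12-D input frames, got {xb.shape[-1]}-D")
    h1 = relu(xb @ params.W1 + params.b1)
    if training and params.dropout_p > 0:
        if rng is None:
            raise ValueError("training-mode encode needs an rng for dropout")
        h1 = h1 * _dropout_mask(rng, h1.shape, params.dropout_p)
    h = relu(h1 @ params.Wb + params.bb)
    return h[0] if single else h


def decode(h: np.ndarray, params: SdaParams, training: bool = False, rng=None) -> np.ndarray:
    """Reconstruct 12-D frames from the 8-D code."""
    h = np.asarray(h, dtype=np.float32)
    single = h.ndim == 1
    hb = h.reshape(1, -1) if single else h
    if hb.shape[-1] != 8:
        raise ValueError(f"expected 8-D codes, got {hb.shape[-1]}-D")
    hd = relu(hb @ params.Wd + params.bd)
    if training and params.dropout_p > 0:
        if rng is None:
            raise ValueError("training-mode decode needs an rng for dropout")
        hd = hd * _dropout_mask(rng, hd.shape, params.dropout_p)
    pre = hd @ params.W2 + params.b2
    out = relu(pre) if params.output_activation == "relu" else pre
    return out[0] if single else out


def reconstruction_loss(x_batch: np.ndarray, xhat_batch: np.ndarray) -> float:
    """Mean over the batch of squared Euclidean reconstruction errors."""
    x = np.asarray(x_batch, dtype=np.float64)
    xh = np.asarray(xhat_batch, dtype=np.float64)
    if x.shape != xh.shape:
        raise ValueError("x and x_hat must have identical shapes")
    if x.ndim == 1:
        x, xh = x[None, :], xh[None, :]
    if x.shape[0] == 0:
        raise ValueError("empty batch")
    return float(np.mean(np.sum((x - xh) ** 2, axis=1)))


def _forward_backward(xb, params: SdaParams, rng):
    """One training-mode forward + backward pass; returns (loss, grads)."""
    p = params
    N = xb.shape[0]
    m1 = _dropout_mask(rng, (N, 40), p.dropout_p) if p.dropout_p > 0 else 1.0
    m2 = _dropout_mask(rng, (N, 40), p.dropout_p) if p.dropout_p > 0 else 1.0

    z1 = xb @ p.W1 + p.b1
    h1 = relu(z1) * m1
    zb = h1 @ p.Wb + p.bb
    h = relu(zb)
    zd = h @ p.Wd + p.bd
    hd = relu(zd) * m2
    z2 = hd @ p.W2 + p.b2
    xhat = relu(z2) if p.output_activation == "relu" else z2

    diff = xhat - xb
    loss = float(np.mean(np.sum(diff.astype(np.float64) ** 2, axis=1)))

    d2 = (2.0 / N) * diff
    if p.output_activation == "relu":
        d2 = d2 * (z2 > 0)
    g = {}
    g["W2"] = hd.T @ d2
    g["b2"] = d2.sum(axis=0)
    dhd = (d2 @ p.W2.T) * m2 * (zd > 0)
    g["Wd"] = h.T @ dhd
    g["bd"] = dhd.sum(axis=0)
    dh = (dhd @ p.Wd.T) * (zb > 0)
    g["Wb"] = h1.T @ dh
    g["bb"] = dh.sum(axis=0)
    dh1 = (dh @ p.Wb.T) * m1 * (z1 > 0)
    g["W1"] = xb.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return loss, {k: v.astype(np.float32) for k, v in g.items()}


def pretrain(frames: np.ndarray, config, params: SdaParams | None = None):
    """Train the autoencoder on normalized 12-D frames.

    Minimizes the batch-mean squared reconstruction error with dropout
    active (the stochastic-corruption/denoising mechanism). Returns the
    trained :class:`SdaParams` and the per-epoch mean training loss.
    Seeded runs are bit-reproducible.

    Parameters
    ----------
    frames : (M, 12) array
        Normalized IMU frames; M must be at least the batch size.
    config : TrainConfig
        Uses ``sda_epochs``/``epochs``, ``lr_sda``, ``batch_size``,
        optimizer decays/epsilon, and ``rng_seed``.
    params : SdaParams, optional
        Warm-start weights; fresh seeded initialization if omitted.
    """
    frames = np.ascontiguousarray(frames, dtype=np.float32)
    if frames.ndim != 2 or frames.shape[1] != 12:
        raise ValueError("frames must be an (M, 12) matrix")
    batch = min(config.batch_size, frames.shape[0])
    if frames.shape[0] < 1:
        raise ValueError("no frames to pretrain on")
    epochs = config.sda_epochs
    rng = np.random.default_rng(config.rng_seed)
    if params is None:
        params = SdaParams.init(seed=int(rng.integers(2**31 - 1)), dropout_p=params_dropout(config))
    pdict = params.as_dict()
    opt = Adam(pdict, lr=config.lr_sda, beta1=config.beta1, beta2=config.beta2, eps=config.eps)

    M = frames.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(M)
        losses = []
        for start in range(0, M, batch):
            xb = frames[order[start : start + batch]]
            loss, grads = _forward_backward(xb, params, rng)
            check_finite(loss, "SDA pretraining")
            opt.step(pdict, grads)
            losses.append(loss * xb.shape[0])
        history.append(float(np.sum(losses) / M))
    return params, history


def params_dropout(config) -> float:
    return getattr(config, "sda_dropout", 0.2)


def extract_features(windows: WindowSet, params: SdaParams, use_code: bool = False) -> WindowSet:
    """Replace every frame of every window by its SDA feature (eval mode).

    Default feature is the 12-D reconstruction decode(encode(frame));
    ``use_code=True`` emits the 8-D bottleneck code instead. Window count,
    labels and subject ids are preserved.
    """
    if windows.D != 12:
        raise ValueError(f"SDA expects 12-D frames, got D={windows.D}")
    flat = windows.windows.reshape(-1, 12)
    codes = encode(flat, params, training=False)
    feats = codes if use_code else decode(codes, params, training=False)
    out = feats.reshape(len(windows), windows.Lw, feats.shape[-1])
    return WindowSet(out, windows.labels.copy(), windows.subject_ids.copy(), windows.Lw, windows.stride)
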