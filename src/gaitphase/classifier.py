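"""Two-layer LSTM gait-phase classifier over SDA feature windows.

Many-to-one sequence labeling: a window of Lw = 50 feature frames (12-D
each) is run through two stacked LSTM layers of 50 hidden units; only the
final hidden state h_T of the top layer feeds a fully connected softmax
head over the four phase classes,

    P(y = k | h_T) = exp(w_k . h_T + b_k) / sum_j exp(w_j . h_T + b_j).

Training minimizes the categorical cross-entropy -log P(y = true | h_T)
with the Adam optimizer (adaptive moment estimation, step
eta * m_hat / (sqrt(v_hat) + eps)). The forward pass, backpropagation
through time and the optimizer are implemented in numpy (float32); seeded
runs are bit-reproducible on a fixed thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, check_finite, sigmoid, softmax
from .preprocess import N_CLASSES, WindowSet

__all__ = ["TrainConfig", "LstmParams", "Prediction", "forward", "cross_entropy", "train", "predict"]

HIDDEN = 50
DEPTH = 2
INPUT_DIM = 12
PROB_FLOOR = 1e-12  # clamp for -log(p) when a probability underflows


@dataclass
class TrainConfig:
    """Hyperparameters of the two-stage training procedure.

    ``epochs`` drives the classifier stage; ``sda_epochs`` (default: same
    as ``epochs``) drives autoencoder pretraining. Learning rates follow
    the two-stage convention: 1e-4 for the feature extractor, 5e-5 for the
    classifier. ``freeze_sda=True`` keeps the feature extractor fixed while
    the classifier trains; False backpropagates the classification loss
    into the autoencoder as well (joint fine-tuning).
    """

    epochs: int = 100
    sda_epochs: int | None = None
    lr_sda: float = 1e-4
    lr_classifier: float = 5e-5
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    rng_seed: int = 0
    freeze_sda: bool = True
    sda_dropout: float = 0.2
    class_weights: tuple | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_sda <= 0 or self.lr_classifier <= 0:
            raise ValueError("learning rates must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.sda_epochs is None:
            self.sda_epochs = self.epochs


@dataclass
class LstmParams:
    """Weights of the 2 x 50-unit LSTM stack and the 4-class softmax head.

    Per layer l: input weights Wx_l (Din x 4H), recurrent weights Wh_l
    (H x 4H), bias b_l (4H), gate order (input, forget, cell, output).
    Head: W_out (H x 4), b_out (4).
    """

    Wx0: np.ndarray
    Wh0: np.ndarray
    b0: np.ndarray
    Wx1: np.ndarray
    Wh1: np.ndarray
    b1: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray
    input_dim: int = INPUT_DIM

    def __post_init__(self):
        shapes = {
            "Wx0": (self.input_dim, 4 * HIDDEN), "Wh0": (HIDDEN, 4 * HIDDEN), "b0": (4 * HIDDEN,),
            "Wx1": (HIDDEN, 4 * HIDDEN), "Wh1": (HIDDEN, 4 * HIDDEN), "b1": (4 * HIDDEN,),
            "W_out": (HIDDEN, N_CLASSES), "b_out": (N_CLASSES,),
        }
        for name, shape in shapes.items():
            arr = np.ascontiguousarray(getattr(self, name), dtype=np.float32)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)

    @classmethod
    def init(cls, seed: int = 0, input_dim: int = INPUT_DIM) -> "LstmParams":
        """Uniform(-1/sqrt(H), 1/sqrt(H)) init; forget-gate biases start at 1."""
        rng = np.random.default_rng(seed)
        k = 1.0 / np.sqrt(HIDDEN)

        def u(*shape):
            return rng.uniform(-k, k, size=shape).astype(np.float32)

        b0 = np.zeros(4 * HIDDEN, np.float32)
        b1 = np.zeros(4 * HIDDEN, np.float32)
        b0[HIDDEN : 2 * HIDDEN] = 1.0
        b1[HIDDEN : 2 * HIDDEN] = 1.0
        return cls(
            Wx0=u(input_dim, 4 * HIDDEN), Wh0=u(HIDDEN, 4 * HIDDEN), b0=b0,
            Wx1=u(HIDDEN, 4 * HIDDEN), Wh1=u(HIDDEN, 4 * HIDDEN), b1=b1,
            W_out=u(HIDDEN, N_CLASSES), b_out=np.zeros(N_CLASSES, np.float32),
            input_dim=input_dim,
        )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("Wx0", "Wh0", "b0", "Wx1", "Wh1", "b1", "W_out", "b_out")}


@dataclass
class Prediction:
    """Softmax class probabilities and the predicted phase label."""

    probs: np.ndarray
    label: int

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float).ravel()
        if self.probs.shape != (N_CLASSES,):
            raise ValueError("probs must be a 4-vector")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must lie on the probability simplex")


def _layer_forward(x, Wx, Wh, b, cache: bool):
    """Run one LSTM layer over a (B, T, Din) batch; returns h-sequence."""
    B, T, _ = x.shape
    H = HIDDEN
    h = np.zeros((B, H), np.float32)
    c = np.zeros((B, H), np.float32)
    hs = np.empty((B, T, H), np.float32)
    caches = [] if cache else None
    xW = x.reshape(B * T, -1) @ Wx  # precompute input contributions
    xW = xW.reshape(B, T, 4 * H)
    for t in range(T):
        a = xW[:, t, :] + h @ Wh + b
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t, :] = h
        if cache:
            caches.append((i, f, g, o, c_prev, tc, h_prev))
    return hs, caches


def _layer_backward(x, hs, caches, Wx, Wh, dh_ext):
    """BPTT for one layer. dh_ext is (B, T, H) gradient w.r.t. each h_t."""
    B, T, Din = x.shape
    H = HIDDEN
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, np.float32)
    dx = np.empty((B, T, Din), np.float32)
    dh_next = np.zeros((B, H), np.float32)
    dc_next = np.zeros((B, H), np.float32)
    da_all = np.empty((B, T, 4 * H), np.float32)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = caches[t]
        dh = dh_ext[:, t, :] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da = np.empty((B, 4 * H), np.float32)
        da[:, :H] = di * i * (1.0 - i)
        da[:, H : 2 * H] = df * f * (1.0 - f)
        da[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
        da[:, 3 * H :] = do * o * (1.0 - o)
        da_all[:, t, :] = da
        dWh += h_prev.T @ da
        db += da.sum(axis=0)
        dh_next = da @ Wh.T
        dc_next = dc * f
    flat_da = da_all.reshape(B * T, 4 * H)
    flat_x = x.reshape(B * T, Din)
    dWx[...] = flat_x.T @ flat_da
    dx[...] = (flat_da @ Wx.T).reshape(B, T, Din)
    return dWx, dWh, db, dx


def _forward_batch(x, params: LstmParams, cache: bool = False):
    """Full network forward on (B, T, D) windows -> (probs, logits, caches)."""
    hs0, c0 = _layer_forward(x, params.Wx0, params.Wh0, params.b0, cache)
    hs1, c1 = _layer_forward(hs0, params.Wx1, params.Wh1, params.b1, cache)
    hT = hs1[:, -1, :]
    logits = hT @ params.W_out + params.b_out
    probs = softmax(logits.astype(np.float64))
    if cache:
        return probs, logits, (hs0, c0, hs1, c1, hT)
    return probs, logits, None


def forward(feature_window: np.ndarray, params: LstmParams) -> Prediction:
    """Classify one Lw x 12 feature window (eval mode, deterministic).

    Only the final time-step hidden state of the top layer feeds the
    softmax head; ties in the probabilities resolve to the smallest class
    index.
    """
    x = np.asarray(feature_window, dtype=np.float32)
    if x.ndim != 2 or x.shape[1] != params.input_dim:
        raise ValueError(f"expected an (Lw, {params.input_dim}) window, got {x.shape}")
    probs, _, _ = _forward_batch(x[None, :, :], params)
    p = probs[0]
    return Prediction(probs=p, label=int(np.argmax(p)))


def cross_entropy(prediction: Prediction | np.ndarray, true_label: int) -> float:
    """Categorical cross-entropy -log P(y = true class).

    A zero probability at the true class is clamped at 1e-12 before the
    log, so the loss is finite (~27.6) rather than infinite.
    """
    probs = prediction.probs if isinstance(prediction, Prediction) else np.asarray(prediction, float)
    if not 0 <= int(true_label) < N_CLASSES:
        raise ValueError("true_label must be in 0..3")
    return float(-np.log(max(probs[int(true_label)], PROB_FLOOR)))


def train(
    features: WindowSet,
    config: TrainConfig,
    sda_params=None,
    init_params: LstmParams | None = None,
):
    """Train the LSTM on labeled feature windows.

    If ``sda_params`` is given and ``config.freeze_sda`` is True (default),
    windows are passed through the frozen feature extractor first; with
    ``freeze_sda=False`` the classification loss is also backpropagated
    into the autoencoder (joint fine-tuning, dropout off).

    Returns ``(LstmParams, history)`` where history is a list of per-epoch
    dicts with keys ``epoch``, ``loss`` (mean cross-entropy) and
    ``accuracy`` (training accuracy). Same seed and config give identical
    final parameters.
    """
    from . import sda as _sda

    labels = features.labels
    if np.any((labels < 0) | (labels >= N_CLASSES)):
        raise ValueError("window labels must lie in 0..3")
    if len(features) < 1:
        raise ValueError("no windows to train on")
    if np.unique(labels).size < 2:
        import warnings

        warnings.warn("training data contains a single class; the task is degenerate")

    joint = sda_params is not None and not config.freeze_sda
    if sda_params is not None and config.freeze_sda:
        features = _sda.extract_features(features, sda_params)

    rng = np.random.default_rng(config.rng_seed + 1)
    params = init_params or LstmParams.init(seed=int(rng.integers(2**31 - 1)), input_dim=features.D)
    pdict = params.as_dict()
    opt = Adam(pdict, lr=config.lr_classifier, beta1=config.beta1, beta2=config.beta2, eps=config.eps)
    if joint:
        sdict = sda_params.as_dict()
        sopt = Adam(sdict, lr=config.lr_classifier, beta1=config.beta1, beta2=config.beta2, eps=config.eps)

    weights = None
    if config.class_weights is not None:
        weights = np.asarray(config.class_weights, dtype=np.float64)

    n = len(features)
    batch = min(config.batch_size, n)
    raw = features.windows
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        tot_loss = 0.0
        tot_correct = 0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb = raw[idx]
            yb = labels[idx]
            B = xb.shape[0]
            if joint:
                flat = xb.reshape(-1, 12)
                code = _sda.encode(flat, sda_params)
                feat = _sda.decode(code, sda_params)
                xin = feat.reshape(B, features.Lw, -1)
            else:
                xin = xb
            probs, logits, caches = _forward_batch(xin, params, cache=True)
            p_true = np.clip(probs[np.arange(B), yb], PROB_FLOOR, None)
            if weights is None:
                loss = float(-np.log(p_true).mean())
                wvec = np.ones(B)
            else:
                wvec = weights[yb]
                loss = float(-(wvec * np.log(p_true)).sum() / wvec.sum())
            check_finite(loss, "LSTM training")
            tot_loss += loss * B
            tot_correct += int((probs.argmax(axis=1) == yb).sum())

            dlogits = probs.copy()
            dlogits[np.arange(B), yb] -= 1.0
            dlogits *= (wvec / wvec.sum())[:, None]
            dlogits = dlogits.astype(np.float32)
            hs0, c0, hs1, c1, hT = caches
            g = {}
            g["W_out"] = hT.T @ dlogits
            g["b_out"] = dlogits.sum(axis=0)
            dh1 = np.zeros_like(hs1)
            dh1[:, -1, :] = dlogits @ params.W_out.T
            g["Wx1"], g["Wh1"], g["b1"], dx1 = _layer_backward(hs0, hs1, c1, params.Wx1, params.Wh1, dh1)
            g["Wx0"], g["Wh0"], g["b0"], dx0 = _layer_backward(xin, hs0, c0, params.Wx0, params.Wh0, dx1)
            opt.step(pdict, g)
            if joint:
                dflat = dx0.reshape(-1, 12)
                sgrads = _sda_backward(flat, code, feat, sda_params, dflat)
                sopt.step(sdict, sgrads)
        history.append(
            {"epoch": epoch + 1, "loss": tot_loss / n, "accuracy": tot_correct / n}
        )
    return params, history


def _sda_backward(x, code, feat, sp, dfeat):
    """Gradients of the classifier loss w.r.t. SDA weights (eval-mode pass)."""
    from ._nn import relu

    h1 = relu(x @ sp.W1 + sp.b1)
    zb = h1 @ sp.Wb + sp.bb
    zd = code @ sp.Wd + sp.bd
    hd = relu(zd)
    z2 = hd @ sp.W2 + sp.b2
    d2 = dfeat * (z2 > 0) if sp.output_activation == "relu" else dfeat
    g = {"W2": hd.T @ d2, "b2": d2.sum(axis=0)}
    dhd = (d2 @ sp.W2.T) * (zd > 0)
    g["Wd"] = code.T @ dhd
    g["bd"] = dhd.sum(axis=0)
    dcode = (dhd @ sp.Wd.T) * (zb > 0)
    g["Wb"] = h1.T @ dcode
    g["bb"] = dcode.sum(axis=0)
    dh1 = (dcode @ sp.Wb.T) * ((x @ sp.W1 + sp.b1) > 0)
    g["W1"] = x.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return {k: v.astype(np.float32) for k, v in g.items()}


def predict(features: WindowSet, params: LstmParams, batch_size: int = 512) -> np.ndarray:
    """Predicted phase label per window (argmax; ties -> smallest index)."""
    n = len(features)
    out = np.empty(n, dtype=np.int64)
    for start in range(0, n, batch_size):
        xb = features.windows[start : start + batch_size]
        probs, _, _ = _forward_batch(xb, params)
        out[start : start + batch_size] = probs.argmax(axis=1)
    return out


def predict_proba(features: WindowSet, params: LstmParams, batch_size: int = 512) -> np.ndarray:
    """Softmax probabilities (n, 4) per window, eval mode."""
    n = len(features)
    out = np.empty((n, N_CLASSES), dtype=np.float64)
    for start in range(0, n, batch_size):
        xb = features.windows[start : start + batch_size]
        probs, _, _ = _forward_batch(xb, params)
        out[start : start + batch_size] = probs
    return out
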