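"""Multi-head-attention encoder classifier, in NumPy.

The classifier follows the standard Transformer-encoder recipe: the K
decomposed mode channels of each record are cut into non-overlapping
frames of ``frame_len`` samples, each frame (all channels flattened) forms
one token, tokens are linearly embedded to ``d_model`` and given sinusoidal
positional encodings, then passed through ``n_layers`` encoder blocks
(multi-head scaled dot-product attention and a position-wise feed-forward
network, each wrapped in a residual connection with layer normalization).
Mean pooling over tokens feeds a fully connected softmax output layer.
Training is cross-entropy with momentum SGD; forward and backward passes
are written out explicitly and verified against finite differences in the
test suite.

The model/results split mirrors statsmodels: ``AttentionClassifier`` is
built from data and configuration, ``fit()`` returns a
``ClassifierResults`` carrying the evaluation report and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EncoderConfig",
    "TrainHyperparams",
    "EvalReport",
    "scaled_dot_product_attention",
    "multi_head_attention",
    "position_wise_ffn",
    "sinusoidal_positions",
    "frame_tokens",
    "encode_modes",
    "AttentionClassifier",
    "ClassifierResults",
    "train_classifier",
    "paired_ttest",
]


@dataclass(frozen=True)
class EncoderConfig:
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    frame_len: int = 16
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.frame_len < 1:
            raise ValueError("frame_len must be >= 1")


@dataclass(frozen=True)
class TrainHyperparams:
    """Momentum-SGD training settings (defaults inside the tuned search space)."""

    batch_size: int = 32
    learning_rate: float = 0.01
    epochs: int = 200
    momentum: float = 0.9
    seed: int = 0


@dataclass
class EvalReport:
    accuracy: float                  # percent
    per_class_accuracy: np.ndarray   # percents
    confusion: np.ndarray            # (n_classes, n_classes) counts, rows=true
    loss_curve: np.ndarray


# ---------------------------------------------------------------------------
# functional building blocks


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_product_attention(Q, K, V, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V; supports leading batch dimensions."""
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("incompatible Q/K/V shapes")
    dk = Q.shape[-1]
    if dk <= 0:
        raise ValueError("d_k must be positive")
    W = _softmax(Q @ np.swapaxes(K, -1, -2) / math.sqrt(dk))
    out = W @ V
    return (out, W) if return_weights else out


def multi_head_attention(X, params: dict, h: int):
    """Self-attention with ``h`` heads over token matrix X (T, d_model).

    ``params``: Wq, Wk, Wv, Wo of shape (d_model, d_model) (optional biases
    bq, bk, bv, bo).  Head splitting slices the projected matrices into h
    blocks of width d_model / h; outputs are concatenated and projected.
    """
    X = np.asarray(X, dtype=float)
    d_model = X.shape[-1]
    if d_model % h != 0:
        raise ValueError(f"d_model ({d_model}) must be divisible by h ({h})")
    dk = d_model // h
    Q = X @ params["Wq"] + params.get("bq", 0.0)
    K = X @ params["Wk"] + params.get("bk", 0.0)
    V = X @ params["Wv"] + params.get("bv", 0.0)
    heads = [
        scaled_dot_product_attention(
            Q[..., i * dk:(i + 1) * dk],
            K[..., i * dk:(i + 1) * dk],
            V[..., i * dk:(i + 1) * dk],
        )
        for i in range(h)
    ]
    return np.concatenate(heads, axis=-1) @ params["Wo"] + params.get("bo", 0.0)


def position_wise_ffn(x, W1, b1, W2, b2):
    """ReLU(x W1 + b1) W2 + b2."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x @ W1 + b1, 0.0) @ W2 + b2


def sinusoidal_positions(n_tokens: int, d_model: int) -> np.ndarray:
    """Classic sin/cos positional encoding matrix (n_tokens, d_model)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((n_tokens, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


def frame_tokens(modes: np.ndarray, frame_len: int) -> np.ndarray:
    """Cut (K, N) mode channels into ceil(N/frame_len) tokens of K*frame_len.

    The last frame is zero-padded.  Token count is independent of K
    because channels are flattened within each token.
    """
    modes = np.atleast_2d(np.asarray(modes, dtype=float))
    if modes.size == 0:
        raise ValueError("modes must be non-empty")
    Kc, N = modes.shape
    n_tok = int(math.ceil(N / frame_len))
    padded = np.zeros((Kc, n_tok * frame_len))
    padded[:, :N] = modes
    # (n_tok, Kc, frame_len) -> flatten channels within each token
    return padded.reshape(Kc, n_tok, frame_len).transpose(1, 0, 2).reshape(n_tok, Kc * frame_len)


def encode_modes(modes, config: EncoderConfig, W_embed=None, b_embed=None,
                 positional: bool = True) -> np.ndarray:
    """Token matrix (n_tokens, d_model) for one record's (K, N) modes.

    When no embedding matrix is given a fixed seeded Gaussian projection is
    used, so the function is deterministic without a trained model.
    """
    tok = frame_tokens(modes, config.frame_len)
    d_in = tok.shape[1]
    if W_embed is None:
        W_embed = np.random.default_rng(0).normal(0.0, 1.0 / math.sqrt(d_in), (d_in, config.d_model))
    emb = tok @ W_embed + (b_embed if b_embed is not None else 0.0)
    if positional:
        emb = emb + sinusoidal_positions(tok.shape[0], config.d_model)
    return emb


# ---------------------------------------------------------------------------
# trainable model with explicit backprop


def _layer_norm_forward(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def _layer_norm_backward(dout, cache):
    xhat, inv, gamma = cache
    d = xhat.shape[-1]
    dgamma = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    dbeta = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * gamma
    dx = inv / d * (
        d * dxhat - dxhat.sum(axis=-1, keepdims=True) - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


class AttentionClassifier:
    """Transformer-encoder classifier over decomposed signal modes.

    Parameters
    ----------
    X_modes : array (n, K, N) -- decomposed records (all with the same K).
    y : int array (n,) -- class labels 0..n_classes-1.
    enc : EncoderConfig
    """

    def __init__(self, X_modes, y, enc: EncoderConfig = EncoderConfig(), dtype=np.float32):
        X_modes = np.asarray(X_modes, dtype=float)
        if X_modes.ndim != 3:
            raise ValueError("X_modes must be (n_records, K, N); mixed mode counts "
                             "across records are not representable")
        self.X = X_modes
        self.y = np.asarray(y, dtype=int)
        self.enc = enc
        self.dtype = dtype
        n, Kc, N = X_modes.shape
        self.d_in = Kc * enc.frame_len
        self.n_tokens = int(math.ceil(N / enc.frame_len))
        self.pe = sinusoidal_positions(self.n_tokens, enc.d_model).astype(dtype)
        # standardize each mode channel to zero mean / unit variance over the
        # whole dataset: channels differ in scale by orders of magnitude (the
        # lowest-frequency mode carries the resting baseline) and the
        # positional encodings have unit scale
        self._mu = X_modes.mean(axis=(0, 2), keepdims=True)
        self._sd = X_modes.std(axis=(0, 2), keepdims=True) + 1e-12
        Z = (X_modes - self._mu) / self._sd
        self.tokens = np.stack(
            [frame_tokens(x, enc.frame_len) for x in Z]
        ).astype(dtype)

    # -- parameters --------------------------------------------------------

    def init_params(self, seed: int = 0) -> dict:
        rng = np.random.default_rng(seed)
        e = self.enc
        p = {}

        dt = self.dtype

        def glorot(shape):
            lim = math.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, shape).astype(dt)

        p["We"] = glorot((self.d_in, e.d_model))
        p["be"] = np.zeros(e.d_model, dtype=dt)
        for l in range(e.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{name}{l}"] = glorot((e.d_model, e.d_model))
                p[f"b{name[1:]}{l}"] = np.zeros(e.d_model, dtype=dt)
            p[f"W1_{l}"] = glorot((e.d_model, e.d_ff))
            p[f"b1_{l}"] = np.zeros(e.d_ff, dtype=dt)
            p[f"W2_{l}"] = glorot((e.d_ff, e.d_model))
            p[f"b2_{l}"] = np.zeros(e.d_model, dtype=dt)
            for ln in ("g1", "g2"):
                p[f"{ln}_{l}"] = np.ones(e.d_model, dtype=dt)
            for ln in ("o1", "o2"):
                p[f"{ln}_{l}"] = np.zeros(e.d_model, dtype=dt)
        p["Wc"] = glorot((e.d_model, e.n_classes))
        p["bc"] = np.zeros(e.n_classes, dtype=dt)
        return p

    # -- forward / backward ------------------------------------------------

    def _forward(self, tok, params, want_cache=False):
        e = self.enc
        h, dk = e.n_heads, e.d_model // e.n_heads
        B, T, _ = tok.shape
        cache = {"tok": tok}
        H = tok @ params["We"] + params["be"] + self.pe[None, :T, :]
        cache["H0"] = H
        for l in range(e.n_layers):
            c = {}
            c["Hin"] = H
            Q = H @ params[f"Wq{l}"] + params[f"bq{l}"]
            K = H @ params[f"Wk{l}"] + params[f"bk{l}"]
            V = H @ params[f"Wv{l}"] + params[f"bv{l}"]
            # (B, h, T, dk)
            Qh = Q.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            Kh = K.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            Vh = V.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            S = Qh @ np.swapaxes(Kh, -1, -2) / math.sqrt(dk)
            A = _softmax(S)
            O = A @ Vh                       # (B, h, T, dk)
            Oc = O.transpose(0, 2, 1, 3).reshape(B, T, e.d_model)
            attn = Oc @ params[f"Wo{l}"] + params[f"bo{l}"]
            Z1, ln1 = _layer_norm_forward(H + attn, params[f"g1_{l}"], params[f"o1_{l}"])
            U = Z1 @ params[f"W1_{l}"] + params[f"b1_{l}"]
            R = np.maximum(U, 0.0)
            F = R @ params[f"W2_{l}"] + params[f"b2_{l}"]
            Z2, ln2 = _layer_norm_forward(Z1 + F, params[f"g2_{l}"], params[f"o2_{l}"])
            c.update(Qh=Qh, Kh=Kh, Vh=Vh, A=A, Oc=Oc, Z1=Z1, ln1=ln1, U=U, R=R, ln2=ln2)
            cache[f"layer{l}"] = c
            H = Z2
        pooled = H.mean(axis=1)
        logits = pooled @ params["Wc"] + params["bc"]
        cache["Hfinal"], cache["pooled"] = H, pooled
        probs = _softmax(logits)
        if want_cache:
            return probs, cache
        return probs

    def _backward(self, probs, y_batch, params, cache):
        e = self.enc
        h, dk = e.n_heads, e.d_model // e.n_heads
        tok = cache["tok"]
        B, T, _ = tok.shape
        g = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y_batch] -= 1.0
        dlogits /= B
        g["Wc"] = cache["pooled"].T @ dlogits
        g["bc"] = dlogits.sum(axis=0)
        dH = (dlogits @ params["Wc"].T)[:, None, :] / T * np.ones((1, T, 1))
        for l in reversed(range(e.n_layers)):
            c = cache[f"layer{l}"]
            dZ2 = dH
            dpre2, g[f"g2_{l}"], g[f"o2_{l}"] = _layer_norm_backward(dZ2, c["ln2"])
            dZ1 = dpre2.copy()
            dF = dpre2
            g[f"W2_{l}"] = c["R"].reshape(-1, e.d_ff).T @ dF.reshape(-1, e.d_model)
            g[f"b2_{l}"] = dF.sum(axis=(0, 1))
            dR = dF @ params[f"W2_{l}"].T
            dU = dR * (c["U"] > 0)
            g[f"W1_{l}"] = c["Z1"].reshape(-1, e.d_model).T @ dU.reshape(-1, e.d_ff)
            g[f"b1_{l}"] = dU.sum(axis=(0, 1))
            dZ1 += dU @ params[f"W1_{l}"].T
            dpre1, g[f"g1_{l}"], g[f"o1_{l}"] = _layer_norm_backward(dZ1, c["ln1"])
            dHres = dpre1.copy()
            dattn = dpre1
            g[f"Wo{l}"] = c["Oc"].reshape(-1, e.d_model).T @ dattn.reshape(-1, e.d_model)
            g[f"bo{l}"] = dattn.sum(axis=(0, 1))
            dOc = dattn @ params[f"Wo{l}"].T
            dO = dOc.reshape(B, T, h, dk).transpose(0, 2, 1, 3)
            A, Qh, Kh, Vh = c["A"], c["Qh"], c["Kh"], c["Vh"]
            dA = dO @ np.swapaxes(Vh, -1, -2)
            dVh = np.swapaxes(A, -1, -2) @ dO
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dS /= math.sqrt(dk)
            dQh = dS @ Kh
            dKh = np.swapaxes(dS, -1, -2) @ Qh
            dQ = dQh.transpose(0, 2, 1, 3).reshape(B, T, e.d_model)
            dK = dKh.transpose(0, 2, 1, 3).reshape(B, T, e.d_model)
            dV = dVh.transpose(0, 2, 1, 3).reshape(B, T, e.d_model)
            Hin = c["Hin"]
            Hf = Hin.reshape(-1, e.d_model)
            g[f"Wq{l}"] = Hf.T @ dQ.reshape(-1, e.d_model)
            g[f"Wk{l}"] = Hf.T @ dK.reshape(-1, e.d_model)
            g[f"Wv{l}"] = Hf.T @ dV.reshape(-1, e.d_model)
            g[f"bq{l}"] = dQ.sum(axis=(0, 1))
            g[f"bk{l}"] = dK.sum(axis=(0, 1))
            g[f"bv{l}"] = dV.sum(axis=(0, 1))
            dHin = (
                dQ @ params[f"Wq{l}"].T
                + dK @ params[f"Wk{l}"].T
                + dV @ params[f"Wv{l}"].T
                + dHres
            )
            dH = dHin
        g["We"] = tok.reshape(-1, self.d_in).T @ dH.reshape(-1, e.d_model)
        g["be"] = dH.sum(axis=(0, 1))
        return g

    def loss(self, params, idx=None):
        """Mean cross-entropy over the given record indices."""
        idx = np.arange(len(self.y)) if idx is None else np.asarray(idx)
        probs = self._forward(self.tokens[idx], params)
        p = np.clip(probs[np.arange(len(idx)), self.y[idx]], 1e-12, None)
        return float(-np.log(p).mean())

    def gradients(self, params, idx):
        probs, cache = self._forward(self.tokens[idx], params, want_cache=True)
        return self._backward(probs, self.y[idx], params, cache)

    # -- fitting -----------------------------------------------------------

    def fit(self, train_idx, test_idx, hp: TrainHyperparams = TrainHyperparams(),
            verbose: bool = False) -> "ClassifierResults":
        rng = np.random.default_rng(hp.seed)
        params = self.init_params(seed=hp.seed)
        vel = {k: np.zeros_like(v) for k, v in params.items()}
        train_idx = np.asarray(train_idx)
        losses = []
        for epoch in range(hp.epochs):
            order = rng.permutation(train_idx)
            ep_loss, n_batches = 0.0, 0
            for s in range(0, order.size, hp.batch_size):
                batch = order[s:s + hp.batch_size]
                probs, cache = self._forward(self.tokens[batch], params, want_cache=True)
                p = np.clip(probs[np.arange(len(batch)), self.y[batch]], 1e-12, None)
                ep_loss += float(-np.log(p).mean())
                n_batches += 1
                grads = self._backward(probs, self.y[batch], params, cache)
                for k in params:
                    vel[k] = hp.momentum * vel[k] - hp.learning_rate * grads[k]
                    params[k] = params[k] + vel[k]
            losses.append(ep_loss / max(n_batches, 1))
            if verbose and (epoch + 1) % 10 == 0:
                print(f"epoch {epoch + 1}: loss {losses[-1]:.4f}")
        report = self.evaluate(params, test_idx, loss_curve=np.asarray(losses))
        return ClassifierResults(model=self, params=params, report=report, hp=hp)

    def predict(self, params, idx) -> np.ndarray:
        probs = self._forward(self.tokens[np.asarray(idx)], params)
        return probs.argmax(axis=1)

    def evaluate(self, params, idx, loss_curve=None) -> EvalReport:
        idx = np.asarray(idx)
        pred = self.predict(params, idx)
        true = self.y[idx]
        nc = self.enc.n_classes
        confusion = np.zeros((nc, nc), dtype=int)
        for t, p in zip(true, pred):
            confusion[t, p] += 1
        acc = 100.0 * np.trace(confusion) / max(confusion.sum(), 1)
        with np.errstate(invalid="ignore"):
            per_class = 100.0 * np.diag(confusion) / np.maximum(confusion.sum(axis=1), 1)
        return EvalReport(
            accuracy=float(acc),
            per_class_accuracy=per_class,
            confusion=confusion,
            loss_curve=np.asarray(loss_curve if loss_curve is not None else []),
        )


@dataclass
class ClassifierResults:
    """Fitted classifier: learned parameters plus the test-set report."""

    model: AttentionClassifier
    params: dict
    report: EvalReport
    hp: TrainHyperparams

    def summary(self) -> str:
        r = self.report
        lines = [
            "Attention classifier results",
            "----------------------------",
            f"test accuracy: {r.accuracy:.2f}%",
            "per-class accuracy: "
            + ", ".join(f"{a:.2f}%" for a in r.per_class_accuracy),
            "confusion matrix (rows = true):",
        ]
        lines += ["  " + "  ".join(f"{v:5d}" for v in row) for row in r.confusion]
        lines.append(
            f"hyperparameters: batch={self.hp.batch_size}, lr={self.hp.learning_rate}, "
            f"epochs={self.hp.epochs}, momentum={self.hp.momentum}, seed={self.hp.seed}"
        )
        return "\n".join(lines)


def train_classifier(X_modes, y, train_idx, test_idx,
                     enc: EncoderConfig = EncoderConfig(),
                     hp: TrainHyperparams = TrainHyperparams()):
    """Convenience wrapper: build, fit, return (results.params, report)."""
    model = AttentionClassifier(X_modes, y, enc)
    res = model.fit(train_idx, test_idx, hp)
    return res, res.report


def paired_ttest(acc_a, acc_b):
    """Two-sided paired t-test on matched accuracy samples.

    Degenerate conventions: identical samples -> (t=0, p=1); constant
    non-zero difference with zero spread -> p floored at 0.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    if np.allclose(d, d[0]):
        return math.copysign(math.inf, d[0]), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
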