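"""NumPy implementation of the attention Bi-LSTM + feature-CNN classifier.

Architecture, following the published design:

* a word-embedding sequence w = (w_1..w_N) feeds a bidirectional LSTM whose
  per-token outputs are merged, m_t = [h_fwd_t ; h_bwd_t];
* an attention layer scores each merged output against a learned word-level
  context vector p_w,

      p_t   = tanh(W_w m_t + b_w)
      alpha = softmax_t(p_t . p_w)
      s     = sum_t alpha_t m_t

* the verb/temporal-keyword embedding matrix E = [X | Y] passes through a
  one-layer CNN (windows over the token axis) with tanh activation and
  global max pooling, yielding f;
* the merged vector c = [s ; f] is projected, z = tanh(W_i c + b_i), and the
  class probabilities are y = softmax(z) over {past, present, future}.

Max pooling is restricted to convolution windows overlapping the content
columns of E, so zero padding appended beyond the content never changes f
and predictions are independent of batch padding width.

All forward passes keep the caches needed for the hand-derived backward
passes; gradients are validated against finite differences in the test
suite.  Training uses categorical cross-entropy with RMSprop (Adam and
plain SGD are also available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLASSES = ("past", "present", "future")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------
def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(rng: np.random.Generator, d: int, hidden: int,
                attn_dim: int | None, cnn_windows: tuple[int, ...],
                cnn_filters: int, n_classes: int = 3) -> dict[str, np.ndarray]:
    """Seeded parameter dictionary for the full network."""
    if attn_dim is None:
        attn_dim = 2 * hidden
    params: dict[str, np.ndarray] = {}
    for direction in ("f", "b"):
        params[f"lstm_{direction}_Wx"] = _glorot(rng, (4 * hidden, d),
                                                 d, hidden)
        params[f"lstm_{direction}_Wh"] = _glorot(rng, (4 * hidden, hidden),
                                                 hidden, hidden)
        bias = np.zeros(4 * hidden)
        bias[hidden:2 * hidden] = 1.0  # forget-gate bias
        params[f"lstm_{direction}_b"] = bias
    params["att_Ww"] = _glorot(rng, (attn_dim, 2 * hidden),
                               2 * hidden, attn_dim)
    params["att_bw"] = np.zeros(attn_dim)
    params["att_pw"] = rng.standard_normal(attn_dim) * 0.1
    for w in cnn_windows:
        params[f"cnn_K_{w}"] = _glorot(rng, (cnn_filters, d, w),
                                       d * w, cnn_filters)
        params[f"cnn_b_{w}"] = np.zeros(cnn_filters)
    feat_dim = 2 * hidden + cnn_filters * len(cnn_windows)
    params["out_W"] = _glorot(rng, (n_classes, feat_dim),
                              feat_dim, n_classes)
    params["out_b"] = np.zeros(n_classes)
    return params


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------
def lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                 b: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run an LSTM over X (B, N, d); returns outputs (B, N, H) and cache."""
    B, N, _ = X.shape
    H = Wh.shape[1]
    I = np.zeros((B, N, H)); F = np.zeros((B, N, H))
    O = np.zeros((B, N, H)); G = np.zeros((B, N, H))
    C = np.zeros((B, N, H)); TC = np.zeros((B, N, H))
    Hs = np.zeros((B, N, H))
    XW = X @ Wx.T  # (B, N, 4H)
    h = np.zeros((B, H)); c = np.zeros((B, H))
    for t in range(N):
        z = XW[:, t] + h @ Wh.T + b
        i = sigmoid(z[:, :H]); f = sigmoid(z[:, H:2 * H])
        o = sigmoid(z[:, 2 * H:3 * H]); g = np.tanh(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        I[:, t], F[:, t], O[:, t], G[:, t] = i, f, o, g
        C[:, t], TC[:, t], Hs[:, t] = c, tc, h
    cache = {"X": X, "I": I, "F": F, "O": O, "G": G, "C": C, "TC": TC,
             "H": Hs, "Wx": Wx, "Wh": Wh}
    return Hs, cache


def lstm_backward(dH: np.ndarray, cache: dict
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Backprop through time; dH is the external gradient on each h_t."""
    X, Wx, Wh = cache["X"], cache["Wx"], cache["Wh"]
    I, F, O, G = cache["I"], cache["F"], cache["O"], cache["G"]
    C, TC, Hs = cache["C"], cache["TC"], cache["H"]
    B, N, H = dH.shape
    dWx = np.zeros_like(Wx); dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H); dX = np.zeros_like(X)
    dh_next = np.zeros((B, H)); dc_next = np.zeros((B, H))
    for t in range(N - 1, -1, -1):
        dh = dH[:, t] + dh_next
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
        h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
        do = dh * TC[:, t]
        dc = dc_next + dh * O[:, t] * (1.0 - TC[:, t] ** 2)
        df = dc * c_prev
        di = dc * G[:, t]
        dg = dc * I[:, t]
        dc_next = dc * F[:, t]
        dz = np.concatenate([
            di * I[:, t] * (1 - I[:, t]),
            df * F[:, t] * (1 - F[:, t]),
            do * O[:, t] * (1 - O[:, t]),
            dg * (1 - G[:, t] ** 2)], axis=1)
        dWx += dz.T @ X[:, t]
        dWh += dz.T @ h_prev
        db += dz.sum(axis=0)
        dX[:, t] = dz @ Wx
        dh_next = dz @ Wh
    return dX, dWx, dWh, db


def bilstm_forward(X: np.ndarray, params: dict
                   ) -> tuple[np.ndarray, dict]:
    """Merged bidirectional outputs M (B, N, 2H)."""
    Hf, cf = lstm_forward(X, params["lstm_f_Wx"], params["lstm_f_Wh"],
                          params["lstm_f_b"])
    Hb_rev, cb = lstm_forward(X[:, ::-1], params["lstm_b_Wx"],
                              params["lstm_b_Wh"], params["lstm_b_b"])
    M = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
    return M, {"f": cf, "b": cb, "H": Hf.shape[2]}


def bilstm_backward(dM: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
    H = cache["H"]
    dXf, dWxf, dWhf, dbf = lstm_backward(dM[:, :, :H], cache["f"])
    dXb, dWxb, dWhb, dbb = lstm_backward(dM[:, ::-1, H:], cache["b"])
    grads["lstm_f_Wx"] = dWxf; grads["lstm_f_Wh"] = dWhf
    grads["lstm_f_b"] = dbf
    grads["lstm_b_Wx"] = dWxb; grads["lstm_b_Wh"] = dWhb
    grads["lstm_b_b"] = dbb
    return dXf + dXb[:, ::-1]


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------
@dataclass
class AttentionParams:
    W_w: np.ndarray
    b_w: np.ndarray
    p_w: np.ndarray


@dataclass
class AttentionOutput:
    weights: np.ndarray         # alpha, shape (N,)
    sentence_vector: np.ndarray  # s, shape (dim of m_t,)


def attention_forward(M: np.ndarray, Ww: np.ndarray, bw: np.ndarray,
                      pw: np.ndarray) -> tuple[np.ndarray, np.ndarray, dict]:
    """Batched attention over M (B, N, Dm); returns s (B, Dm), alpha, cache."""
    if Ww.shape[1] != M.shape[2] or bw.shape[0] != Ww.shape[0] \
            or pw.shape[0] != Ww.shape[0]:
        raise ValueError(
            f"attention dimension mismatch: M columns of length {M.shape[2]}, "
            f"W_w {Ww.shape}, b_w {bw.shape}, p_w {pw.shape}")
    P = np.tanh(M @ Ww.T + bw)            # (B, N, A)
    scores = P @ pw                       # (B, N)
    alpha = softmax(scores, axis=1)
    S = np.einsum("bn,bnh->bh", alpha, M)
    return S, alpha, {"M": M, "P": P, "alpha": alpha, "Ww": Ww, "pw": pw}


def attention_backward(dS: np.ndarray, cache: dict, grads: dict
                       ) -> np.ndarray:
    M, P, alpha = cache["M"], cache["P"], cache["alpha"]
    Ww, pw = cache["Ww"], cache["pw"]
    dalpha = np.einsum("bh,bnh->bn", dS, M)
    dM = alpha[:, :, None] * dS[:, None, :]
    du = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    dP = du[:, :, None] * pw
    grads["att_pw"] = np.einsum("bn,bna->a", du, P)
    dpre = dP * (1.0 - P ** 2)
    grads["att_Ww"] = np.einsum("bna,bnh->ah", dpre, M)
    grads["att_bw"] = dpre.sum(axis=(0, 1))
    dM += np.einsum("bna,ah->bnh", dpre, Ww)
    return dM


def attend(M: np.ndarray, params: AttentionParams) -> AttentionOutput:
    """Attention for a single sequence; M has one column per token."""
    S, alpha, _ = attention_forward(M.T[None], params.W_w, params.b_w,
                                    params.p_w)
    return AttentionOutput(weights=alpha[0], sentence_vector=S[0])


# ---------------------------------------------------------------------------
# CNN branch
# ---------------------------------------------------------------------------
@dataclass
class CnnParams:
    kernels: dict[int, np.ndarray]  # window -> (F, d, w)
    biases: dict[int, np.ndarray]   # window -> (F,)


def conv_window_forward(E: np.ndarray, K: np.ndarray, b: np.ndarray,
                        n_content: np.ndarray
                        ) -> tuple[np.ndarray, dict]:
    """Convolve+tanh+masked global max-pool for one window size.

    E is (B, L, d); K is (F, d, w).  Pooling covers positions
    0..max(0, n_content-w)+... i.e. every window that overlaps content
    (at least position 0 is always valid so a zero-content E yields
    tanh(bias)).
    """
    B, L, d = E.shape
    F, _, w = K.shape
    if L < w:
        raise ValueError(f"E has {L} columns but window is {w}")
    win = np.lib.stride_tricks.sliding_window_view(E, w, axis=1)  # (B,P,d,w)
    pre = np.einsum("bpdw,fdw->bpf", win, K) + b
    A = np.tanh(pre)                       # (B, P, F)
    P_len = A.shape[1]
    valid = np.clip(np.asarray(n_content) - w + 1, 1, P_len)  # (B,)
    pos = np.arange(P_len)
    masked = np.where(pos[None, :, None] < valid[:, None, None], A, -np.inf)
    amax = masked.argmax(axis=1)           # (B, F)
    f_out = np.take_along_axis(A, amax[:, None, :], axis=1)[:, 0, :]
    cache = {"win": win, "A": A, "amax": amax, "K": K, "f": f_out,
             "shape": E.shape}
    return f_out, cache


def conv_window_backward(df: np.ndarray, cache: dict
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    win, amax, K, f_out = cache["win"], cache["amax"], cache["K"], cache["f"]
    B, L, d = cache["shape"]
    F, _, w = K.shape
    P_len = win.shape[1]
    dpre = df * (1.0 - f_out ** 2)         # (B, F)
    bidx = np.broadcast_to(np.arange(B)[:, None], amax.shape)
    sel = win[bidx, amax]                  # (B, F, d, w)
    dK = np.einsum("bf,bfdw->fdw", dpre, sel)
    db = dpre.sum(axis=0)
    contrib = dpre[:, :, None, None] * K[None]      # (B, F, d, w)
    dwin = np.zeros((B, P_len, d, w))
    np.add.at(dwin, (bidx, amax), contrib)
    dE = np.zeros((B, L, d))
    for off in range(w):
        dE[:, off:off + P_len] += dwin[:, :, :, off]
    return dE, dK, db


def convolve_features(E: np.ndarray, params: CnnParams,
                      n_content: int | None = None) -> np.ndarray:
    """CNN branch for a single feature matrix E (d x L columns=tokens)."""
    d, L = E.shape
    n = L if n_content is None else n_content
    outs = []
    for w in sorted(params.kernels):
        f, _ = conv_window_forward(E.T[None], params.kernels[w],
                                   params.biases[w], np.array([n]))
        outs.append(f[0])
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------
def model_forward(params: dict, word: np.ndarray, E: np.ndarray,
                  n_content: np.ndarray, cnn_windows: tuple[int, ...],
                  dropout_rate: float = 0.0,
                  rng: np.random.Generator | None = None,
                  train: bool = False) -> tuple[np.ndarray, dict]:
    """Forward pass over a batch.

    word: (B, N, d) padded word sequences; E: (B, L, d) padded feature
    matrices; n_content: (B,) true k+l per example.  Returns class
    probabilities y (B, 3) and the cache for the backward pass.
    """
    M, lstm_cache = bilstm_forward(word, params)
    S, _, att_cache = attention_forward(M, params["att_Ww"],
                                        params["att_bw"], params["att_pw"])
    conv_caches = {}
    f_parts = []
    for w in cnn_windows:
        f_w, c_w = conv_window_forward(E, params[f"cnn_K_{w}"],
                                       params[f"cnn_b_{w}"], n_content)
        conv_caches[w] = c_w
        f_parts.append(f_w)
    f_all = np.concatenate(f_parts, axis=1)
    c = np.concatenate([S, f_all], axis=1)
    if train and dropout_rate > 0.0:
        if rng is None:
            raise ValueError("dropout requires an rng")
        mask = (rng.random(c.shape) >= dropout_rate) / (1.0 - dropout_rate)
    else:
        mask = None
    ch = c if mask is None else c * mask
    z = np.tanh(ch @ params["out_W"].T + params["out_b"])
    y = softmax(z, axis=1)
    cache = {"lstm": lstm_cache, "att": att_cache, "conv": conv_caches,
             "cnn_windows": cnn_windows, "S_dim": S.shape[1],
             "filters": [fp.shape[1] for fp in f_parts],
             "ch": ch, "mask": mask, "z": z, "y": y,
             "out_W": params["out_W"]}
    return y, cache


def cross_entropy(y: np.ndarray, targets: np.ndarray) -> float:
    """Mean categorical cross-entropy; targets are class indices."""
    eps = 1e-12
    return float(-np.mean(np.log(y[np.arange(len(targets)), targets] + eps)))


def model_backward(cache: dict, targets: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the mean cross-entropy w.r.t. every parameter."""
    y, z, ch, mask = cache["y"], cache["z"], cache["ch"], cache["mask"]
    B = y.shape[0]
    T = np.zeros_like(y)
    T[np.arange(B), targets] = 1.0
    dz = (y - T) / B                      # softmax + CE
    dpre = dz * (1.0 - z ** 2)            # tanh projection
    grads: dict[str, np.ndarray] = {}
    grads["out_W"] = dpre.T @ ch
    grads["out_b"] = dpre.sum(axis=0)
    dch = dpre @ cache["out_W"]
    dc = dch if mask is None else dch * mask
    S_dim = cache["S_dim"]
    dS = dc[:, :S_dim]
    df_all = dc[:, S_dim:]
    offset = 0
    for w, n_f in zip(cache["cnn_windows"], cache["filters"]):
        df_w = df_all[:, offset:offset + n_f]
        offset += n_f
        _, dK, db = conv_window_backward(df_w, cache["conv"][w])
        grads[f"cnn_K_{w}"] = dK
        grads[f"cnn_b_{w}"] = db
    dM = attention_backward(dS, cache["att"], grads)
    bilstm_backward(dM, cache["lstm"], grads)
    return grads


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------
class Optimizer:
    """RMSprop (default), Adam or SGD over a parameter dictionary."""

    def __init__(self, params: dict[str, np.ndarray], name: str = "rmsprop",
                 lr: float = 0.001):
        if name not in ("rmsprop", "adam", "sgd"):
            raise ValueError(f"unknown optimizer {name!r}")
        self.name = name
        self.lr = lr
        self.t = 0
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = ({k: np.zeros_like(v) for k, v in params.items()}
                   if name == "adam" else None)

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        eps = 1e-8
        for key, g in grads.items():
            if self.name == "sgd":
                params[key] -= self.lr * g
            elif self.name == "rmsprop":
                self._m[key] = 0.9 * self._m[key] + 0.1 * g * g
                params[key] -= self.lr * g / (np.sqrt(self._m[key]) + eps)
            else:  # adam
                self._m[key] = 0.9 * self._m[key] + 0.1 * g
                self._v[key] = 0.999 * self._v[key] + 0.001 * g * g
                mhat = self._m[key] / (1 - 0.9 ** self.t)
                vhat = self._v[key] / (1 - 0.999 ** self.t)
                params[key] -= self.lr * mhat / (np.sqrt(vhat) + eps)
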