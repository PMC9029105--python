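"""Minimal NumPy neural-network core for the text classifiers.

Implements exactly the pieces the three architectures need — embedding
lookup, 1-D convolution over time (valid and same padding), ReLU, max
pooling (global and strided), a linear head, softmax cross-entropy and Adam
— with hand-written backward passes.  Sizes here are desk-scale (vocabulary
in the thousands, documents in the hundreds of tokens), for which plain
matmul-based convolutions are fast enough on one CPU core.

All forward functions return ``(output, cache)``; backward functions take
the upstream gradient plus the cache and return input/parameter gradients.
Correctness is pinned by finite-difference gradient checks in the test
suite.
"""

from __future__ import annotations

import numpy as np

PAD_ID = 0


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------

def unfold(X: np.ndarray, k: int) -> np.ndarray:
    """(B, L, d) -> (B, L-k+1, k*d) sliding windows along time."""
    B, L, d = X.shape
    sw = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, L-k+1, d, k)
    return np.ascontiguousarray(sw.transpose(0, 1, 3, 2)).reshape(B, L - k + 1, k * d)


def conv1d(X: np.ndarray, W: np.ndarray, b: np.ndarray, k: int, same: bool = False):
    """Time convolution via unfold+matmul.  W: (k*d, F)."""
    if same:
        pad = (k - 1) // 2, k // 2
        X = np.pad(X, ((0, 0), pad, (0, 0)))
    cols = unfold(X, k)
    Y = cols @ W + b
    return Y, (cols, X.shape, k, same)


def conv1d_backward(dY: np.ndarray, cache, W: np.ndarray):
    cols, x_shape, k, same = cache
    B, Lp, d = x_shape
    Lk = dY.shape[1]
    F = W.shape[1]
    dW = cols.reshape(-1, W.shape[0]).T @ dY.reshape(-1, F)
    db = dY.sum(axis=(0, 1))
    dcols = dY @ W.T  # (B, Lk, k*d)
    dX = np.zeros(x_shape, dtype=dY.dtype)
    for off in range(k):
        dX[:, off : off + Lk, :] += dcols[:, :, off * d : (off + 1) * d]
    if same:
        lo, hi = (k - 1) // 2, k // 2
        dX = dX[:, lo : Lp - hi, :]
    return dX, dW, db


def relu(Z: np.ndarray):
    return np.maximum(Z, 0.0), Z > 0


def relu_backward(dA: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dA * mask


def global_max_pool(Z: np.ndarray):
    """(B, L, F) -> (B, F) max over time."""
    arg = Z.argmax(axis=1)
    out = np.take_along_axis(Z, arg[:, None, :], axis=1)[:, 0, :]
    return out, (arg, Z.shape)


def global_max_pool_backward(dout: np.ndarray, cache) -> np.ndarray:
    arg, shape = cache
    B, L, F = shape
    dZ = np.zeros(shape, dtype=dout.dtype)
    np.add.at(dZ, (np.arange(B)[:, None], arg, np.arange(F)[None, :]), dout)
    return dZ


def max_pool_3_2(Z: np.ndarray):
    """Max pooling, window 3, stride 2, clipped at the sequence end."""
    B, L, F = Z.shape
    starts = np.arange(0, max(L - 1, 1), 2)
    idx = starts[:, None] + np.arange(3)[None, :]  # (Lo, 3)
    valid = idx < L
    idx_c = np.minimum(idx, L - 1)
    Wn = Z[:, idx_c, :]  # (B, Lo, 3, F)
    Wn = np.where(valid[None, :, :, None], Wn, -np.inf)
    arg = Wn.argmax(axis=2)  # (B, Lo, F)
    out = np.take_along_axis(Wn, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, (idx_c, arg, Z.shape)


def max_pool_3_2_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx_c, arg, shape = cache
    B, L, F = shape
    Lo = arg.shape[1]
    pos = idx_c[np.arange(Lo)[None, :, None], arg]  # (B, Lo, F)
    dZ = np.zeros(shape, dtype=dout.dtype)
    np.add.at(dZ, (np.arange(B)[:, None, None], pos, np.arange(F)[None, None, :]), dout)
    return dZ


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch and its gradient wrt logits."""
    z = (logits - logits.max(axis=1, keepdims=True)).astype(np.float64)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    B = len(y)
    loss = float(-np.log(p[np.arange(B), y] + 1e-12).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    return loss, dlogits.astype(logits.dtype)


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


#: working precision of all learned parameters (single precision is ample
#: for these shallow nets and halves both memory traffic and matmul time)
DTYPE = np.float32


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def embed(E: np.ndarray, ids: np.ndarray) -> np.ndarray:
    return E[ids]


def embed_backward(dX: np.ndarray, ids: np.ndarray, vocab_size: int) -> np.ndarray:
    dE = np.zeros((vocab_size, dX.shape[-1]), dtype=dX.dtype)
    np.add.at(dE, ids.reshape(-1), dX.reshape(-1, dX.shape[-1]))
    dE[PAD_ID] = 0.0  # padding embedding stays frozen at zero
    return dE


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------

class TextCNNNet:
    """Shallow CNN: parallel kernels over word embeddings, max-over-time
    pooling per kernel, concatenation, linear head."""

    def __init__(self, vocab_size: int, embedding_dim: int,
                 kernel_sizes: tuple[int, ...], n_filters: int):
        self.V, self.d = vocab_size, embedding_dim
        self.ks = tuple(kernel_sizes)
        self.F = n_filters

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        p = {"E": rng.normal(0.0, 0.1, size=(self.V, self.d)).astype(DTYPE)}
        p["E"][PAD_ID] = 0.0
        for k in self.ks:
            p[f"W{k}"] = _glorot(rng, k * self.d, self.F, (k * self.d, self.F))
            p[f"b{k}"] = np.zeros(self.F, dtype=DTYPE)
        p["Wo"] = _glorot(rng, len(self.ks) * self.F, 2, (len(self.ks) * self.F, 2))
        p["bo"] = np.zeros(2, dtype=DTYPE)
        return p

    def forward(self, params, ids):
        X = embed(params["E"], ids)
        pooled, caches = [], []
        for k in self.ks:
            Z, ccache = conv1d(X, params[f"W{k}"], params[f"b{k}"], k)
            A, rmask = relu(Z)
            m, pcache = global_max_pool(A)
            pooled.append(m)
            caches.append((ccache, rmask, pcache))
        H = np.concatenate(pooled, axis=1)
        logits = H @ params["Wo"] + params["bo"]
        return logits, (ids, X.shape, H, caches)

    def backward(self, params, cache, dlogits):
        ids, x_shape, H, caches = cache
        grads = {"Wo": H.T @ dlogits, "bo": dlogits.sum(axis=0)}
        dH = dlogits @ params["Wo"].T
        dX = np.zeros(x_shape)
        for i, k in enumerate(self.ks):
            ccache, rmask, pcache = caches[i]
            dm = dH[:, i * self.F : (i + 1) * self.F]
            dA = global_max_pool_backward(dm, pcache)
            dZ = relu_backward(dA, rmask)
            dXk, dW, db = conv1d_backward(dZ, ccache, params[f"W{k}"])
            grads[f"W{k}"], grads[f"b{k}"] = dW, db
            dX += dXk
        grads["E"] = embed_backward(dX, ids, self.V)
        return grads


class FastTextNet:
    """Averaged unigram (+hashed bigram) embeddings with a linear head."""

    _P = 1_000_003  # bigram hashing multiplier

    def __init__(self, vocab_size: int, embedding_dim: int,
                 ngrams: int = 2, buckets: int = 2048):
        self.Vbase = vocab_size
        self.d = embedding_dim
        self.ngrams = ngrams
        self.buckets = buckets if ngrams >= 2 else 0
        self.V = vocab_size + self.buckets

    def _features(self, ids: np.ndarray) -> np.ndarray:
        """Unigram ids plus hashed-bigram ids; invalid slots are PAD."""
        if self.ngrams < 2:
            return ids
        left, right = ids[:, :-1], ids[:, 1:]
        valid = (left != PAD_ID) & (right != PAD_ID)
        big = (left * self._P + right) % self.buckets + self.Vbase
        big = np.where(valid, big, PAD_ID)
        return np.concatenate([ids, big], axis=1)

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        p = {
            "E": rng.normal(0.0, 0.1, size=(self.V, self.d)).astype(DTYPE),
            "Wo": _glorot(rng, self.d, 2, (self.d, 2)),
            "bo": np.zeros(2, dtype=DTYPE),
        }
        p["E"][PAD_ID] = 0.0
        return p

    def forward(self, params, ids):
        feats = self._features(ids)
        mask = feats != PAD_ID
        counts = np.maximum(mask.sum(axis=1), 1)
        X = embed(params["E"], feats)
        h = (X * mask[:, :, None]).sum(axis=1) / counts[:, None]
        logits = h @ params["Wo"] + params["bo"]
        return logits, (feats, mask, counts, h)

    def backward(self, params, cache, dlogits):
        feats, mask, counts, h = cache
        grads = {"Wo": h.T @ dlogits, "bo": dlogits.sum(axis=0)}
        dh = dlogits @ params["Wo"].T  # (B, d)
        dX = (dh / counts[:, None])[:, None, :] * mask[:, :, None]
        grads["E"] = embed_backward(dX, feats, self.V)
        return grads


class DPCNNNet:
    """Pyramidal CNN: region convolution, then repeated [downsample ->
    conv -> conv] blocks with residual (shortcut) connections, global max
    pool, linear head.  Each pooling halves the sequence, so depth grows
    logarithmically with document length."""

    def __init__(self, vocab_size: int, embedding_dim: int,
                 n_blocks: int = 3, n_filters: int = 64):
        self.V, self.d = vocab_size, embedding_dim
        self.B = n_blocks
        self.F = n_filters

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        p = {"E": rng.normal(0.0, 0.1, size=(self.V, self.d)).astype(DTYPE)}
        p["E"][PAD_ID] = 0.0
        p["Wr"] = _glorot(rng, 3 * self.d, self.F, (3 * self.d, self.F))
        p["br"] = np.zeros(self.F, dtype=DTYPE)
        for i in range(self.B + 1):  # block 0 runs at full length, pre-pool
            for j in (1, 2):
                p[f"W{i}_{j}"] = _glorot(rng, 3 * self.F, self.F, (3 * self.F, self.F))
                p[f"b{i}_{j}"] = np.zeros(self.F, dtype=DTYPE)
        p["Wo"] = _glorot(rng, self.F, 2, (self.F, 2))
        p["bo"] = np.zeros(2, dtype=DTYPE)
        return p

    def _conv_block(self, params, Z, i):
        A1, m1 = relu(Z)
        C1, c1 = conv1d(A1, params[f"W{i}_1"], params[f"b{i}_1"], 3, same=True)
        A2, m2 = relu(C1)
        C2, c2 = conv1d(A2, params[f"W{i}_2"], params[f"b{i}_2"], 3, same=True)
        return Z + C2, (m1, c1, m2, c2)

    def _conv_block_backward(self, params, dOut, cache, i, grads):
        m1, c1, m2, c2 = cache
        dC2 = dOut
        dA2, dW2, db2 = conv1d_backward(dC2, c2, params[f"W{i}_2"])
        grads[f"W{i}_2"], grads[f"b{i}_2"] = dW2, db2
        dC1 = relu_backward(dA2, m2)
        dA1, dW1, db1 = conv1d_backward(dC1, c1, params[f"W{i}_1"])
        grads[f"W{i}_1"], grads[f"b{i}_1"] = dW1, db1
        return dOut + relu_backward(dA1, m1)  # residual + conv path

    def forward(self, params, ids):
        X = embed(params["E"], ids)
        Z, rcache = conv1d(X, params["Wr"], params["br"], 3, same=True)
        Z, bcache0 = self._conv_block(params, Z, 0)
        block_caches = [bcache0]
        pool_caches = []
        n_pooled = 0
        for i in range(1, self.B + 1):
            if Z.shape[1] < 2:
                break
            Z, pcache = max_pool_3_2(Z)
            Z, bcache = self._conv_block(params, Z, i)
            pool_caches.append(pcache)
            block_caches.append(bcache)
            n_pooled += 1
        g, gcache = global_max_pool(Z)
        logits = g @ params["Wo"] + params["bo"]
        return logits, (ids, X.shape, rcache, block_caches, pool_caches, n_pooled, g, gcache)

    def backward(self, params, cache, dlogits):
        ids, x_shape, rcache, block_caches, pool_caches, n_pooled, g, gcache = cache
        grads = {"Wo": g.T @ dlogits, "bo": dlogits.sum(axis=0)}
        # zero-grads for blocks skipped on short sequences
        for i in range(n_pooled + 1, self.B + 1):
            for j in (1, 2):
                grads[f"W{i}_{j}"] = np.zeros_like(params[f"W{i}_{j}"])
                grads[f"b{i}_{j}"] = np.zeros_like(params[f"b{i}_{j}"])
        dZ = global_max_pool_backward(dlogits @ params["Wo"].T, gcache)
        for i in range(n_pooled, 0, -1):
            dZ = self._conv_block_backward(params, dZ, block_caches[i], i, grads)
            dZ = max_pool_3_2_backward(dZ, pool_caches[i - 1])
        dZ = self._conv_block_backward(params, dZ, block_caches[0], 0, grads)
        dX, dWr, dbr = conv1d_backward(dZ, rcache, params["Wr"])
        grads["Wr"], grads["br"] = dWr, dbr
        grads["E"] = embed_backward(dX, ids, self.V)
        return grads


def predict_logits(net, params: dict[str, np.ndarray], ids: np.ndarray,
                   chunk: int = 256) -> np.ndarray:
    """Forward pass in chunks (inference only)."""
    outs = []
    for i in range(0, len(ids), chunk):
        logits, _ = net.forward(params, ids[i : i + chunk])
        outs.append(logits)
    return np.concatenate(outs, axis=0) if outs else np.zeros((0, 2))
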