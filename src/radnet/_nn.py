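"""Minimal numpy neural-network primitives.

Implements exactly what the feature extractors need: dense and convolutional
autoencoders trained with Adam on a mean-squared-error objective, mini-batch
updates, early stopping with best-weight checkpointing, and deterministic
behaviour under a fixed seed (all state lives in ``numpy`` arrays, all
randomness flows through one ``numpy.random.Generator``).

Convolutions use im2col + GEMM with stride 1 and "same" zero padding; pooling
is 2x2 max with mask-based backward; the decoders upsample by nearest
neighbour. float32 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "DenseAutoencoder", "ConvAutoencoder"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class Adam:
    """Adam optimiser over a flat list of parameter arrays (in-place updates)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


# ---------------------------------------------------------------------------
# Dense autoencoder
# ---------------------------------------------------------------------------


class DenseAutoencoder:
    """Fully connected autoencoder: ReLU hidden layers, linear bottleneck and
    output, symmetric decoder.

    Parameters
    ----------
    input_dim : int
        Width of the (already encoded, [0, 1]-scaled) feature matrix.
    layer_sizes : sequence of int
        Encoder hidden-layer widths, strictly decreasing.
    bottleneck : int
        Embedding width; must be smaller than the last hidden layer.
    """

    def __init__(self, input_dim, layer_sizes=(512, 200, 125), bottleneck=32, seed=0):
        sizes = list(layer_sizes)
        if any(a <= b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("layer sizes must be strictly decreasing")
        if bottleneck >= sizes[-1]:
            raise ValueError("bottleneck must be smaller than the last hidden layer")
        self.input_dim = input_dim
        self.layer_sizes = sizes
        self.bottleneck = bottleneck
        dims = [input_dim] + sizes + [bottleneck]
        dec_dims = dims[::-1]
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.W.append(_he_init(rng, d_in, d_out))
            self.b.append(np.zeros(d_out, dtype=np.float32))
        for d_in, d_out in zip(dec_dims[:-1], dec_dims[1:]):
            self.W.append(_he_init(rng, d_in, d_out))
            self.b.append(np.zeros(d_out, dtype=np.float32))
        self.n_enc = len(dims) - 1
        self.history_ = None

    # -- forward / backward -------------------------------------------------
    def _forward(self, X):
        acts = [X]
        h = X
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            # ReLU on all but the bottleneck and the final reconstruction
            if i != self.n_enc - 1 and i != n_layers - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return acts

    def _backward(self, acts, X):
        n = X.shape[0]
        n_layers = len(self.W)
        grads_W = [None] * n_layers
        grads_b = [None] * n_layers
        delta = 2.0 * (acts[-1] - X) / (n * X.shape[1])
        for i in range(n_layers - 1, -1, -1):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if i - 1 != self.n_enc - 1:  # no ReLU behind the bottleneck
                    delta = delta * (acts[i] > 0)
        return grads_W, grads_b

    # -- API ----------------------------------------------------------------
    def fit(self, X, X_val=None, lr=1e-2, batch_size=32, max_epochs=100,
            patience=5, seed=0):
        """Train with Adam; early-stop after ``patience`` epochs without loss
        improvement (validation loss when ``X_val`` is given, else training
        loss), restoring the best checkpoint."""
        X = np.asarray(X, dtype=np.float32)
        monitor = X_val if X_val is None else np.asarray(X_val, dtype=np.float32)
        rng = np.random.default_rng(seed)
        opt = Adam(self.W + self.b, lr=lr)
        best = np.inf
        best_state = None
        bad = 0
        history = []
        for _epoch in range(max_epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), batch_size):
                batch = X[order[start:start + batch_size]]
                acts = self._forward(batch)
                if not np.isfinite(acts[-1]).all():
                    raise FloatingPointError(
                        "non-finite activations during autoencoder training"
                    )
                gW, gb = self._backward(acts, batch)
                opt.step(gW + gb)
            loss = self.reconstruction_mse(X if monitor is None else monitor)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite autoencoder loss")
            history.append(loss)
            if loss < best - 1e-12:
                best = loss
                best_state = [w.copy() for w in self.W + self.b]
                bad = 0
            else:
                bad += 1
                if bad >= patience:
                    break
        if best_state is not None:
            for p, s in zip(self.W + self.b, best_state):
                p[...] = s
        self.history_ = np.array(history)
        self.best_loss_ = best
        return self

    def transform(self, X):
        """Bottleneck activations, shape (n, bottleneck)."""
        h = np.asarray(X, dtype=np.float32)
        for i in range(self.n_enc):
            h = h @ self.W[i] + self.b[i]
            if i != self.n_enc - 1:
                h = np.maximum(h, 0.0)
        return h

    def reconstruct(self, X):
        return self._forward(np.asarray(X, dtype=np.float32))[-1]

    def reconstruction_mse(self, X):
        X = np.asarray(X, dtype=np.float32)
        return float(np.mean((self.reconstruct(X) - X) ** 2))


def _he_init(rng, d_in, d_out):
    return rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32)


# ---------------------------------------------------------------------------
# Convolution layers (NCHW, 3x3 kernels, stride 1, same padding)
# ---------------------------------------------------------------------------


class _Conv2d:
    def __init__(self, rng, c_in, c_out, k=3):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, k, k)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.W.reshape(len(self.W), -1).T + self.b
        return np.ascontiguousarray(
            out.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, grad_out):
        n, c_out, h, w = grad_out.shape
        k = self.k
        pad = k // 2
        g = grad_out.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        self.gW = (g.T @ self._cols).reshape(self.W.shape)
        self.gb = g.sum(axis=0)
        gcols = g @ self.W.reshape(c_out, -1)  # (n*h*w, c_in*k*k)
        _, c_in, _, _ = self._in_shape
        gcols = gcols.reshape(n, h, w, c_in, k, k)
        gx = np.zeros((n, c_in, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + h, dj:dj + w] += gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        self._cols = None
        return gx[:, :, pad:pad + h, pad:pad + w]

    def grads(self):
        return [self.gW, self.gb]


class _ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        out = g * self._mask
        self._mask = None
        return out

    def grads(self):
        return []


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, g):
        gr = self._mask * g[:, :, :, None, :, None]
        self._mask = None
        n, c, h2, _, w2, _ = gr.shape
        return gr.reshape(n, c, h2 * 2, w2 * 2)

    def grads(self):
        return []


class _Upsample2:
    def params(self):
        return []

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def grads(self):
        return []


class ConvAutoencoder:
    """Mirrored convolutional autoencoder.

    Encoder: for each entry of ``filters`` a 3x3 convolution + ReLU + 2x2 max
    pool; then a final 3x3 convolution with ``final_filters`` channels (ReLU).
    Decoder mirrors the encoder with nearest-neighbour upsampling and a linear
    1-channel output convolution. The embedding is the flattened final encoder
    feature map: ``final_filters * (H / 2**len(filters))**2`` values.
    """

    def __init__(self, filters=(64, 128, 256, 512), final_filters=1024,
                 in_channels=1, seed=0):
        rng = np.random.default_rng(seed)
        self.filters = tuple(filters)
        self.final_filters = final_filters
        enc = []
        c = in_channels
        for f in filters:
            enc += [_Conv2d(rng, c, f), _ReLU(), _MaxPool2()]
            c = f
        enc += [_Conv2d(rng, c, final_filters), _ReLU()]
        dec = []
        c = final_filters
        for f in reversed(filters):
            dec += [_Conv2d(rng, c, f), _ReLU(), _Upsample2()]
            c = f
        dec += [_Conv2d(rng, c, in_channels)]  # linear reconstruction
        self.encoder = enc
        self.decoder = dec
        self.layers = enc + dec
        self.history_ = None

    def embedding_dim(self, side):
        return self.final_filters * (side // 2 ** len(self.filters)) ** 2

    def _params(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def _forward(self, x, encoder_only=False):
        h = x
        for layer in self.encoder:
            h = layer.forward(h)
        if encoder_only:
            return h
        for layer in self.decoder:
            h = layer.forward(h)
        return h

    def _train_step(self, x, opt):
        recon = self._forward(x)
        if not np.isfinite(recon).all():
            raise FloatingPointError("non-finite CAE activations")
        n = x.size
        loss = float(np.mean((recon - x) ** 2))
        g = (2.0 / n) * (recon - x)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        grads = []
        for layer in self.layers:
            grads += layer.grads()
        opt.step(grads)
        return loss

    def fit(self, X, X_val, lr=1e-6, batch_size=32, max_epochs=40,
            patience=5, seed=0):
        """Train with Adam/MSE. Validation loss is evaluated twice per epoch
        (mid-epoch and end of epoch); early stopping counts validation checks
        without improvement and restores the best checkpoint."""
        X = np.asarray(X, dtype=np.float32)
        X_val = np.asarray(X_val, dtype=np.float32)
        rng = np.random.default_rng(seed)
        opt = Adam(self._params(), lr=lr)
        best = np.inf
        best_state = None
        bad = 0
        history = []
        n = len(X)
        n_batches = max(1, (n + batch_size - 1) // batch_size)
        stop = False
        for _epoch in range(max_epochs):
            order = rng.permutation(n)
            checkpoints = {n_batches // 2, n_batches - 1}
            for bi, start in enumerate(range(0, n, batch_size)):
                batch = X[order[start:start + batch_size]]
                self._train_step(batch, opt)
                if bi in checkpoints:
                    vloss = self.reconstruction_mse(X_val, batch_size=batch_size)
                    if not np.isfinite(vloss):
                        raise FloatingPointError("non-finite CAE validation loss")
                    history.append(vloss)
                    if vloss < best - 1e-12:
                        best = vloss
                        best_state = [p.copy() for p in self._params()]
                        bad = 0
                    else:
                        bad += 1
                        if bad >= patience:
                            stop = True
                            break
            if stop:
                break
        if best_state is not None:
            for p, s in zip(self._params(), best_state):
                p[...] = s
        self.history_ = np.array(history)
        self.best_loss_ = best
        return self

    def transform(self, X, batch_size=32):
        """Flattened final encoder feature maps, shape (n, embedding_dim)."""
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, len(X), batch_size):
            h = self._forward(X[start:start + batch_size], encoder_only=True)
            out.append(h.reshape(len(h), -1))
        return np.concatenate(out, axis=0)

    def reconstruct(self, X, batch_size=32):
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, len(X), batch_size):
            out.append(self._forward(X[start:start + batch_size]))
        return np.concatenate(out, axis=0)

    def reconstruction_mse(self, X, batch_size=32):
        X = np.asarray(X, dtype=np.float32)
        total = 0.0
        for start in range(0, len(X), batch_size):
            batch = X[start:start + batch_size]
            total += float(np.sum((self._forward(batch) - batch) ** 2))
        return total / X.size
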