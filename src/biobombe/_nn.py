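"""Compact numpy implementations of the single-bottleneck autoencoders.

Both networks map [0,1]-scaled expression through one dense bottleneck of
``k`` units and reconstruct the input through a sigmoid output layer,
trained with Adam on a binary cross-entropy objective (summed over genes,
averaged over the minibatch). Gradients are written out by hand — the
architectures are small enough that this is both faster and easier to
audit than an autodiff framework.

DAE: masking noise (a random fraction of input entries zeroed per
minibatch) regularizes the encoder; the bottleneck is linear.

VAE: the encoder outputs (mu, log sigma^2) of a diagonal Gaussian, a
reparameterized sample feeds the decoder, and the loss adds a KL
divergence penalty against the standard normal prior, weighted by
``kl_weight``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenoisingAutoencoder", "VariationalAutoencoder"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, (n_in, n_out))


class _Adam:
    """Plain Adam over a list of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DenoisingAutoencoder:
    def __init__(self, n_genes: int, k: int, seed: int, *,
                 learning_rate: float = 5e-4, batch_size: int = 50,
                 epochs: int = 50, noise_fraction: float = 0.1):
        self.k = k
        self.noise_fraction = noise_fraction
        self.batch_size = batch_size
        self.epochs = epochs
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.params = {
            "We": _glorot(rng, n_genes, k),
            "be": np.zeros(k),
            "Wd": _glorot(rng, k, n_genes),
            "bd": np.zeros(n_genes),
        }
        self.opt = _Adam(self.params, learning_rate)

    def fit(self, X: np.ndarray) -> "DenoisingAutoencoder":
        n = X.shape[0]
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                xb = X[order[start:start + self.batch_size]]
                self._step(xb)
        return self

    def _step(self, x: np.ndarray) -> None:
        b = x.shape[0]
        xc = x.copy()
        if self.noise_fraction > 0:
            mask = self.rng.random(x.shape) < self.noise_fraction
            xc[mask] = 0.0
        p = self.params
        h = xc @ p["We"] + p["be"]
        logits = h @ p["Wd"] + p["bd"]
        xhat = _sigmoid(logits)
        dlogits = (xhat - x) / b
        grads = {
            "Wd": h.T @ dlogits,
            "bd": dlogits.sum(axis=0),
        }
        dh = dlogits @ p["Wd"].T
        grads["We"] = xc.T @ dh
        grads["be"] = dh.sum(axis=0)
        self.opt.step(grads)

    # -- inference ---------------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params["We"] + self.params["be"]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        return _sigmoid(Z @ self.params["Wd"] + self.params["bd"])

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    @property
    def decoder_weights(self) -> np.ndarray:
        """genes x k matrix (decoder weights transposed)."""
        return self.params["Wd"].T.copy()

    @property
    def encoder_weights(self) -> np.ndarray:
        return self.params["We"].copy()


class VariationalAutoencoder:
    def __init__(self, n_genes: int, k: int, seed: int, *,
                 learning_rate: float = 5e-4, batch_size: int = 50,
                 epochs: int = 50, kl_weight: float = 1.0):
        self.k = k
        self.kl_weight = kl_weight
        self.batch_size = batch_size
        self.epochs = epochs
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.params = {
            "Wmu": _glorot(rng, n_genes, k),
            "bmu": np.zeros(k),
            "Wlv": _glorot(rng, n_genes, k),
            "blv": np.zeros(k),
            "Wd": _glorot(rng, k, n_genes),
            "bd": np.zeros(n_genes),
        }
        self.opt = _Adam(self.params, learning_rate)

    def fit(self, X: np.ndarray) -> "VariationalAutoencoder":
        n = X.shape[0]
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, self.batch_size):
                xb = X[order[start:start + self.batch_size]]
                self._step(xb)
        return self

    def _step(self, x: np.ndarray) -> None:
        b = x.shape[0]
        p = self.params
        mu = x @ p["Wmu"] + p["bmu"]
        lv = np.clip(x @ p["Wlv"] + p["blv"], -10.0, 10.0)
        eps = self.rng.standard_normal(mu.shape)
        sigma = np.exp(0.5 * lv)
        z = mu + eps * sigma
        logits = z @ p["Wd"] + p["bd"]
        xhat = _sigmoid(logits)

        w = self.kl_weight
        dlogits = (xhat - x) / b
        dz = dlogits @ p["Wd"].T
        dmu = dz + w * mu / b
        dlv = dz * eps * 0.5 * sigma + w * 0.5 * (np.exp(lv) - 1.0) / b
        grads = {
            "Wd": z.T @ dlogits,
            "bd": dlogits.sum(axis=0),
            "Wmu": x.T @ dmu,
            "bmu": dmu.sum(axis=0),
            "Wlv": x.T @ dlv,
            "blv": dlv.sum(axis=0),
        }
        self.opt.step(grads)

    # -- inference ---------------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        """Posterior mean activations (the deterministic embedding)."""
        return X @ self.params["Wmu"] + self.params["bmu"]

    def decode(self, Z: np.ndarray) -> np.ndarray:
        return _sigmoid(Z @ self.params["Wd"] + self.params["bd"])

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    @property
    def decoder_weights(self) -> np.ndarray:
        return self.params["Wd"].T.copy()

    @property
    def encoder_weights(self) -> np.ndarray:
        return self.params["Wmu"].copy()
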