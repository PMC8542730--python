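"""Variational autoencoder for mixed-type tabular data, in pure numpy.

The model is a standard amortised-inference VAE with a diagonal-gaussian
posterior and a standard-normal prior.  Each output column has its own
likelihood: gaussian with a learned per-column variance for continuous
(standardised) variables, bernoulli-with-logit for binary variables — so the
evidence lower bound (ELBO) is

    ELBO = sum_j E_q[log p(x_j | z)] - KL(q(z | x) || N(0, I)).

Encoder and decoder are small tanh MLPs (two hidden layers); gradients are
written out analytically and optimised with Adam.  The network is small
enough (p = 13 inputs) that this trains in seconds on one CPU core, and the
implementation is fully deterministic for a fixed seed.

A linear KL warm-up (weight 0 -> 1 over the first 20% of epochs) guards
against posterior collapse on tabular data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))
_MIN_LOGVAR = float(np.log(1e-4))  # floor on the learned observation variance


@dataclass
class VaeConfig:
    """Hyper-parameters of the mixed-likelihood VAE."""

    latent_dim: int = 9
    hidden_widths: tuple[int, int] = (64, 64)
    learning_rate: float = 1e-3
    epochs: int = 120
    batch_size: int = 256
    kl_warmup_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0.0 <= self.kl_warmup_frac <= 1.0:
            raise ValueError("kl_warmup_frac must be in [0, 1]")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


class MixedVae:
    """Fitted mixed-likelihood VAE.

    Parameters
    ----------
    column_kinds:
        Sequence of ``"continuous"`` / ``"binary"``, one per input column;
        fixes the per-column likelihood (gaussian / bernoulli).
    config:
        :class:`VaeConfig`.
    """

    def __init__(self, column_kinds: Sequence[str], config: VaeConfig):
        kinds = np.asarray(list(column_kinds))
        bad = set(kinds) - {"continuous", "binary"}
        if bad:
            raise ValueError(f"unknown column kinds {bad}")
        self.cont_idx = np.flatnonzero(kinds == "continuous")
        self.bin_idx = np.flatnonzero(kinds == "binary")
        self.p = len(kinds)
        if config.latent_dim >= self.p:
            raise ValueError(
                f"latent_dim {config.latent_dim} must be < feature count {self.p}"
            )
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        self.training_log: list[dict[str, float]] = []
        self._fitted = False

    # ---------------------------------------------------------------- setup

    def _init_params(self, rng: np.random.Generator) -> None:
        d, (h1, h2) = self.config.latent_dim, self.config.hidden_widths
        p = self.p
        P = {
            "We1": _glorot(rng, p, h1), "be1": np.zeros(h1),
            "We2": _glorot(rng, h1, h2), "be2": np.zeros(h2),
            "Wmu": _glorot(rng, h2, d), "bmu": np.zeros(d),
            "Wlv": _glorot(rng, h2, d), "blv": np.zeros(d) - 1.0,
            "Wd1": _glorot(rng, d, h2), "cd1": np.zeros(h2),
            "Wd2": _glorot(rng, h2, h1), "cd2": np.zeros(h1),
            "Wout": _glorot(rng, h1, p), "cout": np.zeros(p),
            # learned log observation variance, one per continuous column
            "loglam": np.zeros(len(self.cont_idx)),
        }
        self.params = P

    # -------------------------------------------------------------- forward

    def _encode(self, X: np.ndarray):
        P = self.params
        h1 = np.tanh(X @ P["We1"] + P["be1"])
        h2 = np.tanh(h1 @ P["We2"] + P["be2"])
        mu = h2 @ P["Wmu"] + P["bmu"]
        lv = np.clip(h2 @ P["Wlv"] + P["blv"], -10.0, 10.0)
        return h1, h2, mu, lv

    def _decode(self, z: np.ndarray):
        P = self.params
        g1 = np.tanh(z @ P["Wd1"] + P["cd1"])
        g2 = np.tanh(g1 @ P["Wd2"] + P["cd2"])
        out = g2 @ P["Wout"] + P["cout"]
        return g1, g2, out

    def _nll(self, X: np.ndarray, out: np.ndarray) -> float:
        """Mean per-sample negative reconstruction log-likelihood."""
        P = self.params
        total = 0.0
        if len(self.cont_idx):
            loglam = np.maximum(P["loglam"], _MIN_LOGVAR)
            lam = np.exp(loglam)
            diff = X[:, self.cont_idx] - out[:, self.cont_idx]
            total += 0.5 * float(
                np.mean(np.sum(loglam + diff**2 / lam + _LOG2PI, axis=1))
            )
        if len(self.bin_idx):
            t = out[:, self.bin_idx]
            x = X[:, self.bin_idx]
            total += float(np.mean(np.sum(_softplus(t) - x * t, axis=1)))
        return float(total)

    # ----------------------------------------------------------------- fit

    def fit(self, X: np.ndarray) -> "MixedVae":
        """Train by stochastic gradient ascent on the (warmed-up) ELBO."""
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p != self.p:
            raise ValueError(f"X has {p} columns, schema has {self.p}")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self._init_params(rng)
        P = self.params
        mstate = {k: np.zeros_like(v) for k, v in P.items()}
        vstate = {k: np.zeros_like(v) for k, v in P.items()}
        beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
        step = 0
        warm_epochs = max(1, int(round(cfg.kl_warmup_frac * cfg.epochs)))

        for epoch in range(cfg.epochs):
            kl_weight = min(1.0, (epoch + 1) / warm_epochs)
            order = rng.permutation(n)
            ep_recon = ep_kl = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = X[idx]
                B = len(xb)
                h1, h2, mu, lv = self._encode(xb)
                eps = rng.standard_normal(mu.shape)
                std = np.exp(0.5 * lv)
                z = mu + std * eps
                g1, g2, out = self._decode(z)

                grads = {k: np.zeros_like(v) for k, v in P.items()}

                # --- gradient of mean NLL wrt decoder output
                dout = np.zeros_like(out)
                recon = 0.0
                if len(self.cont_idx):
                    loglam = np.maximum(P["loglam"], _MIN_LOGVAR)
                    lam = np.exp(loglam)
                    diff = out[:, self.cont_idx] - xb[:, self.cont_idx]
                    dout[:, self.cont_idx] = diff / lam / B
                    recon += 0.5 * float(
                        np.sum(loglam + diff**2 / lam + _LOG2PI) / B
                    )
                    dloglam = 0.5 * np.sum(1.0 - diff**2 / lam, axis=0) / B
                    dloglam[P["loglam"] < _MIN_LOGVAR] = np.minimum(
                        dloglam[P["loglam"] < _MIN_LOGVAR], 0.0
                    )
                    grads["loglam"] = dloglam
                if len(self.bin_idx):
                    t = out[:, self.bin_idx]
                    x = xb[:, self.bin_idx]
                    dout[:, self.bin_idx] = (_sigmoid(t) - x) / B
                    recon += float(np.sum(_softplus(t) - x * t) / B)

                # --- decoder backprop
                grads["Wout"] = g2.T @ dout
                grads["cout"] = dout.sum(axis=0)
                dg2 = dout @ P["Wout"].T
                dpre2 = dg2 * (1.0 - g2**2)
                grads["Wd2"] = g1.T @ dpre2
                grads["cd2"] = dpre2.sum(axis=0)
                dg1 = dpre2 @ P["Wd2"].T
                dpre1 = dg1 * (1.0 - g1**2)
                grads["Wd1"] = z.T @ dpre1
                grads["cd1"] = dpre1.sum(axis=0)
                dz = dpre1 @ P["Wd1"].T

                # --- KL divergence and its gradients
                kl = 0.5 * float(np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / B)
                dmu = dz + kl_weight * mu / B
                dlv = dz * eps * 0.5 * std + kl_weight * 0.5 * (np.exp(lv) - 1.0) / B

                # --- encoder backprop (lv clip: pass-through inside range)
                pre_lv = h2 @ P["Wlv"] + P["blv"]
                dlv = dlv * ((pre_lv > -10.0) & (pre_lv < 10.0))
                grads["Wmu"] = h2.T @ dmu
                grads["bmu"] = dmu.sum(axis=0)
                grads["Wlv"] = h2.T @ dlv
                grads["blv"] = dlv.sum(axis=0)
                dh2 = dmu @ P["Wmu"].T + dlv @ P["Wlv"].T
                dpre_e2 = dh2 * (1.0 - h2**2)
                grads["We2"] = h1.T @ dpre_e2
                grads["be2"] = dpre_e2.sum(axis=0)
                dh1 = dpre_e2 @ P["We2"].T
                dpre_e1 = dh1 * (1.0 - h1**2)
                grads["We1"] = xb.T @ dpre_e1
                grads["be1"] = dpre_e1.sum(axis=0)

                if not np.isfinite(recon) or not np.isfinite(kl):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: recon={recon}, kl={kl}"
                    )

                # --- Adam update
                step += 1
                lr_t = cfg.learning_rate * (
                    np.sqrt(1.0 - beta2**step) / (1.0 - beta1**step)
                )
                for k in P:
                    g = grads[k]
                    mstate[k] = beta1 * mstate[k] + (1.0 - beta1) * g
                    vstate[k] = beta2 * vstate[k] + (1.0 - beta2) * g**2
                    P[k] -= lr_t * mstate[k] / (np.sqrt(vstate[k]) + eps_adam)
                P["loglam"] = np.maximum(P["loglam"], _MIN_LOGVAR)

                ep_recon += recon
                ep_kl += kl
                n_batches += 1

            recon_mean = ep_recon / n_batches
            kl_mean = ep_kl / n_batches
            self.training_log.append(
                {
                    "epoch": epoch,
                    "recon_nll": recon_mean,
                    "kl": kl_mean,
                    "kl_weight": kl_weight,
                    "objective": recon_mean + kl_weight * kl_mean,
                    "elbo": -(recon_mean + kl_mean),
                }
            )
        self._fitted = True
        return self

    # ------------------------------------------------------------ inference

    def _require_fitted(self) -> None:
        if not self._fitted:
            raise RuntimeError("VAE is not fitted")

    def encode_mean(self, X: np.ndarray) -> np.ndarray:
        """Posterior-mean latent coordinates (no sampling noise)."""
        self._require_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.p:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.p}"
            )
        _, _, mu, _ = self._encode(X)
        return mu

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Decode the posterior mean: continuous columns as means, binary
        columns as probabilities."""
        self._require_fitted()
        mu = self.encode_mean(X)
        _, _, out = self._decode(mu)
        rec = out.copy()
        if len(self.bin_idx):
            rec[:, self.bin_idx] = _sigmoid(out[:, self.bin_idx])
        return rec

    def reconstruction_mse(self, X: np.ndarray) -> float:
        """Mean squared reconstruction error over continuous columns."""
        X = np.asarray(X, dtype=float)
        rec = self.reconstruct(X)
        idx = self.cont_idx if len(self.cont_idx) else np.arange(self.p)
        return float(np.mean((X[:, idx] - rec[:, idx]) ** 2))
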