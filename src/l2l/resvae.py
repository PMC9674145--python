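"""Residual variational autoencoder over binary leaf skeletons.

The encoder maps a skeleton to a diagonal-Gaussian posterior N(μ_x, σ_x)
over a low-dimensional latent space (size 32 by default); the decoder
reconstructs the skeleton from a reparameterized sample z = μ + σ⊙ε.
Training minimizes

    L(x, x̂) = ‖x − x̂‖₂² + β · KL[N(μ_x, σ_x) ‖ N(0, 1)],

the squared-L2 reconstruction norm plus the β-weighted KL divergence
that keeps the aggregate posterior close to the standard normal and
makes the latent space sampleable.  The decoder carries residual blocks
(h(x) = r(x) + x) for extra capacity and receives additive skip
connections from the encoder stages during reconstruction; when
generating from a raw latent draw the skip inputs are zero grids, since
no encoder features exist for a sampled z.

Exact layer tables are an open design choice here: the default is a
4-stage strided-convolution encoder doubling channels, a mirrored
nearest-upsample decoder, and two residual blocks, all configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError, StateError
from .images import SkeletonImage
from .nn import Adam, Conv2d, Linear, NearestUpsample, ReLU, Residual, Sequential, Sigmoid
from .nn.layers import F32, collect_params


@dataclass(frozen=True)
class VaeConfig:
    latent_dim: int = 32
    image_side: int = 256
    beta: float = 1.0
    n_residual_blocks: int = 2
    base_channels: int = 8
    learning_rate: float = 2e-4
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    binarize_threshold: float = 0.5
    # fraction of batches trained with zeroed skip inputs, so the decoder
    # also learns to work from the latent alone (pure generation path)
    skip_dropout: float = 0.5

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ParameterError("latent_dim must be >= 1")
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if self.image_side % 16 != 0 or self.image_side < 16:
            raise ParameterError("image_side must be a positive multiple of 16")


@dataclass(frozen=True)
class LatentDistribution:
    """Diagonal-Gaussian posterior: per-dimension mean and std (σ > 0)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=np.float64))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=np.float64))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != sigma.shape:
            raise ParameterError("mu and sigma must have identical shape")
        if np.any(sigma <= 0):
            raise ParameterError("sigma must be strictly positive")

    @property
    def dim(self) -> int:
        return self.mu.shape[-1]


@dataclass(frozen=True)
class VaeLossParts:
    reconstruction: float
    kl: float
    total: float


def kl_divergence(dist: LatentDistribution) -> float:
    """KL[N(μ, σ) ‖ N(0, 1)] = Σ_i ½(μ_i² + σ_i² − 1 − ln σ_i²)."""
    mu, sigma = dist.mu, dist.sigma
    return float(np.sum(0.5 * (mu ** 2 + sigma ** 2 - 1.0 - np.log(sigma ** 2))))


def sample_latent(dist: LatentDistribution, rng: np.random.Generator) -> np.ndarray:
    """Reparameterized draw z = μ + σ ⊙ ε with ε ~ N(0, I)."""
    eps = rng.standard_normal(dist.mu.shape)
    return dist.mu + dist.sigma * eps


def vae_loss(x: np.ndarray, x_hat: np.ndarray, dist: LatentDistribution,
             beta: float) -> VaeLossParts:
    """Squared-L2 reconstruction plus β-weighted KL."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ParameterError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    rec = float(np.sum((x - x_hat) ** 2))
    kl = kl_divergence(dist)
    return VaeLossParts(rec, kl, rec + beta * kl)


class _VaeNet:
    """Encoder/decoder with explicit forward caches and manual backprop."""

    def __init__(self, cfg: VaeConfig, rng: np.random.Generator):
        b, d, s = cfg.base_channels, cfg.latent_dim, cfg.image_side
        chans = [1, b, 2 * b, 4 * b, 8 * b]
        self.enc = [(Conv2d(chans[i], chans[i + 1], 3, stride=2, rng=rng), ReLU())
                    for i in range(4)]
        self.feat_side = s // 16
        flat = 8 * b * self.feat_side ** 2
        self.fc_mu = Linear(flat, d, rng)
        self.fc_logvar = Linear(flat, d, rng)
        self.fc_dec = Linear(d, flat, rng)
        self.dec_act0 = ReLU()
        dchans = [8 * b, 4 * b, 2 * b, b, b]
        self.dec = [(NearestUpsample(), Conv2d(dchans[i], dchans[i + 1], 3, rng=rng), ReLU())
                    for i in range(4)]
        # decoder stage i output matches encoder feature 2 - i (additive skips)
        self.skip_of_stage = {0: 2, 1: 1, 2: 0}
        self.res = [Residual(Sequential(Conv2d(b, b, 3, rng=rng), ReLU(),
                                        Conv2d(b, b, 3, rng=rng)))
                    for _ in range(cfg.n_residual_blocks)]
        self.out_conv = Conv2d(b, 1, 3, rng=rng)
        self.out_act = Sigmoid()
        self.cfg = cfg

    # ---- parameter plumbing -------------------------------------------------
    def modules(self):
        for i, (c, _) in enumerate(self.enc):
            yield f"enc{i}", c
        yield "fc_mu", self.fc_mu
        yield "fc_logvar", self.fc_logvar
        yield "fc_dec", self.fc_dec
        for i, (_, c, _) in enumerate(self.dec):
            yield f"dec{i}", c
        for i, r in enumerate(self.res):
            yield f"res{i}", r
        yield "out", self.out_conv

    def param_triples(self):
        for prefix, mod in self.modules():
            for name, p, g in collect_params(mod):
                yield f"{prefix}.{name}", p, g

    def zero_grad(self):
        for _, _, g in self.param_triples():
            g[...] = 0.0

    # ---- forward ------------------------------------------------------------
    def encode(self, x: np.ndarray):
        h = x
        feats = []
        for conv, act in self.enc:
            h = act.forward(conv.forward(h))
            feats.append(h)
        n = h.shape[0]
        self._flat_shape = h.shape
        flat = h.reshape(n, -1)
        return self.fc_mu.forward(flat), self.fc_logvar.forward(flat), feats

    def decode(self, z: np.ndarray, feats=None):
        n = z.shape[0]
        b = self.cfg.base_channels
        h = self.dec_act0.forward(self.fc_dec.forward(z))
        h = h.reshape(n, 8 * b, self.feat_side, self.feat_side)
        self._used_skips = feats is not None
        for i, (up, conv, act) in enumerate(self.dec):
            h = act.forward(conv.forward(up.forward(h)))
            if feats is not None and i in self.skip_of_stage:
                h = h + feats[self.skip_of_stage[i]]
        for r in self.res:
            h = r.forward(h)
        return self.out_act.forward(self.out_conv.forward(h))

    # ---- backward -----------------------------------------------------------
    def backward_decode(self, d_out: np.ndarray):
        """Returns (d_z, skip_grads keyed by encoder-feature index)."""
        d = self.out_conv.backward(self.out_act.backward(d_out))
        for r in reversed(self.res):
            d = r.backward(d)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(4)):
            up, conv, act = self.dec[i]
            if self._used_skips and i in self.skip_of_stage:
                skip_grads[self.skip_of_stage[i]] = d
            d = up.backward(conv.backward(act.backward(d)))
        n = d.shape[0]
        d_z = self.fc_dec.backward(self.dec_act0.backward(d.reshape(n, -1)))
        return d_z, skip_grads

    def backward_encode(self, d_mu, d_logvar, skip_grads):
        d_flat = self.fc_mu.backward(d_mu) + self.fc_logvar.backward(d_logvar)
        d = d_flat.reshape(self._flat_shape)
        for i in reversed(range(4)):
            if i in skip_grads:          # additive skip taps encoder feature i
                d = d + skip_grads[i]
            conv, act = self.enc[i]
            d = conv.backward(act.backward(d))
        return d

    # state (checkpointing)
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p for name, p, _ in self.param_triples()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for name, p, _ in self.param_triples():
            p[...] = arrays[name]


# ---------------------------------------------------------------------------
# model / results


def _as_batch(skeletons, side: int) -> np.ndarray:
    arrs = []
    for s in skeletons:
        a = s.as_float() if isinstance(s, SkeletonImage) else np.asarray(s, dtype=np.float64)
        if a.ndim != 2 or a.shape != (side, side):
            raise ParameterError(f"skeleton shape {a.shape} != ({side}, {side})")
        arrs.append(a)
    return np.stack(arrs)[:, None, :, :].astype(F32)


class ResidualVAE:
    """Generative model of binary leaf skeletons.

    Parameters
    ----------
    skeletons
        Training set: sequence of :class:`SkeletonImage` or (side, side)
        arrays in [0, 1].
    config
        :class:`VaeConfig`; ``image_side`` must match the data.

    ``fit()`` returns a :class:`ResidualVAEResults` carrying the trained
    parameters, the per-epoch loss history and the posterior statistics
    used by the empirical latent-sampling mode.
    """

    def __init__(self, skeletons, config: VaeConfig = VaeConfig()):
        if len(skeletons) < 1:
            raise ParameterError("training set must not be empty")
        self.config = config
        self.data = _as_batch(skeletons, config.image_side)

    def fit(self, epochs: int | None = None) -> "ResidualVAEResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed)
        net = _VaeNet(cfg, rng)
        opt = Adam(net.param_triples(), lr=cfg.learning_rate)
        n = self.data.shape[0]
        history: list[VaeLossParts] = []
        for _ in range(n_epochs):
            order = rng.permutation(n)
            ep_rec = ep_kl = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                x = self.data[idx]
                bsz = x.shape[0]
                mu, logvar, feats = net.encode(x)
                sigma = np.exp(0.5 * logvar)
                eps = rng.standard_normal(mu.shape).astype(F32)
                z = mu + sigma * eps
                if rng.random() < cfg.skip_dropout:
                    feats = None         # train the pure-generation path too
                x_hat = net.decode(z, feats)
                rec = float(np.sum((x - x_hat) ** 2))
                kl = float(np.sum(0.5 * (mu ** 2 + sigma ** 2 - 1.0 - logvar)))
                ep_rec += rec
                ep_kl += kl
                net.zero_grad()
                d_xhat = (2.0 * (x_hat - x) / bsz).astype(F32)
                d_z, skip_grads = net.backward_decode(d_xhat)
                d_mu = d_z + cfg.beta * mu / bsz
                d_logvar = (d_z * eps * 0.5 * sigma
                            + cfg.beta * 0.5 * (np.exp(logvar) - 1.0) / bsz).astype(F32)
                net.backward_encode(d_mu.astype(F32), d_logvar, skip_grads)
                opt.step()
            history.append(VaeLossParts(ep_rec / n, ep_kl / n,
                                        ep_rec / n + cfg.beta * ep_kl / n))
        return ResidualVAEResults(net, cfg, history, self._posterior_stats(net))

    def _posterior_stats(self, net: _VaeNet) -> tuple[np.ndarray, np.ndarray]:
        """Diagonal Gaussian fitted to the training-set posterior means."""
        mus = []
        for start in range(0, self.data.shape[0], self.config.batch_size):
            mu, _, _ = net.encode(self.data[start:start + self.config.batch_size])
            mus.append(mu)
        mus = np.concatenate(mus).astype(np.float64)
        sd = mus.std(axis=0)
        return mus.mean(axis=0), np.where(sd > 1e-6, sd, 1.0)


class ResidualVAEResults:
    """Fitted skeleton VAE: parameters, loss history, sampling utilities."""

    def __init__(self, net: _VaeNet, config: VaeConfig, history: list[VaeLossParts],
                 latent_stats: tuple[np.ndarray, np.ndarray]):
        self.net = net
        self.config = config
        self.history = history
        self.latent_mean, self.latent_std = latent_stats

    # -- inference ---------------------------------------------------------
    def encode(self, x) -> LatentDistribution:
        batch = _as_batch([x], self.config.image_side)
        mu, logvar, _ = self.net.encode(batch)
        return LatentDistribution(mu[0].astype(np.float64),
                                  np.exp(0.5 * logvar[0]).astype(np.float64))

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decode a latent vector with zero skip inputs (pure generation)."""
        z = np.asarray(z, dtype=np.float64)
        if z.ndim != 1 or z.shape[0] != self.config.latent_dim:
            raise ParameterError(
                f"latent length {z.shape} != ({self.config.latent_dim},)")
        out = self.net.decode(z[None].astype(F32), feats=None)
        return out[0, 0].astype(np.float64)

    def reconstruct(self, x) -> np.ndarray:
        """Autoencode one skeleton (skip connections active)."""
        batch = _as_batch([x], self.config.image_side)
        mu, _, feats = self.net.encode(batch)
        return self.net.decode(mu, feats)[0, 0].astype(np.float64)

    def sample_skeletons(self, n: int, rng: np.random.Generator | int = 0,
                         empirical: bool = False) -> list[SkeletonImage]:
        """Draw latents from the prior (N(0, I), or the empirical Gaussian
        fitted to training posterior means) and decode + binarize."""
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        out = []
        for _ in range(n):
            z = rng.standard_normal(self.config.latent_dim)
            if empirical:
                z = self.latent_mean + self.latent_std * z
            out.append(SkeletonImage(self.decode(z) > self.config.binarize_threshold))
        return out

    # -- reporting / persistence -------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        n_par = sum(p.size for _, p, _ in self.net.param_triples())
        lines = [
            "Residual VAE over leaf skeletons",
            "=" * 40,
            f"latent dim          {cfg.latent_dim}",
            f"image side          {cfg.image_side}",
            f"beta                {cfg.beta}",
            f"residual blocks     {cfg.n_residual_blocks}",
            f"parameters          {n_par}",
            f"epochs trained      {len(self.history)}",
        ]
        if self.history:
            lines += [
                f"loss (epoch 1)      total {self.history[0].total:.3f} "
                f"(rec {self.history[0].reconstruction:.3f}, kl {self.history[0].kl:.3f})",
                f"loss (final)        total {self.history[-1].total:.3f} "
                f"(rec {self.history[-1].reconstruction:.3f}, kl {self.history[-1].kl:.3f})",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "history": [asdict(h) for h in self.history],
        }
        np.savez(path,
                 __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 __latent_mean__=self.latent_mean,
                 __latent_std__=self.latent_std,
                 **self.net.state_arrays())

    @classmethod
    def load(cls, path) -> "ResidualVAEResults":
        path = Path(path)
        if not path.exists():
            raise StateError(f"checkpoint not found: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = VaeConfig(**meta["config"])
            net = _VaeNet(cfg, np.random.default_rng(cfg.seed))
            net.load_state({k: data[k] for k in data.files
                            if not k.startswith("__")})
            history = [VaeLossParts(**h) for h in meta["history"]]
            stats = (data["__latent_mean__"], data["__latent_std__"])
        return cls(net, cfg, history, stats)


# ---------------------------------------------------------------------------
# functional interface


def encode(x, results: ResidualVAEResults) -> LatentDistribution:
    return results.encode(x)


def decode(z: np.ndarray, results: ResidualVAEResults) -> np.ndarray:
    return results.decode(z)


def train_vae(dataset, config: VaeConfig = VaeConfig()):
    """Train on a list of skeletons; returns (results, per-epoch loss parts)."""
    if len(dataset) < 2:
        raise ParameterError("training requires at least 2 skeletons")
    res = ResidualVAE(dataset, config).fit()
    return res, res.history
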