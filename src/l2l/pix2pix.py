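"""Conditional GAN translating binary skeletons into colorized leaves.

The generator G learns a mapping G(z|y) from a conditioning skeleton y
(one input channel) to an RGB or R/G/NIR leaf image; the discriminator D
sees (skeleton, image) pairs and scores, per receptive patch, the
probability that the pair is real.  The objective is the conditional-GAN
min–max game plus a λ-weighted L1 term that keeps the generator near the
ground truth while discouraging blur:

    G*, D* = arg min_G max_D  L_cGAN(D, G) + λ · L_L1(G).

Architecture follows the standard encoder–decoder-with-skips generator
and patch discriminator convention; the noise source z is realized as
dropout in the decoder (active during training and, optionally, at
stochastic inference).  The generator optimizes the non-saturating form
−E[log D(G(z|y))], which shares its fixed points with the literal
log(1 − D) objective but keeps gradients alive early in training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, StateError
from .images import RGB, RGNIR, LeafImage, SkeletonImage
from .nn import Adam, Conv2d, Dropout, LeakyReLU, ReLU, Sigmoid
from .nn.layers import F32, collect_params

_EPS = 1e-7


@dataclass(frozen=True)
class GanConfig:
    lambda_l1: float = 100.0
    image_side: int = 256
    channels_out: int = 3
    base_channels: int = 8
    learning_rate_g: float = 2e-4
    learning_rate_d: float = 2e-4
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    dropout: float = 0.5
    mode: str = "rgb"                     # "rgb" or "rgnir" (R, G, NIR targets)

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ParameterError("lambda_l1 must be >= 0")
        if self.image_side % 16 != 0:
            raise ParameterError("image_side must be a multiple of 16")
        if self.mode not in ("rgb", "rgnir"):
            raise ParameterError("mode must be 'rgb' or 'rgnir'")

    @property
    def bands(self) -> tuple[str, ...]:
        return RGB if self.mode == "rgb" else RGNIR


@dataclass(frozen=True)
class GanLossParts:
    d_loss: float
    g_adv: float
    g_l1: float
    g_total: float


@dataclass
class TranslationPair:
    condition: SkeletonImage
    target: LeafImage

    def __post_init__(self):
        if self.condition.shape != self.target.shape:
            raise ParameterError("condition and target must share spatial size")


def l1_loss(target: np.ndarray, generated: np.ndarray) -> float:
    """Sum of absolute pixel differences, ‖target − generated‖₁."""
    a = np.asarray(target, dtype=np.float64)
    b = np.asarray(generated, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


def cgan_losses(d_real: np.ndarray, d_fake: np.ndarray, target: np.ndarray,
                generated: np.ndarray, lam: float) -> GanLossParts:
    """Binary-cross-entropy discriminator loss, non-saturating generator
    adversarial term, and the per-pixel-normalized L1 term."""
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    d_loss = float(-np.mean(np.log(dr)) - np.mean(np.log(1.0 - df)))
    g_adv = float(-np.mean(np.log(df)))
    g_l1 = l1_loss(target, generated) / np.asarray(target).size
    return GanLossParts(d_loss, g_adv, g_l1, g_adv + lam * g_l1)


class _Generator:
    """U-net: strided-conv encoder, nearest-upsample decoder with
    concatenated skips and dropout (the noise source z)."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        b = cfg.base_channels
        self.enc = [
            (Conv2d(1, b, 3, stride=2, rng=rng), LeakyReLU()),
            (Conv2d(b, 2 * b, 3, stride=2, rng=rng), LeakyReLU()),
            (Conv2d(2 * b, 4 * b, 3, stride=2, rng=rng), LeakyReLU()),
            (Conv2d(4 * b, 8 * b, 3, stride=2, rng=rng), LeakyReLU()),
        ]
        from .nn import NearestUpsample
        self.dec = [
            (NearestUpsample(), Conv2d(8 * b, 4 * b, 3, rng=rng), ReLU(), Dropout(cfg.dropout)),
            (NearestUpsample(), Conv2d(8 * b, 2 * b, 3, rng=rng), ReLU(), Dropout(cfg.dropout)),
            (NearestUpsample(), Conv2d(4 * b, b, 3, rng=rng), ReLU(), None),
            (NearestUpsample(), Conv2d(2 * b, b, 3, rng=rng), ReLU(), None),
        ]
        self.out_conv = Conv2d(b, cfg.channels_out, 3, rng=rng)
        self.out_act = Sigmoid()
        self.cfg = cfg

    def modules(self):
        for i, (c, _) in enumerate(self.enc):
            yield f"genc{i}", c
        for i, (_, c, _, _) in enumerate(self.dec):
            yield f"gdec{i}", c
        yield "gout", self.out_conv

    def param_triples(self):
        for prefix, mod in self.modules():
            for name, p, g in collect_params(mod):
                yield f"{prefix}.{name}", p, g

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for stage in self.dec:
            if stage[3] is not None:
                stage[3].set_rng(rng)

    def forward(self, y: np.ndarray, train: bool = True) -> np.ndarray:
        h = y
        feats = []
        for conv, act in self.enc:
            h = act.forward(conv.forward(h))
            feats.append(h)
        self._cat_sizes = []
        for i, (up, conv, act, drop) in enumerate(self.dec):
            h = act.forward(conv.forward(up.forward(h)))
            if drop is not None:
                h = drop.forward(h, train=train)
            if i < 3:                    # concat encoder feature at same scale
                skip = feats[2 - i]
                self._cat_sizes.append(h.shape[1])
                h = np.concatenate([h, skip], axis=1)
        return self.out_act.forward(self.out_conv.forward(h))

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        d = self.out_conv.backward(self.out_act.backward(d_out))
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(4)):
            up, conv, act, drop = self.dec[i]
            if i < 3:
                own = self._cat_sizes[i]
                skip_grads[2 - i] = d[:, own:]
                d = d[:, :own]
            if drop is not None:
                d = drop.backward(d)
            d = up.backward(conv.backward(act.backward(d)))
        for i in reversed(range(4)):
            if i in skip_grads:
                d = d + skip_grads[i]
            conv, act = self.enc[i]
            d = conv.backward(act.backward(d))
        return d


class _Discriminator:
    """Patch discriminator on concatenated (skeleton, candidate) channels;
    output grid is 1/8 of the input side, each cell a patch probability."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        b = cfg.base_channels
        c_in = 1 + cfg.channels_out
        self.stack = [
            (Conv2d(c_in, b, 3, stride=2, rng=rng), LeakyReLU()),
            (Conv2d(b, 2 * b, 3, stride=2, rng=rng), LeakyReLU()),
            (Conv2d(2 * b, 4 * b, 3, stride=2, rng=rng), LeakyReLU()),
            (Conv2d(4 * b, 1, 3, stride=1, rng=rng), Sigmoid()),
        ]

    def modules(self):
        for i, (c, _) in enumerate(self.stack):
            yield f"d{i}", c

    def param_triples(self):
        for prefix, mod in self.modules():
            for name, p, g in collect_params(mod):
                yield f"{prefix}.{name}", p, g

    def forward(self, y: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        h = np.concatenate([y, candidate], axis=1)
        self._split = y.shape[1]
        for conv, act in self.stack:
            h = act.forward(conv.forward(h))
        return h

    def backward(self, d_out: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = d_out
        for conv, act in reversed(self.stack):
            d = conv.backward(act.backward(d))
        return d[:, :self._split], d[:, self._split:]


def _zero_grads(triples):
    for _, _, g in triples:
        g[...] = 0.0


class Pix2Pix:
    """Skeleton→leaf translation model.

    Parameters
    ----------
    pairs
        Sequence of :class:`TranslationPair` (condition skeleton plus RGB
        or R/G/NIR target of matching size).
    config
        :class:`GanConfig`.

    ``fit()`` alternates discriminator and generator Adam updates and
    returns a :class:`Pix2PixResults`.
    """

    def __init__(self, pairs: list[TranslationPair], config: GanConfig = GanConfig()):
        if len(pairs) < 1:
            raise ParameterError("training pairs must not be empty")
        s = config.image_side
        for p in pairs:
            if p.condition.shape != (s, s):
                raise ParameterError(f"pair size {p.condition.shape} != ({s}, {s})")
        self.config = config
        self.y = np.stack([p.condition.as_float() for p in pairs])[:, None].astype(F32)
        self.x = np.stack([p.target.channels for p in pairs]).astype(F32)
        if self.x.shape[1] != config.channels_out:
            raise ParameterError(
                f"targets have {self.x.shape[1]} channels, config expects {config.channels_out}")

    def fit(self, epochs: int | None = None) -> "Pix2PixResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed)
        gen = _Generator(cfg, rng)
        disc = _Discriminator(cfg, rng)
        gen.set_dropout_rng(rng)
        g_triples = list(gen.param_triples())
        d_triples = list(disc.param_triples())
        opt_g = Adam(g_triples, lr=cfg.learning_rate_g)
        opt_d = Adam(d_triples, lr=cfg.learning_rate_d)
        n = self.y.shape[0]
        npix = self.x[0].size
        history: list[GanLossParts] = []
        for _ in range(n_epochs):
            order = rng.permutation(n)
            ep = np.zeros(4)
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                y, x = self.y[idx], self.x[idx]
                bsz = y.shape[0]

                # --- discriminator update (generator frozen) ---------------
                fake = gen.forward(y, train=True)
                p_real = disc.forward(y, x)
                m = p_real.size
                _zero_grads(d_triples)
                d_real_grad = (-1.0 / np.clip(p_real, _EPS, 1 - _EPS) / m).astype(F32)
                disc.backward(d_real_grad)
                p_fake = disc.forward(y, fake)
                d_fake_grad = (1.0 / np.clip(1.0 - p_fake, _EPS, 1 - _EPS) / m).astype(F32)
                disc.backward(d_fake_grad)
                opt_d.step()
                d_loss = float(-np.mean(np.log(np.clip(p_real, _EPS, 1)))
                               - np.mean(np.log(np.clip(1 - p_fake, _EPS, 1))))

                # --- generator update (discriminator frozen) ---------------
                p_fake2 = disc.forward(y, fake)
                _zero_grads(d_triples)       # discard grads from the pass-through
                g_adv_grad = (-1.0 / np.clip(p_fake2, _EPS, 1 - _EPS) / p_fake2.size).astype(F32)
                _, d_candidate = disc.backward(g_adv_grad)
                _zero_grads(d_triples)
                l1_grad = (cfg.lambda_l1 * np.sign(fake - x) / (npix * bsz)).astype(F32)
                _zero_grads(g_triples)
                gen.backward(d_candidate + l1_grad)
                opt_g.step()

                g_adv = float(-np.mean(np.log(np.clip(p_fake2, _EPS, 1))))
                g_l1 = float(np.abs(fake - x).sum() / (npix * bsz))
                ep += (d_loss, g_adv, g_l1, g_adv + cfg.lambda_l1 * g_l1)
                n_batches += 1
            history.append(GanLossParts(*(float(v) for v in ep / n_batches)))
        return Pix2PixResults(gen, disc, cfg, history)


class Pix2PixResults:
    """Fitted translator: generator/discriminator parameters and history."""

    def __init__(self, gen: _Generator, disc: _Discriminator, config: GanConfig,
                 history: list[GanLossParts]):
        self.gen = gen
        self.disc = disc
        self.config = config
        self.history = history

    def translate(self, skeleton, stochastic: bool = False,
                  rng: np.random.Generator | int = 0) -> LeafImage:
        """Colorize one skeleton.  With ``stochastic`` the decoder dropout
        stays active at inference, realizing the noise source z."""
        y = skeleton.as_float() if isinstance(skeleton, SkeletonImage) else np.asarray(skeleton)
        s = self.config.image_side
        if y.shape != (s, s):
            raise ParameterError(f"skeleton shape {y.shape} != ({s}, {s})")
        if stochastic:
            if isinstance(rng, (int, np.integer)):
                rng = np.random.default_rng(rng)
            self.gen.set_dropout_rng(rng)
        out = self.gen.forward(y[None, None].astype(F32), train=stochastic)
        return LeafImage(np.clip(out[0].astype(np.float64), 0, 1), self.config.bands)

    def discriminate(self, skeleton, candidate: LeafImage) -> np.ndarray:
        """Patch-probability grid for a (skeleton, candidate) pair."""
        y = skeleton.as_float() if isinstance(skeleton, SkeletonImage) else np.asarray(skeleton)
        if y.shape != candidate.shape:
            raise ParameterError("skeleton and candidate must share spatial size")
        return self.disc.forward(y[None, None].astype(F32),
                                 candidate.channels[None].astype(F32))[0, 0].astype(np.float64)

    def summary(self) -> str:
        cfg = self.config
        n_g = sum(p.size for _, p, _ in self.gen.param_triples())
        n_d = sum(p.size for _, p, _ in self.disc.param_triples())
        lines = [
            "Pix2pix skeleton→leaf translator",
            "=" * 40,
            f"mode                {cfg.mode} ({'/'.join(cfg.bands)})",
            f"image side          {cfg.image_side}",
            f"lambda (L1 weight)  {cfg.lambda_l1}",
            f"generator params    {n_g}",
            f"discriminator params {n_d}",
            f"epochs trained      {len(self.history)}",
        ]
        if self.history:
            h0, h1 = self.history[0], self.history[-1]
            lines += [
                f"epoch 1   d {h0.d_loss:.4f}  g_adv {h0.g_adv:.4f}  g_l1 {h0.g_l1:.4f}",
                f"final     d {h1.d_loss:.4f}  g_adv {h1.g_adv:.4f}  g_l1 {h1.g_l1:.4f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {"config": asdict(self.config),
                "history": [asdict(h) for h in self.history]}
        arrays = {f"G:{k}": p for k, p, _ in self.gen.param_triples()}
        arrays.update({f"D:{k}": p for k, p, _ in self.disc.param_triples()})
        np.savez(path,
                 __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Pix2PixResults":
        path = Path(path)
        if not path.exists():
            raise StateError(f"checkpoint not found: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = GanConfig(**meta["config"])
            rng = np.random.default_rng(cfg.seed)
            gen = _Generator(cfg, rng)
            disc = _Discriminator(cfg, rng)
            for k, p, _ in gen.param_triples():
                p[...] = data[f"G:{k}"]
            for k, p, _ in disc.param_triples():
                p[...] = data[f"D:{k}"]
            history = [GanLossParts(**h) for h in meta["history"]]
        return cls(gen, disc, cfg, history)


# ---------------------------------------------------------------------------
# functional interface


def generator_forward(y, results: Pix2PixResults, stochastic: bool = False,
                      rng: np.random.Generator | int = 0) -> LeafImage:
    return results.translate(y, stochastic=stochastic, rng=rng)


def discriminator_forward(y, candidate: LeafImage, results: Pix2PixResults) -> np.ndarray:
    return results.discriminate(y, candidate)


def train_pix2pix(pairs: list[TranslationPair], config: GanConfig = GanConfig()):
    """Train on translation pairs; returns (results, per-epoch loss parts)."""
    if len(pairs) < 2:
        raise ParameterError("training requires at least 2 pairs")
    res = Pix2Pix(pairs, config).fit()
    return res, res.history
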