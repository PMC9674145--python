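"""Quantitative quality assessment of generated leaves.

A plain convolutional autoencoder is trained to be the identity operator
on *real* leaf images only.  Because it never sees synthetic images, a
candidate that deviates from the real-image manifold reconstructs badly;
its anomaly score — the reconstruction error s_x — is high.  Sweeping a
threshold on s_x over a pool of real and synthetic images yields the ROC
curve with the fake-as-positive convention

    FPR = FP / (FP + TN),   TPR = TP / (TP + FN),

where TP counts genuinely fake images classified fake and TN genuinely
real images classified real.  The area under the curve (AUC) summarizes
how distinguishable the synthetic images are: 0.5 is chance, values
below 0.5 mean the synthetics are scored as *more* real than the reals.

The AE reuses the skeleton-VAE encoder/decoder layout without the
variational head and without skip connections (skips would make identity
reconstruction trivial and the score uninformative).  The score is the
mean squared pixel error by default; mean absolute error is available
behind ``score_kind="mae"``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError, StateError
from .images import LeafImage
from .nn import Adam, Conv2d, Linear, NearestUpsample, ReLU, Residual, Sequential, Sigmoid
from .nn.layers import F32, collect_params


@dataclass(frozen=True)
class AeConfig:
    latent_dim: int = 64
    image_side: int = 256
    channels: int = 3
    base_channels: int = 8
    n_residual_blocks: int = 1
    learning_rate: float = 2e-4
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    score_kind: str = "mse"              # "mse" or "mae"

    def __post_init__(self):
        if self.image_side % 16 != 0:
            raise ParameterError("image_side must be a multiple of 16")
        if self.score_kind not in ("mse", "mae"):
            raise ParameterError("score_kind must be 'mse' or 'mae'")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass(frozen=True)
class RocResult:
    thresholds: tuple[float, ...]        # descending
    points: tuple[tuple[float, float], ...]   # (fpr, tpr), (0,0) → (1,1)
    auc: float


class _AeNet:
    """Conv encoder → dense bottleneck → upsample decoder, no skips."""

    def __init__(self, cfg: AeConfig, rng: np.random.Generator):
        b, d, s, c = cfg.base_channels, cfg.latent_dim, cfg.image_side, cfg.channels
        chans = [c, b, 2 * b, 4 * b, 8 * b]
        self.enc = [(Conv2d(chans[i], chans[i + 1], 3, stride=2, rng=rng), ReLU())
                    for i in range(4)]
        self.feat_side = s // 16
        flat = 8 * b * self.feat_side ** 2
        self.fc_enc = Linear(flat, d, rng)
        self.fc_dec = Linear(d, flat, rng)
        self.act_mid = ReLU()
        dchans = [8 * b, 4 * b, 2 * b, b, b]
        self.dec = [(NearestUpsample(), Conv2d(dchans[i], dchans[i + 1], 3, rng=rng), ReLU())
                    for i in range(4)]
        self.res = [Residual(Sequential(Conv2d(b, b, 3, rng=rng), ReLU(),
                                        Conv2d(b, b, 3, rng=rng)))
                    for _ in range(cfg.n_residual_blocks)]
        self.out_conv = Conv2d(b, c, 3, rng=rng)
        self.out_act = Sigmoid()
        self.cfg = cfg

    def modules(self):
        for i, (cv, _) in enumerate(self.enc):
            yield f"enc{i}", cv
        yield "fc_enc", self.fc_enc
        yield "fc_dec", self.fc_dec
        for i, (_, cv, _) in enumerate(self.dec):
            yield f"dec{i}", cv
        for i, r in enumerate(self.res):
            yield f"res{i}", r
        yield "out", self.out_conv

    def param_triples(self):
        for prefix, mod in self.modules():
            for name, p, g in collect_params(mod):
                yield f"{prefix}.{name}", p, g

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for conv, act in self.enc:
            h = act.forward(conv.forward(h))
        n = h.shape[0]
        self._flat_shape = h.shape
        z = self.fc_enc.forward(h.reshape(n, -1))
        h = self.act_mid.forward(self.fc_dec.forward(z))
        h = h.reshape(n, 8 * self.cfg.base_channels, self.feat_side, self.feat_side)
        for up, conv, act in self.dec:
            h = act.forward(conv.forward(up.forward(h)))
        for r in self.res:
            h = r.forward(h)
        return self.out_act.forward(self.out_conv.forward(h))

    def backward(self, d_out: np.ndarray) -> None:
        d = self.out_conv.backward(self.out_act.backward(d_out))
        for r in reversed(self.res):
            d = r.backward(d)
        for up, conv, act in reversed(self.dec):
            d = up.backward(conv.backward(act.backward(d)))
        n = d.shape[0]
        d = self.fc_dec.backward(self.act_mid.backward(d.reshape(n, -1)))
        d = self.fc_enc.backward(d).reshape(self._flat_shape)
        for conv, act in reversed(self.enc):
            d = conv.backward(act.backward(d))

    def zero_grad(self):
        for _, _, g in self.param_triples():
            g[...] = 0.0


def _as_image_batch(images, cfg: AeConfig) -> np.ndarray:
    arrs = []
    for im in images:
        a = im.channels if isinstance(im, LeafImage) else np.asarray(im, dtype=np.float64)
        if a.ndim == 2:
            a = a[None]
        if a.shape != (cfg.channels, cfg.image_side, cfg.image_side):
            raise ParameterError(
                f"image shape {a.shape} != ({cfg.channels}, {cfg.image_side}, {cfg.image_side})")
        arrs.append(a)
    return np.stack(arrs).astype(F32)


class AnomalyAutoencoder:
    """Identity-operator AE over real leaf images; fit() → results with
    per-image anomaly scoring."""

    def __init__(self, real_images, config: AeConfig = AeConfig()):
        if len(real_images) < 1:
            raise ParameterError("training set must not be empty")
        self.config = config
        self.data = _as_image_batch(real_images, config)

    def fit(self, epochs: int | None = None) -> "AnomalyAEResults":
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed)
        net = _AeNet(cfg, rng)
        opt = Adam(net.param_triples(), lr=cfg.learning_rate)
        n = self.data.shape[0]
        history: list[float] = []
        for _ in range(n_epochs):
            order = rng.permutation(n)
            ep = 0.0
            for start in range(0, n, cfg.batch_size):
                x = self.data[order[start:start + cfg.batch_size]]
                bsz = x.shape[0]
                x_hat = net.forward(x)
                ep += float(np.sum((x - x_hat) ** 2))
                net.zero_grad()
                net.backward((2.0 * (x_hat - x) / bsz).astype(F32))
                opt.step()
            history.append(ep / n)       # per-sample summed squared error
        return AnomalyAEResults(net, cfg, history)


class AnomalyAEResults:
    def __init__(self, net: _AeNet, config: AeConfig, history: list[float]):
        self.net = net
        self.config = config
        self.history = history

    def reconstruct(self, image) -> np.ndarray:
        x = _as_image_batch([image], self.config)
        return self.net.forward(x)[0].astype(np.float64)

    def score(self, image) -> float:
        """Anomaly score s_x: mean reconstruction error (squared or absolute)."""
        x = _as_image_batch([image], self.config).astype(np.float64)[0]
        return score_from_reconstruction(x, self.reconstruct(image),
                                         self.config.score_kind)

    def score_many(self, images) -> list[float]:
        return [self.score(im) for im in images]

    def summary(self) -> str:
        lines = [
            "Anomaly autoencoder (identity operator on real leaves)",
            "=" * 50,
            f"latent dim     {self.config.latent_dim}",
            f"image side     {self.config.image_side}",
            f"score          {self.config.score_kind}",
            f"epochs trained {len(self.history)}",
        ]
        if self.history:
            lines += [f"loss (epoch 1) {self.history[0]:.4f}",
                      f"loss (final)   {self.history[-1]:.4f}"]
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {"config": asdict(self.config), "history": self.history}
        np.savez(path,
                 __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **{k: p for k, p, _ in self.net.param_triples()})

    @classmethod
    def load(cls, path) -> "AnomalyAEResults":
        path = Path(path)
        if not path.exists():
            raise StateError(f"checkpoint not found: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = AeConfig(**meta["config"])
            net = _AeNet(cfg, np.random.default_rng(cfg.seed))
            for k, p, _ in net.param_triples():
                p[...] = data[k]
        return cls(net, cfg, meta["history"])


def score_from_reconstruction(x: np.ndarray, reconstruction: np.ndarray,
                              kind: str = "mse") -> float:
    """Anomaly score from an image and its AE reconstruction."""
    x = np.asarray(x, dtype=np.float64)
    r = np.asarray(reconstruction, dtype=np.float64)
    if x.shape != r.shape:
        raise ParameterError(f"shape mismatch: {x.shape} vs {r.shape}")
    if kind == "mae":
        return float(np.mean(np.abs(x - r)))
    return float(np.mean((x - r) ** 2))


# ---------------------------------------------------------------------------
# ROC / AUC


def confusion_at(scores_real, scores_fake, threshold: float) -> ConfusionCounts:
    """Fake-as-positive confusion at a threshold; score ≥ threshold ⇒ positive."""
    sr = np.asarray(scores_real, dtype=np.float64)
    sf = np.asarray(scores_fake, dtype=np.float64)
    if sr.size == 0 or sf.size == 0:
        raise ParameterError("score lists must be non-empty")
    tp = int(np.sum(sf >= threshold))
    fp = int(np.sum(sr >= threshold))
    return ConfusionCounts(tp=tp, tn=sr.size - fp, fp=fp, fn=sf.size - tp)


def roc_auc(scores_real, scores_fake) -> RocResult:
    """ROC over all observed score thresholds plus a +∞ sentinel,
    with trapezoidal AUC."""
    sr = np.asarray(scores_real, dtype=np.float64)
    sf = np.asarray(scores_fake, dtype=np.float64)
    if sr.size == 0 or sf.size == 0:
        raise ParameterError("score lists must be non-empty")
    thresholds = [np.inf] + sorted(set(np.concatenate([sr, sf]).tolist()), reverse=True)
    points = []
    for t in thresholds:
        c = ConfusionCounts(tp=int(np.sum(sf >= t)), fp=int(np.sum(sr >= t)),
                            tn=int(np.sum(sr < t)), fn=int(np.sum(sf < t)))
        fpr = c.fp / (c.fp + c.tn)
        tpr = c.tp / (c.tp + c.fn)
        points.append((fpr, tpr))
    fprs, tprs = zip(*points)
    auc = float(np.trapezoid(tprs, fprs))
    return RocResult(tuple(thresholds), tuple(points), auc)


# ---------------------------------------------------------------------------
# functional interface


def train_anomaly_ae(real_images, config: AeConfig = AeConfig()) -> AnomalyAEResults:
    if len(real_images) < 2:
        raise ParameterError("training requires at least 2 images")
    return AnomalyAutoencoder(real_images, config).fit()


def anomaly_score(image, results: AnomalyAEResults) -> float:
    return results.score(image)
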