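"""Pipeline configuration, seed fan-out and the end-to-end runner.

A :class:`RunConfig` captures everything one run needs: the global seed,
image side, translation mode and the per-stage hyperparameters.  One
master seed fans out to stage seeds via fixed offsets so each stage is
independently reproducible:

    fixtures +0, augment +1, VAE +2, GAN +3, generation +4, evaluation +5.

``run_pipeline`` executes the requested stages in order (fixtures →
preprocess → augment → train-vae → train-pix2pix → generate → evaluate)
and writes a JSON manifest of artifacts, seeds and the config hash.
Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError, StateError
from .evaluate import AeConfig, AnomalyAutoencoder, roc_auc
from .fixtures import LeafSpec, make_dataset, save_sample
from .generate import generate_batch
from .images import SkeletonImage
from .pix2pix import GanConfig, Pix2Pix, Pix2PixResults, TranslationPair
from .preprocess import augment, preprocess_sample
from .resvae import ResidualVAE, ResidualVAEResults, VaeConfig

log = logging.getLogger("l2l")

ALL_STAGES = ("fixtures", "preprocess", "augment", "train-vae",
              "train-pix2pix", "generate", "evaluate")

_SEED_OFFSET = {"fixtures": 0, "augment": 1, "train-vae": 2,
                "train-pix2pix": 3, "generate": 4, "evaluate": 5}


@dataclass
class RunConfig:
    seed: int = 0
    image_side: int = 64
    mode: str = "rgb"                    # "rgb" | "rgnir"
    out_dir: str = "l2l_run"
    stages: tuple[str, ...] = ALL_STAGES
    n_fixtures: int = 64
    n_generate: int = 10
    latent_dim: int = 32
    beta: float = 1.0
    lambda_l1: float = 100.0
    base_channels: int = 8
    epochs_vae: int = 30
    epochs_gan: int = 30
    epochs_ae: int = 30
    refine: bool = True

    def __post_init__(self):
        side = self.image_side
        if side < 64 or side & (side - 1):
            raise ParameterError("config.image_side must be a power of two >= 64")
        if self.mode not in ("rgb", "rgnir"):
            raise ParameterError("config.mode must be 'rgb' or 'rgnir'")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"config.stages contains unknown stages {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        return self.seed + _SEED_OFFSET[stage]

    @property
    def bands(self) -> tuple[str, ...]:
        return ("R", "G", "B") if self.mode == "rgb" else ("R", "G", "NIR")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return (and write) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seeds": {s: config.stage_seed(s) for s in _SEED_OFFSET},
        "stages": {},
    }
    side = config.image_side
    vae_ckpt = out / "vae.npz"
    gan_ckpt = out / "gan.npz"

    samples = pre = None
    if "fixtures" in config.stages:
        log.info("stage fixtures: n=%d side=%d", config.n_fixtures, side)
        samples = make_dataset(config.n_fixtures, LeafSpec(side=side),
                               seed=config.stage_seed("fixtures"))
        fx_dir = out / "fixtures"
        for i, s in enumerate(samples[:4]):     # keep a browsable sample on disk
            save_sample(s, fx_dir, i)
        manifest["stages"]["fixtures"] = {"n": len(samples), "dir": str(fx_dir)}

    if "preprocess" in config.stages:
        if samples is None:
            raise StateError("preprocess requires the fixtures stage")
        log.info("stage preprocess: %d samples", len(samples))
        pre = [preprocess_sample(s.image, s.probes, side=side) for s in samples]
        manifest["stages"]["preprocess"] = {"n": len(pre), "side": side}

    augmented = pre
    if "augment" in config.stages:
        if pre is None:
            raise StateError("augment requires the preprocess stage")
        augmented = augment(pre, seed=config.stage_seed("augment"))
        manifest["stages"]["augment"] = {"n_in": len(pre), "n_out": len(augmented)}

    vae_res: ResidualVAEResults | None = None
    if "train-vae" in config.stages:
        if augmented is None:
            raise StateError("train-vae requires preprocessed samples")
        cfg = VaeConfig(latent_dim=config.latent_dim, image_side=side,
                        beta=config.beta, base_channels=config.base_channels,
                        epochs=config.epochs_vae, seed=config.stage_seed("train-vae"))
        log.info("stage train-vae: %d skeletons, %d epochs", len(augmented), cfg.epochs)
        vae_res = ResidualVAE([p.skeleton for p in augmented], cfg).fit()
        vae_res.save(vae_ckpt)
        manifest["stages"]["train-vae"] = {
            "checkpoint": str(vae_ckpt),
            "loss_first": vae_res.history[0].total if vae_res.history else None,
            "loss_final": vae_res.history[-1].total if vae_res.history else None,
        }

    gan_res: Pix2PixResults | None = None
    if "train-pix2pix" in config.stages:
        if augmented is None:
            raise StateError("train-pix2pix requires preprocessed samples")
        pairs = [TranslationPair(p.skeleton, p.image.select(config.bands))
                 for p in augmented]
        cfg = GanConfig(lambda_l1=config.lambda_l1, image_side=side,
                        base_channels=config.base_channels, mode=config.mode,
                        epochs=config.epochs_gan, seed=config.stage_seed("train-pix2pix"))
        log.info("stage train-pix2pix: %d pairs, %d epochs", len(pairs), cfg.epochs)
        gan_res = Pix2Pix(pairs, cfg).fit()
        gan_res.save(gan_ckpt)
        manifest["stages"]["train-pix2pix"] = {
            "checkpoint": str(gan_ckpt),
            "g_l1_first": gan_res.history[0].g_l1 if gan_res.history else None,
            "g_l1_final": gan_res.history[-1].g_l1 if gan_res.history else None,
        }

    leaves = None
    if "generate" in config.stages:
        if vae_res is None:
            if not vae_ckpt.exists():
                raise StateError(f"generate requires a VAE checkpoint: {vae_ckpt}")
            vae_res = ResidualVAEResults.load(vae_ckpt)
        if gan_res is None:
            if not gan_ckpt.exists():
                raise StateError(f"generate requires a GAN checkpoint: {gan_ckpt}")
            gan_res = Pix2PixResults.load(gan_ckpt)
        log.info("stage generate: n=%d", config.n_generate)
        leaves = generate_batch(config.n_generate, config.stage_seed("generate"),
                                vae_res, gan_res, refine=config.refine)
        gen_dir = out / "generated"
        gen_dir.mkdir(exist_ok=True)
        import imageio.v3 as iio
        latents = []
        for i, leaf in enumerate(leaves):
            rgbish = np.clip(leaf.image.channels, 0, 1)
            iio.imwrite(gen_dir / f"{i:04d}_leaf.png",
                        np.round(rgbish * 255).astype(np.uint8).transpose(1, 2, 0))
            iio.imwrite(gen_dir / f"{i:04d}_skeleton.png",
                        leaf.skeleton.mask.astype(np.uint8) * 255)
            latents.append(leaf.latent.tolist())
        (gen_dir / "latents.json").write_text(json.dumps(
            {"seed": config.stage_seed("generate"), "latents": latents}))
        manifest["stages"]["generate"] = {
            "n": len(leaves), "dir": str(gen_dir),
            "n_empty_skeletons": int(sum(not l.skeleton.mask.any() for l in leaves)),
        }

    if "evaluate" in config.stages:
        if pre is None or leaves is None:
            raise StateError("evaluate requires the preprocess and generate stages")
        cfg = AeConfig(image_side=side, channels=len(config.bands),
                       base_channels=config.base_channels, epochs=config.epochs_ae,
                       seed=config.stage_seed("evaluate"))
        real = [p.image.select(config.bands) for p in pre]
        log.info("stage evaluate: AE on %d real images", len(real))
        ae = AnomalyAutoencoder(real, cfg).fit()
        scores_real = ae.score_many(real)
        scores_fake = ae.score_many([l.image for l in leaves])
        roc = roc_auc(scores_real, scores_fake)
        report = {
            "auc": roc.auc,
            "mean_score_real": float(np.mean(scores_real)),
            "mean_score_fake": float(np.mean(scores_fake)),
        }
        (out / "evaluation.json").write_text(json.dumps(report, indent=2))
        np.savetxt(out / "roc_points.csv", np.asarray(roc.points),
                   delimiter=",", header="fpr,tpr", comments="")
        manifest["stages"]["evaluate"] = report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
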