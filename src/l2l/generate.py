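"""End-to-end leaf generation: random latent → skeleton → colorized leaf.

The workflow chains the two trained models: draw a latent vector from
the prior (standard normal by default, or a diagonal Gaussian fitted to
the training posterior means), decode it into a binary skeleton with the
VAE decoder, optionally refine away off-blade artifacts, and translate
the skeleton into an RGB / R-G-NIR leaf with the Pix2pix generator.

Refinement is procedural: the leaf is the largest 8-connected foreground
component; any component lying wholly outside that component's filled
outer contour is deleted, while pixels and background holes enclosed by
the contour are left bit-identical (holes are natural — overlapping
lobes, herbivory, disease — and must survive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError, StateError
from .images import LeafImage, SkeletonImage
from .pix2pix import Pix2PixResults
from .resvae import ResidualVAEResults


@dataclass
class SyntheticLeaf:
    skeleton: SkeletonImage
    image: LeafImage
    latent: np.ndarray
    refined: bool

    def __post_init__(self):
        if self.skeleton.shape != self.image.shape:
            raise ParameterError("skeleton and image must share spatial size")


def sample_skeleton(vae: ResidualVAEResults, rng: np.random.Generator | int = 0,
                    empirical: bool = False) -> SkeletonImage:
    """Draw one latent from the prior and decode + binarize it."""
    if not isinstance(vae, ResidualVAEResults):
        raise StateError("sample_skeleton requires fitted ResidualVAEResults")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return vae.sample_skeletons(1, rng, empirical=empirical)[0]


def translate(skeleton: SkeletonImage, gan: Pix2PixResults,
              mode: str | None = None) -> LeafImage:
    """Colorize a skeleton with the trained translator."""
    if not isinstance(gan, Pix2PixResults):
        raise StateError("translate requires fitted Pix2PixResults")
    if mode is not None and mode != gan.config.mode:
        raise StateError(
            f"requested mode {mode!r} but translator was trained for {gan.config.mode!r}")
    return gan.translate(skeleton)


def refine_skeleton(binary: SkeletonImage | np.ndarray) -> SkeletonImage:
    """Remove foreground components lying outside the leaf's outer contour.

    The leaf is the largest 8-connected component by area.  Its outer
    contour is filled; every other component intersecting the filled
    region (i.e. inside the contour, including inside holes) is kept
    untouched, the rest are deleted.  Idempotent; never adds pixels.
    """
    mask = binary.mask if isinstance(binary, SkeletonImage) else np.asarray(binary).astype(bool)
    if not mask.any():
        raise DegenerateInputError("empty foreground")
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 1:
        return SkeletonImage(mask.copy())
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    main = 1 + int(np.argmax(sizes))
    filled = ndimage.binary_fill_holes(lab == main)
    keep = np.zeros(n + 1, dtype=bool)
    keep[main] = True
    for comp in range(1, n + 1):
        if comp != main and filled[lab == comp].any():
            keep[comp] = True
    return SkeletonImage(np.where(keep[lab], mask, False))


def generate_batch(n: int, seed: int, vae: ResidualVAEResults, gan: Pix2PixResults,
                   mode: str | None = None, refine: bool = True,
                   empirical: bool = False) -> list[SyntheticLeaf]:
    """Generate ``n`` synthetic leaves; fully reproducible under ``seed``.

    Degenerate latents can decode to an empty skeleton; those samples are
    carried through with an all-background image rather than crashing.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if mode is not None and mode != gan.config.mode:
        raise StateError(
            f"requested mode {mode!r} but translator was trained for {gan.config.mode!r}")
    rng = np.random.default_rng(seed)
    out: list[SyntheticLeaf] = []
    for _ in range(n):
        z = rng.standard_normal(vae.config.latent_dim)
        if empirical:
            z = vae.latent_mean + vae.latent_std * z
        sk = SkeletonImage(vae.decode(z) > vae.config.binarize_threshold)
        if refine and sk.mask.any():
            sk = refine_skeleton(sk)
        img = gan.translate(sk)
        out.append(SyntheticLeaf(sk, img, z, refine))
    return out
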