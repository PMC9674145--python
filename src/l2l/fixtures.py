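"""Procedural leaf-like fixtures with known ground truth.

Real acquisitions image single leaves on a dark background with three
in-frame reflectance probes; the companion skeleton is the blade contour
plus the vein tree.  This module emulates that statistical structure so
the whole pipeline is testable offline: a lobed star-convex blade
silhouette (sum-of-cosines polar radius), a recursively branching vein
tree clipped inside the blade, a smooth multiplicative colour field over
the blade, bright flat NIR, corner probes at reflectances 0.02 / 0.50 /
0.99, and optional injected hot pixels.

All randomness flows through one ``numpy`` generator seeded per sample;
``make_dataset`` derives per-sample seeds as ``master_seed + index``.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .errors import ParameterError
from .images import RGBNIR, LeafImage, Probe, SkeletonImage

PROBE_REFLECTANCES = (0.02, 0.50, 0.99)


@dataclass(frozen=True)
class LeafSpec:
    """Parameters of one procedural leaf."""

    side: int = 128
    n_lobes: int = 5
    blade_radius_px: float | None = None   # default 0.38 * side
    vein_depth: int = 3
    vein_angle_jitter: float = 0.15        # radians
    hue_base: float = 0.33                 # green
    hue_noise_sd: float = 0.08
    background_level: float = 0.03
    seed: int = 0

    @property
    def radius(self) -> float:
        return 0.38 * self.side if self.blade_radius_px is None else self.blade_radius_px


@dataclass
class FixtureSample:
    image: LeafImage               # bands R, G, B, NIR
    skeleton: SkeletonImage        # boundary + veins
    blade_mask: np.ndarray         # (H, W) bool silhouette
    probes: list[Probe]
    spec: LeafSpec


def _blade_silhouette(spec: LeafSpec, rng: np.random.Generator) -> np.ndarray:
    """Star-convex lobed silhouette: r(θ) = R(1 + a·cos(nθ + φ) + jitter harmonics)."""
    s = spec.side
    yy, xx = np.mgrid[0:s, 0:s]
    cy = cx = (s - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    phase = rng.uniform(0, 2 * np.pi)
    r_mod = 1.0 + 0.15 * np.cos(spec.n_lobes * theta + phase)
    # two low-order harmonics give per-leaf asymmetry without pinching
    for h in (2, 3):
        r_mod += 0.04 * rng.uniform(-1, 1) * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    mask = np.hypot(dy, dx) <= spec.radius * r_mod
    # radial-monotone test yields a hole-free region; keep the largest
    # 4-connected component to make the single-component invariant robust
    lab, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _vein_tree(spec: LeafSpec, blade: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Recursive midrib-plus-branches, 1–2 px strokes, clipped to the blade interior."""
    s = spec.side
    veins = np.zeros((s, s), dtype=bool)
    interior = ndimage.binary_erosion(blade, structure=np.ones((3, 3)), iterations=2)
    cy = cx = (s - 1) / 2.0

    def draw_segment(p0, p1, width):
        rr, cc = draw_line(int(round(p0[0])), int(round(p0[1])),
                           int(round(p1[0])), int(round(p1[1])))
        ok = (rr >= 0) & (rr < s) & (cc >= 0) & (cc < s)
        rr, cc = rr[ok], cc[ok]
        keep = interior[rr, cc]
        veins[rr[keep], cc[keep]] = True
        if width > 1:
            cc2 = np.clip(cc + 1, 0, s - 1)
            keep2 = interior[rr, cc2]
            veins[rr[keep2], cc2[keep2]] = True

    def branch(p0, angle, length, depth, width):
        p1 = (p0[0] - length * np.sin(angle), p0[1] + length * np.cos(angle))
        draw_segment(p0, p1, width)
        if depth <= 0:
            return
        for t, sign in ((0.35, 1), (0.35, -1), (0.7, 1), (0.7, -1)):
            q = (p0[0] + t * (p1[0] - p0[0]), p0[1] + t * (p1[1] - p0[1]))
            da = sign * (0.7 + rng.uniform(-1, 1) * spec.vein_angle_jitter)
            branch(q, angle + da, 0.45 * length, depth - 1, 1)

    if spec.vein_depth > 0:
        base = (cy + spec.radius * 0.85, cx)
        branch(base, np.pi / 2, spec.radius * 1.7, spec.vein_depth - 1, 2)
    return veins


def _boundary(blade: np.ndarray) -> np.ndarray:
    """Inner boundary: blade pixels with a background pixel in their 8-neighbourhood."""
    return blade & ~ndimage.binary_erosion(blade, structure=np.ones((3, 3)))


def _probe_layout(side: int) -> list[Probe]:
    sz = max(6, side // 12)
    m = 2
    corners = [(m, m), (m, side - m - sz), (side - m - sz, m)]
    return [Probe(r, c, r + sz, c + sz, refl)
            for (r, c), refl in zip(corners, PROBE_REFLECTANCES)]


def make_leaf(spec: LeafSpec) -> FixtureSample:
    """Generate one leaf sample; identical spec (including seed) → identical output."""
    if spec.side < 64:
        raise ParameterError(f"image side must be >= 64, got {spec.side}")
    if not 1 <= spec.n_lobes <= 9:
        raise ParameterError(f"n_lobes must be in [1, 9], got {spec.n_lobes}")
    rng = np.random.default_rng(spec.seed)
    s = spec.side
    blade = _blade_silhouette(spec, rng)
    veins = _vein_tree(spec, blade, rng)
    boundary = _boundary(blade)
    skeleton = SkeletonImage(boundary | veins)

    # smooth multiplicative brightness field over the blade
    field = ndimage.gaussian_filter(rng.standard_normal((s, s)), sigma=s / 8.0)
    sd = field.std()
    field = 1.0 + spec.hue_noise_sd * (field / sd if sd > 0 else field)

    base_rgb = colorsys.hsv_to_rgb(spec.hue_base, 0.7, 0.55)
    chans = np.full((4, s, s), spec.background_level, dtype=np.float64)
    for ci, base in enumerate(base_rgb):
        chans[ci][blade] = np.clip(max(base, 0.12) * field[blade], 0.10, 0.97)
    # NIR: bright and flat over the tissue, veins markedly darker
    nir_field = 0.78 * (0.5 + 0.5 * field)
    chans[3][blade] = np.clip(nir_field[blade], 0.45, 0.97)
    chans[3][veins] *= 0.55
    chans[0][veins] = np.clip(chans[0][veins] * 1.3, 0, 0.97)

    probes = _probe_layout(s)
    for p in probes:
        chans[:, p.row0:p.row1, p.col0:p.col1] = p.reflectance

    return FixtureSample(LeafImage(chans, RGBNIR), skeleton, blade, probes, spec)


def make_dataset(n: int, base_spec: LeafSpec = LeafSpec(), seed: int = 0) -> list[FixtureSample]:
    """n samples with per-sample seed = seed + index (deterministic split)."""
    if n < 1:
        raise ParameterError(f"dataset size must be >= 1, got {n}")
    return [make_leaf(replace(base_spec, seed=seed + i)) for i in range(n)]


def inject_hot_pixels(image: LeafImage, k: int, seed: int = 0,
                      fraction: float = 0.10) -> tuple[LeafImage, list[tuple[int, int]]]:
    """Raise k isolated pixels (every channel) above all 8 neighbours by more
    than ``fraction`` of the intensity midrange, mimicking sensor hot pixels.

    Returns the corrupted image and the injected (row, col) coordinates.
    """
    h, w = image.shape
    if k < 0 or k >= 0.01 * h * w:
        raise ParameterError(f"k must satisfy 0 <= k < 1% of pixels, got {k}")
    chans = image.channels.copy()
    if k == 0:
        return LeafImage(chans, image.bands), []
    rng = np.random.default_rng(seed)
    coords: list[tuple[int, int]] = []
    taken = np.zeros((h, w), dtype=bool)
    tries = 0
    while len(coords) < k:
        tries += 1
        if tries > 10000:
            raise ParameterError("could not place hot pixels away from bright regions")
        r = int(rng.integers(2, h - 2))
        c = int(rng.integers(2, w - 2))
        if taken[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3].any():
            continue
        nb = chans[:, r - 1:r + 2, c - 1:c + 2]
        nb_max = max(np.delete(nb[ci].reshape(-1), 4).max()
                     for ci in range(chans.shape[0]))
        if nb_max >= 0.90:        # needs clear headroom over every neighbour
            continue
        ok = True
        for ci in range(chans.shape[0]):
            ch = chans[ci]
            neigh = np.delete(ch[r - 1:r + 2, c - 1:c + 2].reshape(-1), 4)
            v = 1.0
            crit = fraction * (min(ch.min(), v) + max(ch.max(), v)) / 2.0
            if not np.all(v - neigh > crit):
                ok = False
                break
        if not ok:
            continue
        chans[:, r, c] = 1.0
        taken[r, c] = True
        coords.append((r, c))
    return LeafImage(chans, image.bands), coords


# ---------------------------------------------------------------------------
# on-disk fixture datasets

def save_sample(sample: FixtureSample, out_dir: Path, index: int) -> None:
    """Write 8-bit PNGs (RGB + skeleton), a 16-bit RGNIR TIFF and a sidecar JSON."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{index:04d}"
    rgb = np.clip(sample.image.select(("R", "G", "B")).channels, 0, 1)
    iio.imwrite(out_dir / f"{stem}_rgb.png",
                (np.round(rgb * 255)).astype(np.uint8).transpose(1, 2, 0))
    iio.imwrite(out_dir / f"{stem}_skeleton.png",
                (sample.skeleton.mask * np.uint8(255)))
    rgnir = np.clip(sample.image.select(("R", "G", "NIR")).channels, 0, 1)
    tifffile.imwrite(out_dir / f"{stem}_rgnir.tiff",
                     (np.round(rgnir * 65535)).astype(np.uint16))
    meta = {
        "spec": asdict(sample.spec),
        "probes": [p.as_dict() for p in sample.probes],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))


def write_dataset(n: int, out_dir: Path, base_spec: LeafSpec = LeafSpec(),
                  seed: int = 0) -> list[Path]:
    samples = make_dataset(n, base_spec, seed)
    for i, s in enumerate(samples):
        save_sample(s, out_dir, i)
    return sorted(Path(out_dir).glob("*_rgb.png"))
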