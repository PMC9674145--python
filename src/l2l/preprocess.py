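"""Preprocessing of raw multichannel leaf images.

The chain mirrors the acquisition protocol for single leaves imaged on a
dark background with in-frame reflectance probes:

1. hot-pixel removal — an interior pixel whose excess over *all* eight
   neighbours exceeds 10% of the image midrange ``(min+max)/2`` is
   replaced by the neighbour mean (single pass, decisions on the input);
2. per-channel normalization against the 2% / 99% reflectance probes:
   ``p <- (p - m) / (M - m)`` clipped to [0, 1];
3. companion-skeleton creation from the NIR channel: Otsu binarization,
   Moore-Neighbor tracing of the outer leaf boundary, and vein detection
   inside the blade (adaptive local threshold + morphological thinning);
4. automatic square crop centred on the blade and resize to 256×256.

Augmentation triples a dataset by adding two randomly flipped / rotated
(±π/4) / zoomed (±20%) variants per sample, with the identical geometric
transform applied to image and skeleton.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform
from skimage.morphology import thin as skthin

from .errors import CalibrationError, DegenerateInputError, ParameterError
from .images import LeafImage, Probe, SkeletonImage

# 8-neighbour offsets in clockwise order starting west (rows grow downward)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


@dataclass(frozen=True)
class ProbeCalibration:
    """m: minimum inside the 2% probe; M: maximum inside the 99% probe."""

    m: float
    M: float

    def __post_init__(self):
        if not self.M > self.m:
            raise CalibrationError(f"M ({self.M}) must exceed m ({self.m})")

    @classmethod
    def from_probes(cls, channel: np.ndarray, probes: list[Probe]) -> "ProbeCalibration":
        low = min(probes, key=lambda p: p.reflectance)
        high = max(probes, key=lambda p: p.reflectance)
        return cls(m=float(low.region(channel).min()),
                   M=float(high.region(channel).max()))


@dataclass
class PreprocessedSample:
    image: LeafImage
    skeleton: SkeletonImage


def remove_hot_pixels(image: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Replace isolated hot pixels by their 8-neighbour mean.

    A pixel is hot when its value exceeds every one of its 8 neighbours
    by more than ``fraction`` of the image midrange (min+max)/2.  Border
    pixels lack a full neighbourhood and are left untouched.  One pass;
    all decisions use the input image.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ParameterError("image must be 2-D and at least 3x3")
    crit = fraction * (img.min() + img.max()) / 2.0
    core = img[1:-1, 1:-1]
    shifted = np.stack([img[1 + dr:img.shape[0] - 1 + dr, 1 + dc:img.shape[1] - 1 + dc]
                        for dr, dc in _MOORE])
    hot = np.all(core - shifted > crit, axis=0)
    out = img.copy()
    out[1:-1, 1:-1] = np.where(hot, shifted.mean(axis=0), core)
    return out


def normalize_channel(channel: np.ndarray, cal: ProbeCalibration) -> np.ndarray:
    """Affine probe normalization, clipped to [0, 1]."""
    return np.clip((np.asarray(channel, dtype=np.float64) - cal.m) / (cal.M - cal.m),
                   0.0, 1.0)


def otsu_threshold(channel: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold minimizing intraclass variance (Otsu).

    Candidate thresholds are the interior bin edges; binarization is
    ``channel > t``.  Ties resolve to the lowest threshold.
    """
    x = np.asarray(channel, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise DegenerateInputError("constant image has no threshold")
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    sums, _ = np.histogram(x, bins=n_bins, range=(lo, hi), weights=x)
    w = counts.astype(np.float64)
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(sums)              # exact per-class sums, not bin centers
    total_w, total_m = cum_w[-1], cum_m[-1]
    # split after bin k: class0 = bins [0..k], class1 = bins [k+1..]
    w0 = cum_w[:-1]
    w1 = total_w - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(w0 > 0, cum_m[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (total_m - cum_m[:-1]) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(between))          # argmax takes the first (lowest) tie
    return float(edges[k + 1])


def _largest_component(binary: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(binary, structure=np.ones((3, 3)))
    if n == 0:
        raise DegenerateInputError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def trace_boundary(binary: np.ndarray) -> list[tuple[int, int]]:
    """Moore-Neighbor tracing of the outer boundary of the largest component.

    Returns the closed, ordered boundary path (without repeating the
    start).  Termination follows Jacob's criterion: stop when the start
    pixel is re-entered from its original backtrack direction.
    """
    fg = np.asarray(binary).astype(bool)
    if not fg.any():
        raise DegenerateInputError("empty foreground")
    fg = _largest_component(fg)
    h, w = fg.shape

    def is_fg(r, c):
        return 0 <= r < h and 0 <= c < w and fg[r, c]

    start = tuple(int(v) for v in np.argwhere(fg)[0])   # raster order: top-most, then left-most
    # entered scanning left-to-right, so the initial backtrack is the west neighbour
    cur, back = start, (start[0], start[1] - 1)
    seen: dict[tuple, int] = {}
    states: list[tuple] = []
    while (cur, back) not in seen:
        seen[(cur, back)] = len(states)
        states.append((cur, back))
        # scan Moore neighbours clockwise starting just after the backtrack
        start_idx = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for i in range(1, 9):
            dr, dc = _MOORE[(start_idx + i) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if is_fg(*cand):
                nxt = cand
                prev_dr, prev_dc = _MOORE[(start_idx + i - 1) % 8]
                back = (cur[0] + prev_dr, cur[1] + prev_dc)
                break
        if nxt is None:                   # isolated pixel
            return [start]
        cur = nxt
    # the walk is deterministic, so it closes on the first repeated
    # (pixel, backtrack) state; the boundary is that cycle (when it closes
    # on the initial state this is exactly Jacob's stopping criterion)
    first = seen[(cur, back)]
    cycle = states[first:]
    # rotate so the path starts at the start pixel when it lies on the cycle
    for k, (p, _) in enumerate(cycle):
        if p == start:
            cycle = cycle[k:] + cycle[:k]
            break
    return [p for p, _ in cycle]


def blade_mask_from_nir(nir: np.ndarray) -> np.ndarray:
    """Blade silhouette: Otsu foreground, largest component, holes filled."""
    t = otsu_threshold(nir)
    fg = np.asarray(nir) > t
    if not fg.any():
        raise DegenerateInputError("no foreground after Otsu thresholding")
    return ndimage.binary_fill_holes(_largest_component(fg))


def detect_veins(nir: np.ndarray, blade: np.ndarray,
                 window: int | None = None, offset: float = 0.05) -> np.ndarray:
    """Veins inside the blade: locally dark NIR ridges, thinned to <=2 px.

    The local reference is a boxcar mean over ``window`` (default side//8,
    odd); a pixel is a vein candidate when it is darker than the local
    mean by ``offset``.  Candidates are restricted to the eroded blade and
    morphologically thinned.
    """
    nir = np.asarray(nir, dtype=np.float64)
    if window is None:
        window = max(9, (nir.shape[0] // 8) | 1)
    interior = ndimage.binary_erosion(blade, structure=np.ones((3, 3)), iterations=2)
    # masked boxcar mean so the dark background does not bias the blade edge
    blade_f = blade.astype(np.float64)
    num = ndimage.uniform_filter(nir * blade_f, size=window, mode="nearest")
    den = ndimage.uniform_filter(blade_f, size=window, mode="nearest")
    local_mean = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    cand = interior & (nir < local_mean - offset)
    return skthin(cand)


def extract_skeleton(nir: np.ndarray) -> SkeletonImage:
    """Companion skeleton from the normalized NIR channel: traced outer
    boundary of the blade plus detected veins."""
    blade = blade_mask_from_nir(nir)
    path = trace_boundary(blade)
    sk = np.zeros(blade.shape, dtype=bool)
    rows, cols = zip(*path)
    sk[list(rows), list(cols)] = True
    sk |= detect_veins(nir, blade)
    return SkeletonImage(sk)


def crop_and_resize(image: LeafImage, skeleton: SkeletonImage, side: int = 256,
                    blade_mask: np.ndarray | None = None) -> PreprocessedSample:
    """Square crop centred on the blade, resized to ``side``×``side``.

    The crop is centred on the blade centroid with a 10% margin around
    the blade bounding box (padded where the window leaves the frame).
    Intensity channels are resized bilinearly; the skeleton with nearest
    interpolation and re-binarized at 0.5.
    """
    if blade_mask is None:
        band = "NIR" if "NIR" in image.bands else image.bands[-1]
        blade_mask = blade_mask_from_nir(image.channel(band))
    blade_mask = np.asarray(blade_mask).astype(bool)
    if not blade_mask.any():
        raise DegenerateInputError("empty blade mask")
    rows, cols = np.nonzero(blade_mask)
    cy, cx = rows.mean(), cols.mean()
    extent = max(rows.max() - rows.min(), cols.max() - cols.min()) + 1
    half = 0.55 * extent
    # one subpixel affine warp: output pixel (r, c) samples the source at
    # centroid + (r − (side−1)/2) · k, keeping the blade centroid at the
    # crop centre without integer-window rounding
    k = 2.0 * half / side
    tf = sktransform.AffineTransform(
        scale=k, translation=(cx - k * (side - 1) / 2, cy - k * (side - 1) / 2))
    chans = np.stack([
        sktransform.warp(c, tf, output_shape=(side, side), order=1, cval=0.0,
                         preserve_range=True)
        for c in image.channels
    ])
    sk = sktransform.warp(skeleton.as_float(), tf, output_shape=(side, side),
                          order=0, cval=0.0, preserve_range=True)
    return PreprocessedSample(LeafImage(np.clip(chans, 0, 1), image.bands),
                              SkeletonImage(sk > 0.5))


def _random_transform(rng: np.random.Generator, shape: tuple[int, int]):
    hflip = bool(rng.integers(0, 2))
    vflip = bool(rng.integers(0, 2))
    angle = rng.uniform(-np.pi / 4, np.pi / 4)
    zoom = 1.0 + rng.uniform(-0.20, 0.20)
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (sktransform.AffineTransform(translation=-center)
          + sktransform.AffineTransform(scale=(-1 if hflip else 1, -1 if vflip else 1))
          + sktransform.AffineTransform(rotation=angle, scale=zoom)
          + sktransform.AffineTransform(translation=center))
    return tf


def augment(samples: list[PreprocessedSample], seed: int = 0) -> list[PreprocessedSample]:
    """Originals plus two random geometric variants each (3x expansion).

    Each variant draws an independent horizontal/vertical flip, a
    rotation uniform in [-π/4, π/4] and a zoom uniform in ±20%; image and
    skeleton share the transform (bilinear vs nearest interpolation).
    """
    if not samples:
        raise ParameterError("augment requires a non-empty sample list")
    rng = np.random.default_rng(seed)
    out: list[PreprocessedSample] = list(samples)
    for s in samples:
        for _ in range(2):
            tf = _random_transform(rng, s.skeleton.shape)
            chans = np.stack([
                sktransform.warp(c, tf.inverse, order=1, cval=0.0, preserve_range=True)
                for c in s.image.channels
            ])
            sk = sktransform.warp(s.skeleton.as_float(), tf.inverse, order=0,
                                  cval=0.0, preserve_range=True)
            out.append(PreprocessedSample(LeafImage(np.clip(chans, 0, 1), s.image.bands),
                                          SkeletonImage(sk > 0.5)))
    return out


def preprocess_sample(image: LeafImage, probes: list[Probe], side: int = 256) -> PreprocessedSample:
    """Full chain: hot-pixel removal → probe normalization → skeleton →
    crop/resize.  Expects an image containing an NIR band."""
    cleaned = []
    for c in image.channels:
        ch = remove_hot_pixels(c)
        cal = ProbeCalibration.from_probes(ch, probes)
        cleaned.append(normalize_channel(ch, cal))
    norm = LeafImage(np.stack(cleaned), image.bands)
    skeleton = extract_skeleton(norm.channel("NIR"))
    blade = blade_mask_from_nir(norm.channel("NIR"))
    return crop_and_resize(norm, skeleton, side=side, blade_mask=blade)
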