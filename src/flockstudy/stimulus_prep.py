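"""Stimulus preparation for two-alternative medical-image discrimination studies.

The experiments this package models present square histology or mammogram
patches to trained observers.  Before a study, stimulus sets are expanded by
rigid rotations and flips, resized to the display resolution, optionally
repainted to a single hue so that no class-specific colour information
survives, equalized in brightness/contrast between the two classes, degraded
by JPEG compression to a target byte-size ratio, and partitioned into
difficulty-balanced training/testing sets.  Every operation here is
deterministic (or seeded) so that a full stimulus set can be rebuilt
bit-for-bit from a manifest.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "LABELS",
    "MAGNIFICATIONS",
    "ORIENTATIONS",
    "StimulusImage",
    "MonochromeSpec",
    "CompressionSpec",
    "CompressionResult",
    "DifficultyItem",
    "Partition",
    "orient_pixels",
    "augment_orientations",
    "resize_to_display",
    "to_monochrome_hue",
    "equalize_sets",
    "compress_to_ratio",
    "decode_compressed",
    "jpeg_sizes",
    "partition_by_difficulty",
]

LABELS = ("positive", "negative")
MAGNIFICATIONS = ("4x", "10x", "20x", "n/a")
ORIENTATIONS = ("r0", "r90", "r180", "r270", "hflip", "vflip")

#: Rec. 601 luma weights used for every grayscale reduction in the package.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

# Smallest value channel (out of 255) assigned to a non-black pixel by the
# hue-normalization step.  8-bit RGB cannot express an arbitrary hue at very
# low chroma; flooring the value channel keeps the repainted hue within one
# degree of the target for every saturated pixel.
_HUE_VALUE_FLOOR = 30


@dataclass
class StimulusImage:
    """A single stimulus: an 8-bit RGB pixel grid plus study metadata.

    ``label`` follows the convention positive = malignant (histology) or
    calcification-present (mammograms).  ``orientation`` is ``r0`` for the
    unmodified source view; the rotation tags use a clockwise convention with
    the origin at the top-left of the grid.  ``compression_ratio`` is the
    encoded-byte fraction relative to the lossless reference (1.0 = never
    passed through a lossy codec).
    """

    id: str
    pixels: np.ndarray
    label: str
    magnification: str = "n/a"
    orientation: str = "r0"
    compression_ratio: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"unknown magnification {self.magnification!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if not (0.0 < self.compression_ratio <= 1.0):
            raise ValueError("compression_ratio must be in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def luminance(self) -> np.ndarray:
        """Per-pixel luminance on a 0-1 scale."""
        return (self.pixels.astype(float) @ LUMA_WEIGHTS) / 255.0


@dataclass(frozen=True)
class MonochromeSpec:
    """Settings for the single-hue repaint of a grayscale-reduced stimulus."""

    target_hue: float = 290.0
    equalize_brightness: bool = True
    equalize_contrast: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_hue < 360.0):
            raise ValueError("target_hue must lie in [0, 360)")


@dataclass(frozen=True)
class CompressionSpec:
    """Target byte-size fraction for lossy re-encoding.

    ``target_ratio`` is measured against the losslessly encoded reference
    (PNG), e.g. 0.07 for 15:1 and 0.04 for 27:1 compression.  ``tolerance``
    is the allowed relative deviation of the achieved ratio.
    """

    target_ratio: float
    tolerance: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.target_ratio <= 1.0):
            raise ValueError("target_ratio must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


class CompressionResult(NamedTuple):
    data: bytes
    achieved_ratio: float
    quality: int | None
    format: str


@dataclass(frozen=True)
class DifficultyItem:
    """Per-stimulus difficulty used to balance set splits.

    ``difficulty`` is the mean accuracy of an expert human panel on the
    stimulus (0 = everyone wrong, 1 = everyone right), so *larger* means
    *easier*.
    """

    stimulus_id: str
    label: str
    difficulty: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if not (0.0 <= self.difficulty <= 1.0):
            raise ValueError("difficulty must be in [0, 1]")


class Partition(NamedTuple):
    set_a: list[DifficultyItem]
    set_b: list[DifficultyItem]
    gap: float


# ---------------------------------------------------------------------------
# Orientation augmentation
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "r0": lambda a: a,
    "r90": lambda a: np.rot90(a, k=-1),  # clockwise
    "r180": lambda a: np.rot90(a, k=2),
    "r270": lambda a: np.rot90(a, k=1),
    "hflip": lambda a: a[:, ::-1],
    "vflip": lambda a: a[::-1, :],
}


def orient_pixels(pixels: np.ndarray, orientation: str) -> np.ndarray:
    """Apply one of the six rigid views to a pixel grid (returns a copy)."""
    if orientation not in _TRANSFORMS:
        raise ValueError(f"unknown orientation {orientation!r}")
    return np.ascontiguousarray(_TRANSFORMS[orientation](pixels))


def augment_orientations(image: StimulusImage) -> list[StimulusImage]:
    """Expand a source stimulus into its six rigid views.

    Returns the unmodified view plus the 90/180/270-degree rotations and the
    horizontal and vertical flips, in the fixed order of ``ORIENTATIONS``.
    Derived ids are ``"<source id>__<orientation>"`` except the source view,
    which keeps its id.
    """
    if image.orientation != "r0":
        raise ValueError("orientation augmentation starts from the r0 view")
    h, w = image.shape
    if h != w:
        raise ValueError(f"image must be square to rotate in place, got {h}x{w}")
    out = []
    for o in ORIENTATIONS:
        oid = image.id if o == "r0" else f"{image.id}__{o}"
        out.append(replace(image, id=oid, pixels=orient_pixels(image.pixels, o), orientation=o))
    return out


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------


def resize_to_display(image: StimulusImage, side: int = 308) -> StimulusImage:
    """Resize a stimulus to ``side x side`` pixels (bilinear interpolation).

    A stimulus already at the target size is returned unchanged (identity),
    so repeated preparation passes are idempotent.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    if image.pixels.size == 0:
        raise ValueError("cannot resize an empty image")
    if image.shape == (side, side):
        return replace(image, pixels=image.pixels.copy())
    pil = Image.fromarray(image.pixels)
    resized = pil.resize((side, side), Image.BILINEAR)
    return replace(image, pixels=np.asarray(resized, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Single-hue repaint
# ---------------------------------------------------------------------------

# Channel layout of an HSV hue sector when saturation is 1: which of (r, g, b)
# carries the value channel ("B"), the intermediate channel ("X"), and zero.
_SECTOR_LAYOUT = {
    0: ("B", "X", "0"),
    1: ("X", "B", "0"),
    2: ("0", "B", "X"),
    3: ("0", "X", "B"),
    4: ("X", "0", "B"),
    5: ("B", "0", "X"),
}


def to_monochrome_hue(image: StimulusImage, spec: MonochromeSpec | None = None) -> StimulusImage:
    """Reduce a stimulus to grayscale, then repaint every pixel with one hue.

    The luminance of each pixel becomes the HSV value channel and saturation
    is set to its maximum, so intensity structure survives but no
    class-specific chromatic information does: two inputs with identical
    grayscale reductions map to identical outputs.  The default hue of 290
    degrees approximates the average hue of an H&E-stained section.

    Because 8-bit RGB quantizes chroma, very dark (but non-black) pixels are
    lifted to a small value floor; the value channel remains a monotone
    function of input luminance and the repainted hue stays within one degree
    of the target for every pixel with non-zero saturation.
    """
    spec = spec or MonochromeSpec()
    gray = np.rint(image.pixels.astype(float) @ LUMA_WEIGHTS).astype(int)

    h = spec.target_hue % 360.0
    sector = int(h // 60.0) % 6
    frac = (h - 60.0 * sector) / 60.0
    # Intermediate-channel fraction of the value channel within this sector.
    ratio = frac if sector % 2 == 0 else 1.0 - frac

    value = np.where(gray > 0, np.maximum(gray, _HUE_VALUE_FLOOR), 0)
    mid = np.rint(ratio * value).astype(int)
    zero = np.zeros_like(value)
    src = {"B": value, "X": mid, "0": zero}
    channels = [src[c] for c in _SECTOR_LAYOUT[sector]]
    pixels = np.stack(channels, axis=-1).astype(np.uint8)
    return replace(image, pixels=pixels)


# ---------------------------------------------------------------------------
# Between-class brightness/contrast equalization
# ---------------------------------------------------------------------------


def _pooled_stats(images: Sequence[StimulusImage]) -> tuple[float, float]:
    lum = np.concatenate([im.luminance().ravel() for im in images])
    return float(lum.mean()), float(lum.std())


def _affine_remap(images: Sequence[StimulusImage], gain: float, offset: float) -> list[StimulusImage]:
    out = []
    for im in images:
        x = im.pixels.astype(float) / 255.0
        y = np.clip(gain * x + offset, 0.0, 1.0)
        out.append(replace(im, pixels=np.rint(y * 255.0).astype(np.uint8)))
    return out


def equalize_sets(
    images_pos: Sequence[StimulusImage],
    images_neg: Sequence[StimulusImage],
    eps: float = 0.01,
) -> tuple[list[StimulusImage], list[StimulusImage], dict]:
    """Match pooled luminance mean and SD between the two class sets.

    Each set receives one affine intensity remap (identical coefficients for
    every image in the set), which preserves the within-set rank order of
    image luminances.  This is a reproducible surrogate for the by-hand
    brightness/contrast adjustment used when preparing single-hue stimulus
    sets, where systematic intensity differences between classes would
    otherwise be a trivially learnable cue.

    Returns the adjusted sets and a report dict with the achieved mean and SD
    gaps.  If a set has zero luminance variance, contrast matching is skipped
    for both sets and reported via a warning.
    """
    if not images_pos or not images_neg:
        raise ValueError("both stimulus sets must be non-empty")

    mu_p, sd_p = _pooled_stats(images_pos)
    mu_n, sd_n = _pooled_stats(images_neg)
    mu_t = 0.5 * (mu_p + mu_n)

    if sd_p == 0.0 or sd_n == 0.0:
        warnings.warn(
            "a stimulus set has zero luminance variance; contrast matching skipped",
            stacklevel=2,
        )
        gains = (1.0, 1.0)
    else:
        sd_t = 0.5 * (sd_p + sd_n)
        gains = (sd_t / sd_p, sd_t / sd_n)

    out_pos = _affine_remap(images_pos, gains[0], mu_t - gains[0] * mu_p)
    out_neg = _affine_remap(images_neg, gains[1], mu_t - gains[1] * mu_n)

    mu_p2, sd_p2 = _pooled_stats(out_pos)
    mu_n2, sd_n2 = _pooled_stats(out_neg)
    report = {
        "mean_gap": abs(mu_p2 - mu_n2),
        "sd_gap": abs(sd_p2 - sd_n2),
        "contrast_matched": sd_p != 0.0 and sd_n != 0.0,
        "eps": eps,
    }
    if report["mean_gap"] > eps or (report["contrast_matched"] and report["sd_gap"] > eps):
        warnings.warn(
            f"equalization residual exceeds eps={eps}: {report}", stacklevel=2
        )
    return out_pos, out_neg, report


# ---------------------------------------------------------------------------
# Targeted JPEG compression
# ---------------------------------------------------------------------------


def _encode(pixels: np.ndarray, fmt: str, **kwargs) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(pixels).save(buf, fmt, **kwargs)
    return buf.getvalue()


def reference_bytes(image: StimulusImage) -> bytes:
    """Losslessly encoded (PNG) reference defining the 1:1 size."""
    return _encode(image.pixels, "PNG", optimize=True)


def jpeg_sizes(image: StimulusImage, qualities: Sequence[int]) -> list[int]:
    """Encoded byte counts of the stimulus over a JPEG quality grid."""
    return [len(_encode(image.pixels, "JPEG", quality=int(q))) for q in qualities]


def compress_to_ratio(image: StimulusImage, spec: CompressionSpec) -> CompressionResult:
    """Re-encode a stimulus so its byte size hits a target fraction of the
    lossless reference.

    The JPEG quality parameter is swept over its full range and the quality
    whose achieved ratio is closest to ``spec.target_ratio`` is selected
    (encoded size is monotone in quality for natural textures, so this is a
    monotone search).  A target of 1.0 returns the lossless reference
    unchanged.  If even the lowest quality cannot reach the target within
    tolerance, an error reports the smallest achievable ratio.
    """
    ref = reference_bytes(image)
    ref_size = len(ref)
    if spec.target_ratio == 1.0:
        return CompressionResult(ref, 1.0, None, "PNG")

    qualities = range(1, 96)
    sizes = jpeg_sizes(image, qualities)
    ratios = np.array(sizes, dtype=float) / ref_size
    best = int(np.argmin(np.abs(ratios - spec.target_ratio)))
    achieved = float(ratios[best])
    if abs(achieved - spec.target_ratio) / spec.target_ratio > spec.tolerance:
        raise ValueError(
            f"target ratio {spec.target_ratio} unreachable within tolerance "
            f"{spec.tolerance}; smallest achievable ratio is {ratios.min():.4f}"
        )
    quality = list(qualities)[best]
    data = _encode(image.pixels, "JPEG", quality=quality)
    return CompressionResult(data, achieved, quality, "JPEG")


def decode_compressed(image: StimulusImage, result: CompressionResult) -> StimulusImage:
    """Decode a compressed stimulus back to pixels, tagging the ratio."""
    pil = Image.open(io.BytesIO(result.data)).convert("RGB")
    return replace(
        image,
        pixels=np.asarray(pil, dtype=np.uint8),
        compression_ratio=result.achieved_ratio,
    )


# ---------------------------------------------------------------------------
# Difficulty-balanced partitioning
# ---------------------------------------------------------------------------


def _exact_split(diff: np.ndarray, k: int) -> list[np.ndarray]:
    """All k-subsets of ``range(len(diff))`` as an index array, with sums."""
    idx = np.array(list(combinations(range(len(diff)), k)), dtype=int)
    return [idx, diff[idx].sum(axis=1)]


def partition_by_difficulty(
    items: Sequence[DifficultyItem], k_per_class: int, seed: int = 0
) -> Partition:
    """Split stimuli into two sets balanced on class counts and human difficulty.

    Each output set receives exactly ``k_per_class`` positives and
    ``k_per_class`` negatives, chosen to minimize the absolute difference of
    the two sets' mean difficulty.  For up to 20 items per class the optimum
    is found exactly by a meet-in-the-middle search over per-class subset
    sums; beyond that a deterministic greedy assignment with pairwise-swap
    refinement is used.  Ties are broken by the first candidate encountered
    when items are enumerated in lexicographic id order, so the result is
    reproducible.
    """
    if k_per_class < 1:
        raise ValueError("k_per_class must be >= 1")
    by_label = {lab: sorted((i for i in items if i.label == lab), key=lambda i: i.stimulus_id)
                for lab in LABELS}
    for lab in LABELS:
        if len(by_label[lab]) != 2 * k_per_class:
            raise ValueError(
                f"class {lab!r} must contain exactly {2 * k_per_class} items, "
                f"got {len(by_label[lab])}"
            )

    pos, neg = by_label["positive"], by_label["negative"]
    d_pos = np.array([i.difficulty for i in pos])
    d_neg = np.array([i.difficulty for i in neg])
    total = d_pos.sum() + d_neg.sum()

    if 2 * k_per_class <= 20:
        pos_idx, pos_sums = _exact_split(d_pos, k_per_class)
        neg_idx, neg_sums = _exact_split(d_neg, k_per_class)
        order = np.argsort(neg_sums, kind="stable")
        ns_sorted = neg_sums[order]
        targets = total / 2.0 - pos_sums
        j = np.searchsorted(ns_sorted, targets)
        best_gap, best_pair = np.inf, None
        for jj in (np.clip(j - 1, 0, len(ns_sorted) - 1), np.clip(j, 0, len(ns_sorted) - 1)):
            gaps = np.abs(pos_sums + ns_sorted[jj] - total / 2.0)
            b = int(np.argmin(gaps))
            if gaps[b] < best_gap - 1e-15:
                best_gap = float(gaps[b])
                best_pair = (b, int(order[jj[b]]))
        pi, ni = best_pair
        a_pos = set(pos_idx[pi])
        a_neg = set(neg_idx[ni])
    else:
        a_pos = _greedy_half(d_pos, k_per_class)
        a_neg = _greedy_half(d_neg, k_per_class)
        a_pos, a_neg = _swap_refine(d_pos, d_neg, a_pos, a_neg, total)

    set_a = [pos[i] for i in sorted(a_pos)] + [neg[i] for i in sorted(a_neg)]
    set_b = [p for i, p in enumerate(pos) if i not in a_pos] + [
        n for i, n in enumerate(neg) if i not in a_neg
    ]
    gap = abs(
        np.mean([i.difficulty for i in set_a]) - np.mean([i.difficulty for i in set_b])
    )
    return Partition(set_a, set_b, float(gap))


def _greedy_half(diff: np.ndarray, k: int) -> set[int]:
    """Snake assignment: alternate the difficulty-sorted items between sets."""
    order = np.argsort(-diff, kind="stable")
    return {int(i) for pos, i in enumerate(order) if pos % 2 == 0}


def _swap_refine(
    d_pos: np.ndarray,
    d_neg: np.ndarray,
    a_pos: set[int],
    a_neg: set[int],
    total: float,
) -> tuple[set[int], set[int]]:
    """Pairwise within-class swaps until the set-mean gap stops improving."""

    def gap(ap: set[int], an: set[int]) -> float:
        s = d_pos[sorted(ap)].sum() + d_neg[sorted(an)].sum()
        return abs(2.0 * s - total)

    improved = True
    while improved:
        improved = False
        for d, a in ((d_pos, a_pos), (d_neg, a_neg)):
            outside = [i for i in range(len(d)) if i not in a]
            for i in sorted(a):
                for j in outside:
                    trial = (a - {i}) | {j}
                    if d is d_pos:
                        g_new, g_old = gap(trial, a_neg), gap(a_pos, a_neg)
                    else:
                        g_new, g_old = gap(a_pos, trial), gap(a_pos, a_neg)
                    if g_new < g_old - 1e-12:
                        a.clear()
                        a.update(trial)
                        improved = True
                        break
                if improved:
                    break
    return a_pos, a_neg
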