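"""Frame preprocessing and training-time augmentation.

All operations are strictly per-frame and never change the number of frames
or the spacing metadata. Intensity steps (min-max normalisation, percentile
histogram stretching) map every frame into [0, 1]; geometry steps
(center-crop-padding, augmentation) treat images and masks with the same
transform, resampling masks nearest-neighbour so they stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

__all__ = [
    "minmax_normalize",
    "histogram_stretch",
    "center_crop_pad",
    "AugmentParams",
    "augment",
    "preprocess_frame",
]


def minmax_normalize(frame: np.ndarray) -> np.ndarray:
    """Scale intensities to [0, 1] as (x - min) / (max - min).

    A constant frame maps to all zeros: there is no contrast to preserve and
    the output-range contract must hold.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    lo = frame.min()
    hi = frame.max()
    if hi == lo:
        return np.zeros_like(frame)
    return (frame - lo) / (hi - lo)


def histogram_stretch(frame: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Percentile contrast stretch: map [P_low, P_high] linearly onto [0, 1].

    Values outside the percentile window are clipped, which suppresses the
    bright flow-artifact outliers typical of FLASH cine frames. Degenerate
    windows (P_low == P_high) fall back to :func:`minmax_normalize`.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low < high <= 100, got {low_pct}, {high_pct}")
    frame = np.asarray(frame, dtype=np.float64)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    p_low, p_high = np.percentile(frame, [low_pct, high_pct])
    if p_high == p_low:
        return minmax_normalize(frame)
    return np.clip((frame - p_low) / (p_high - p_low), 0.0, 1.0)


def center_crop_pad(frame: np.ndarray, target: int) -> np.ndarray:
    """Crop/zero-pad a frame symmetrically about its center to ``target``².

    Dimensions larger than ``target`` are center-cropped, smaller ones are
    zero-padded; on odd size differences the extra pixel goes to the trailing
    side, so the image center is preserved.
    """
    if target < 1:
        raise ValueError("target size must be >= 1")
    frame = np.asarray(frame)
    out = frame
    for axis in (0, 1):
        n = out.shape[axis]
        if n > target:
            start = (n - target) // 2
            out = np.take(out, range(start, start + target), axis=axis)
        elif n < target:
            before = (target - n) // 2
            after = target - n - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant")
    return out


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for random training-time augmentation.

    Defaults: rotation +/-15 deg, horizontal/vertical flip each with p=0.5,
    affine scale 0.9-1.1 and translation +/-5% of the frame size.
    """

    rotation_deg: float = 15.0
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.05

    @classmethod
    def none(cls) -> "AugmentParams":
        return cls(rotation_deg=0.0, p_hflip=0.0, p_vflip=0.0, scale_range=(1.0, 1.0), translate_frac=0.0)


def augment(
    frame: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams = AugmentParams(),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random rotation/flip/affine draw to an image-mask pair.

    The identical geometric transform is applied to both arrays; the image is
    resampled bilinearly and the mask nearest-neighbour (so it stays {0,1}).
    Passing the same seed reproduces the same draw.
    """
    frame = np.asarray(frame, dtype=np.float64)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError(f"frame {frame.shape} and mask {mask.shape} differ in shape")
    rng = np.random.default_rng(rng)

    angle = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg))
    scale = rng.uniform(*params.scale_range)
    h, w = frame.shape
    t_r = rng.uniform(-params.translate_frac, params.translate_frac) * h
    t_c = rng.uniform(-params.translate_frac, params.translate_frac) * w
    hflip = rng.random() < params.p_hflip
    vflip = rng.random() < params.p_vflip

    # rotate/scale about the image center, then translate
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # skimage uses (x, y)
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=angle, scale=scale)
        + AffineTransform(translation=center + np.array([t_c, t_r]))
    )
    identity = (
        angle == 0.0 and scale == 1.0 and t_r == 0.0 and t_c == 0.0 and not hflip and not vflip
    )
    if identity:
        return frame.copy(), mask.copy()

    out_frame = warp(frame, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True)
    out_mask = warp(
        mask.astype(np.float64), tf.inverse, order=0, mode="constant", cval=0.0, preserve_range=True
    )
    if hflip:
        out_frame = out_frame[:, ::-1]
        out_mask = out_mask[:, ::-1]
    if vflip:
        out_frame = out_frame[::-1, :]
        out_mask = out_mask[::-1, :]
    return np.ascontiguousarray(out_frame), np.ascontiguousarray(out_mask > 0.5).astype(mask.dtype)


def preprocess_frame(
    frame: np.ndarray,
    target: int = 256,
    stretch: bool = True,
    low_pct: float = 1.0,
    high_pct: float = 99.0,
) -> np.ndarray:
    """Standard preprocessing chain: stretch -> normalize -> center-crop-pad."""
    out = histogram_stretch(frame, low_pct, high_pct) if stretch else np.asarray(frame, float)
    out = minmax_normalize(out)
    return center_crop_pad(out, target)
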