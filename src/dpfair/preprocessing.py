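"""Image normalization and label binarization for radiograph- and CT-style data.

Radiograph-style 2D images go through resize → per-image min-max scaling to
uint8 [0, 255] → global histogram equalization.  CT-style volumes are clipped
to an abdominal Hounsfield window and resized.  Five-level severity labels are
collapsed to binary: "negative"/"uncertain" (and the cardiomegaly-specific
"normal"/"uncertain") count as negative, everything more severe as positive.

Rounding: wherever intensities are quantized, round-half-up is used
(``floor(x + 0.5)``) so that examples are bit-reproducible.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "resize",
    "normalize_minmax_uint8",
    "histogram_equalize",
    "binarize_labels",
    "window_hu",
    "SEVERITY_VOCAB",
    "CARDIOMEGALY_VOCAB",
    "prepare_cxr_image",
    "prepare_ct_volume",
]

#: Generic five-level severity vocabulary and its binary collapse.
SEVERITY_VOCAB: Mapping[str, int] = {
    "negative": 0,
    "uncertain": 0,
    "mild": 1,
    "moderate": 1,
    "severe": 1,
}

#: Cardiomegaly uses its own five-level wording.
CARDIOMEGALY_VOCAB: Mapping[str, int] = {
    "normal": 0,
    "uncertain": 0,
    "borderline": 1,
    "enlarged": 1,
    "massively enlarged": 1,
}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def resize(img: np.ndarray, target_extents: Sequence[int]) -> np.ndarray:
    """Resize by bilinear (2D) / trilinear (3D) interpolation.

    Output pixel centers are mapped onto input pixel centers, so an exact 2x
    downsample averages each 2x2 (2x2x2) block.
    """
    img = np.asarray(img, dtype=float)
    target = tuple(int(t) for t in target_extents)
    if len(target) != img.ndim:
        raise ValueError(
            f"target extents {target} do not match image rank {img.ndim}"
        )
    if any(t <= 0 for t in target):
        raise ValueError(f"target extents must be positive, got {target}")
    if target == img.shape:
        return img.copy()
    axes = [
        (np.arange(t) + 0.5) * (s / t) - 0.5 for t, s in zip(target, img.shape)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = map_coordinates(img, coords, order=1, mode="nearest")
    return out.reshape(target)


def normalize_minmax_uint8(img: np.ndarray) -> np.ndarray:
    """Shift to zero minimum, scale the maximum to 255, quantize to uint8.

    A constant image has no dynamic range and maps to all zeros.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = _round_half_up(255.0 * (img - lo) / (hi - lo))
    return np.clip(scaled, 0, 255).astype(np.uint8)


def histogram_equalize(img: np.ndarray) -> np.ndarray:
    """Classical global histogram equalization of a uint8 image.

    Maps intensity p to round(255 · CDF(p)) computed on the full frame; the
    mapping is monotone non-decreasing, so intensity ordering is preserved.
    """
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise TypeError(f"histogram_equalize expects uint8 input, got {img.dtype}")
    counts = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(counts) / img.size
    lut = np.clip(_round_half_up(255.0 * cdf), 0, 255).astype(np.uint8)
    return lut[img]


def binarize_labels(
    severities: Mapping[str, str], labels: Sequence[str] | None = None
) -> dict[str, int]:
    """Collapse per-label 5-level severities to binary findings.

    Parameters
    ----------
    severities : mapping label -> severity token
    labels : optional ordering/subset of labels to emit

    Cardiomegaly-named labels are checked against the cardiomegaly vocabulary,
    all others against the generic one; an unknown token raises, naming both
    token and label.
    """
    keys = list(labels) if labels is not None else list(severities)
    out: dict[str, int] = {}
    for label in keys:
        token = severities[label]
        vocab = CARDIOMEGALY_VOCAB if "cardiomegaly" in label.lower() else SEVERITY_VOCAB
        if token not in vocab:
            raise ValueError(
                f"unknown severity token {token!r} for label {label!r}; "
                f"expected one of {sorted(vocab)}"
            )
        out[label] = vocab[token]
    return out


def window_hu(volume: np.ndarray, lo: float = -150.0, hi: float = 250.0) -> np.ndarray:
    """Clip voxel densities to a Hounsfield window (default abdominal)."""
    if not lo < hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    return np.clip(np.asarray(volume, dtype=float), lo, hi)


def prepare_cxr_image(
    img: np.ndarray, target_extents: Sequence[int] | None = None
) -> np.ndarray:
    """Full radiograph pipeline: resize, min-max to uint8, equalize."""
    if target_extents is not None:
        img = resize(img, target_extents)
    return histogram_equalize(normalize_minmax_uint8(img))


def prepare_ct_volume(
    volume: np.ndarray,
    target_extents: Sequence[int] | None = None,
    lo: float = -150.0,
    hi: float = 250.0,
) -> np.ndarray:
    """Full CT pipeline: Hounsfield windowing then resize."""
    volume = window_hu(volume, lo, hi)
    if target_extents is not None:
        volume = resize(volume, target_extents)
    return volume
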