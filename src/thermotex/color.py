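"""Decomposition of 8-bit RGB false-color thermograms into grayscale planes.

A thermal camera renders surface temperature as false color. Texture
analysis, however, operates on grayscale images, so each thermogram is
decomposed into ten grayscale component planes drawn from four color
models:

* RGB   — the Red, Green and Blue channels, copied without conversion;
* YUV   — Brightness (Y) and the two chrominance axes U, V;
* YIQ   — the NTSC in-phase (I, orange–cyan) and quadrature (Q,
          magenta–green) chrominance axes; Y is shared with YUV;
* HSB   — Hue and Saturation derived from the centered chrominance
          vector; Brightness is again the shared Y.

All chrominance transforms are integer-weighted linear maps offset by
``theta`` (2**n − 1 = 255 for 8-bit input) and scaled so that the full
RGB cube maps exactly onto gray levels 0..255.  Outputs are rounded half
away from zero and clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "COMPONENT_IDS",
    "ColorTransformConfig",
    "split_rgb",
    "to_Y",
    "to_U",
    "to_V",
    "to_I",
    "to_Q",
    "to_H",
    "to_S",
    "transform_all",
]

#: Fixed naming of the ten grayscale planes in all outputs.
COMPONENT_IDS = ("R", "G", "B", "Y", "U", "V", "I", "Q", "H", "S")


@dataclass(frozen=True)
class ColorTransformConfig:
    """Options for the chrominance transforms.

    Parameters
    ----------
    theta:
        Intensity offset added to center chrominance on mid-gray;
        255 (= 2^8 − 1) is the only value that maps every transform's
        range exactly onto [0, 255].
    rounding:
        ``"half-away"`` (default) rounds half away from zero;
        ``"floor"`` truncates, for comparison with software that does.
    corrected_signs:
        The published Q-transform B-weight and the H/S chroma R-weight
        carry typographic sign errors (with the literal signs the gray
        axis does not cancel and ranges do not reach [0, 255]).  True
        (default) uses the internally consistent corrected signs; False
        reproduces the literal printed formulas.
    """

    theta: float = 255.0
    rounding: str = "half-away"
    corrected_signs: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"theta must be positive and finite, got {self.theta}")
        if self.rounding not in ("half-away", "floor"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")


DEFAULT_COLOR_CONFIG = ColorTransformConfig()


def _as_rgb_channels(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image of shape (N, M, 3), got {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit (uint8) input, got dtype {image.dtype}")
    r, g, b = (image[..., i].astype(np.float64) for i in range(3))
    return r, g, b


def _quantize(values: np.ndarray, cfg: ColorTransformConfig) -> np.ndarray:
    if cfg.rounding == "half-away":
        out = np.floor(np.abs(values) + 0.5) * np.sign(values)
    else:
        out = np.floor(values)
    return np.clip(out, 0, 255).astype(np.uint8)


def split_rgb(image: np.ndarray) -> dict[str, np.ndarray]:
    """Separate the R, G, B channels without any conversion."""
    image = np.asarray(image)
    _as_rgb_channels(image)  # validation only
    return {"R": image[..., 0].copy(), "G": image[..., 1].copy(), "B": image[..., 2].copy()}


def to_Y(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """Brightness: Y = (299R + 587G + 114B) / 1000."""
    r, g, b = _as_rgb_channels(image)
    return _quantize((299 * r + 587 * g + 114 * b) / 1000, cfg)


def to_U(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """U chrominance: U = (886B − 587G − 299R + 886Θ) / 1772."""
    r, g, b = _as_rgb_channels(image)
    return _quantize((886 * b - 587 * g - 299 * r + 886 * cfg.theta) / 1772, cfg)


def to_V(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """V chrominance: V = (−114B − 587G + 701R + 701Θ) / 1402."""
    r, g, b = _as_rgb_channels(image)
    return _quantize((-114 * b - 587 * g + 701 * r + 701 * cfg.theta) / 1402, cfg)


def to_I(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """In-phase chrominance: I = (−3213B − 2744G + 5957R + 5958Θ) / 11916."""
    r, g, b = _as_rgb_channels(image)
    return _quantize((-3213 * b - 2744 * g + 5957 * r + 5958 * cfg.theta) / 11916, cfg)


def to_Q(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """Quadrature (magenta–green) chrominance.

    Q = (3111B − 5226G + 2115R + 5226Θ) / 10452 with the corrected
    (positive) B-weight: 3111 − 5226 + 2115 = 0 on the gray axis and the
    magenta corner maps to exactly 255.
    """
    r, g, b = _as_rgb_channels(image)
    b_sign = 1.0 if cfg.corrected_signs else -1.0
    return _quantize(
        (b_sign * 3111 * b - 5226 * g + 2115 * r + 5226 * cfg.theta) / 10452, cfg
    )


def _chroma_uv(image: np.ndarray, cfg: ColorTransformConfig) -> tuple[np.ndarray, np.ndarray]:
    # Centered chrominance vector used by Hue and Saturation.
    r, g, b = _as_rgb_channels(image)
    u = (886 * b - 587 * g - 299 * r) / 886
    r_sign = 1.0 if cfg.corrected_signs else -1.0
    v = (-114 * b - 587 * g + r_sign * 701 * r) / 701
    return u, v


def to_H(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """Hue: H = Θ/(2π) · arg(u + j·v), argument taken in [0, 2π).

    Achromatic pixels (u = v = 0) are assigned H = 0.
    """
    u, v = _chroma_uv(image, cfg)
    angle = np.arctan2(v, u)
    angle = np.where(angle < 0, angle + 2 * np.pi, angle)
    angle = np.where((u == 0) & (v == 0), 0.0, angle)
    return _quantize(cfg.theta * angle / (2 * np.pi), cfg)


def to_S(image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG) -> np.ndarray:
    """Saturation: S = 0.937 · sqrt(u² + v²).

    0.937 normalizes the maximum chroma (the magenta corner of the RGB
    cube) to 255.
    """
    u, v = _chroma_uv(image, cfg)
    return _quantize(0.937 * np.hypot(u, v), cfg)


def transform_all(
    image: np.ndarray, cfg: ColorTransformConfig = DEFAULT_COLOR_CONFIG
) -> dict[str, np.ndarray]:
    """All ten grayscale component planes of an RGB thermogram.

    Returns a dict keyed by :data:`COMPONENT_IDS`; the Brightness plane
    of YUV/YIQ/HSB is the single shared Y.
    """
    planes = split_rgb(image)
    planes["Y"] = to_Y(image, cfg)
    planes["U"] = to_U(image, cfg)
    planes["V"] = to_V(image, cfg)
    planes["I"] = to_I(image, cfg)
    planes["Q"] = to_Q(image, cfg)
    planes["H"] = to_H(image, cfg)
    planes["S"] = to_S(image, cfg)
    return {cid: planes[cid] for cid in COMPONENT_IDS}
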