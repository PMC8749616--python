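"""First- and second-order texture features inside a region of interest.

Two families of features are computed on each grayscale component plane,
restricted to the ROI mask:

* **Histogram Statistics (HS)** — 13 first-order features of the
  normalized gray-level histogram (moments, percentiles, windowed
  dominants), blind to pixel arrangement.
* **Haralick features** — 11 second-order features of the normalized
  gray-level co-occurrence matrix, which counts ordered pairs of gray
  levels at a fixed pixel displacement (horizontal, distance 1 by
  default).  The matrix is either *symmetric* (GLCM: pairs are counted
  in both directions) or *asymmetric* (GLCH: forward direction only).

All pair counting requires both endpoints inside the mask; gray levels
are 0-based (k, l ∈ 0..K−1); entropies use the natural logarithm with
the convention 0·log 0 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .color import COMPONENT_IDS, DEFAULT_COLOR_CONFIG, ColorTransformConfig, transform_all

__all__ = [
    "HS_FEATURES",
    "GLCM_FEATURES",
    "NormalizedHistogram",
    "CoOccurrenceMatrix",
    "TextureConfig",
    "roi_histogram",
    "hs_features",
    "build_cooccurrence",
    "glcm_features",
    "extract_all",
    "extract_table",
]

HS_FEATURES = (
    "Mean", "Variance", "Skewness", "Kurtosis",
    "Perc01", "Perc10", "Perc50", "Perc90", "Perc99",
    "Domn01", "Domn10", "Maxm01", "Maxm10",
)

GLCM_FEATURES = (
    "AngScMom", "Contrast", "Correlat", "SumOfSqs", "InvDefMom",
    "SumAverg", "SumVarnc", "SumEntrp", "Entropy", "DifVarnc", "DifEntrp",
)


@dataclass(frozen=True)
class NormalizedHistogram:
    """Gray-level probabilities H(k), k = 0..K−1, over the ROI pixels."""

    probs: np.ndarray
    counts: np.ndarray
    n_pixels: int

    @property
    def levels(self) -> int:
        return len(self.probs)


@dataclass(frozen=True)
class CoOccurrenceMatrix:
    """Normalized co-occurrence probabilities p(k, l) at one displacement."""

    probs: np.ndarray          # (K, K), sums to 1
    counts: np.ndarray         # raw pair counts
    offset: tuple[int, int]    # (row, column) displacement
    symmetric: bool            # True = GLCM, False = GLCH

    @property
    def levels(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class TextureConfig:
    """Texture-extraction options.

    gray_levels: number of gray levels K (256 keeps the full 8-bit
    depth; smaller values quantize planes down for speed).
    offset: (row, col) pixel displacement; (0, 1) is horizontal d = 1,
    the study default.
    window_radii: widths r of the Domn/Maxm sliding windows.
    components / approaches: subsets to extract, for targeted runs.
    """

    gray_levels: int = 256
    offset: tuple[int, int] = (0, 1)
    window_radii: tuple[int, int] = (1, 10)
    components: tuple[str, ...] = COMPONENT_IDS
    approaches: tuple[str, ...] = ("HS", "GLCM", "GLCH")
    color: ColorTransformConfig = field(default_factory=ColorTransformConfig)

    def __post_init__(self) -> None:
        if self.gray_levels < 2 or self.gray_levels > 256:
            raise ValueError("gray_levels must be in 2..256")
        if self.offset == (0, 0):
            raise ValueError("offset must be non-zero")
        unknown = set(self.components) - set(COMPONENT_IDS)
        if unknown:
            raise ValueError(f"unknown components: {sorted(unknown)}")
        unknown = set(self.approaches) - {"HS", "GLCM", "GLCH"}
        if unknown:
            raise ValueError(f"unknown approaches: {sorted(unknown)}")


DEFAULT_TEXTURE_CONFIG = TextureConfig()


def _validated_mask(plane: np.ndarray, mask: np.ndarray) -> np.ndarray:
    plane = np.asarray(plane)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != plane.shape:
        raise ValueError(f"mask shape {mask.shape} != plane shape {plane.shape}")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return mask


def roi_histogram(plane: np.ndarray, mask: np.ndarray, levels: int = 256) -> NormalizedHistogram:
    """Normalized gray-level histogram of the masked pixels."""
    mask = _validated_mask(plane, mask)
    values = np.asarray(plane)[mask].astype(np.int64)
    if values.min() < 0 or values.max() >= levels:
        raise ValueError(f"plane values outside 0..{levels - 1}")
    counts = np.bincount(values, minlength=levels)
    return NormalizedHistogram(
        probs=counts / counts.sum(), counts=counts, n_pixels=int(counts.sum())
    )


def hs_features(
    hist: NormalizedHistogram, window_radii: tuple[int, int] = (1, 10)
) -> dict[str, float]:
    """The 13 first-order Histogram Statistics features.

    Percentiles follow the discrete min-K rule PercQQ = min{K : Σ_{k≤K}
    H(k) ≥ QQ/100}.  Domn_r / Maxm_r are the location and height of the
    highest-probability window of r consecutive gray levels (ties break
    to the smallest level).  Skewness and Kurtosis are the standardized
    3rd and 4th central moments (Kurtosis in excess form), defined as 0
    for a degenerate (zero-variance) histogram.
    """
    h = hist.probs
    k = np.arange(hist.levels, dtype=np.float64)
    mean = float(np.sum(k * h))
    var = float(np.sum((k - mean) ** 2 * h))
    if var > 0:
        skew = float(np.sum((k - mean) ** 3 * h) * var ** -1.5)
        kurt = float(np.sum((k - mean) ** 4 * h) * var ** -2.0 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0

    out = {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
    cum = np.cumsum(h)
    for qq in (1, 10, 50, 90, 99):
        out[f"Perc{qq:02d}"] = float(np.argmax(cum >= qq / 100 - 1e-12))
    for r in window_radii:
        r_eff = min(r, hist.levels)  # a window wider than the histogram covers it all
        # window pixel counts are exact integers, so ties break cleanly
        window_counts = np.convolve(hist.counts, np.ones(r_eff, dtype=np.int64), mode="valid")
        kmax = int(np.argmax(window_counts))  # first maximum = smallest k on ties
        out[f"Domn{r:02d}"] = float(kmax)
        out[f"Maxm{r:02d}"] = float(window_counts[kmax] / hist.n_pixels)
    return out


def build_cooccurrence(
    plane: np.ndarray,
    mask: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = False,
    levels: int = 256,
) -> CoOccurrenceMatrix:
    """Co-occurrence matrix of gray-level pairs at a fixed displacement.

    Counts ordered pairs (pixel, pixel + offset) whose endpoints both
    lie inside the mask.  The symmetric variant (GLCM) additionally
    counts every pair in the reverse direction, i.e. adds the transpose.
    """
    plane = np.asarray(plane)
    mask = _validated_mask(plane, mask)
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ValueError("offset must be non-zero")
    nrow, ncol = plane.shape

    src = mask.copy()
    # Pairs whose shifted endpoint stays inside the image bounds.
    rows = slice(max(0, -dr), min(nrow, nrow - dr))
    cols = slice(max(0, -dc), min(ncol, ncol - dc))
    valid = np.zeros_like(mask)
    valid[rows, cols] = src[rows, cols] & mask[
        rows.start + dr : rows.stop + dr, cols.start + dc : cols.stop + dc
    ]
    if not valid.any():
        raise ValueError("no valid co-occurrence pairs inside the ROI")

    k = plane[valid].astype(np.int64)
    shifted = np.roll(np.roll(plane, -dr, axis=0), -dc, axis=1)
    l = shifted[valid].astype(np.int64)
    if k.max() >= levels or l.max() >= levels or k.min() < 0 or l.min() < 0:
        raise ValueError(f"plane values outside 0..{levels - 1}")
    counts = np.bincount(k * levels + l, minlength=levels * levels).reshape(levels, levels)
    if symmetric:
        counts = counts + counts.T
    return CoOccurrenceMatrix(
        probs=counts / counts.sum(), counts=counts, offset=(dr, dc), symmetric=symmetric
    )


def _sum_diff_indices(levels: int) -> tuple[np.ndarray, np.ndarray]:
    k = np.arange(levels)
    return k[:, None] + k[None, :], np.abs(k[:, None] - k[None, :])


def glcm_features(com: CoOccurrenceMatrix) -> dict[str, float]:
    """The 11 Haralick features of a normalized co-occurrence matrix.

    Marginal means/SDs μ, σ are moments of the row/column marginals of
    p(k, l); the sum and difference distributions are the masses of
    p at constant k+l and |k−l|.  Correlation is defined 0 when either
    marginal SD vanishes.
    """
    p = com.probs
    levels = com.levels
    k = np.arange(levels, dtype=np.float64)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_k = float(np.sum(k * px))
    mu_l = float(np.sum(k * py))
    var_k = float(np.sum((k - mu_k) ** 2 * px))
    var_l = float(np.sum((k - mu_l) ** 2 * py))
    sd_k, sd_l = np.sqrt(var_k), np.sqrt(var_l)

    sum_idx, diff_idx = _sum_diff_indices(levels)
    p_sum = np.bincount(sum_idx.ravel(), weights=p.ravel(), minlength=2 * levels - 1)
    p_diff = np.bincount(diff_idx.ravel(), weights=p.ravel(), minlength=levels)
    m_sum = np.arange(2 * levels - 1, dtype=np.float64)
    m_diff = np.arange(levels, dtype=np.float64)

    ang_sc_mom = float(np.sum(p * p))
    contrast = float(np.sum(m_diff**2 * p_diff))
    if sd_k * sd_l > 0:
        correlat = float((np.sum(np.outer(k, k) * p) - mu_k * mu_l) / (sd_k * sd_l))
    else:
        correlat = 0.0
    sum_of_sqs = var_k
    inv_def_mom = float(np.sum(p_diff / (1.0 + m_diff**2)))
    sum_averg = float(np.sum(m_sum * p_sum))
    sum_varnc = float(np.sum((m_sum - sum_averg) ** 2 * p_sum))
    sum_entrp = float(-np.sum(xlogy(p_sum, p_sum)))
    entropy = float(-np.sum(xlogy(p, p)))
    diff_mean = float(np.sum(m_diff * p_diff))
    dif_varnc = float(np.sum((m_diff - diff_mean) ** 2 * p_diff))
    dif_entrp = float(-np.sum(xlogy(p_diff, p_diff)))

    return {
        "AngScMom": ang_sc_mom,
        "Contrast": contrast,
        "Correlat": correlat,
        "SumOfSqs": sum_of_sqs,
        "InvDefMom": inv_def_mom,
        "SumAverg": sum_averg,
        "SumVarnc": sum_varnc,
        "SumEntrp": sum_entrp,
        "Entropy": entropy,
        "DifVarnc": dif_varnc,
        "DifEntrp": dif_entrp,
    }


def _quantize_plane(plane: np.ndarray, levels: int) -> np.ndarray:
    if levels == 256:
        return plane
    return (plane.astype(np.int64) * levels) // 256


def extract_all(frame, cfg: TextureConfig = DEFAULT_TEXTURE_CONFIG) -> pd.DataFrame:
    """All color/feature combinations of one frame as tidy records.

    For the full default configuration this yields 10 components × (13
    HS + 11 GLCM + 11 GLCH) = 350 rows with columns mare_id, group,
    subgroup, month, session, component, approach, feature, value.
    """
    planes = transform_all(frame.image, cfg.color)
    records: list[tuple] = []
    meta = (frame.mare_id, frame.group, frame.subgroup, frame.month, frame.session)
    for cid in cfg.components:
        plane = _quantize_plane(planes[cid], cfg.gray_levels)
        if "HS" in cfg.approaches:
            hist = roi_histogram(plane, frame.mask, cfg.gray_levels)
            for name, value in hs_features(hist, cfg.window_radii).items():
                records.append(meta + (cid, "HS", name, value))
        for approach, symmetric in (("GLCM", True), ("GLCH", False)):
            if approach not in cfg.approaches:
                continue
            com = build_cooccurrence(
                plane, frame.mask, cfg.offset, symmetric=symmetric, levels=cfg.gray_levels
            )
            for name, value in glcm_features(com).items():
                records.append(meta + (cid, approach, name, value))
    return pd.DataFrame(
        records,
        columns=[
            "mare_id", "group", "subgroup", "month", "session",
            "component", "approach", "feature", "value",
        ],
    )


def extract_table(frames, cfg: TextureConfig = DEFAULT_TEXTURE_CONFIG) -> pd.DataFrame:
    """Feature table over a collection of frames (one tidy row per value)."""
    tables = [extract_all(frame, cfg) for frame in frames]
    if not tables:
        raise ValueError("no frames to extract")
    return pd.concat(tables, ignore_index=True)
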