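"""Seeded synthetic thermal cohorts emulating the mare imaging study.

The original raw thermograms are not publicly deposited, so this module
generates surrogate cohorts with the statistical structure the analysis
assumes: 14 non-pregnant mares imaged at four sessions and two pregnant
subgroups of 13 mares imaged at gestation months {4, 6, 8, 10} and
{5, 7, 9, 11} — 160 frames in total under the default design.

A frame is produced in three steps:

1. a surface-temperature field in °C — a base temperature plus a
   per-mare random intercept, spatially smooth correlated noise, and
   (for pregnant mares) a month-growing elliptical hot spot over the
   flank together with month-growing fine-grain heterogeneity, clipped
   to the camera range (10–40 °C);
2. false-color rendering through a piecewise-linear palette
   (blue → cyan → green → magenta → red, so that low temperature is
   blue-annotated, medium-high magenta and high red);
3. a polygonal flank ROI mask rasterized by pixel-center containment.

Everything is reproducible bit-for-bit from the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "CohortDesign",
    "EffectModel",
    "PaletteSpec",
    "ThermalFrame",
    "DEFAULT_PALETTE",
    "DEFAULT_ROI_FRACTIONS",
    "default_roi_polygon",
    "generate_temperature_field",
    "render_thermal_image",
    "generate_roi_mask",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: who is imaged when."""

    n_nonpregnant: int = 14
    n_pregnant_per_subgroup: int = 13
    months_subgroup_a: tuple[int, ...] = (4, 6, 8, 10)
    months_subgroup_b: tuple[int, ...] = (5, 7, 9, 11)
    n_sessions_nonpregnant: int = 4
    seed: int = 0
    frame_shape: tuple[int, int] = (120, 160)

    def __post_init__(self) -> None:
        for name in ("n_nonpregnant", "n_pregnant_per_subgroup", "n_sessions_nonpregnant"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for months in (self.months_subgroup_a, self.months_subgroup_b):
            if list(months) != sorted(set(months)):
                raise ValueError(f"month list must be strictly increasing, got {months}")
            if any(m < 4 or m > 11 for m in months):
                raise ValueError(f"months must lie in 4..11, got {months}")

    @property
    def scheduled_months(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.months_subgroup_a) | set(self.months_subgroup_b)))

    @property
    def n_frames(self) -> int:
        return (
            self.n_nonpregnant * self.n_sessions_nonpregnant
            + self.n_pregnant_per_subgroup
            * (len(self.months_subgroup_a) + len(self.months_subgroup_b))
        )


@dataclass(frozen=True)
class EffectModel:
    """Thermal effect sizes, all in °C or pixels.

    The pregnancy effect enters through three month-dependent terms,
    each non-decreasing in gestation month m and absent (amplitude 0,
    heterogeneity at the non-pregnant baseline) for non-pregnant mares:
    a hot-spot amplitude ``amp_per_month·(m − 3)``, a hot-spot radius
    ``radius_base + radius_per_month·(m − 3)`` and fine-grain
    heterogeneity SD ``het_base · het_growth^(m − 3)``.  The geometric
    heterogeneity schedule makes the monthly increase uniform on the
    (logarithmic) scale of entropy-type texture features, emulating a
    steady month-over-month rise in texture heterogeneity.
    """

    base_temp: float = 27.0
    mare_intercept_sd: float = 0.5
    ambient_drift_sd: float = 0.0
    smooth_noise_sd: float = 0.2
    smooth_corr_len: float = 6.0
    amp_per_month: float = 0.4
    radius_base: float = 8.0
    radius_per_month: float = 3.0
    het_base: float = 0.12
    het_growth: float = 1.35
    hotspot_center_frac: tuple[float, float] = (0.45, 0.68)
    hotspot_aspect: float = 1.4
    center_jitter: float = 3.0
    camera_range: tuple[float, float] = (10.0, 40.0)

    def __post_init__(self) -> None:
        values = [
            self.base_temp, self.mare_intercept_sd, self.ambient_drift_sd,
            self.smooth_noise_sd, self.smooth_corr_len, self.amp_per_month,
            self.radius_base, self.radius_per_month, self.het_base,
            self.het_growth, self.hotspot_aspect, self.center_jitter,
            *self.camera_range,
        ]
        if not all(np.isfinite(values)):
            raise ValueError("EffectModel parameters must be finite")
        if self.camera_range[0] >= self.camera_range[1]:
            raise ValueError("camera_range must satisfy min < max")
        if min(self.amp_per_month, self.radius_per_month) < 0:
            raise ValueError("monthly effect slopes must be non-negative")
        if self.het_growth < 1.0:
            raise ValueError("het_growth must be >= 1 (heterogeneity non-decreasing in month)")

    def hotspot_amp(self, month: int | None) -> float:
        """Hot-spot peak amplitude in °C (0 for non-pregnant)."""
        return 0.0 if month is None else self.amp_per_month * (month - 3)

    def hotspot_radius(self, month: int | None) -> float:
        """Hot-spot Gaussian scale in pixels."""
        if month is None:
            return self.radius_base
        return self.radius_base + self.radius_per_month * (month - 3)

    def heterogeneity_sd(self, month: int | None) -> float:
        """SD of the fine-grain (pixel-wise) temperature noise in °C."""
        if month is None:
            return self.het_base
        return self.het_base * self.het_growth ** (month - 3)

    @classmethod
    def null(cls, **overrides) -> "EffectModel":
        """A no-effect model: pregnant and non-pregnant frames are exchangeable."""
        return cls(amp_per_month=0.0, het_growth=1.0, **overrides)


@dataclass(frozen=True)
class PaletteSpec:
    """Piecewise-linear false-color palette.

    ``control_points`` maps normalized temperature fractions in [0, 1]
    (strictly increasing, starting at 0 and ending at 1) to RGB triples;
    channels are interpolated linearly between control points.
    """

    control_points: tuple[tuple[float, tuple[int, int, int]], ...]
    name: str = "palette"

    def __post_init__(self) -> None:
        fracs = [f for f, _ in self.control_points]
        if len(fracs) < 2 or fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValueError("control points must start at 0 and end at 1")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("control-point fractions must be strictly increasing")

    def lookup(self, fractions: np.ndarray) -> np.ndarray:
        """Float RGB values (not yet quantized) for fractions in [0, 1]."""
        fracs = np.array([f for f, _ in self.control_points])
        colors = np.array([c for _, c in self.control_points], dtype=np.float64)
        out = np.empty(fractions.shape + (3,))
        for ch in range(3):
            out[..., ch] = np.interp(fractions, fracs, colors[:, ch])
        return out


#: Blue→cyan→green→magenta→red rainbow: low temperatures blue, medium-high
#: magenta, extremes red — the annotation scheme of consumer thermal cameras.
DEFAULT_PALETTE = PaletteSpec(
    control_points=(
        (0.00, (0, 0, 255)),
        (0.25, (0, 255, 255)),
        (0.50, (0, 255, 0)),
        (0.75, (255, 0, 255)),
        (1.00, (255, 0, 0)),
    ),
    name="rainbow5",
)

#: Default flank ROI: a pentagon bounded on the left by the vertical
#: through the tuber coxae, as (row, col) fractions of the frame extent.
DEFAULT_ROI_FRACTIONS = (
    (0.126, 0.534), (0.210, 0.943), (0.756, 0.943), (0.840, 0.597), (0.462, 0.472)
)


def default_roi_polygon(shape: tuple[int, int]) -> tuple[tuple[float, float], ...]:
    """The default flank pentagon scaled to a concrete frame shape."""
    return tuple(
        (fr * (shape[0] - 1), fc * (shape[1] - 1)) for fr, fc in DEFAULT_ROI_FRACTIONS
    )


@dataclass(frozen=True)
class ThermalFrame:
    """One false-color thermogram with its ROI mask and metadata."""

    image: np.ndarray          # (N, M, 3) uint8
    mask: np.ndarray           # (N, M) bool
    mare_id: str
    group: str                 # "NP" or "P"
    subgroup: str              # "A", "B" or "-"
    month: int | None          # gestation month, None for non-pregnant
    session: int               # 1-based imaging session

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3 or self.image.dtype != np.uint8:
            raise ValueError("image must be (N, M, 3) uint8")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask shape must match the image")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def generate_temperature_field(
    shape: tuple[int, int],
    effect: EffectModel,
    month: int | None,
    rng_seed: int,
) -> np.ndarray:
    """Surface-temperature field in °C for one frame.

    base + smooth correlated noise + (pregnant only) elliptical Gaussian
    hot spot + fine-grain noise, clipped to the camera range; month None
    means non-pregnant.  Deterministic for a fixed seed.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ValueError(f"frame shape must be at least 64×64, got {shape}")
    rng = np.random.default_rng(rng_seed)
    field_t = np.full(shape, effect.base_temp, dtype=np.float64)

    if effect.smooth_noise_sd > 0:
        white = rng.standard_normal(shape)
        smooth = gaussian_filter(white, sigma=effect.smooth_corr_len)
        sd = smooth.std()
        if sd > 0:
            field_t += smooth * (effect.smooth_noise_sd / sd)

    amp = effect.hotspot_amp(month)
    if amp > 0:
        radius = effect.hotspot_radius(month)
        cr = effect.hotspot_center_frac[0] * shape[0]
        cc = effect.hotspot_center_frac[1] * shape[1]
        if effect.center_jitter > 0:
            cr += rng.uniform(-effect.center_jitter, effect.center_jitter)
            cc += rng.uniform(-effect.center_jitter, effect.center_jitter)
        rows, cols = np.ogrid[: shape[0], : shape[1]]
        field_t += amp * np.exp(
            -(
                (rows - cr) ** 2 / (2 * radius**2)
                + (cols - cc) ** 2 / (2 * (effect.hotspot_aspect * radius) ** 2)
            )
        )

    het = effect.heterogeneity_sd(month)
    if het > 0:
        field_t += het * rng.standard_normal(shape)

    return np.clip(field_t, *effect.camera_range)


def render_thermal_image(
    field: np.ndarray,
    palette: PaletteSpec = DEFAULT_PALETTE,
    camera_range: tuple[float, float] = (10.0, 40.0),
) -> np.ndarray:
    """False-color 8-bit RGB rendering of a temperature field."""
    tmin, tmax = camera_range
    if not tmin < tmax:
        raise ValueError(f"degenerate temperature range {camera_range}")
    t_norm = np.clip((np.asarray(field, dtype=np.float64) - tmin) / (tmax - tmin), 0.0, 1.0)
    rgb = palette.lookup(t_norm)
    return (np.floor(np.abs(rgb) + 0.5) * np.sign(rgb)).clip(0, 255).astype(np.uint8)


def _point_in_polygon(point: tuple[float, float], vertices) -> bool:
    """Even-odd ray-casting test, used for both validation and small inputs."""
    r, c = point
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_cross = c1 + (r - r1) / (r2 - r1) * (c2 - c1)
            if c < c_cross:
                inside = not inside
    return inside


def generate_roi_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Binary mask: True where the pixel center lies inside the polygon.

    Containment uses the even-odd rule on pixel centers (row + 0, col +
    0 — integer coordinates are the centers in this package's 0-based
    (row, col) convention).  A polygon enclosing no pixel center (e.g.
    degenerate/collinear vertices) is an error.
    """
    vertices = [(float(r), float(c)) for r, c in polygon]
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    for r, c in vertices:
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise ValueError(f"vertex ({r}, {c}) outside image bounds {shape}")
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    rows = rows.astype(np.float64)
    cols = cols.astype(np.float64)
    inside = np.zeros(shape, dtype=bool)
    n = len(vertices)
    for i in range(n):  # vectorized even-odd crossing count over all pixel centers
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        crosses = (r1 > rows) != (r2 > rows)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_cross = c1 + (rows - r1) / (r2 - r1) * (c2 - c1)
        inside ^= crosses & (cols < c_cross)
    if not inside.any():
        raise ValueError("polygon encloses no pixel center (degenerate ROI)")
    return inside


def _mare_table(design: CohortDesign) -> list[tuple[str, str, str, tuple[int, ...] | None]]:
    mares: list[tuple[str, str, str, tuple[int, ...] | None]] = []
    for i in range(design.n_nonpregnant):
        mares.append((f"NP{i + 1:02d}", "NP", "-", None))
    for i in range(design.n_pregnant_per_subgroup):
        mares.append((f"PA{i + 1:02d}", "P", "A", design.months_subgroup_a))
    for i in range(design.n_pregnant_per_subgroup):
        mares.append((f"PB{i + 1:02d}", "P", "B", design.months_subgroup_b))
    return mares


def generate_cohort(
    design: CohortDesign = CohortDesign(),
    effect: EffectModel = EffectModel(),
    palette: PaletteSpec = DEFAULT_PALETTE,
    roi_polygon=None,
) -> tuple[list[ThermalFrame], pd.DataFrame]:
    """Full synthetic cohort: frames plus a tidy metadata table.

    Per-mare biological variation is a Gaussian random intercept on the
    base temperature; an optional per-session ambient drift is shared by
    all mares imaged in that session.  The metadata table carries one
    row per frame (mare_id, group, subgroup, month, session).
    """
    shape = design.frame_shape
    if roi_polygon is None:
        roi_polygon = default_roi_polygon(shape)
    mask = generate_roi_mask(shape, roi_polygon)
    root = np.random.SeedSequence(design.seed)
    n_sessions = max(
        design.n_sessions_nonpregnant,
        len(design.months_subgroup_a),
        len(design.months_subgroup_b),
    )
    drift_rng = np.random.default_rng(root.spawn(1)[0])
    drifts = (
        drift_rng.normal(0.0, effect.ambient_drift_sd, size=n_sessions)
        if effect.ambient_drift_sd > 0
        else np.zeros(n_sessions)
    )

    frames: list[ThermalFrame] = []
    rows = []
    mares = _mare_table(design)
    mare_seeds = root.spawn(len(mares))
    for (mare_id, group, subgroup, months), mare_seq in zip(mares, mare_seeds):
        mare_rng = np.random.default_rng(mare_seq)
        intercept = mare_rng.normal(0.0, effect.mare_intercept_sd)
        session_months: list[tuple[int, int | None]]
        if months is None:
            session_months = [(s + 1, None) for s in range(design.n_sessions_nonpregnant)]
        else:
            session_months = [(s + 1, m) for s, m in enumerate(months)]
        frame_seeds = mare_rng.integers(0, 2**31 - 1, size=len(session_months))
        for (session, month), fseed in zip(session_months, frame_seeds):
            eff = replace(effect, base_temp=effect.base_temp + intercept + drifts[session - 1])
            field_t = generate_temperature_field(shape, eff, month, int(fseed))
            image = render_thermal_image(field_t, palette, effect.camera_range)
            frames.append(
                ThermalFrame(
                    image=image, mask=mask, mare_id=mare_id, group=group,
                    subgroup=subgroup, month=month, session=session,
                )
            )
            rows.append((mare_id, group, subgroup, month, session))
    metadata = pd.DataFrame(rows, columns=["mare_id", "group", "subgroup", "month", "session"])
    metadata["month"] = metadata["month"].astype("Int64")
    return frames, metadata
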