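"""Synthetic study design and false-color thermogram generator.

The original imaging campaign — 12 horses each ridden by 6 riders split
into light (L), moderate (M) and heavy (H) bodyweight groups, imaged
before and after a standardized exercise test, 144 thermograms in all —
is emulated here so every downstream stage can be exercised end to end.

The texture model is deliberately minimal: a temperature field is a
smooth background (Gaussian-filtered white noise with a fixed correlation
length) plus i.i.d. Gaussian "irregularity" noise whose amplitude depends
on session and rider group, with a warm-region gain applied inside the
ROI masks after exercise.  Irregularity rises post-exercise in every
group and rises with rider group after exercise, so texture-entropy
measures have a planted, monotone signal to recover.  The field is
rendered to 8-bit RGB through a fixed blue-to-green-to-red lookup table,
putting the warm signal predominantly in the red channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .detection import bodyweight_ratio
from .errors import ConfigurationError, DimensionError
from .image_prep import ROISpec

__all__ = [
    "StudyDesign",
    "TextureModel",
    "SyntheticImage",
    "make_design",
    "generate_thermogram",
    "render_false_color",
    "default_rois",
    "GROUPS",
    "SESSIONS",
]

GROUPS = ("L", "M", "H")
SESSIONS = ("pre", "post")

# Printed group-mean rider bodyweights are 59.0 / 76.0 / 91.5 kg with two
# riders per group; the default pairs below hit those means exactly.
_DEFAULT_RIDERS = (
    ("rider1", "L", 58.0, 165.0),
    ("rider2", "L", 60.0, 168.0),
    ("rider3", "M", 75.0, 166.0),
    ("rider4", "M", 77.0, 170.0),
    ("rider5", "H", 91.0, 164.0),
    ("rider6", "H", 92.0, 172.0),
)


@dataclass
class StudyDesign:
    """Configuration of the simulated imaging campaign.

    ``riders`` is a list of (rider_id, group, bodyweight kg, height cm).
    Horse bodyweights are drawn around ``horse_weight_mean`` with SD
    ``horse_weight_sd``; saddle weights uniformly within
    ``saddle_weight_range``.  The default configuration yields
    12 horses x 6 riders x 2 sessions = 144 rows.
    """

    n_horses: int = 12
    riders: tuple = _DEFAULT_RIDERS
    horse_weight_mean: float = 566.7
    horse_weight_sd: float = 13.7
    saddle_weight_range: tuple[float, float] = (4.1, 4.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_horses < 1:
            raise ConfigurationError("need at least one horse")
        counts = {g: 0 for g in GROUPS}
        for rider in self.riders:
            if len(rider) != 4:
                raise ConfigurationError(f"malformed rider spec: {rider!r}")
            group = rider[1]
            if group not in counts:
                raise ConfigurationError(f"unknown rider group {group!r}")
            counts[group] += 1
        populated = {g: c for g, c in counts.items() if c > 0}
        if not populated:
            raise ConfigurationError("need at least one rider")
        if len(set(populated.values())) != 1:
            raise ConfigurationError(f"populated rider groups must be balanced, got {counts}")


def make_design(config: StudyDesign | None = None) -> pd.DataFrame:
    """Enumerate the (horse, rider, session) design table.

    Each horse is paired with every rider exactly once per session.  The
    rider:horse bodyweight ratio column is computed from the sampled
    rider, saddle and horse weights.  Deterministic given ``config.seed``.
    """
    config = config or StudyDesign()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    horse_ids = [f"horse{h + 1:02d}" for h in range(config.n_horses)]
    horse_kg = config.horse_weight_mean + config.horse_weight_sd * rng.standard_normal(
        config.n_horses
    )
    lo, hi = config.saddle_weight_range
    saddle_kg = rng.uniform(lo, hi, config.n_horses)
    rows = []
    for h, horse in enumerate(horse_ids):
        for rider_id, group, rider_kg, rider_cm in config.riders:
            for session in SESSIONS:
                rows.append(
                    {
                        "horse": horse,
                        "rider": rider_id,
                        "group": group,
                        "session": session,
                        "rider_kg": float(rider_kg),
                        "rider_cm": float(rider_cm),
                        "saddle_kg": round(float(saddle_kg[h]), 2),
                        "horse_kg": round(float(horse_kg[h]), 1),
                    }
                )
    design = pd.DataFrame(rows)
    design["ratio_pct"] = [
        bodyweight_ratio(r, s, h)
        for r, s, h in zip(design.rider_kg, design.saddle_kg, design.horse_kg)
    ]
    return design


def _default_amplitude(session: str, group: str) -> float:
    if session == "pre":
        return 0.5
    return {"L": 1.0, "M": 1.5, "H": 2.0}[group]


@dataclass
class TextureModel:
    """Parameters of the planted-texture temperature field.

    Amplitudes are in the same arbitrary intensity units as the
    background SD; the defaults give a clear but unsaturated entropy
    separation between sessions and groups.
    """

    base_temperature: float = 30.0
    smooth_field_scale: float = 8.0
    background_sd: float = 4.0
    irregularity_amplitude: callable = field(default=None)  # (session, group) -> float
    hot_region_gain: float = 1.2
    colormap: str = "thermal"

    def __post_init__(self) -> None:
        if self.irregularity_amplitude is None:
            self.irregularity_amplitude = _default_amplitude


@dataclass
class SyntheticImage:
    """One rendered thermogram with its ground-truth field and metadata."""

    rgb: np.ndarray
    temperature_field: np.ndarray
    roi_specs: list[ROISpec]
    metadata: dict


def _thermal_lut() -> np.ndarray:
    """256-entry blue->green->red lookup table (8-bit RGB rows).

    Red is non-decreasing and blue non-increasing in temperature, so the
    hottest pixel always has red > blue and the coldest the reverse.
    """
    t = np.linspace(0.0, 1.0, 256)
    red = np.clip((t - 1 / 3) / (2 / 3), 0, 1)
    green = 1.0 - np.abs(2 * t - 1.0)
    blue = np.clip((2 / 3 - t) / (2 / 3), 0, 1)
    lut = np.stack([red, green, blue], axis=1)
    return np.floor(lut * 255 + 0.5).astype(np.uint8)


_LUT = _thermal_lut()


def render_false_color(temperature_field: np.ndarray, colormap: str = "thermal") -> np.ndarray:
    """Map a temperature field to an 8-bit false-color RGB image.

    The field is min-max normalized per image and sent through the fixed
    rainbow-type lookup table.  A constant field has zero range; by
    documented rule it renders uniformly at the middle of the colormap.
    """
    if colormap != "thermal":
        raise ConfigurationError(f"unknown colormap {colormap!r}")
    f = np.asarray(temperature_field, dtype=float)
    if not np.all(np.isfinite(f)):
        raise DimensionError("temperature field contains non-finite values")
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        idx = np.full(f.shape, 128, dtype=np.intp)
    else:
        t = (f - lo) / (hi - lo)
        idx = np.floor(t * 255 + 0.5).astype(np.intp)
    return _LUT[idx]


def default_rois(size: tuple[int, int] = (96, 160), roi_size: int = 64) -> list[ROISpec]:
    """Two square ROIs (withers left, thoracic spine right) inside the image."""
    h, w = size
    margin_y = (h - roi_size) // 2
    gap = (w - 2 * roi_size) // 3
    if margin_y < 0 or gap < 0:
        raise DimensionError(f"image {h}x{w} cannot hold two {roi_size}x{roi_size} ROIs")
    return [
        ROISpec("ROI1_withers", gap, margin_y, gap + roi_size, margin_y + roi_size),
        ROISpec(
            "ROI2_thoracic",
            2 * gap + roi_size,
            margin_y,
            2 * gap + 2 * roi_size,
            margin_y + roi_size,
        ),
    ]


def generate_thermogram(
    design_row: dict | pd.Series,
    texture_model: TextureModel | None = None,
    size: tuple[int, int] = (96, 160),
    roi_specs: list[ROISpec] | None = None,
    seed: int = 0,
) -> SyntheticImage:
    """Render one synthetic thermogram for a design-table row.

    The temperature field is the smooth background plus i.i.d. Gaussian
    irregularity noise at the amplitude dictated by (session, group);
    post-exercise rows get ``hot_region_gain`` applied inside both ROI
    masks.  Bit-identical output for identical (design_row, seed).
    """
    model = texture_model or TextureModel()
    h, w = size
    rois = roi_specs if roi_specs is not None else default_rois(size)
    for roi in rois:
        if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > w or roi.y1 > h:
            raise DimensionError(f"ROI {roi.label!r} outside image {h}x{w}")
    session = design_row["session"]
    group = design_row["group"]
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    background = gaussian_filter(rng.standard_normal((h, w)), model.smooth_field_scale)
    bg_sd = background.std()
    if bg_sd > 0:
        background *= model.background_sd / bg_sd
    field = model.base_temperature + background
    amp = float(model.irregularity_amplitude(session, group))
    if amp < 0:
        raise ConfigurationError("irregularity amplitude must be non-negative")
    if amp > 0:
        field = field + amp * rng.standard_normal((h, w))
    else:
        rng.standard_normal((h, w))  # keep the stream position session-independent
    if session == "post":
        for roi in rois:
            field[roi.y0 : roi.y1, roi.x0 : roi.x1] *= model.hot_region_gain
    rgb = render_false_color(field, model.colormap)
    metadata = dict(design_row) if not isinstance(design_row, dict) else dict(design_row)
    return SyntheticImage(rgb=rgb, temperature_field=field, roi_specs=rois, metadata=metadata)
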