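"""Image loading, rectangular ROI extraction, and color decomposition.

Thermal images arrive as 8-bit RGB false-color renderings.  Each
rectangular region of interest (ROI 1 = withers, ROI 2 = thoracic spine)
is cut out and decomposed into four intensity components — grayscale
plus the raw red, green and blue channels — which are what the entropy
and GLCM stages consume.

Coordinates are 0-based and half-open: an ROI spans rows [y0, y1) and
columns [x0, x1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DimensionError, EquithermError

__all__ = [
    "ROISpec",
    "ComponentSet",
    "load_image",
    "extract_roi",
    "decompose_components",
    "read_roi_specs",
    "write_roi_specs",
    "COMPONENTS",
]

#: Component names in extraction order.
COMPONENTS = ("gray", "red", "green", "blue")

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class ROISpec:
    """A labeled axis-aligned rectangle, 0-based half-open."""

    label: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise DimensionError(
                f"ROI {self.label!r}: need x1 > x0 and y1 > y0, got "
                f"({self.x0},{self.y0},{self.x1},{self.y1})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.y1 - self.y0, self.x1 - self.x0)


@dataclass
class ComponentSet:
    """Grayscale plus raw red/green/blue channel matrices of one ROI."""

    gray: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in COMPONENTS:
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        return ((name, getattr(self, name)) for name in COMPONENTS)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/BMP/TIFF image as an H x W x 3 uint8 array.

    16-bit inputs are rescaled to 8 bits by integer division by 257
    (65535 -> 255).  Grayscale and paletted files are rejected: the
    pipeline needs the original false-color channels.
    """
    path = Path(path)
    if not path.exists():
        raise EquithermError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.array(im)
    except (UnidentifiedImageError, ValueError, OSError) as exc:
        raise EquithermError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise EquithermError(
            f"{path}: expected a 3-channel RGB image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint16:
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise EquithermError(f"{path}: unsupported dtype {arr.dtype}")
    return arr


def extract_roi(rgb: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Cut the ROI rectangle out of an H x W x 3 image."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 image, got shape {rgb.shape}")
    h, w = rgb.shape[:2]
    if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > w or roi.y1 > h:
        raise DimensionError(
            f"ROI {roi.label!r} ({roi.x0},{roi.y0},{roi.x1},{roi.y1}) "
            f"outside image bounds {w}x{h}"
        )
    return rgb[roi.y0 : roi.y1, roi.x0 : roi.x1, :]


def decompose_components(rgb: np.ndarray) -> ComponentSet:
    """Split an RGB patch into gray/red/green/blue intensity matrices.

    Grayscale is BT.601 luma, rounded half away from zero:
    round(0.299 R + 0.587 G + 0.114 B).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 patch, got shape {rgb.shape}")
    luma = rgb.astype(float) @ _LUMA
    gray = np.floor(luma + 0.5).astype(np.uint8)
    return ComponentSet(
        gray=gray,
        red=rgb[:, :, 0].copy(),
        green=rgb[:, :, 1].copy(),
        blue=rgb[:, :, 2].copy(),
    )


def write_roi_specs(path: str | Path, specs: dict[str, list[ROISpec]]) -> None:
    """Write ROI rectangles as JSON: [{"image", "rois": [...]}, ...]."""
    payload = [
        {
            "image": name,
            "rois": [
                {"label": r.label, "x0": r.x0, "y0": r.y0, "x1": r.x1, "y1": r.y1}
                for r in rois
            ],
        }
        for name, rois in specs.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_roi_specs(path: str | Path) -> dict[str, list[ROISpec]]:
    payload = json.loads(Path(path).read_text())
    return {
        entry["image"]: [
            ROISpec(
                label=r["label"], x0=r["x0"], y0=r["y0"], x1=r["x1"], y1=r["y1"]
            )
            for r in entry["rois"]
        ]
        for entry in payload
    }
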