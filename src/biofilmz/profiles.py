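"""Extraction of ROI line profiles from xz-section images.

Emulates the microscope software's histogram export: the xz-section is
split laterally into ``n_roi`` equal strips and each strip's mean
intensity per depth row becomes one :class:`~biofilmz.profile.ZProfile`,
so the analysis can run end-to-end from TIFF images instead of CSV
exports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .profile import ProfileSet, ZProfile

__all__ = ["SectionImage", "extract_profiles", "read_stack"]


@dataclass
class SectionImage:
    """A single grayscale xz-section: rows are depth (z), columns lateral (x)."""

    pixels: np.ndarray
    pixel_size_x_um: float
    pixel_size_z_um: float
    image_id: str = "section"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if self.pixels.shape[0] < 3:
            raise ValueError("need at least 3 z rows")
        if self.pixel_size_x_um <= 0 or self.pixel_size_z_um <= 0:
            raise ValueError("pixel sizes must be > 0")

    @property
    def width_um(self) -> float:
        return self.pixels.shape[1] * self.pixel_size_x_um


def extract_profiles(
    image: SectionImage,
    n_roi: int = 10,
    statistic: str = "mean",
) -> ProfileSet:
    """Split the section into ``n_roi`` vertical strips, one profile each.

    Columns are partitioned into equal-width strips left to right (any
    remainder columns join the last strip); the profile value at each
    depth is the mean (or median) pixel intensity across the strip's
    columns. z positions are row index × pixel_size_z_um.
    """
    if n_roi < 1:
        raise ValueError("n_roi must be >= 1")
    width = image.pixels.shape[1]
    if n_roi > width:
        raise ValueError(f"n_roi={n_roi} exceeds image width {width} px")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    agg = np.mean if statistic == "mean" else np.median

    strip = width // n_roi
    z = np.arange(image.pixels.shape[0], dtype=float) * image.pixel_size_z_um
    profiles = []
    for k in range(n_roi):
        lo = k * strip
        hi = (k + 1) * strip if k < n_roi - 1 else width
        vals = agg(image.pixels[:, lo:hi].astype(float), axis=1)
        profiles.append(
            ZProfile(roi_id=k + 1, image_id=image.image_id, z=z, intensity=vals)
        )
    return ProfileSet(
        profiles=profiles,
        image_width_um=image.width_um,
        roi_width_um=image.width_um / n_roi,
    )


def _pixel_size_from_tags(tif: "tifffile.TiffFile") -> tuple[Optional[float], Optional[float]]:
    """Pixel sizes in µm from TIFF resolution tags (pixels per unit)."""
    page = tif.pages[0]
    tags = page.tags
    try:
        unit = tags["ResolutionUnit"].value
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
    except KeyError:
        return None, None
    # value may be a (num, den) rational
    def as_float(v):
        if isinstance(v, tuple):
            num, den = v
            return num / den if den else None
        return float(v)

    xres, yres = as_float(xres), as_float(yres)
    if not xres or not yres:
        return None, None
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, centimetre
    if unit_um is None:
        return None, None
    return unit_um / xres, unit_um / yres


def read_stack(
    path,
    pixel_size_x_um: Optional[float] = None,
    pixel_size_z_um: Optional[float] = None,
    channel: Optional[int] = None,
) -> SectionImage:
    """Read one grayscale xz-section from a TIFF file.

    Resolution tags, when present, provide the pixel sizes (x from
    XResolution, z from YResolution); explicit arguments override them and
    are required when tags are absent. Multi-channel images need an
    explicit ``channel`` index (for stained biofilms the quantitative
    channel is the all-cell stain, e.g. Syto9/green).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_x, tag_z = _pixel_size_from_tags(tif)

    if data.ndim == 3:
        # channel axis: smallest dimension, commonly last (h, w, c) or first (c, h, w)
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel image; select a channel explicitly"
            )
        axis = int(np.argmin(data.shape))
        data = np.take(data, channel, axis=axis)
    elif data.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {data.ndim}")

    px = pixel_size_x_um if pixel_size_x_um is not None else tag_x
    pz = pixel_size_z_um if pixel_size_z_um is not None else tag_z
    if px is None or pz is None:
        raise ValueError(
            f"{path}: pixel size not in TIFF tags; pass pixel_size_x_um/pixel_size_z_um"
        )
    return SectionImage(
        pixels=data, pixel_size_x_um=px, pixel_size_z_um=pz, image_id=path.stem
    )
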