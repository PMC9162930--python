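"""Core data containers for depth-resolved fluorescence line profiles.

A :class:`ZProfile` holds one region of interest (ROI): fluorescence
intensity as a function of depth ``z`` within a vertical strip of a
confocal xz-section. A :class:`ProfileSet` groups the profiles of one or
more z-images, together with the physical geometry (image width, ROI
width) when known.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = ["Orientation", "ZProfile", "ProfileSet"]


class Orientation:
    """Where the electrode sits on the z axis of a profile.

    ``ELECTRODE_LOW_Z`` is the acquisition convention for inverted-stage
    confocal imaging of electrode-grown biofilms: the first acquired plane
    is at (or inside) the electrode, the last is in the bulk buffer.
    """

    ELECTRODE_LOW_Z = "electrode_low_z"
    ELECTRODE_HIGH_Z = "electrode_high_z"

    CHOICES = (ELECTRODE_LOW_Z, ELECTRODE_HIGH_Z)


@dataclass
class ZProfile:
    """Fluorescence intensity versus depth for one ROI.

    Parameters
    ----------
    roi_id
        Small integer label, 1-based, ordered by lateral position.
    image_id
        Identifier of the z-image the ROI belongs to.
    z
        Depth positions in µm, strictly monotonic.
    intensity
        Fluorescence in arbitrary detector units, same length as ``z``,
        finite and non-negative.
    orientation
        Side of the z axis the electrode is on; ``None`` defers to the
        analysis configuration.
    """

    roi_id: int
    image_id: str
    z: np.ndarray
    intensity: np.ndarray
    orientation: Optional[str] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.z.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("z and intensity must be 1-D")
        if len(self.z) != len(self.intensity):
            raise ValueError(
                f"z and intensity lengths differ: {len(self.z)} vs {len(self.intensity)}"
            )
        if len(self.z) < 3:
            raise ValueError("profile needs at least 3 samples")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotonic")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.orientation is not None and self.orientation not in Orientation.CHOICES:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.z)

    @property
    def z_step_um(self) -> float:
        """Median |Δz| of the sampling grid."""
        return float(np.median(np.abs(np.diff(self.z))))

    @property
    def z_range_um(self) -> float:
        return float(abs(self.z[-1] - self.z[0]))


@dataclass
class ProfileSet:
    """Profiles of one or more z-images plus optional geometry metadata."""

    profiles: list = field(default_factory=list)
    image_width_um: Optional[float] = None
    roi_width_um: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict = {}
        for p in self.profiles:
            key = p.image_id
            ids = seen.setdefault(key, set())
            if p.roi_id in ids:
                raise ValueError(f"duplicate roi_id {p.roi_id} in image {key!r}")
            ids.add(p.roi_id)
        for image_id in seen:
            grids = [p.z for p in self.profiles if p.image_id == image_id]
            for g in grids[1:]:
                if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
                    raise ValueError(f"profiles of image {image_id!r} have differing z grids")
        if self.image_width_um is not None and self.roi_width_um is not None:
            n = len(self.image_ids()) and max(
                len([p for p in self.profiles if p.image_id == i]) for i in self.image_ids()
            )
            if n and not np.isclose(self.roi_width_um, self.image_width_um / n):
                raise ValueError("roi_width_um inconsistent with image_width_um / n_roi")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[ZProfile]:
        return iter(self.profiles)

    def image_ids(self) -> list:
        out = []
        for p in self.profiles:
            if p.image_id not in out:
                out.append(p.image_id)
        return out

    def for_image(self, image_id: str) -> list:
        return [p for p in self.profiles if p.image_id == image_id]
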