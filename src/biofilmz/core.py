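"""Boundary detection and thickness measurement on single ROI profiles.

The measurement model: a fluorescently stained biofilm sits on an
electrode; a line profile of intensity versus depth shows a bright slab
(the biofilm) between two dim background regions with *different* mean
levels — reflections and autofluorescence at the electrode side, buffer
plus free-floating (planktonic) cells above the biofilm. A sample belongs
to the biofilm when its intensity exceeds ``multiplier × mean(background)``
for the background of *its* side of the profile maximum.

The lower boundary (electrode/biofilm interface) is the first sample,
scanning away from the electrode, that exceeds the electrode-side
threshold. The upper boundary (biofilm/buffer interface) is the end of
the contiguous above-threshold run that contains the profile maximum:
above-threshold samples separated from that run by at least one
sub-threshold sample are planktonic-cell artifacts and are rejected, so
they never extend the measured thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Set

import numpy as np

from .profile import Orientation, ZProfile

__all__ = [
    "BackgroundEstimate",
    "ThresholdConfig",
    "Boundaries",
    "ThicknessResult",
    "find_peak",
    "estimate_background",
    "find_lower_boundary",
    "find_upper_boundary",
    "roi_thickness",
    "FLAG_NO_SIGNAL",
    "FLAG_SATURATED",
    "FLAG_SPIKE_REJECTED",
    "FLAG_BOUNDARY_AT_EDGE",
]

FLAG_NO_SIGNAL = "no_signal"
FLAG_SATURATED = "saturated"
FLAG_SPIKE_REJECTED = "spike_rejected"
FLAG_BOUNDARY_AT_EDGE = "boundary_at_edge"

SIDE_ELECTRODE = "electrode"
SIDE_BUFFER = "buffer"


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean background level on one side of the profile maximum."""

    side: str
    mean_intensity: float
    n_samples: int
    window_fraction: float

    def __post_init__(self) -> None:
        if self.mean_intensity < 0:
            raise ValueError("mean_intensity must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass(frozen=True)
class ThresholdConfig:
    """Tunable parameters of the thresholding step.

    multiplier
        Threshold = multiplier × mean background. 3 is the default; 2 is
        the documented fallback for substrates with bright background
        fluorescence (e.g. some electrode coatings).
    background_window_fraction
        Fraction of the profile, taken from each end, used to estimate
        that side's background (at least one sample is always used).
    background_mode
        ``"window"``: plain mean over the edge window. ``"iterative"``:
        start from the window mean, then re-estimate over all samples of
        that side below the implied threshold until a fixed point.
    require_contiguity_below
        If true (default), the lower boundary is the start of the
        contiguous above-threshold run containing the peak — the
        artifact-rejection principle of the upper boundary applied to the
        electrode side, where isolated above-threshold noise samples in
        the background would otherwise pull the boundary toward the
        electrode. Set false for plain first-exceedance scanning from
        the electrode edge.
    orientation
        Default electrode side when a profile does not carry its own.
    saturation_level
        Detector full scale; intensities at or above it flag the result
        ``saturated``. ``None`` disables the check.
    """

    multiplier: float = 3.0
    background_window_fraction: float = 0.10
    background_mode: str = "window"
    require_contiguity_below: bool = True
    orientation: str = Orientation.ELECTRODE_LOW_Z
    saturation_level: Optional[float] = None

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be > 0")
        if not 0 < self.background_window_fraction <= 0.5:
            raise ValueError("background_window_fraction must be in (0, 0.5]")
        if self.background_mode not in ("window", "iterative"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.orientation not in Orientation.CHOICES:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def with_(self, **kw) -> "ThresholdConfig":
        return replace(self, **kw)


@dataclass
class Boundaries:
    """Detected biofilm extent, indices into the original profile.

    ``lower``/``upper`` are ordered by z (lower_z <= upper_z); for the
    default orientation the lower boundary is the electrode interface.
    """

    id_max: int
    lower_idx: Optional[int] = None
    upper_idx: Optional[int] = None
    lower_z: Optional[float] = None
    upper_z: Optional[float] = None
    lower_found: bool = False
    upper_found: bool = False


@dataclass
class ThicknessResult:
    """Everything measured on one ROI, intermediate values included."""

    roi_id: int
    image_id: str
    thickness_um: Optional[float]
    boundaries: Boundaries
    threshold_left: float
    threshold_right: float
    background_electrode: float
    background_buffer: float
    flags: Set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return self.thickness_um is not None


class BoundaryHit(NamedTuple):
    index: Optional[int]
    found: bool
    at_edge: bool = False
    spike_rejected: bool = False


def find_peak(profile) -> int:
    """Index of the profile maximum; ties break to the smallest index.

    Accepts a :class:`~biofilmz.profile.ZProfile` or a bare intensity array.
    """
    intensity = getattr(profile, "intensity", profile)
    return int(np.argmax(intensity))


def _window_size(n: int, fraction: float) -> int:
    return max(1, int(n * fraction))


def _coarse_cut(intensity: np.ndarray) -> Optional[float]:
    """Coarse background/signal cut at min + ¼ of the intensity range.

    For a detectable biofilm the background must sit below one third of
    the slab amplitude (or no 3×-background threshold can separate them),
    while planktonic specks are at most a few times the slab amplitude;
    a quarter of the min-to-max range then always falls strictly between
    background and slab. The cut only selects *support* samples for the
    background mean and the run anchor — the actual boundary thresholds
    remain multiplier × mean(background). Returns ``None`` for a flat
    profile.
    """
    lo, hi = float(np.min(intensity)), float(np.max(intensity))
    if hi <= lo:
        return None
    return lo + 0.25 * (hi - lo)


def estimate_background(
    intensity: np.ndarray,
    side: str,
    id_max: int,
    config: ThresholdConfig = ThresholdConfig(),
    support: Optional[np.ndarray] = None,
) -> BackgroundEstimate:
    """Mean background on one side of the peak.

    ``intensity`` must already be oriented with the electrode at index 0.
    The window sits at the profile end belonging to the side (electrode:
    first samples, buffer: last samples) and is clipped so it never
    includes the peak — unless the peak is at that very edge, in which
    case a single-sample window is used (the result will carry a
    boundary-at-edge flag downstream anyway).

    ``support``, when given, is a boolean mask of plausible background
    samples (see :func:`roi_thickness`); the window then consists of the
    outermost ``window_fraction`` support samples of that side, so bright
    structures inside the nominal window (slab reaching into it, drifting
    planktonic cells) cannot inflate the mean.
    """
    n = len(intensity)
    if n < 3:
        raise ValueError("profile too short for background estimation")
    if side not in (SIDE_ELECTRODE, SIDE_BUFFER):
        raise ValueError(f"unknown side {side!r}")
    k = _window_size(n, config.background_window_fraction)
    window = None
    if support is not None:
        if side == SIDE_ELECTRODE:
            idx = np.flatnonzero(support[:id_max])
            if not len(idx):
                # signal touches the electrode edge: no background on this
                # side at all; borrow the dimmest support samples available
                idx = np.flatnonzero(support)
            if len(idx):
                window = intensity[idx[:k]]
        else:
            idx = id_max + 1 + np.flatnonzero(support[id_max + 1:])
            if not len(idx):
                idx = np.flatnonzero(support)
            if len(idx):
                window = intensity[idx[-k:]]
    if window is None:  # plain edge window
        if side == SIDE_ELECTRODE:
            k = min(k, max(1, id_max))
            window = intensity[:k]
        else:
            k = min(k, max(1, n - 1 - id_max))
            window = intensity[n - k:]
    if side == SIDE_ELECTRODE:
        side_samples = intensity[:id_max] if id_max > 0 else intensity[:1]
    else:
        side_samples = intensity[id_max + 1:] if id_max < n - 1 else intensity[-1:]
    mean = float(np.mean(window))
    n_used = int(len(window))

    if config.background_mode == "iterative":
        # refine over all sub-threshold samples of this side to a fixed point
        for _ in range(100):
            below = side_samples[side_samples < config.multiplier * mean]
            if len(below) == 0:
                break
            new = float(np.mean(below))
            if np.isclose(new, mean, rtol=1e-12, atol=1e-12):
                mean = new
                n_used = int(len(below))
                break
            mean, n_used = new, int(len(below))

    return BackgroundEstimate(
        side=side,
        mean_intensity=mean,
        n_samples=n_used,
        window_fraction=config.background_window_fraction,
    )


def _anchor_peak(intensity: np.ndarray, cut: float, peak: int) -> int:
    """Peak index of the above-cut run with the largest summed signal.

    The biofilm slab dwarfs any planktonic speck in *integrated*
    intensity even when it loses on raw brightness, so the boundary
    search pivots on the peak of the heaviest run rather than the raw
    argmax. For speck-free profiles this is the argmax itself. Falls
    back to ``peak`` when nothing exceeds the cut.
    """
    n = len(intensity)
    above = intensity > cut
    if not above.any():
        return peak
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)
    best_slice = max(
        (slice(s, e) for s, e in zip(starts, ends)),
        key=lambda sl: float(intensity[sl].sum()),
    )
    return best_slice.start + int(np.argmax(intensity[best_slice]))


def find_lower_boundary(
    intensity: np.ndarray,
    threshold: float,
    id_max: int,
    require_contiguity: bool = False,
) -> BoundaryHit:
    """Electrode/biofilm interface on an electrode-at-index-0 profile.

    Default rule: the first index, scanning from the electrode edge
    toward the peak, whose intensity strictly exceeds ``threshold``.
    With ``require_contiguity`` the start of the contiguous
    above-threshold run containing the peak is returned instead.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if require_contiguity:
        if not intensity[id_max] > threshold:
            return BoundaryHit(None, False)
        i = id_max
        while i - 1 >= 0 and intensity[i - 1] > threshold:
            i -= 1
        return BoundaryHit(i, True, at_edge=(i == 0))
    for i in range(id_max + 1):
        if intensity[i] > threshold:
            return BoundaryHit(i, True, at_edge=(i == 0))
    return BoundaryHit(None, False)


def find_upper_boundary(
    intensity: np.ndarray,
    threshold: float,
    id_max: int,
) -> BoundaryHit:
    """Biofilm/buffer interface: end of the above-threshold run at the peak.

    Walking from the peak toward the buffer, the boundary is the last
    consecutive sample above ``threshold``. Any above-threshold samples
    beyond the first sub-threshold gap are planktonic-cell artifacts and
    are reported via ``spike_rejected`` without moving the boundary.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = len(intensity)
    if not intensity[id_max] > threshold:
        return BoundaryHit(None, False)
    j = id_max
    while j + 1 < n and intensity[j + 1] > threshold:
        j += 1
    spike = bool(np.any(intensity[j + 1:] > threshold))
    return BoundaryHit(j, True, at_edge=(j == n - 1), spike_rejected=spike)


def roi_thickness(
    profile: ZProfile,
    config: ThresholdConfig = ThresholdConfig(),
) -> ThicknessResult:
    """Full per-ROI measurement: peak, backgrounds, boundaries, thickness.

    The profile is internally normalised to electrode-at-low-index;
    reported indices and z positions refer to the original ordering, with
    the boundary pair sorted by z. ``thickness_um`` is ``None`` (never 0)
    when either boundary is not found, and the result is flagged
    ``no_signal``.
    """
    profile.validate()
    orientation = profile.orientation or config.orientation

    z = profile.z
    intensity = profile.intensity
    n = len(intensity)
    # normalise: electrode at index 0 in the working arrays
    flip = orientation == Orientation.ELECTRODE_HIGH_Z
    work = intensity[::-1] if flip else intensity

    flags: Set[str] = set()
    if config.saturation_level is not None and np.any(
        intensity >= config.saturation_level
    ):
        flags.add(FLAG_SATURATED)

    peak_w = find_peak(work)
    if np.all(work == work[0]):
        flags.add(FLAG_NO_SIGNAL)

    cut = _coarse_cut(work)
    if cut is None:
        support = None
        id_max_w = peak_w
    else:
        support = work <= cut
        id_max_w = _anchor_peak(work, cut, peak_w)
    if id_max_w != peak_w:
        flags.add(FLAG_SPIKE_REJECTED)

    bg_el = estimate_background(work, SIDE_ELECTRODE, id_max_w, config, support=support)
    bg_bu = estimate_background(work, SIDE_BUFFER, id_max_w, config, support=support)
    thr_left = config.multiplier * bg_el.mean_intensity
    thr_right = config.multiplier * bg_bu.mean_intensity

    lo = find_lower_boundary(
        work, thr_left, id_max_w, require_contiguity=config.require_contiguity_below
    )
    up = find_upper_boundary(work, thr_right, id_max_w)

    def to_orig(i: Optional[int]) -> Optional[int]:
        if i is None:
            return None
        return n - 1 - i if flip else i

    id_max = to_orig(id_max_w)
    bounds = Boundaries(id_max=id_max)

    if lo.found and up.found:
        i_lo, i_up = to_orig(lo.index), to_orig(up.index)
        z_lo, z_up = float(z[i_lo]), float(z[i_up])
        # order by z so lower_z <= upper_z regardless of orientation
        if z_lo > z_up:
            i_lo, i_up, z_lo, z_up = i_up, i_lo, z_up, z_lo
        bounds.lower_idx, bounds.upper_idx = i_lo, i_up
        bounds.lower_z, bounds.upper_z = z_lo, z_up
        bounds.lower_found = bounds.upper_found = True
        thickness: Optional[float] = z_up - z_lo
    else:
        # record whichever boundary was found, in z-order
        for hit, electrode_side in ((lo, True), (up, False)):
            if not hit.found:
                continue
            i = to_orig(hit.index)
            zv = float(z[i])
            low_side = electrode_side != flip
            if low_side:
                bounds.lower_idx, bounds.lower_z, bounds.lower_found = i, zv, True
            else:
                bounds.upper_idx, bounds.upper_z, bounds.upper_found = i, zv, True
        thickness = None
        flags.add(FLAG_NO_SIGNAL)

    if lo.at_edge or up.at_edge:
        flags.add(FLAG_BOUNDARY_AT_EDGE)
    if up.spike_rejected:
        flags.add(FLAG_SPIKE_REJECTED)

    return ThicknessResult(
        roi_id=profile.roi_id,
        image_id=profile.image_id,
        thickness_um=thickness,
        boundaries=bounds,
        threshold_left=thr_left,
        threshold_right=thr_right,
        background_electrode=bg_el.mean_intensity,
        background_buffer=bg_bu.mean_intensity,
        flags=flags,
    )
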