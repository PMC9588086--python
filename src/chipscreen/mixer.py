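"""Image-based mixing quantification for two-stream micromixer channels.

Mixing in a serpentine diffusive mixer is read off micrographs: a cross-width
intensity profile of the dye channel is extracted, normalized to the dye and
chip-background references, and summarized by the absolute mixing index

    AMI = sigma / <I> = sqrt( (1/N) sum_i (I_i - <I>)^2 ) / <I>,

the population coefficient of variation of the profile.  AMI = 0 means the
two streams are fully mixed; larger values mean a sharper residual gradient.
A complementary linear-slope metric (least-squares slope of intensity vs
position) is also provided, along with end-of-mixer dilution estimation for
gradient-generator output channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from chipscreen.exceptions import InvalidInputError, NoContrastError, UndefinedIndexError

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class ChannelImage:
    """A micrograph of a channel with a rectangular region of interest.

    ``pixels`` is (rows, cols) or (rows, cols, 3); the channel width runs
    along the column axis.  ``roi`` is (row0, row1, col0, col1), 0-based,
    half-open; ``None`` means the whole image.  ``pixel_size`` is um/pixel.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    roi: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise InvalidInputError(f"pixels must be 2-D or 2-D x3, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] != 3:
            raise InvalidInputError(f"color images must have 3 channels, got {px.shape[2]}")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise InvalidInputError("intensities must be finite and >= 0")
        if not (self.pixel_size > 0):
            raise InvalidInputError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)
        if self.roi is not None:
            r0, r1, c0, c1 = self.roi
            nr, nc = px.shape[:2]
            if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
                raise InvalidInputError(
                    f"roi {self.roi} out of bounds for image of shape {px.shape[:2]}"
                )

    def roi_pixels(self) -> np.ndarray:
        if self.roi is None:
            return self.pixels
        r0, r1, c0, c1 = self.roi
        return self.pixels[r0:r1, c0:c1]


@dataclass(frozen=True)
class IntensityProfile:
    """Cross-width intensity profile: positions (um) and intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.shape != inten.shape or pos.ndim != 1:
            raise InvalidInputError("positions and intensities must be equal-length 1-D arrays")
        if pos.size >= 2 and not np.all(np.diff(pos) > 0):
            raise InvalidInputError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def n(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class MixingMetrics:
    """Summary of one profile: AMI, OLS slope (1/um) and mean intensity."""

    ami: float
    slope: float
    mean_intensity: float


def _select_channel(px: np.ndarray, channel: str) -> np.ndarray:
    if px.ndim == 2:
        # grayscale: every selector refers to the single channel
        return px.astype(float)
    if channel == "luma":
        # ITU-R BT.601 weights
        return px @ np.array([0.299, 0.587, 0.114])
    try:
        return px[..., _CHANNEL_INDEX[channel]].astype(float)
    except KeyError:
        raise InvalidInputError(
            f"unknown channel selector {channel!r}; use red/green/blue/luma"
        ) from None


def extract_profile(image: ChannelImage, channel: str = "blue") -> IntensityProfile:
    """Cross-width profile: per-column mean of the selected color channel in the ROI.

    The dye used for mixing visualization absorbs red/green, so the blue RGB
    channel carries the concentration signal; ``channel="blue"`` is the default.
    """
    roi = image.roi_pixels()
    if roi.size == 0:
        raise InvalidInputError("empty roi")
    plane = _select_channel(roi, channel)
    intensities = plane.mean(axis=0)
    col_offset = 0 if image.roi is None else image.roi[2]
    positions = (np.arange(intensities.size) + col_offset) * image.pixel_size
    return IntensityProfile(positions=positions, intensities=intensities)


def normalize_profile(
    profile: IntensityProfile, lo_ref: float, hi_ref: float
) -> IntensityProfile:
    """Rescale intensities to [0, 1] between the background and dye references.

    ``hi_ref`` is the intensity of the undiluted dye stream (maps to 1),
    ``lo_ref`` the chip background (maps to 0); values outside the references
    are clamped.
    """
    if not (hi_ref > lo_ref):
        raise InvalidInputError(f"hi_ref ({hi_ref}) must exceed lo_ref ({lo_ref})")
    scaled = np.clip((profile.intensities - lo_ref) / (hi_ref - lo_ref), 0.0, 1.0)
    return IntensityProfile(positions=profile.positions, intensities=scaled)


def auto_normalize(profiles: Sequence[IntensityProfile]) -> list[IntensityProfile]:
    """Normalize a set of profiles by the min/max over the whole set.

    Convenience mode only; explicit dye/background references
    (:func:`normalize_profile`) are preferred and are the default workflow.
    """
    if not profiles:
        raise InvalidInputError("no profiles to normalize")
    lo = min(float(p.intensities.min()) for p in profiles)
    hi = max(float(p.intensities.max()) for p in profiles)
    if not hi > lo:
        raise InvalidInputError("profiles are all constant; references are degenerate")
    return [normalize_profile(p, lo, hi) for p in profiles]


def absolute_mixing_index(profile: IntensityProfile) -> float:
    """AMI = population std of the profile divided by its mean.

    Zero iff the profile is constant (complete mixing); invariant under
    rescaling of intensities.
    """
    if profile.n < 2:
        raise InvalidInputError(f"AMI needs >= 2 samples, got {profile.n}")
    mean = float(profile.intensities.mean())
    if mean == 0.0:
        raise UndefinedIndexError("AMI undefined: mean intensity is zero")
    sigma = float(profile.intensities.std(ddof=0))
    return sigma / mean


def profile_slope(profile: IntensityProfile, signed: bool = True) -> float:
    """Ordinary least-squares slope of intensity vs position, 1/um.

    Zero slope indicates a flat profile, i.e. complete mixing.  ``signed=False``
    returns the magnitude.
    """
    if profile.n < 2:
        raise InvalidInputError(f"slope needs >= 2 samples, got {profile.n}")
    if np.ptp(profile.positions) == 0:
        raise InvalidInputError("degenerate positions: all equal")
    slope = float(np.polyfit(profile.positions, profile.intensities, 1)[0])
    return slope if signed else abs(slope)


def mixing_metrics(profile: IntensityProfile) -> MixingMetrics:
    """AMI, slope and mean intensity of one (normalized) profile."""
    return MixingMetrics(
        ami=absolute_mixing_index(profile),
        slope=profile_slope(profile),
        mean_intensity=float(profile.intensities.mean()),
    )


def estimate_dilution(
    end_images: Sequence[ChannelImage], channel: str = "blue"
) -> np.ndarray:
    """Dilution fractions (% of inlet) for gradient-generator output channels.

    The first image is the 100% (undiluted) channel and the last the 0%
    (buffer) channel; every channel's mean ROI intensity is linearly
    interpolated between those two references:

        fraction_k = 100 (I_k - I_last) / (I_first - I_last).

    Affine changes of the imaging response (gain/offset) cancel.
    """
    if len(end_images) < 2:
        raise InvalidInputError("need at least the 100% and 0% reference channels")
    means = np.array(
        [float(_select_channel(img.roi_pixels(), channel).mean()) for img in end_images]
    )
    hi, lo = means[0], means[-1]
    if hi == lo:
        raise NoContrastError(
            f"reference channels have equal mean intensity ({hi}); cannot interpolate"
        )
    return 100.0 * (means - lo) / (hi - lo)


def mixing_vs_flowrate(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS fit of a mixing metric (slope or AMI) against volumetric flow rate.

    Returns (slope, intercept, r_squared).  Diffusive mixers trade residence
    time against flow rate, so the metric is expected to rise roughly
    linearly with flow rate over the operating range.
    """
    if len(pairs) < 3:
        raise InvalidInputError(f"need >= 3 (flow, metric) pairs, got {len(pairs)}")
    x, y = np.asarray(pairs, dtype=float).T
    if np.ptp(x) == 0:
        raise InvalidInputError("flow rates are all equal; fit is degenerate")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
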