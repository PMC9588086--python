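"""Ground-truthed synthetic inputs for every analysis stage.

Each generator is a pure function of its spec and seed and returns both the
artefact (image, curve, table) and the exact ground truth it encodes, so
every analysis module can be validated closed-loop without any microscope
data:

* two-stream mixing-channel micrographs with an analytic erf cross-width
  concentration profile set by the residence time L/v;
* two-channel (live green / dead red) cell fields of non-overlapping disks
  with exact counts, plus the matching threshold/label counter;
* triplet-model FCS autocorrelation curves with multiplicative noise;
* Hill-model dose-response viability tables with additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf
from skimage import measure

from chipscreen.doseresponse import DoseResponseData, hill_curve
from chipscreen.exceptions import InvalidInputError, PlacementError
from chipscreen.fcs import FcsCurve, FcsParams, autocorrelation
from chipscreen.mixer import ChannelImage, IntensityProfile


@dataclass(frozen=True)
class MixingImageSpec:
    """Spec for a synthetic two-stream mixing micrograph.

    The dye stream occupies one half of the channel at the inlet; after a
    downstream length ``downstream_len`` at velocity ``velocity`` the
    cross-width concentration is the erf profile of 1-D interdiffusion over
    the residence time t = L/v.  Concentration maps linearly into the blue
    channel of an RGB image between ``background_level`` and ``dye_level``.
    """

    width_px: int = 200
    height_px: int = 40
    channel_width: float = 150.0  # um
    diffusivity: float = 3.31e-10  # m^2/s, mixing dye in water
    velocity: float = 1.11e-3  # m/s, 1 uL/min operating point
    downstream_len: float = 18.5e-3  # m, serpentine mixer length
    dye_level: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 2 or self.height_px < 1:
            raise InvalidInputError("image must be at least 2 px wide and 1 px tall")
        if not (self.channel_width > 0 and self.diffusivity > 0):
            raise InvalidInputError("channel_width and diffusivity must be > 0")
        if not (self.velocity > 0):
            raise InvalidInputError("velocity must be > 0")
        if self.downstream_len < 0 or self.noise_sd < 0:
            raise InvalidInputError("downstream_len and noise_sd must be >= 0")


def mixing_ground_truth(spec: MixingImageSpec) -> IntensityProfile:
    """Analytic cross-width concentration profile (0..1) for a mixing spec."""
    pixel_size = spec.channel_width / spec.width_px
    y = (np.arange(spec.width_px) + 0.5) * pixel_size  # um, pixel centres
    residence = spec.downstream_len / spec.velocity
    spread = 2.0 * np.sqrt(spec.diffusivity * residence) * 1e6  # um
    centre = spec.channel_width / 2.0
    if spread == 0.0:
        conc = (y > centre).astype(float)
    else:
        conc = 0.5 * (1.0 + erf((y - centre) / spread))
    return IntensityProfile(positions=y, intensities=conc)


def make_mixing_image(spec: MixingImageSpec) -> tuple[ChannelImage, IntensityProfile]:
    """Synthetic RGB mixing micrograph plus its ground-truth profile."""
    truth = mixing_ground_truth(spec)
    rng = np.random.default_rng(spec.seed)
    blue_row = spec.background_level + truth.intensities * (
        spec.dye_level - spec.background_level
    )
    img = np.empty((spec.height_px, spec.width_px, 3))
    img[..., 0] = spec.background_level
    img[..., 1] = spec.background_level
    img[..., 2] = blue_row[np.newaxis, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    image = ChannelImage(pixels=img, pixel_size=spec.channel_width / spec.width_px)
    return image, truth


@dataclass(frozen=True)
class CellImageSpec:
    """Spec for a two-channel live/dead cell field of disk-shaped cells."""

    n_live: int
    n_dead: int
    cell_radius_px: int = 5
    width_px: int = 256
    height_px: int = 256
    live_level: float = 200.0
    dead_level: float = 200.0
    background_level: float = 5.0
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_live < 0 or self.n_dead < 0:
            raise InvalidInputError("cell counts must be >= 0")
        if self.cell_radius_px < 1:
            raise InvalidInputError("cell_radius_px must be >= 1")
        if self.width_px < 2 * self.cell_radius_px or self.height_px < 2 * self.cell_radius_px:
            raise InvalidInputError("field too small for the requested cell radius")


def _place_disks(
    rng: np.random.Generator,
    n: int,
    spec: CellImageSpec,
    occupied: list[tuple[float, float]],
    max_tries: int = 2000,
) -> list[tuple[float, float]]:
    r = spec.cell_radius_px
    centres: list[tuple[float, float]] = []
    # +3 keeps at least a 2-pixel background gap after rasterization, so
    # neighbouring disks never touch under 8-connectivity
    min_sep2 = (2 * r + 3) ** 2
    for _ in range(n):
        for _ in range(max_tries):
            cy = rng.uniform(r, spec.height_px - 1 - r)
            cx = rng.uniform(r, spec.width_px - 1 - r)
            if spec.allow_overlap or all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= min_sep2 for oy, ox in occupied
            ):
                centres.append((cy, cx))
                occupied.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place {n} non-overlapping cells of radius {r} px "
                f"in a {spec.height_px}x{spec.width_px} field"
            )
    return centres


def make_cell_image(spec: CellImageSpec) -> tuple[np.ndarray, tuple[int, int]]:
    """Two-channel (live, dead) image of disk cells plus the exact counts.

    Channel 0 is the live (green/DiOC-like) stain, channel 1 the dead
    (red/PI-like) stain.  Placement is uniform-random, non-overlapping across
    both channels by default, and bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    occupied: list[tuple[float, float]] = []
    live = _place_disks(rng, spec.n_live, spec, occupied)
    dead = _place_disks(rng, spec.n_dead, spec, occupied)
    img = np.full((spec.height_px, spec.width_px, 2), spec.background_level)
    yy, xx = np.mgrid[0 : spec.height_px, 0 : spec.width_px]
    for centres, ch, level in ((live, 0, spec.live_level), (dead, 1, spec.dead_level)):
        for cy, cx in centres:
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.cell_radius_px**2
            img[mask, ch] = level
    return img, (spec.n_live, spec.n_dead)


def count_cells(
    image: np.ndarray, threshold: float = 50.0, min_area_px: int = 4
) -> tuple[int, int]:
    """Count (live, dead) cells by thresholding + 8-connected labelling.

    Components smaller than ``min_area_px`` are discarded (speckle filter).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 2:
        raise InvalidInputError("expected a (rows, cols, 2) live/dead image")
    counts = []
    for ch in range(2):
        mask = image[..., ch] > threshold
        labels = measure.label(mask, connectivity=2)
        areas = np.bincount(labels.ravel())[1:]  # skip background label 0
        counts.append(int(np.sum(areas >= min_area_px)))
    return counts[0], counts[1]


def make_fcs_curve(
    params: FcsParams,
    lags,
    noise_frac: float = 0.0,
    seed: int = 0,
    p_squared: bool = True,
) -> tuple[FcsCurve, FcsParams]:
    """Triplet-model curve on a lag grid with multiplicative Gaussian noise.

    Each point is G(tau) * (1 + noise_frac * eps), eps ~ N(0, 1), seeded.
    Returns the curve together with the generating parameters.
    """
    if noise_frac < 0:
        raise InvalidInputError(f"noise_frac must be >= 0, got {noise_frac}")
    lags = np.asarray(lags, dtype=float)
    g = autocorrelation(lags, params, p_squared=p_squared)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + noise_frac * rng.standard_normal(g.shape))
    return FcsCurve(lags=lags, g=g), params


def make_dose_response(
    top: float,
    bottom: float,
    ec50: float,
    hill: float,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DoseResponseData, dict]:
    """Hill-model viability table with additive Gaussian noise, clamped to [0, 100].

    Returns the data plus the ground-truth parameter dict.
    """
    if noise_sd < 0:
        raise InvalidInputError(f"noise_sd must be >= 0, got {noise_sd}")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise InvalidInputError("doses must be >= 0")
    v = hill_curve(doses, top, bottom, ec50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + noise_sd * rng.standard_normal(doses.shape)
    v = np.clip(v, 0.0, 100.0)
    truth = {"top": top, "bottom": bottom, "ec50": ec50, "hill": hill}
    return DoseResponseData(concentrations=doses, viabilities=v), truth
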