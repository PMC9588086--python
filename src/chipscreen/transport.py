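"""Stokes-Einstein transport chain for small molecules in microchannels.

Treats each solute as a hard sphere whose radius follows from its molar
volume,

    r = cbrt( 3 (MW / (N_A rho)) / (4 pi) ),

whose diffusivity follows from Stokes-Einstein,

    D = k T / (6 pi mu r),

and whose characteristic time to diffuse a distance ``x`` (e.g. the mixing
channel width) is ``t = x^2 / (2 D)``.  These three maps, chained over a
list of molecules, produce the design table used to pick the operating flow
rate of a diffusive micromixer.

Units are SI internally (m, s, K, Pa.s).  Constructors accept the
conventional bench units (g/mol, g/cm^3) and convert once at the boundary.

The default conditions are T = 310.15 K (cell-culture temperature) with a
dynamic viscosity of 1.01e-3 Pa.s.  The viscosity default is a calibration:
it is the value that makes the chain reproduce published design tables for
these molecules, and is closer to water at 20 °C than at 37 °C; both values
are plain constructor arguments, so either convention is one keyword away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from chipscreen.exceptions import InvalidInputError

#: Boltzmann constant, J/K (exact, 2019 SI).
K_BOLTZMANN = 1.380649e-23
#: Avogadro number, 1/mol (4 significant figures, matching design-table precision).
N_AVOGADRO = 6.022e23

#: Default absolute temperature, K (37 °C incubator).
DEFAULT_TEMPERATURE = 310.15
#: Default dynamic viscosity, Pa.s (calibrated; see module docstring).
DEFAULT_VISCOSITY = 1.01e-3


@dataclass(frozen=True)
class Molecule:
    """A solute modelled as a hard sphere.

    Parameters
    ----------
    name : str
        Label carried through result tables.
    mw : float
        Molecular weight, g/mol.
    density : float
        Bulk density, g/cm^3.
    """

    name: str
    mw: float
    density: float

    def __post_init__(self) -> None:
        if not (self.mw > 0):
            raise InvalidInputError(f"{self.name!r}: molecular weight must be > 0, got {self.mw}")
        if not (self.density > 0):
            raise InvalidInputError(f"{self.name!r}: density must be > 0, got {self.density}")


@dataclass(frozen=True)
class TransportConditions:
    """Temperature/viscosity context for Stokes-Einstein calculations."""

    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = DEFAULT_VISCOSITY
    boltzmann: float = K_BOLTZMANN
    avogadro: float = N_AVOGADRO

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature}")
        if not (self.viscosity > 0):
            raise InvalidInputError(f"viscosity must be > 0 Pa.s, got {self.viscosity}")


DEFAULT_CONDITIONS = TransportConditions()


@dataclass(frozen=True)
class TransportResult:
    """Radius, diffusivity and crossing time for one molecule."""

    molecule: Molecule
    radius: float  # m
    diffusivity: float  # m^2/s
    distance: float  # m
    crossing_time: float  # s
    conditions: TransportConditions = field(default=DEFAULT_CONDITIONS, repr=False)


def hydrodynamic_radius(
    molecule: Molecule, conditions: TransportConditions = DEFAULT_CONDITIONS
) -> float:
    """Hard-sphere radius (m) from molecular weight and bulk density.

    The molar volume MW/(N_A rho) is taken as the volume of a single
    spherical particle; note the result is independent of temperature
    and viscosity.
    """
    # molar volume in cm^3 -> m^3 (1e-6)
    particle_volume = molecule.mw / (conditions.avogadro * molecule.density) * 1e-6
    return (3.0 * particle_volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def stokes_einstein_diffusivity(
    radius: float, conditions: TransportConditions = DEFAULT_CONDITIONS
) -> float:
    """Diffusion coefficient D = kT/(6 pi mu r), m^2/s."""
    if not (radius > 0):
        raise InvalidInputError(f"radius must be > 0 m, got {radius}")
    return conditions.boltzmann * conditions.temperature / (
        6.0 * math.pi * conditions.viscosity * radius
    )


def channel_crossing_time(diffusivity: float, distance: float) -> float:
    """Characteristic 1-D diffusion time t = x^2/(2D), s.

    ``distance`` is typically the mixing-channel width; ``distance = 0``
    returns 0.
    """
    if not (diffusivity > 0):
        raise InvalidInputError(f"diffusivity must be > 0 m^2/s, got {diffusivity}")
    if distance < 0:
        raise InvalidInputError(f"distance must be >= 0 m, got {distance}")
    return distance**2 / (2.0 * diffusivity)


def analyze_molecule(
    molecule: Molecule,
    conditions: TransportConditions = DEFAULT_CONDITIONS,
    distance: float = 150e-6,
) -> TransportResult:
    """Chain radius -> diffusivity -> crossing time for one molecule."""
    r = hydrodynamic_radius(molecule, conditions)
    d = stokes_einstein_diffusivity(r, conditions)
    t = channel_crossing_time(d, distance)
    return TransportResult(
        molecule=molecule,
        radius=r,
        diffusivity=d,
        distance=distance,
        crossing_time=t,
        conditions=conditions,
    )


def transport_table(
    molecules: list[Molecule],
    conditions: TransportConditions = DEFAULT_CONDITIONS,
    distance: float = 150e-6,
) -> pd.DataFrame:
    """Design table (name, mw, density, r, D, t) for a list of molecules.

    Raises
    ------
    InvalidInputError
        On an empty molecule list; per-molecule errors propagate with the
        offending molecule named.
    """
    if not molecules:
        raise InvalidInputError("transport_table requires at least one molecule")
    rows = []
    for mol in molecules:
        try:
            res = analyze_molecule(mol, conditions, distance)
        except InvalidInputError as exc:
            raise InvalidInputError(f"molecule {mol.name!r}: {exc}") from exc
        rows.append(
            {
                "name": mol.name,
                "mw_g_per_mol": mol.mw,
                "density_g_per_cm3": mol.density,
                "radius_m": res.radius,
                "diffusivity_m2_per_s": res.diffusivity,
                "crossing_time_s": res.crossing_time,
            }
        )
    return pd.DataFrame(rows)


def mean_velocity(total_flow: float, n_channels: int, width: float, height: float) -> float:
    """Mean linear velocity (m/s) of flow split over identical rectangular channels.

    v = (Q_total / n) / (w h).  With both inlets at 1 uL/min feeding four
    150 x 50 um channels this gives ~1.1 mm/s, the capillary-like operating
    point of the perfusion layer.
    """
    if not (total_flow > 0):
        raise InvalidInputError(f"total_flow must be > 0, got {total_flow}")
    if not (n_channels > 0):
        raise InvalidInputError(f"n_channels must be > 0, got {n_channels}")
    area = width * height
    if not (area > 0):
        raise InvalidInputError(f"channel cross-section must have positive area, got {area}")
    return (total_flow / n_channels) / area


#: The six small molecules of the chip's design table: the visualization dye
#: used for mixing characterization plus five chemotherapeutics.
CHEMOTHERAPEUTICS: tuple[Molecule, ...] = (
    Molecule("Brilliant Blue FCF", 792.9, 1.0),
    Molecule("Temozolomide", 194.2, 2.0),
    Molecule("Paclitaxel", 853.9, 1.4),
    Molecule("Doxorubicin", 543.5, 1.6),
    Molecule("Carmustine", 214.1, 1.7),
    Molecule("Lomustine", 233.7, 1.4),
)
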