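"""Width-tuned dilution-network model for tree-like gradient generators.

A tree-like microfluidic concentration gradient generator (MCGG) produces a
discrete dilution ladder by merging dye and buffer streams.  When all feed
channels share length and height, the flow each contributes is proportional
to its width, so choosing feed widths sets the merge ratios: merging equal
150 um dye and buffer feeds gives the 1/2 rung, and a 50 um dye feed against
a 150 um buffer feed gives the 1/4 rung, yielding the 1 : 1/2 : 1/4 : 0
ladder of the chip studied here.

Merges are modelled as ideal flow-weighted mixing,

    c_out = sum(q_i c_i) / sum(q_i),

which conserves solute mass exactly.  A rectangular-duct Poiseuille
resistance is included for the cases where channel lengths are known and
weights should come from a hydraulic network rather than the width heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from chipscreen.exceptions import ConfigError, InvalidInputError


@dataclass(frozen=True)
class Stream:
    """A merging stream: volumetric flow (or proportional weight) and solute fraction."""

    flow: float
    conc: float

    def __post_init__(self) -> None:
        if not (self.flow > 0):
            raise InvalidInputError(f"stream flow must be > 0, got {self.flow}")
        if not (0.0 <= self.conc <= 1.0):
            raise InvalidInputError(f"stream conc must be in [0, 1], got {self.conc}")


@dataclass(frozen=True)
class ChannelSegment:
    """Rectangular channel segment (width, height, length in m)."""

    width: float
    height: float
    length: float

    def __post_init__(self) -> None:
        for name in ("width", "height", "length"):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"segment {name} must be > 0")


def merge_concentration(streams: Sequence[Stream]) -> float:
    """Flow-weighted outlet concentration of merging streams.

    Mass conservation holds by construction: sum(q c) in equals q_out c_out.
    """
    if len(streams) < 2:
        raise InvalidInputError(f"a merge needs >= 2 streams, got {len(streams)}")
    total_flow = sum(s.flow for s in streams)
    return sum(s.flow * s.conc for s in streams) / total_flow


def rectangular_resistance(
    segment: ChannelSegment, viscosity: float, n_terms: int = 20
) -> float:
    """Hydraulic resistance (Pa.s/m^3) of laminar flow in a rectangular duct.

    Uses the Fourier-series solution for pressure-driven Poiseuille flow,

        R = 12 mu L / (w h^3 [1 - (192 h)/(pi^5 w) * sum_{n odd} tanh(n pi w / 2h)/n^5]),

    with ``w >= h`` (dimensions swapped internally otherwise).  The w >> h
    limit is the parallel-plate result 12 mu L / (w h^3); a square duct gives
    the familiar 28.45 mu L / h^4.
    """
    if not (viscosity > 0):
        raise InvalidInputError(f"viscosity must be > 0, got {viscosity}")
    if n_terms < 1:
        raise InvalidInputError(f"n_terms must be >= 1, got {n_terms}")
    w, h = max(segment.width, segment.height), min(segment.width, segment.height)
    series = sum(
        math.tanh(n * math.pi * w / (2.0 * h)) / n**5 for n in range(1, 2 * n_terms, 2)
    )
    correction = 1.0 - (192.0 * h) / (math.pi**5 * w) * series
    return 12.0 * viscosity * segment.length / (w * h**3 * correction)


#: Reconstructed two-stage width network of the studied chip: the 1/2 rung
#: merges equal 150 um dye/buffer feeds; the 1/4 rung merges a 50 um dye feed
#: with a 150 um buffer feed.  The interior routing of the physical device is
#: not fully published, so this ships as an example configuration, not as
#: hard-coded truth.
WIDTH_LADDER_NETWORK: dict = {
    "inlets": {"dye": 1.0, "buffer": 0.0},
    "merges": [
        {"name": "half", "streams": [["dye", 150.0], ["buffer", 150.0]]},
        {"name": "quarter", "streams": [["dye", 50.0], ["buffer", 150.0]]},
    ],
    "outputs": ["dye", "half", "quarter", "buffer"],
}


def ladder_fractions(network: Mapping) -> list[float]:
    """Output solute fractions of a staged merge network.

    ``network`` maps ``inlets`` (name -> concentration fraction), ``merges``
    (ordered stages, each with a ``name`` and ``streams`` of
    ``[source, weight]`` pairs referencing inlets or earlier merges) and
    ``outputs`` (ordered source names).  Weights may be channel widths
    (flow proportional to width) or explicit flows.
    """
    try:
        inlets = dict(network["inlets"])
        merges = list(network.get("merges", []))
        outputs = list(network["outputs"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"network spec must define inlets and outputs: {exc}") from exc
    conc: dict[str, float] = {}
    for name, c in inlets.items():
        conc[name] = float(c)
    for stage in merges:
        try:
            name = stage["name"]
            raw_streams = stage["streams"]
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed merge stage {stage!r}") from exc
        streams = []
        for source, weight in raw_streams:
            if source not in conc:
                raise ConfigError(
                    f"merge {name!r} references unknown source {source!r} "
                    "(not an inlet or earlier merge)"
                )
            streams.append(Stream(flow=float(weight), conc=conc[source]))
        conc[name] = merge_concentration(streams)
    missing = [o for o in outputs if o not in conc]
    if missing:
        raise ConfigError(f"outputs reference unknown sources: {missing}")
    return [conc[o] for o in outputs]
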