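"""Förster-relation conversion between FRET efficiency and inter-dye distance.

The FRET efficiency of a donor/acceptor pair separated by a distance ``R``
follows ``E = 1 / (1 + (R/R0)^6)``, where ``R0`` is the Förster radius of the
dye pair — the separation at which transfer is 50% efficient.  Inverting gives
``R = R0 * (1/E - 1)^(1/6)``.  The default ``R0`` of 60 Å is the standard
literature value for the Alexa Fluor 488 / Alexa Fluor 594 pair.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ForsterParams:
    """Förster radius of the dye pair, in Å."""

    R0: float = 60.0

    def __post_init__(self) -> None:
        if self.R0 <= 0:
            raise ValueError(f"R0 must be positive, got {self.R0}")


@dataclass(frozen=True)
class StateDistance:
    """A labelled conformational state with its mean efficiency and distance."""

    state_label: str
    E_mean: float
    R: float
    provenance: str = ""


def distance_from_E(E: float, params: ForsterParams = ForsterParams()) -> float:
    """Inter-dye distance (Å) from a FRET efficiency in the open interval (0, 1)."""
    if not 0.0 < E < 1.0:
        raise ValueError(f"E must lie strictly in (0, 1), got {E}")
    return params.R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


def E_from_distance(R: float, params: ForsterParams = ForsterParams()) -> float:
    """FRET efficiency at inter-dye distance ``R`` (Å); inverse of distance_from_E."""
    if R <= 0:
        raise ValueError(f"R must be positive, got {R}")
    return 1.0 / (1.0 + (R / params.R0) ** 6)


def delta_distance(E_a: float, E_b: float, params: ForsterParams = ForsterParams()) -> float:
    """Distance change ΔR = R(E_a) − R(E_b) in Å between two states."""
    return distance_from_E(E_a, params) - distance_from_E(E_b, params)
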