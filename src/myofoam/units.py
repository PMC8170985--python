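"""Unit-system handling.

Everything inside the package is SI (m, s, kg, Pa).  Input decks are commonly
written in mm-ms-kg (stresses in GPa, forces in kN); the factors below convert
deck quantities into SI on read.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitSystem:
    """Conversion factors from a declared unit system into SI."""

    name: str
    length: float  # -> m
    time: float    # -> s
    mass: float    # -> kg

    @property
    def density(self) -> float:
        return self.mass / self.length**3

    @property
    def stress(self) -> float:
        # mass / (length * time^2)
        return self.mass / (self.length * self.time**2)

    @property
    def velocity(self) -> float:
        return self.length / self.time

    @property
    def acceleration(self) -> float:
        return self.length / self.time**2

    @property
    def force(self) -> float:
        return self.mass * self.length / self.time**2

    @property
    def rate(self) -> float:
        return 1.0 / self.time


SI = UnitSystem("si", 1.0, 1.0, 1.0)
MM_MS_KG = UnitSystem("mm_ms_kg", 1e-3, 1e-3, 1.0)

_SYSTEMS = {"si": SI, "mm_ms_kg": MM_MS_KG}


def get_unit_system(name: str) -> UnitSystem:
    try:
        return _SYSTEMS[name]
    except KeyError:
        raise ValueError(
            f"unknown unit system {name!r}; choose from {sorted(_SYSTEMS)}"
        ) from None
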