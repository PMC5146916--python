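"""Reduced Lennard-Jones units and SI conversions.

The whole simulator works in reduced (LJ) units in which the backbone bead
diameter ``a``, the bead mass ``m``, the repulsion energy scale ``epsilon``
and Boltzmann's constant are all 1.  The mapping onto a physical
single-stranded-DNA / graphene system is fixed by three numbers:

====================  =========================
length   a            0.3 nm
mass     m            1.6e-25 kg
energy   epsilon      2.74e-21 J
====================  =========================

Every other scale follows: time = sqrt(m a^2 / epsilon) ~ 2.3 ps,
force = epsilon / a ~ 9.1 pN, temperature = epsilon / k_B ~ 198 K (so the
polymer temperature T_p = 3/2 corresponds to ~300 K), friction = m / time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

K_BOLTZMANN_SI = 1.380649e-23  # J/K


@dataclass(frozen=True)
class UnitSystem:
    """SI values of the three defining LJ scales, plus derived scales.

    ``scale(kind)`` returns the SI value of one LJ unit of ``kind``.
    """

    length: float = 0.3e-9      # m
    mass: float = 1.6e-25       # kg
    energy: float = 2.74e-21    # J

    @property
    def time(self) -> float:
        return math.sqrt(self.mass * self.length**2 / self.energy)

    @property
    def force(self) -> float:
        return self.energy / self.length

    @property
    def velocity(self) -> float:
        return self.length / self.time

    @property
    def temperature(self) -> float:
        # k_B = 1 in LJ units, so one LJ temperature unit is epsilon/k_B.
        return self.energy / K_BOLTZMANN_SI

    @property
    def friction(self) -> float:
        # Langevin friction xi has dimensions mass/time.
        return self.mass / self.time

    def scale(self, kind: str) -> float:
        try:
            return float(getattr(self, kind))
        except AttributeError:
            raise ValueError(
                f"unknown quantity kind {kind!r}; expected one of "
                "length, mass, energy, temperature, force, time, velocity, friction"
            ) from None


DEFAULT_UNITS = UnitSystem()


def lj_to_si(value: float, kind: str, units: UnitSystem = DEFAULT_UNITS) -> float:
    """Convert a value in reduced LJ units to SI."""
    return value * units.scale(kind)


def si_to_lj(value: float, kind: str, units: UnitSystem = DEFAULT_UNITS) -> float:
    """Convert an SI value to reduced LJ units."""
    return value / units.scale(kind)
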