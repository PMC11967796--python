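"""Unit helpers.

The library computes in SI (m, s, kg, Pa) but lab inputs arrive in the
units practitioners use: micrometres for channel dimensions, millimetres
for rotor radii, rpm for rotational speed, mN/m for interfacial tension,
mPa*s for viscosity, microlitres for sample volumes.  These constants and
converters make the ingest explicit.
"""

from __future__ import annotations

import math

#: metres per micrometre
UM = 1e-6
#: metres per millimetre
MM = 1e-3
#: cubic metres per microlitre (1 uL = 1 mm^3)
UL = 1e-9
#: cubic metres per nanolitre
NL = 1e-12
#: Pa*s per mPa*s
MPA_S = 1e-3
#: N/m per mN/m
MN_PER_M = 1e-3


def rpm_to_rad_per_s(rpm: float) -> float:
    """Convert rotational speed in revolutions per minute to rad/s."""
    return rpm * 2.0 * math.pi / 60.0


def rad_per_s_to_rpm(omega: float) -> float:
    return omega * 60.0 / (2.0 * math.pi)


def deg_to_rad(deg: float) -> float:
    return math.radians(deg)


def m3_to_uL(volume: float) -> float:
    return volume / UL


def uL_to_m3(volume_uL: float) -> float:
    return volume_uL * UL


def per_uL_to_per_m3(c: float) -> float:
    """Convert a number concentration from counts/uL to counts/m^3."""
    return c / UL


def per_mL_to_per_m3(c: float) -> float:
    return c * 1e6
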