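"""Confocal observation-volume geometry.

The detection profile of a point-FCS measurement is modelled as a 3D
Gaussian,

    W(x, y, z) = exp(-2 (x^2 + y^2) / omega_xy^2 - 2 z^2 / omega_z^2),

with lateral 1/e^2 radius ``omega_xy`` and axial radius
``omega_z = AR * omega_xy``, where AR is the structural parameter
(axial-to-lateral aspect ratio).  The effective volume is

    V_eff = pi^(3/2) * AR * omega_xy^3,

the volume for which the zero-lag autocorrelation amplitude of N freely
diffusing molecules equals 1/N.  With radii in micrometres, V_eff in
cubic micrometres is numerically equal to V_eff in femtolitres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = ["ObservationVolume", "molecules_per_um3", "concentration_nM"]

#: molecules per um^3 for a 1 nM solution (1 nM = 1e-9 mol/L, 1 um^3 = 1e-15 L)
_MOLECULES_PER_UM3_PER_NM = Avogadro * 1e-9 * 1e-15


def molecules_per_um3(conc_nM: float) -> float:
    """Number density (molecules / um^3) of a solution of ``conc_nM`` nanomolar."""
    return conc_nM * _MOLECULES_PER_UM3_PER_NM


def concentration_nM(n_molecules: float, volume_fl: float) -> float:
    """Concentration in nM of ``n_molecules`` in ``volume_fl`` femtolitres."""
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    return n_molecules / (volume_fl * _MOLECULES_PER_UM3_PER_NM)


@dataclass(frozen=True)
class ObservationVolume:
    """Geometry of the 3D Gaussian detection volume.

    Construct from any two of (omega_xy, AR, V_eff) via the class methods;
    the third is fixed by ``V_eff = pi^(3/2) * AR * omega_xy^3``.

    Attributes
    ----------
    omega_xy:
        Lateral 1/e^2 radius, um.
    ar:
        Axial-to-lateral aspect ratio ``omega_z / omega_xy`` (>= 1).
    """

    omega_xy: float
    ar: float

    def __post_init__(self) -> None:
        if not self.omega_xy > 0:
            raise ValueError("omega_xy must be positive")
        if not self.ar >= 1:
            raise ValueError("AR must be >= 1")

    @property
    def omega_z(self) -> float:
        """Axial 1/e^2 radius, um."""
        return self.ar * self.omega_xy

    @property
    def v_eff(self) -> float:
        """Effective volume, fl (== um^3)."""
        return math.pi ** 1.5 * self.ar * self.omega_xy ** 3

    @classmethod
    def from_radii(cls, omega_xy: float, ar: float) -> "ObservationVolume":
        return cls(omega_xy=omega_xy, ar=ar)

    @classmethod
    def from_v_eff(cls, v_eff: float, ar: float) -> "ObservationVolume":
        """Build from effective volume (fl) and aspect ratio."""
        if v_eff <= 0:
            raise ValueError("V_eff must be positive")
        omega_xy = (v_eff / (math.pi ** 1.5 * ar)) ** (1.0 / 3.0)
        return cls(omega_xy=omega_xy, ar=ar)

    @classmethod
    def from_v_eff_and_omega(cls, v_eff: float, omega_xy: float) -> "ObservationVolume":
        """Build from effective volume (fl) and lateral radius (um)."""
        ar = v_eff / (math.pi ** 1.5 * omega_xy ** 3)
        return cls(omega_xy=omega_xy, ar=ar)

    def occupancy(self, conc_nM: float) -> float:
        """Expected number of molecules in V_eff at concentration ``conc_nM``."""
        return molecules_per_um3(conc_nM) * self.v_eff

    def concentration_for_occupancy(self, n: float) -> float:
        """Concentration (nM) that puts on average ``n`` molecules in V_eff."""
        return concentration_nM(n, self.v_eff)


#: the instrument geometry used throughout: V_eff ~ 0.25 fl, AR = 5
DEFAULT_VOLUME = ObservationVolume.from_v_eff(0.25, 5.0)
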