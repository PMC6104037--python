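"""Ground-truth rheology models for the tissue phantom.

Each model returns a pair of dynamic moduli (storage E', loss E'') at an
angular frequency ``omega`` and an indentation strain ``strain``.  Strain
stiffening is modelled multiplicatively on the elastic part,
``E_eff = E0 * (1 + c * strain)``, which is the simplest form that
reproduces a monotone stiffness increase with indentation depth.

Supported kinds:

``elastic``
    Frequency-independent spring: E' = E0*(1+c*eps), E'' = 0.
``kelvin_voigt``
    Spring in parallel with a dashpot: E' = E0*(1+c*eps), E'' = omega*eta.
``power_law``
    Soft-glassy power law: |E*| = E0*(omega/omega_ref)**beta with constant
    loss tangent tan(pi*beta/2); converges to ``elastic`` as beta -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["RheologyModel"]

_KINDS = ("elastic", "kelvin_voigt", "power_law")


@dataclass(frozen=True)
class RheologyModel:
    """Viscoelastic constitutive model of one phantom region.

    Parameters
    ----------
    kind : {"elastic", "kelvin_voigt", "power_law"}
    E0 : float
        Reference elastic modulus in Pa (at omega_ref for power_law).
    eta : float
        Viscosity in Pa*s (kelvin_voigt only).
    beta : float
        Power-law exponent, 0 <= beta < 1 (power_law only).
    ref_freq : float
        Reference frequency in Hz for the power law.
    stiffening : float
        Dimensionless strain-stiffening coefficient c.
    """

    kind: str
    E0: float
    eta: float = 0.0
    beta: float = 0.0
    ref_freq: float = 1.0
    stiffening: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown rheology kind {self.kind!r}; expected one of {_KINDS}")
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError("beta must satisfy 0 <= beta < 1")
        if self.ref_freq <= 0:
            raise ValueError("ref_freq must be positive")

    def complex_modulus(self, omega: float, strain: float = 0.0) -> tuple[float, float]:
        """Return (E_storage, E_loss) in Pa at angular frequency omega [rad/s].

        Both components are non-negative for omega >= 0.
        """
        if omega < 0:
            raise ValueError("omega must be non-negative")
        e_el = self.E0 * (1.0 + self.stiffening * strain)
        if self.kind == "elastic":
            return e_el, 0.0
        if self.kind == "kelvin_voigt":
            return e_el, omega * self.eta
        # power_law
        omega_ref = 2.0 * math.pi * self.ref_freq
        mag = e_el * (omega / omega_ref) ** self.beta if omega > 0 else (e_el if self.beta == 0 else 0.0)
        half = 0.5 * math.pi * self.beta
        return mag * math.cos(half), mag * math.sin(half)

    def storage(self, omega: float, strain: float = 0.0) -> float:
        return self.complex_modulus(omega, strain)[0]
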