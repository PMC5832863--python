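"""Lipari-Szabo model-free forward model for backbone 15N relaxation.

The two-timescale spectral density

    J(w) = (2/5) [ S^2 tau_c / (1 + (w tau_c)^2)
                   + (1 - S^2) tau / (1 + (w tau)^2) ],   1/tau = 1/tau_c + 1/tau_e

combined with the N-H dipolar interaction and the axially symmetric 15N CSA
gives R1, R2 and the steady-state 1H-15N NOE.  An exchange term Rex adds to
R2 only.  This is the forward model the synthetic-data generator uses; the
analysis side never fits S2/tau_e/Rex per residue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C

__all__ = ["SpinParams", "spectral_density", "modelfree_rates", "rigid_r2_over_r1"]


@dataclass(frozen=True)
class SpinParams:
    """Model-free spin parameters for one amide.

    Parameters
    ----------
    s2 : order parameter S^2, dimensionless in [0, 1].
    tau_c : global rotational correlation time, ns.
    tau_e : internal correlation time, ps (0 = no internal motion term).
    rex : exchange contribution to R2, s^-1.
    field_h1 : spectrometer 1H frequency, MHz.
    """

    s2: float
    tau_c: float
    tau_e: float = 0.0
    rex: float = 0.0
    field_h1: float = 800.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError(f"order parameter S2 must be in [0, 1], got {self.s2}")
        if self.tau_c <= 0:
            raise ValueError(f"tau_c must be positive (ns), got {self.tau_c}")
        if self.tau_e < 0:
            raise ValueError(f"tau_e must be >= 0 (ps), got {self.tau_e}")
        if self.rex < 0:
            raise ValueError(f"rex must be >= 0 (1/s), got {self.rex}")
        if self.field_h1 <= 0:
            raise ValueError(f"field_h1 must be positive (MHz), got {self.field_h1}")


def spectral_density(omega: float | np.ndarray, s2: float, tau_c_s: float,
                     tau_e_s: float) -> float | np.ndarray:
    """Model-free J(omega) in s/rad; times in seconds."""
    omega = np.asarray(omega, dtype=float)
    j = s2 * tau_c_s / (1.0 + (omega * tau_c_s) ** 2)
    if s2 < 1.0 and tau_e_s > 0.0:
        tau = 1.0 / (1.0 / tau_c_s + 1.0 / tau_e_s)
        j = j + (1.0 - s2) * tau / (1.0 + (omega * tau) ** 2)
    return (2.0 / 5.0) * j


def modelfree_rates(params: SpinParams) -> tuple[float, float, float]:
    """Forward-calculate (R1, R2, NOE) for one amide.

    Returns rates in s^-1 and the dimensionless steady-state NOE
    I_sat/I_ref.  Rex is added to R2 only.
    """
    tau_c_s = params.tau_c * 1e-9
    tau_e_s = params.tau_e * 1e-12
    omega_h, omega_n = C.larmor_omega(params.field_h1)

    d = C.dipolar_coupling_constant()
    d2 = 0.25 * d * d  # (d/2)^2 prefactor of the standard rate expressions
    # axially symmetric CSA interaction: c^2 = (omega_N * delta_sigma)^2 / 3
    c2 = (omega_n * C.CSA_N_PPM * 1e-6) ** 2 / 3.0

    def j(w: float) -> float:
        return float(spectral_density(w, params.s2, tau_c_s, tau_e_s))

    j0 = j(0.0)
    jn = j(omega_n)
    jh = j(omega_h)
    jhmn = j(omega_h - omega_n)
    jhpn = j(omega_h + omega_n)

    r1 = d2 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c2 * jn
    r2 = 0.5 * d2 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn) \
        + (c2 / 6.0) * (4.0 * j0 + 3.0 * jn) + params.rex
    noe = 1.0 + (d2 / r1) * (C.GAMMA_H / C.GAMMA_N) * (6.0 * jhpn - jhmn)
    return r1, r2, noe


def rigid_r2_over_r1(tau_c_ns: float, field_h1_mhz: float) -> float:
    """R2/R1 of a rigid isotropic tumbler (S2=1, Rex=0) as a function of
    tau_c; strictly increasing over the slow-tumbling range, which makes it
    invertible for tumbling-time estimation."""
    r1, r2, _ = modelfree_rates(
        SpinParams(s2=1.0, tau_c=tau_c_ns, tau_e=0.0, rex=0.0, field_h1=field_h1_mhz))
    return r2 / r1
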