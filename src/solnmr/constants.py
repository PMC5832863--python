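"""Physical constants used across the relaxation and thermodynamics modules.

All spin-interaction constants are collected here (and echoed into run
manifests) so that every derived rate is traceable to one set of values.
"""

import math

#: Vacuum permeability, T^2 m^3 J^-1 (SI).
MU_0 = 4.0e-7 * math.pi

#: Reduced Planck constant, J s.
HBAR = 1.054571817e-34

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.6752218744e8

#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative).
GAMMA_N = GAMMA_H / -9.8656

#: N-H bond length used for the dipolar coupling, m (1.02 Angstrom).
R_NH = 1.02e-10

#: 15N chemical-shift anisotropy, ppm (axially symmetric, sigma_par - sigma_perp).
CSA_N_PPM = -172.0

#: Gas constant in kcal mol^-1 K^-1, for Delta-G = R T ln(KD).
R_KCAL = 1.987e-3

#: Conventional lab temperature for experiments quoted at 25 degrees C, K.
T_STANDARD = 298.15


def dipolar_coupling_constant(r_nh: float = R_NH) -> float:
    """N-H dipolar interaction constant d = (mu0/4pi) hbar gammaH gammaN / r^3,
    in rad s^-1.  Negative because gammaN < 0; rates use d**2."""
    return (MU_0 / (4.0 * math.pi)) * HBAR * GAMMA_H * GAMMA_N / r_nh**3


def larmor_omega(field_h1_mhz: float) -> tuple[float, float]:
    """Angular Larmor frequencies (omega_H, omega_N) in rad s^-1 for a
    spectrometer stated by its 1H frequency in MHz.

    omega_N carries the sign of gamma_N; spectral densities are even in
    omega so only magnitudes matter downstream, but sums/differences
    (omega_H +/- omega_N) must be formed with signed values.
    """
    omega_h = 2.0 * math.pi * field_h1_mhz * 1e6
    omega_n = omega_h * (GAMMA_N / GAMMA_H)
    return omega_h, omega_n
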