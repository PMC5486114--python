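"""Dipolar relaxation rate constants for homonuclear 1H spin pairs.

Convention: the reduced spectral density is J(w) = tau / (1 + w^2 tau^2);
all physical prefactors live in the dipolar constant ``DIPOLAR_Q`` so the
cross- and auto-relaxation rates are

    sigma = (q / r^6) * (6 J(2 w0) - J(0))
    rho   = (q / r^6) * (J(0) + 3 J(w0) + 6 J(2 w0))

with q = (1/10) * gamma_H^4 * hbar^2 * (mu0 / 4 pi)^2.
"""

from __future__ import annotations

import math

__all__ = [
    "DIPOLAR_Q",
    "spectral_density",
    "methyl_spectral_density",
    "cross_relaxation_rate",
    "auto_relaxation_rate",
]

GAMMA_H = 2.6752218744e8  # 1H gyromagnetic ratio, rad s^-1 T^-1 (CODATA 2018)
HBAR = 1.054571817e-34  # J s
MU0_OVER_4PI = 1.0e-7  # T m A^-1

#: Dipolar constant q = (1/10) gamma^4 hbar^2 (mu0/4pi)^2, in m^6 s^-2.
#: Numerically 5.6965e-50; dividing by r^6 in m^6 and multiplying by a
#: spectral density in seconds yields a rate in s^-1.
DIPOLAR_Q = 0.1 * GAMMA_H**4 * HBAR**2 * MU0_OVER_4PI**2

ANGSTROM = 1.0e-10
MIN_PROTON_SEPARATION_A = 0.5  # below this, nuclei would overlap


def spectral_density(omega: float, tau: float) -> float:
    """Isotropic rigid-rotor reduced spectral density J(w) = tau/(1+w^2 tau^2)."""
    if tau <= 0:
        raise ValueError("correlation time must be positive")
    return tau / (1.0 + (omega * tau) ** 2)


def methyl_spectral_density(
    omega: float,
    tau_c: float,
    tau_internal: float,
    order_param_sq: float = 0.25,
) -> float:
    """Model-free spectral density for pairs involving methyl protons.

    J = S^2 * tau_c/(1 + w^2 tau_c^2) + (1 - S^2) * tau_e/(1 + w^2 tau_e^2)
    with 1/tau_e = 1/tau_c + 1/tau_internal.  ``order_param_sq`` is S^2.
    """
    if not 0.0 <= order_param_sq <= 1.0:
        raise ValueError("order parameter S^2 must lie in [0, 1]")
    if tau_internal <= 0 or tau_c <= 0:
        raise ValueError("correlation times must be positive")
    if tau_internal >= tau_c:
        raise ValueError("internal correlation time must be shorter than tau_c")
    tau_e = 1.0 / (1.0 / tau_c + 1.0 / tau_internal)
    return order_param_sq * spectral_density(omega, tau_c) + (
        1.0 - order_param_sq
    ) * spectral_density(omega, tau_e)


def _check_distance(r_angstrom: float) -> float:
    if r_angstrom < MIN_PROTON_SEPARATION_A:
        raise ValueError(
            f"interproton distance {r_angstrom} A is unphysically short"
        )
    return r_angstrom * ANGSTROM


def cross_relaxation_rate(
    r_angstrom: float,
    tau: float,
    omega0: float,
    j_of=None,
) -> float:
    """Dipolar cross-relaxation rate sigma (s^-1) for a proton pair.

    Positive for fast tumbling, negative past w0*tau = sqrt(5)/2 (the
    spin-diffusion / negative-NOE regime).  ``j_of`` may override the
    spectral density as a callable J(omega) (e.g. the methyl model-free
    form); ``tau`` is ignored when it is given.
    """
    r = _check_distance(r_angstrom)
    j = j_of if j_of is not None else (lambda w: spectral_density(w, tau))
    return (DIPOLAR_Q / r**6) * (6.0 * j(2.0 * omega0) - j(0.0))


def auto_relaxation_rate(
    r_angstrom: float,
    tau: float,
    omega0: float,
    j_of=None,
) -> float:
    """Dipolar auto-relaxation contribution rho (s^-1) of one pair partner."""
    r = _check_distance(r_angstrom)
    j = j_of if j_of is not None else (lambda w: spectral_density(w, tau))
    return (DIPOLAR_Q / r**6) * (
        j(0.0) + 3.0 * j(omega0) + 6.0 * j(2.0 * omega0)
    )
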