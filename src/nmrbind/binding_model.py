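"""Equilibrium and two-site exchange arithmetic shared by the estimators.

All public functions work in a single consistent molar unit: as long as
``p0``, ``l0`` and ``kd`` share a unit (M, µM, mM, ...), the returned complex
concentration carries that same unit and the bound fraction is dimensionless.
The dataclasses that hold experiment conditions accept µM/mM at the interface
and convert once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SampleConditions",
    "ExchangeKinetics",
    "solve_mass_balance",
    "bound_fraction",
    "free_concentrations",
    "DEFAULT_KON",
]

#: Diffusion-limited association rate (M^-1 s^-1) assumed when only an
#: equilibrium constant is known.  Overridable everywhere it is consumed.
DEFAULT_KON = 1.0e8

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SampleConditions:
    """NMR sample conditions for a binding experiment.

    Parameters
    ----------
    protein_total_conc_uM : float
        Total protein concentration in µM.
    ligand_total_conc_uM : float
        Total ligand concentration in µM.
    temperature_K : float
        Sample temperature in kelvin.
    spectrometer_MHz : float
        Proton resonance frequency in MHz; the Larmor angular frequency in
        rad/s is derived from it.
    """

    protein_total_conc_uM: float
    ligand_total_conc_uM: float
    temperature_K: float = 298.0
    spectrometer_MHz: float = 600.0
    field_larmor_1H: float = field(init=False)

    def __post_init__(self) -> None:
        if self.protein_total_conc_uM <= 0:
            raise ValueError("protein concentration must be positive")
        if self.ligand_total_conc_uM <= 0:
            raise ValueError("ligand concentration must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.spectrometer_MHz <= 0:
            raise ValueError("spectrometer frequency must be positive")
        object.__setattr__(
            self, "field_larmor_1H", TWO_PI * self.spectrometer_MHz * 1e6
        )

    @property
    def protein_total_conc_M(self) -> float:
        return self.protein_total_conc_uM * 1e-6

    @property
    def ligand_total_conc_M(self) -> float:
        return self.ligand_total_conc_uM * 1e-6

    @property
    def ligand_excess(self) -> float:
        """Molar ratio [L]0/[P]0 (the '1:N' excess of an STD sample)."""
        return self.ligand_total_conc_uM / self.protein_total_conc_uM


def _check_concs(p0: float, l0: float, kd: float) -> None:
    if p0 <= 0 or l0 <= 0:
        raise ValueError(
            f"total concentrations must be positive (got p0={p0}, l0={l0})"
        )
    if kd < 0:
        raise ValueError(f"dissociation constant must be non-negative (got {kd})")
    if not (math.isfinite(p0) and math.isfinite(l0)):
        raise ValueError("total concentrations must be finite")


def solve_mass_balance(p0: float, l0: float, kd: float) -> float:
    """Equilibrium complex concentration [PL] for 1:1 binding.

    Solves ``[PL]^2 - (p0 + l0 + kd)[PL] + p0*l0 = 0`` for the physical
    (smaller) root.  ``kd = 0`` is handled analytically as stoichiometric
    binding; ``kd = inf`` returns 0.  All three inputs must share a unit and
    the result carries it.
    """
    _check_concs(p0, l0, kd)
    if kd == 0.0:
        return min(p0, l0)
    if math.isinf(kd):
        return 0.0
    s = p0 + l0 + kd
    disc = s * s - 4.0 * p0 * l0
    # disc >= (p0 - l0)^2 + kd^2 > 0 but guard against rounding
    root = math.sqrt(max(disc, 0.0))
    # stable form of the smaller quadratic root (avoids cancellation when
    # kd >> p0*l0 / s)
    pl = 2.0 * p0 * l0 / (s + root)
    return min(pl, p0, l0)


def bound_fraction(p0: float, l0: float, kd: float) -> float:
    """Fraction of ligand bound, f_bound = [PL]/[L]0, in [0, min(1, p0/l0)]."""
    return solve_mass_balance(p0, l0, kd) / l0


def free_concentrations(p0: float, l0: float, kd: float) -> tuple[float, float]:
    """Equilibrium free protein and free ligand, ([P]f, [L]f).

    Each free concentration solves its own quadratic, written in the
    cancellation-free form (e.g. [P]f = 2 kd p0 / (b + sqrt(b^2 + 4 kd p0))
    with b = l0 - p0 + kd when b >= 0), so detailed balance
    [P]f [L]f = kd [PL] holds to ~1e-12 relative even when one species is
    almost fully bound and the naive ``p0 - [PL]`` difference would lose
    most of its digits.
    """
    _check_concs(p0, l0, kd)
    if kd == 0.0:
        pl = min(p0, l0)
        return p0 - pl, l0 - pl
    if math.isinf(kd):
        return p0, l0

    def _free(total: float, other: float) -> float:
        b = other - total + kd
        root = math.sqrt(b * b + 4.0 * kd * total)
        if b >= 0.0:
            return 2.0 * kd * total / (b + root)
        return 0.5 * (-b + root)

    return _free(p0, l0), _free(l0, p0)


@dataclass(frozen=True)
class ExchangeKinetics:
    """Two-site exchange kinetics derived from equilibrium conditions.

    Concentrations are stored in M.  ``koff = kd * kon`` holds by
    construction; ``bound_lifetime`` is ``1/koff``.
    """

    kd_M: float
    kon_per_M_s: float
    complex_conc_M: float
    free_protein_M: float
    free_ligand_M: float
    bound_fraction_ligand: float

    @property
    def koff_per_s(self) -> float:
        return self.kd_M * self.kon_per_M_s

    @property
    def bound_lifetime_s(self) -> float:
        koff = self.koff_per_s
        if koff == 0.0:
            return math.inf
        return 1.0 / koff

    @property
    def pseudo_first_order_kon_per_s(self) -> float:
        """Binding rate of a free ligand molecule, kon*[P]free (s^-1)."""
        return self.kon_per_M_s * self.free_protein_M

    @classmethod
    def from_equilibrium(
        cls,
        p0_M: float,
        l0_M: float,
        kd_M: float,
        kon_per_M_s: float = DEFAULT_KON,
    ) -> "ExchangeKinetics":
        if kon_per_M_s <= 0:
            raise ValueError("kon must be positive")
        pl = solve_mass_balance(p0_M, l0_M, kd_M)
        pf, lf = free_concentrations(p0_M, l0_M, kd_M)
        return cls(
            kd_M=kd_M,
            kon_per_M_s=kon_per_M_s,
            complex_conc_M=pl,
            free_protein_M=pf,
            free_ligand_M=lf,
            bound_fraction_ligand=pl / l0_M,
        )
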