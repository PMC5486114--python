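"""Exchange-coupled relaxation-matrix propagation of saturation transfer.

The magnetization vector stacks three pools: free-ligand spins, bound-ligand
spins and bound-protein spins (free protein is omitted: at the large ligand
excess of an STD sample its saturation dynamics do not feed back on the
ligand).  Relaxation acts within each molecular species; chemical exchange
couples the two ligand pools with pseudo-first-order rate kon*[P]free into
the complex and koff out of it.  Saturated protein spins are clamped at zero
z-magnetization from t=0 and the remaining deviation magnetization evolves
as a linear system solved by eigendecomposition (matrix-exponential
fallback).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from nmrbind.binding_model import DEFAULT_KON, ExchangeKinetics
from nmrbind.corcema.rates import (
    DIPOLAR_Q,
    ANGSTROM,
    MIN_PROTON_SEPARATION_A,
    methyl_spectral_density,
    spectral_density,
)
from nmrbind.corcema.spin_system import SpinSystem

__all__ = [
    "CorcemaConditions",
    "CorcemaResult",
    "build_relaxation_matrix",
    "assemble_exchange_system",
    "predict_std",
    "noe_r_factor",
]


@dataclass(frozen=True)
class CorcemaConditions:
    """Kinetic and spectroscopic conditions for the STD forward simulation.

    Defaults follow the benchmark conditions of the packaged workflows:
    30 µM protein, 1.5 mM ligand, Kd 10 µM, correlation times 22 ns
    (complex) and 0.4 ns (free ligand), 8 A protein-proton cutoff and a
    10 ps methyl internal correlation time at 600 MHz.
    """

    tau_c_free_ns: float = 0.4
    tau_c_bound_ns: float = 22.0
    tau_methyl_internal_ps: float = 10.0
    methyl_order_param_sq: float = 0.25
    p0_uM: float = 30.0
    l0_mM: float = 1.5
    kd_uM: float = 10.0
    kon_per_M_s: float = DEFAULT_KON
    spectrometer_MHz: float = 600.0
    distance_cutoff_A: float = 8.0
    leak_rate_per_s: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "tau_c_free_ns",
            "tau_c_bound_ns",
            "tau_methyl_internal_ps",
            "p0_uM",
            "l0_mM",
            "kon_per_M_s",
            "spectrometer_MHz",
            "distance_cutoff_A",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kd_uM < 0 or self.leak_rate_per_s < 0:
            raise ValueError("kd and leak rate must be non-negative")

    @property
    def omega0(self) -> float:
        return 2.0 * np.pi * self.spectrometer_MHz * 1e6

    def kinetics(self) -> ExchangeKinetics:
        return ExchangeKinetics.from_equilibrium(
            p0_M=self.p0_uM * 1e-6,
            l0_M=self.l0_mM * 1e-3,
            kd_M=self.kd_uM * 1e-6,
            kon_per_M_s=self.kon_per_M_s,
        )


@dataclass
class CorcemaResult:
    """Predicted per-proton STD build-up, optionally scored vs experiment."""

    saturation_times: np.ndarray
    ligand_labels: list[str]
    std_fractions: np.ndarray  # (n_ligand_protons, n_times)
    experimental: np.ndarray | None = None

    def r_factor(self) -> float:
        if self.experimental is None:
            raise ValueError("no experimental STD attached")
        return noe_r_factor(self.std_fractions, self.experimental)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.std_fractions,
            index=self.ligand_labels,
            columns=[f"t={t:g}s" for t in self.saturation_times],
        )


def _pair_spectral_densities(
    omega0: float, tau: float, conds: CorcemaConditions
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """(J(0), J(w0), J(2w0)) for rigid pairs and for methyl-involving pairs."""
    rigid = tuple(spectral_density(w, tau) for w in (0.0, omega0, 2.0 * omega0))
    methyl = tuple(
        methyl_spectral_density(
            w, tau, conds.tau_methyl_internal_ps * 1e-12,
            conds.methyl_order_param_sq,
        )
        for w in (0.0, omega0, 2.0 * omega0)
    )
    return rigid, methyl


def _relaxation_matrix_from_coords(
    coords: np.ndarray,
    methyl_ids: np.ndarray,
    tau: float,
    conds: CorcemaConditions,
) -> np.ndarray:
    n = coords.shape[0]
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < MIN_PROTON_SEPARATION_A):
        raise ValueError("interproton distance below 0.5 A: unphysical overlap")
    with np.errstate(divide="ignore"):
        inv_r6 = np.where(off, (r * ANGSTROM) ** -6.0, 0.0)

    (j0, jw, j2w), (mj0, mjw, mj2w) = _pair_spectral_densities(
        conds.omega0, tau, conds
    )
    is_methyl = methyl_ids >= 0
    methyl_pair = is_methyl[:, None] | is_methyl[None, :]
    sigma_scale = np.where(methyl_pair, 6.0 * mj2w - mj0, 6.0 * j2w - j0)
    rho_scale = np.where(
        methyl_pair, mj0 + 3.0 * mjw + 6.0 * mj2w, j0 + 3.0 * jw + 6.0 * j2w
    )
    sigma = DIPOLAR_Q * inv_r6 * sigma_scale
    rho_pairs = DIPOLAR_Q * inv_r6 * rho_scale

    R = sigma.copy()
    np.fill_diagonal(R, rho_pairs.sum(axis=1) + conds.leak_rate_per_s)
    return R


def build_relaxation_matrix(
    system: SpinSystem,
    state: str,
    conds: CorcemaConditions,
) -> tuple[np.ndarray, np.ndarray]:
    """Dipolar relaxation matrix R for one exchange state.

    ``state="free"`` uses the free-ligand geometry and the free correlation
    time over ligand protons only.  ``state="bound"`` uses the complex
    geometry and the bound correlation time over ligand protons plus the
    protein protons within ``distance_cutoff_A`` of any ligand proton.

    Returns ``(R, indices)`` where ``indices`` maps matrix rows back to
    proton indices of the system (free state: ligand proton positions).
    """
    lig_idx = np.flatnonzero(system.is_ligand)
    if state == "free":
        coords = system.free_ligand_coords()
        idx = lig_idx
        methyl = system.methyl_ids[lig_idx]
        tau = conds.tau_c_free_ns * 1e-9
    elif state == "bound":
        prot_idx = np.flatnonzero(system.is_protein)
        lig_xyz = system.coords_bound[lig_idx]
        prot_xyz = system.coords_bound[prot_idx]
        if prot_idx.size:
            d = np.linalg.norm(
                prot_xyz[:, None, :] - lig_xyz[None, :, :], axis=-1
            ).min(axis=1)
            prot_idx = prot_idx[d <= conds.distance_cutoff_A]
        if prot_idx.size == 0:
            raise ValueError(
                "no protein protons within "
                f"{conds.distance_cutoff_A} A of the ligand"
            )
        idx = np.concatenate([lig_idx, prot_idx])
        coords = system.coords_bound[idx]
        methyl = system.methyl_ids[idx]
        tau = conds.tau_c_bound_ns * 1e-9
    else:
        raise ValueError(f"unknown state {state!r}; expected 'free' or 'bound'")
    if idx.size < 2:
        raise ValueError("need at least 2 protons in the state")
    return _relaxation_matrix_from_coords(coords, methyl, tau, conds), idx


def assemble_exchange_system(
    system: SpinSystem, conds: CorcemaConditions
) -> dict:
    """Assemble the full exchange-coupled linear system.

    Returns a dict with the dynamics matrix ``D`` (dM'/dt = -D M' for the
    deviation magnetization M' = M - M_eq), the equilibrium magnetization
    ``m_eq`` in concentration units (M), the boolean ``clamped`` mask of
    saturated spins, and the pool layout.  Exposed separately so the
    propagation can be cross-checked against direct ODE integration.
    """
    kin = conds.kinetics()
    n_lig = int(system.is_ligand.sum())
    if n_lig == 0:
        raise ValueError("system has no ligand protons")

    R_bound, bound_idx = build_relaxation_matrix(system, "bound", conds)
    n_bound = bound_idx.size
    n_prot = n_bound - n_lig
    n_tot = n_lig + n_bound  # free-ligand + bound pools

    R = np.zeros((n_tot, n_tot))
    if n_lig >= 2:
        R_free, _ = build_relaxation_matrix(system, "free", conds)
        R[:n_lig, :n_lig] = R_free
    else:
        R[0, 0] = conds.leak_rate_per_s
    R[n_lig:, n_lig:] = R_bound

    # exchange block: free-ligand spin i <-> bound-ligand spin i; column sums
    # of K vanish so total magnetization of each pair is exchange-conserved
    k_on_pseudo = kin.pseudo_first_order_kon_per_s
    k_off = kin.koff_per_s
    K = np.zeros((n_tot, n_tot))
    for i in range(n_lig):
        K[i, i] -= k_on_pseudo
        K[n_lig + i, i] += k_on_pseudo
        K[n_lig + i, n_lig + i] -= k_off
        K[i, n_lig + i] += k_off

    m_eq = np.concatenate(
        [
            np.full(n_lig, kin.free_ligand_M),
            np.full(n_lig, kin.complex_conc_M),
            np.full(n_prot, kin.complex_conc_M),
        ]
    )
    clamped = np.zeros(n_tot, dtype=bool)
    clamped[2 * n_lig:] = system.saturated[bound_idx[n_lig:]]

    return {
        "D": R - K,
        "m_eq": m_eq,
        "clamped": clamped,
        "n_ligand": n_lig,
        "bound_indices": bound_idx,
        "kinetics": kin,
    }


def _propagate(
    D_ff: np.ndarray,
    m_ss: np.ndarray,
    times: np.ndarray,
    method: str,
) -> np.ndarray:
    """Deviation magnetization of the free-evolving spins at each time.

    Solves m(t) = m_ss - exp(-D_ff t) m_ss (initial deviation zero).
    Returns shape (n_times, n_free).
    """
    if method == "eig":
        w, V = np.linalg.eig(D_ff)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            method = "expm"  # defective or near-defective: fall back
        else:
            c = np.linalg.solve(V, m_ss)
            out = np.empty((times.size, m_ss.size))
            for k, t in enumerate(times):
                mt = m_ss - (V * np.exp(-w * t)) @ c
                out[k] = mt.real
            return out
    if method == "expm":
        out = np.empty((times.size, m_ss.size))
        for k, t in enumerate(times):
            out[k] = m_ss - scipy.linalg.expm(-D_ff * t) @ m_ss
        return out
    raise ValueError(f"unknown propagation method {method!r}")


def predict_std(
    system: SpinSystem,
    conds: CorcemaConditions,
    saturation_times,
    method: str = "eig",
) -> CorcemaResult:
    """Predicted STD fraction per ligand proton at each saturation time.

    Saturated protein spins are clamped at zero z-magnetization from t=0;
    each ligand proton's STD is the population-weighted deficit of its free
    and bound pools relative to the total ligand magnetization.
    """
    times = np.asarray(saturation_times, dtype=float)
    if times.ndim != 1 or np.any(times < 0):
        raise ValueError("saturation times must be a 1-D array of non-negatives")

    sysd = assemble_exchange_system(system, conds)
    n_lig = sysd["n_ligand"]
    lig_labels = system.ligand_labels
    D, m_eq, clamped = sysd["D"], sysd["m_eq"], sysd["clamped"]

    l_total = m_eq[0] + m_eq[n_lig]  # free + bound ligand concentration
    if not np.any(clamped) or sysd["kinetics"].complex_conc_M == 0.0:
        # nothing perturbed (or no complex): no transfer at any time
        return CorcemaResult(times, lig_labels, np.zeros((n_lig, times.size)))

    free_ix = np.flatnonzero(~clamped)
    sat_ix = np.flatnonzero(clamped)
    D_ff = D[np.ix_(free_ix, free_ix)]
    D_fs = D[np.ix_(free_ix, sat_ix)]

    # clamped deviation is -m_eq; steady state solves D_ff m_ss = D_fs m_eq_S
    rhs = D_fs @ m_eq[sat_ix]
    try:
        m_ss = np.linalg.solve(D_ff, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular dynamics matrix: no relaxation path") from exc

    dev = _propagate(D_ff, m_ss, times, method)  # (n_times, n_free)

    # map free-evolving rows back to pool positions
    full = np.zeros((times.size, D.shape[0]))
    full[:, free_ix] = dev
    full[:, sat_ix] = -m_eq[sat_ix]

    std = -(full[:, :n_lig] + full[:, n_lig : 2 * n_lig]) / l_total
    return CorcemaResult(times, lig_labels, std.T.copy())


def noe_r_factor(predicted, experimental) -> float:
    """Normalized discrepancy sqrt(sum (exp-calc)^2 / sum exp^2)."""
    calc = np.asarray(predicted, dtype=float).ravel()
    exp = np.asarray(experimental, dtype=float).ravel()
    if calc.size == 0 or calc.shape != exp.shape:
        raise ValueError("predicted and experimental must align and be non-empty")
    denom = float((exp**2).sum())
    if denom == 0.0:
        raise ValueError("R-factor undefined: experimental values are all zero")
    return float(np.sqrt(((exp - calc) ** 2).sum() / denom))
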