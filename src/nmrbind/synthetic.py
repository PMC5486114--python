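"""Seedable generators for every pipeline input.

Each generator is the pushforward of the corresponding estimator's model, so
noise-free generation followed by estimation is the identity on parameters.
All randomness flows through a single :class:`numpy.random.Generator` held
by the :class:`NoiseModel`; re-creating a model with the same seed
reproduces the byte stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from nmrbind.corcema.spin_system import SpinSystem
from nmrbind.std_affinity import AFTitration
from nmrbind.std_buildup import BuildupCurve
from nmrbind.t1sel import InversionRecoveryTrace, T1Titration, model_t1obs

__all__ = [
    "NoiseModel",
    "DEFAULT_T1_LADDER_UM",
    "DEFAULT_SATURATION_TIMES_S",
    "gen_buildup",
    "gen_af_titration",
    "gen_t1_titration",
    "gen_toy_complex",
]

#: Ligand ladder of the packaged selective-T1 benchmark (µM, at 20 µM protein).
DEFAULT_T1_LADDER_UM = (80.0, 160.0, 320.0, 480.0, 640.0)
#: Saturation-time grid of the packaged STD benchmark (s).
DEFAULT_SATURATION_TIMES_S = (0.5, 1.0, 2.0, 3.0, 4.0)


@dataclass
class NoiseModel:
    """Additive Gaussian noise, relative to signal or absolute.

    ``sigma`` is interpreted as a fraction of each signal value when
    ``kind="fraction"`` and as an absolute standard deviation when
    ``kind="absolute"``.  ``sigma=0`` returns exact model values.
    """

    sigma: float = 0.0
    kind: str = "fraction"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind not in ("fraction", "absolute"):
            raise ValueError("kind must be 'fraction' or 'absolute'")
        self._rng = np.random.default_rng(self.seed)

    @property
    def rng(self) -> np.random.Generator:
        return self._rng

    def apply(self, signal: np.ndarray) -> np.ndarray:
        signal = np.asarray(signal, dtype=float)
        if self.sigma == 0.0:
            return signal.copy()
        scale = (
            self.sigma * np.abs(signal) if self.kind == "fraction" else self.sigma
        )
        return signal + self._rng.normal(0.0, 1.0, signal.shape) * scale


def gen_buildup(
    a: float,
    b: float,
    times=DEFAULT_SATURATION_TIMES_S,
    noise: NoiseModel | None = None,
    proton_label: str = "H1",
    ligand_id: str = "syn",
) -> BuildupCurve:
    """STD build-up curve from ``a*(1-exp(-b*t))`` plus optional noise.

    Noisy values are clipped to the physical [0, 1] range of an STD
    fraction.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("plateau a must lie in [0, 1]")
    if b <= 0:
        raise ValueError("rate b must be positive")
    t = np.asarray(times, dtype=float)
    y = a * (1.0 - np.exp(-b * t))
    if noise is not None:
        y = np.clip(noise.apply(y), 0.0, 1.0)
    return BuildupCurve(
        proton_label=proton_label,
        ligand_id=ligand_id,
        saturation_times=t,
        std_fractions=y,
    )


def gen_af_titration(
    af0_max: float,
    ic50: float,
    ladder=None,
    noise: NoiseModel | None = None,
    protein_conc: float = 19e-3,
) -> AFTitration:
    """STD-AF0 Langmuir isotherm ``af0_max*L/(L+ic50)`` over a ladder.

    Default ladder is a geometric series bracketing the IC50 (the packaged
    choice for identifiability of both parameters); units follow ``ic50``.
    """
    if af0_max <= 0 or ic50 <= 0:
        raise ValueError("af0_max and ic50 must be positive")
    if ladder is None:
        ladder = ic50 * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    c = np.asarray(ladder, dtype=float)
    v = af0_max * c / (c + ic50)
    if noise is not None:
        v = np.clip(noise.apply(v), 0.0, None)
    return AFTitration(ligand_concs=c, protein_conc=protein_conc, af0_values=v)


def _ir_trace(
    t1: float,
    l0_uM: float,
    p0_uM: float,
    noise: NoiseModel | None,
    i0: float = 1.0,
    amp: float = 2.0,
    n_delays: int = 12,
) -> InversionRecoveryTrace:
    # delays span ~4*T1 so the plateau is constrained
    delays = np.concatenate([[0.01 * t1], np.linspace(0.1, 4.0, n_delays - 1) * t1])
    y = i0 * (1.0 - amp * np.exp(-delays / t1))
    if noise is not None:
        y = noise.apply(y)
    return InversionRecoveryTrace(
        recovery_delays=delays,
        intensities=y,
        ligand_conc_uM=l0_uM,
        protein_conc_uM=p0_uM,
    )


def gen_t1_titration(
    ic50_uM: float,
    ladder_uM=DEFAULT_T1_LADDER_UM,
    p0_uM: float = 20.0,
    t1_bound_plus_tau_s: float = 0.1,
    noise: NoiseModel | None = None,
    mode: str = "linear",
    t1_free_s: float = math.inf,
    fbound_method: str = "linear",
    as_traces: bool = False,
):
    """Selective-T1 titration from the linear or the full two-site model.

    ``mode="linear"`` generates ``T1obs = ([L]0 + IC50)(T1b + taub)/[P]0``,
    exactly the model the x-intercept estimator inverts.  ``mode="full"``
    adds a finite free-ligand T1; its bound fraction uses the same
    excess-ligand approximation by default (so the two modes agree in the
    ``t1_free -> inf`` limit) or the exact quadratic mass balance with
    ``fbound_method="exact"``.  With ``as_traces=True`` each concentration
    yields a synthetic inversion-recovery trace instead of a (conc, T1obs)
    row; noise then acts on trace intensities rather than on T1obs
    directly.
    """
    if ic50_uM < 0 or p0_uM <= 0 or t1_bound_plus_tau_s <= 0:
        raise ValueError("invalid titration parameters")
    if mode not in ("linear", "full"):
        raise ValueError("mode must be 'linear' or 'full'")
    c = np.asarray(ladder_uM, dtype=float)
    if mode == "linear":
        t1obs = (c + ic50_uM) * t1_bound_plus_tau_s / p0_uM
    else:
        t1obs = np.array(
            [
                model_t1obs(
                    l0_uM=l,
                    p0_uM=p0_uM,
                    kd_uM=ic50_uM,
                    t1_free_s=t1_free_s,
                    t1_bound_s=t1_bound_plus_tau_s,
                    tau_bound_s=0.0,
                    fbound_method=fbound_method,
                )
                for l in c
            ]
        )
    if as_traces:
        return [
            _ir_trace(t1, l0_uM=l, p0_uM=p0_uM, noise=noise)
            for t1, l in zip(t1obs, c)
        ]
    if noise is not None:
        t1obs = np.clip(noise.apply(t1obs), 1e-12, None)
    return T1Titration(
        ligand_concs_uM=c,
        t1_obs_s=t1obs,
        protein_conc_uM=p0_uM,
        t1_free_s=None if math.isinf(t1_free_s) else t1_free_s,
    )


def gen_toy_complex(
    n_ligand_protons: int,
    n_protein_protons: int,
    seed: int = 0,
    min_separation_A: float = 1.7,
    shell_A: float = 6.0,
    max_attempts: int = 2000,
) -> SpinSystem:
    """Random but physical toy complex for the relaxation-matrix engine.

    Protons are packed by rejection sampling inside a compact box with all
    pairwise distances >= ``min_separation_A``; every ligand proton ends up
    within ``shell_A`` of at least one protein proton so the bound-state
    cutoff always finds neighbors.  All protein protons are marked
    saturated.  Deterministic for a fixed seed.
    """
    if n_ligand_protons < 1 or n_protein_protons < 1:
        raise ValueError("need at least one proton of each owner")
    rng = np.random.default_rng(seed)
    n = n_ligand_protons + n_protein_protons
    # box sized to hold n spheres comfortably at the required separation
    box = min_separation_A * max(2.0, 1.2 * n ** (1.0 / 3.0) + 1.0)

    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        if attempts > max_attempts:
            raise RuntimeError(
                f"packing failed after {max_attempts} attempts "
                f"(n={n}, box={box:.1f} A)"
            )
        attempts += 1
        # protein protons first, then ligand protons biased to sit near them
        if len(placed) < n_protein_protons:
            cand = rng.uniform(0.0, box, 3)
        else:
            anchor = placed[rng.integers(0, n_protein_protons)]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(min_separation_A, shell_A)
            cand = anchor + radius * direction
        if all(np.linalg.norm(cand - p) >= min_separation_A for p in placed):
            placed.append(cand)

    coords = np.array(placed)
    # vector layout: ligand protons first
    coords = np.concatenate([coords[n_protein_protons:], coords[:n_protein_protons]])
    owners = ["ligand"] * n_ligand_protons + ["protein"] * n_protein_protons
    labels = [f"L{i + 1}" for i in range(n_ligand_protons)] + [
        f"P{i + 1}" for i in range(n_protein_protons)
    ]
    saturated = np.array([False] * n_ligand_protons + [True] * n_protein_protons)
    return SpinSystem(
        labels=labels,
        owners=owners,
        coords_bound=coords,
        saturated=saturated,
    )
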