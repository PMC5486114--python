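"""STD build-up curve fitting and initial rates (STD0).

The saturation-transfer-difference fraction of a ligand proton grows with
saturation time as ``STD(t) = a * (1 - exp(-b*t))``; the initial rate
``STD0 = a*b`` is a relaxation-corrected measure of transfer efficiency.
Per-proton STD0 values are reported both absolute and relative to the
strongest proton of a compound (scaled to 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BuildupCurve", "BuildupFit", "FitError", "fit_buildup", "relative_std0"]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge after bounded restarts."""


def _buildup_model(t: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * (1.0 - np.exp(-b * t))


@dataclass(frozen=True)
class BuildupCurve:
    """Per-proton STD fraction versus saturation time.

    ``std_fractions`` are the dimensionless (I0 - Isat)/I0 values; times are
    in seconds, strictly increasing and positive.
    """

    proton_label: str
    ligand_id: str
    saturation_times: np.ndarray
    std_fractions: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.saturation_times, dtype=float)
        y = np.asarray(self.std_fractions, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and std fractions must be 1-D of equal length")
        if t.size and (np.any(t <= 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("saturation times must be strictly increasing and > 0")
        if np.any(y < -1e-12) or np.any(y > 1 + 1e-12):
            raise ValueError("std fractions must lie in [0, 1]")
        object.__setattr__(self, "saturation_times", t)
        object.__setattr__(self, "std_fractions", y)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != t.shape or np.any(s <= 0):
                raise ValueError("sigma must be positive and match the data length")
            object.__setattr__(self, "sigma", s)


@dataclass(frozen=True)
class BuildupFit:
    """Result of a mono-exponential build-up fit.

    ``std_max`` is the asymptotic plateau (coefficient a), ``k_sat`` the
    build-up rate in 1/s (coefficient b) and ``std0 = std_max * k_sat`` the
    initial rate in 1/s.
    """

    proton_label: str
    ligand_id: str
    std_max: float
    k_sat: float
    residual_norm: float
    std_max_err: float
    k_sat_err: float

    @property
    def std0(self) -> float:
        return self.std_max * self.k_sat

    @property
    def std0_err(self) -> float:
        # first-order propagation ignoring the (reported-anyway) covariance
        return float(
            np.hypot(self.k_sat * self.std_max_err, self.std_max * self.k_sat_err)
        )


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # a: plateau ~ largest observed fraction; b: log-linearized slope of the
    # first two points, since e^{-bt} = 1 - y/a
    a0 = float(np.max(y))
    if a0 <= 0:
        return 1e-6, 1.0
    z = np.clip(1.0 - y[:2] / (a0 * 1.05), 1e-9, None)
    with np.errstate(divide="ignore"):
        slope = np.polyfit(t[:2], np.log(z), 1)[0]
    b0 = max(-float(slope), 1e-3)
    return a0, b0


def fit_buildup(curve: BuildupCurve, max_restarts: int = 2, seed: int = 0) -> BuildupFit:
    """Least-squares fit of ``a*(1 - exp(-b*t))`` to an STD build-up curve.

    On noise-free model data the generating ``(a, b)`` are recovered to
    better than 1e-6 relative.  On failure of the deterministic start, up to
    ``max_restarts`` seeded random restarts are attempted before raising
    :class:`FitError`.
    """
    t = curve.saturation_times
    y = curve.std_fractions
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct saturation times")
    if np.any(y < 0):
        warnings.warn(
            f"negative STD fractions for {curve.ligand_id}/{curve.proton_label}; "
            "fitting with plateau bounded at 0",
            stacklevel=2,
        )

    if np.all(y == 0.0):
        # flat-zero data: the plateau is exactly 0 and the rate is moot
        return BuildupFit(
            proton_label=curve.proton_label,
            ligand_id=curve.ligand_id,
            std_max=0.0,
            k_sat=0.0,
            residual_norm=0.0,
            std_max_err=np.inf,
            k_sat_err=np.inf,
        )

    rng = np.random.default_rng(seed)
    a0, b0 = _initial_guesses(t, y)
    starts = [(a0, b0)]
    starts += [
        (a0 * rng.uniform(0.5, 2.0), b0 * rng.uniform(0.2, 5.0))
        for _ in range(max_restarts)
    ]

    last_exc: Exception | None = None
    for a_start, b_start in starts:
        try:
            popt, pcov = curve_fit(
                _buildup_model,
                t,
                y,
                p0=[a_start, b_start],
                sigma=curve.sigma,
                absolute_sigma=curve.sigma is not None,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError as exc:  # pragma: no cover - rare on 5-point data
            last_exc = exc
            continue
        a, b = float(popt[0]), float(popt[1])
        resid = y - _buildup_model(t, a, b)
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
        return BuildupFit(
            proton_label=curve.proton_label,
            ligand_id=curve.ligand_id,
            std_max=a,
            k_sat=b,
            residual_norm=float(np.linalg.norm(resid)),
            std_max_err=float(perr[0]),
            k_sat_err=float(perr[1]),
        )
    raise FitError(
        f"build-up fit failed for {curve.ligand_id}/{curve.proton_label} after "
        f"{len(starts)} starts: {last_exc}"
    )


def relative_std0(fits: Sequence[BuildupFit | float]) -> list[float]:
    """Scale STD0 values to percent of the maximum (largest becomes 100).

    Accepts fit objects or raw STD0 numbers.  Raises if the collection is
    empty or all values are zero.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    values = np.array(
        [f.std0 if isinstance(f, BuildupFit) else float(f) for f in fits]
    )
    top = values.max()
    if top <= 0:
        raise ValueError("relative STD0 undefined: all STD0 are zero")
    return list(100.0 * values / top)
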