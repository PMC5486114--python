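"""STD amplification-factor titration and Langmuir IC50 estimation.

The amplification factor STD-AF multiplies the STD fraction by the ligand
excess [L]0/[P]0, so the initial slope of its build-up (STD-AF0) scales with
receptor occupancy.  Plotting STD-AF0 against ligand concentration gives a
Langmuir isotherm ``af0_max * L / (L + IC50)`` whose midpoint is the IC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from nmrbind.std_buildup import BuildupCurve, FitError, fit_buildup

__all__ = [
    "AFTitration",
    "LangmuirFit",
    "std_af",
    "af_buildup_initial_slope",
    "fit_langmuir",
]


@dataclass(frozen=True)
class AFTitration:
    """STD-AF0 initial slopes across a ligand concentration ladder.

    ``ligand_concs`` and the fitted IC50 share whatever concentration unit the
    caller uses (the packaged workflows use mM); ``protein_conc`` is the fixed
    receptor concentration in the same unit. ``af0_values`` are in 1/s.
    """

    ligand_concs: np.ndarray
    protein_conc: float
    af0_values: np.ndarray
    af0_errors: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_concs, dtype=float)
        v = np.asarray(self.af0_values, dtype=float)
        if c.ndim != 1 or v.shape != c.shape:
            raise ValueError("concentration and af0 arrays must match in length")
        if np.any(c <= 0):
            raise ValueError("ligand concentrations must be positive")
        if np.unique(c).size != c.size:
            raise ValueError("ligand concentrations must be distinct")
        if np.any(v < 0):
            raise ValueError("af0 values must be non-negative")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")
        object.__setattr__(self, "ligand_concs", c)
        object.__setattr__(self, "af0_values", v)
        if self.af0_errors is not None:
            e = np.asarray(self.af0_errors, dtype=float)
            if e.shape != c.shape or np.any(e <= 0):
                raise ValueError("af0 errors must be positive and match length")
            object.__setattr__(self, "af0_errors", e)


@dataclass(frozen=True)
class LangmuirFit:
    """Fitted binding isotherm ``af0(L) = af0_max * L / (L + ic50)``."""

    af0_max: float
    ic50: float
    residual_norm: float
    af0_max_err: float
    ic50_err: float

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        conc = np.asarray(conc, dtype=float)
        return self.af0_max * conc / (conc + self.ic50)


def std_af(std_fraction: float | np.ndarray, l0: float, p0: float) -> float | np.ndarray:
    """Amplification factor: STD fraction scaled by the ligand excess l0/p0."""
    if p0 <= 0:
        raise ValueError("protein concentration must be positive")
    if l0 <= 0:
        raise ValueError("ligand concentration must be positive")
    return np.asarray(std_fraction, dtype=float) * (l0 / p0) if np.ndim(
        std_fraction
    ) else float(std_fraction) * (l0 / p0)


def af_buildup_initial_slope(curve: BuildupCurve, l0: float, p0: float) -> float:
    """STD-AF0: initial slope of the amplification-factor build-up (1/s).

    Equals the excess ratio times the plain STD0 of the same curve; computed
    here by fitting the AF-scaled build-up directly so that error handling
    matches :func:`nmrbind.std_buildup.fit_buildup`.
    """
    if p0 <= 0 or l0 <= 0:
        raise ValueError("concentrations must be positive")
    excess = l0 / p0
    fit = fit_buildup(curve)
    # a*(1-e^{-bt}) scaled by a constant keeps b and scales a: AF0 = excess*a*b
    return excess * fit.std0


def _langmuir(conc: np.ndarray, af0_max: float, ic50: float) -> np.ndarray:
    return af0_max * conc / (conc + ic50)


def fit_langmuir(titration: AFTitration, seed: int = 0) -> LangmuirFit:
    """Least-squares Langmuir fit of an STD-AF0 isotherm.

    Warns when the titration does not saturate (largest concentration below
    the fitted IC50), in which case the reported uncertainty is wide.
    """
    c = titration.ligand_concs
    v = titration.af0_values
    if c.size < 3:
        raise ValueError("need at least 3 concentrations")

    rng = np.random.default_rng(seed)
    max_start = float(np.max(v)) or 1.0
    mid_start = float(np.median(c))
    starts = [(max_start, mid_start)] + [
        (max_start * rng.uniform(0.5, 3.0), mid_start * rng.uniform(0.2, 5.0))
        for _ in range(2)
    ]
    last_exc: Exception | None = None
    for a_s, k_s in starts:
        try:
            popt, pcov = curve_fit(
                _langmuir,
                c,
                v,
                p0=[a_s, k_s],
                sigma=titration.af0_errors,
                absolute_sigma=titration.af0_errors is not None,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
            break
        except RuntimeError as exc:  # pragma: no cover
            last_exc = exc
    else:  # pragma: no cover
        raise FitError(f"Langmuir fit failed after {len(starts)} starts: {last_exc}")

    af0_max, ic50 = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if ic50 > np.max(c):
        warnings.warn(
            f"isotherm not saturated: fitted IC50 ({ic50:.3g}) exceeds the largest "
            f"titrated concentration ({np.max(c):.3g}); confidence interval is wide",
            stacklevel=2,
        )
    resid = v - _langmuir(c, af0_max, ic50)
    return LangmuirFit(
        af0_max=af0_max,
        ic50=ic50,
        residual_norm=float(np.linalg.norm(resid)),
        af0_max_err=float(perr[0]),
        ic50_err=float(perr[1]),
    )
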