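"""Selective longitudinal relaxation (T1sel) IC50 estimation.

Under fast exchange with ligand in excess, binding shortens the selective T1
of a ligand resonance:

    1/T1obs = 1/T1free + f_bound / (T1bound + tau_bound)

Neglecting the free-ligand term, total ligand concentration and T1obs obey

    [P]0 * T1obs = ([L]0 + IC50) * (T1bound + tau_bound)

so a straight line fitted to ([L]0, [P]0*T1obs) crosses the x axis at
-IC50.  The estimator follows that linearization verbatim; an optional mode
subtracts the free-ligand relaxation rate first when a ligand-only reference
T1 is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from nmrbind.binding_model import bound_fraction
from nmrbind.std_buildup import FitError

__all__ = [
    "InversionRecoveryTrace",
    "T1Fit",
    "T1Titration",
    "fit_inversion_recovery",
    "model_t1obs",
    "estimate_ic50_t1",
]


@dataclass(frozen=True)
class InversionRecoveryTrace:
    """Signal intensity versus recovery delay at one ligand concentration."""

    recovery_delays: np.ndarray
    intensities: np.ndarray
    ligand_conc_uM: float
    protein_conc_uM: float
    ligand_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.recovery_delays, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("delays and intensities must be 1-D of equal length")
        if t.size < 4:
            raise ValueError("need at least 4 recovery delays")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("delays must be >= 0 and strictly increasing")
        object.__setattr__(self, "recovery_delays", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class T1Fit:
    """Parameters of ``f(t) = i0 * (1 - amp * exp(-t/t1_sel))``.

    ``amp`` is the inversion efficiency (2 for a perfect 180° pulse) and is
    fitted, not fixed.
    """

    i0: float
    amp: float
    t1_sel: float
    residual_norm: float
    t1_err: float

    @property
    def null_time(self) -> float:
        """Zero-crossing delay t = T1 * ln(amp) (amp > 1 required)."""
        if self.amp <= 1:
            raise ValueError("no null point for amp <= 1")
        return self.t1_sel * math.log(self.amp)


@dataclass(frozen=True)
class T1Titration:
    """Observed selective T1 across a ligand concentration ladder."""

    ligand_concs_uM: np.ndarray
    t1_obs_s: np.ndarray
    protein_conc_uM: float
    t1_free_s: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.ligand_concs_uM, dtype=float)
        t1 = np.asarray(self.t1_obs_s, dtype=float)
        if c.ndim != 1 or t1.shape != c.shape:
            raise ValueError("concentration and T1 arrays must match in length")
        if c.size < 3:
            raise ValueError("need at least 3 concentrations")
        if np.any(c <= 0) or np.any(t1 <= 0):
            raise ValueError("concentrations and T1 values must be positive")
        if self.protein_conc_uM <= 0:
            raise ValueError("protein concentration must be positive")
        object.__setattr__(self, "ligand_concs_uM", c)
        object.__setattr__(self, "t1_obs_s", t1)


def _ir_model(t: np.ndarray, i0: float, amp: float, t1: float) -> np.ndarray:
    return i0 * (1.0 - amp * np.exp(-t / t1))


def fit_inversion_recovery(trace: InversionRecoveryTrace, seed: int = 0) -> T1Fit:
    """Three-parameter inversion-recovery fit returning the selective T1."""
    t = trace.recovery_delays
    y = trace.intensities
    span = t[-1] - t[0]

    i0_start = float(y[-1]) if y[-1] > 0 else float(np.max(np.abs(y))) or 1.0
    t1_start = span / 3.0 if span > 0 else 1.0
    rng = np.random.default_rng(seed)
    starts = [(i0_start, 2.0, t1_start)] + [
        (i0_start * rng.uniform(0.5, 2.0), rng.uniform(1.2, 2.0),
         t1_start * rng.uniform(0.3, 3.0))
        for _ in range(2)
    ]
    last_exc: Exception | None = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _ir_model,
                t,
                y,
                p0=list(p0),
                bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            break
        except RuntimeError as exc:  # pragma: no cover
            last_exc = exc
    else:  # pragma: no cover
        raise FitError(f"inversion-recovery fit failed: {last_exc}")

    i0, amp, t1_sel = (float(v) for v in popt)
    if t1_sel > 10 * span:
        warnings.warn(
            "fitted T1 far exceeds the sampled delay range; value is poorly "
            "constrained",
            stacklevel=2,
        )
    resid = y - _ir_model(t, i0, amp, t1_sel)
    t1_err = float(np.sqrt(max(pcov[2, 2], 0.0)))
    return T1Fit(
        i0=i0,
        amp=amp,
        t1_sel=t1_sel,
        residual_norm=float(np.linalg.norm(resid)),
        t1_err=t1_err,
    )


def model_t1obs(
    l0_uM: float,
    p0_uM: float,
    kd_uM: float,
    t1_free_s: float,
    t1_bound_s: float,
    tau_bound_s: float,
    fbound_method: str = "exact",
) -> float:
    """Forward model of the observed selective T1 under fast exchange.

    ``1/T1obs = 1/T1free + f_bound/(T1bound + tau_bound)``.  By default the
    bound fraction comes from the exact quadratic mass balance;
    ``fbound_method="linear"`` uses the excess-ligand approximation
    ``f_bound = [P]0/([L]0 + Kd)``, the form whose inversion is the linear
    x-intercept estimator.  ``t1_free_s`` may be ``inf`` to drop the
    free-relaxation term (the fully linearized regime).
    """
    if t1_bound_s <= 0 or tau_bound_s < 0:
        raise ValueError("bound-state times must be positive")
    if t1_free_s <= 0:
        raise ValueError("t1_free must be positive (may be inf)")
    if fbound_method == "exact":
        fb = bound_fraction(p0_uM, l0_uM, kd_uM)
    elif fbound_method == "linear":
        fb = p0_uM / (l0_uM + kd_uM)
    else:
        raise ValueError("fbound_method must be 'exact' or 'linear'")
    rate = fb / (t1_bound_s + tau_bound_s)
    if math.isfinite(t1_free_s):
        rate += 1.0 / t1_free_s
    if rate == 0.0:
        return math.inf
    return 1.0 / rate


def estimate_ic50_t1(
    titration: T1Titration, subtract_free_rate: bool = False
) -> tuple[float, float]:
    """IC50 (µM) from the x-intercept of [P]0*T1obs versus [L]0.

    Ordinary least squares on ``y = [P]0 * T1obs``; IC50 = intercept/slope.
    With ``subtract_free_rate=True`` and a ligand-only reference T1 on the
    titration, the free relaxation rate is removed from each observed rate
    before linearization.  Returns ``(ic50_uM, standard_error_uM)``.
    """
    c = titration.ligand_concs_uM
    t1 = titration.t1_obs_s
    if subtract_free_rate:
        if titration.t1_free_s is None:
            raise ValueError("subtract_free_rate requires t1_free_s on the titration")
        rates = 1.0 / t1 - 1.0 / titration.t1_free_s
        if np.any(rates <= 0):
            raise ValueError(
                "free-rate subtraction produced non-positive bound rates; "
                "no binding signal"
            )
        t1 = 1.0 / rates
    y = titration.protein_conc_uM * t1

    res = linregress(c, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise ValueError("no binding signal: fitted slope is not positive")
    ic50 = intercept / slope
    # variance of the ratio by first-order propagation with the OLS
    # slope/intercept covariance cov = -mean(x) * var(slope)
    cov_si = -float(np.mean(c)) * res.stderr**2
    var = (
        (res.intercept_stderr / slope) ** 2
        + (intercept * res.stderr / slope**2) ** 2
        - 2.0 * intercept / slope**3 * cov_si
    )
    se = math.sqrt(max(var, 0.0))
    if ic50 < 0:
        warnings.warn(
            f"negative IC50 ({ic50:.3g} µM): x-intercept lies at positive "
            "concentration; data may lack a binding signal",
            stacklevel=2,
        )
    return ic50, se
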