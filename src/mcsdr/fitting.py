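"""Rate-constant estimation from fluorescence traces.

The procedure mirrors standard plate-reader practice: reporter fluorescence
is linear in the released output strand, so a calibration line converts the
signal to concentration; the one-step second-order model is then fitted by
minimizing the sum of squared residuals with a derivative-free simplex
search, with a large fixed penalty for negative rate candidates (instead of
letting the integrator run on an unphysical parameter).  The ODE inside the
objective is solved with the same stiff-capable integrator as the kinetics
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .trace import Trace

__all__ = [
    "CalibrationModel",
    "FitResult",
    "signal_to_concentration",
    "fit_rate_constant",
    "calibration_from_controls",
    "NEGATIVE_PARAM_PENALTY",
]

#: fixed objective value returned for negative rate candidates
NEGATIVE_PARAM_PENALTY = 1e12


class CalibrationError(ValueError):
    """Calibration slope is unusable."""


class InsufficientDataError(ValueError):
    """Too few time points to constrain a rate."""


@dataclass(frozen=True)
class CalibrationModel:
    """signal = slope * concentration + intercept."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")

    def to_signal(self, conc: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(conc, dtype=float)

    def to_concentration(self, signal: np.ndarray) -> np.ndarray:
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class FitResult:
    k_hat: float
    objective_value: float
    n_iterations: int
    converged: bool
    penalized: bool


def signal_to_concentration(trace: Trace, cal: CalibrationModel) -> Trace:
    """Invert the linear reporter calibration; times are unchanged."""
    return trace.with_values(cal.to_concentration(trace.values), unit="M")


def calibration_from_controls(F_m: float, F_b: float, B0: float) -> CalibrationModel:
    """Calibration from the saturation control (large excess of matched
    target, complete probe conversion) and the buffer blank."""
    if B0 <= 0:
        raise CalibrationError("probe concentration must be positive")
    return CalibrationModel(slope=(F_m - F_b) / B0, intercept=F_b)


def _ode_product(k: float, A0: float, B0: float, times: np.ndarray, scale: float) -> np.ndarray:
    a0, b0 = A0 / scale, B0 / scale
    ks = k * scale
    t_eval = times
    prepend = times[0] > 0
    if prepend:
        t_eval = np.concatenate([[0.0], times])
    sol = solve_ivp(
        lambda _, y: [ks * (a0 - y[0]) * (b0 - y[0])],
        (0.0, float(t_eval[-1])),
        [0.0],
        method="LSODA",
        t_eval=t_eval,
        rtol=1e-8,
        atol=1e-12,
    )
    c = sol.y[0]
    if prepend:
        c = c[1:]
    return c * scale


def fit_rate_constant(
    conc_trace: Trace,
    A0: float,
    B0: float,
    k_init: float = 1e3,
    max_iter: int = 2000,
) -> FitResult:
    """Estimate the apparent second-order rate from a concentration trace.

    Nelder-Mead simplex on the single rate parameter; the objective is the
    sum of squared concentration residuals against the ODE solution, with
    ``NEGATIVE_PARAM_PENALTY`` substituted whenever the candidate rate is
    negative.
    """
    if A0 <= 0 or B0 <= 0:
        raise ValueError("A0 and B0 must be positive")
    if len(conc_trace) < 3:
        raise InsufficientDataError("need at least 3 time points to fit a rate")
    times = conc_trace.times
    values = conc_trace.values
    scale = max(A0, B0)
    penalized_any = False

    def objective(x):
        nonlocal penalized_any
        k = float(x[0])
        if k < 0:
            penalized_any = True
            return NEGATIVE_PARAM_PENALTY
        r = (_ode_product(k, A0, B0, times, scale) - values) / scale
        return float(r @ r)

    x0 = np.array([k_init], dtype=float)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 1e-8 * max(abs(k_init), 1.0),
            "fatol": 1e-8,
            "maxiter": max_iter,
            "maxfev": max_iter,
        },
    )
    k_hat = float(res.x[0])
    penalized = k_hat < 0
    if penalized:  # the simplex ended on a penalized candidate; clamp to the boundary
        k_hat = 0.0
    return FitResult(
        k_hat=k_hat,
        objective_value=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
        penalized=penalized or penalized_any,
    )
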