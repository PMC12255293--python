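"""Deterministic ODE models of strand-displacement kinetics.

Three nested models, all of the form ``A + B -> C + D`` overall (A the target
complex, B the reporter probe, C the product duplex, D the released output
strand, so [D] = [C]):

* ``simulate_tsdr`` -- the one-step second-order reaction with a single
  effective rate constant.
* ``simulate_mcsdr`` -- the two-step remote-toehold model: reversible toehold
  docking followed by an internal diffusion/alignment step; a mismatched
  target additionally has to pass a base-breathing step whose opening is a
  rare excursion (forward ``nu_breathe * exp(-dG_open/RT)``, re-closing
  ``nu_breathe``, so the step obeys detailed balance).
* ``simulate_multiclosure`` -- the three-stage generalization: a mismatched
  target closed over ``n_close`` bases must pass one breathing step per
  closed base before alignment can commit.

Undocking rates derive from the nearest-neighbor toehold free energy through
detailed balance, ``k_undock = k_dock * C0 * exp(dG_toehold / RT)``.

Mass conservation is honoured by construction: the integrated state holds only
intermediates and product, and [A], [B] are recovered from the conservation
laws, so the invariant A + I + I* + C = A0 is exact to floating point.
Integration uses a stiff-capable solver (LSODA) on concentrations normalised
by the largest initial concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from . import metrics, thermo
from .strand_model import ProbeSystem
from .trace import Trace

__all__ = [
    "KineticParams",
    "RateSet",
    "simulate_tsdr",
    "simulate_mcsdr",
    "simulate_multiclosure",
    "effective_rate_from_toehold",
    "apparent_second_order_rate",
    "second_order_solution",
    "sweep_grid",
    "fit_time_grid",
]

C_STANDARD = 1.0  # M, reference concentration for bimolecular detailed balance

RTOL = 1e-8
ATOL = 1e-12  # on concentrations normalised by max(A0, B0)


@dataclass(frozen=True)
class KineticParams:
    """Elementary rate constants of the displacement pathway.

    k_dock : bimolecular toehold association, 1/M/s (literature 1-6e6).
    k_align : internal diffusion/alignment commitment, 1/s.  The toehold is
        remote from the displacement duplex (association domain + spacer), so
        alignment is orders of magnitude slower than a contiguous toehold's
        branch-migration initiation.
    k_bm : committed branch-migration rate over a freed domain, 1/s (not
        rate-limiting in the coarse model; retained for completeness).
    nu_breathe : breathing attempt frequency, 1/s.
    dG_open : opening cost of the first branch-migration pair, kcal/mol;
        ``None`` derives it from the sequence (flanking stack terms).
    """

    k_dock: float = 3.0e6
    k_align: float = 0.02
    k_bm: float = 50.0
    nu_breathe: float = 1.0e4
    dG_open: float | None = None
    temperature: float = 310.15

    def __post_init__(self) -> None:
        for name in ("k_dock", "k_align", "k_bm", "nu_breathe"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class RateSet:
    """Sequence-resolved elementary rates for one system/variant."""

    k_dock: float
    k_undock: float
    k_align: float
    k_open: float
    k_close: float
    dG_toehold: float
    dG_open: float
    free_toehold_len: int
    n_breathe: int


def derive_rates(
    system: ProbeSystem,
    variant: Literal["PM", "MM"],
    params: KineticParams | None = None,
    tparams: thermo.ThermoParams | None = None,
) -> RateSet:
    """Thermodynamically couple the elementary rates to the design.

    The matched target docks on the full toehold and needs no breathing; the
    mismatched target docks on the closure-shortened toehold and must breathe
    once per closed base.
    """
    params = params or KineticParams()
    tparams = tparams or thermo.ThermoParams()
    rt = thermo.GAS_CONSTANT_KCAL * params.temperature
    if variant == "PM":
        free_len = system.toehold_len
        n_breathe = 0
    else:
        free_len = system.mm_free_toehold_len
        n_breathe = system.n_close
    dg_toe = thermo.toehold_dG(system, free_len, tparams)
    k_undock = params.k_dock * C_STANDARD * math.exp(dg_toe / rt)
    dg_open = params.dG_open if params.dG_open is not None else thermo.opening_cost(system, tparams)
    return RateSet(
        k_dock=params.k_dock,
        k_undock=k_undock,
        k_align=params.k_align,
        k_open=params.nu_breathe * math.exp(-dg_open / rt),
        k_close=params.nu_breathe,
        dG_toehold=dg_toe,
        dG_open=dg_open,
        free_toehold_len=free_len,
        n_breathe=n_breathe,
    )


def effective_rate_from_toehold(
    dG_toehold: float,
    params: KineticParams | None = None,
    k_commit: float | None = None,
) -> float:
    """Apparent second-order rate of dock -> commit for a given toehold energy.

    Saturates at ``k_dock`` for strong (very negative) toeholds and falls
    exponentially as the toehold weakens.
    """
    params = params or KineticParams()
    if not math.isfinite(dG_toehold):
        if dG_toehold < 0:
            return params.k_dock
        return 0.0
    k_c = params.k_align if k_commit is None else k_commit
    rt = thermo.GAS_CONSTANT_KCAL * params.temperature
    k_undock = params.k_dock * C_STANDARD * math.exp(dG_toehold / rt)
    if k_c == 0 and k_undock == 0:
        return 0.0
    return params.k_dock * k_c / (k_c + k_undock)


# -- integration helpers --------------------------------------------------------


def _prepare_grid(t_grid: Sequence[float]) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("t_grid must be non-empty")
    if np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("t_grid must be non-negative and strictly increasing")
    return t


def _integrate(rhs: Callable, n_states: int, t_grid: np.ndarray) -> np.ndarray:
    """Integrate from the all-zero intermediate state; returns states x times."""
    t_eval = t_grid
    prepend = t_grid[0] > 0
    if prepend:
        t_eval = np.concatenate([[0.0], t_grid])
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        np.zeros(n_states),
        method="LSODA",
        t_eval=t_eval,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:  # pragma: no cover - LSODA failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = sol.y
    return y[:, 1:] if prepend else y


def simulate_tsdr(k1: float, A0: float, B0: float, t_grid: Sequence[float]) -> Trace:
    """One-step second-order displacement; returns the output-strand trace [D]."""
    if k1 < 0 or A0 < 0 or B0 < 0:
        raise ValueError("rate and concentrations must be non-negative")
    t = _prepare_grid(t_grid)
    scale = max(A0, B0, 1e-30)
    a0, b0 = A0 / scale, B0 / scale
    k = k1 * scale

    def rhs(_, y):
        c = y[0]
        return [k * (a0 - c) * (b0 - c)]

    c = _integrate(rhs, 1, t)[0]
    return Trace(t, np.clip(c, 0.0, None) * scale, {"unit": "M", "model": "tsdr", "A0": A0, "B0": B0, "k1": k1})


def _chain_rhs(rates: RateSet, n_breathe: int, a0: float, b0: float, scale: float) -> tuple[Callable, int]:
    """Docked intermediate chain: I0 (docked), I1..In (breathed), then C.

    Every intermediate can undock; breathing steps are reversible; the last
    intermediate commits through alignment.
    """
    kd = rates.k_dock * scale
    ku = rates.k_undock
    ko, kc, ka = rates.k_open, rates.k_close, rates.k_align
    n = n_breathe
    n_states = n + 2  # I0..In, C

    def rhs(_, y):
        inter = y[:-1]
        c = y[-1]
        bound = inter.sum() + c
        a = a0 - bound
        b = b0 - bound
        dy = np.empty_like(y)
        # docking into I0; undocking from every intermediate
        dy[0] = kd * a * b - ku * inter[0]
        for j in range(1, n + 1):
            dy[j] = -ku * inter[j]
        # reversible breathing ladder
        for j in range(n):
            f = ko * inter[j] - kc * inter[j + 1]
            dy[j] -= f
            dy[j + 1] += f
        # alignment commits from the last intermediate
        dy[n] -= ka * inter[n]
        dy[-1] = ka * inter[n]
        return dy

    return rhs, n_states


def _simulate_chain(
    system: ProbeSystem,
    variant: str,
    n_breathe: int,
    params: KineticParams,
    A0: float,
    B0: float,
    t_grid: np.ndarray,
    tparams: thermo.ThermoParams | None,
    model: str,
) -> Trace:
    rates = derive_rates(system, variant, params, tparams)
    scale = max(A0, B0, 1e-30)
    rhs, n_states = _chain_rhs(rates, n_breathe, A0 / scale, B0 / scale, scale)
    y = _integrate(rhs, n_states, t_grid)
    species = {f"I{j}": y[j] * scale for j in range(n_states - 1)}
    species["C"] = y[-1] * scale
    bound = y[:-1].sum(axis=0) + y[-1]
    species["A"] = A0 - bound * scale
    species["B"] = B0 - bound * scale
    d = np.clip(y[-1], 0.0, None) * scale
    meta = {
        "unit": "M",
        "model": model,
        "variant": variant,
        "A0": A0,
        "B0": B0,
        "n_close": system.n_close,
        "toehold_len": system.toehold_len,
        "free_toehold_len": rates.free_toehold_len,
    }
    trace = Trace(t_grid, d, meta)
    trace.species = species  # per-species trajectories for conservation checks
    return trace


def simulate_mcsdr(
    system: ProbeSystem,
    variant: Literal["PM", "MM"],
    params: KineticParams | None = None,
    A0: float = 250e-9,
    B0: float = 250e-9,
    t_grid: Sequence[float] = (3600.0,),
    tparams: thermo.ThermoParams | None = None,
) -> Trace:
    """Two-step model: reversible docking, then alignment (PM) or one
    breathing step followed by alignment (MM)."""
    params = params or KineticParams()
    t = _prepare_grid(t_grid)
    n_breathe = 0 if variant == "PM" else 1
    return _simulate_chain(system, variant, n_breathe, params, A0, B0, t, tparams, "mcsdr2")


def simulate_multiclosure(
    system: ProbeSystem,
    params: KineticParams | None = None,
    A0: float = 250e-9,
    B0: float = 250e-9,
    t_grid: Sequence[float] = (3600.0,),
    variant: Literal["PM", "MM"] = "PM",
    tparams: thermo.ThermoParams | None = None,
) -> Trace:
    """Multi-closure model: a mismatched target breathes once per closed base.

    Reduces exactly to ``simulate_mcsdr`` at ``n_close = 1``.  The matched
    target sheds the (mismatched) helper closure and follows the normal
    pathway, so its trace does not depend on ``n_close``.
    """
    if system.n_close < 1:
        raise ValueError("n_close = 0 has no closure; use simulate_tsdr")
    params = params or KineticParams()
    t = _prepare_grid(t_grid)
    n_breathe = 0 if variant == "PM" else system.n_close
    return _simulate_chain(system, variant, n_breathe, params, A0, B0, t, tparams, "multiclosure")


# -- apparent-rate extraction ---------------------------------------------------


def second_order_solution(k: float, A0: float, B0: float, t: np.ndarray) -> np.ndarray:
    """Closed-form product concentration of A + B -> C at rate k."""
    t = np.asarray(t, dtype=float)
    if k == 0 or A0 == 0 or B0 == 0:
        return np.zeros_like(t)
    delta = B0 - A0
    x = np.clip(delta * k * t, None, 500.0)
    with np.errstate(over="ignore"):
        em = np.expm1(x)
    # C = A0*B0*expm1(x) / (B0*expm1(x) + delta); smooth at delta -> 0
    small = np.abs(x) < 1e-8
    phi = np.where(small, 1.0 + x / 2.0, em / np.where(x == 0, 1.0, x))
    kt = k * t
    return A0 * B0 * kt * phi / (B0 * kt * phi + 1.0)


def apparent_second_order_rate(
    trace: Trace,
    A0: float,
    B0: float,
    full: bool = False,
):
    """Least-squares fit of the one-step second-order model to a
    concentration trace; returns the apparent rate in 1/M/s.

    A flat zero trace is degenerate and yields 0.
    """
    if A0 <= 0 or B0 <= 0:
        raise ValueError("A0 and B0 must be positive")
    values = trace.values
    cap = min(A0, B0)
    if np.max(values) <= 1e-12 * cap:
        return (0.0, {"degenerate": True}) if full else 0.0

    def sse_log10(lk):
        model = second_order_solution(10.0**lk, A0, B0, trace.times)
        r = (model - values) / cap
        return float(r @ r)

    res = minimize_scalar(sse_log10, bounds=(-6.0, 10.0), method="bounded", options={"xatol": 1e-10})
    k = float(10.0 ** res.x)
    if full:
        return k, {"degenerate": False, "objective": res.fun, "n_iterations": res.nfev}
    return k


def fit_time_grid(t_end: float = 3600.0, n: int = 60) -> np.ndarray:
    """Log-spaced fitting grid from 1 s to the assay endpoint."""
    return np.geomspace(1.0, t_end, n)


# -- design-space sweep ---------------------------------------------------------


def sweep_grid(
    toehold_lens: Iterable[int] = range(6, 12),
    n_closes: Iterable[int] = range(1, 6),
    params: KineticParams | None = None,
    t_end: float = 3600.0,
    system_factory: Callable[[int, int], ProbeSystem] | None = None,
    A0: float = 250e-9,
    B0: float = 250e-9,
    tparams: thermo.ThermoParams | None = None,
) -> pd.DataFrame:
    """Simulate the toehold-length x closure-count design grid.

    For each cell the matched and mismatched targets are simulated with the
    multi-closure model; the table records endpoint yields, fitted apparent
    rates, the discrimination factor DF (endpoint signals, probe-only blank
    at zero) and DDF = yield_PM^2 / yield_MM.  Cells whose mismatched yield
    sits below the metric floor are flagged as NaN rather than extrapolated.
    """
    from .reference import reference_system

    params = params or KineticParams()
    factory = system_factory or (lambda tl, nc: reference_system(toehold_len=tl, n_close=nc))
    t_grid = fit_time_grid(t_end)
    cap = min(A0, B0)
    rows = []
    for tl in toehold_lens:
        for nc in n_closes:
            system = factory(tl, nc)
            tr_pm = simulate_multiclosure(system, params, A0, B0, t_grid, "PM", tparams)
            tr_mm = simulate_multiclosure(system, params, A0, B0, t_grid, "MM", tparams)
            y_pm = tr_pm.endpoint / cap
            y_mm = tr_mm.endpoint / cap
            try:
                df_val = metrics.discrimination_factor(y_pm, y_mm, 0.0)
            except metrics.UndefinedMetricError:
                df_val = float("nan")
            try:
                ddf_val = metrics.ddf(y_pm, y_mm)
            except metrics.UndefinedMetricError:
                ddf_val = float("nan")
            rows.append(
                {
                    "toehold_len": tl,
                    "n_close": nc,
                    "yield_pm": y_pm,
                    "yield_mm": y_mm,
                    "rate_pm": apparent_second_order_rate(tr_pm, A0, B0),
                    "rate_mm": apparent_second_order_rate(tr_mm, A0, B0),
                    "df": df_val,
                    "ddf": ddf_val,
                }
            )
    return pd.DataFrame(rows)
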