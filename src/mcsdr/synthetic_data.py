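"""Synthetic plate-reader experiments: fluorescence traces with the
statistical structure the analysis pipeline assumes.

Signals are linear in the released output strand plus a background offset
and Gaussian noise with an absolute and a signal-proportional component.
Every generator draws from one seeded generator per trace, recorded in the
trace metadata, so panels are reproducible bit-for-bit.

Default assay emulation: 250 nM target, 250 nM probe (and helper), 37 degC,
1 h endpoint.  The saturation control drives the probe to completion with a
40-fold excess of matched target and anchors the yield calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import thermo
from .fitting import CalibrationModel
from .kinetics import KineticParams, derive_rates, simulate_multiclosure
from .strand_model import ProbeSystem
from .trace import Trace

__all__ = [
    "NoiseModel",
    "PanelSpec",
    "generate_trace",
    "generate_vaf_panel",
    "generate_saturation_control",
]


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader-like noise: sd = sigma_abs + sigma_rel * |signal|.

    ``sigma_abs = None`` defaults to 0.5% of the saturation signal at
    generation time.
    """

    sigma_rel: float = 0.01
    sigma_abs: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0 or (self.sigma_abs is not None and self.sigma_abs < 0):
            raise ValueError("noise magnitudes must be non-negative")

    def resolve_abs(self, saturation_signal: float) -> float:
        return 0.005 * saturation_signal if self.sigma_abs is None else self.sigma_abs


@dataclass(frozen=True)
class PanelSpec:
    """Variant-allele-fraction / target-probe-ratio panel layout."""

    vaf_list: tuple[float, ...] = (0.0, 0.001, 0.01, 0.1, 1.0)
    total_conc: float = 250e-9
    tp_ratios: tuple[float, ...] = (1.0,)
    replicates: int = 1

    def __post_init__(self) -> None:
        if not self.vaf_list:
            raise ValueError("vaf_list must be non-empty")
        if any(not 0 <= v <= 1 for v in self.vaf_list):
            raise ValueError("VAFs must lie in [0, 1]")
        if self.total_conc <= 0:
            raise ValueError("total_conc must be positive")


def _noisy_signal(clean: np.ndarray, noise: NoiseModel, cal: CalibrationModel, B0: float, rng_seed) -> np.ndarray:
    rng = np.random.default_rng(rng_seed)
    sat = cal.to_signal(np.array([B0]))[0]
    sd = noise.resolve_abs(sat) + noise.sigma_rel * np.abs(clean)
    return clean + rng.normal(0.0, 1.0, clean.size) * sd


def generate_trace(
    system: ProbeSystem,
    variant: Literal["PM", "MM"],
    kparams: KineticParams | None = None,
    A0: float = 250e-9,
    B0: float = 250e-9,
    cal: CalibrationModel | None = None,
    noise: NoiseModel | None = None,
    t_grid: Sequence[float] = (3600.0,),
    tparams: thermo.ThermoParams | None = None,
) -> Trace:
    """Simulate one assay well and emit a fluorescence-signal trace."""
    cal = cal or CalibrationModel(slope=1e9, intercept=0.0)  # ~1 signal unit per nM
    noise = noise or NoiseModel()
    conc = simulate_multiclosure(system, kparams, A0, B0, t_grid, variant, tparams)
    clean = cal.to_signal(conc.values)
    signal = _noisy_signal(clean, noise, cal, B0, [noise.seed])
    meta = {
        **conc.meta,
        "unit": "au",
        "seed": noise.seed,
        "slope": cal.slope,
        "intercept": cal.intercept,
    }
    return Trace(conc.times, signal, meta)


def _competitive_product(
    system: ProbeSystem,
    kparams: KineticParams,
    pm0: float,
    mm0: float,
    B0: float,
    t_grid: np.ndarray,
    tparams: thermo.ThermoParams | None,
) -> np.ndarray:
    """Total output [D] when matched and mismatched targets share one probe pool."""
    from .kinetics import ATOL, RTOL, _integrate

    r_pm = derive_rates(system, "PM", kparams, tparams)
    r_mm = derive_rates(system, "MM", kparams, tparams)
    n = system.n_close
    scale = max(pm0 + mm0, B0, 1e-30)
    p0, m0, b0 = pm0 / scale, mm0 / scale, B0 / scale
    kd_p = r_pm.k_dock * scale
    kd_m = r_mm.k_dock * scale

    # state: [Ip, Cp, Im_0..Im_n, Cm]
    def rhs(_, y):
        ip, cp = y[0], y[1]
        im = y[2 : 2 + n + 1]
        cm = y[-1]
        b = b0 - (ip + cp + im.sum() + cm)
        ap = p0 - ip - cp
        am = m0 - im.sum() - cm
        dy = np.empty_like(y)
        dy[0] = kd_p * ap * b - (r_pm.k_undock + r_pm.k_align) * ip
        dy[1] = r_pm.k_align * ip
        dim = np.empty(n + 1)
        dim[0] = kd_m * am * b - r_mm.k_undock * im[0]
        for j in range(1, n + 1):
            dim[j] = -r_mm.k_undock * im[j]
        for j in range(n):
            f = r_mm.k_open * im[j] - r_mm.k_close * im[j + 1]
            dim[j] -= f
            dim[j + 1] += f
        dim[n] -= r_mm.k_align * im[n]
        dy[2 : 2 + n + 1] = dim
        dy[-1] = r_mm.k_align * im[n]
        return dy

    y = _integrate(rhs, n + 4, t_grid)
    return np.clip(y[1] + y[-1], 0.0, None) * scale


def generate_vaf_panel(
    system: ProbeSystem,
    spec: PanelSpec,
    kparams: KineticParams | None = None,
    cal: CalibrationModel | None = None,
    noise: NoiseModel | None = None,
    t_grid: Sequence[float] = (3600.0,),
    tparams: thermo.ThermoParams | None = None,
) -> list[Trace]:
    """Competitive-kinetics panel over variant allele fractions.

    For each VAF ``v`` the matched target enters at ``v * total`` and the
    mismatched at ``(1 - v) * total``, both competing for one probe pool; the
    endpoint signal rises monotonically with ``v`` at zero noise.
    """
    from .kinetics import _prepare_grid

    kparams = kparams or KineticParams()
    cal = cal or CalibrationModel(slope=1e9, intercept=0.0)
    noise = noise or NoiseModel()
    t = _prepare_grid(t_grid)
    traces = []
    for i_r, ratio in enumerate(spec.tp_ratios):
        a_total = ratio * spec.total_conc
        b0 = spec.total_conc
        for i_v, v in enumerate(spec.vaf_list):
            d = _competitive_product(system, kparams, v * a_total, (1 - v) * a_total, b0, t, tparams)
            clean = cal.to_signal(d)
            for rep in range(spec.replicates):
                seed_key = [noise.seed, i_r, i_v, rep]
                signal = _noisy_signal(clean, noise, cal, b0, seed_key)
                traces.append(
                    Trace(
                        t,
                        signal,
                        {
                            "unit": "au",
                            "vaf": v,
                            "tp_ratio": ratio,
                            "replicate": rep,
                            "label": f"vaf={v:g},tp={ratio:g}",
                            "variant": "mix",
                            "A0": a_total,
                            "B0": b0,
                            "seed": noise.seed,
                            "seed_key": tuple(seed_key),
                        },
                    )
                )
    return traces


def generate_saturation_control(
    system: ProbeSystem,
    kparams: KineticParams | None = None,
    cal: CalibrationModel | None = None,
    noise: NoiseModel | None = None,
    t_grid: Sequence[float] = (3600.0,),
    B0: float = 250e-9,
    excess: float = 40.0,
    tparams: thermo.ThermoParams | None = None,
) -> Trace:
    """Matched target in large excess: drives the probe to completion; the
    endpoint signal is the saturating F_m of the yield calibration."""
    tr = generate_trace(
        system,
        "PM",
        kparams,
        A0=excess * B0,
        B0=B0,
        cal=cal,
        noise=noise,
        t_grid=t_grid,
        tparams=tparams,
    )
    tr.meta.update(label="saturation_control", excess=excess)
    return tr
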