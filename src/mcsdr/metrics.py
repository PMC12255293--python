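"""Scalar figures of merit: discrimination factor, hybridization yield, DDF,
and fluorescence normalization.

Conventions follow the assay bookkeeping: ``F_wt`` is the signal of the
probe-matched target, ``F_mt`` of the target carrying the interrogated
mismatch, ``F_p`` the probe-only blank, ``F_b`` the buffer background and
``F_m`` the saturating signal from a large excess of matched target.  (In a
mutation assay the probe-matched species is the mutant allele; the neutral
aliases ``F_match``/``F_mismatch`` avoid the wt/mt ambiguity.)

Denominators close to zero mark conditions where the metric is unreliable;
they raise :class:`UndefinedMetricError` instead of returning huge or
infinite values, mirroring how low-yield assay cells are flagged rather than
extrapolated.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .trace import Trace

__all__ = [
    "UndefinedMetricError",
    "CalibrationRangeError",
    "discrimination_factor",
    "hybridization_yield",
    "ddf",
    "normalize_traces",
]

#: relative floor (of the reference scale) under which a denominator is
#: considered unresolvable
EPS_FLOOR = 1e-6


class UndefinedMetricError(ValueError):
    """The metric's denominator is below the resolvable floor."""


class CalibrationRangeError(ValueError):
    """Saturation and background signals do not bracket a usable range."""


def discrimination_factor(F_match: float, F_mismatch: float, F_blank: float, eps: float | None = None) -> float:
    """DF = (F_match - F_blank) / (F_mismatch - F_blank).

    ``eps`` defaults to ``EPS_FLOOR`` of the matched signal above blank.
    """
    num = F_match - F_blank
    den = F_mismatch - F_blank
    if eps is None:
        eps = EPS_FLOOR * abs(num)
    if den <= eps:
        raise UndefinedMetricError(
            f"mismatch signal within {eps:g} of blank; DF unresolvable"
        )
    return num / den


def hybridization_yield(F_x: float, F_b: float, F_m: float) -> float:
    """yield = (F_x - F_b) / (F_m - F_b), unclamped.

    Values outside [0, 1] are reported as-is with a warning (they indicate a
    calibration drift, not a computational failure).
    """
    if F_m <= F_b:
        raise CalibrationRangeError("saturating signal must exceed background")
    y = (F_x - F_b) / (F_m - F_b)
    if y < 0 or y > 1:
        warnings.warn(f"hybridization yield {y:.3g} outside [0, 1]", stacklevel=2)
    return y


def ddf(yield_pm: float, yield_mm: float, eps: float = EPS_FLOOR) -> float:
    """DDF = yield_PM^2 / yield_MM, the combined sensitivity-specificity score."""
    if yield_mm <= eps:
        raise UndefinedMetricError(f"mismatch yield {yield_mm:.3g} below floor {eps:g}")
    return yield_pm**2 / yield_mm


def normalize_traces(traces: Sequence[Trace], ref_label: str | None = None) -> list[Trace]:
    """Normalize a probe set by the mean of the reference condition's maxima.

    ``ref_label`` picks the reference condition by ``meta['label']``; by
    default the highest-signal condition in the set is the reference, so the
    reference trace normalizes to 1 at its plateau.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty trace set")
    if ref_label is None:
        ref = [max(t.values.max() for t in traces)]
    else:
        ref = [t.values.max() for t in traces if t.meta.get("label") == ref_label]
        if not ref:
            raise ValueError(f"no trace labelled {ref_label!r}")
    denom = float(np.mean(ref))
    if denom <= 0:
        raise UndefinedMetricError("reference condition has no signal")
    return [t.with_values(t.values / denom, unit="normalized") for t in traces]
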