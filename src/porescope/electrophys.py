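"""Conductance from I/V series and normalized conductance change.

Conductance is the ordinary least-squares slope of current (pA) against
voltage (mV) restricted to a voltage window (default +-20 mV); pA/mV equals
nS. The fit is not forced through the origin, so recording offsets land in
the intercept, never the slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import IVSeries

__all__ = ["ConductanceResult", "conductance", "normalized_conductance"]


@dataclass(frozen=True)
class ConductanceResult:
    g_nS: float
    intercept_pA: float
    v_range_mV: tuple
    r_squared: float


def conductance(iv: IVSeries, v_range: tuple = (-20.0, 20.0)) -> ConductanceResult:
    lo, hi = v_range
    if hi <= lo:
        raise ValueError("invalid voltage range")
    mask = (iv.voltage_mV >= lo) & (iv.voltage_mV <= hi)
    v = iv.voltage_mV[mask]
    i = iv.current_pA[mask]
    if len(np.unique(v)) < 2:
        raise ValueError(
            f"need >= 2 distinct voltages in [{lo}, {hi}] mV, found {len(np.unique(v))}"
        )
    vm, im = v.mean(), i.mean()
    dv = v - vm
    slope = float(np.dot(dv, i - im) / np.dot(dv, dv))
    intercept = float(im - slope * vm)
    resid = i - (slope * v + intercept)
    ss_tot = float(np.dot(i - im, i - im))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.dot(resid, resid)) / ss_tot
    return ConductanceResult(slope, intercept, (lo, hi), r2)


def normalized_conductance(g_test: float, g_reference: float) -> float:
    if g_reference == 0:
        raise ValueError("reference conductance is zero")
    return g_test / g_reference
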