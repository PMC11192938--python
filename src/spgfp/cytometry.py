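"""Negative-control gating and positive-fraction estimation.

Flow-cytometry positivity is defined relative to a negative control: the
gate is placed at a high quantile of the control's fluorescence
distribution (default 0.995, a 0.5% false-positive allowance) and events
of the sample strictly above the gate are counted positive.  Quantiles
use numpy's linear-interpolation definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Gate", "PositiveFraction", "compute_gate", "fraction_positive"]

MIN_CONTROL_EVENTS = 100


@dataclass(frozen=True)
class Gate:
    tau: float
    quantile: float
    n_control: int


@dataclass(frozen=True)
class PositiveFraction:
    fraction: float
    count: int
    n: int

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def compute_gate(control_events: np.ndarray, quantile: float = 0.995) -> Gate:
    """Gate threshold from a negative-control sample.

    ``tau`` is the empirical ``quantile``-quantile (linear interpolation)
    of the control values; at least 100 control events are required.
    """
    control = np.asarray(control_events, dtype=float)
    if control.ndim != 1:
        control = control.ravel()
    if control.size < MIN_CONTROL_EVENTS:
        raise ValueError(
            f"need >= {MIN_CONTROL_EVENTS} control events, got {control.size}"
        )
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    tau = float(np.quantile(control, quantile))
    return Gate(tau=tau, quantile=quantile, n_control=int(control.size))


def fraction_positive(events: np.ndarray, tau: float) -> PositiveFraction:
    """Fraction of events strictly above the gate threshold."""
    events = np.asarray(events, dtype=float).ravel()
    if events.size == 0:
        raise ValueError("empty event set")
    if not np.isfinite(tau):
        raise ValueError("gate threshold must be finite")
    count = int(np.sum(events > tau))
    return PositiveFraction(fraction=count / events.size, count=count, n=int(events.size))
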