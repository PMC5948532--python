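"""Proportional cursor control from classifier outputs and mean power.

Cursor speed is proportional to the muscle effort above a rest-drift
threshold,

    v(t) = H( P(t)/P_max − p_th ),      H(u) = max(0, u),

and the on-screen displacement per control tick is

    Δ(t) = gain · v(t) · (qr − ql, qu − qd),

with the classifier output q = (ql, qr, qu, qd).  The threshold p_th is
calibrated from a rest recording so that involuntary muscle-tone jitter
does not move the cursor; P_max comes from a maximal-effort segment.
Screen axes: x rightward, y upward, origin at the bottom-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureStream


@dataclass
class ControlState:
    """Calibrated constants of the proportional control law."""

    p_max: float
    p_th: float
    gain: float = 20.0
    rest_baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.p_max <= 0:
            raise ValueError("p_max must be positive")
        if not 0.0 <= self.p_th < 1.0:
            raise ValueError("p_th must lie in [0, 1)")
        if self.gain <= 0:
            raise ValueError("gain must be positive")


def calibrate(
    rest_features: FeatureStream,
    max_effort_features: FeatureStream,
    gain: float = 20.0,
    drift_quantile: float = 0.95,
) -> ControlState:
    """Calibrate the control law from a rest and a maximal-effort stream.

    ``p_max`` is the maximal mean power over the effort stream, the
    drift threshold ``p_th`` the ``drift_quantile`` (default 95th
    percentile) of the relative rest power, and ``rest_baseline`` the
    mean rest RMS per channel (subtractable from features upstream).
    """
    if rest_features.n_frames == 0 or max_effort_features.n_frames == 0:
        raise ValueError("calibration streams must be non-empty")
    p_max = float(max_effort_features.P.max())
    if p_max <= 0:
        raise ValueError("maximal-effort stream has zero power")
    p_th = float(np.quantile(rest_features.P / p_max, drift_quantile))
    p_th = min(p_th, np.nextafter(1.0, 0.0))
    return ControlState(
        p_max=p_max,
        p_th=p_th,
        gain=gain,
        rest_baseline=rest_features.V.mean(axis=0),
    )


def velocity(P_frame: float, state: ControlState) -> float:
    """Rectified relative effort v = max(0, P/P_max − p_th)."""
    if P_frame < 0:
        raise ValueError("mean power cannot be negative")
    return max(0.0, P_frame / state.p_max - state.p_th)


def displacement(q: np.ndarray, v: float, state: ControlState) -> tuple[float, float]:
    """Screen displacement Δ = gain · v · (qr − ql, qu − qd)."""
    ql, qr, qu, qd = np.asarray(q, dtype=float)[:4]
    return (state.gain * v * (qr - ql), state.gain * v * (qu - qd))
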