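"""Decision-quality analysis of pursuit-game traces.

While a user chases a moving target there is no ground-truth gesture,
so classification indices do not apply.  Instead, each recorded cursor
state is compared against the *best interception direction*: assuming
the cursor keeps its current speed ||ω_p|| and the target its current
velocity ω_c, the earliest interception time t* > 0 solves

    ||ω_p|| t* = ||d + ω_c t*||,        d = ρ_c − ρ_p,

a quadratic in t*; the best direction is the unit vector
n = (d + ω_c t*)/||·||.  When no positive root exists (e.g. the target
recedes faster than the cursor can move) the direction toward the
target's position one time step ahead is used instead.

The signed angle α(t) between the cursor's actual velocity and n
quantifies the decision error; its circular statistics (modal angle and
circular spread) summarize a trial.  Separately, the classifier output
is reduced to the intent vector δ = (qr − ql, qu − qd): a gesture is
*optimal* when δ points within a fixed-cosine cone around n
((δ, n)/||δ|| > d_th, a cone of arccos(d_th) ≈ 0.93 rad for the default
d_th = 0.6) and *incorrect* otherwise.  Gestures are attributed to the
left/right/up/down group of their dominant δ component when it exceeds
a prevalence threshold of 0.2 standard deviations, giving eight
disjoint rate sets whose relative cardinalities expose per-direction
"problematic" gestures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GameTrace:
    """Time-stamped cursor/target positions with classifier outputs."""

    times: np.ndarray
    cursor: np.ndarray  # (n, 2)
    target: np.ndarray  # (n, 2)
    q: np.ndarray | None = None  # (n, 4) ANN outputs (ql, qr, qu, qd)
    level: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cursor = np.asarray(self.cursor, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.cursor.shape != (len(self.times), 2):
            raise ValueError("cursor must be (n, 2)")
        if self.target.shape != self.cursor.shape:
            raise ValueError("target must match cursor shape")
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        cols = {
            "time_s": self.times,
            "px": self.cursor[:, 0],
            "py": self.cursor[:, 1],
            "cx": self.target[:, 0],
            "cy": self.target[:, 1],
        }
        if self.q is not None:
            for i, name in enumerate(("ql", "qr", "qu", "qd")):
                cols[name] = self.q[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GameTrace":
        df = pd.read_csv(path)
        q = None
        if "ql" in df.columns:
            q = df[["ql", "qr", "qu", "qd"]].to_numpy(dtype=float)
        return cls(
            times=df["time_s"].to_numpy(dtype=float),
            cursor=df[["px", "py"]].to_numpy(dtype=float),
            target=df[["cx", "cy"]].to_numpy(dtype=float),
            q=q,
        )


def downsample(trace: GameTrace, max_points: int = 100, spacing_s: float = 0.05) -> GameTrace:
    """Uniform decimation to at most ``max_points`` at ≈``spacing_s``
    sample spacing, preserving both endpoints.

    Positions are taken at the retained instants; the classifier output
    q is averaged over each retained interval (anti-aliased), so that
    the intent vector δ lives on the same time scale as the
    finite-difference velocities computed downstream."""
    n = len(trace)
    if n < 2:
        raise ValueError("cannot downsample a trace with fewer than 2 points")
    duration = trace.times[-1] - trace.times[0]
    wanted = min(max_points, max(2, int(round(duration / spacing_s)) + 1))
    if n <= wanted:
        return trace
    idx = np.unique(np.round(np.linspace(0, n - 1, wanted)).astype(int))
    q = None
    if trace.q is not None:
        q = np.empty((len(idx), trace.q.shape[1]))
        for j in range(len(idx) - 1):
            q[j] = trace.q[idx[j] : idx[j + 1]].mean(axis=0)
        q[-1] = trace.q[idx[-1]]
    return GameTrace(
        times=trace.times[idx],
        cursor=trace.cursor[idx],
        target=trace.target[idx],
        q=q,
        level=trace.level,
        score=trace.score,
    )


def velocities(positions: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Forward-difference velocity estimates; one fewer row than input."""
    positions = np.asarray(positions, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("velocity needs at least 2 points")
    dt = np.diff(times)
    if np.any(dt == 0):
        raise ValueError("repeated timestamps in trace")
    return np.diff(positions, axis=0) / dt[:, None]


def interception_time(
    rho_p: np.ndarray,
    omega_p: np.ndarray,
    rho_c: np.ndarray,
    omega_c: np.ndarray,
) -> float | None:
    """Smallest positive root of ||ω_p|| t = ||d + ω_c t||, or None.

    Squaring gives (||ω_c||² − ||ω_p||²) t² + 2 (d·ω_c) t + ||d||² = 0.
    """
    d = np.asarray(rho_c, float) - np.asarray(rho_p, float)
    omega_p = np.asarray(omega_p, float)
    omega_c = np.asarray(omega_c, float)
    a = float(omega_c @ omega_c - omega_p @ omega_p)
    b = 2.0 * float(d @ omega_c)
    c = float(d @ d)
    if c == 0:
        return 0.0
    if abs(a) < 1e-12:
        # equal speeds: linear equation b t + c = 0
        if b >= 0:
            return None
        return -c / b
    disc = b * b - 4 * a * c
    if disc < 0:
        return None
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / (2 * a), (-b + sq) / (2 * a)))
    for t in roots:
        if t > 0:
            return t
    return None


def best_direction(
    rho_p: np.ndarray,
    omega_p: np.ndarray,
    rho_c: np.ndarray,
    omega_c: np.ndarray,
    dt_next: float,
) -> np.ndarray:
    """Unit vector toward the earliest interception point.

    Falls back to the direction of the target's position one time step
    (``dt_next``) ahead when no positive interception time exists
    (including a motionless cursor).
    """
    rho_p = np.asarray(rho_p, float)
    rho_c = np.asarray(rho_c, float)
    omega_c = np.asarray(omega_c, float)
    d = rho_c - rho_p
    if float(np.hypot(*d)) == 0.0:
        raise ValueError("cursor and target coincide; direction undefined")
    t_star = interception_time(rho_p, omega_p, rho_c, omega_c)
    if t_star is None or t_star == 0.0:
        t_star = dt_next
    v = d + omega_c * t_star
    norm = float(np.hypot(*v))
    if norm == 0.0:
        v = d
        norm = float(np.hypot(*v))
    return v / norm


def best_directions(trace: GameTrace) -> np.ndarray:
    """Best direction at every step but the last ((n−1, 2); rows of NaN
    where the cursor and target coincide)."""
    omega_p = velocities(trace.cursor, trace.times)
    omega_c = velocities(trace.target, trace.times)
    dts = np.diff(trace.times)
    out = np.full((len(trace) - 1, 2), np.nan)
    for i in range(len(trace) - 1):
        d = trace.target[i] - trace.cursor[i]
        if float(np.hypot(*d)) == 0.0:
            continue
        out[i] = best_direction(
            trace.cursor[i], omega_p[i], trace.target[i], omega_c[i], dts[i]
        )
    return out


def continuous_target_steps(trace: GameTrace) -> np.ndarray:
    """Boolean mask over the n−1 velocity frames marking steps where the
    target moved continuously.  A caught target reappearing elsewhere
    produces one step far faster than its normal motion; such frames
    belong to no pursuit trajectory and are excluded from decision
    statistics."""
    speeds = np.hypot(*velocities(trace.target, trace.times).T)
    med = float(np.median(speeds))
    if med <= 1e-12:
        return speeds <= 1e-12
    return speeds <= 4.0 * med


def signed_angle(reference: np.ndarray, vector: np.ndarray) -> float:
    """Signed angle from ``reference`` to ``vector`` in (−π, π],
    counter-clockwise positive."""
    cross = reference[0] * vector[1] - reference[1] * vector[0]
    dot = reference[0] * vector[0] + reference[1] * vector[1]
    return math.atan2(cross, dot)


def angular_deviation(trace: GameTrace) -> np.ndarray:
    """Signed angle α(t) between the cursor velocity and the best
    direction, per step; frames with zero cursor velocity are skipped."""
    if len(trace) < 3:
        raise ValueError("angular deviation needs at least 3 points")
    omega_p = velocities(trace.cursor, trace.times)
    n_vecs = best_directions(trace)
    ok = continuous_target_steps(trace)
    alphas = []
    skipped = 0
    for i in range(len(trace) - 1):
        if not ok[i] or np.any(np.isnan(n_vecs[i])):
            skipped += 1
            continue
        if float(np.hypot(*omega_p[i])) == 0.0:
            skipped += 1
            continue
        alphas.append(signed_angle(n_vecs[i], omega_p[i]))
    if skipped:
        log.info("angular_deviation: skipped %d degenerate frames", skipped)
    return np.asarray(alphas)


@dataclass
class DecisionStats:
    """Circular summary of the angular-deviation distribution."""

    hist_counts: np.ndarray
    hist_edges: np.ndarray
    peak_location: float
    spread: float
    peak_stable: bool
    n: int
    rates: dict = field(default_factory=dict)
    total_gestures: int = 0

    def to_dict(self) -> dict:
        return {
            "peak_location": self.peak_location,
            "spread": self.spread,
            "peak_stable": self.peak_stable,
            "n": self.n,
            "rates": {f"{d}_{k}": v for (d, k), v in self.rates.items()},
            "total_gestures": self.total_gestures,
        }


def decision_stats(alpha: np.ndarray, bins: int = 36) -> DecisionStats:
    """Histogram, modal angle and circular spread of a deviation series.

    The peak is the center of the modal histogram bin; the spread is the
    circular standard deviation.  With a nearly uniform distribution
    (mean resultant length < 0.1) the peak is flagged unstable.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.size < 10:
        raise ValueError("decision statistics need at least 10 angles")
    counts, edges = np.histogram(alpha, bins=bins, range=(-math.pi, math.pi))
    peak_bin = int(counts.argmax())
    peak = 0.5 * (edges[peak_bin] + edges[peak_bin + 1])
    spread = float(stats.circstd(alpha, high=math.pi, low=-math.pi))
    resultant = float(np.hypot(np.cos(alpha).mean(), np.sin(alpha).mean()))
    return DecisionStats(
        hist_counts=counts,
        hist_edges=edges,
        peak_location=peak,
        spread=spread,
        peak_stable=resultant >= 0.1,
        n=int(alpha.size),
    )


def gesture_fidelity(
    trace: GameTrace,
    d_th: float = 0.6,
    prevalence_frac: float = 0.2,
) -> DecisionStats:
    """Rates of optimal / incorrect left, right, up and down gestures.

    The intent vector δ(t) = (qr − ql, qu − qd) is *optimal* when its
    cosine with the best direction exceeds ``d_th`` and incorrect
    otherwise.  Each gesture is attributed to the direction of its
    dominant component, provided that component exceeds
    ``prevalence_frac`` standard deviations (σ computed per component
    over the whole trace); gestures below threshold fall in no set, so
    the eight sets are disjoint and their rates sum to at most 1.
    Rates are relative to L, the number of evaluated gesture frames.
    """
    if trace.q is None:
        raise ValueError("trace has no classifier output vectors")
    delta = np.column_stack(
        [trace.q[:, 1] - trace.q[:, 0], trace.q[:, 2] - trace.q[:, 3]]
    )
    if not np.any(np.abs(delta) > 0):
        raise ValueError("all-zero intent vectors; nothing to evaluate")
    sigma = delta.std(axis=0)
    if np.any(sigma == 0):
        raise ValueError("an intent component has zero variance")

    n_vecs = best_directions(trace)
    ok = continuous_target_steps(trace)
    counts = {(d, k): 0 for d in ("left", "right", "up", "down") for k in ("opt", "inc")}
    L = 0
    for i in range(len(trace) - 1):
        if not ok[i] or np.any(np.isnan(n_vecs[i])):
            continue
        L += 1
        dvec = delta[i]
        norm = float(np.hypot(*dvec))
        if norm == 0.0:
            continue
        optimal = float(dvec @ n_vecs[i]) / norm > d_th
        a1 = abs(dvec[0]) / sigma[0]
        a2 = abs(dvec[1]) / sigma[1]
        if max(a1, a2) <= prevalence_frac:
            continue
        if a1 >= a2:
            direction = "left" if dvec[0] < 0 else "right"
        else:
            direction = "up" if dvec[1] > 0 else "down"
        counts[(direction, "opt" if optimal else "inc")] += 1

    if L == 0:
        raise ValueError("no evaluable frames in trace")
    alpha = angular_deviation(trace)
    base = (
        decision_stats(alpha)
        if alpha.size >= 10
        else DecisionStats(
            hist_counts=np.zeros(0),
            hist_edges=np.zeros(0),
            peak_location=float("nan"),
            spread=float("nan"),
            peak_stable=False,
            n=int(alpha.size),
        )
    )
    base.rates = {key: c / L for key, c in counts.items()}
    base.total_gestures = L
    return base
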