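"""Synthetic sEMG recordings, subject cohorts, and pursuit-game traces.

Forward model
-------------
Eight electrodes ring a forearm whose activity is dominated by five
muscles: *flexor carpi radialis* (FR), *extensor carpi radialis longus*
(ER), *extensor digitorum* (ED), *extensor carpi ulnaris* (EU), and
*flexor carpi ulnaris* (FU).  Each muscle k has a fixed non-negative
loading column W_k peaked at one electrode (2, 4, 5, 6, 8 in 1-based
numbering), and the noise-free electrode mix is the linear combination

    x(t) = Σ_k W_k · s_k(t) · c_k(t),

where s_k(t) is the muscle's slowly varying activation envelope and
c_k(t) an independent zero-mean, unit-variance band-limited (20–450 Hz)
noise carrier — the standard amplitude-modulated surrogate for raw sEMG.

Gestures set the envelopes: each gesture activates its synergist muscles
per an activation template, and the subject's antagonist *co-activation*
factor adds a scaled copy of the opposite gesture's template (poorly
coordinated subjects contract antagonists along with synergists, which
lowers the measured synergist–antagonist coefficient).  Envelopes ramp
linearly over ~100 ms at gesture transitions and fluctuate slowly
(execution variability).  A subject *attenuation* factor in (0, 1]
scales the recorded mixture — emulating signal loss through body fatty
tissue; the body-fat index is mapped monotonically decreasing from it.

The game simulator replays the pursuit task: a simulated user aims at
the optimal interception direction but acts with a reaction delay,
angular noise, and per-gesture substitution errors, and the emitted
classifier output vector drives the cursor through the proportional
control law.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import gestures as G
from .features import EmgRecording

#: muscle names in column order of the default loadings matrix
SOURCES = ("FR", "ER", "ED", "EU", "FU")

#: 1-based electrode under which each default source peaks
PEAK_CHANNELS = (2, 4, 5, 6, 8)

# Synergist activation level of each muscle for the basic gestures.
# Flexors (FR, FU) drive flexion/left, extensors (ER, EU) extension/right,
# the radial pair (FR, ER) radial deviation/up, the ulnar pair (EU, FU)
# ulnar deviation/down.  The extensor digitorum (ED) assists extension
# strongly and both deviations moderately.
_BASIC_TEMPLATES = {
    "G0": {},
    "G1": {"FR": 1.0, "FU": 1.0},
    "G2": {"ER": 1.0, "EU": 1.0, "ED": 1.0},
    "G3": {"FR": 1.0, "ER": 1.0, "ED": 0.6},
    "G4": {"EU": 1.0, "FU": 1.0, "ED": 0.6},
}


def _default_templates() -> dict[str, np.ndarray]:
    templates = {}
    for g, levels in _BASIC_TEMPLATES.items():
        v = np.zeros(len(SOURCES))
        for name, level in levels.items():
            v[SOURCES.index(name)] = level
        templates[g] = v
    # compound gestures: sum of parents scaled by 1/sqrt(2) keeps the
    # total signal power comparable to a basic gesture
    for g, (p1, p2) in G.COMPOUND_PARENTS.items():
        templates[g] = (templates[p1] + templates[p2]) / math.sqrt(2.0)
    return templates


def _ring_distance(a: int, b: int, n: int = 8) -> int:
    d = abs(a - b) % n
    return min(d, n - d)


def _default_loadings() -> np.ndarray:
    """(8, 5) mixing matrix: peak 1.0, ring-neighbors 0.25, next 0.05."""
    w = np.zeros((8, len(SOURCES)))
    fall_off = {0: 1.0, 1: 0.25, 2: 0.05}
    for k, peak in enumerate(PEAK_CHANNELS):
        for ch in range(1, 9):
            d = _ring_distance(ch, peak)
            w[ch - 1, k] = fall_off.get(d, 0.0)
    return w


@dataclass
class MuscleModel:
    """Linear forward model from muscle sources to electrodes."""

    loadings: np.ndarray = field(default_factory=_default_loadings)
    activation_templates: dict = field(default_factory=_default_templates)
    n_channels: int = 8
    n_sources: int = len(SOURCES)

    def __post_init__(self) -> None:
        w = np.asarray(self.loadings, dtype=float)
        if w.shape != (self.n_channels, self.n_sources):
            raise ValueError("loadings must be (n_channels, n_sources)")
        if (w < 0).any():
            raise ValueError("loadings must be non-negative")
        peaks = w.argmax(axis=0)
        if len(set(peaks.tolist())) != self.n_sources:
            raise ValueError("each source must peak at a distinct channel")
        self.loadings = w
        rest = self.activation_templates.get(G.REST)
        if rest is not None and np.any(np.asarray(rest) != 0):
            raise ValueError("rest template must be all-zeros")

    @property
    def peak_channel_per_source(self) -> list[int]:
        """1-based electrode index under which each source peaks."""
        return [int(i) + 1 for i in self.loadings.argmax(axis=0)]

    def envelope_template(self, gesture: str, co_activation: float) -> np.ndarray:
        """Per-source target level for a gesture, antagonists included."""
        try:
            base = self.activation_templates[gesture]
        except KeyError:
            raise ValueError(f"unknown gesture id {gesture!r}") from None
        opp = self.activation_templates[G.OPPOSITE[gesture]]
        return np.asarray(base) + co_activation * np.asarray(opp)


def bf_from_attenuation(attenuation: float) -> float:
    """Body-fat index (%) mapped linearly, decreasing, from signal gain."""
    return 44.0 - 40.0 * attenuation


@dataclass
class SubjectProfile:
    """Latent factors of a simulated subject.

    co_activation    : antagonist activation as a fraction of synergist
                       activation, in [0, 1) — drives the SAC down
    attenuation      : multiplicative gain on the recorded signal in
                       (0, 1] — emulates body-fat attenuation
    reaction_delay   : seconds between game state and the user's response
    angular_noise_sd : radians of noise on the intended direction
    per_gesture_error_rate : per-gesture articulation-error probability:
                       with this probability a newly needed gesture is
                       evoked late — it only appears after an extra
                       delay, by which time the optimal direction has
                       moved on, so the late gesture lands outside the
                       decision cone
    """

    co_activation: float = 0.2
    attenuation: float = 1.0
    reaction_delay: float = 0.25
    angular_noise_sd: float = 0.25
    per_gesture_error_rate: dict = field(
        default_factory=lambda: {g: 0.05 for g in G.DIRECTIONAL}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.co_activation < 1.0:
            raise ValueError("co_activation must be in [0, 1)")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must be in (0, 1]")
        for g, p in self.per_gesture_error_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"error rate for {g} must be in [0, 1]")

    @property
    def bf_index(self) -> float:
        return bf_from_attenuation(self.attenuation)

    def to_dict(self) -> dict:
        return {
            "co_activation": self.co_activation,
            "attenuation": self.attenuation,
            "bf_index": self.bf_index,
            "reaction_delay": self.reaction_delay,
            "angular_noise_sd": self.angular_noise_sd,
            "per_gesture_error_rate": dict(self.per_gesture_error_rate),
        }


def _bandlimited_noise(rng, n, rate, band=(20.0, 450.0)) -> np.ndarray:
    """Zero-mean, unit-variance band-limited Gaussian noise."""
    hi = min(band[1], 0.499 * rate)
    sos = sps.butter(4, [band[0], hi], btype="band", fs=rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    return x / x.std()


def _slow_noise(rng, n, rate, cutoff_hz=1.0) -> np.ndarray:
    """Unit-variance low-pass noise for execution variability."""
    sos = sps.butter(2, cutoff_hz, btype="low", fs=rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_recording(
    model: MuscleModel,
    profile: SubjectProfile,
    gesture_sequence: list[tuple[str, float]],
    rate: float = 1000.0,
    seed: int = 0,
    *,
    ramp_ms: float = 100.0,
    exec_noise_sd: float = 0.15,
    trial_jitter_sd: float = 0.2,
    background_noise_sd: float = 0.05,
    sensor_noise_sd: float = 0.15,
) -> EmgRecording:
    """Simulate a labeled 8-channel sEMG recording.

    Each channel is ``attenuation × (Σ_k W_k s_k(t) c_k(t) + background)
    + sensor noise``.  The background term models physiological noise
    that is attenuated together with the muscle signal; the sensor term
    is electrode-referred noise that does *not* scale with the tissue
    gain — which is exactly why low attenuation (high body fat) lowers
    the signal-to-noise ratio of the interface.

    Parameters
    ----------
    gesture_sequence : list of (gesture id, duration in seconds)
    ramp_ms : linear onset/offset ramp applied to envelopes
    exec_noise_sd : relative slow (~1 Hz) fluctuation of the activation
        level within a held gesture
    trial_jitter_sd : relative log-normal variability of each muscle's
        overall level between gesture repetitions
    """
    if rate < 200:
        raise ValueError("rate must be at least 200 Hz")
    rng = np.random.default_rng(seed)

    # per-sample target envelope per source
    segments = []
    labels = []
    for gesture, duration in gesture_sequence:
        if duration <= 0:
            raise ValueError("gesture durations must be positive")
        n = int(round(duration * rate))
        levels = model.envelope_template(gesture, profile.co_activation)
        if trial_jitter_sd > 0:
            levels = levels * np.exp(
                trial_jitter_sd * rng.standard_normal(len(levels))
                - 0.5 * trial_jitter_sd**2
            )
        segments.append(np.tile(levels, (n, 1)))
        labels.extend([gesture] * n)
    env = np.concatenate(segments, axis=0)
    labels = np.asarray(labels)
    T = env.shape[0]

    # linear onset/offset ramps: moving average turns steps into ramps
    n_ramp = max(1, int(round(ramp_ms * rate / 1000.0)))
    kernel = np.ones(n_ramp) / n_ramp
    for k in range(env.shape[1]):
        env[:, k] = np.convolve(env[:, k], kernel, mode="same")

    # slow multiplicative execution variability, independent per source
    if exec_noise_sd > 0:
        for k in range(env.shape[1]):
            env[:, k] = env[:, k] * np.clip(
                1.0 + exec_noise_sd * _slow_noise(rng, T, rate), 0.0, None
            )

    carriers = np.column_stack(
        [_bandlimited_noise(rng, T, rate) for _ in range(model.n_sources)]
    )
    mix = (env * carriers) @ model.loadings.T

    if background_noise_sd > 0:
        mix = mix + background_noise_sd * rng.standard_normal(mix.shape)
    samples = profile.attenuation * mix
    if sensor_noise_sd > 0:
        samples = samples + sensor_noise_sd * rng.standard_normal(samples.shape)

    return EmgRecording(
        samples=samples,
        rate=rate,
        labels=labels,
        meta={
            "seed": seed,
            "profile": profile.to_dict(),
            "source_envelopes": env,
            "source_names": list(SOURCES),
        },
    )


#: gesture sequence used for cohort train/test recordings: every
#: directional gesture held for `hold` seconds, separated by rest,
#: the whole block repeated `reps` times
def standard_sequence(
    hold: float = 2.0, rest: float = 1.0, reps: int = 1, gestures=G.DIRECTIONAL
) -> list:
    seq = [(G.REST, rest)]
    for _ in range(reps):
        for g in gestures:
            seq.append((g, hold))
            seq.append((G.REST, rest))
    return seq


def basic_gesture_sequence(reps: int = 8, hold: float = 3.0, rest: float = 0.5) -> list:
    """Repeated blocks of the four basic gestures — the protocol used
    for muscle-source localization, where repetitions with independent
    trial-to-trial variability are what lets ICA tell the muscles apart."""
    return standard_sequence(hold=hold, rest=rest, reps=reps, gestures=G.BASIC)


DEFAULT_FACTOR_RANGES = {
    "co_activation": (0.15, 0.45),
    "attenuation": (0.15, 1.0),
    "reaction_delay": (0.15, 0.45),
    "angular_noise_sd": (0.1, 0.5),
    "gesture_error_rate": (0.02, 0.15),
}


def _draw(rng, lo, hi):
    if lo > hi:
        raise ValueError(f"degenerate range: min {lo} > max {hi}")
    return lo if lo == hi else rng.uniform(lo, hi)


def draw_profile(rng, factor_ranges: dict | None = None) -> SubjectProfile:
    """Draw one subject's latent factors from uniform ranges."""
    ranges = dict(DEFAULT_FACTOR_RANGES)
    if factor_ranges:
        ranges.update(factor_ranges)
    err = _draw(rng, *ranges["gesture_error_rate"])
    return SubjectProfile(
        co_activation=_draw(rng, *ranges["co_activation"]),
        attenuation=_draw(rng, *ranges["attenuation"]),
        reaction_delay=_draw(rng, *ranges["reaction_delay"]),
        angular_noise_sd=_draw(rng, *ranges["angular_noise_sd"]),
        per_gesture_error_rate={g: err for g in G.DIRECTIONAL},
    )


def simulate_cohort(
    n_subjects: int,
    factor_ranges: dict | None = None,
    seed: int = 0,
    *,
    model: MuscleModel | None = None,
    hold: float = 2.0,
    rest: float = 1.0,
    reps: int = 3,
    rate: float = 1000.0,
) -> list[tuple[SubjectProfile, dict]]:
    """Simulate a cohort: per subject, latent factors plus one training
    and one testing recording of all gestures (rest and G1–G8), each
    gesture repeated ``reps`` times per recording.

    Returns a list of ``(profile, {"train": EmgRecording, "test":
    EmgRecording})``.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    model = model or MuscleModel()
    root = np.random.SeedSequence(seed)
    out = []
    seq = standard_sequence(hold=hold, rest=rest, reps=reps)
    for subject_ss in root.spawn(n_subjects):
        prof_seed, train_seed, test_seed = subject_ss.generate_state(3) >> 1
        rng = np.random.default_rng(int(prof_seed))
        profile = draw_profile(rng, factor_ranges)
        recs = {
            "train": simulate_recording(
                model, profile, seq, rate=rate, seed=int(train_seed)
            ),
            "test": simulate_recording(
                model, profile, seq, rate=rate, seed=int(test_seed)
            ),
        }
        out.append((profile, recs))
    return out


# ---------------------------------------------------------------------------
# pursuit game


@dataclass
class GameScenario:
    """Arena and target trajectory of one pursuit level.

    The target moves along the way-point polyline at constant speed per
    segment, looping; when caught it reappears at a random way-point.
    """

    arena: tuple[float, float] = (800.0, 600.0)
    waypoints: np.ndarray | None = None
    speed: float = 60.0
    cursor_start: tuple[float, float] = (400.0, 300.0)
    duration: float = 60.0
    catch_radius: float = 20.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not np.isfinite(self.speed):
            raise ValueError("speed must be finite")
        if self.waypoints is None:
            w, h = self.arena
            self.waypoints = np.array(
                [
                    [0.15 * w, 0.2 * h],
                    [0.85 * w, 0.3 * h],
                    [0.7 * w, 0.85 * h],
                    [0.25 * w, 0.7 * h],
                ]
            )
        self.waypoints = np.asarray(self.waypoints, dtype=float)
        w, h = self.arena
        if (
            (self.waypoints[:, 0] < 0).any()
            or (self.waypoints[:, 0] > w).any()
            or (self.waypoints[:, 1] < 0).any()
            or (self.waypoints[:, 1] > h).any()
        ):
            raise ValueError("target way-points must stay inside the arena")


class _TargetWalker:
    """Constant-speed walk along a looping way-point polyline."""

    def __init__(self, scenario: GameScenario, start_index: int = 0):
        self.scenario = scenario
        self.idx = start_index % len(scenario.waypoints)
        self.pos = scenario.waypoints[self.idx].copy()

    def step(self, dt: float) -> np.ndarray:
        remaining = self.scenario.speed * dt
        while remaining > 0:
            nxt = self.scenario.waypoints[
                (self.idx + 1) % len(self.scenario.waypoints)
            ]
            leg = nxt - self.pos
            dist = float(np.hypot(*leg))
            if dist <= remaining:
                self.pos = nxt.copy()
                self.idx = (self.idx + 1) % len(self.scenario.waypoints)
                remaining -= dist
                if dist == 0 and remaining > 0:
                    break
            else:
                self.pos = self.pos + leg * (remaining / dist)
                remaining = 0.0
        return self.pos.copy()

    def respawn(self, rng) -> None:
        self.idx = int(rng.integers(len(self.scenario.waypoints)))
        self.pos = self.scenario.waypoints[self.idx].copy()


def ideal_emitter(encoding=None):
    """Emitter that outputs the ideal target vector of each gesture at
    full effort (v = 1)."""
    from .classifiers import directional_encoding

    enc = encoding or directional_encoding()

    def emit(gesture: str, rng) -> tuple[np.ndarray, float]:
        return enc.target(gesture), 1.0

    return emit


def simulate_game_trace(
    scenario: GameScenario,
    profile: SubjectProfile,
    emitter=None,
    seed: int = 0,
    *,
    gain: float = 20.0,
    tick_s: float = 0.1,
    error_delay_s: float = 0.5,
    level: int = 0,
):
    """Simulate a pursuit-game trial and return a GameTrace.

    At every control tick the simulated user computes the optimal
    interception direction from the game state as it was
    ``reaction_delay`` seconds ago, perturbs it with angular noise, and
    quantizes it to the nearest of the eight directional gestures.
    Articulation errors delay the evocation: when the intent switches
    to gesture g, with probability ``per_gesture_error_rate[g]`` the
    switch only takes effect ``error_delay_s`` later — the user keeps
    emitting the old gesture meanwhile, and the late g is emitted even
    though the optimal direction has moved on.  The emitted classifier
    output ``q`` and effort ``v`` come from ``emitter(gesture, rng)``,
    and the cursor moves by ``gain · v · (qr − ql, qu − qd)``.
    """
    from .game import GameTrace, best_direction

    emitter = emitter or ideal_emitter()
    rng = np.random.default_rng(seed)
    n_steps = int(round(scenario.duration / tick_s))
    if n_steps < 2:
        raise ValueError("duration must cover at least two ticks")

    walker = _TargetWalker(scenario)
    cursor = np.asarray(scenario.cursor_start, dtype=float).copy()
    delay_steps = max(0, int(round(profile.reaction_delay / tick_s)))

    times = np.zeros(n_steps)
    cur_hist = np.zeros((n_steps, 2))
    tgt_hist = np.zeros((n_steps, 2))
    q_hist = np.zeros((n_steps, 4))
    score = 0
    emitted = None
    pending = None  # (gesture, step at which the late gesture appears)
    error_ticks = max(1, int(round(error_delay_s / tick_s)))

    w, h = scenario.arena
    for i in range(n_steps):
        times[i] = i * tick_s
        cur_hist[i] = cursor
        tgt_hist[i] = walker.pos

        j = max(0, i - delay_steps)
        jp = max(0, j - 1)
        rho_p = cur_hist[j]
        rho_c = tgt_hist[j]
        if j > jp:
            omega_p = (cur_hist[j] - cur_hist[jp]) / tick_s
            omega_c = (tgt_hist[j] - tgt_hist[jp]) / tick_s
        else:
            omega_p = np.zeros(2)
            omega_c = np.zeros(2)

        d = rho_c - rho_p
        if np.hypot(*d) < 1e-9:
            n_vec = np.array([1.0, 0.0])
        else:
            n_vec = best_direction(rho_p, omega_p, rho_c, omega_c, tick_s)
        angle = math.atan2(n_vec[1], n_vec[0])
        angle += profile.angular_noise_sd * rng.standard_normal()
        intent = G.nearest_gesture(angle)
        if emitted is None:
            emitted = intent
        elif pending is not None:
            if i >= pending[1]:  # the delayed gesture finally appears
                emitted = pending[0]
                pending = None
        elif intent != emitted:
            p_err = profile.per_gesture_error_rate.get(intent, 0.0)
            if p_err > 0 and rng.random() < p_err:
                pending = (intent, i + error_ticks)
            else:
                emitted = intent
        gesture = emitted

        q, v = emitter(gesture, rng)
        q_hist[i] = q
        ql, qr, qu, qd = q
        cursor = cursor + gain * v * np.array([qr - ql, qu - qd])
        cursor[0] = min(max(cursor[0], 0.0), w)
        cursor[1] = min(max(cursor[1], 0.0), h)

        walker.step(tick_s)
        if np.hypot(*(walker.pos - cursor)) < scenario.catch_radius:
            score += 1
            walker.respawn(rng)

    return GameTrace(
        times=times,
        cursor=cur_hist,
        target=tgt_hist,
        q=q_hist,
        level=level,
        score=score,
    )


def write_manifest(rec: EmgRecording, path) -> None:
    """Sidecar JSON manifest for a recording CSV."""
    meta = {k: v for k, v in rec.meta.items() if k != "source_envelopes"}
    meta["rate"] = rec.rate
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
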