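"""Windowed RMS and mean-power features of multichannel sEMG.

The raw data flow ``x(t) ∈ R^K`` (K electrodes, 1 kHz by default) is cut
into overlapping trailing windows of N samples advanced by M samples.
Per channel the window RMS

    V(t) = sqrt( (1/N) Σ_{n=0}^{N-1} x(t-n)^2 )

is the amplitude feature fed to the classifiers, and the mean power
pooled over window samples and all channels

    P(t) = (1/(N K)) Σ_{n=0}^{N-1} ||x(t-n)||_1

estimates the overall muscle effort that drives proportional control.
Windows are causal; a frame's timestamp is the right edge of its window,
and leading partial windows are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EmgRecording:
    """A labeled multichannel sEMG time series.

    samples : array (T, K), arbitrary amplitude units
    rate    : sampling rate in Hz
    labels  : array (T,) of per-sample gesture ids (strings)
    meta    : free-form provenance (subject profile, seed, ground truth)
    """

    samples: np.ndarray
    rate: float
    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (T, K) matrix")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.samples.shape[0]:
            raise ValueError("labels must have one entry per sample")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def to_csv(self, path) -> None:
        """Write as CSV with columns time_s, ch1..chK, gesture_label."""
        t = np.arange(self.n_samples) / self.rate
        cols = {"time_s": t}
        for k in range(self.n_channels):
            cols[f"ch{k + 1}"] = self.samples[:, k]
        cols["gesture_label"] = self.labels
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate: float | None = None) -> "EmgRecording":
        df = pd.read_csv(path)
        chans = [c for c in df.columns if c.startswith("ch")]
        if rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            rate = 1.0 / float(np.median(dt))
        return cls(
            samples=df[chans].to_numpy(dtype=float),
            rate=rate,
            labels=df["gesture_label"].to_numpy(),
        )


@dataclass
class FeatureStream:
    """Per-window RMS vectors and mean power of a recording.

    V              : array (frames, K), window RMS per channel
    P              : array (frames,), mean power pooled over channels
    frame_times    : seconds, right edge of each window
    window_samples : N
    step_samples   : M
    labels         : per-frame gesture id (majority label in the window)
    """

    V: np.ndarray
    P: np.ndarray
    frame_times: np.ndarray
    window_samples: int
    step_samples: int
    labels: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.V.shape[0]

    @property
    def n_channels(self) -> int:
        return self.V.shape[1]

    def to_csv(self, path) -> None:
        cols = {"frame_time": self.frame_times}
        for k in range(self.n_channels):
            cols[f"V{k + 1}"] = self.V[:, k]
        cols["P"] = self.P
        cols["label"] = self.labels
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureStream":
        df = pd.read_csv(path)
        vcols = [c for c in df.columns if c.startswith("V")]
        t = df["frame_time"].to_numpy(dtype=float)
        step = float(np.median(np.diff(t))) if len(t) > 1 else 0.1
        return cls(
            V=df[vcols].to_numpy(dtype=float),
            P=df["P"].to_numpy(dtype=float),
            frame_times=t,
            window_samples=0,
            step_samples=int(round(step * 1000)),
            labels=df["label"].to_numpy(),
        )

    def subset(self, mask: np.ndarray) -> "FeatureStream":
        """Frames selected by a boolean mask, as a new stream."""
        return FeatureStream(
            V=self.V[mask],
            P=self.P[mask],
            frame_times=self.frame_times[mask],
            window_samples=self.window_samples,
            step_samples=self.step_samples,
            labels=self.labels[mask],
        )


def _frame_layout(T: int, rate: float, window_ms: float, step_ms: float):
    if window_ms < step_ms:
        raise ValueError("window_ms must be >= step_ms")
    N = int(round(window_ms * rate / 1000.0))
    M = int(round(step_ms * rate / 1000.0))
    if N < 1 or M < 1:
        raise ValueError("window and step must span at least one sample")
    if T < N:
        raise ValueError(
            f"recording of {T} samples is shorter than one {N}-sample window"
        )
    n_frames = (T - N) // M + 1
    # index of the last sample of each window
    ends = N - 1 + M * np.arange(n_frames)
    return N, M, ends


def _majority_labels(labels: np.ndarray, ends: np.ndarray, N: int) -> np.ndarray:
    codes, inv = np.unique(labels, return_inverse=True)
    out = np.empty(len(ends), dtype=labels.dtype)
    for i, e in enumerate(ends):
        window = inv[e - N + 1 : e + 1]
        out[i] = codes[np.bincount(window).argmax()]
    return out


def rms_windows(
    rec: EmgRecording,
    window_ms: float = 200.0,
    step_ms: float = 100.0,
    drop_transitions: bool = False,
) -> FeatureStream:
    """Sliding-window RMS envelope (and mean power) of a recording.

    Parameters
    ----------
    rec : EmgRecording
    window_ms, step_ms : window length and hop, in milliseconds
        (defaults 200/100 ms, i.e. half-overlapping windows at 1 kHz).
    drop_transitions : discard frames whose window spans more than one
        gesture label (useful when only static gestures are of interest).
    """
    x = rec.samples
    N, M, ends = _frame_layout(rec.n_samples, rec.rate, window_ms, step_ms)

    csq = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(x**2, axis=0)])
    V = np.sqrt((csq[ends + 1] - csq[ends + 1 - N]) / N)

    cab = np.concatenate([np.zeros((1, x.shape[1])), np.cumsum(np.abs(x), axis=0)])
    P = (cab[ends + 1] - cab[ends + 1 - N]).sum(axis=1) / (N * x.shape[1])

    labels = _majority_labels(rec.labels, ends, N)
    stream = FeatureStream(
        V=V,
        P=P,
        frame_times=(ends + 1) / rec.rate,
        window_samples=N,
        step_samples=M,
        labels=labels,
    )
    if drop_transitions:
        pure = np.array(
            [
                len(np.unique(rec.labels[e - N + 1 : e + 1])) == 1
                for e in ends
            ]
        )
        stream = stream.subset(pure)
    return stream


def mean_power(
    rec: EmgRecording, window_ms: float = 200.0, step_ms: float = 100.0
) -> np.ndarray:
    """Windowed mean power P(t): mean |x| pooled over window and channels."""
    return rms_windows(rec, window_ms, step_ms).P
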