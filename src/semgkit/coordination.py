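"""Muscle-source separation and the synergist–antagonist coefficient.

The RMS envelopes V(t) ∈ R^8 recorded by the electrode ring are modeled
as a linear mixture of m muscle sources,

    V(t) = Σ_{k=1}^{m} W_k s_k(t),

and independent component analysis (ICA) estimates both the loadings
W_k and the activations s_k(t).  On forearm recordings of the four
basic wrist gestures the mixture is dominated by five spatially
localized sources whose loadings peak under electrodes 2, 4, 5, 6 and
8 — the flexor carpi radialis, extensor carpi radialis longus, extensor
digitorum, extensor carpi ulnaris and flexor carpi ulnaris.

That localization justifies reading electrodes 2, 4, 6 and 8 directly
as the four muscles relevant to coordination (the extensor digitorum,
electrode 5, is left out).  Each basic gesture has two synergist and
two antagonist muscles among them; with the per-gesture mean RMS vector
V̄ the synergist and antagonist sums are

    left:  S1 = V̄2 + V̄8, A1 = V̄4 + V̄6      right: S2 = V̄4 + V̄6, A2 = V̄2 + V̄8
    up:    S3 = V̄2 + V̄4, A3 = V̄6 + V̄8      down:  S4 = V̄6 + V̄8, A4 = V̄2 + V̄4

and the synergist–antagonist coefficient of a subject is

    SAC = ln( (1/4) Σ_k S_k / A_k ).

SAC = 0 means synergists and antagonists are equally active; larger SAC
means cleaner, better-coordinated activation.  Because it is a ratio of
simultaneously recorded amplitudes, SAC is invariant to any common gain
on the recording (e.g. body-fat attenuation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .features import FeatureStream

#: 1-based synergist electrodes per basic gesture; antagonists are the
#: opposite gesture's synergists
SYNERGIST_CHANNELS = {
    "G1": (2, 8),
    "G2": (4, 6),
    "G3": (2, 4),
    "G4": (6, 8),
}
ANTAGONIST_CHANNELS = {
    "G1": (4, 6),
    "G2": (2, 8),
    "G3": (6, 8),
    "G4": (2, 4),
}


@dataclass
class IcaResult:
    """ICA decomposition of an RMS stream.

    loadings       : (channels, m) amplitude-scale mixing columns W_k,
                     ordered by explained variance, peak entries positive
    activations    : (frames, m) amplitude-scale source activations s_k(t)
    power_loadings : (channels, m) mixing columns of the power-domain
                     model (elementwise square of the amplitude loadings)
    power_activations : (frames, m) unmixed power envelopes
    explained      : fraction of total power variance per component
    localization   : per-component 1-based peak electrode
    """

    loadings: np.ndarray
    activations: np.ndarray
    power_loadings: np.ndarray
    power_activations: np.ndarray
    explained: np.ndarray

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    @property
    def localization(self) -> list[int]:
        return [int(i) + 1 for i in np.abs(self.loadings).argmax(axis=0)]

    def reconstruct(self) -> np.ndarray:
        """RMS matrix rebuilt from the retained components (power
        contributions add; amplitudes add in quadrature)."""
        power = self.power_activations @ self.power_loadings.T
        return np.sqrt(np.clip(power, 0.0, None))

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "loadings": self.loadings.tolist(),
            "explained": self.explained.tolist(),
            "localization": self.localization,
        }


def _run_fastica(X: np.ndarray, m: int, seed: int, n_restarts: int = 5):
    """FastICA with seed-controlled restarts on non-convergence."""
    last_err = None
    for attempt_seed in np.random.SeedSequence(seed).generate_state(n_restarts):
        ica = FastICA(
            n_components=m,
            whiten="unit-variance",
            max_iter=2000,
            tol=1e-4,
            random_state=int(attempt_seed >> 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica.fit(X)
                return ica.components_, ica.mixing_
            except ConvergenceWarning as err:  # pragma: no cover - rare
                last_err = err
    raise RuntimeError(
        f"ICA did not converge after {n_restarts} restarts; "
        f"try a different seed (last error: {last_err})"
    )


def decompose(
    features: FeatureStream,
    m: int | None = 5,
    seed: int = 0,
    var_threshold: float = 0.05,
    refine: bool = True,
) -> IcaResult:
    """ICA of the RMS stream into spatially localized muscle sources.

    The decomposition works in the power domain: for independent source
    carriers the windowed signal powers of the sources add linearly on
    every electrode, so the squared RMS matrix follows the linear
    mixture model exactly, with mixing columns equal to the squared
    amplitude loadings.  The unmixing matrix is estimated by FastICA on
    the first differences of the power envelopes — differencing
    suppresses the slow gesture on/off structure (which is shared
    between synergists and hence correlated) and leaves the fast
    per-muscle fluctuations, which are independent — and is then applied
    to the full power stream.  Because the power-domain model is also
    non-negative, the ICA solution is refined by default with a short
    non-negative matrix factorization (ICA resolves the rotational
    ambiguity that NMF alone would have; NMF enforces the
    non-negativity that ICA ignores).  Activations and loadings are
    reported on the amplitude (RMS) scale as the square roots of their
    power-domain counterparts.

    With an integer ``m`` exactly that many components are extracted
    (default 5).  With ``m=None`` the source count is selected
    automatically: the principal-component spectrum of the differenced
    power stream fixes the candidate dimension (eigenvalues carrying at
    least ``var_threshold`` of the total), and a component is then
    retained only if it explains at least ``var_threshold`` of the
    power variance and peaks at an electrode no stronger component
    claims.

    Components are ordered by explained variance and sign-fixed so the
    peak loading entry is positive.
    """
    V = features.V
    if V.shape[1] != 8:
        raise ValueError("expected 8-channel RMS features")
    X = V**2
    dX = np.diff(X, axis=0)
    auto = m is None
    if auto:
        eigvals = np.linalg.eigvalsh(np.cov(dX.T))[::-1]
        n_extract = max(1, int((eigvals / eigvals.sum() >= var_threshold).sum()))
    else:
        n_extract = m
    if X.shape[0] < 4 * n_extract + 1:
        raise ValueError("too few frames for a stable decomposition")

    unmixing, A = _run_fastica(dX, n_extract, seed)

    # apply the unmixing to the (uncentered) power stream; sources are
    # non-negative powers, so orient each component to positive mean
    S = X @ unmixing.T
    signs = np.sign(S.mean(axis=0))
    signs[signs == 0] = 1.0
    S = S * signs
    A = A * signs

    total_var = X.var(axis=0).sum()
    comp_var = (A**2).sum(axis=0) * S.var(axis=0)
    explained = comp_var / max(total_var, 1e-300)
    order = np.argsort(explained)[::-1]
    S, A, explained = S[:, order], A[:, order], explained[order]

    if auto:
        keep = explained >= var_threshold
        seen: set[int] = set()
        for j in np.flatnonzero(keep):
            peak = int(np.abs(A[:, j]).argmax())
            if peak in seen:  # keep the stronger (earlier) component
                keep[j] = False
            else:
                seen.add(peak)
        S, A, explained = S[:, keep], A[:, keep], explained[keep]

    # negative entries in the power mixing are estimation noise
    A_pos = np.clip(A, 0.0, None)
    S_pos = np.clip(S, 0.0, None)

    if refine and A_pos.shape[1] > 0:
        from sklearn.decomposition import NMF

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nmf = NMF(
                n_components=A_pos.shape[1],
                init="custom",
                max_iter=500,
                tol=1e-6,
            )
            S_pos = nmf.fit_transform(
                X,
                W=np.clip(S_pos, 1e-9, None).copy(order="C"),
                H=np.clip(A_pos.T, 1e-9, None).copy(order="C"),
            )
        A_pos = nmf.components_.T
        explained = (A_pos**2).sum(axis=0) * S_pos.var(axis=0) / max(total_var, 1e-300)
        order = np.argsort(explained)[::-1]
        S_pos, A_pos, explained = S_pos[:, order], A_pos[:, order], explained[order]

    return IcaResult(
        loadings=np.sqrt(A_pos),
        activations=np.sqrt(S_pos),
        power_loadings=A_pos,
        power_activations=S_pos,
        explained=explained,
    )


def mean_rms_per_gesture(
    features: FeatureStream, gestures=("G1", "G2", "G3", "G4")
) -> dict[str, np.ndarray]:
    """Mean RMS vector V̄ over the frames of each requested gesture."""
    out = {}
    labels = np.asarray(features.labels)
    for g in gestures:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"gesture {g} has no frames in the stream")
        out[g] = features.V[mask].mean(axis=0)
    return out


@dataclass
class SacReport:
    """Synergist/antagonist sums and the scalar coefficient."""

    synergist: dict[str, float]
    antagonist: dict[str, float]
    ratios: dict[str, float]
    sac: float

    def to_dict(self) -> dict:
        return {
            "synergist": self.synergist,
            "antagonist": self.antagonist,
            "ratios": self.ratios,
            "sac": self.sac,
        }


def sac(
    per_gesture_vbar: dict[str, np.ndarray],
    synergist_channels: dict | None = None,
    antagonist_channels: dict | None = None,
) -> SacReport:
    """Synergist–antagonist coefficient from per-gesture mean RMS.

    SAC = ln( (1/M) Σ_k S_k/A_k ) over the M = 4 basic gestures, using
    1-based electrodes 2, 4, 6, 8.
    """
    syn_map = synergist_channels or SYNERGIST_CHANNELS
    ant_map = antagonist_channels or ANTAGONIST_CHANNELS
    S, A, ratios = {}, {}, {}
    for g in syn_map:
        if g not in per_gesture_vbar:
            raise ValueError(f"mean RMS for gesture {g} is missing")
        vbar = np.asarray(per_gesture_vbar[g], dtype=float)
        s_val = float(sum(vbar[c - 1] for c in syn_map[g]))
        a_val = float(sum(vbar[c - 1] for c in ant_map[g]))
        if a_val == 0:
            raise ValueError(
                f"antagonist sum for {g} is zero; the ratio is infinite"
            )
        S[g], A[g] = s_val, a_val
        ratios[g] = s_val / a_val
    value = float(np.log(np.mean(list(ratios.values()))))
    return SacReport(synergist=S, antagonist=A, ratios=ratios, sac=value)


def sac_from_features(features: FeatureStream) -> SacReport:
    """Convenience: SAC straight from a labeled feature stream."""
    return sac(mean_rms_per_gesture(features))
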