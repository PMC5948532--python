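"""End-to-end synthetic study: cohort → features → classifiers →
coordination and game metrics → latent-factor regressions.

``run_synthetic_study`` simulates a cohort of subjects with latent
co-activation and attenuation factors, trains the gesture network per
subject, measures E_MS / F-measures / SAC, simulates pursuit-game play
driven by each subject's own trained classifier on their own held-out
feature frames (so classification errors propagate into game control),
and finally regresses the performance index Re on SAC and on the
body-fat index, and the game score on Re.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifiers as clf
from . import control as ctl
from . import coordination as coord
from . import evaluation as ev
from . import game as gm
from . import gestures as G
from . import synthetic as syn
from .features import rms_windows


@dataclass
class RunConfig:
    """Configuration of a full synthetic study."""

    n_subjects: int = 20
    seed: int = 0
    factor_ranges: dict | None = None
    hold: float = 2.0
    rest: float = 1.0
    reps: int = 3
    rate: float = 1000.0
    window_ms: float = 200.0
    step_ms: float = 100.0
    ann_hyper: dict = field(default_factory=dict)
    n_out: int = 4
    gain: float = 20.0
    game_duration: float = 120.0
    game_tick: float = 0.1
    target_speed: float = 60.0
    d_th: float = 0.6
    prevalence_frac: float = 0.2
    bins: int = 36
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def classifier_emitter(model, features, state, encoding):
    """Game emitter backed by a trained classifier.

    For an intended gesture it draws one of the subject's held-out
    feature frames with that label, runs the network on it, and derives
    the effort from the frame's mean power — so the cursor is driven by
    what the interface would actually output for this subject.
    """
    frames_by_gesture = {}
    labels = np.asarray(features.labels)
    for g in G.ALL:
        idx = np.flatnonzero(labels == g)
        if idx.size:
            frames_by_gesture[g] = idx

    def emit(gesture: str, rng):
        idx = frames_by_gesture.get(gesture)
        if idx is None:
            return encoding.target(gesture)[:4], 1.0
        i = int(idx[rng.integers(idx.size)])
        q = clf.predict_ann(model, features.V[i])[:4]
        v = ctl.velocity(features.P[i], state)
        return q, v

    return emit


def analyze_subject(
    profile: syn.SubjectProfile,
    recs: dict,
    config: RunConfig,
    seed: int,
) -> dict:
    """All per-subject measurements of the study."""
    f_train = rms_windows(
        recs["train"], config.window_ms, config.step_ms, drop_transitions=True
    )
    f_test = rms_windows(
        recs["test"], config.window_ms, config.step_ms, drop_transitions=True
    )

    encoding = clf.directional_encoding(config.n_out)
    model, report = clf.train_ann(
        f_train, f_test, encoding, hyper=config.ann_hyper, seed=seed
    )
    e_ms = clf.ems(clf.predict_ann(model, f_test.V), encoding.matrix(f_test.labels))

    basic_tr = f_train.subset(np.isin(f_train.labels, G.BASIC))
    basic_te = f_test.subset(np.isin(f_test.labels, G.BASIC))
    ann_pred = clf.ann_argmax_label(model, basic_te.V, encoding)
    ann_f = ev.f_measure(ev.ConfusionCounts.from_labels(basic_te.labels, ann_pred))
    lda_model = clf.train_lda(basic_tr)
    lda_pred = clf.predict_lda(lda_model, basic_te.V)
    lda_f = ev.f_measure(ev.ConfusionCounts.from_labels(basic_te.labels, lda_pred))

    sac_report = coord.sac_from_features(f_test)

    rest_stream = f_test.subset(np.asarray(f_test.labels) == G.REST)
    state = ctl.calibrate(rest_stream, f_test, gain=config.gain)
    scenario = syn.GameScenario(
        duration=config.game_duration, speed=config.target_speed
    )
    emitter = classifier_emitter(model, f_test, state, encoding)
    trace = syn.simulate_game_trace(
        scenario,
        profile,
        emitter,
        seed=seed,
        gain=config.gain,
        tick_s=config.game_tick,
    )
    sparse = gm.downsample(trace)
    fidelity = gm.gesture_fidelity(sparse, config.d_th, config.prevalence_frac)

    return {
        "profile": profile,
        "model": model,
        "train_report": report,
        "e_ms": e_ms,
        "ann_f": ann_f,
        "lda_f": lda_f,
        "sac": sac_report.sac,
        "score": trace.score,
        "game_stats": fidelity,
        "trace": trace,
    }


@dataclass
class CohortResult:
    """Per-subject metrics and cohort-level regression summaries."""

    table: pd.DataFrame
    e_m: float
    regressions: dict
    seeds: dict

    def to_json(self) -> dict:
        return {
            "e_m": self.e_m,
            "regressions": {k: r.to_dict() for k, r in self.regressions.items()},
            "seeds": self.seeds,
            "subjects": self.table.to_dict(orient="records"),
        }


def run_synthetic_study(config: RunConfig) -> CohortResult:
    """Run the full pipeline on one simulated cohort."""
    if config.n_subjects < 3:
        raise ValueError("the study needs at least 3 subjects")
    cohort = syn.simulate_cohort(
        config.n_subjects,
        config.factor_ranges,
        seed=config.seed,
        hold=config.hold,
        rest=config.rest,
        reps=config.reps,
        rate=config.rate,
    )
    analysis_seeds = (
        np.random.SeedSequence(config.seed).generate_state(config.n_subjects, np.uint64)
        >> np.uint64(33)
    )

    rows = []
    per_subject = []
    for i, (profile, recs) in enumerate(cohort):
        res = analyze_subject(profile, recs, config, seed=int(analysis_seeds[i]))
        per_subject.append(res)
        rows.append(
            {
                "subject": i,
                "co_activation": profile.co_activation,
                "attenuation": profile.attenuation,
                "bf_index": profile.bf_index,
                "e_ms": res["e_ms"],
                "sac": res["sac"],
                "score": res["score"],
                "ann_pooled_f": res["ann_f"].pooled_f,
                "lda_pooled_f": res["lda_f"].pooled_f,
                "spread": res["game_stats"].spread,
                "peak_location": res["game_stats"].peak_location,
            }
        )
    table = pd.DataFrame(rows)
    table["re"] = ev.performance_index(table["e_ms"].to_numpy())
    e_m = float(np.median(table["e_ms"]))

    regressions = {
        "re_on_sac": ev.factor_regression(table["sac"], table["re"]),
        "re_on_bf": ev.factor_regression(table["bf_index"], table["re"]),
        "score_on_re": ev.factor_regression(table["re"], table["score"]),
    }
    result = CohortResult(
        table=table,
        e_m=e_m,
        regressions=regressions,
        seeds={"cohort_seed": config.seed},
    )

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "subjects.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(result.to_json(), fh, indent=2, default=float)
        with open(out / "report.txt", "w") as fh:
            fh.write(report(result, per_subject))
        config.to_yaml(out / "config.yaml")
    return result


def report(result: CohortResult, per_subject: list | None = None) -> str:
    """Human-readable study summary regenerable from the saved tables."""
    if result.table.empty:
        raise ValueError("cannot report on an empty cohort")
    lines = []
    lines.append("Synthetic sEMG-interface study")
    lines.append("=" * 40)
    lines.append(f"subjects: {len(result.table)}")
    for name, value in result.seeds.items():
        lines.append(f"seed {name}: {value}")
    lines.append(f"median E_MS (E_m): {result.e_m:.4f}")
    lines.append("")
    lines.append("Regressions (slope ± se, p):")
    for name, r in result.regressions.items():
        lines.append(
            f"  {name}: slope={r.slope:+.4f} ± {r.slope_se:.4f}, "
            f"intercept={r.intercept:+.4f}, p={r.p_value:.4g}, n={r.n}"
        )
    lines.append("")
    lines.append("Per-subject metrics:")
    lines.append(
        result.table.to_string(
            index=False, float_format=lambda v: f"{v:.4f}"
        )
    )
    if per_subject:
        lines.append("")
        lines.append("Per-gesture F-measure (ANN vs LDA), subject 0:")
        res = per_subject[0]
        for g in G.BASIC:
            fa = res["ann_f"].per_gesture.get(g, (None, None, None))[2]
            fl = res["lda_f"].per_gesture.get(g, (None, None, None))[2]
            fa = "n/a" if fa is None else f"{fa:.3f}"
            fl = "n/a" if fl is None else f"{fl:.3f}"
            lines.append(f"  {g}: ANN {fa}   LDA {fl}")
        lines.append("")
        lines.append("Optimal / incorrect gesture rates, subject 0:")
        for (d, k), v in res["game_stats"].rates.items():
            lines.append(f"  {d:>5} {k}: {v:.3f}")
    return "\n".join(lines) + "\n"
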