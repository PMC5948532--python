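# semgkit

Analysis toolkit for surface-EMG (sEMG) cursor interfaces: what limits
how well different people can drive a computer by hand gestures?

An eight-electrode bracelet on the forearm records muscle activity at
1 kHz; a classifier maps the windowed RMS pattern V(t) ∈ R⁸ to one of
nine hand states (rest, four wrist movements, four diagonal
combinations), and the mean signal power scales the cursor speed
(proportional control).  Mean recognition accuracy of such interfaces
is high, but performance varies enormously between users.  `semgkit`
implements the full analysis chain used to dissect that variance on
synthetic data — no human recordings are required:

* **synthetic** — a five-muscle forward model (flexor carpi radialis,
  extensor carpi radialis longus, extensor digitorum, extensor carpi
  ulnaris, flexor carpi ulnaris) mixing amplitude-modulated noise
  carriers onto eight electrodes, with per-subject latent factors:
  antagonist **co-activation** (poor muscle coordination) and signal
  **attenuation** (body-fat tissue between muscle and electrode, which
  lowers the signal-to-noise ratio); plus a pursuit-game simulator.
* **features** — sliding-window RMS, `V(t) = sqrt(1/N Σ x²)`, and mean
  power `P(t) = 1/(NK) Σ ||x||₁` (200 ms windows, 100 ms step).
* **classifiers** — a one-hidden-layer perceptron trained by
  backpropagation with a compound target encoding (basic gestures are
  one-hot on the left/right/up/down output neurons; diagonal gestures
  put ½ on their two parents) and early stopping on held-out error,
  plus an LDA baseline; the error measure is
  `E_MS = 1/(NM) Σ ||q − u||²`.
* **control** — cursor velocity `v = max(0, P/P_max − p_th)` with a
  rest-calibrated drift threshold, displacement
  `Δ = 20·v·(qr − ql, qu − qd)`.
* **evaluation** — precision/recall/F per gesture, the per-subject
  performance index `Re = ln(E_MS / median E_MS)`, and OLS regressions
  of Re (and the game score) on latent factors.
* **coordination** — ICA-based separation of the RMS envelopes into
  spatially localized muscle sources (loadings peak under electrodes
  2, 4, 5, 6, 8) and the **synergist–antagonist coefficient**
  `SAC = ln(¼ Σ_k S_k/A_k)`, where S_k and A_k sum the mean RMS of the
  two synergist and two antagonist electrodes of each basic gesture.
  SAC = 0 means synergists and antagonists fire equally; higher is
  better coordination, and a pure recording gain cancels out of it.
* **game** — decision quality in pursuit traces: the optimal
  interception direction n solves `||ω_p|| t* = ||d + ω_c t*||` for the
  earliest t* > 0; the signed angle α between the cursor velocity and n
  is summarized by circular statistics, and classifier outputs are
  classed optimal/incorrect by a cosine cone `(δ, n)/||δ|| > 0.6`
  (a 0.93 rad cone) and split into left/right/up/down rate sets.
* **pipeline** — an end-to-end synthetic study tying it all together.

## Worked example

A full 20-subject synthetic study from the command line:

```bash
semgkit study --n-subjects 20 --seed 0 --outdir study
```

prints

```
re_on_sac: slope=-1.5599 (p=4.737e-10)
re_on_bf: slope=+0.0200 (p=0.02616)
score_on_re: slope=-8.5217 (p=0.05637)
median E_MS = 0.0189; outputs in study
```

Reading: the classification-error index Re falls steeply with the
synergist–antagonist coefficient (better-coordinated subjects have
cleaner sEMG patterns and lower error), rises with the body-fat index
(tissue attenuation lowers SNR), and subjects with higher Re catch
fewer targets in the game.  The cohort's median E_MS of 0.019 means
the typical network output is within ~0.14 of its target per neuron.
`study/subjects.csv` holds the per-subject table, `study/summary.json`
the regression summaries, `study/report.txt` a readable report.

The same steps are available as library calls and as individual CLI
verbs (`simulate`, `extract`, `train`, `evaluate`, `sac`,
`game-analyze`):

```bash
semgkit simulate --seed 3 --out rec.csv          # one subject, all gestures
semgkit extract --recording rec.csv --out feat.csv
semgkit sac --features feat.csv --report sac.json
# -> SAC = 1.4920  (strong synergist dominance: a clean subject)
semgkit train --features feat.csv --test feat.csv --model model.json
# -> trained 5000 epochs (best test E_MS 0.0079)
```

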