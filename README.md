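# devconn

Directed functional-connectivity analysis for developing
entorhinal–hippocampal–prefrontal (LEC–HP–PFC) circuits.

Neonatal cortical activity is discontinuous: spindle-shaped theta–beta
oscillations (4–30 Hz) ride on a continuous 2–4 Hz slow rhythm, and the
question of *who drives whom* — does the lateral entorhinal cortex boost the
hippocampus, which in turn entrains the prefrontal cortex? — has to be
answered from multichannel LFP and spiking data with estimators that are
robust to volume conduction and to the discontinuity of the signal.
`devconn` implements that full chain for electrophysiologists working with
developmental (or any event-structured) recordings:

* unsupervised **spindle-burst detection** from the RMS envelope of the
  3–100 Hz band (Gaussian fit to the RMS histogram body, variance-dependent
  threshold, > 1 s duration floor);
* **event-based Welch spectra** with baseline normalization `P(f)/P0(f)`;
* **magnitude and imaginary coherence** over co-occurring one-second
  oscillatory epochs, with an epoch-shuffling surrogate floor —
  the imaginary part is blind to instantaneous (volume-conducted) mixing;
* **generalized partial directed coherence (gPDC)** from MVAR models fit to
  the epochs,

      gPDC_{i←j}(f) = (|Ā_ij(f)|/σ_i) / sqrt(Σ_k |Ā_kj(f)|²/σ_k²),
      Ā(f) = I − Σ_r A_r e^{−2πifr/fs},

  band-averaged per ordered region pair, with the column normalization
  Σ_i gPDC² = 1 asserted on every call;
* **optogenetic read-outs**: firing probability (spikes in the 20 ms
  post-pulse window / pulse count), PSTHs, a permutation-tested modulation
  index, stimulus-locked LFP amplitude, laminar current source density,
  ramp/train power- and coherence-change metrics, and eEPSC feature
  extraction (amplitude, 10 pA/ms onset, 20–80 % rise time, CV);
* the study-style **statistics**: Wilcoxon rank-sum (ranksum/z/p
  reporting), one-way ANOVA, paired t, Yates-corrected chi-square for two
  proportions, discrimination-index scoring with the < 20 cm/min exclusion
  rule;
* a **synthetic-data generator** with exact ground truth (latent MVAR with
  known directed gains, gated bursts, 1/f + slow-rhythm background, laminar
  dipole geometry, phase-coupled and light-responsive spike trains, behavior
  tables) so every stage has a recovery test — including a control vs. "GE"
  (dual-hit risk model) contrast with reduced LEC→HP gain, burst power and
  responder fraction.

See `docs/methods.md` for the model, estimator conventions, and the
construction every test tolerance derives from.

## Worked example

Simulate two minutes of the control condition, detect bursts, and estimate
the directed coupling:

```python
from devconn import SimConfig
from devconn.synthetic import simulate_lfp
from devconn.events import detect_oscillations, score_detection
from devconn.connectivity import gpdc_pipeline

cfg = SimConfig(duration_s=120.0)
rec, truth, model = simulate_lfp(cfg, rng=1)     # ground truth returned
det = detect_oscillations(rec)
score = score_detection(det, truth)
print(f"events: {len(det.channel(0))} detected / {len(truth.channel(0))} true "
      f"(recall {score['recall']:.2f}, precision {score['precision']:.2f})")
_, table = gpdc_pipeline(rec, det, order=model.order)
print(table.round(3).to_string(index=False))
```

prints

```
events: 10 detected / 10 true (recall 1.00, precision 1.00)
source target  gpdc
   LEC     HP 0.443
   LEC    PFC 0.117
    HP    LEC 0.089
    HP    PFC 0.368
   PFC    LEC 0.054
   PFC     HP 0.085
```

The detector recovered every true burst, and the estimated information flow
reproduces the seeded hierarchy: strong LEC→HP drive, moderate HP→PFC,
weak direct LEC→PFC, and near-floor values in the reverse directions (the
generating gains were 0.35 / 0.25 / 0.08 / 0).

The same pipeline is scriptable from the shell:

```bash
devconn run --config demo.yaml --seed 5 --out results/
devconn simulate --seed 3 --out sim/          # one synthetic recording
devconn detect-events --in sim/recording.h5 --out sim/events.csv
devconn gpdc --in sim/recording.h5 --events sim/events.csv --out sim/gpdc.csv
```

`run` writes a CON-vs-GE gPDC contrast table, power summaries, behavior
scores and a JSON manifest with the fanned-out per-stage seeds; reruns with
the same configuration are byte-identical.

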