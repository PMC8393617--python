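# capdet

Automated detection of **cyclic alternating pattern (CAP)** phases in sleep
EEG.

CAP is a recurring NREM-sleep EEG pattern: short periods of cerebral
activation (**phase A** — K-complexes, delta bursts, arousals, 2–60 s)
alternating with the intervening background (**phase B**).  The CAP rate
(CAP time / NREM time) is a marker of sleep instability and rises in many
sleep disorders, but manual CAP scoring is slow and error-prone.  `capdet`
is for sleep researchers and biomedical-signal engineers who want a
reproducible, fully scriptable phase A/B detector and CAP-rule engine that
runs end-to-end on EDF recordings or on its built-in synthetic generator.

## Method

1. **Preprocessing** — each EEG channel (typically C4-A1 and F4-C4) is
   bandpass filtered (0.5–35 Hz Butterworth, order 4, zero-phase), min-max
   normalized to [0, 1] per recording, and resampled to a 64 Hz analysis
   rate.
2. **Optimal wavelet filter bank** — an orthogonal lowpass
   *h*[0..*L*−1] is designed to minimize the mean-squared (RMS) bandwidth

   B² = (1/2π) ∫ ω² |H(ω)|² dω = (π²/3) r[0] + 4 Σ_{k≥1} (−1)^k r[k]/k²,

   a linear functional of the autocorrelation *r*.  The minimization over
   the convex set of orthogonal autocorrelations with *p* vanishing moments
   (a zero of order 2*p* of R(ω) = |H(ω)|² at ω = π) and R(ω) ≥ 0 is solved
   as a linear program; minimum-phase spectral factorization recovers *h*,
   and the conjugate-quadrature rule g[n] = (−1)^n h[L−1−n] gives the
   highpass.  The production bank uses L = 12, p = 4 and reaches
   B² = 0.8679, below the 0.9056 of the Daubechies length-12 filter.
3. **Features** — a 5-level decomposition yields six subbands
   (0–1, 1–2, 2–4, 4–8, 8–16, 16–32 Hz); per subband, wavelet entropy
   −Σ|cᵢ|log|cᵢ| and the three Hjorth parameters (activity σ²(x),
   mobility σ(x′)/σ(x), complexity μ(x′)/μ(x)) give 24 features per
   channel, 48 for two channels, rankable by the Kruskal–Wallis H test.
4. **CAP rules** — Terzano logic: phase-A events closer than 2 s merge,
   phase durations must lie in [2, 60] s, >60 s without CAP terminates a
   sequence, and a CAP sequence needs at least three A phases (A–B–A–B–A);
   CAP rate = CAP time / NREM time.
5. **Classification** — balanced epochs (random undersampling), ensembles
   of bagged or boosted decision trees (plus SVM, kNN, logistic, single
   tree), sample-wise stratified 10-fold cross-validation, metrics from the
   pooled confusion matrix: ACA, precision, recall, F1, Cohen's κ, AUC.

## Worked example

```python
import numpy as np
from capdet import design_omsbm_filter, compute_rms_bandwidth
from capdet.pipeline import PipelineConfig, run_pipeline

fb = design_omsbm_filter(L=12, p=4, levels=5)
print("lowpass h:", np.round(fb.h, 4))
print("vanishing moments:", fb.vanishing_moments)
print("RMS bandwidth B^2: %.5f" % compute_rms_bandwidth(fb.h).b_sq)

cfg = PipelineConfig(
    synthetic={"amp_ratio": 5.0, "n_epochs": 500},
    balance_seed=1, cv_seed=2, model_seed=3, synth_seed=4,
)
metrics, report = run_pipeline(cfg)
print("ACA = %.2f%%  kappa = %.2f  AUC = %.3f" % (metrics.aca, metrics.kappa, metrics.auc))
print("confusion (counts):", metrics.confusion.tolist())
```

prints

```
lowpass h: [-0.0064  0.0198  0.0057 -0.0757  0.038   0.1356 -0.0982 -0.238   0.1207
  0.6559  0.6473  0.2095]
vanishing moments: 4
RMS bandwidth B^2: 0.86785
ACA = 99.80%  kappa = 1.00  AUC = 1.000
confusion (counts): [[498, 0], [2, 500]]
```

The filter satisfies every orthogonality invariant to machine precision and
carries exactly four vanishing moments.  On the synthetic "separable"
preset (phase-A delta bursts at five times the background RMS, 500 epochs
per class) the full pipeline separates the phases almost perfectly; with
`amp_ratio=1.0` the two classes are generated from the identical law and
accuracy drops to chance, as it should.

The same pipeline is available from the shell:

```sh
capdet design-filter --length 12 --vm 4 --out omsbm12.txt
capdet simulate --preset separable --n 12 --seed 7 --out-edf s.edf --out-ann s.tsv
capdet segment --edf s.edf --ann s.tsv --epoch-len 2 --seed 42 --out epochs.npz
capdet features --epochs epochs.npz --filter omsbm12.txt --out features.csv
capdet evaluate --features features.csv --classifier bagged_trees --report report.json
```

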