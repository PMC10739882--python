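# asymrpe

Analysis pipeline for **asymmetric reward-prediction-error (RPE) coding
in intracranial high-frequency activity (HFA)**, exercised end-to-end on
synthetic cohorts with known ground truth.

The scientific question: when feedback arrives, do neural populations in
the salience network (dorsomedial prefrontal cortex, dMPFC, and insula,
INS) encode the *value* of the surprise (signed RPE), its *salience*
(unsigned magnitude), or positive and negative surprises **separately
and asymmetrically**? The package implements the full analysis chain
needed to ask this of feedback-locked iEEG data, and a synthetic-data
generator that lets every stage be validated against ground truth:

1. **Task simulation** (`asymrpe.task`) — an interval-timing task whose
   error tolerance *t* is driven by dual asymmetric staircases (easy:
   −3/+12 ms after wins/losses; hard: −12/+3 ms; tolerance clamped to
   15–200 ms), clamping accuracy near `up/(up+down)` = 80% / 20%.
2. **Trial-level RPEs** (`asymrpe.rl`) — per-participant logistic value
   model `p_win = 1/(1+e^{−(β₀+β₁ t)})`, expected value
   `EV = 2·p_win − 1`, and the decomposition `sRPE = reward − EV`,
   `pRPE = max(sRPE, 0)`, `nRPE = max(−sRPE, 0)`, `uRPE = |sRPE|`.
3. **RT adaptation** (`asymrpe.behavior`, `asymrpe.lmm`) — a hierarchical
   ladder of linear mixed models for trial-to-trial RT change
   (`rt_change ~ prev_rt * outcome + pRPE + nRPE + (1 + prev_rt | subject)`
   at the top), compared by likelihood-ratio tests and AIC.
4. **HFA extraction** (`asymrpe.hfa`) — multitaper 70–150 Hz sub-band log
   power, bootstrap baseline z-scoring against pre-stimulus data, and
   50 ms sliding windows (25 ms step) over 0–0.6 s post-feedback.
5. **Encoding models** (`asymrpe.encoding`) — per window and region,
   mixed models `HFA ~ nRPE + pRPE + EV` (vs value and salience
   variants) with subject and channel-within-subject random effects;
   AIC model comparison, FDR across windows, channel-level conditional
   coefficients, and four-category channel classification
   (pRPE / nRPE / sRPE / uRPE, regular or inverted polarity).
6. **Directed connectivity** (`asymrpe.connectivity`) — per-trial lagged
   cross-correlation between INS and dMPFC channels (±400 ms, 25 ms
   steps; positive lag = INS leads), per-lag mixed models of the RPE
   modulation, peak-lag extraction, and pair categorization.
7. **Synthetic cohorts** (`asymrpe.synth`) — behavioral agents with
   planted RPE-dependent RT effects, channels with ground-truth coding
   categories and gains, raw broadband rendering, and lag-coupled
   channel pairs with RPE-modulated coupling.

`docs/methods.md` describes the models, generator assumptions and
numerical choices in detail.

## Worked example

`examples/behavioral_adaptation.py` simulates six agents on the
staircased task with a planted post-positive-RPE slowing of 0.02 s per
unit pRPE, derives RPEs through the fitted value model, and runs the
model ladder:

```
Model comparison (each model vs its designated null):
model null  df     chi2      p
   b1   b0   3 804.9632 0.0000
   b2   b1   1  22.6511 0.0000
   b3   b2   1   0.1700 0.6801
   b4   b3   1  18.8173 0.0000
   b5   b3   1   8.8400 0.0029
   b6   b3   2  24.7761 0.0000

Asymmetric-RPE model coefficients (excerpt):
prev_rt     -0.7181  (p < 1e-4)
prev_prpe    0.0192  (p < 1e-4)
prev_nrpe   -0.0047  (p = 0.29)
```

Read: RTs revert strongly toward the target (previous-RT slope ≈ −0.72);
the asymmetric-RPE model beats the null (χ²(2) = 24.8) and has the
lowest AIC; the pRPE coefficient recovers the planted 0.02 s slowing
while the nRPE coefficient stays at zero — behavioral adaptation follows
positive, not negative, surprises, which is the behavioral signature the
neural analyses then look for in HFA.

The other examples cover the spectral pipeline
(`examples/hfa_extraction.py`), encoding-model comparison and channel
classification (`examples/encoding_channels.py`), and directed
connectivity with a planted +75 ms INS-leading coupling
(`examples/directed_connectivity.py`).

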