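# attnrhythm

Tracking the locus and strength of covert spatial attention from
multichannel neurophysiological recordings — and testing whether
attention samples multiple stimuli rhythmically.

When people weigh three peripheral stimuli without moving their eyes,
where is their attention from moment to moment?  This package
reimplements, as a tested pipeline over synthetic ground-truth data,
an analysis chain that answers that question at the single-sample
level:

1. **Inverted encoding model (IEM).**  Sensor activity is modelled as a
   weighted sum of three angular information channels (targets at 0°,
   120°, 240°; tuning curves `f = |cos⁵(0.5(θ−μ)π/180)|`).  Weights
   `w_k = X c_kᵀ(c_k c_kᵀ)⁻¹` are fit on single-stimulus localizer
   epochs, pre-whitened with shrinkage-regularized residual covariance
   (`g_k = E_k⁻¹w_k(w_kᵀE_k⁻¹w_k)⁻¹`, so `g_kᵀw_k = 1`), and inverted
   on decision epochs: `C = GᵀX`.
2. **Attentional vector.**  The three channel responses are summed as
   planar vectors: length = attention strength, angle = attended locus,
   and the maximum angular similarity (MAS) to the three targets
   indexes selectivity (minimum 0.5, exactly midway between targets).
3. **Rhythm.**  Band-limited strength fluctuations via a quarter-octave
   Butterworth + Hilbert filterbank (2.8–90.5 Hz), dB-normalized to the
   pre-stimulus baseline.
4. **Attentional events.**  Samples where MAS and length both exceed
   their 90th percentiles mark discrete "attentional saccades", labelled
   stay/switch by the locus sequence.  Inter-event-interval histograms
   against trial-shuffle nulls expose the sampling rhythm: mode spacing
   estimates the cycle length, switches sit half a cycle before stays.
5. **Oculomotor coupling.**  (Micro)saccades detected by a 6×-median
   velocity threshold are aligned to attentional events, recovering
   planted saccade-before-switch coupling.

A synthetic-session generator (`attnrhythm.synth`) plants a known
~11 Hz attentional process, forward model, and gaze behaviour, so every
stage is validated by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run one full synthetic session
(150 decision trials, 24 sensors, snr 1, 11 Hz planted rhythm with a
0.37 switch fraction) and write their tables under `results/`:

```bash
python analysis/01_simulate_session.py
python analysis/02_train_encoder.py
python analysis/03_decode_attention.py
python analysis/04_attention_spectra.py
python analysis/05_attentional_events.py
python analysis/06_perievent_and_oculomotor.py
```

Selected output from one run:

```
Selected training window: 0.140-0.170 s (held-out score 0.959)
g'w per channel: [1. 1. 1.]  (identity holds)
Band-limited attention-strength increase peaks at 11.31 Hz (+2.49 dB vs pre-stimulus baseline)
Detected 2597 attentional events (1313 stay / 1134 switch / 150 first-in-trial)
  stay: modes at 94 ms, 183 ms, 276 ms; cycle length 0.0889 s
  switch: modes at 47 ms, 137 ms, 231 ms; cycle length 0.0902 s
  second-order first-mode offset (stay-after-stay vs stay-after-switch, planted events): 0.0 ms (history invariant — reset regime)
  saccade-rate change peaks -0.155 s around switch events (planted coupling: -0.150 s before switches)
```

Reading it: cross-validation finds the planted 140–170 ms response
latency; the strength spectrum peaks at the filterbank center nearest
the planted 11 Hz; the stay-interval histogram shows modes one cycle
(~91 ms) apart while the first switch mode sits at roughly half a
cycle (~46 ms) — switches and stays lock to opposite phases of the
attentional rhythm; the second-order analysis identifies the planted
phase-reset regime; and the saccade-rate peak recovers the planted
0.15 s saccade-to-switch lead.

## Layout

```
src/attnrhythm/     library: design, synth, encoding, attention,
                    spectral, events, perievent, oculomotor, stats, io
analysis/           numbered drivers for the synthetic-session analysis
tests/              pytest suite incl. end-to-end acceptance checks
docs/methods.md     model, parameters, numerical choices, limitations
```
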