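# qeeg-mcao

Quantitative EEG (qEEG) analysis of continuous single-channel ECoG for
experimental cerebral **ischemia–reperfusion** monitoring, in the rodent
middle-cerebral-artery-occlusion (MCAO) model: relative band-power
decomposition, the DTR/DAR/DTABR stroke indices with published ischemia
thresholds, the study-level statistical battery, infarct-area
quantification from histology masks — and a calibrated synthetic-cohort
generator so the whole pipeline can be exercised and validated without
animal recordings.

Intended users: electrophysiologists and translational-stroke researchers
who want a tested, scriptable qEEG index pipeline, and methods developers
who need a ground-truth-bearing synthetic ECoG cohort.

## The quantities

A session `x(t)` (1 kHz, 5–10 min) is high-pass filtered at 0.3 Hz,
cut into 30 s epochs, amplitude-screened (±500 µV), and its one-sided
power spectral density `P(f)` estimated by Welch's method (Hann window,
16 s segments, 50% overlap). With band power
`S_B = ∫_B P(f) df` over the half-open bands
δ = [1, 4), θ = [4, 8), α = [8, 12), β = [12, 28) Hz and reference
R = [1, 40) Hz, the relative band power is `S_B / S_R` and the stroke
indices are

```
DTR   = S_δ / S_θ
DAR   = S_δ / S_α
DTABR = (S_δ + S_θ) / (S_α + S_β)
```

A session is classified ischemic when `DAR > 3.7` or `DTABR > 3.5`
(strict exceedance; both thresholds from the acute-stroke qEEG
literature). Infarct extent is quantified from binary masks as
`PIA = 100 · lesion px / ipsilateral-hemisphere px`.

Synthetic sessions are sums of independent band-limited Gaussian noises
whose per-band variances realize a target fraction vector; acute-phase
targets are obtained by *inverting* published index triples into band
fractions, so the generator's ground truth is exactly the published
operating points and the pipeline's job is to recover them.

## Worked example

```python
import numpy as np
from qeeg_mcao import (analyze_recording, generate_recording, phase_presets,
                       percent_infarct_area, generate_lesion_mask)

# one 5-min ischemic-phase session, jitter-free, at the published operating point
preset = phase_presets(jitter_sigma=0.0)["isp"]
rec = generate_recording(preset, duration_s=300, rate_hz=1000, seed=1)
bp, qi, ps = analyze_recording(rec)
print("relative band power:", {b: round(v, 3) for b, v in bp.relative.items()})
print(f"DTR = {qi.dtr:.2f}  DAR = {qi.dar:.2f}  DTABR = {qi.dtabr:.2f}")
print(f"DAR > 3.7  -> ischemic: {qi.dar_ischemic}")
print(f"DTABR > 3.5 -> ischemic: {qi.dtabr_ischemic}")

masks = generate_lesion_mask((200, 200), target_pia=46.22, seed=1)
print(f"PIA = {percent_infarct_area(masks):.2f}%")
```

prints

```
relative band power: {'delta': 0.681, 'theta': 0.171, 'alpha': 0.053, 'beta': 0.046, 'residual': 0.05}
DTR = 3.99  DAR = 12.89  DTABR = 8.63
DAR > 3.7  -> ischemic: True
DTABR > 3.5 -> ischemic: True
PIA = 46.22%
```

The generator was calibrated to the ischemic-phase index triple
(DTR, DAR, DTABR) = (4.20, 13.07, 8.68); the pipeline recovers it from a
single 5-minute realization to within a few percent (delta-dominant
spectrum, fraction 0.68), and both exceedance rules fire, as they should
during occlusion. The mask example reproduces the percentage-infarct
formula on a synthetic lesion grown to 46.22% of an elliptical
hemisphere.

## Command line

```sh
qeeg-mcao run-all --seed 42 --out results/       # simulate + analyze + report
qeeg-mcao simulate --config cfg.toml --seed 42   # cohort + manifest only
qeeg-mcao analyze  --manifest results/manifest.csv --out results/
qeeg-mcao report   --out results/
qeeg-mcao selftest                               # reduced-scale end-to-end check
```

The default design is 2 groups (sham, occluded) × 6 animals × 11 phases
(awake baseline, anesthetized, ischemic phase, immediate reperfusion,
days 1–7). Outputs are CSV tables (band power, indices, per-phase
frequency distributions, mean ± SD summaries with Tukey letters, ANOVA
and Tukey families) plus a plain-text report; everything is
byte-reproducible from the seed.

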