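# Methods

This note records the models, estimator choices and numerical decisions
behind `qeeg_mcao`, and what the synthetic validation does and does not
establish about real recordings.

## Signal model and preprocessing

The unit of analysis is a single-channel ECoG session: a uniformly
sampled voltage trace (µV) at 1 kHz, 5 or 10 minutes long, labeled with
an animal, a group (sham / occluded) and a study phase (awake baseline,
anesthetized baseline, ischemic stroke phase ISP, immediate reperfusion
phase IRP, or post-occlusion days 1–7).

Preprocessing replicates a standard acquisition front end digitally:

* **High-pass, 0.3 Hz** — 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`), so the filter is zero-phase and band
  powers are unaffected by phase distortion. Edges are padded
  reflectively over three filter time constants (≈1.6 s at 0.3 Hz/1 kHz)
  to keep the DC step at the boundaries from ringing inward.
* **Epoching, 30 s** — non-overlapping windows, trailing remainder
  dropped; ten epochs per 5-minute session. Epochs are an internal unit:
  long enough for spectral averaging, short enough to isolate artifacts.
* **Artifact rejection, ±500 µV** — an epoch containing any sample
  beyond the threshold is excluded whole. 500 µV is a conventional
  rodent-ECoG artifact bound; it is configurable, and rejection only
  ever touches the keep-mask, never sample values. No notch filter is
  applied: mains frequencies lie above the 40 Hz analysis ceiling.

## Spectral estimation

Welch's method, Hann window, **16 s segments** (0.0625 Hz resolution),
50% overlap, averaged over all kept epochs. The segment length matters
more here than in generic EEG work: ischemic spectra have a large
density step at the 4 Hz delta/theta edge (delta density is roughly
15× theta density at the ischemic operating point), and the Hann
kernel smears each bin over its neighbours. At 0.5 Hz resolution that
smearing moves ≈0.07 of total power out of delta, biasing the
delta/alpha ratio by about −20%; at 0.0625 Hz the bias falls to a few
percent, well inside the inter-animal variability the indices are used
against. The resolution floor (≤ 0.5 Hz, i.e. segments ≥ 2 s) is
enforced as a precondition because coarser grids cannot even resolve
the 1 Hz band edge.

Band power integrates the one-sided density over half-open bands
[lo, hi), so adjacent bands never double-count a bin and the five
component bands (delta, theta, alpha, beta, plus the 28–40 Hz
*residual*) sum exactly to the 1–40 Hz reference power. Relative power
is normalized by the reference-band total; whether the original
analysis normalized by 1–40 or 1–28 Hz is not determinable, but the
choice rescales all fractions by a common factor and therefore cancels
out of every index. Parseval consistency (integrated PSD within 5% of
signal variance) is property-tested.

Analysis is session-level: one PSD, one band-power set and one index
triple per animal per phase; cohort statistics are computed across
animals (mean of ratios, not ratio of means — the alternative
aggregation is a one-line change where group band-power tables are
available).

## Indices and classification

DTR = δ/θ, DAR = δ/α, DTABR = (δ+θ)/(α+β). Classification uses strict
exceedance of DAR > 3.7 and DTABR > 3.5, the published acute-ischemia
discrimination thresholds; a value exactly at a threshold is *not*
flagged. Note that the anesthetized control operating point itself has
DAR 6.45 > 3.7 — ketamine/xylazine anesthesia is delta-dominant — so
threshold crossings are reported without clinical interpretation; the
discriminating contrast in this design is ischemia vs reperfusion, not
vs an awake norm.

## Synthetic cohorts

Each session is synthesized as

x(t) = √P_tot · Σ_b √f_b · u_b(t)

where f is the band-fraction vector (five components summing to 1),
P_tot the target variance (µV²), and each u_b unit-variance Gaussian
noise band-limited **exactly** to its band by spectral masking: white
noise is Fourier-transformed, coefficients outside [lo, hi) are zeroed,
and the inverse transform is rescaled to unit empirical variance. Only
second-order structure matters to the analysis, so a Gaussian band
mixture is the simplest model the pipeline must invert. IIR band-pass
synthesis (Butterworth, forward–backward) was evaluated for this role
and rejected: its roll-off leaks enough cross-band power to bias
recovered DAR by −12…−16% regardless of estimator resolution, which
would swamp the calibration the generator exists to provide.

**Calibration.** The acute presets (anesthetized, ISP, IRP) invert the
published index triples into fractions: setting α' = 1, δ' = DAR,
θ' = DAR/DTR, β' = (δ'+θ')/DTABR − 1 and rescaling the four to sum to
1 − residual. The inversion→recomputation round trip is an exact
algebraic identity for any feasible triple (β' > 0). The residual
(28–40 Hz) fraction is fixed at 0.05: the published record gives no
high-band content, and a small non-zero value keeps the reference band
honest. Total powers (2000 µV² anesthetized, 2500 ISP, 4000 IRP — the
reperfusion doubling is reported only qualitatively) set realistic
amplitude scale and cancel out of all relative quantities.

**Subacute presets (days 1–7) and the awake baseline are qualitative.**
They encode reported directions only: every component fraction below
the awake control's (the freed probability mass sits in the residual
band), theta elevated on days 3–4, alpha on days 4/6/7, DTABR peaking
on day 3, and globally suppressed total power. They are excluded from
numeric validation targets.

**Variability and seeding.** Inter-animal variability multiplies each
fraction by LogNormal(0, σ = 0.10) and renormalizes — producing
index spreads of the same order as the published SDs without claiming
to match them. Every animal × phase session draws from an independent
substream spawned from the design seed via `SeedSequence(seed,
spawn_key=(group, animal, phase))`, so cohorts are byte-reproducible
and order-independent. Sham animals realize the anesthetized (control)
profile in every phase.

**What passing tests show.** Recovery tests demonstrate that the
pipeline correctly inverts band-power signatures of stationary Gaussian
band mixtures at the published operating points, and that the
classification rules behave as published *under those spectra*. Real
ECoG is nonstationary within sessions, has 1/f background, oscillatory
peaks, and artifacts with spectral (not just amplitude) signatures —
none of which the generator emulates. Passing therefore validates the
computational chain, not the biology.

## I/O formats

EDF (16-bit, single signal, 1 s records, physical dimension µV,
group/phase/animal in the recording-identification field) and delimited
CSV (`time_s,voltage_uV`, full float precision). The EDF codec is a
minimal single-channel implementation of the fixed-layout header; its
output is cross-checked in the tests against an independent EDF reader.
EDF export requires an integer sampling rate and whole seconds (the
format stores integer samples-per-record); all study sessions satisfy
this and other traces belong in the delimited format. Writer physical
min/max are re-parsed from their 8-character header fields before
quantization so a write→read round trip is consistent to within half a
digital step. Files carry fixed epoch dates and no timestamps:
output trees are byte-identical across reruns of one seed.

## Statistics

* **Normality**: Kolmogorov–Smirnov statistic against a normal with
  mean/SD estimated from the sample; since estimated parameters shrink
  the null distribution, the p-value is calibrated by Monte-Carlo
  simulation (Lilliefors construction; 10 000 standard-normal replicates
  of the same n, fixed internal seed so the calibration is part of the
  method, not of the caller's RNG).
* **Two groups**: pooled-variance Student's t (not Welch's t, matching
  the source battery). Zero pooled variance with equal means returns
  (t = 0, p = 1); with unequal means it is an error.
* **One-way ANOVA**: explicit between/within sums of squares; p from
  the F distribution. **Two-way ANOVA**: balanced fixed-effects
  decomposition with interaction; unbalanced designs are rejected
  rather than silently approximated (the published design is balanced,
  n = 6 per cell).
* **Tukey HSD**: Tukey–Kramer q with harmonic pair n, adjusted p from
  `scipy.stats.studentized_range` (2-D numerical integration) with the
  ANOVA's within-group df. The q statistics are exposed separately from
  the p integral because comparisons against a single critical value
  (e.g. error-rate calibration over thousands of null replicates) do
  not need per-pair p's, which are expensive to integrate.
* **Letters**: compact letter display by greedy clique cover of the
  non-significance graph in label order, with back-absorption of earlier
  compatible groups (so a chain A≈B, B≈C, A≠C renders a / ab / b).
  Groups sharing no letter differ significantly; the cover is not
  guaranteed globally minimal for adversarial graphs, which matches the
  convention's usual implementations.
* Calibration (type-I error 0.05 ± 0.01 for ANOVA over 5000 null
  replicates; Tukey family-wise error ≤ 0.06) is asserted in the test
  suite.
* The subacute comparison is run as a one-way ANOVA over 8 groups per
  band (pooled sham control plus days 1–7 of the occluded group). The
  published degrees of freedom for this phase are not reconstructible
  with certainty from the record, so the layout is a package choice and
  is reported with its own df.

## Infarct quantification

PIA = 100 × lesion px / hemisphere px on binary masks; pixel scale
cancels. Histology segmentation is out of scope — masks are the input
contract (8-bit PNG or 0/1 text grids). The synthetic mask generator
grows a lesion from a random interior point of an elliptical hemisphere
by morphological dilation clipped to the hemisphere, trimming the final
ring in raster order so the lesion hits the rounded pixel target
exactly; percentage error vs the requested target is bounded by half a
pixel's share.

## Problem sizes and determinism

Validation runs use the study's native session scale: 5-minute, 1 kHz
sessions; six-session jitter-free cohorts for the calibration-recovery
checks; 200 jittered sessions for the classification-sensitivity check;
5000 replicates for statistical calibration. End-to-end pipeline
determinism is asserted on a reduced cohort (2 animals/group, 3 phases,
250 Hz) since byte-identity is scale-independent, while the CLI default
remains the full 132-recording design. All randomness flows from
explicit seeds through NumPy `SeedSequence` spawning.

## Known limitations

* The generator's stationary Gaussian band mixture omits 1/f structure,
  oscillatory peaks, nonstationarity and realistic artifacts.
* Subacute presets are directional, not quantitative.
* Single channel only; no montage support, no event annotations in EDF.
* The statistical layer implements the source battery (KS, t, ANOVA,
  Tukey); it does not provide repeated-measures or non-parametric
  alternatives, which a longitudinal day-1…7 design could arguably
  prefer.
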