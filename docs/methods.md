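# Methods

This note records the models implemented in `cerauto`, the conventions and
tunable parameters that matter, what the synthetic generator does and does
not emulate, and the numerical choices made where the field's conventions
leave room.

## Signals and preprocessing

All waveform channels live on a common 200 Hz grid. Artifact repair follows
a derivative rule: within a 10-s sliding evaluation window, samples whose
absolute first difference exceeds twice the window's difference SD are
replaced by linear interpolation between the nearest clean neighbours. A
constant signal (zero difference SD) is returned unchanged. The rule is
deliberately simple and over-flags heavy-tailed noise (about 4–5% of samples
of pure Gaussian noise exceed 2 SD); on waveform data this acts as mild
smoothing of extreme excursions. Idempotence holds for isolated-spike
contamination, which is the regime the rule targets.

Systolic peaks are local maxima of the ABP waveform found with a prominence
gate (25% of the signal range) and a 0.25-s refractory period — enough
headroom for 240 beats/min against the 140 beats/min ceiling of the
heart-rate band. R peaks are picked the same way on an 8–20 Hz second-order
Butterworth band-passed ECG; the filter is applied forward–backward
(zero-phase) so R-wave latency is not biased, at the cost of doubling the
effective order. RR intervals for HRV are ECG-derived; pulse intervals for
xBRS and joint symbolic dynamics are ABP-derived (systolic-peak
differences), with both anchor conventions exposed (interval start vs end).

Beat averaging computes per-beat means on half-open intervals
[beat_i, beat_{i+1}) and anchors each mean at the interval midpoint before
cubic-spline interpolation to a uniform 4 Hz grid. Midpoint anchoring makes
the operation exact on linear trends (a start-anchored mean of a ramp is
biased by slope·Δ/2) and affine-equivariant; since both TFA channels are
anchored identically, the choice does not affect cross-spectral phase.

Whole-epoch heart rate is the amplitude-spectrum maximum of the ABP signal
restricted to 0.67–2.33 Hz (40–140 beats/min); a maximum within 2% of the
band width from either edge sets a warning flag, since the true fundamental
likely lies outside the band. Respiratory rate is 60·(n−1)/span over
detected capnogram plateau cycles; the paced-protocol compliance gate
accepts |rate − target| ≤ 1 breath/min.

## Transfer function analysis

The pressure–flow relationship is modelled as a linear transfer function on
the 4 Hz beat-averaged series. Means are subtracted; no detrending. Welch
segments use a Hanning window and 50% overlap. The nominal 102.4-s window is
409.6 samples at 4 Hz, which is not an integer; the implementation uses 410
samples (102.5 s), frequency resolution ≈ 0.00976 Hz, and documents this
one-sample discrepancy rather than hiding it. A 5-min epoch yields L = 4
windows.

Phase sign convention: positive = CBv leads ABP, reported in degrees on the
principal value (−180°, 180°]; gain is |S_xy|/S_xx ≥ 0. Band averages are
unweighted arithmetic means over bins whose centres lie in the closed band,
after two exclusions: (i) bins with magnitude-squared coherence below the
95% confidence limit 1 − α^{1/(L−1)} with α = 0.05 and L the nominal segment
count (overlap-induced dependence between segments is ignored; the formula
is cross-checked against a Monte-Carlo oracle with independent windows, for
which it is exact); (ii) negative-phase bins below 0.1 Hz, removed — not
rectified — to avoid phase wrapping. A numerical tolerance of 1e-9° keeps
identically-zero phases (identity systems) in the average. A band in which
every bin is excluded reports NaN metrics with `n_bins_used = 0`.

Bands: VLF 0.02–0.07 Hz; breathing-frequency bands centred at 0.10, 0.17,
0.25 Hz ± 0.02 Hz for paced 6/10/15 breaths/min; for spontaneous breathing,
mean respiratory rate ± SD (in Hz), widened to a minimum 0.04 Hz width so a
near-zero rate SD cannot produce an empty band.

## Heart rate variability

Time domain follows the standard definitions (SDNN uses the sample SD,
pNNX = 100·#{|ΔRR| > X ms}/(n−1)). The spectral path spline-resamples the RR
series to 4 Hz and uses 120-s Welch segments with 50% overlap on 5-min
epochs (the segment length is a package choice; conventions differ).
Normalization: LFn = LF/(LF+HF), HFn = HF/(LF+HF), i.e. total power is
defined over 0.04–0.40 Hz, so LFn + HFn = 1. LF/HF is flagged NaN when HF
power is zero.

Entropies use m = 2 and r = 0.2·SD of the original series (literature
convention). SampEn excludes self-matches and uses N − m templates at both
lengths; an absent match count yields NaN, never a substituted infinity.
FuzzyEn removes each template's local mean and applies the exponential
membership exp(−(d/r)²) to Chebyshev distances. MSEn is the mean SampEn over
coarse-grained scales 1–3 with r fixed from the scale-1 SD; longer scales
are not supported because 5-min epochs (~350–500 beats) cannot populate
them, and a series shorter than 100·max(scale) intervals returns a flagged
NaN. Whether a multiscale value should be a mean across scales or a
single-scale value is a genuine convention fork; the mean over scales 1–3 is
this package's documented choice.

## xBRS

Both beat series are placed on a common 1 Hz grid by sample-and-hold (each
grid second carries the most recent beat's value). Sample-and-hold keeps
grid samples equal to actual beat values and, unlike linear interpolation,
does not manufacture serial correlation inside the 10-point windows — with
linear interpolation the windowed Pearson test's null acceptance rate
exceeds the 10% budget the estimator is designed to meet. For each 10-s
window sliding by 1 s and each delay in {0, 1, 2, 3} s, the pulse-interval
segment is correlated with the pressure segment; the best positive
correlation is selected (baroreflex sign constraint), and the window
contributes its regression slope if the two-sided p-value is below 0.05 and
no flagged ectopic beat falls in the window. Ectopic flag: an interval
deviating more than 25% from the median of its 10 nearest neighbours (the
parameters are package choices). The per-epoch xBRS is the **median** of
accepted slopes — robust, given that the aggregator convention is not fixed
in the method family — plus the modal delay and the window counts. An epoch
with zero accepted windows is flagged undefined, not zero.

## Joint symbolic dynamics

Symbolization: s_n = 1 iff x_n − x_{n+1} < l with l = 0, so ties map to 0 by
strict inequality. Overlapping 3-symbol words are encoded MSB-first in time
(affects labelling only). The joint distribution of the 64 (RR word, SAP
word) pairs forms the 8×8 matrix W, normalized to relative frequencies.
JSD_sym = trace(W); JSD_diam = antidiagonal sum; for an 8×8 matrix the two
sets are disjoint, so JSD_sym + JSD_diam ≤ 1. Alignment: the word-pairing
lag is a parameter (default 0). In the epoch pipeline the interval ending at
beat n+1 is paired with the pressure value at beat n, so a pressure change
drives the subsequent interval, which is the baroreflex-physiological
embedding; the supplementary alignment conventions in the literature differ,
and the configurable lag records that ambiguity rather than resolving it.

## Cohort statistics

Friedman's rank ANOVA is implemented directly (average-rank ties, tie
correction C = 1 − Σ(t³−t)/(nk(k²−1))), with all-tied data defined to
chi² = 0, p = 1, and is cross-checked against an independent implementation
in the tests. Participants missing any condition are dropped listwise; the n
used is reported, since coherence gating legitimately removes VLF estimates
for some participants. Kendall's W = chi²/(n(k−1)). Wilcoxon post-hocs drop
zero differences, use the exact null for ≤ 25 non-zero pairs and the
continuity-corrected normal approximation above, and declare significance at
the Bonferroni threshold α/m. Spearman matrices are pairwise-complete with
≥ 10 observations per cell.

The mixed-effects interface fits, per (CA metric, ANS metric) pair, a
random-participant-intercept model with the ANS metric, respiratory rate and
EtCO₂ as fixed effects, by REML via statsmodels MixedLM. Inference is a Wald
F per coefficient (the squared z statistic, 1 numerator df, chi-square
reference) and is labelled as such; Satterthwaite-type denominator degrees
of freedom are not available from the delegated estimator. In the
zero-random-variance limit this matches the OLS F within 1%, and its type-I
error calibrates to 3–7% at n = 20 participants in simulation.

## Synthetic generator: what it emulates, what it does not

The generator's stated world: heart rate 70 beats/min, systolic base
120 mmHg with 40 mmHg pulse pressure, Mayer-wave amplitude 3 mmHg at 0.1 Hz,
respiratory pressure oscillation 2 mmHg, respiratory sinus arrhythmia 40 ms,
baroreflex slope 10 ms/mmHg acting after a 2-s delay (the dominant delay in
healthy adults), CBv base 57 cm/s, EtCO₂ base 36.5 mmHg falling
0.45 mmHg per breath/min above the 6/min reference — values chosen once from
cohort medians for young healthy volunteers and not revisited. Defaults for
per-channel measurement noise are small (0.2–0.5 physical units; 0.01 mV
ECG; 3 ms RR).

Beat dynamics run in the beat domain: RR_n = RR₀ + slope·(SAP_{n−k} −
SAP_base) + RSA(t_n) + noise with k the delay rounded to beats, because both
xBRS and JSD operate beat-to-beat. RR_n is anchored at the beat *starting*
the interval, making the RR–SAP pair exactly affine at zero delay — the
property the exact-recovery tests rely on. The ABP pulse is a raised-cosine
systolic upstroke (0.12 s) with exponential diastolic decay: simple,
peak-detectable, and with its maximum exactly at the configured SAP. CBv is
the mean-removed ABP passed through the configured gain/phase transfer
function (frequency-domain multiplication; positive phase = CBv leads) on a
constant baseline. EtCO₂ is a breath-synchronous plateau wave whose
per-breath maximum is the end-tidal level. One seeded generator drives all
channels, so identical configurations are bit-identical.

Not emulated: nonlinear autoregulation dynamics, CO₂-reactivity feedback on
CBv, tidal-volume physiology (end-tidal level is driven directly by the
breathing rate), ectopy beyond optional injected outliers, and realistic ECG
morphology beyond an R spike and T wave. A green parameter-recovery test
therefore establishes that the estimator chain is correct for a linear,
stationary, well-coupled world — not that it is robust to arrhythmia,
probe artifacts or nonstationarity in clinical data.

## Known limitations

* EDF input is not supported (no EDF reader in the dependency set); the CSV
  dialect is the interchange format.
* The coherence confidence limit uses the nominal window count; with 50%
  overlap the effective independence is lower, so the gate is slightly
  conservative-to-liberal depending on band — consistent with common TFA
  practice but not exact.
* Mixed-model p-values are Wald chi-square based; small-cohort denominator
  df corrections are not applied.
* The artifact rule is not robust to sustained (multi-second) dropouts;
  those should be excluded upstream.
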