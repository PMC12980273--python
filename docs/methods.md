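# Methods

## Problem setting

Behavioural assays often cannot tell whether a compound that, say,
suppresses locomotion is sedative, anxiolytic, antipsychotic or simply
toxic. Pharmaco-EEG sidesteps behaviour: a drug's action on the brain
is read from how it shifts the spectral composition of cortical
activity. The pipeline implemented here assumes a library of such
shifts for reference drugs with known receptor profiles and asks, for a
new compound, *which reference drug does its ECoG effect resemble?*

The unit of analysis is one administration in one animal: a 60-s
quiet-wake sample immediately before injection and another 20 minutes
after, on six epidural channels (FP1/FP2 motor, C3/C4 somatosensory,
O1/O2 visual cortex) sampled at 500 Hz through a 0.5–35 Hz passband.
Samples are assumed pre-screened for movement artefacts and epileptic
activity; the package performs no artefact rejection.

## Feature extraction (132 values per recording)

Per channel, four whole-signal statistics and, for each of six band
entities, three rhythm measures:

| block | values |
|---|---|
| whole signal | mean amplitude, max amplitude, amplitude SD, LZ compression ratio |
| δ, θ, α, β, β-LF, β-HF | mean band amplitude, rhythm index, mean band power |

giving 6 × (4 + 6×3) = 132. Published feature counts for this protocol
are only consistent with the full β band (14–35 Hz) being reported
*alongside* its low/high halves, so the β entity is included as a sixth
band; the scheme is configurable (`BandScheme`).

Definitions and conventions:

* **Amplitude** is operationalised as absolute deviation from the
  sample mean (peak-to-peak and envelope conventions exist; vendor
  software does not publish its choice). The SD is the population
  standard deviation of the samples.
* **Spectra** come from an averaged tapered periodogram: 5-s epochs,
  30 % overlap, each epoch truncated to its first 2048 samples and
  Hann-windowed before a 2048-point FFT. Truncation (rather than
  zero-padding or splitting) keeps the bin spacing at fs/2048 ≈ 0.244 Hz
  with one unbroken epoch grid. Bins are normalised so that one
  spectrum sums to the window-gain-corrected variance of its epochs
  (Parseval holds to <1 %); a pure tone of amplitude A integrates to
  A²/2.
* **Band assignment** is by bin-centre frequency on half-open
  intervals, so δ+θ+α+β-LF+β-HF tile the passband exactly and their
  rhythm indices sum to 1 (tested at 1e-6). The shared 14 Hz edge
  belongs to β-LF. **Mean band power** is the arithmetic mean of the
  bins in the band; the **rhythm index** is the band's share of total
  spectral area.
* **Band amplitudes** use a zero-phase 4th-order Butterworth band-pass
  with 1 s trimmed at each end to drop filter transients.
* **LZ compression ratio**: the signal is binarised at its median and
  parsed with the LZ76 exhaustive-history rule; with phrase count c(n)
  the ratio is n / (c(n)·log₂ n), so repeatable signals score *higher*
  and an i.i.d. binary sequence tends to 1. The parser is verified
  against a brute-force exhaustive-history oracle on every binary
  string up to length 12. A constant signal parses to two phrases —
  the defined maximum of the ratio for its length, not an error.

A drug administration is then the element-wise **post/pre ratio** of
the two feature vectors. Any pre-injection feature at or below 1e-12
aborts with an error naming the feature rather than emitting an
infinity.

## Dimensionality reduction and classification

Effect matrices are standardised column-wise by the training mean and
SD (ddof = 1); near-constant columns (SD < 1e-12) are dropped and
recorded on the model. The correlation matrix of the standardised data
is eigendecomposed (`numpy.linalg.eigh`); eigenvalues are clipped at
zero, sorted descending, and each component's sign is fixed so its
largest-magnitude loading is positive — score tables are therefore
identical across runs and platforms. The default k = 6 components
matches the protocol's choice; a cumulative explained-variance rule is
available. PCA is fitted on training records only by default
(`pca_population="training"`); pooling test records before the fit is
available as `"all"` for workflows that compute scores for every record
at once, at the cost of leakage.

The naive Bayes classifier stores, per class and component, the sample
mean and unbiased variance of the training scores, floored at
`variance_floor` (1e-9 on the standardised-score scale) so degenerate
classes keep finite densities. Priors are uniform by default — the
reference groups are near-equally sized (7–10 records) by design —
with empirical priors as an option. Posteriors are computed in the log
domain and normalised per record with log-sum-exp; they are verified
against a direct scipy density-product oracle at 1e-12. Note that with
fewer than ~10 records per class the per-class variance estimates are
noisy, and a class that draws an atypically tight sample on one
component will repel moderately distant records much harder than its
population would; group sizes of 10+ temper this.

**MPS** (median probability of similarity): per test group and training
class, the median over the group's records of the posterior assigned to
that class. An even record count takes the mean of the two middle
values. Groups are ranked by descending MPS; exact ties are broken by
class name order and flagged in the output.

## Synthetic panel generator

No public recordings exist for this protocol, so the generator emulates
the statistical structure the analysis assumes rather than any
particular animal:

* **Baseline** — per channel, a sum of five band-limited Gaussian-noise
  components (unit-variance noise, zero-phase Butterworth band-pass,
  scaled to a target RMS per band) over a 1/f broadband floor limited
  to 0.5–35 Hz. Defaults: δ 40, θ 30, α 15, β-LF 8, β-HF 5 µV RMS with
  a 5 µV floor — low-frequency-dominant spectra typical of quiet-wake
  rodent cortex. Noise components are generated with 1 s of padding at
  each end which is discarded, removing filter warm-up. Band components
  are shaped with an 8th-order zero-phase Butterworth, deliberately
  steeper than the 4th-order analysis filters: with 4th-order shaping
  enough power leaks through the skirts that a single-band signal no
  longer measures as ≥95 % of spectral area inside its own band, which
  would defeat the generator's purpose of realising designed spectra.
  Noise (not sinusoids) keeps rhythm indices non-degenerate and LZ
  complexity realistic.
* **Drug signatures** — a 3-region × 5-band grid of positive power
  multipliers (frontal/parietal/occipital × δ…β-HF) plus a lognormal
  jitter SD. The post phase scales each region-band component's power
  by multiplier × lognormal(0, jitter_sd); both phases share per-animal
  channel gains (lognormal, SD 0.1 log-scale), so post/pre ratios
  cancel electrode and anatomy variability exactly as the real
  normalisation intends. Multiplicative jitter suits strictly positive
  powers and median fold-change reporting.
* **Default panel** — 19 signatures mirroring the reference training
  design (nine agents at one to three doses plus saline). The grids
  qualitatively follow the reported per-drug band/region changes
  (galantamine < 1 broadband, dexmedetomidine ≫ 1 frontally, mixed
  dizocilpine effect, …) but their magnitudes are invented fixtures:
  no quantitative effect sizes are published for the protocol, so these
  numbers are calibration targets for the pipeline, not ground truth
  about the drugs.

Determinism: every record's randomness derives from a unique integer
seed (< 2³¹) drawn deterministically from the panel seed; regenerating
a panel with the same seed is bit-for-bit identical.

What the generator does *not* model — movement artefacts, sleep/wake
transitions, epileptiform events, pharmacokinetic time-courses,
channel cross-correlation structure (components are drawn independently
per channel), or non-stationarity within the 60-s sample. Passing the
simulation-recovery tests therefore shows that the pipeline recovers
*designed spectral effects under multiplicative inter-record
variability*; it does not certify performance on real recordings, where
artefact screening and within-group heterogeneity dominate.

## Validation design

* Oracle equivalences: PCA against an independent SVD (and
  scikit-learn cross-check) at 1e-8; naive Bayes against a direct
  density product at 1e-12; LZ76 against exhaustive brute force.
* Designed-vs-measured: a ×2 δ-power signature is recovered from
  measured post/pre band powers within 10 % averaged over 20 records;
  frontal-only signatures leave other regions' ratios at 1; the
  designed jitter SD is recovered after subtracting the
  spectral-estimation noise floor measured with a jitter-free
  signature.
* Full-size recovery: on the 19-group × 10-record panel (60-s phases,
  jitter 0.1, fixed seed) leave-one-record-out classification must
  place ≥ 80 % of groups on their own class via top MPS, and MPS
  against saline must fall strictly monotonically along a
  saline→reference signature interpolation. These sizes match the
  study design the package targets; smaller panels (5–6 groups, 20–30-s
  phases) are used elsewhere in the suite to keep it fast.

Published per-component variance shares (and the 83.57 % six-component
total reported for the original feature matrix) depend on raw
recordings that were never released; they are not reproduction targets,
and the explained variance of synthetic panels differs legitimately.

## Known limitations

* Exact numeric agreement with the vendor acquisition software
  (amplitude, windowing and LZ conventions unpublished) and with
  spreadsheet NBC implementations (prior/variance conventions
  unpublished) is not claimable; reproduction tolerances reflect this.
* EDF support is read-only and requires the optional `mne` dependency.
* The classifier is the protocol's: no alternative classifiers or
  cross-validation machinery beyond the leave-one-out check used in
  validation.
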