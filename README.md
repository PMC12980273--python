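# pharmeeg

Pharmaco-EEG screening of psychotropic drug activity from rodent
electrocorticogram (ECoG). Given paired recordings taken immediately
before and 20 minutes after an intraperitoneal injection, the package
quantifies each administration as a vector of amplitude-spectral
changes, compresses those vectors with principal component analysis,
and scores test compounds against a reference panel of drugs with known
mechanisms using a Gaussian naive Bayes classifier. A seeded synthetic
ECoG generator stands in for animal recordings, so the whole pipeline
is testable end to end with zero downloads.

## Who this is for

Neuropharmacology groups using quantitative EEG/ECoG to place novel
compounds among reference psychotropics (antipsychotics, anxiolytics,
cholinergics, α2-agonists, ...), and methodologists who want a tested,
scriptable reimplementation of the feature → PCA → naive-Bayes → MPS
chain usually run through spreadsheet tooling.

## The method

For each of 6 channels (FP1, FP2 motor, C3, C4 somatosensory, O1, O2
visual cortex; 500 Hz, 0.5–35 Hz passband) and each 60-s sample:

* **Whole-signal statistics** — mean amplitude, maximum amplitude,
  amplitude SD, and the Lempel–Ziv compression ratio
  `n / (c(n) · log₂ n)` of the median-binarised signal, where `c(n)` is
  the LZ76 exhaustive-history phrase count (more repeatable signal →
  higher ratio).
* **Per-rhythm measures** for δ (0.5–4 Hz), θ (4–8), α (8–14),
  β (14–35) and its low (14–20) / high (20–35) halves: mean
  band-filtered amplitude, rhythm index (fraction of spectral area in
  the band), and mean band power from an averaged Hann-tapered
  periodogram (5-s epochs, 30 % overlap, 2048-point FFT).

That is 6 × (4 + 6×3) = **132 features**. A drug administration is the
element-wise **post/pre ratio** of the two feature vectors. Ratios are
standardised, `X_norm = (X − mean(X)) / std(X)`, the correlation matrix
is eigendecomposed, and each record is summarised by its first k = 6
component scores. A naive Bayes classifier models every training class
by independent per-component Gaussians; for each test group the
**median probability of similarity (MPS)** to each training class — the
group median of the per-record posteriors — says which reference drug
the compound behaves like.

## Worked example

`examples/02_classify_panel.py` simulates five reference groups
(6 paired records each), extracts the effect matrix and classifies the
panel against itself:

```
effect matrix: 30 records x 132 features
variance explained by the first 6 components: 81.1%
  DEX 0.005  -> top class DEX 0.005  (MPS 1.000)
  GAL 1.0    -> top class GAL 1.0    (MPS 1.000)
  HXZ 5.0    -> top class HXZ 5.0    (MPS 1.000)
  NaCl       -> top class NaCl       (MPS 1.000)
  PHE 0.1    -> top class PHE 0.1    (MPS 1.000)
-> each group's highest group-median posterior should point back at itself.
```

Each line reports, for one drug-dose group, the training class with the
highest group-median posterior; MPS 1.000 means every record in the
group was attributed to that class with near certainty. The other
examples show single-pair effect vectors (`01_simulate_and_extract.py`)
and classification straight from a PC-score table, bypassing feature
extraction (`03_score_table_workflow.py`).

The same pipeline is scriptable from a shell:

```sh
pharmeeg demo --seed 0 --out runs/demo          # end-to-end smoke run
pharmeeg simulate --seed 1 --n-per-group 10 --out runs/panel
pharmeeg extract  --manifest runs/panel/manifest.csv --out runs/effects.csv
pharmeeg classify --train runs/effects.csv --out runs/cls
pharmeeg report   --mps runs/cls/mps.csv --out runs/cls/mps.png
```

## Layout

* `src/pharmeeg/sim.py` — seeded synthetic pre/post ECoG panels with
  configurable drug-class spectral signatures
* `src/pharmeeg/features.py` — the 132 amplitude-spectral features and
  effect ratios
* `src/pharmeeg/model.py` — correlation-matrix PCA, Gaussian naive
  Bayes, MPS tables, leave-one-out validation
* `src/pharmeeg/io.py` — delimited-text recordings and tables (EDF
  read-only), locale-tolerant score-table parsing
* `src/pharmeeg/pipeline.py`, `src/pharmeeg/cli.py` — orchestration and
  the thin command line
* `docs/methods.md` — model, assumptions, parameter choices and
  limitations
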