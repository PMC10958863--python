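# grscreen

Analysis toolkit for image-based organoid drug screens. Patient-derived
organoid (PDO) lines grow at very different baseline rates, so raw viability
readouts confound drug effect with intrinsic growth. `grscreen` implements a
growth-rate-normalized analysis of such screens end to end:

* **NOGR** — the normalized organoid growth rate. From per-well viability
  `V` (organoid area minus cell-death signal area), the growth fraction
  `G = (V(x) − V(0))/V(0)` is rescaled against the within-plate controls:
  `G/G_medNeg` for growing wells, `G/|G_medPos|` for shrinking wells,
  clipped to [−1, 1]. NOGR = 1 means growth as in vehicle, 0 stasis, −1
  killing as strong as the positive control, so cytostatic and cytotoxic
  effects are read off the same scale.
* **GR dose-response fitting** — `GR(c) = GRinf + (1 − GRinf)/(1 +
  (c/GEC50)^h)` fit per replicate with a one-pass outlier rule (absolute
  residual > 2.5× the mean residual and > 0.25), then `NOGR50` (dose at
  response 0.5) and `AOC_n` (normalized area over the fitted curve on the
  log-dose axis, in [0, 1], higher = stronger response).
* **Synergy** — ZIP, Bliss, Loewe and HSA reference models scored on
  NNOGR = (NOGR + 1)·50 combination matrices, with a summary score per
  model (|score| > 10 ⇒ non-additive) and the combination sensitivity
  score (CSS) for overall combination efficacy.
* **Response classification** — resistant / intermediate / sensitive by the
  33rd and 66th percentiles of the per-line `AOC_n`.
* **Biomarkers** — genewise Pearson correlation of baseline expression with
  `AOC_n` (p < 0.01 signatures), preranked gene-set enrichment (NES),
  single-marker ROC with Youden cutoff, an exhaustive shallow decision
  tree, first-order partial correlation networks, and per-patient
  fraction-of-positive-cells Spearman correlation for single-cell
  validation.
* **Synthetic screens** — a fully seeded generator that emulates the plate
  design (anchor drug 500–3000 nM × library drugs 10–5000 nM in 6×4
  matrices, controls, 0/72/120 h timepoints), measurement noise, planted
  outliers, and expression/single-cell matrices with planted markers, so
  the whole pipeline is testable without instrument data.

The core fitting and grouping steps are scikit-learn style estimators
(`GRDoseResponse`, `PercentileResponseClassifier`) and compose with sklearn
tooling; everything else is plain functions over pandas tables.

See `docs/methods.md` for the models, assumptions, numerical choices and
known limitations.

## Worked example

Run the full pipeline on a simulated study-scale screen (9 lines, anchor
drug + 11 library drugs, 2 replicate plates):

```bash
grscreen run --seed 42 --outdir out/
```

prints the per-line response classification:

```
report: out/report.json
  LU_46N: AOC=0.255 -> sensitive
  LU_51N: AOC=0.176 -> intermediate
  NKI_120: AOC=0.262 -> sensitive
  NKI_125: AOC=0.091 -> resistant
  PDAC_010: AOC=0.273 -> sensitive
  PDAC_044: AOC=0.204 -> intermediate
  PDAC_061: AOC=0.136 -> resistant
  PDAC_071: AOC=0.161 -> intermediate
  PDAC_087: AOC=0.136 -> resistant
```

Each line's `AOC` is the mean normalized area over its fitted anchor-drug
dose-response curves (0 = no response, 1 = complete killing across the
tested range); the groups split at the 33rd/66th percentiles of those nine
values. `out/` then contains the complete trail: `plate.csv` (simulated
wells) and `truth.json` (ground truth), `nogr.csv` (per-well NOGR),
`fits.csv` (216 curve fits; this seed flags 27 of 1260 monotherapy
datapoints as outliers), `synergy.csv` (4 model scores + CSS for each of
the 99 line × drug-pair matrices, e.g. Auranofin + ASTX029 in LU_46N: ZIP
1.6 → additive, CSS 64.6), `classification.csv`, `correlations.csv` and
`signatures.gmt` (54 positively and 60 negatively AOC-correlated genes at
p < 0.01), and `report.json` with the machine-readable summary.

The same stages are available as library calls and as per-stage subcommands
(`simulate`, `nogr`, `fit`, `synergy`, `classify`, `biomarker`), e.g.:

```python
import numpy as np
from grscreen import GRDoseResponse, log_titration

doses = np.array(log_titration(10, 5000, 6).values, float)  # 10 … 5000 nM
est = GRDoseResponse().fit(doses, observed_nogr)
est.grinf_, est.gec50_, est.h_, est.nogr50(), est.aoc()
```

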