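# Methods

`grscreen` implements the analysis layer of an image-based organoid drug
screen: per-well viability values go in, normalized growth-rate response
metrics, drug-combination synergy scores, response-group labels and
transcriptome biomarkers come out. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Growth normalization (NOGR)

Viability `V` is an image-derived area per well (total organoid area minus
the cell-death signal area). The growth fraction over the assay window is

    G = (V(x) - V(0)) / V(0)

and the normalized organoid growth rate rescales `G` against the within-plate
controls:

    NOGR = G_drug / G_medNeg          if G_drug > 0
    NOGR = G_drug / |G_medPos|        if G_drug < 0
    NOGR = 0                          if G_drug = 0
    NOGR = clip(NOGR, [-1, 1])

where `G_medNeg` / `G_medPos` are the median growth fractions of the vehicle
and positive-control wells of the same plate, line and timepoint. The
scale anchors at +1 (growth as in vehicle), 0 (stasis) and -1 (killing as in
the positive control). The killing branch divides by the *magnitude* of the
positive-control median: dividing by the signed value would return +1 at
complete killing, contradicting the -1 anchor that defines the scale, so the
anchoring endpoints are treated as the operative contract. Control medians
are never pooled across plates. Wells with `V(0) <= 0` (segmentation
failures) are excluded and logged, never imputed. `NNOGR = (NOGR + 1) * 50`
maps the scale onto [0, 100] for synergy-model input.

## Dose-response model and outlier rule

The response at concentration `c` (nM) follows the growth-rate (GR)
sigmoid

    GR(c) = GRinf + (1 - GRinf) / (1 + (c / GEC50)^h_GR)

with `GRinf` the plateau at infinite dose (in [-1, 1]), `GEC50` the
half-effect concentration and `h_GR` the Hill steepness. Fits use fixed
initial guesses (0.1, median tested concentration, 2) and box constraints
`GRinf in [-1, 1]`, `GEC50 in [c_min/10, c_max*10]`, `h_GR in [0.1, 10]`;
a half-effect concentration far outside the tested range is not
identifiable, and NOGR itself is clipped to [-1, 1].

Aberrant wells are removed by a one-pass rule: a point is an outlier when
its absolute residual exceeds **both** 2.5x the curve's mean absolute
residual **and** 0.25 NOGR units. Two numerical choices matter here:

* **Robust detection pass.** The residuals that feed the rule come from a
  soft-L1 fit with `f_scale = 0.25` (the absolute gate). An ordinary
  least-squares provisional fit chases a single aberrant well and spreads
  the misfit over its neighbours, diluting the outlier's own residual below
  the 2.5x-mean gate; with the robust pass the provisional curve stays with
  the majority of points and the aberrant well keeps its full residual.
* **The reported model is plain least squares.** After flagging, the final
  parameters always come from an ordinary least-squares fit on the retained
  points, so the robust loss influences only which points are kept.

One detection/refit cycle is performed, never iterated. If the rule would
reject every point the fit is reported as degenerate. Non-convergence
returns a diagnosable failure object rather than raising.

An identifiability limit is worth stating: a deviation that leaves the data
consistent with *some* monotone sigmoid — for example a shifted top-dose
point, which just moves the apparent plateau — cannot be distinguished from
a different true curve by any residual rule. Detection is therefore reliable
(measured at ~100% for deviations of 0.55 at measurement noise 0.05) only
for shape-violating deviations such as an upward bump on a descending
curve; monotone-consistent shifts are absorbed by design.

Derived metrics:

* `NOGR50 = GEC50 * (0.5 / (0.5 - GRinf))^(1/h_GR)`, the concentration at
  which the fitted curve crosses 0.5; undefined (flagged, not an error)
  when `GRinf >= 0.5`.
* `AOC_n`, the area over the fitted curve up to y = 1, integrated by
  adaptive quadrature on the log10 concentration axis over the tested range
  only, and normalized by the maximum attainable area
  `2 * (log10 c_max - log10 c_min)`. The floor of the normalization is -1
  because NOGR is clipped there; `AOC_n` then lies in [0, 1] with higher =
  stronger response. Fits are per biological replicate; downstream stages
  consume the mean `AOC_n` per line x drug.

Titrations are geometric series rounded to integer nM; the screen's designs
are 500-3000 nM in 4 steps (500, 909, 1651, 3000) for the anchor compound
and 10-5000 nM in 6 steps for the library drugs. Clinical unit conversions
use the molar mass of auranofin (678.48 g/mol) and the atomic mass of gold.

## Synergy scoring

Combination grids are scored on fractional inhibition
`y = (100 - NNOGR)/100`. Four reference models define the no-interaction
expectation per cell; the summary score is 100x the mean of
(observed-or-modeled minus expected) over the combination cells only, and
|score| > 10 is read as non-additive (synergistic above, antagonistic
below).

* **Bliss**: `yA + yB - yA*yB` from the observed monotherapy responses.
* **HSA**: `max(yA, yB)`. Since `max(a,b) <= a + b - ab` on [0,1], HSA
  deltas dominate Bliss deltas cellwise.
* **Loewe**: monotherapies are fit with log-logistic inhibition curves
  (plateau free in [0, 1]); the expected effect solves
  `dA/DA(y) + dB/DB(y) = 1` by bracketing bisection (tolerance 1e-6) on the
  fitted inverses. Cells whose additive demand exceeds the weaker drug's
  plateau are capped at the attainable maximum and flagged. An inactive
  partner reduces the expectation to the active drug's fitted curve.
* **ZIP**: along each row (fixed anchor dose) and column, a potency-shifted
  curve is refit with the partner's fitted monotherapy effect as the fixed
  floor and free top asymptote; the delta is the mean of the row- and
  column-fitted values minus the Bliss expectation of the fitted
  monotherapy curves. Row/column fit failures fall back to the observed
  values for that axis.

The combination sensitivity score (CSS) summarizes overall combination
efficacy: for each orientation the partner dose nearest the partner's
fitted relative IC50 is selected as anchor, the combination response along
the other axis is refit with a free floor, and percent inhibition is
integrated over the tested log10 dose range normalized to the range width;
CSS is the mean of the two orientations, in [0, 100]. Exact numeric parity
with external synergy software is not claimed: whether such tools are fed
percent viability or percent inhibition, and which anchor dose they choose,
is implementation-defined there; the transformation used here is fixed and
documented above.

## Response classification

Lines are split on the 33rd and 66th percentiles of the normalized AOC
vector being classified (linear interpolation between order statistics,
the common default; the percentile method is otherwise a free choice).
Strictly below the 33rd percentile is resistant, strictly above the 66th
sensitive, boundaries inclusive intermediate — with all-equal inputs every
line is intermediate. The grouping is invariant under strictly monotone
rescaling of the AOC values.

## Biomarker discovery

* **Genewise correlation**: Pearson r of each gene against the per-line
  AOC (mean across replicates), p from the exact t transform with n-2
  degrees of freedom. Zero-variance genes are flagged, not dropped
  silently. Signature membership uses the raw p < 0.01 cutoff (positive r
  -> PCGS, negative -> NCGS); a Benjamini-Hochberg column is emitted for
  transparency but does not gate membership, matching the raw-cutoff
  design.
* **Preranked enrichment**: weighted Kolmogorov-Smirnov running sum with
  weight exponent 1. The null permutes set membership over genes (the
  use-case ranks one contrast, so sample permutation is unavailable);
  NES = ES / mean |ES| of same-sign null scores, p is the same-sign
  permutation fraction with a +1 continuity floor, so p >= 1/(n_perm+1).
  Default 1000 permutations, seeded.
* **Single-marker ROC**: AUC by the rank (Mann-Whitney) construction,
  p from the Mann-Whitney test (exact when both classes have <= 10
  samples). The reported cutoff maximizes Youden's J over midpoints
  between consecutive sorted values; ties break toward higher specificity.
  The response dichotomy pools sensitive + intermediate against resistant.
* **Decision tree**: exhaustive search over (gene, midpoint threshold)
  splits minimizing weighted Gini impurity, depth <= 2 — finite,
  deterministic and reproducible, unlike sampled splitters.
* **Partial correlation**: first-order
  `r_xy.z = (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2))` between a seed
  gene and each partner, controlling one remaining partner at a time; the
  edge weight is the minimum-magnitude partial r (the most conservative
  single-control estimate). Collinear controls flag the edge undefined.
* **Fraction-positive correlation**: per-patient fraction of cells with
  count > 0 for two genes, compared by Spearman rank correlation across
  patients (>= 5 patients required).

## Synthetic-data generator

The generator exists so every stage is testable without external data. It
emulates, with defaults chosen to mirror the screen design:

* 9 lines (2 normal, 7 tumor) with heterogeneous baseline growth —
  terminal vehicle growth fractions uniform on [0.5, 1.5], i.e. 1.5- to
  2.5-fold growth over a 120 h window, measured at 0/72/120 h;
* an anchor drug (4-point, 500-3000 nM) crossed with 11 library drugs
  (6-point, 10-5000 nM) in 6x4 matrices plus monotherapy wells, 4 vehicle
  and 4 positive-control wells per line, 2 replicate plates;
* per line x drug GR truths: `GRinf ~ U(-1, 0.6)`, `GEC50` log-uniform
  within the tested range, `h_GR ~ U(1, 3)`;
* viability `V(t) = 100 * (1 + G_terminal * t/T)` with multiplicative
  lognormal noise (sigma 0.05 by default) — areas are positive and
  scale-dependent, which an additive Gaussian would violate. The instrument
  noise distribution is a modeling assumption, not a measured fact;
* positive-control wells decline to a terminal growth fraction of -0.8
  (strong but incomplete killing);
* outlier wells (2.7% of treated wells by default) shifted by a uniform
  +-[0.3, 0.8] in NOGR units — chosen to exceed the 0.25 absolute gate of
  the outlier rule;
* combination cells follow a configurable interaction model per drug pair:
  Bliss/HSA/Loewe nulls, a potency shift, or a fixed inhibition boost;
* expression matrices with planted positively/negatively AOC-correlated
  genes (slope 2 per AOC standard deviation, Gaussian noise sigma 0.5 by
  default) plus two named sentinels: a resistance marker high in low-AOC
  lines and a split marker high only in the lowest-AOC tertile;
* zero-inflated single-cell counts whose per-patient positive fractions
  are rank-linked between a marker and partner genes with tunable strength
  (positive counts per patient are exact, so link = 1 gives Spearman rho
  of exactly 1).

It does **not** emulate: images or segmentation error structure, plate-edge
or spatial effects, drug cross-contamination, batch effects between
replicate plates, library-size or count-depth artifacts in expression data,
or realistic single-cell dropout profiles. Passing tests therefore
demonstrate correctness of the computations under the stated statistical
model, not robustness to every artifact of real instruments.

Everything is reproducible bit-for-bit from the seed; the pipeline stamps
every output with the seed and a configuration hash, and re-running an
identical configuration yields byte-identical files.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the generator at the study's
own scale (9 lines, 11 combinations, 2 replicates — 1260 monotherapy
datapoints per run) for end-to-end checks, 100 seeded matrices per synergy
null, 10,000 x 10 null expression matrices for signature calibration, and
60-200 replicates for fit-distortion and sensitivity properties. These
sizes were chosen to make the Monte Carlo bands in the assertions tight at
interactive runtimes.

## Known limitations

* Single outlier wells that remain consistent with a monotone sigmoid are
  not detectable (see the identifiability note above).
* Loewe and ZIP scores depend on monotherapy curve fits; with fewer than 4
  informative doses or non-monotone monotherapies the fallbacks (capped
  expectation, observed-value rows) activate and are flagged rather than
  silently interpolated.
* `AOC_n` integrates over the tested dose range only; it is not comparable
  across screens with different ranges.
* No multiple-testing correction gates signature membership; with ~10
  samples the raw p < 0.01 cutoff admits ~1% of null genes by design.
* No 3+ drug combinations, dose-region-localized synergy maps, or bootstrap
  confidence intervals on synergy scores.
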