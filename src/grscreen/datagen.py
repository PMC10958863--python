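"""Synthetic screen generator: plates, expression and single-cell matrices.

The generator emulates the statistical structure of an image-based organoid
drug screen so that every downstream stage (NOGR normalization, GR curve
fitting, synergy scoring, classification, biomarker discovery) can be tested
end to end without external data:

* per-line baseline growth heterogeneity over the assay window;
* an anchor drug titrated in 4 log steps (500-3000 nM) crossed with library
  drugs in 6 log steps (10-5000 nM), giving 6x4 combination matrices plus
  monotherapy, vehicle and positive-control wells at 0/72/120 h;
* multiplicative lognormal measurement noise on viability (areas are
  positive and scale-dependent);
* a small fraction of wells perturbed by a +-[0.3, 0.8] NOGR shift,
  emulating segmentation artifacts the downstream outlier rule must catch;
* expression matrices with planted positively/negatively AOC-correlated
  genes and two named sentinel markers (CA12-like resistance marker,
  IGFL1-like resistant/sensitive split marker);
* zero-inflated single-cell count matrices whose per-patient
  fraction-of-positive-cells is rank-linked between a marker and its
  partner genes with tunable strength.

Everything is bit-reproducible from the seed carried by the truth object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import gr_model, log_titration
from .errors import ConfigError
from .growth import PLATE_COLUMNS
from .synergy import SynergyMatrix, _loewe_expected, hill_inhibition

__all__ = [
    "ScreenDesign",
    "SimTruth",
    "default_design",
    "default_truth",
    "simulate_plate",
    "simulate_expression",
    "simulate_cells",
    "simulate_synergy_matrix",
]

#: Default study conditions: assay window and imaging timepoints (hours).
DEFAULT_TIMEPOINTS = (0.0, 72.0, 120.0)
#: Positive-control terminal growth fraction: strong but incomplete killing.
POSITIVE_CONTROL_G = -0.8
#: Baseline well viability (area units) at seeding.
V0 = 100.0
#: Injected outlier deviation range in NOGR units; must exceed the 0.25
#: absolute-error gate of the fitting outlier rule.
OUTLIER_SHIFT = (0.3, 0.8)


@dataclass(frozen=True)
class ScreenDesign:
    """Plate layout: lines, drugs, titrations, timepoints and controls.

    ``drugs[0]`` is the anchor compound (titrated with ``titration_anchor``
    and crossed against every other drug); the remaining drugs use
    ``titration_single``.
    """

    lines: tuple  # of (line_id, role) with role in {"tumor", "normal"}
    drugs: tuple
    titration_single: tuple = (10.0, 5000.0, 6)  # (low nM, high nM, n)
    titration_anchor: tuple = (500.0, 3000.0, 4)
    timepoints_h: tuple = DEFAULT_TIMEPOINTS
    replicates: int = 2
    n_vehicle: int = 4
    n_positive: int = 4

    def __post_init__(self):
        for low, high, n in (self.titration_single, self.titration_anchor):
            if not (0 < low < high) or n < 2:
                raise ConfigError("titration requires low < high and n >= 2")
        if 0 not in self.timepoints_h:
            raise ConfigError("timepoints must include 0")
        if self.n_vehicle < 1 or self.n_positive < 1:
            raise ConfigError("need at least one vehicle and one positive-control well")

    @property
    def anchor(self) -> str:
        return self.drugs[0]

    @property
    def library(self) -> tuple:
        return self.drugs[1:]

    def doses(self, drug: str) -> tuple:
        spec = self.titration_anchor if drug == self.anchor else self.titration_single
        return log_titration(*spec).values


@dataclass
class SimTruth:
    """Ground truth behind a simulated screen.

    ``gr_params`` maps (line_id, drug) -> (GRinf, GEC50 nM, h_GR);
    ``baseline_g`` maps line_id -> terminal vehicle growth fraction;
    ``interactions`` maps a (anchor, drug) pair -> interaction model, one of
    ``("bliss_null",)``, ``("hsa_null",)``, ``("loewe_null",)``,
    ``("potency_shift", strength)`` or ``("fixed_delta", value)``.
    """

    baseline_g: dict
    gr_params: dict
    noise_sd: float = 0.05
    outlier_rate: float = 0.027
    interactions: dict = field(default_factory=dict)
    positive_g: float = POSITIVE_CONTROL_G
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.outlier_rate < 1:
            raise ConfigError("outlier_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for key, (grinf, gec50, h) in self.gr_params.items():
            if gec50 <= 0 or h <= 0 or not -1 <= grinf <= 1:
                raise ConfigError(f"invalid GR parameters for {key}: "
                                  f"{(grinf, gec50, h)}")

    def interaction(self, pair) -> tuple:
        return self.interactions.get(tuple(pair), ("bliss_null",))


DEFAULT_LINES = (
    ("LU_46N", "normal"),
    ("LU_51N", "normal"),
    ("NKI_120", "tumor"),
    ("NKI_125", "tumor"),
    ("PDAC_010", "tumor"),
    ("PDAC_044", "tumor"),
    ("PDAC_061", "tumor"),
    ("PDAC_071", "tumor"),
    ("PDAC_087", "tumor"),
)

DEFAULT_DRUGS = (
    "Auranofin",
    "Anlotinib",
    "Buparlisib",
    "MK2206",
    "Everolimus",
    "Trametinib",
    "ASTX029",
    "IM156",
    "Palbociclib",
    "Cisplatin",
    "Gemcitabine",
    "Paclitaxel",
)


def default_design(n_lines=None, n_library=None) -> ScreenDesign:
    """The study-scale design: 9 lines, anchor + 11 library drugs.

    ``n_lines`` / ``n_library`` trim the panel for cheaper test scenarios
    without changing titrations, timepoints or controls.
    """
    lines = DEFAULT_LINES if n_lines is None else DEFAULT_LINES[:n_lines]
    drugs = (
        DEFAULT_DRUGS
        if n_library is None
        else DEFAULT_DRUGS[: n_library + 1]
    )
    return ScreenDesign(lines=lines, drugs=drugs)


def default_truth(design: ScreenDesign, seed: int = 0, **overrides) -> SimTruth:
    """Draw a plausible ground truth for a design, reproducibly from seed.

    Baseline terminal growth fractions are uniform on [0.5, 1.5] (1.5- to
    2.5-fold growth over the window); per line x drug the response plateau
    GRinf is uniform on [-1, 0.6], GEC50 log-uniform within the tested
    range, and the Hill slope uniform on [1, 3].
    """
    rng = np.random.default_rng(seed)
    baseline = {lid: float(rng.uniform(0.5, 1.5)) for lid, _ in design.lines}
    params = {}
    for lid, _ in design.lines:
        for drug in design.drugs:
            lo, hi, _ = (
                design.titration_anchor if drug == design.anchor
                else design.titration_single
            )
            params[(lid, drug)] = (
                float(rng.uniform(-1.0, 0.6)),
                float(np.exp(rng.uniform(np.log(lo * 2), np.log(hi)))),
                float(rng.uniform(1.0, 3.0)),
            )
    kwargs = dict(baseline_g=baseline, gr_params=params, seed=seed)
    kwargs.update(overrides)
    return SimTruth(**kwargs)


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------

def _combine_inhibition(ya, yb, model, params_a, params_b, doses):
    """Expected combination inhibition under the truth interaction model."""
    kind = model[0]
    if kind == "bliss_null":
        return ya + yb - ya * yb
    if kind == "hsa_null":
        return max(ya, yb)
    if kind == "loewe_null":
        pa = ((1.0 - params_a[0]) / 2.0, params_a[1], params_a[2])
        pb = ((1.0 - params_b[0]) / 2.0, params_b[1], params_b[2])
        return _loewe_expected(doses[0], doses[1], pa, pb)[0]
    if kind == "potency_shift":
        strength = model[1]
        ya_s = _mono_inhibition(doses[0] * (1.0 + strength), params_a)
        yb_s = _mono_inhibition(doses[1] * (1.0 + strength), params_b)
        return ya_s + yb_s - ya_s * yb_s
    if kind == "fixed_delta":
        return float(np.clip(ya + yb - ya * yb + model[1], 0.0, 1.0))
    raise ConfigError(f"unknown interaction model {model!r}")


def _mono_inhibition(c, params):
    """True fractional inhibition of one drug at dose c: (1 - NOGR)/2."""
    return (1.0 - gr_model(c, *params)) / 2.0


def _true_nogr(line, drug1, c1, drug2, c2, truth: SimTruth):
    pa = truth.gr_params.get((line, drug1))
    if pa is None:
        raise ConfigError(f"no truth parameters for line {line!r}, drug {drug1!r}")
    if drug2 is None or c2 == 0:
        return gr_model(c1, *pa) if c1 > 0 else 1.0
    pb = truth.gr_params.get((line, drug2))
    if pb is None:
        raise ConfigError(f"no truth parameters for line {line!r}, drug {drug2!r}")
    ya = _mono_inhibition(c1, pa)
    yb = _mono_inhibition(c2, pb)
    y = _combine_inhibition(
        ya, yb, truth.interaction((drug1, drug2)), pa, pb, (c1, c2)
    )
    return float(np.clip(1.0 - 2.0 * y, -1.0, 1.0))


def _enumerate_wells(design: ScreenDesign, line: str):
    """Yield (drug1, c1, drug2, c2, role) for every well of one line."""
    for _ in range(design.n_vehicle):
        yield (None, 0.0, None, 0.0, "vehicle")
    for _ in range(design.n_positive):
        yield (None, 0.0, None, 0.0, "positive_control")
    for c in design.doses(design.anchor):
        yield (design.anchor, float(c), None, 0.0, "treated")
    for drug in design.library:
        for c in design.doses(drug):
            yield (drug, float(c), None, 0.0, "treated")
        for ca in design.doses(design.anchor):
            for c in design.doses(drug):
                yield (design.anchor, float(ca), drug, float(c), "treated")


def simulate_plate(design: ScreenDesign, truth: SimTruth) -> pd.DataFrame:
    """Simulate the full screen as a long-format plate table.

    One plate per replicate, all lines on each plate.  Viability follows
    ``V(t) = V0 * (1 + G_terminal * t / T)`` where the terminal growth
    fraction is the line's baseline for vehicle wells, ``positive_g`` for
    the positive control, and the truth NOGR mapped back through the
    normalization branches for treated wells.  Multiplicative lognormal
    noise and NOGR-shift outliers are applied per measurement/well.  The
    returned frame carries ``attrs['outlier_wells']`` with the planted
    (plate_id, well) pairs.
    """
    for line, drug in truth.gr_params:
        if drug not in design.drugs:
            raise ConfigError(f"truth references unknown drug {drug!r}")
        if line not in {lid for lid, _ in design.lines}:
            raise ConfigError(f"truth references unknown line {line!r}")

    rng = np.random.default_rng(truth.seed)
    t_final = max(design.timepoints_h)
    rows = []
    outliers = []
    for rep in range(design.replicates):
        plate_id = f"P{rep + 1}"
        for line, _role in design.lines:
            g_base = truth.baseline_g[line]
            g_pos = truth.positive_g
            for widx, (d1, c1, d2, c2, role) in enumerate(
                _enumerate_wells(design, line)
            ):
                well = f"{line}-W{widx:03d}"
                if role == "vehicle":
                    g_term = g_base
                elif role == "positive_control":
                    g_term = g_pos
                else:
                    nogr_true = _true_nogr(line, d1, c1, d2, c2, truth)
                    if role == "treated" and rng.random() < truth.outlier_rate:
                        shift = rng.uniform(*OUTLIER_SHIFT)
                        sign = 1.0 if rng.random() < 0.5 else -1.0
                        if not -1.0 <= nogr_true + sign * shift <= 1.0:
                            sign = -sign
                        nogr_true = float(
                            np.clip(nogr_true + sign * shift, -1.0, 1.0)
                        )
                        outliers.append((plate_id, well))
                    g_term = (
                        nogr_true * g_base if nogr_true >= 0
                        else nogr_true * abs(g_pos)
                    )
                for t in design.timepoints_h:
                    v = V0 * (1.0 + g_term * t / t_final)
                    if truth.noise_sd > 0:
                        v *= np.exp(rng.normal(0.0, truth.noise_sd))
                    rows.append(
                        (
                            plate_id,
                            well,
                            line,
                            float(t),
                            d1 or "",
                            c1,
                            d2 or "",
                            c2,
                            role,
                            float(v),
                        )
                    )
    plate = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    plate.attrs["outlier_wells"] = outliers
    return plate


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

#: Named sentinel markers appended to every simulated expression matrix.
SENTINEL_RESISTANCE = "CA12"   # high in low-AOC (resistant) lines
SENTINEL_SPLIT = "IGFL1"       # high only in the resistant tertile


def simulate_expression(
    aoc_by_line: dict,
    n_genes: int = 1000,
    n_pos: int = 50,
    n_neg: int = 50,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a log2-scale expression matrix tied to drug response.

    ``n_pos`` genes are positive linear functions of the standardized AOC
    (plus Gaussian noise of sd ``noise_sd``), ``n_neg`` negative, and the
    remainder pure noise.  Two named sentinel rows are appended on top of
    ``n_genes``: a resistance marker declining linearly in AOC (CA12-like)
    and a split marker high only in the lowest-AOC tertile (IGFL1-like).
    Planted gene lists are exposed via ``attrs``.
    """
    lines = sorted(aoc_by_line)
    if len(lines) < 4:
        raise ValueError("need at least 4 lines for a usable correlation")
    if n_pos + n_neg > n_genes:
        raise ValueError("n_pos + n_neg must not exceed n_genes")
    rng = np.random.default_rng(seed)
    aoc = np.array([aoc_by_line[k] for k in lines], dtype=float)
    z = (aoc - aoc.mean()) / (aoc.std() if aoc.std() > 0 else 1.0)
    n_lines = len(lines)

    names, blocks = [], []
    baseline = rng.uniform(2.0, 10.0, size=n_genes)
    for i in range(n_pos):
        names.append(f"POS{i + 1:04d}")
        blocks.append(baseline[i] + 2.0 * z + noise_sd * rng.normal(size=n_lines))
    for i in range(n_neg):
        names.append(f"NEG{i + 1:04d}")
        blocks.append(
            baseline[n_pos + i] - 2.0 * z + noise_sd * rng.normal(size=n_lines)
        )
    for i in range(n_genes - n_pos - n_neg):
        names.append(f"RND{i + 1:05d}")
        blocks.append(baseline[n_pos + n_neg + i] + rng.normal(size=n_lines))

    names.append(SENTINEL_RESISTANCE)
    blocks.append(8.0 - 3.0 * z + noise_sd * rng.normal(size=n_lines))
    tertile = np.quantile(aoc, 1.0 / 3.0)
    names.append(SENTINEL_SPLIT)
    blocks.append(
        np.where(aoc <= tertile, 8.0, 2.0) + noise_sd * rng.normal(size=n_lines)
    )

    expr = pd.DataFrame(np.vstack(blocks), index=names, columns=lines)
    expr.attrs["planted_pos"] = names[:n_pos]
    expr.attrs["planted_neg"] = names[n_pos : n_pos + n_neg]
    return expr


# ---------------------------------------------------------------------------
# single-cell simulation
# ---------------------------------------------------------------------------

CELL_MARKER = "CA12"
CELL_PARTNERS = ("NFKB1", "NFKB2", "RELA", "RELB")


def simulate_cells(
    n_patients: int,
    cells_per_patient: int = 100,
    frac_positive_link: float = 0.7,
    seed: int = 0,
):
    """Zero-inflated count matrix with rank-linked positive fractions.

    Each patient gets a latent rank; the marker's positive-cell fraction is
    monotone in that rank, and each partner gene's fraction follows a latent
    that mixes the marker rank (weight ``frac_positive_link``) with an
    independent uniform draw.  Positive-cell counts per patient are exact
    (``round(fraction * cells)``), so with link 1 the per-patient fractions
    are perfectly rank-correlated.  Returns (counts genes x cells, patient
    Series indexed by cell id).
    """
    if n_patients < 5:
        raise ValueError("need at least 5 patients")
    if not 0.0 <= frac_positive_link <= 1.0:
        raise ValueError("frac_positive_link must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    pats = [f"PT{i + 1:02d}" for i in range(n_patients)]
    ranks = rng.permutation(n_patients) / (n_patients - 1)
    frac_marker = 0.05 + 0.7 * ranks

    genes = [CELL_MARKER, *CELL_PARTNERS]
    fracs = {CELL_MARKER: frac_marker}
    for g in CELL_PARTNERS:
        latent = frac_positive_link * ranks + (
            1.0 - frac_positive_link
        ) * rng.uniform(size=n_patients)
        order = np.argsort(np.argsort(latent))
        fracs[g] = 0.05 + 0.7 * order / (n_patients - 1)

    cols, data = [], {g: [] for g in genes}
    patient_of = {}
    for pi, pat in enumerate(pats):
        for ci in range(cells_per_patient):
            cell = f"{pat}_c{ci + 1:03d}"
            cols.append(cell)
            patient_of[cell] = pat
        for g in genes:
            n_posi = int(round(fracs[g][pi] * cells_per_patient))
            counts = np.zeros(cells_per_patient, dtype=int)
            if n_posi:
                which = rng.choice(cells_per_patient, size=n_posi, replace=False)
                counts[which] = rng.poisson(1.5, size=n_posi) + 1
            data[g].extend(counts.tolist())
    counts = pd.DataFrame(data, index=cols).T
    patients = pd.Series(patient_of, name="patient")
    return counts, patients


# ---------------------------------------------------------------------------
# direct synergy-matrix simulation (for null calibration)
# ---------------------------------------------------------------------------

def simulate_synergy_matrix(
    model=("bliss_null",),
    seed: int = 0,
    row_doses=None,
    col_doses=None,
    noise_sd: float = 0.01,
    params_row=None,
    params_col=None,
    line_id: str = "SIM",
) -> SynergyMatrix:
    """Simulate one NNOGR combination matrix under a null or perturbation.

    Monotherapy inhibition curves are Hill with plateaus drawn uniformly in
    [0.4, 0.95], EC50 log-uniform inside each dose range and slope in
    [0.8, 2.5]; the combination cells follow the requested interaction model
    (same vocabulary as :class:`SimTruth`).  Gaussian noise of sd
    ``noise_sd`` is added on the inhibition scale and the grid returned as
    NNOGR.
    """
    rng = np.random.default_rng(seed)
    if row_doses is None:
        row_doses = np.array([0.0, *log_titration(500, 3000, 4).values], dtype=float)
    if col_doses is None:
        col_doses = np.array([0.0, *log_titration(10, 5000, 6).values], dtype=float)
    row_doses = np.asarray(row_doses, dtype=float)
    col_doses = np.asarray(col_doses, dtype=float)

    def draw(doses):
        pos = doses[doses > 0]
        return (
            float(rng.uniform(0.4, 0.95)),
            float(np.exp(rng.uniform(np.log(pos.min()), np.log(pos.max())))),
            float(rng.uniform(0.8, 2.5)),
        )

    pa = params_row if params_row is not None else draw(row_doses)
    pb = params_col if params_col is not None else draw(col_doses)

    # truth GR-parameter form for _combine_inhibition: NOGR plateau etc.
    gr_pa = (1.0 - 2.0 * pa[0], pa[1], pa[2])
    gr_pb = (1.0 - 2.0 * pb[0], pb[1], pb[2])

    y = np.zeros((row_doses.size, col_doses.size))
    for i, da in enumerate(row_doses):
        for j, db in enumerate(col_doses):
            ya = hill_inhibition(da, *pa)
            yb = hill_inhibition(db, *pb)
            if da == 0 and db == 0:
                y[i, j] = 0.0
            elif db == 0:
                y[i, j] = ya
            elif da == 0:
                y[i, j] = yb
            else:
                y[i, j] = _combine_inhibition(
                    ya, yb, model, gr_pa, gr_pb, (da, db)
                )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, 1.0)
    return SynergyMatrix(
        line_id=line_id,
        drug_row="drugA",
        drug_col="drugB",
        row_doses=row_doses,
        col_doses=col_doses,
        response=100.0 * (1.0 - y),
    )
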