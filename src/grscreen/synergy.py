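"""Drug-combination synergy scoring on NNOGR dose matrices.

A combination is screened as a dose grid (anchor drug on one axis, library
drug on the other) whose cells hold NNOGR values in [0, 100], including the
zero-dose row and column from the monotherapy wells.  Reference models work
on fractional inhibition ``y = (100 - NNOGR) / 100``:

* Bliss  — probabilistic independence, expected ``yA + yB - yA*yB`` from the
  observed monotherapy responses;
* HSA    — highest single agent, expected ``max(yA, yB)``;
* Loewe  — dose additivity, expected effect ``y*`` solves
  ``dA / DA(y*) + dB / DB(y*) = 1`` on fitted monotherapy curves;
* ZIP    — potency shift: along each row/column a curve is refitted with the
  partner's fitted effect as the floor; the delta is the mean fitted
  combination effect minus the Bliss expectation of the fitted monotherapy
  curves.

Each model's summary score is 100x the mean delta (observed or modeled
minus expected inhibition) over the combination cells only.  Scores above
+10 are read as synergistic, below -10 antagonistic, additive in between.
The combination sensitivity score (CSS) summarizes overall combination
efficacy in [0, 100]: the dose-response of each drug at the partner dose
nearest the partner's fitted relative IC50 is refit and its percent
inhibition integrated over the tested log-dose range; CSS is the mean of
the two orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SynergyMatrix",
    "to_inhibition",
    "bliss_score",
    "hsa_score",
    "loewe_score",
    "zip_score",
    "css_score",
    "score_all",
    "classify_interaction",
    "compare_models",
    "hill_inhibition",
    "fit_hill_inhibition",
]

MODELS = ("zip", "bliss", "loewe", "hsa")
SYNERGY_THRESHOLD = 10.0  # |score| above this is non-additive


@dataclass
class SynergyMatrix:
    """NNOGR response grid for one drug pair in one line.

    ``response[i, j]`` is the NNOGR at ``row_doses[i]`` of ``drug_row``
    combined with ``col_doses[j]`` of ``drug_col``; dose 0 must be the first
    entry on both axes so the monotherapies are the first row/column.
    """

    line_id: str
    drug_row: str
    drug_col: str
    row_doses: np.ndarray
    col_doses: np.ndarray
    response: np.ndarray
    scores: dict = field(default_factory=dict)
    delta_grid: dict = field(default_factory=dict)
    css: float | None = None

    def __post_init__(self):
        self.row_doses = np.asarray(self.row_doses, dtype=float)
        self.col_doses = np.asarray(self.col_doses, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.row_doses.size, self.col_doses.size):
            raise ValueError("response grid shape does not match dose axes")
        if self.row_doses[0] != 0 or self.col_doses[0] != 0:
            raise ValueError("dose axes must start with the zero dose")
        if np.any(self.response < 0) or np.any(self.response > 100):
            raise ValueError("NNOGR values must lie in [0, 100]")


def to_inhibition(matrix: SynergyMatrix) -> np.ndarray:
    """Fractional inhibition grid ``(100 - NNOGR) / 100`` in [0, 1]."""
    return (100.0 - matrix.response) / 100.0


def hill_inhibition(d, emax, ec50, h, floor=0.0):
    """Log-logistic inhibition curve rising from ``floor`` at dose 0 to
    ``emax`` at infinite dose."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(d > 0, d**h / (d**h + ec50**h), 0.0)
    out = floor + (emax - floor) * frac
    return out if out.ndim else float(out)


def fit_hill_inhibition(doses, y, floor=0.0, fit_floor=False):
    """Fit the inhibition Hill curve; returns (emax, ec50, h[, floor]).

    ``fit_floor=True`` frees the dose-0 asymptote in [0, 1] (used for the
    anchored CSS curves, whose baseline is the partner's monotherapy
    effect).  Falls back to a coarse grid + local refinement if the least
    squares solver fails.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = doses > 0
    dmed = float(np.median(doses[pos]))
    dlo, dhi = doses[pos].min() / 10.0, doses[pos].max() * 10.0
    if fit_floor:
        p0 = (min(max(y.max(), 1e-3), 1.0), dmed, 1.0, min(max(y.min(), 0.0), 1.0))
        lo, hi = (0.0, dlo, 0.1, 0.0), (1.0, dhi, 10.0, 1.0)
        fun = lambda d, emax, ec50, h, fl: hill_inhibition(d, emax, ec50, h, fl)
    else:
        p0 = (min(max(y.max(), 1e-3), 1.0), dmed, 1.0)
        lo, hi = (0.0, dlo, 0.1), (1.0, dhi, 10.0)
        fun = lambda d, emax, ec50, h: hill_inhibition(d, emax, ec50, h, floor)
    p0 = tuple(np.clip(p0, lo, hi))
    try:
        popt, _ = optimize.curve_fit(fun, doses, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        return tuple(float(v) for v in popt)
    except RuntimeError:
        # coarse grid over ec50/h, emax floor-constrained least squares
        best, best_sse = p0, np.inf
        for ec50 in np.geomspace(dlo, dhi, 25):
            for h in (0.3, 0.7, 1.0, 2.0, 4.0):
                frac = hill_inhibition(doses, 1.0, ec50, h)
                emax = float(np.clip((y * frac).sum() / max((frac**2).sum(), 1e-12), 0, 1))
                pred = emax * frac
                sse = float(((y - pred) ** 2).sum())
                if sse < best_sse:
                    best_sse = sse
                    best = (emax, ec50, h) + ((float(y[doses == 0].mean()),) if fit_floor else ())
        return best


def _monotherapies(matrix: SynergyMatrix):
    """Observed monotherapy inhibition vectors (row drug, col drug)."""
    y = to_inhibition(matrix)
    return y[1:, 0], y[0, 1:]  # row drug alone, col drug alone


def _summary(delta: np.ndarray) -> float:
    return float(100.0 * np.mean(delta))


def bliss_score(matrix: SynergyMatrix):
    """Bliss independence: expected ``yA + yB - yA*yB`` from observed monos."""
    y = to_inhibition(matrix)
    ya, yb = _monotherapies(matrix)
    expected = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    delta = y[1:, 1:] - expected
    return _summary(delta), delta


def hsa_score(matrix: SynergyMatrix):
    """Highest single agent: expected ``max(yA, yB)`` from observed monos."""
    y = to_inhibition(matrix)
    ya, yb = _monotherapies(matrix)
    expected = np.maximum(ya[:, None], yb[None, :])
    delta = y[1:, 1:] - expected
    return _summary(delta), delta


def _loewe_expected(da, db, pa, pb, tol=1e-6):
    """Solve the dose-additivity equation for one cell by bisection.

    ``pa``/``pb`` are (emax, ec50, h) of the fitted monotherapy curves.
    Returns (expected inhibition, capped flag).
    """
    ea, ca, ha = pa
    eb, cb, hb = pb
    tiny = 1e-6
    if ea < tiny and eb < tiny:
        return 0.0, False
    if ea < tiny:
        return hill_inhibition(db, eb, cb, hb), False
    if eb < tiny:
        return hill_inhibition(da, ea, ca, ha), False

    ymax = min(ea, eb)

    def dose_for(y, emax, ec50, h):
        # inverse of the Hill curve; y < emax guaranteed by the bracket
        return ec50 * (y / (emax - y)) ** (1.0 / h)

    def f(y):
        return da / dose_for(y, ea, ca, ha) + db / dose_for(y, eb, cb, hb) - 1.0

    lo, hi = tiny * ymax, (1.0 - 1e-9) * ymax
    if f(hi) > 0:  # even the attainable maximum cannot satisfy additivity
        return ymax, True
    if f(lo) < 0:
        return lo, False
    return float(optimize.brentq(f, lo, hi, xtol=tol)), False


def loewe_score(matrix: SynergyMatrix):
    """Loewe dose additivity on fitted monotherapy curves."""
    y = to_inhibition(matrix)
    ya, yb = _monotherapies(matrix)
    pa = fit_hill_inhibition(matrix.row_doses, y[:, 0])[:3]
    pb = fit_hill_inhibition(matrix.col_doses, y[0, :])[:3]
    nr, nc = ya.size, yb.size
    expected = np.empty((nr, nc))
    capped = np.zeros((nr, nc), dtype=bool)
    for i, da in enumerate(matrix.row_doses[1:]):
        for j, db in enumerate(matrix.col_doses[1:]):
            expected[i, j], capped[i, j] = _loewe_expected(da, db, pa, pb)
    delta = y[1:, 1:] - expected
    return _summary(delta), delta


def zip_score(matrix: SynergyMatrix):
    """ZIP delta score: potency-shift fits against the Bliss expectation of
    the fitted monotherapy curves."""
    y = to_inhibition(matrix)
    row_doses, col_doses = matrix.row_doses, matrix.col_doses
    pa = fit_hill_inhibition(row_doses, y[:, 0])[:3]
    pb = fit_hill_inhibition(col_doses, y[0, :])[:3]
    ya_fit = hill_inhibition(row_doses[1:], *pa)
    yb_fit = hill_inhibition(col_doses[1:], *pb)
    nr, nc = row_doses.size - 1, col_doses.size - 1

    # row fits: at fixed row-drug dose, response to the column drug with the
    # row drug's fitted effect as floor and upper asymptote 1
    row_fit = np.empty((nr, nc))
    for i in range(nr):
        floor = float(ya_fit[i])
        obs = y[i + 1, :]
        try:
            emax, ec50, h = _fit_shifted(col_doses, obs, floor)
            row_fit[i] = hill_inhibition(col_doses[1:], emax, ec50, h, floor)
        except RuntimeError:
            row_fit[i] = obs[1:]  # fall back to observed values
    col_fit = np.empty((nr, nc))
    for j in range(nc):
        floor = float(yb_fit[j])
        obs = y[:, j + 1]
        try:
            emax, ec50, h = _fit_shifted(row_doses, obs, floor)
            col_fit[:, j] = hill_inhibition(row_doses[1:], emax, ec50, h, floor)
        except RuntimeError:
            col_fit[:, j] = obs[1:]

    expected = ya_fit[:, None] + yb_fit[None, :] - ya_fit[:, None] * yb_fit[None, :]
    delta = 0.5 * (row_fit + col_fit) - expected
    return _summary(delta), delta


def _fit_shifted(doses, y, floor):
    """Potency-shifted curve for ZIP: floor fixed, top asymptote free."""
    doses = np.asarray(doses, dtype=float)
    pos = doses > 0
    dmed = float(np.median(doses[pos]))
    lo = (floor, doses[pos].min() / 10.0, 0.1)
    hi = (1.0, doses[pos].max() * 10.0, 10.0)
    p0 = tuple(np.clip((max(np.max(y), floor + 1e-3), dmed, 1.0), lo, hi))
    popt, _ = optimize.curve_fit(
        lambda d, emax, ec50, h: hill_inhibition(d, emax, ec50, h, floor),
        doses,
        y,
        p0=p0,
        bounds=(lo, hi),
        maxfev=20000,
    )
    return tuple(float(v) for v in popt)


def css_score(matrix: SynergyMatrix):
    """Combination sensitivity score: mean anchored-curve AUC in [0, 100].

    For each orientation the partner dose nearest the partner's fitted
    relative IC50 is selected; the combination response along the other
    axis at that anchor is refit (floor free) and percent inhibition is
    integrated over the tested log10 dose range, normalized to the range
    width.
    """
    y = to_inhibition(matrix)

    def one_side(axis_doses, partner_doses, partner_mono, slab):
        # slab(j) -> inhibition vector along axis_doses at partner dose j>0
        emax_p, ec50_p, h_p = fit_hill_inhibition(partner_doses, partner_mono)[:3]
        pos = partner_doses[1:]
        anchor = int(np.argmin(np.abs(np.log(pos) - np.log(ec50_p))))
        resp = slab(anchor)
        emax, ec50, h, fl = fit_hill_inhibition(axis_doses, resp, fit_floor=True)
        dpos = axis_doses[axis_doses > 0]
        lo, hi = np.log10(dpos.min()), np.log10(dpos.max())
        grid = np.linspace(lo, hi, 513)
        vals = hill_inhibition(10.0**grid, emax, ec50, h, fl)
        auc = np.trapezoid(vals, grid) / (hi - lo)
        return 100.0 * auc

    # row drug titrated, column drug anchored near its IC50 (and vice versa)
    css_row = one_side(
        matrix.row_doses,
        matrix.col_doses,
        y[0, :],
        lambda j: y[:, j + 1],
    )
    css_col = one_side(
        matrix.col_doses,
        matrix.row_doses,
        y[:, 0],
        lambda i: y[i + 1, :],
    )
    return float(np.clip(0.5 * (css_row + css_col), 0.0, 100.0))


def classify_interaction(score: float) -> str:
    """Map a summary synergy score to its interaction class."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if score > SYNERGY_THRESHOLD:
        return "synergistic"
    if score < -SYNERGY_THRESHOLD:
        return "antagonistic"
    return "additive"


def score_all(matrix: SynergyMatrix, models=MODELS, css=True) -> SynergyMatrix:
    """Score a matrix under the requested reference models in place."""
    scorers = {
        "bliss": bliss_score,
        "hsa": hsa_score,
        "loewe": loewe_score,
        "zip": zip_score,
    }
    for model in models:
        summary, delta = scorers[model](matrix)
        matrix.scores[model] = summary
        matrix.delta_grid[model] = delta
    if css:
        matrix.css = css_score(matrix)
    return matrix


def compare_models(scores_by_model: dict) -> dict:
    """Pairwise Pearson correlation between per-matrix score vectors.

    ``scores_by_model`` maps model name -> sequence of summary scores over
    the same matrices.  Constant vectors yield a NaN entry (flagged, not an
    error).
    """
    models = sorted(scores_by_model)
    n = {m: len(scores_by_model[m]) for m in models}
    if len(set(n.values())) != 1:
        raise ValueError("score vectors must have equal length")
    if next(iter(n.values())) < 3:
        raise ValueError("need at least 3 matrices to correlate models")
    out = {}
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            va = np.asarray(scores_by_model[a], dtype=float)
            vb = np.asarray(scores_by_model[b], dtype=float)
            if np.std(va) == 0 or np.std(vb) == 0:
                out[(a, b)] = float("nan")
            else:
                out[(a, b)] = float(stats.pearsonr(va, vb).statistic)
    return out
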