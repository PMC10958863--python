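"""GR dose-response fitting, outlier rejection and derived response metrics.

The sigmoidal growth-rate (GR) model

    GR(c) = GRinf + (1 - GRinf) / (1 + (c / GEC50)^h_GR)

maps concentration ``c`` (nM) to a NOGR value: 1 at zero dose, GRinf at
infinite dose.  Fitting uses fixed initial guesses (GRinf = 0.1, GEC50 =
median tested concentration, h_GR = 2) and two passes: a robust (soft-L1)
detection pass whose absolute residuals feed the outlier rule — residual
exceeding 2.5x the mean absolute residual AND 0.25 flags the point — and a
plain nonlinear least-squares fit on the retained points, which is the
reported model.  The robust detection pass is what lets an aberrant well be
flagged instead of being absorbed into the provisional curve; deviations
that stay consistent with some monotone sigmoid (e.g. a shifted plateau
dose) are not identifiable as outliers by any residual rule and are
absorbed by design.

Derived metrics:

* ``NOGR50`` — concentration at which the fitted curve crosses 0.5
  (undefined when GRinf >= 0.5);
* ``AOC_n`` — area over the fitted curve up to y = 1, integrated on the
  log10 concentration axis over the tested range and normalized by the
  maximum attainable area ``2 * (log10 c_max - log10 c_min)`` (the NOGR
  floor is -1), so AOC_n lies in [0, 1] and higher means stronger response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from sklearn.base import BaseEstimator

from .errors import DegenerateFitError

__all__ = [
    "gr_model",
    "GRDoseResponse",
    "DoseResponseFit",
    "fit_curve",
    "fit_screen",
    "nogr50",
    "aoc_normalized",
    "log_titration",
    "TitrationDesign",
    "clinical_conversion",
    "exclusion_rate",
    "AURANOFIN_MOLAR_MASS",
    "GOLD_ATOMIC_MASS",
]

#: Molar mass of auranofin (g/mol) and atomic mass of gold, used for the
#: clinical concentration conversions.
AURANOFIN_MOLAR_MASS = 678.48
GOLD_ATOMIC_MASS = 196.96657

# Outlier rule constants: residual > RESID_FACTOR x mean residual AND
# > RESID_FLOOR (absolute NOGR units).
RESID_FACTOR = 2.5
RESID_FLOOR = 0.25


def gr_model(c, grinf, gec50, h_gr):
    """Sigmoidal GR dose-response; accepts scalar or array ``c`` in nM."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / gec50) ** h_gr, 0.0)
    out = grinf + (1.0 - grinf) / (1.0 + ratio)
    return out if out.ndim else float(out)


class GRDoseResponse(BaseEstimator):
    """Scikit-learn style estimator for the GR dose-response model.

    Parameters
    ----------
    grinf_bounds, gec50_rel_bounds, h_bounds:
        Box constraints for the fit.  GEC50 bounds are relative to the
        tested concentration range (``[c_min / 10, c_max * 10]`` by
        default) because a half-effect concentration far outside that
        range is not identifiable.
    reject_outliers:
        Apply the one-pass residual rule and refit.

    Attributes
    ----------
    grinf_, gec50_, h_ : fitted parameters (final pass).
    outlier_mask_ : boolean array, True where a point was rejected.
    fitted_ : model value at each input concentration (final pass).
    first_pass_params_ : (grinf, gec50, h) before outlier rejection.
    converged_ : False when scipy could not fit; parameters then carry the
        initial guesses and ``diagnostics_`` holds the error message.
    """

    def __init__(
        self,
        grinf_bounds=(-1.0, 1.0),
        gec50_rel_bounds=(0.1, 10.0),
        h_bounds=(0.1, 10.0),
        reject_outliers=True,
    ):
        self.grinf_bounds = grinf_bounds
        self.gec50_rel_bounds = gec50_rel_bounds
        self.h_bounds = h_bounds
        self.reject_outliers = reject_outliers

    # -- core fitting ------------------------------------------------------
    def _solve(self, conc, obs, robust=False):
        p0 = (0.1, float(np.median(conc)), 2.0)
        lo = (
            self.grinf_bounds[0],
            conc.min() * self.gec50_rel_bounds[0],
            self.h_bounds[0],
        )
        hi = (
            self.grinf_bounds[1],
            conc.max() * self.gec50_rel_bounds[1],
            self.h_bounds[1],
        )
        p0 = tuple(np.clip(p0, lo, hi))
        # the detection pass down-weights residuals beyond the outlier gate
        # (soft-L1) so a single aberrant well cannot drag the provisional
        # curve and dilute its own residual below the 2.5x-mean rule
        extra = dict(loss="soft_l1", f_scale=RESID_FLOOR) if robust else {}
        popt, _ = optimize.curve_fit(
            gr_model, conc, obs, p0=p0, bounds=(lo, hi), maxfev=20000, **extra
        )
        return tuple(float(v) for v in popt)

    def fit(self, X, y):
        """Fit to concentrations ``X`` (nM) and observed NOGR values ``y``."""
        conc = np.asarray(X, dtype=float).ravel()
        obs = np.asarray(y, dtype=float).ravel()
        if conc.shape != obs.shape:
            raise ValueError("X and y must have the same length")
        if conc.size < 4:
            raise ValueError("need at least 4 points to fit")
        if np.unique(conc).size < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")

        self.n_obs_ = conc.size
        self.concentrations_ = conc
        self.observed_ = obs
        self.diagnostics_ = None
        try:
            # detection pass (robust); the reported model below is always a
            # plain least-squares fit on the retained points
            params = self._solve(conc, obs, robust=self.reject_outliers)
            self.converged_ = True
        except RuntimeError as exc:  # non-convergence is a result, not a crash
            params = (0.1, float(np.median(conc)), 2.0)
            self.converged_ = False
            self.diagnostics_ = str(exc)
        self.first_pass_params_ = params

        mask = np.zeros(conc.size, dtype=bool)
        if self.converged_ and self.reject_outliers:
            resid = np.abs(obs - gr_model(conc, *params))
            mask = (resid > RESID_FACTOR * resid.mean()) & (resid > RESID_FLOOR)
            if mask.all():
                raise DegenerateFitError("outlier rule rejected every point")
        if self.converged_:
            try:
                params = self._solve(conc[~mask], obs[~mask])
            except RuntimeError as exc:
                self.converged_ = False
                self.diagnostics_ = str(exc)
        self.outlier_mask_ = mask
        self.grinf_, self.gec50_, self.h_ = params
        self.fitted_ = gr_model(conc, *params)
        return self

    def predict(self, X):
        """Fitted NOGR at concentrations ``X`` (nM)."""
        return gr_model(np.asarray(X, dtype=float), self.grinf_, self.gec50_, self.h_)

    # -- derived metrics ---------------------------------------------------
    def nogr50(self):
        """Concentration where the fitted curve equals 0.5, or None.

        Analytic inversion ``GEC50 * (0.5 / (0.5 - GRinf))^(1/h)``; the
        curve never reaches 0.5 when GRinf >= 0.5.
        """
        if self.grinf_ >= 0.5:
            return None
        return self.gec50_ * (0.5 / (0.5 - self.grinf_)) ** (1.0 / self.h_)

    def aoc(self, c_min=None, c_max=None):
        """Normalized area over the fitted curve on the tested log10 range."""
        if c_min is None:
            c_min = float(self.concentrations_.min())
        if c_max is None:
            c_max = float(self.concentrations_.max())
        return aoc_normalized(self.grinf_, self.gec50_, self.h_, c_min, c_max)


@dataclass
class DoseResponseFit:
    """Fit result for one line x drug (x replicate)."""

    line_id: str
    drug: str
    concentrations: np.ndarray
    observed: np.ndarray
    GRinf: float
    GEC50: float
    h_GR: float
    outlier_mask: np.ndarray
    fitted: np.ndarray
    NOGR50: float | None
    AOC_n: float
    converged: bool
    replicate_id: str = ""
    diagnostics: str | None = None
    first_pass_params: tuple = field(default=None, repr=False)

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())


def fit_curve(
    concentrations,
    observed,
    line_id="",
    drug="",
    replicate_id="",
    c_min=None,
    c_max=None,
) -> DoseResponseFit:
    """Fit one dose-response curve; thin wrapper over :class:`GRDoseResponse`."""
    est = GRDoseResponse().fit(concentrations, observed)
    n50 = est.nogr50() if est.converged_ else None
    return DoseResponseFit(
        line_id=line_id,
        drug=drug,
        concentrations=est.concentrations_,
        observed=est.observed_,
        GRinf=est.grinf_,
        GEC50=est.gec50_,
        h_GR=est.h_,
        outlier_mask=est.outlier_mask_,
        fitted=est.fitted_,
        NOGR50=n50,
        AOC_n=est.aoc(c_min, c_max) if est.converged_ else float("nan"),
        converged=est.converged_,
        replicate_id=replicate_id,
        diagnostics=est.diagnostics_,
        first_pass_params=est.first_pass_params_,
    )


def nogr50(fit: DoseResponseFit):
    """Concentration at which the fitted curve equals 0.5 (None if never)."""
    if fit.GRinf >= 0.5:
        return None
    return fit.GEC50 * (0.5 / (0.5 - fit.GRinf)) ** (1.0 / fit.h_GR)


def aoc_normalized(grinf, gec50, h_gr, c_min, c_max):
    """Area over the fitted curve up to y = 1 on log10 dose, normalized.

    ``integral of (1 - GR(c)) d log10 c`` over ``[c_min, c_max]`` divided by
    ``2 * (log10 c_max - log10 c_min)`` (the maximum area given the NOGR
    floor of -1), clipped to [0, 1].
    """
    if not (0 < c_min < c_max):
        raise ValueError("require 0 < c_min < c_max")
    lo, hi = math.log10(c_min), math.log10(c_max)
    val, _ = integrate.quad(
        lambda u: 1.0 - gr_model(10.0**u, grinf, gec50, h_gr), lo, hi, limit=200
    )
    return float(np.clip(val / (2.0 * (hi - lo)), 0.0, 1.0))


def fit_screen(nogr_df: pd.DataFrame, timepoint_h=None) -> pd.DataFrame:
    """Fit monotherapy curves for every line x drug x plate (replicate).

    Takes the per-well NOGR table from :func:`grscreen.growth.nogr_table`,
    restricts to single-agent treated wells at the final (or given)
    timepoint, and fits one curve per plate replicate.  Returns one row per
    fit with parameters, NOGR50, AOC_n and the outlier count; the mean
    AOC_n per line x drug across replicates is what downstream
    classification consumes.
    """
    df = nogr_df[nogr_df["role"] == "treated"]
    t = timepoint_h if timepoint_h is not None else df["timepoint_h"].max()
    df = df[df["timepoint_h"] == t]
    mono = df[(df["conc1_nM"] > 0) & (df["conc2_nM"] == 0)]
    rows = []
    for (line, drug, plate), grp in mono.groupby(
        ["line_id", "drug1", "plate_id"], sort=True
    ):
        fit = fit_curve(
            grp["conc1_nM"].to_numpy(),
            grp["NOGR"].to_numpy(),
            line_id=line,
            drug=drug,
            replicate_id=str(plate),
        )
        rows.append(
            {
                "line_id": line,
                "drug": drug,
                "replicate_id": str(plate),
                "GRinf": fit.GRinf,
                "GEC50_nM": fit.GEC50,
                "h_GR": fit.h_GR,
                "NOGR50_nM": fit.NOGR50 if fit.NOGR50 is not None else np.nan,
                "AOC_n": fit.AOC_n,
                "n_points": len(fit.observed),
                "n_outliers": fit.n_outliers,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TitrationDesign:
    """Logarithmic titration: geometric series rounded to integer nM."""

    low: float
    high: float
    n: int
    values: tuple

    def __iter__(self):
        return iter(self.values)


def log_titration(low, high, n) -> TitrationDesign:
    """Geometric dose series ``low * (high/low)^(k/(n-1))``, integer-rounded.

    Reproduces the screen's printed designs, e.g. ``log_titration(500, 3000,
    4)`` gives 500, 909, 1651, 3000 nM.
    """
    if not (0 < low < high):
        raise ValueError("require 0 < low < high")
    if n < 2:
        raise ValueError("need at least 2 points")
    ratio = (high / low) ** (1.0 / (n - 1))
    values = tuple(int(round(low * ratio**k)) for k in range(n))
    return TitrationDesign(low=low, high=high, n=n, values=values)


def clinical_conversion(value, mode):
    """Pharmacology unit conversions for auranofin exposure levels.

    ``gold_uM_to_AF_uM``: multiply a plasma gold concentration by gold's
    mass fraction of auranofin (Au 196.97 / 678.48 g/mol), reported to 2
    decimals.  ``AF_ug_per_ml_to_uM``: convert a mass concentration of
    auranofin to molarity, reported to 1 decimal.
    """
    if value <= 0:
        raise ValueError("concentration must be positive")
    if mode == "gold_uM_to_AF_uM":
        return round(value * GOLD_ATOMIC_MASS / AURANOFIN_MOLAR_MASS, 2)
    if mode == "AF_ug_per_ml_to_uM":
        # ug/ml == mg/l; dividing by g/mol gives mmol/l, x1000 -> uM
        return round(value / AURANOFIN_MOLAR_MASS * 1000.0, 1)
    raise ValueError(f"unknown conversion mode {mode!r}")


def exclusion_rate(n_excluded, n_total):
    """Outlier exclusion rate as a percentage rounded to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_excluded / n_total, 2)
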