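"""Growth-fraction and NOGR computation with control-based normalization.

Viability ``V`` is an image-derived area per well per timepoint.  The growth
fraction is ``G = (V(x) - V(0)) / V(0)``.  The normalized organoid growth
rate (NOGR) rescales ``G`` against the within-plate control wells so that

* ``NOGR = 1``  — growth as in the vehicle control,
* ``NOGR = 0``  — complete growth inhibition (stasis),
* ``NOGR = -1`` — killing as strong as the positive control.

Growing wells (``G > 0``) are normalized by the median vehicle ``G``;
shrinking wells (``G < 0``) by the magnitude of the median positive-control
``G``, so the positive control anchors exactly at -1.  The result is clipped
once to ``[-1, 1]``.  NNOGR is the affine rescaling of NOGR onto
``[0, 100]`` used as synergy-model input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ControlQCError, InvalidWellError

#: Columns of a long-format plate table, one row per well per timepoint.
PLATE_COLUMNS = [
    "plate_id",
    "well",
    "line_id",
    "timepoint_h",
    "drug1",
    "conc1_nM",
    "drug2",
    "conc2_nM",
    "role",
    "viability",
]

ROLES = ("treated", "vehicle", "positive_control")


@dataclass(frozen=True)
class GrowthResult:
    """NOGR of one well with the normalization branch that produced it."""

    G: float
    NOGR: float
    NNOGR: float
    branch: str  # "growth" | "killing" | "stasis"


def growth_fraction(v0: float, vx: float) -> float:
    """Relative viability change from timepoint 0: ``(vx - v0) / v0``.

    Raises
    ------
    InvalidWellError
        If ``v0 <= 0`` (a segmentation failure; such wells are excluded
        rather than imputed).
    """
    if v0 <= 0:
        raise InvalidWellError(f"baseline viability must be positive, got {v0}")
    return (vx - v0) / v0


def nogr(g_drug: float, g_med_neg: float, g_med_pos: float) -> float:
    """Normalize a growth fraction against the plate controls.

    Parameters
    ----------
    g_drug : growth fraction of the treated well.
    g_med_neg : median growth fraction of the vehicle wells (must be > 0).
    g_med_pos : median growth fraction of the positive-control wells
        (must be < 0).

    Returns the NOGR value clipped to ``[-1, 1]``.
    """
    if g_med_neg <= 0:
        raise ControlQCError(f"vehicle control failed: median G = {g_med_neg}")
    if g_med_pos >= 0:
        raise ControlQCError(f"positive control failed: median G = {g_med_pos}")
    if g_drug > 0:
        value = g_drug / g_med_neg
    elif g_drug < 0:
        # |g_med_pos| so that the positive control anchors at -1, matching
        # the classification endpoint "complete killing as in positive
        # control".
        value = g_drug / abs(g_med_pos)
    else:
        value = 0.0
    return float(np.clip(value, -1.0, 1.0))


def nogr_branch(g_drug: float) -> str:
    if g_drug > 0:
        return "growth"
    if g_drug < 0:
        return "killing"
    return "stasis"


def nnogr(nogr_value: float) -> float:
    """Rescale NOGR from ``[-1, 1]`` onto ``[0, 100]``: ``(NOGR + 1) * 50``."""
    if not -1.0 <= nogr_value <= 1.0:
        raise ValueError(f"NOGR must lie in [-1, 1], got {nogr_value}")
    return (nogr_value + 1.0) * 50.0


def nnogr_inverse(nnogr_value: float) -> float:
    """Inverse of :func:`nnogr`: ``NNOGR / 50 - 1``."""
    if not 0.0 <= nnogr_value <= 100.0:
        raise ValueError(f"NNOGR must lie in [0, 100], got {nnogr_value}")
    return nnogr_value / 50.0 - 1.0


def growth_result(g_drug: float, g_med_neg: float, g_med_pos: float) -> GrowthResult:
    """Bundle G, NOGR, NNOGR and the branch for one well."""
    value = nogr(g_drug, g_med_neg, g_med_pos)
    return GrowthResult(
        G=g_drug, NOGR=value, NNOGR=nnogr(value), branch=nogr_branch(g_drug)
    )


def _validate_plate(plate: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")


def control_qc(plate: pd.DataFrame) -> pd.DataFrame:
    """Per plate x line control summary with pass/fail flags.

    For every (plate_id, line_id) the median growth fraction of the vehicle
    and positive-control wells at each post-baseline timepoint is computed.
    A group passes when the vehicle median is positive and the
    positive-control median negative (the preconditions of :func:`nogr`).

    Raises
    ------
    ControlQCError
        If a plate x line lacks a vehicle or positive-control group.
    """
    _validate_plate(plate)
    growth = _well_growth(plate)
    rows = []
    for (plate_id, line_id, t), grp in growth.groupby(
        ["plate_id", "line_id", "timepoint_h"], sort=True
    ):
        veh = grp.loc[grp["role"] == "vehicle", "G"]
        pos = grp.loc[grp["role"] == "positive_control", "G"]
        if veh.empty or pos.empty:
            raise ControlQCError(
                f"plate {plate_id!r} line {line_id!r}: missing "
                f"{'vehicle' if veh.empty else 'positive-control'} wells"
            )
        g_med_neg = float(veh.median())
        g_med_pos = float(pos.median())
        rows.append(
            {
                "plate_id": plate_id,
                "line_id": line_id,
                "timepoint_h": t,
                "g_med_neg": g_med_neg,
                "g_med_pos": g_med_pos,
                "vehicle_ok": g_med_neg > 0,
                "positive_ok": g_med_pos < 0,
                "qc_pass": g_med_neg > 0 and g_med_pos < 0,
            }
        )
    return pd.DataFrame(rows)


def _well_growth(plate: pd.DataFrame) -> pd.DataFrame:
    """Growth fraction per well per post-baseline timepoint.

    Wells with baseline viability <= 0 are dropped (listed in the
    ``excluded_wells`` attribute of the result).
    """
    base = plate[plate["timepoint_h"] == 0].set_index(["plate_id", "well"])[
        "viability"
    ]
    later = plate[plate["timepoint_h"] > 0].copy()
    v0 = base.reindex(pd.MultiIndex.from_frame(later[["plate_id", "well"]]))
    later["v0"] = v0.to_numpy()
    bad = later["v0"].isna() | (later["v0"] <= 0)
    excluded = later.loc[bad, ["plate_id", "well"]].drop_duplicates()
    later = later[~bad].copy()
    later["G"] = (later["viability"] - later["v0"]) / later["v0"]
    later.attrs["excluded_wells"] = excluded
    return later


def nogr_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well NOGR at every post-baseline timepoint.

    Control medians are taken within plate x line x timepoint (never across
    plates).  Output columns: the plate schema minus viability, plus ``G``,
    ``NOGR``, ``NNOGR`` and ``branch``.
    """
    _validate_plate(plate)
    growth = _well_growth(plate)
    qc = control_qc(plate).set_index(["plate_id", "line_id", "timepoint_h"])
    out = growth.merge(
        qc.reset_index()[
            ["plate_id", "line_id", "timepoint_h", "g_med_neg", "g_med_pos"]
        ],
        on=["plate_id", "line_id", "timepoint_h"],
        how="left",
    )
    records = []
    for row in out.itertuples(index=False):
        res = growth_result(row.G, row.g_med_neg, row.g_med_pos)
        records.append((res.NOGR, res.NNOGR, res.branch))
    out[["NOGR", "NNOGR", "branch"]] = pd.DataFrame(records, index=out.index)
    cols = [
        "plate_id",
        "well",
        "line_id",
        "timepoint_h",
        "drug1",
        "conc1_nM",
        "drug2",
        "conc2_nM",
        "role",
        "G",
        "NOGR",
        "NNOGR",
        "branch",
    ]
    result = out[cols].sort_values(
        ["plate_id", "line_id", "timepoint_h", "well"], kind="mergesort"
    )
    result = result.reset_index(drop=True)
    result.attrs["excluded_wells"] = growth.attrs["excluded_wells"]
    return result
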