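"""Pipeline orchestration: growth -> fit -> synergy -> classify -> biomarker.

``run_pipeline`` takes a :class:`PipelineConfig` (or the equivalent YAML via
the CLI), executes the stages in order and writes one CSV per stage plus a
machine-readable JSON report.  Every output carries the seed and a hash of
the configuration so identical runs are byte-identical and attributable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datagen, growth, io, synergy
from .biomarker import build_signatures, genewise_correlation
from .classify import classify_lines
from .doseresponse import fit_screen
from .errors import GrscreenError

log = logging.getLogger("grscreen")


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run.

    Either ``plate_csv`` points at an existing plate table or ``simulate``
    is true and a synthetic screen is generated (``n_lines`` /
    ``n_library`` trim the default design).  ``expression_tsv`` is optional;
    when absent (and not simulated) the biomarker stage is skipped.
    """

    outdir: str = "grscreen_out"
    seed: int = 0
    simulate: bool = True
    n_lines: int | None = None
    n_library: int | None = None
    plate_csv: str | None = None
    expression_tsv: str | None = None
    simulate_expression: bool = True
    n_genes: int = 1000
    n_pos: int = 50
    n_neg: int = 50
    expression_noise_sd: float = 0.5
    signature_cutoff: float = 0.01
    synergy_models: tuple = synergy.MODELS
    anchor_drug: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v for k, v in vars(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except GrscreenError as exc:
                raise GrscreenError(f"stage {name}: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def _synergy_matrices(nogr_df: pd.DataFrame, anchor: str):
    """Assemble one NNOGR grid per line x library drug from the well table."""
    t = nogr_df["timepoint_h"].max()
    df = nogr_df[(nogr_df["timepoint_h"] == t) & (nogr_df["role"] == "treated")]
    # mean NNOGR across plates (replicates) per condition
    agg = (
        df.groupby(["line_id", "drug1", "conc1_nM", "drug2", "conc2_nM"])["NNOGR"]
        .mean()
        .reset_index()
    )
    out = []
    combos = agg[(agg["drug1"] == anchor) & (agg["drug2"] != "")]
    for (line, drug2), grp in combos.groupby(["line_id", "drug2"], sort=True):
        row_doses = np.sort(grp["conc1_nM"].unique())
        col_doses = np.sort(grp["conc2_nM"].unique())
        mono_a = agg[
            (agg["line_id"] == line) & (agg["drug1"] == anchor) & (agg["drug2"] == "")
        ].set_index("conc1_nM")["NNOGR"]
        mono_b = agg[
            (agg["line_id"] == line) & (agg["drug1"] == drug2) & (agg["drug2"] == "")
        ].set_index("conc1_nM")["NNOGR"]
        if mono_a.empty or mono_b.empty:
            log.warning("line %s pair (%s, %s): missing monotherapy, skipped",
                        line, anchor, drug2)
            continue
        nr, nc = row_doses.size + 1, col_doses.size + 1
        grid = np.empty((nr, nc))
        grid[0, 0] = 100.0  # untreated reference
        for i, da in enumerate(row_doses):
            grid[i + 1, 0] = np.clip(mono_a.get(da, np.nan), 0, 100)
        for j, db in enumerate(col_doses):
            grid[0, j + 1] = np.clip(mono_b.get(db, np.nan), 0, 100)
        cell = grp.set_index(["conc1_nM", "conc2_nM"])["NNOGR"]
        for i, da in enumerate(row_doses):
            for j, db in enumerate(col_doses):
                grid[i + 1, j + 1] = np.clip(cell.get((da, db), np.nan), 0, 100)
        if np.isnan(grid).any():
            log.warning("line %s pair (%s, %s): incomplete grid, skipped",
                        line, anchor, drug2)
            continue
        out.append(
            synergy.SynergyMatrix(
                line_id=line,
                drug_row=anchor,
                drug_col=drug2,
                row_doses=np.concatenate([[0.0], row_doses]),
                col_doses=np.concatenate([[0.0], col_doses]),
                response=grid,
            )
        )
    return out


@_stage("synergy")
def run_synergy(nogr_df, anchor, models):
    matrices = [
        synergy.score_all(m, models=models) for m in _synergy_matrices(nogr_df, anchor)
    ]
    rows = []
    for m in matrices:
        for model in models:
            rows.append(
                {
                    "line_id": m.line_id,
                    "drug_row": m.drug_row,
                    "drug_col": m.drug_col,
                    "model": model,
                    "score": m.scores[model],
                    "classification": synergy.classify_interaction(m.scores[model]),
                    "css": m.css,
                }
            )
    return matrices, pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the in-memory result bundle.

    Output files land in ``config.outdir``: ``plate.csv``, ``nogr.csv``,
    ``fits.csv``, ``synergy.csv`` (+ ``synergy_deltas.json``),
    ``classification.csv``, ``correlations.csv``, ``signatures.gmt`` and
    ``report.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash()}
    results: dict = {"meta": meta}

    # --- input / simulation ------------------------------------------------
    if config.plate_csv:
        plate = io.read_plate_table(config.plate_csv)
        design = None
    elif config.simulate:
        design = datagen.default_design(config.n_lines, config.n_library)
        truth = datagen.default_truth(design, seed=config.seed)
        plate = datagen.simulate_plate(design, truth)
        io.write_json(
            {
                "baseline_g": truth.baseline_g,
                "gr_params": {f"{k[0]}|{k[1]}": v for k, v in truth.gr_params.items()},
                "noise_sd": truth.noise_sd,
                "outlier_rate": truth.outlier_rate,
                "seed": truth.seed,
                "outlier_wells": plate.attrs["outlier_wells"],
            },
            outdir / "truth.json",
        )
    else:
        raise GrscreenError("config provides neither plate_csv nor simulate=True")
    io.write_plate_table(plate, outdir / "plate.csv")

    anchor = config.anchor_drug or (
        design.anchor if design is not None else sorted(plate.loc[plate["drug2"] != "", "drug1"].unique())[0]
    )

    # --- growth ------------------------------------------------------------
    nogr_df = _stage("growth")(growth.nogr_table)(plate)
    excluded = nogr_df.attrs.get("excluded_wells")
    if excluded is not None and len(excluded):
        log.info("excluded %d wells with invalid baseline", len(excluded))
    nogr_df.to_csv(outdir / "nogr.csv", index=False, float_format=io.FLOAT_FORMAT)
    results["nogr"] = nogr_df

    # --- dose-response fits --------------------------------------------------
    fits = _stage("fit")(fit_screen)(nogr_df)
    fits.to_csv(outdir / "fits.csv", index=False, float_format=io.FLOAT_FORMAT)
    results["fits"] = fits

    # --- synergy -------------------------------------------------------------
    matrices, scores = run_synergy(nogr_df, anchor, config.synergy_models)
    scores.to_csv(outdir / "synergy.csv", index=False, float_format=io.FLOAT_FORMAT)
    io.write_json(
        {
            f"{m.line_id}|{m.drug_row}|{m.drug_col}": {
                model: m.delta_grid[model] for model in config.synergy_models
            }
            for m in matrices
        },
        outdir / "synergy_deltas.json",
    )
    results["synergy"] = scores
    results["matrices"] = matrices

    # --- classification --------------------------------------------------------
    anchor_fits = fits[(fits["drug"] == anchor) & fits["converged"]]
    aoc_by_line = anchor_fits.groupby("line_id")["AOC_n"].mean().to_dict()
    classification = _stage("classify")(classify_lines)(aoc_by_line)
    classification.to_csv(
        outdir / "classification.csv", index=False, float_format=io.FLOAT_FORMAT
    )
    results["classification"] = classification

    # --- biomarker ---------------------------------------------------------------
    expr = None
    if config.expression_tsv:
        expr = io.read_expression(config.expression_tsv)
    elif config.simulate_expression and config.simulate:
        expr = datagen.simulate_expression(
            aoc_by_line,
            n_genes=config.n_genes,
            n_pos=config.n_pos,
            n_neg=config.n_neg,
            noise_sd=config.expression_noise_sd,
            seed=config.seed,
        )
        io.write_expression(expr, outdir / "expression.tsv")
    if expr is None:
        log.info("no expression matrix: biomarker stage skipped")
        results["signatures"] = None
    else:
        cors = _stage("biomarker")(genewise_correlation)(expr, aoc_by_line)
        cors.to_csv(outdir / "correlations.csv", float_format=io.FLOAT_FORMAT,
                    index_label="gene")
        sig = build_signatures(cors, cutoff=config.signature_cutoff)
        io.write_gmt({"PCGS": sig.pcgs, "NCGS": sig.ncgs}, outdir / "signatures.gmt",
                     description=f"p<{config.signature_cutoff}")
        results["correlations"] = cors
        results["signatures"] = sig

    write_report(results, outdir / "report.json")
    return results


def write_report(results: dict, path) -> None:
    """Machine-readable JSON summary of a (possibly partial) result bundle."""
    report = {"meta": results.get("meta", {})}
    fits = results.get("fits")
    if fits is not None and len(fits):
        report["fits"] = {
            "n_fits": int(len(fits)),
            "n_outliers": int(fits["n_outliers"].sum()),
            "n_points": int(fits["n_points"].sum()),
        }
    cls = results.get("classification")
    if cls is not None and len(cls):
        report["classification"] = {
            row.line_id: {"aoc": row.aoc, "group": row.group}
            for row in cls.itertuples()
        }
        report["boundaries"] = {"p33": float(cls["p33"].iloc[0]),
                                "p66": float(cls["p66"].iloc[0])}
    syn = results.get("synergy")
    if syn is not None and len(syn):
        report["synergy"] = [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in rec.items()}
            for rec in syn.to_dict(orient="records")
        ]
    sig = results.get("signatures")
    if sig is not None:
        report["signatures"] = {
            "n_positive": sig.n_positive,
            "n_negative": sig.n_negative,
            "cutoff": sig.cutoff,
        }
    io.write_json(report, path)
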