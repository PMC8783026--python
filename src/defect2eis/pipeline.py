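"""End-to-end studies: detection accuracy vs spectral deviation, and fitting.

`run_accuracy_study` reproduces the core numerical experiment of the
pipeline: degrade a true defect set over a grid of (n_remove, n_add) cases,
model the EIS spectrum of the truth and of every degraded set, and tabulate
detection accuracy (F1, Q_N) against spectral-feature deviations
(Delta f_log, Delta argY).  `run_fit_study` runs the (r_def, rho_sub) grid
search for a true and a predicted defect set against a common reference
spectrum and reports both recoveries side by side.

Both entry points write a YAML manifest (inputs, seeds, package version)
sufficient to reproduce their outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defect_sets import DefectSet, defect_density, voronoi_sigma
from .degradation_sim import case_grid, generate_batch
from .eis_model import (
    EISSpectrum,
    FrequencyGrid,
    MembraneParams,
    MeshParams,
    compare_spectra,
    model_spectrum,
)
from .param_fit import FitGrid, FitResult, fit

log = logging.getLogger("defect2eis")

#: F1 bands used when summarising systematic spectral shifts.
DEFAULT_F1_BANDS = ((0.5, 0.6), (0.6, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 0.95), (0.95, 1.0))


@dataclasses.dataclass(frozen=True)
class AccuracyStudyConfig:
    """Configuration of one accuracy study run."""

    seed: int
    s: float = 4.0
    bandwidth: float = 400.0
    cases: tuple[tuple[int, int], ...] | None = None
    mp: MembraneParams = MembraneParams()
    fg: FrequencyGrid | None = None
    mesh: MeshParams = MeshParams()
    iou_threshold: float = 0.5
    f1_bands: tuple[tuple[float, float], ...] = DEFAULT_F1_BANDS


def run_accuracy_study(
    true_set: DefectSet, config: AccuracyStudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every degradation case by detection metrics and spectral deviation.

    Returns ``(table, summary)``: one row per case with columns
    ``n_remove, n_add, precision, recall, f1, q_n, sigma, delta_f_log,
    delta_arg_y``, and the per-F1-band mean/SD summary of the deviations.
    """
    fg = config.fg if config.fg is not None else FrequencyGrid.logspaced()
    cases = list(config.cases) if config.cases is not None else case_grid(len(true_set))
    log.info("accuracy study: N=%d, %d cases", len(true_set), len(cases))
    true_spectrum = model_spectrum(true_set, config.mp, fg, config.mesh)
    rows = []
    for i, case in enumerate(
        generate_batch(
            true_set,
            config.seed,
            s=config.s,
            bandwidth=config.bandwidth,
            cases=cases,
            iou_threshold=config.iou_threshold,
        )
    ):
        try:
            pred_spectrum = model_spectrum(case.defect_set, config.mp, fg, config.mesh)
            delta = compare_spectra(true_spectrum, pred_spectrum)
            d_f_log, d_arg_y = delta.delta_f_log, delta.delta_arg_y
        except Exception:
            log.exception(
                "case %d (n_remove=%d, n_add=%d) failed",
                i, case.params.n_remove, case.params.n_add,
            )
            raise
        rows.append(
            {
                "case": i,
                "n_remove": case.params.n_remove,
                "n_add": case.params.n_add,
                "precision": case.metrics.precision,
                "recall": case.metrics.recall,
                "f1": case.metrics.f1,
                "q_n": case.metrics.q_n,
                "sigma": case.sigma,
                "delta_f_log": d_f_log,
                "delta_arg_y": d_arg_y,
            }
        )
    table = pd.DataFrame(rows)
    summary = summarize_by_f1_band(table, config.f1_bands)
    return table, summary


def summarize_by_f1_band(
    table: pd.DataFrame,
    bands: tuple[tuple[float, float], ...] = DEFAULT_F1_BANDS,
) -> pd.DataFrame:
    """Mean and SD of the spectral deviations within each F1 band (inclusive edges)."""
    rows = []
    for lo, hi in bands:
        sel = table[(table["f1"] >= lo) & (table["f1"] <= hi)]
        rows.append(
            {
                "f1_lo": lo,
                "f1_hi": hi,
                "n_cases": len(sel),
                "mean_delta_f_log": sel["delta_f_log"].mean(),
                "sd_delta_f_log": sel["delta_f_log"].std(),
                "mean_delta_arg_y": sel["delta_arg_y"].mean(),
                "sd_delta_arg_y": sel["delta_arg_y"].std(),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class FitStudyResult:
    true_fit: FitResult
    pred_fit: FitResult


def run_fit_study(
    true_set: DefectSet,
    pred_set: DefectSet,
    reference: EISSpectrum,
    grid: FitGrid = FitGrid(),
    mp_base: MembraneParams = MembraneParams(),
    fg: FrequencyGrid | None = None,
    mesh: MeshParams = MeshParams(),
) -> FitStudyResult:
    """Grid-fit the true and the predicted defect set against one reference."""
    log.info("fit study: grid of %d combinations", len(grid.r_values) * len(grid.rho_exponents))
    true_fit = fit(true_set, reference, grid, mp_base, fg, mesh)
    pred_fit = fit(pred_set, reference, grid, mp_base, fg, mesh)
    return FitStudyResult(true_fit=true_fit, pred_fit=pred_fit)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(out_dir: str | Path, name: str, payload: dict) -> Path:
    """Write a reproducibility manifest (inputs, seeds, version, content hash)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    body = dict(payload)
    body["package_version"] = __version__
    digest = hashlib.sha256(
        json.dumps(body, sort_keys=True, default=str).encode()
    ).hexdigest()
    body["config_sha256"] = digest
    path = out_dir / f"{name}.manifest.yaml"
    path.write_text(yaml.safe_dump(body, sort_keys=False))
    return path


def describe_set(defect_set: DefectSet) -> dict:
    """Headline statistics of a defect set (N, density, sigma when defined)."""
    stats = {
        "n": len(defect_set),
        "density_per_um2": defect_density(defect_set),
        "field_nm": [defect_set.field_width, defect_set.field_height],
        "label": defect_set.label,
    }
    if len(defect_set) >= 3:
        stats["sigma"] = voronoi_sigma(defect_set)
    return stats
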