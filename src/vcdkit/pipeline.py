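"""End-to-end driver: dedup, selection, weighting, spectra, comparison.

``run_pipeline`` consumes precomputed quantum-chemistry outputs (a
multi-XYZ ensemble, an energy table, per-conformer frequency tables,
optionally experimental spectra) and executes the post-processing
protocol:

1. energy-window selection (default 2.5 kcal/mol, single-point energies),
2. duplicate removal (energy / RMSD / rotational-constant criteria),
3. Boltzmann weighting (Gibbs free energies by default),
4. Lorentzian-broadened ensemble IR and VCD spectra,
5. optional overlap comparison with experimental spectra, including the
   frequency-scaling search.

Every run writes a JSON manifest with all parameters and the conformer
bookkeeping (found >= within window >= unique >= significant), so a run
is reproducible from its manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .dedup import DedupThresholds, prune_duplicates
from .errors import VCDKitError
from .io import (
    attach_energies,
    frequency_table_to_sticks,
    read_energy_csv,
    read_experimental,
    read_frequency_table,
    read_multixyz,
    write_spectrum,
)
from .similarity import DEFAULT_F_RANGE, ComparisonResult, optimize_scaling, overlap_estimate
from .spectra import DEFAULT_FWHM, ensemble_spectrum, match_intensity
from .thermo import boltzmann_weights, energy_window_filter, significant_conformers

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All parameters and paths of one pipeline run."""

    xyz_path: Path
    energy_csv: Optional[Path] = None
    freq_dir: Optional[Path] = None
    freq_dialect: str = "tsv"
    exp_ir: Optional[Path] = None
    exp_vcd: Optional[Path] = None
    outdir: Path = Path("vcdkit_out")

    window: float = 2.5  # kcal/mol
    window_energy_field: str = "electronic"
    weight_energy_field: str = "gibbs"
    temperature: float = 298.15  # K
    thresholds: DedupThresholds = field(default_factory=DedupThresholds)
    dedup_energy_field: str = "electronic"
    fwhm: float = DEFAULT_FWHM  # cm^-1
    region: tuple[float, float] = (1500.0, 1800.0)
    f_range: tuple[float, float, float] = DEFAULT_F_RANGE
    significance_cutoff: float = 0.05
    restrict_to_significant: bool = False
    grid_step: float = 1.0

    def validate(self) -> None:
        if not (self.window > 0 and self.temperature > 0 and self.fwhm > 0):
            raise VCDKitError("window, temperature and fwhm must be positive")
        if not 0 <= self.significance_cutoff < 1:
            raise VCDKitError("significance cutoff must be in [0, 1)")

    def to_dict(self) -> dict:
        d = {
            "xyz_path": str(self.xyz_path),
            "energy_csv": str(self.energy_csv) if self.energy_csv else None,
            "freq_dir": str(self.freq_dir) if self.freq_dir else None,
            "freq_dialect": self.freq_dialect,
            "exp_ir": str(self.exp_ir) if self.exp_ir else None,
            "exp_vcd": str(self.exp_vcd) if self.exp_vcd else None,
            "outdir": str(self.outdir),
            "window_kcal": self.window,
            "window_energy_field": self.window_energy_field,
            "weight_energy_field": self.weight_energy_field,
            "dedup_energy_field": self.dedup_energy_field,
            "temperature_K": self.temperature,
            "thresholds": {
                "energy_kcal": self.thresholds.energy_thr,
                "rmsd_A": self.thresholds.rmsd_thr,
                "rotconst_rel": self.thresholds.rotconst_rel_thr,
            },
            "fwhm_cm": self.fwhm,
            "region_cm": list(self.region),
            "f_range": list(self.f_range),
            "significance_cutoff": self.significance_cutoff,
            "restrict_to_significant": self.restrict_to_significant,
            "grid_step_cm": self.grid_step,
        }
        return d


class StageError(VCDKitError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> tuple[Optional[ComparisonResult], dict]:
    """Execute the full post-processing protocol; returns (comparison, manifest).

    All artifacts are written under ``config.outdir``; on any stage error
    partially written artifacts are removed and a stage-tagged
    :class:`StageError` is raised.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        return _run(config, emit)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError("pipeline", exc) from exc


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def _run(config: RunConfig, emit) -> tuple[Optional[ComparisonResult], dict]:
    # --- read inputs -----------------------------------------------------
    @_stage("read")
    def read_inputs():
        ensemble = read_multixyz(config.xyz_path)
        if config.energy_csv:
            records = read_energy_csv(config.energy_csv)
            ensemble = attach_energies(ensemble, records, warn=logger.warning)
        return ensemble

    ensemble = read_inputs()
    n_found = len(ensemble)

    # --- energy window (single-point energies, Table-3-style bookkeeping) -
    @_stage("window")
    def window(ens):
        return energy_window_filter(ens, config.window, config.window_energy_field)

    selected = window(ensemble)
    n_window = len(selected)

    # --- duplicate removal ------------------------------------------------
    @_stage("dedup")
    def dedup(ens):
        return prune_duplicates(ens, config.thresholds, config.dedup_energy_field)

    unique, report = dedup(selected)
    n_unique = len(unique)
    report_rows = [
        {"label": lab, "status": "kept", "match": "", "dE_kcal": "", "rmsd_A": "", "dB_rel": ""}
        for lab in report.kept
    ] + [
        {
            "label": lab,
            "status": "removed",
            "match": match,
            "dE_kcal": f"{m.delta_e:.6f}",
            "rmsd_A": f"{m.rmsd:.6f}",
            "dB_rel": f"{m.max_rel_rotconst:.6f}",
        }
        for lab, match, m in report.removed
    ]
    pd.DataFrame(report_rows).to_csv(emit("dedup_report.csv"), index=False)

    # --- Boltzmann weights ------------------------------------------------
    @_stage("weights")
    def weigh(ens):
        return boltzmann_weights(ens, config.weight_energy_field, config.temperature)

    weights = weigh(unique)
    significant = significant_conformers(weights, config.significance_cutoff)
    n_significant = len(significant)
    weights.to_frame().to_csv(emit("weights.csv"), index=False)

    averaged_labels = weights.labels
    if config.restrict_to_significant:
        @_stage("weights")
        def truncate():
            from .ensemble import Ensemble

            keep = [c for c in unique if c.label in significant]
            return boltzmann_weights(
                Ensemble(conformers=keep), config.weight_energy_field, config.temperature
            )

        weights = truncate()
        averaged_labels = weights.labels

    # --- ensemble spectra -------------------------------------------------
    comparison: Optional[ComparisonResult] = None
    spectra_meta: dict = {}
    if config.freq_dir:
        @_stage("spectra")
        def build_spectra():
            tables = {}
            for lab in averaged_labels:
                path = Path(config.freq_dir) / f"freq_{lab}.tsv"
                tables[lab] = read_frequency_table(
                    path, dialect=config.freq_dialect, conformer_label=lab
                )
            ir_sticks = [frequency_table_to_sticks(tables[lab], "IR") for lab in averaged_labels]
            vcd_sticks = [frequency_table_to_sticks(tables[lab], "VCD") for lab in averaged_labels]
            pad = 5.0 * config.fwhm
            lo, hi = min(config.region), max(config.region)
            grid_spec = (max(lo - pad, config.grid_step), hi + pad, config.grid_step)
            ir = ensemble_spectrum(ir_sticks, weights, fwhm=config.fwhm, grid_spec=grid_spec)
            vcd = ensemble_spectrum(vcd_sticks, weights, fwhm=config.fwhm, grid_spec=grid_spec)
            return ir_sticks, vcd_sticks, ir, vcd

        ir_sticks, vcd_sticks, ir_spec, vcd_spec = build_spectra()
        write_spectrum(ir_spec, emit("calc_ir.txt"))
        write_spectrum(vcd_spec, emit("calc_vcd.txt"))
        stick_rows = []
        for sticks in ir_sticks + vcd_sticks:
            w = weights.weight_of(sticks.conformer_label)
            for f, s in zip(sticks.frequencies, sticks.strengths):
                stick_rows.append(
                    {
                        "modality": sticks.modality,
                        "frequency_cm": f,
                        "strength": s,
                        "conformer": sticks.conformer_label,
                        "weight": w,
                    }
                )
        pd.DataFrame(stick_rows).to_csv(emit("sticks.csv"), index=False)
        spectra_meta = {"fwhm_cm": config.fwhm, "n_averaged": len(averaged_labels)}

        # --- optional comparison with experiment --------------------------
        if config.exp_ir and config.exp_vcd:
            @_stage("compare")
            def compare():
                exp_ir = read_experimental(config.exp_ir, modality="IR")
                exp_vcd = read_experimental(config.exp_vcd, modality="VCD")
                result, scan = optimize_scaling(
                    ir_sticks,
                    vcd_sticks,
                    weights,
                    exp_ir,
                    exp_vcd,
                    region=config.region,
                    f_range=config.f_range,
                    fwhm=config.fwhm,
                    grid_step=config.grid_step,
                    return_scan=True,
                )
                _, factor = match_intensity(ir_spec, exp_ir)
                result.intensity_factor = factor
                return result, scan

            comparison, scan = compare()
            scan.to_csv(emit("scaling_scan.csv"), index=False)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "parameters": config.to_dict(),
        "counts": {
            "found": n_found,
            "within_window": n_window,
            "unique": n_unique,
            "significant": n_significant,
        },
        "kept_labels": [c.label for c in unique],
        "significant_labels": significant,
        "weights": {
            lab: round(float(w), 12) for lab, w in zip(weights.labels, weights.weights)
        },
        "spectra": spectra_meta,
        "comparison": comparison.to_dict() if comparison else None,
    }
    manifest_path = emit("manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return comparison, manifest
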