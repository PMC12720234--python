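"""End-to-end orchestration: energies -> scans -> (diabatize) -> fits -> cases.

The electronic-structure step is a hard boundary: the pipeline never invokes
a quantum-chemistry program. It consumes an energy table (produced by any
external engine, or by the synthetic generator), the equilibrium geometry
and, optionally, the modes file for the motion-type categorization, and
writes the per-mode metric, category, case and crossing tables plus a run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

import modescan
from modescan import classification, harmonicity, mode_character, mode_io, scan_model
from modescan.errors import ModescanError

logger = logging.getLogger("modescan")


@dataclass
class PipelineConfig:
    energies: str
    geometry: str | None = None
    modes: str | None = None
    unit: str = "eV"
    gap_threshold: float = scan_model.DEFAULT_GAP_THRESHOLD
    excitation_offset: str | float = "auto"   # "auto" or a fixed eV value
    k_sd: float = 1.0
    sd_convention: str = "sample"
    dominance: float = mode_character.DEFAULT_DOMINANCE
    outdir: str = "modescan_out"
    seed: int = 0
    log_level: str = "INFO"
    write_scans: bool = True

    def to_manifest(self) -> dict[str, Any]:
        return {
            "config": asdict(self),
            "versions": {
                "modescan": modescan.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }

    @classmethod
    def from_manifest(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data["config"])


@dataclass
class PipelineResult:
    scans: list[scan_model.ScanSet]
    crossings: dict[int, scan_model.CrossingReport | None]
    metrics: list[harmonicity.ModeMetrics]
    thresholds: classification.ThresholdSet
    cases: list[classification.CaseAssignment]
    categories: dict[int, mode_character.PedBreakdown] = field(default_factory=dict)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.metrics:
            rows.append({
                "mode": m.mode_index, "freq_cm1": m.frequency,
                "a_s0": m.fit_s0.a, "b_s0": m.fit_s0.b, "c_s0": m.fit_s0.c,
                "r2_s0": m.fit_s0.r2, "rmsd_s0": m.fit_s0.rmsd,
                "a_s1": m.fit_s1.a, "b_s1": m.fit_s1.b, "c_s1": m.fit_s1.c,
                "r2_s1": m.fit_s1.r2, "rmsd_s1": m.fit_s1.rmsd,
                "ratio_s0": m.rmsd_ratio_s0, "ratio_s1": m.rmsd_ratio_s1,
                "delta_a": m.delta_a, "delta_b": m.delta_b,
                "delta_rmsd": m.delta_rmsd, "delta_ratio": m.delta_rmsd_ratio,
                "lambda_eV": m.lamda, "diabatized": m.diabatized,
                "lambda_fallback": m.lambda_fallback,
            })
        return pd.DataFrame(rows)

    def cases_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            ped = self.categories.get(c.mode_index)
            rows.append({
                "mode": c.mode_index, "case": c.case_number,
                "s0_anharmonic": c.s0_anharmonic, "s1_excess": c.s1_excess_anharmonic,
                "fc_active": c.fc_active,
                "category": ped.category if ped is not None else "",
            })
        return pd.DataFrame(rows)

    def ped_frame(self) -> pd.DataFrame:
        rows = []
        for mode, ped in sorted(self.categories.items()):
            row = {"mode": mode, "category": ped.category}
            row.update({f"pct_{k.lower()}": v for k, v in ped.percentages.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def crossings_frame(self) -> pd.DataFrame:
        rows = []
        by_mode = {s.mode_index: s for s in self.scans}
        for mode, c in sorted(self.crossings.items()):
            if c is None:
                continue
            rows.append({
                "mode": mode,
                "crossing_index": c.crossing_index,
                "i_crossing": by_mode[mode].factors[c.crossing_index],
                "gap_min_eV": c.gap_min,
                "delta_E_CI_S1min_eV": c.delta_E_CI_S1min,
                "delta_E_CI_S1min_kcalmol": c.delta_E_CI_S1min * scan_model.EV_TO_KCALMOL,
                "swapped": c.swapped,
            })
        return pd.DataFrame(
            rows,
            columns=["mode", "crossing_index", "i_crossing", "gap_min_eV",
                     "delta_E_CI_S1min_eV", "delta_E_CI_S1min_kcalmol", "swapped"],
        )


def run_pipeline(config: PipelineConfig, energy_table: pd.DataFrame | None = None) -> PipelineResult:
    """Execute scan assembly, crossing handling, fitting, categorization and
    classification, writing all report tables under ``config.outdir``.

    *energy_table* may be passed directly (e.g., from the synthetic
    generator); otherwise it is read from ``config.energies``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if energy_table is None:
            sep = "\t" if str(config.energies).endswith((".tsv", ".txt")) else ","
            energy_table = pd.read_csv(config.energies, sep=sep)
        stage = "assemble"
        scans = scan_model.assemble_scans(energy_table, unit=config.unit)

        stage = "crossing"
        crossings: dict[int, scan_model.CrossingReport | None] = {}
        processed: list[scan_model.ScanSet] = []
        for scan in scans:
            report = None
            if "S1" in scan.energies and "S2" in scan.energies:
                report = scan_model.detect_crossing(scan, "S1", "S2", config.gap_threshold)
                if report is not None:
                    scan = scan_model.diabatize(scan, report)
            crossings[scan.mode_index] = report
            processed.append(scan)
        scans = processed

        stage = "fit"
        offset = None if config.excitation_offset == "auto" else float(config.excitation_offset)
        metrics = []
        for scan in scans:
            fits = {s: harmonicity.fit_quadratic(scan.factors, e) for s, e in scan.energies.items()}
            m = harmonicity.mode_metrics(scan, fits, excitation_offset=offset)
            metrics.append(m)

        stage = "character"
        categories: dict[int, mode_character.PedBreakdown] = {}
        if config.geometry and config.modes:
            geometry = mode_io.load_geometry(config.geometry)
            modeset = mode_io.load_modes(config.modes, geometry)
            coords = mode_character.perceive_topology(geometry)
            freq_by_mode = {m.index: m.frequency for m in modeset.modes}
            for m in metrics:
                if m.mode_index in freq_by_mode:
                    m.frequency = freq_by_mode[m.mode_index]
                    categories[m.mode_index] = mode_character.ped_percentages(
                        modeset, m.mode_index, coords, dominance=config.dominance
                    )

        stage = "classify"
        thresholds, cases = classification.classify_all(
            metrics, k_sd=config.k_sd, sd_convention=config.sd_convention
        )
    except ModescanError as exc:
        raise ModescanError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(
        scans=scans, crossings=crossings, metrics=metrics,
        thresholds=thresholds, cases=cases, categories=categories,
    )

    for m, c in zip(metrics, cases):
        logger.info(
            "mode %d: rmsd_s0=%.2e rmsd_s1=%.2e lambda=%.4f eV flags=(%d,%d,%d) case=%d%s",
            m.mode_index, m.fit_s0.rmsd, m.fit_s1.rmsd, m.lamda,
            c.s0_anharmonic, c.s1_excess_anharmonic, c.fc_active, c.case_number,
            " [diabatized]" if m.diabatized else "",
        )

    result.metrics_frame().to_csv(outdir / "metrics.csv", index=False)
    result.cases_frame().to_csv(outdir / "cases.csv", index=False)
    result.crossings_frame().to_csv(outdir / "crossings.csv", index=False)
    if categories:
        result.ped_frame().to_csv(outdir / "ped.csv", index=False)
    if config.write_scans:
        scan_model.scans_to_json(scans, crossings, outdir / "scans.json")

    manifest = config.to_manifest()
    manifest["thresholds"] = {
        "s0_anh": thresholds.s0_anh_threshold,
        "s1_excess": thresholds.s1_excess_threshold,
        "fc": thresholds.fc_threshold,
        "k_sd": thresholds.k_sd,
        "sd_convention": thresholds.sd_convention,
    }
    manifest["per_mode"] = {
        str(m.mode_index): {"diabatized": m.diabatized, "lambda_fallback": m.lambda_fallback}
        for m in metrics
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
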