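"""End-to-end waveband-optimization pipeline and the plain GA-PLS baseline.

Pipeline stages, in order:

1. split the samples (random testing holdout, SPXY calibration/validation)
   and scatter-correct every spectrum with SNV;
2. grid-search moving-window scan: PLS per admissible (N, S) waveband,
   ranked by validation RMSE; keep the top-k disjoint wavebands;
3. compress each kept waveband to latent principal components fitted on the
   calibration part;
4. genetic refinement of the component subset per waveband, scanning the
   crossover/mutation grid, and pick the waveband whose refined model has
   the lowest validation RMSE;
5. score the winning model on the untouched testing set.

The baseline mode runs a conventional GA-PLS over the raw wavelength flags
of the full spectrum (no window scan, no component compression) for
comparison on the same split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ga_engine import GAConfig, GATrace, derive_cell_seed, evolve, parametric_scan
from .lpc import LPCBasis, fit_lpc, project
from .partition import SplitIndices, split_dataset
from .regression import EvaluationReport, evaluate, fit_pls, max_components, predict
from .spectra import SpectralDataset, snv_transform
from .window_search import (GSMWResult, WindowGrid, WindowRecord,
                            gsmw_search, select_top_windows)

__all__ = ["FrameworkConfig", "WavebandResult", "FrameworkReport",
           "run_framework", "run_baseline_ga"]


@dataclass(frozen=True)
class FrameworkConfig:
    n_cal: int = 90
    n_val: int = 50
    n_test: int = 54
    split_seed: int = 0
    grid: WindowGrid = field(default_factory=lambda: WindowGrid.from_spec("1:1:100,110:10:300,320:20:700"))
    k: int = 5                       # disjoint top wavebands kept for refinement
    lv_cap: int = 15                 # latent-variable ceiling per window model
    lpc_max_components: int | None = None   # None -> keep all above rank tolerance
    crossover_pct_grid: tuple[float, ...] = (40.0, 50.0, 60.0)
    mutation_pct_grid: tuple[float, ...] = (0.8, 1.2, 1.5)
    ga_population: int | None = None        # None -> scaled to the input dimension
    ga_max_iterations: int = 500
    ga_stall_window: int = 20
    ga_stall_tolerance: float = 1e-6
    ga_seed: int = 0
    run_baseline: bool = False
    baseline_population: int = 50
    baseline_crossover_pct: float = 50.0
    baseline_mutation_pct: float = 1.2
    baseline_max_iterations: int = 500


@dataclass(frozen=True)
class WavebandResult:
    """One refined waveband: the window-stage and GA-stage outcomes."""

    record: WindowRecord              # pre-GA: best PLS window model
    basis: LPCBasis
    ga_config: GAConfig               # winning scan cell
    ga_trace: GATrace

    def row(self, axis) -> dict:
        w = self.record.window
        return {
            "start_nm": w.start_nm(axis),
            "end_nm": w.end_nm(axis),
            "S": w.S,
            "N": w.N,
            "n_lpc": self.basis.m,
            "pre_ga_rmsev": self.record.rmsev,
            "pre_ga_r_v": self.record.r_v,
            "post_ga_rmsev": self.ga_trace.best_rmsev,
            "post_ga_r_v": self.ga_trace.best_r_v,
            "crossover_pct": self.ga_config.p_crossover * 100.0,
            "mutation_pct": self.ga_config.p_mutation * 100.0,
            "stop_iteration": self.ga_trace.stop_iteration,
            "stop_reason": self.ga_trace.stop_reason,
            "n_selected_lpc": int(self.ga_trace.best_chromosome.sum()),
        }


@dataclass(frozen=True)
class FrameworkReport:
    config: FrameworkConfig
    split: SplitIndices
    gsmw: GSMWResult
    wavebands: tuple[WavebandResult, ...]
    best_index: int                   # index into wavebands
    validation: EvaluationReport
    testing: EvaluationReport
    baseline_testing: EvaluationReport | None = None

    @property
    def best(self) -> WavebandResult:
        return self.wavebands[self.best_index]

    def to_frame(self) -> pd.DataFrame:
        rows = [wb.row(self.gsmw.axis) for wb in self.wavebands]
        df = pd.DataFrame(rows)
        df.insert(0, "rank", np.arange(1, len(rows) + 1))
        df["is_best"] = [i == self.best_index for i in range(len(rows))]
        return df


def _final_prediction(basis: LPCBasis, flags: np.ndarray,
                      cal: SpectralDataset, target: SpectralDataset
                      ) -> np.ndarray:
    """Refit the winning least-squares model and predict a target set."""
    w = basis.window
    sc = project(basis, cal.window_matrix(w.S, w.N))[:, flags]
    st = project(basis, target.window_matrix(w.S, w.N))[:, flags]
    A = np.column_stack([np.ones(sc.shape[0]), sc])
    beta, *_ = np.linalg.lstsq(A, cal.y, rcond=None)
    return np.column_stack([np.ones(st.shape[0]), st]) @ beta


def run_framework(dataset: SpectralDataset, config: FrameworkConfig,
                  outdir: str | Path | None = None) -> FrameworkReport:
    """Run the full pipeline; optionally write all stage artifacts to ``outdir``."""
    stage = "split"
    try:
        split = split_dataset(dataset, config.n_cal, config.n_val,
                              config.n_test, seed=config.split_seed)
        stage = "snv"
        snv = snv_transform(dataset)
        cal = snv.subset(split.calibration)
        val = snv.subset(split.validation)
        test = snv.subset(split.testing)

        stage = "gsmw"
        gsmw = gsmw_search(cal, val, config.grid, lv_cap=config.lv_cap)
        tops = select_top_windows(gsmw, config.k)

        stage = "ga"
        base_cfg = GAConfig(p_crossover=0.5, p_mutation=0.012,
                            population_size=config.ga_population,
                            max_iterations=config.ga_max_iterations,
                            stall_window=config.ga_stall_window,
                            stall_tolerance=config.ga_stall_tolerance,
                            seed=config.ga_seed)
        wavebands: list[WavebandResult] = []
        for rank, rec in enumerate(tops):
            w = rec.window
            basis = fit_lpc(cal.window_matrix(w.S, w.N), window=w,
                            max_components=config.lpc_max_components)
            sc = project(basis, cal.window_matrix(w.S, w.N))
            sv = project(basis, val.window_matrix(w.S, w.N))
            cell_base = dataclasses.replace(
                base_cfg, seed=derive_cell_seed(config.ga_seed, 1000 + rank))
            ga_cfg, trace, _ = parametric_scan(
                sc, cal.y, sv, val.y,
                config.crossover_pct_grid, config.mutation_pct_grid, cell_base)
            wavebands.append(WavebandResult(record=rec, basis=basis,
                                            ga_config=ga_cfg, ga_trace=trace))

        stage = "final-model"
        best_index = int(np.argmin([wb.ga_trace.best_rmsev for wb in wavebands]))
        best = wavebands[best_index]
        flags = best.ga_trace.best_chromosome
        val_rep = evaluate(val.y, _final_prediction(best.basis, flags, cal, val),
                           which_set="validation")
        test_rep = evaluate(test.y, _final_prediction(best.basis, flags, cal, test),
                            which_set="testing")

        baseline_rep = None
        if config.run_baseline:
            stage = "baseline"
            baseline_rep = run_baseline_ga(dataset, config, split=split)
    except Exception as exc:
        raise RuntimeError(f"framework stage '{stage}' failed: {exc}") from exc

    report = FrameworkReport(config=config, split=split, gsmw=gsmw,
                             wavebands=tuple(wavebands), best_index=best_index,
                             validation=val_rep, testing=test_rep,
                             baseline_testing=baseline_rep)
    if outdir is not None:
        _write_artifacts(report, Path(outdir))
    return report


def run_baseline_ga(dataset: SpectralDataset, config: FrameworkConfig,
                    split: SplitIndices | None = None) -> EvaluationReport:
    """Conventional GA-PLS over the raw wavelength flags of the full spectrum.

    Chromosome length equals the channel count P; fitness is the validation
    RMSE of a PLS model restricted to the flagged channels (latent-variable
    count chosen by validation RMSE, same ceiling as the window scan).
    Returns testing-set metrics for comparison with the pipeline model.
    """
    if split is None:
        split = split_dataset(dataset, config.n_cal, config.n_val,
                              config.n_test, seed=config.split_seed)
    snv = snv_transform(dataset)
    cal = snv.subset(split.calibration)
    val = snv.subset(split.validation)
    test = snv.subset(split.testing)

    def pls_rmsev(flags: np.ndarray, target: SpectralDataset | None = None):
        idx = np.flatnonzero(flags)
        a_max = max_components(idx.size, cal.n_samples, cap=config.lv_cap)
        if a_max < 1:
            return float("inf") if target is None else None
        model = fit_pls(cal.absorbance[:, idx], cal.y, a_max)
        Xv = val.absorbance[:, idx]
        rmsevs = [float(np.sqrt(np.mean((predict(model, Xv, a) - val.y) ** 2)))
                  for a in range(1, model.n_components + 1)]
        if target is None:
            return min(rmsevs)
        best_a = 1 + int(np.argmin(rmsevs))
        return predict(model, target.absorbance[:, idx], best_a)

    pop = config.baseline_population + (config.baseline_population % 2)
    cfg = GAConfig(p_crossover=config.baseline_crossover_pct / 100.0,
                   p_mutation=config.baseline_mutation_pct / 100.0,
                   population_size=pop,
                   max_iterations=config.baseline_max_iterations,
                   stall_window=config.ga_stall_window,
                   stall_tolerance=config.ga_stall_tolerance,
                   seed=derive_cell_seed(config.ga_seed, 999_983))
    trace = evolve(cal.absorbance, cal.y, val.absorbance, val.y, cfg,
                   objective=pls_rmsev)
    pred_test = pls_rmsev(trace.best_chromosome, target=test)
    return evaluate(test.y, pred_test, which_set="testing")


def _write_artifacts(report: FrameworkReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    axis = report.gsmw.axis
    report.gsmw.to_frame().to_csv(outdir / "gsmw_surface.csv", index=False)
    report.to_frame().to_csv(outdir / "report.csv", index=False)

    top = pd.DataFrame([{
        "rank": i + 1, "S": wb.record.window.S, "N": wb.record.window.N,
        "start_nm": wb.record.window.start_nm(axis),
        "end_nm": wb.record.window.end_nm(axis),
        "best_LV": wb.record.best_lv, "RMSEV": wb.record.rmsev,
        "R_V": wb.record.r_v,
    } for i, wb in enumerate(report.wavebands)])
    top.to_csv(outdir / "top_windows.csv", index=False)

    for i, wb in enumerate(report.wavebands):
        tr = pd.DataFrame({
            "iteration": np.arange(1, wb.ga_trace.best_rmsev_per_iteration.size + 1),
            "best_rmsev": wb.ga_trace.best_rmsev_per_iteration,
        })
        tr.to_csv(outdir / f"ga_trace_band{i + 1}.csv", index=False)

    cfg = report.config
    lines = [
        "nirband run manifest",
        f"split: n_cal={cfg.n_cal} n_val={cfg.n_val} n_test={cfg.n_test} seed={cfg.split_seed}",
        f"grid N values: {list(cfg.grid.n_values)}",
        f"k={cfg.k} lv_cap={cfg.lv_cap} lpc_max_components={cfg.lpc_max_components}",
        f"ga: crossover%={list(cfg.crossover_pct_grid)} mutation%={list(cfg.mutation_pct_grid)}",
        f"ga: population={cfg.ga_population} max_iterations={cfg.ga_max_iterations} "
        f"stall_window={cfg.ga_stall_window} tol={cfg.ga_stall_tolerance} seed={cfg.ga_seed}",
        f"windows evaluated: {len(report.gsmw.records)}",
        f"best waveband: {report.to_frame().iloc[report.best_index].to_dict()}",
        f"validation: rmse={report.validation.rmse:.6f} r={report.validation.r}",
        f"testing: rmse={report.testing.rmse:.6f} r={report.testing.r}",
    ]
    if report.baseline_testing is not None:
        lines.append(
            "baseline (full-spectrum GA-PLS over wavelength flags): "
            f"rmse={report.baseline_testing.rmse:.6f} r={report.baseline_testing.r}")
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")
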