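"""End-to-end orchestration: simulate/load, test, classify, report.

`run_pipeline` ties the pieces together: per-condition rhythm scans with
BH-adjusted q-values, amplitude estimation at the detected period/phase,
cross-condition classification, and summary counts, all deterministic
given the configuration and seed.  Outputs are delimited text plus a JSON
run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from circadia import __version__
from circadia.classify import (
    DEFAULT_P_THRESHOLD,
    call_rhythm_class,
    cross_condition_classify,
)
from circadia.io import read_expression_matrix, write_results_table
from circadia.jtk import RhythmScanner, TimeGrid, bh_adjust
from circadia.metrics import amplitude_estimate, mean_phase_advance
from circadia.simulate import CONDITIONS, SimulationConfig, simulate_dataset, truth_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "analyze_matrix", "export_heatmap_matrix"]

log = logging.getLogger("circadia")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (condition -> matrix path) or ``simulation``
    must be provided.  Genes are matched across conditions by identifier
    string, case-sensitively; the intersection is analysed.
    """

    seed: int
    inputs: dict[str, str] | None = None
    simulation: SimulationConfig | None = None
    period_min: float = 10.0
    period_max: float = 40.0
    period_step: float = 1.0
    phase_step: float | None = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    known_harmonics: tuple[str, ...] = ()
    relaxed_harmonic_p: float = 0.1
    system_driven_floor: float = 0.75
    bonferroni: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("provide exactly one of inputs= or simulation=")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 < self.period_min <= self.period_max):
            raise ValueError("need 0 < period_min <= period_max")


@dataclass
class PipelineResult:
    """All artefacts of one run, also written to ``out_dir`` when set."""

    results: dict[str, pd.DataFrame]      # per-condition result tables
    classification: pd.DataFrame
    summary: dict
    truth: pd.DataFrame | None = None     # only for simulated runs
    matrices: dict[str, pd.DataFrame] = field(default_factory=dict)


def analyze_matrix(matrix: pd.DataFrame, grid: TimeGrid,
                   scanner: RhythmScanner,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Scan every gene, BH-adjust within the matrix, estimate amplitudes."""
    results = scanner.scan_matrix(matrix.values, matrix.index, rng=rng)
    rows = []
    for res, (gene, series) in zip(results, matrix.iterrows()):
        half_amp = fold = math.nan
        if math.isfinite(res.best_period):
            est = amplitude_estimate(series.values, grid, res.best_period,
                                     res.best_phase, gene_id=gene)
            half_amp, fold = est.half_amplitude, est.fold_amplitude
        rows.append({
            "gene_id": gene, "p_value": res.p_value, "q_value": math.nan,
            "period": res.best_period, "phase": res.best_phase,
            "half_amplitude": half_amp, "fold_amplitude": fold,
            "tau": res.tau, "s_statistic": res.s_statistic,
            "method": res.method,
        })
    out = pd.DataFrame(rows).set_index("gene_id")
    out["q_value"] = bh_adjust(out["p_value"].values)
    return out


def _condition_summary(results: pd.DataFrame, p_threshold: float) -> dict:
    sig = results[results["p_value"] < p_threshold]
    fdr = float(sig["q_value"].max()) if len(sig) else math.nan
    periods = sig["period"].dropna()
    hist_edges = np.arange(10.0, 42.0, 2.0)
    hist, _ = np.histogram(periods, bins=hist_edges)
    return {
        "n_genes": int(len(results)),
        "n_cycling": int(len(sig)),
        "fdr_at_threshold": fdr,
        "mean_period": float(periods.mean()) if len(periods) else math.nan,
        "period_histogram": {f"{lo:g}-{lo + 2:g}": int(c)
                             for lo, c in zip(hist_edges[:-1], hist)},
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Simulate or load matrices, then test, classify and summarise."""
    rng = np.random.default_rng(config.seed)
    truth = None
    if config.simulation is not None:
        matrices, truths = simulate_dataset(config.simulation)
        grid = config.simulation.grid
        truth = truth_table(truths)
        log.info("simulated %d genes x %d time points x %d conditions",
                 len(truth), grid.n, len(matrices))
    else:
        matrices = {}
        grid = None
        for condition, path in config.inputs.items():
            df, g = read_expression_matrix(path)
            if grid is not None and g.times != grid.times:
                raise ValueError(
                    f"{path}: time grid differs from the other conditions")
            grid = g
            matrices[condition] = df
        shared = None
        for df in matrices.values():
            shared = df.index if shared is None else shared.intersection(df.index)
        if len(shared) == 0:
            raise ValueError("no genes shared across the input matrices")
        matrices = {c: df.loc[shared] for c, df in matrices.items()}
        log.info("loaded %d conditions; %d shared genes",
                 len(matrices), len(shared))

    scanner = RhythmScanner(grid, config.period_min, config.period_max,
                            config.period_step, config.phase_step,
                            config.bonferroni)
    results = {}
    for condition in matrices:
        results[condition] = analyze_matrix(matrices[condition], grid,
                                            scanner, rng)
        log.info("%s: %d/%d cycling at p<%g", condition,
                 int((results[condition]["p_value"] < config.p_threshold).sum()),
                 len(results[condition]), config.p_threshold)

    classification = _classify_all(results, config)
    summary = {
        "conditions": {c: _condition_summary(results[c], config.p_threshold)
                       for c in results},
        "categories": classification["category"].value_counts().to_dict(),
        "p_threshold": config.p_threshold,
    }
    rescued = classification[classification["category"] == "rescued_24h"]
    if len(rescued):
        summary["rescued"] = {
            "n": int(len(rescued)),
            "mean_phase_advance_h": mean_phase_advance(
                list(zip(rescued["wildtype_phase"], rescued["rescue_phase"]))),
            "median_amplitude_ratio": float(rescued["amplitude_ratio"].median()),
            "n_amplitude_reduced": int((rescued["amplitude_ratio"] < 1).sum()),
            "n_system_driven_candidates": int(
                rescued["system_driven_candidate"].sum()),
        }

    result = PipelineResult(results=results, classification=classification,
                            summary=summary, truth=truth, matrices=matrices)
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _classify_all(results: dict[str, pd.DataFrame],
                  config: PipelineConfig) -> pd.DataFrame:
    conditions = list(results)
    wt_name = "wildtype" if "wildtype" in results else conditions[0]
    rescue_name = "rescue" if "rescue" in results else conditions[min(1, len(conditions) - 1)]
    mutant_name = "mutant" if "mutant" in results else None
    known = set(config.known_harmonics)

    rows = []
    for gene in results[wt_name].index:
        calls = {}
        for condition in conditions:
            row = results[condition].loc[gene]
            res = _row_to_result(gene, row)
            calls[condition] = call_rhythm_class(
                res, p_threshold=config.p_threshold, condition=condition)
        wt_fold = results[wt_name].loc[gene, "fold_amplitude"]
        rescue_fold = results[rescue_name].loc[gene, "fold_amplitude"]
        amp_ratio = (rescue_fold / wt_fold
                     if math.isfinite(wt_fold) and wt_fold > 0
                     and math.isfinite(rescue_fold) else math.nan)
        record = cross_condition_classify(
            calls[wt_name], calls[rescue_name],
            calls.get(mutant_name) if mutant_name else None,
            amp_ratio=amp_ratio,
            known_harmonic=gene in known,
            relaxed_p=config.relaxed_harmonic_p,
            system_driven_floor=config.system_driven_floor)
        row_out = {"gene_id": gene, "category": record.category,
                   "amplitude_ratio": record.amplitude_ratio,
                   "system_driven_candidate": record.system_driven_candidate}
        for condition in conditions:
            res_row = results[condition].loc[gene]
            for col in ("p_value", "q_value", "period", "phase",
                        "fold_amplitude"):
                short = col.replace("_value", "").replace("fold_amplitude", "fold")
                row_out[f"{condition}_{short}"] = res_row[col]
            row_out[f"{condition}_class"] = calls[condition].rhythm_class
        rows.append(row_out)
    return pd.DataFrame(rows).set_index("gene_id")


def _row_to_result(gene: str, row: pd.Series):
    from circadia.jtk import RhythmTestResult
    return RhythmTestResult(
        gene_id=gene, best_period=row["period"], best_phase=row["phase"],
        s_statistic=int(row["s_statistic"]), tau=row["tau"],
        p_value=row["p_value"], q_value=row["q_value"],
        half_amplitude=row["half_amplitude"],
        fold_amplitude=row["fold_amplitude"], method=row["method"])


def export_heatmap_matrix(results: pd.DataFrame,
                          matrix: pd.DataFrame) -> pd.DataFrame:
    """Median-normalise each gene row and order rows by ascending phase.

    The standard presentation of a cycling-gene heatmap: every exported row
    has median 1, rows sorted by peak time (ties broken by gene id); genes
    with a zero median are skipped with a warning in the log.
    """
    missing = results.index.difference(matrix.index)
    if len(missing):
        raise ValueError(f"genes absent from the matrix: {list(missing)[:5]}")
    phases = results["phase"]
    order = sorted(results.index, key=lambda g: (phases[g], g))
    rows = []
    for gene in order:
        med = float(np.median(matrix.loc[gene]))
        if med == 0:
            log.warning("gene %s skipped: zero median expression", gene)
            continue
        rows.append(matrix.loc[gene] / med)
    return pd.DataFrame(rows)


def _fixture_checksums() -> dict[str, str]:
    sums = {}
    for name in ("table2.csv", "table3.csv"):
        data = resources.files("circadia.data").joinpath(name).read_bytes()
        sums[name] = hashlib.sha256(data).hexdigest()[:16]
    return sums


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for condition, df in result.results.items():
        write_results_table(df, out / f"results_{condition}.tsv")
    write_results_table(result.classification, out / "classification.tsv")
    if result.truth is not None:
        write_results_table(result.truth, out / "truth.tsv")
    cfg = dataclasses.asdict(config)
    if cfg.get("simulation") is not None:
        cfg["simulation"]["grid"] = list(config.simulation.grid.times)
    manifest = {"version": __version__, "config": cfg,
                "fixtures": _fixture_checksums(), "summary": result.summary}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    log.info("outputs written to %s", out)
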