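"""Packaged transcriptions of the study's printed gene tables.

Two fixtures ship with the package as CSV, transcribed from the printed
tables of the source study:

* ``table2.csv`` — the 92 genes whose 24-h liver rhythms are restored by
  brain-specific rescue (per-condition q, p, period, phase and peak:trough
  fold amplitude for wildtype and rescue, plus five literature annotation
  flags).
* ``table3.csv`` — the 11 genes with wildtype 12-h (harmonic) rhythms, with
  p, FDR, period and phase in wildtype, rescue and mutant conditions.

Values are stored exactly as printed (one-decimal amplitudes, half-hour
phases, mutant p-values of 1.00 as 1.0), so summary statistics recomputed
from them inherit the printed rounding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from circadia.classify import (
    annotation_overlap_count,
    count_amplitude_reductions,
    harmonic_reversion_assess,
)
from circadia.metrics import mean_phase_advance

import numpy as np

__all__ = [
    "RescuedGeneRecord",
    "HarmonicGeneRecord",
    "load_table2",
    "load_table3",
    "reproduce_paper_counts",
    "PaperCountsReport",
]

ANNOTATION_FLAGS = (
    "hughes2009_rhythmic",
    "kornmann_system_driven",
    "kornmann_reanalysis_system_driven",
    "lemartelot_reverba_target",
    "rey_bmal_target",
)


@dataclass(frozen=True)
class RescuedGeneRecord:
    """One row of the 92-gene rescued-cycler table."""

    gene: str
    wt_q: float
    wt_p: float
    wt_period: float
    wt_phase: float
    wt_amplitude: float
    rescue_q: float
    rescue_p: float
    rescue_period: float
    rescue_phase: float
    rescue_amplitude: float
    hughes2009_rhythmic: bool
    kornmann_system_driven: bool
    kornmann_reanalysis_system_driven: bool
    lemartelot_reverba_target: bool
    rey_bmal_target: bool


@dataclass(frozen=True)
class HarmonicGeneRecord:
    """One row of the 11-gene harmonic (12-h rhythm) table."""

    probe_set_id: str
    gene: str
    wt_p: float
    wt_fdr: float
    wt_period: float
    wt_phase: float
    rescue_p: float
    rescue_fdr: float
    rescue_period: float
    rescue_phase: float
    mutant_p: float
    mutant_fdr: float
    mutant_period: float
    mutant_phase: float


class CorruptedFixtureError(RuntimeError):
    """A packaged table failed its row-count or value-range validation."""


def _read_fixture(name: str) -> list[dict[str, str]]:
    path = resources.files("circadia.data").joinpath(name)
    with path.open("r", newline="") as fh:
        return list(csv.DictReader(fh))


def load_table2() -> list[RescuedGeneRecord]:
    """The 92 rescued circadian genes, validated against printed invariants."""
    rows = _read_fixture("table2.csv")
    if len(rows) != 92:
        raise CorruptedFixtureError(f"table2 has {len(rows)} rows, expected 92")
    records = []
    for row in rows:
        rec = RescuedGeneRecord(
            gene=row["gene"],
            **{k: float(row[k]) for k in (
                "wt_q", "wt_p", "wt_period", "wt_phase", "wt_amplitude",
                "rescue_q", "rescue_p", "rescue_period", "rescue_phase",
                "rescue_amplitude")},
            **{k: row[k].strip().upper() == "YES" for k in ANNOTATION_FLAGS},
        )
        if not (rec.wt_p < 0.0011 and rec.rescue_p < 0.0011):
            raise CorruptedFixtureError(f"{rec.gene}: p-value out of range")
        if rec.wt_period < 20 or rec.rescue_period < 20:
            raise CorruptedFixtureError(f"{rec.gene}: period below circadian band")
        if rec.wt_amplitude < 1 or rec.rescue_amplitude < 1:
            raise CorruptedFixtureError(f"{rec.gene}: fold amplitude below 1")
        records.append(rec)
    return records


def load_table3() -> list[HarmonicGeneRecord]:
    """The 11 wildtype 12-h harmonic genes."""
    rows = _read_fixture("table3.csv")
    if len(rows) != 11:
        raise CorruptedFixtureError(f"table3 has {len(rows)} rows, expected 11")
    records = []
    for row in rows:
        rec = HarmonicGeneRecord(
            probe_set_id=row["probe_set_id"], gene=row["gene"],
            **{k: float(row[k]) for k in (
                "wt_p", "wt_fdr", "wt_period", "wt_phase",
                "rescue_p", "rescue_fdr", "rescue_period", "rescue_phase",
                "mutant_p", "mutant_fdr", "mutant_period", "mutant_phase")},
        )
        if rec.wt_period != 12:
            raise CorruptedFixtureError(f"{rec.gene}: wildtype period is not 12 h")
        records.append(rec)
    return records


@dataclass(frozen=True)
class PaperCountsReport:
    """Summary statistics recomputed from the packaged tables."""

    n_rescued: int
    amplitude_reductions: int          # strict rescue < wildtype on printed folds
    amplitude_reductions_nonstrict: int  # ties at printed precision included
    median_amplitude_ratio: float      # median of per-gene rescue/wildtype folds
    mean_phase_advance_h: float        # mean wrapped (wildtype - rescue) phase
    hughes2009_overlap: int
    kornmann_overlap: int
    kornmann_reanalysis_overlap: int
    lemartelot_target_count: int
    rey_target_count: int
    n_harmonic: int
    harmonic_reverted: int             # rescue p < 0.0011 and period >= 20 h
    harmonic_phase_similar: int        # within 3 h (mod 12) of the panel cluster


def reproduce_paper_counts(p_threshold: float = 0.0011,
                           phase_similarity_threshold: float = 3.0) -> PaperCountsReport:
    """Recompute the printed summary numbers from the packaged tables."""
    t2 = load_table2()
    t3 = load_table3()
    ratios = [r.rescue_amplitude / r.wt_amplitude for r in t2]
    summary = harmonic_reversion_assess(
        t3, p_threshold=p_threshold,
        phase_similarity_threshold=phase_similarity_threshold)
    return PaperCountsReport(
        n_rescued=len(t2),
        amplitude_reductions=count_amplitude_reductions(t2, strict=True),
        amplitude_reductions_nonstrict=count_amplitude_reductions(t2, strict=False),
        median_amplitude_ratio=float(np.median(ratios)),
        mean_phase_advance_h=mean_phase_advance(
            [(r.wt_phase, r.rescue_phase) for r in t2]),
        hughes2009_overlap=annotation_overlap_count(t2, "hughes2009_rhythmic"),
        kornmann_overlap=annotation_overlap_count(t2, "kornmann_system_driven"),
        kornmann_reanalysis_overlap=annotation_overlap_count(
            t2, "kornmann_reanalysis_system_driven"),
        lemartelot_target_count=annotation_overlap_count(
            t2, "lemartelot_reverba_target"),
        rey_target_count=annotation_overlap_count(t2, "rey_bmal_target"),
        n_harmonic=len(t3),
        harmonic_reverted=summary.n_reverted,
        harmonic_phase_similar=summary.n_phase_similar,
    )
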