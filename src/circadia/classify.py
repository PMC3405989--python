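"""Cross-condition classification of rhythm-detection results.

Converts per-condition test results into the categories used when comparing
wildtype, brain-rescue and clock-mutant liver transcriptomes: genes whose
24-h rhythm is restored by the rescue, genes rhythmic only with an intact
local clock, 12-h harmonics that revert to 24-h rhythms under rescue, genes
rhythmic only outside wildtype, and everything else.

Band conventions (configurable): a *circadian* call needs a period of at
least 20 h; a *harmonic* call needs a period in the 10-14 h band (8-h
harmonics fall below the scanned period window and are out of scope); a
significant rhythm outside both bands is reported as ``long_period``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from circadia.jtk import RhythmTestResult
from circadia.metrics import circular_distance, circular_mean

__all__ = [
    "CIRCADIAN_24", "HARMONIC_12", "LONG_PERIOD", "ARRHYTHMIC",
    "RhythmCall", "CrossConditionRecord", "HarmonicReversionSummary",
    "call_rhythm_class", "cross_condition_classify",
    "count_amplitude_reductions", "annotation_overlap_count",
    "harmonic_reversion_assess",
]

CIRCADIAN_24 = "circadian_24"
HARMONIC_12 = "harmonic_12"
LONG_PERIOD = "long_period"
ARRHYTHMIC = "arrhythmic"

#: default detection threshold: the p-value corresponding to q < 0.05 in the
#: wildtype condition of the emulated study design
DEFAULT_P_THRESHOLD = 0.0011

RESCUED_24H = "rescued_24h"
WILDTYPE_ONLY = "wildtype_only"
HARMONIC_REVERTED = "harmonic_reverted"
NON_WILDTYPE_CYCLER = "non_wildtype_cycler"
ARRHYTHMIC_EVERYWHERE = "arrhythmic_everywhere"


@dataclass(frozen=True)
class RhythmCall:
    """One gene's rhythm class in one condition."""

    gene_id: str
    condition: str
    significant: bool
    rhythm_class: str
    period: float = math.nan
    phase: float = math.nan
    p_value: float = math.nan
    fold_amplitude: float = math.nan


@dataclass
class CrossConditionRecord:
    """A gene's calls across conditions plus its assigned category."""

    gene_id: str
    calls: dict[str, RhythmCall]
    category: str
    amplitude_ratio: float = math.nan  # rescue fold / wildtype fold
    system_driven_candidate: bool = False
    flags: dict[str, bool] = field(default_factory=dict)


def call_rhythm_class(result: RhythmTestResult,
                      p_threshold: float = DEFAULT_P_THRESHOLD,
                      condition: str = "",
                      circadian_min_period: float = 20.0,
                      harmonic_band: tuple[float, float] = (10.0, 14.0)) -> RhythmCall:
    """Deterministic class from a test result and a significance threshold."""
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    significant = bool(result.p_value < p_threshold)
    period = result.best_period
    if not significant or not math.isfinite(period):
        cls = ARRHYTHMIC
    elif period >= circadian_min_period:
        cls = CIRCADIAN_24
    elif harmonic_band[0] <= period <= harmonic_band[1]:
        cls = HARMONIC_12
    else:
        cls = LONG_PERIOD
    return RhythmCall(gene_id=result.gene_id, condition=condition,
                      significant=significant, rhythm_class=cls,
                      period=period, phase=result.best_phase,
                      p_value=result.p_value,
                      fold_amplitude=result.fold_amplitude)


def cross_condition_classify(wt: RhythmCall, rescue: RhythmCall,
                             mutant: RhythmCall | None = None,
                             amp_ratio: float = math.nan,
                             known_harmonic: bool = False,
                             relaxed_p: float = 0.1,
                             system_driven_floor: float = 0.75) -> CrossConditionRecord:
    """Assign one gene's cross-condition category.

    ``known_harmonic`` admits previously described 12-h genes into the
    harmonic-reversion category at the relaxed threshold ``relaxed_p``
    (the convention for re-assessing published harmonics), provided the
    scan still placed their wildtype period in the harmonic band.
    """
    ids = {wt.gene_id, rescue.gene_id} | ({mutant.gene_id} if mutant else set())
    if len(ids) != 1:
        raise ValueError(f"gene ids differ across conditions: {sorted(ids)}")

    # a known 12-h gene qualifies at the relaxed threshold provided the scan
    # still put its wildtype period in the harmonic band
    wt_harmonic = (wt.significant and wt.rhythm_class == HARMONIC_12) or (
        known_harmonic and math.isfinite(wt.period)
        and 10.0 <= wt.period <= 14.0 and wt.p_value < relaxed_p)
    rescue_circadian = rescue.significant and rescue.rhythm_class == CIRCADIAN_24

    if wt_harmonic and rescue_circadian:
        category = HARMONIC_REVERTED
    elif (wt.significant and wt.rhythm_class == CIRCADIAN_24 and rescue_circadian):
        category = RESCUED_24H
    elif wt.significant:
        category = WILDTYPE_ONLY
    elif rescue.significant or (mutant is not None and mutant.significant):
        category = NON_WILDTYPE_CYCLER
    else:
        category = ARRHYTHMIC_EVERYWHERE

    record = CrossConditionRecord(
        gene_id=wt.gene_id,
        calls={c.condition or k: c for k, c in
               (("wildtype", wt), ("rescue", rescue))} |
              ({mutant.condition or "mutant": mutant} if mutant else {}),
        category=category,
        amplitude_ratio=float(amp_ratio))
    if category == RESCUED_24H and math.isfinite(amp_ratio):
        record.system_driven_candidate = amp_ratio >= system_driven_floor
    return record


def count_amplitude_reductions(rescued: Sequence, strict: bool = True,
                               wt_attr: str = "wt_amplitude",
                               rescue_attr: str = "rescue_amplitude") -> int:
    """Number of rescued genes whose rescue fold amplitude is below wildtype.

    ``strict=False`` counts ties as reductions, which brackets counts made
    on unrounded values when the inputs are printed at limited precision.
    """
    count = 0
    for rec in rescued:
        wt_amp = getattr(rec, wt_attr)
        rescue_amp = getattr(rec, rescue_attr)
        if wt_amp is None or rescue_amp is None or not (
                math.isfinite(wt_amp) and math.isfinite(rescue_amp)):
            raise ValueError(
                f"record {getattr(rec, 'gene', rec)} is missing an amplitude")
        if (rescue_amp < wt_amp) or (not strict and rescue_amp == wt_amp):
            count += 1
    return count


def annotation_overlap_count(records: Sequence, flag_name: str) -> int:
    """Number of records whose boolean annotation ``flag_name`` is set."""
    count = 0
    for rec in records:
        if not hasattr(rec, flag_name):
            raise ValueError(f"unknown annotation flag {flag_name!r}")
        if bool(getattr(rec, flag_name)):
            count += 1
    return count


@dataclass
class HarmonicReversionSummary:
    """Outcome of re-assessing a panel of 12-h (harmonic) genes."""

    n_genes: int
    reverted_genes: list[str]
    phase_similar_genes: list[str]
    amplitude_pairs: list[tuple[str, float, float]]  # (gene, wt fold, rescue fold)

    @property
    def n_reverted(self) -> int:
        return len(self.reverted_genes)

    @property
    def n_phase_similar(self) -> int:
        return len(self.phase_similar_genes)


def harmonic_reversion_assess(records: Sequence,
                              p_threshold: float = DEFAULT_P_THRESHOLD,
                              phase_similarity_threshold: float = 3.0,
                              circadian_min_period: float = 20.0) -> HarmonicReversionSummary:
    """Assess reversion of wildtype 12-h rhythms to 24-h rhythms in rescue.

    A gene *reverts* when its rescue rhythm is significant at ``p_threshold``
    with a circadian-band period.  *Phase similarity* is assessed against the
    panel's phase cluster: both the wildtype and the rescue peak time (mod
    12 h, since a 12-h rhythm's phase is only defined modulo 12) must lie
    within ``phase_similarity_threshold`` hours of the respective group
    circular mean.  When records carry wildtype/rescue fold amplitudes the
    per-gene amplitude pairs are reported as well.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one harmonic record")
    reverted = [r.gene for r in records
                if r.rescue_p < p_threshold and r.rescue_period >= circadian_min_period]

    wt_center = circular_mean([r.wt_phase for r in records], modulus=12.0)
    rescue_center = circular_mean([r.rescue_phase for r in records], modulus=12.0)
    similar = [
        r.gene for r in records
        if circular_distance(r.wt_phase, wt_center, 12.0) <= phase_similarity_threshold
        and circular_distance(r.rescue_phase, rescue_center, 12.0) <= phase_similarity_threshold]

    pairs = []
    for r in records:
        wt_fold = getattr(r, "wt_fold", None)
        rescue_fold = getattr(r, "rescue_fold", None)
        if wt_fold is not None and rescue_fold is not None:
            pairs.append((r.gene, float(wt_fold), float(rescue_fold)))

    return HarmonicReversionSummary(
        n_genes=len(records), reverted_genes=reverted,
        phase_similar_genes=similar, amplitude_pairs=pairs)
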