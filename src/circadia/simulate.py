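"""Synthetic three-condition circadian expression data with known truth.

The generator emulates a liver time-course design: one expression matrix
per condition (wildtype, brain-rescue, clock-mutant), 24 time points
sampled every 2 h for 48 h in constant darkness, and four gene classes:

``arrhythmic``
    flat expression, multiplicative noise only;
``local_only``
    a 24-h cosine rhythm in wildtype that is lost in both rescue and
    mutant (local-clock output);
``rescued``
    a systemically driven 24-h cosine present in wildtype and rescue
    (rescue amplitude attenuated so that its peak:trough fold is
    ``rescue_amplitude_factor`` times the wildtype fold) and, in the
    mutant, the same component at a long free-running period
    (``Normal(27.6, 4.5)`` h, clipped to the scan window) at 0.3 times the
    wildtype relative amplitude;
``harmonic``
    a 12-h rhythm in wildtype built from two equal circular (von
    Mises-shaped) peaks 12 h apart — a systemic peak that persists in
    rescue (where the gene becomes a 24-h rhythm of undiminished
    amplitude) and a local peak that is lost outside wildtype; flat in the
    mutant.  Pure antiphase cosines would cancel identically, so peaks are
    the natural waveform for a two-peaks-per-day rhythm.

Expression is ``B * (1 + sum_k a_k * w_k(t)) * eps`` with log-normal noise
``eps`` of unit mean and coefficient of variation ``noise_cv``.  All
randomness flows from the mandatory ``seed``; identical configurations
give bit-identical matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from circadia.jtk import TimeGrid

__all__ = [
    "SimulationConfig",
    "Component",
    "GeneTruth",
    "simulate_dataset",
    "truth_table",
    "CONDITIONS",
]

CONDITIONS = ("wildtype", "rescue", "mutant")

GeneClass = Literal["arrhythmic", "local_only", "rescued", "harmonic"]


@dataclass(frozen=True)
class Component:
    """One oscillatory component of a gene in one condition."""

    period: float          # hours
    phase: float           # circadian time of the component peak, hours
    rel_amplitude: float   # amplitude relative to baseline
    waveform: str = "cosine"  # "cosine" or "peak" (von Mises bump)


@dataclass(frozen=True)
class GeneTruth:
    """Generative parameters of one gene, for recovery scoring."""

    gene_id: str
    gene_class: str
    baseline: float
    components: dict[str, tuple[Component, ...]]  # condition -> components


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the emulated design: 2-h sampling for 48 h, mutant
    free-running periods of 27.6 +/- 4.5 h, rescue fold amplitudes 0.8x
    wildtype, and a residual mutant relative amplitude of 0.3x.
    """

    seed: int
    n_arrhythmic: int = 200
    n_local_only: int = 100
    n_rescued: int = 100
    n_harmonic: int = 60
    grid: TimeGrid = field(default_factory=TimeGrid.regular)
    mutant_period_mean: float = 27.6
    mutant_period_sd: float = 4.5
    mutant_period_clip: tuple[float, float] = (10.0, 40.0)
    rescue_amplitude_factor: float = 0.8
    mutant_amplitude_factor: float = 0.3
    noise_cv: float = 0.1
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 0.5
    rel_amplitude_range: tuple[float, float] = (0.3, 0.6)
    # von Mises kappa of harmonic peaks; 2.45 solves 2*I2(k) = I1(k), making
    # the 12-h fundamental of the two-peak wildtype waveform equal to the
    # 24-h fundamental of the single rescue peak, i.e. harmonics keep their
    # amplitude when they revert
    harmonic_sharpness: float = 2.45
    replicates: int = 1  # pooled: noise is averaged over replicates

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed: a seed is mandatory (no implicit randomness)")
        for name in ("n_arrhythmic", "n_local_only", "n_rescued", "n_harmonic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: gene counts must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv: coefficient of variation must be >= 0")
        if not (0 <= self.rescue_amplitude_factor):
            raise ValueError("rescue_amplitude_factor: must be >= 0")
        if self.mutant_period_sd < 0:
            raise ValueError("mutant_period_sd: must be >= 0")
        lo, hi = self.rel_amplitude_range
        if not (0 <= lo <= hi):
            raise ValueError("rel_amplitude_range: need 0 <= low <= high")
        if hi >= 1:
            raise ValueError("rel_amplitude_range: amplitudes must stay below "
                             "1 to keep expression positive")
        if self.replicates < 1:
            raise ValueError("replicates: must be >= 1")

    @property
    def n_genes(self) -> int:
        return (self.n_arrhythmic + self.n_local_only
                + self.n_rescued + self.n_harmonic)


def _evaluate(component: Component, t: np.ndarray, kappa: float) -> np.ndarray:
    x = 2.0 * np.pi * (t - component.phase) / component.period
    if component.waveform == "cosine":
        w = np.cos(x)
    elif component.waveform == "peak":
        w = np.exp(kappa * (np.cos(x) - 1.0))
    else:
        raise ValueError(f"unknown waveform {component.waveform!r}")
    return component.rel_amplitude * w


def _noiseless(truth: GeneTruth, condition: str, t: np.ndarray,
               kappa: float) -> np.ndarray:
    signal = np.ones_like(t)
    for comp in truth.components.get(condition, ()):
        signal = signal + _evaluate(comp, t, kappa)
    return truth.baseline * signal


def _fold_of(rel_amp: float, cos_p10: float) -> float:
    """Noiseless peak:trough fold of ``B(1 + a cos)`` with trough = 10th pct."""
    return (1.0 + rel_amp * cos_p10 + 2.0 * rel_amp) / (1.0 + rel_amp * cos_p10)


def _rel_amp_for_fold(target_fold: float, cos_p10: float) -> float:
    """Invert :func:`_fold_of`; zero when the target fold is <= 1 (flat)."""
    if target_fold <= 1.0:
        return 0.0
    return (target_fold - 1.0) / (2.0 + cos_p10 * (1.0 - target_fold))


def simulate_dataset(config: SimulationConfig
                     ) -> tuple[dict[str, pd.DataFrame], list[GeneTruth]]:
    """Generate the three condition matrices and the per-gene ground truth.

    Returns a ``{condition: DataFrame}`` mapping (genes x time points, with
    the time grid in hours as columns) and the list of :class:`GeneTruth`.
    """
    rng = np.random.default_rng(config.seed)
    t = config.grid.as_array()
    lo, hi = config.rel_amplitude_range
    truths: list[GeneTruth] = []

    def baseline() -> float:
        return float(rng.lognormal(config.baseline_log_mean, config.baseline_log_sd))

    def mutant_period() -> float:
        draw = rng.normal(config.mutant_period_mean, config.mutant_period_sd)
        return float(np.clip(draw, *config.mutant_period_clip))

    for i in range(config.n_arrhythmic):
        truths.append(GeneTruth(f"arr_{i:04d}", "arrhythmic", baseline(), {}))

    for i in range(config.n_local_only):
        a = float(rng.uniform(lo, hi))
        phase = float(rng.uniform(0.0, 24.0))
        comp = Component(24.0, phase, a)
        truths.append(GeneTruth(f"loc_{i:04d}", "local_only", baseline(),
                                {"wildtype": (comp,)}))

    for i in range(config.n_rescued):
        a = float(rng.uniform(lo, hi))
        phase = float(rng.uniform(0.0, 24.0))
        cos_p10 = float(np.percentile(np.cos(2 * np.pi * (t - phase) / 24.0), 10))
        wt_fold = _fold_of(a, cos_p10)
        a_rescue = _rel_amp_for_fold(config.rescue_amplitude_factor * wt_fold,
                                     cos_p10)
        truths.append(GeneTruth(
            f"res_{i:04d}", "rescued", baseline(),
            {"wildtype": (Component(24.0, phase, a),),
             "rescue": (Component(24.0, phase, a_rescue),),
             "mutant": (Component(mutant_period(), phase,
                                  config.mutant_amplitude_factor * a),)}))

    for i in range(config.n_harmonic):
        a = float(rng.uniform(lo, hi))
        phase = float(rng.uniform(0.0, 24.0))
        systemic = Component(24.0, phase, a, waveform="peak")
        local = Component(24.0, (phase + 12.0) % 24.0, a, waveform="peak")
        truths.append(GeneTruth(
            f"har_{i:04d}", "harmonic", baseline(),
            {"wildtype": (systemic, local), "rescue": (systemic,)}))

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
        mu = -0.5 * sigma ** 2
    matrices: dict[str, pd.DataFrame] = {}
    for condition in CONDITIONS:
        values = np.empty((len(truths), len(t)))
        for row, truth in enumerate(truths):
            values[row] = _noiseless(truth, condition, t, config.harmonic_sharpness)
        if config.noise_cv > 0:
            eps = rng.lognormal(mu, sigma,
                                size=(config.replicates,) + values.shape)
            values = values * eps.mean(axis=0)
        matrices[condition] = pd.DataFrame(
            values, index=[tr.gene_id for tr in truths], columns=t)
        matrices[condition].index.name = "gene_id"
    return matrices, truths


def truth_table(truths: Sequence[GeneTruth]) -> pd.DataFrame:
    """Flatten ground truth to one row per gene for recovery scoring.

    Per-condition columns give the period/phase/relative amplitude of the
    first component (and of the second wildtype component for harmonic
    genes); empty for conditions where the gene is flat.
    """
    if not truths:
        raise ValueError("need at least one gene truth")
    rows = []
    for tr in truths:
        row: dict[str, object] = {"gene_id": tr.gene_id, "gene_class": tr.gene_class,
                                  "baseline": tr.baseline}
        for condition in CONDITIONS:
            comps = tr.components.get(condition, ())
            row[f"{condition}_period"] = comps[0].period if comps else np.nan
            row[f"{condition}_phase"] = comps[0].phase if comps else np.nan
            row[f"{condition}_rel_amplitude"] = (comps[0].rel_amplitude
                                                 if comps else np.nan)
        wt = tr.components.get("wildtype", ())
        if len(wt) > 1:
            row["wildtype_phase2"] = wt[1].phase
            row["wildtype_rel_amplitude2"] = wt[1].rel_amplitude
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
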