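"""Simulate a three-condition circadian study with known ground truth.

Generates wildtype, brain-rescue and clock-mutant expression matrices for
four gene classes (arrhythmic background, local-clock output, systemically
rescued cyclers, 12-h harmonics) and prints how many genes each condition
detects as cycling at the study threshold p < 0.0011.
"""

import numpy as np

from circadia import RhythmScanner, SimulationConfig, simulate_dataset

config = SimulationConfig(seed=42, n_arrhythmic=100, n_local_only=50,
                          n_rescued=50, n_harmonic=25)
matrices, truths = simulate_dataset(config)
print(f"simulated {len(truths)} genes x {config.grid.n} time points "
      f"x {len(matrices)} conditions\n")

scanner = RhythmScanner(config.grid)
rng = np.random.default_rng(0)
for condition, df in matrices.items():
    results = scanner.scan_matrix(df.values, df.index, rng=rng)
    n_cycling = sum(r.p_value < 0.0011 for r in results)
    print(f"{condition:9s} {n_cycling:3d} cycling genes at p<0.0011")

print("\nA working local clock (wildtype) detects the most cyclers; the "
      "brain-rescue restores an intermediate share; the mutant keeps only "
      "weak long-period rhythms.")
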