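"""From ROI time series to phase-lag-index connectivity features.

Generates one recording with a strong quarter-cycle-lagged coupling
planted on a single ROI pair, runs the band-pass -> epoch -> phase -> PLI
chain, and prints the 15-entry feature vector: the planted pair should
dominate, and an uncoupled pair should sit at the estimator's noise floor.
"""

import math

import numpy as np

from dmnstrat import BANDS, SimulationConfig, pli_matrix, simulate_coupled_sources
from dmnstrat.simulate import PairCoupling

config = SimulationConfig(
    n_patients=1,
    n_controls=0,
    subgroup_sizes=(1,),
    duration=336.0,
    seed=3,
    coupling_spec={
        "theta": (PairCoupling("LP_L", "PCC_L", delta=math.pi / 2, kappa=0.8),)
    },
    clinical_effects={},
)
cohort = simulate_coupled_sources(config)

features = pli_matrix(cohort.recordings[0], BANDS["theta"])
print("theta-band PLI features (epoch-averaged over the first 40 8-s epochs):")
for name, value in zip(features.feature_names, features.vector):
    marker = "  <- planted coupling" if name == "LP_L--PCC_L" else ""
    print(f"  {name:<16s} {value:.3f}{marker}")

print(f"\nplanted pair:   {features.matrix[0, 2]:.3f} (kappa=0.8, quarter-cycle lag)")
print(f"median of rest: {np.median(np.sort(features.vector)[:-1]):.3f} "
      "(the estimator's noise floor for independent narrowband signals)")
# A PLI near 1 needs both a strong shared drive and a consistent nonzero
# lag; pairs without planted coupling stay near ~0.1, which is the bias
# floor of the epoch-averaged estimator, not evidence of interaction.
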