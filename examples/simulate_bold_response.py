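"""Simulate a block-design BOLD response from the Balloon model.

Builds a 9-block on/off design (20 s blocks, TR 2 s), integrates the
hemodynamic ODEs for a vein-dominated voxel (V0 = 0.1) and prints the peak
signal change and state excursions — the forward model every later stage
inverts.
"""

import numpy as np

from balloonassim import DEFAULT_PARAMS, simulate_bold
from balloonassim.synthetic import default_single_region_scenario

scenario = default_single_region_scenario(seed=7)
sim = simulate_bold(scenario.params, scenario.stimulus(),
                    scenario.sample_times(), noise_sd=0.002, seed=7)

peak = np.max(np.abs(sim.bold_noiseless))
print(f"scenario: {scenario.name} (V0 = {scenario.params.V0})")
print(f"peak BOLD change      : {peak:.4f}  ({100 * peak:.1f} % signal change)")
print(f"peak inflow f         : {sim.states[:, 1].max():.3f}  (rest = 1)")
print(f"peak venous volume v  : {sim.states[:, 2].max():.3f}")
print(f"min dHb content q     : {sim.states[:, 3].min():.3f}")
print(f"noise sd added        : {sim.noise_sd}")
# The BOLD excursion is a few percent and the inflow rises ~50 %: the
# physiological regime of a strongly activated visual voxel.
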