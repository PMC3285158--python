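"""The headline effect: an assumed V0 fits the BOLD signal but distorts
states and efficacy.

Assimilates the same vein-dominated series (truth V0 = 0.1) twice — once
with the calibrated V0 and once with the conventional assumed V0 = 0.02 —
and prints the side-by-side contrast.
"""

from balloonassim import FilterConfig, compare_v0_scenarios
from balloonassim.synthetic import (default_single_region_scenario,
                                    make_single_region_dataset)

scenario = default_single_region_scenario(seed=7)
data = make_single_region_dataset(scenario)
config = FilterConfig(measurement_var=data.noise_sd ** 2)

cmp = compare_v0_scenarios(data.times, data.bold_noisy, scenario.stimulus(),
                           v0_actual=0.1, v0_assumed=0.02, config=config)
r = cmp.report

print(f"truth: eps = {scenario.params.epsilon}, V0 = 0.1\n")
print(f"{'':22s} {'actual V0=0.1':>14s} {'assumed V0=0.02':>16s}")
print(f"{'BOLD fit RMSE':22s} {r['bold_rmse']['actual']:14.5f} "
      f"{r['bold_rmse']['assumed']:16.5f}")
print(f"{'estimated epsilon':22s} {r['epsilon']['actual']:14.3f} "
      f"{r['epsilon']['assumed']:16.3f}")
print(f"{'epsilon * V0':22s} {r['epsilon_v0_product']['actual']:14.4f} "
      f"{r['epsilon_v0_product']['assumed']:16.4f}")
for k, label in (("f", "peak |f - 1|"), ("v", "peak |v - 1|"),
                 ("q", "peak |1 - q|")):
    print(f"{label:22s} {r['state_excursions']['actual'][k]:14.3f} "
          f"{r['state_excursions']['assumed'][k]:16.3f}")
print(f"\nRMSE ratio (assumed/actual): {r['bold_rmse_ratio']:.2f}")
# Both runs reproduce the measured BOLD almost equally well, but the
# assumed (underestimated) V0 inflates the neuronal efficacy several-fold
# and exaggerates every reconstructed physiological excursion: signal
# reconstruction is insensitive to V0, state/parameter inference is not.
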