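"""Two-region effective connectivity under actual vs assumed V0.

Simulates a two-node hierarchy (region 1 vein-dominated, V0 = 0.1; region 2
tissue-only, V0 = 0.02) driven by a block squarewave, then estimates the
inter-region couplings twice: with the correct per-region V0 and with the
conventional V0 = 0.02 assumed in both regions.
"""

from balloonassim import FilterConfig, compare_dcm_v0_scenarios
from balloonassim.synthetic import (default_two_region_scenario,
                                    make_two_region_dataset)

scenario = default_two_region_scenario(seed=7)
data = make_two_region_dataset(scenario)
truth = scenario.model.connectivity

cmp = compare_dcm_v0_scenarios(
    data.times, data.bold_noisy, scenario.stimulus(),
    v0_actual=(0.1, 0.02), v0_assumed=(0.02, 0.02),
    config=FilterConfig(),
    measurement_vars=[s ** 2 for s in data.noise_sd])

ca, cb = cmp["connectivity"]["actual"], cmp["connectivity"]["assumed"]
print(f"{'coupling':10s} {'truth':>7s} {'actual V0':>10s} {'assumed V0':>11s} {'shift/sd':>9s}")
for name, tv in (("a12", truth.a12), ("a21", truth.a21)):
    s = cmp["coupling_shifts"][name]
    print(f"{name:10s} {tv:7.2f} {ca[name]:10.3f} {cb[name]:11.3f} "
          f"{s['shift_over_sd']:9.2f}")
print(f"\nmax coupling shift / posterior sd: {cmp['max_shift_over_sd']:.2f}")
# With the correct per-region V0 both coupling signs are recovered; assuming
# tissue-level V0 in the vein-dominated region shifts the connectivity
# estimates by several posterior standard deviations — effective
# connectivity inherits the V0 bias through the inflated efficacy.
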