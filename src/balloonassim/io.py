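"""CSV / YAML / JSON interchange for series, scenarios and results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import BoldSimulation, StimulusTrain
from .synthetic import SyntheticScenario, TwoRegionScenario

__all__ = [
    "save_series_csv",
    "load_series_csv",
    "save_stimulus_yaml",
    "load_stimulus_yaml",
    "save_scenario_yaml",
    "load_scenario_yaml",
    "save_json",
]


def save_series_csv(sim: BoldSimulation, path, sidecar: bool = True) -> None:
    """Write a simulated series as CSV plus a JSON sidecar with the truth."""
    path = Path(path)
    sim.to_frame().to_csv(path, index=False)
    if sidecar:
        p = sim.params
        meta = {
            "params": {k: getattr(p, k) for k in
                       ("epsilon", "tau_s", "tau_f", "tau_0", "E0", "alpha", "V0")},
            "noise_sd": sim.noise_sd,
            "seed": sim.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_series_csv(path):
    """Read (times, bold) from a CSV with time_s and a bold column."""
    df = pd.read_csv(path)
    col = "bold_noisy" if "bold_noisy" in df else "bold"
    return df["time_s"].to_numpy(), df[col].to_numpy()


def save_stimulus_yaml(stimulus: StimulusTrain, path) -> None:
    Path(path).write_text(yaml.safe_dump(stimulus.to_dict()))


def load_stimulus_yaml(path) -> StimulusTrain:
    return StimulusTrain.from_dict(yaml.safe_load(Path(path).read_text()))


def save_scenario_yaml(scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario.to_dict()))


def load_scenario_yaml(path, two_region: bool = False):
    d = yaml.safe_load(Path(path).read_text())
    cls = TwoRegionScenario if two_region else SyntheticScenario
    return cls.from_dict(d)


def save_json(obj, path) -> None:
    """JSON dump that tolerates numpy scalars/arrays."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
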