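"""Deterministic example datasets for tests, documentation and smoke runs.

Each fixture is a CSV + matching YAML analysis config written to disk;
identical (name, seed) always produces byte-identical files.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .data import TrialData
from .io import write_trial_csv
from .joint_model import JointParams
from .simulation import (
    ScenarioConfig,
    default_effect_scenario,
    null_scenario,
    simulate_trial,
)

__all__ = ["FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = ("null", "effect", "skewed-needs-boxcox", "missingness", "separation")


def _config_dict(threshold: float, boxcox="off") -> dict:
    return {
        "direction": "at_least",
        "threshold": float(threshold),
        "continuous_label": "continuous component",
        "binary_label": "binary component",
        "conf_level": 0.95,
        "boxcox": boxcox,
        "seed": 0,
    }


def make_fixture(name: str, seed: int, out_dir) -> dict[str, Path]:
    """Write fixture ``name`` under ``out_dir``; returns the file paths.

    Fixtures:
      null                 no treatment effect, n = 100/arm
      effect               default effect scenario at n = 500/arm
      skewed-needs-boxcox  log-normal continuous component (threshold 1);
                           its Box-Cox profile likelihood peaks near 0
      missingness          effect scenario with 15% missing per component
      separation           every binary component equals 1, so the logistic
                           sub-model is inestimable and the fit flags it
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    threshold, boxcox = 0.0, "off"
    if name == "null":
        data = simulate_trial(null_scenario(n_per_arm=100, seed=seed), 0)
    elif name == "effect":
        data = simulate_trial(default_effect_scenario(n_per_arm=500, seed=seed), 0)
    elif name == "skewed-needs-boxcox":
        base = simulate_trial(default_effect_scenario(n_per_arm=300, seed=seed), 0)
        data = TrialData(base.ids, base.z, np.exp(base.y), base.b, dict(base.meta))
        threshold, boxcox = 1.0, "auto"  # exp(0): same responder set as y >= 0
    elif name == "missingness":
        scen = default_effect_scenario(n_per_arm=200, seed=seed).with_(
            miss_y=0.15, miss_b=0.15
        )
        data = simulate_trial(scen, 0)
    else:  # separation
        scen = ScenarioConfig(
            n_per_arm=100,
            true_params=JointParams(0.0, 0.4, 1.0, 30.0, 0.0, 0.0),
            rule=null_scenario().rule,
            seed=seed,
        )
        data = simulate_trial(scen, 0)

    slug = name.replace("-", "_")
    csv_path = out_dir / f"{slug}.csv"
    cfg_path = out_dir / f"{slug}_config.yaml"
    write_trial_csv(data, csv_path)
    cfg_path.write_text(
        yaml.safe_dump(_config_dict(threshold, boxcox), sort_keys=True)
    )
    return {"data": csv_path, "config": cfg_path}
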