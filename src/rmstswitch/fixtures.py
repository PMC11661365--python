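"""Small deterministic survival datasets for demonstrations and tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .power import resolve_scenario, simulate_trial

__all__ = ["FIXTURE_KINDS", "generate_fixture"]

FIXTURE_KINDS = ("tiny-km", "exponential-two-arm", "switching-demo")


def generate_fixture(kind: str, seed: int = 0) -> pd.DataFrame:
    """A (time, event, arm) table of the requested kind, deterministic in seed.

    ``tiny-km``: three control subjects whose Kaplan-Meier curve, RMST and
    variance are reproducible by hand.  ``exponential-two-arm``: 200 subjects
    per arm with exponential event times (medians 6.0 and 6.4) under
    administrative censoring at 26 time units.  ``switching-demo``: one
    simulated trial (50 per arm) with gamma-family switching.
    """
    if kind == "tiny-km":
        return pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [0, 1, 1], "arm": "control"}
        )
    if kind == "exponential-two-arm":
        rng = np.random.default_rng(seed)
        frames = []
        for arm, median in (("control", 6.0), ("experimental", 6.4)):
            t = rng.exponential(median / np.log(2.0), 200)
            frames.append(
                pd.DataFrame(
                    {
                        "time": np.minimum(t, 26.0),
                        "event": (t <= 26.0).astype(int),
                        "arm": arm,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)
    if kind == "switching-demo":
        config = ScenarioConfig(
            n=50, m1=6.0, m2=6.4, Ta=0.0, Te=26.0, tau=12.0, f1=0.8,
            ps=0.5, rs=0.3, rho_s=0.5, s_dist="gamma",
            censoring_rate="AC.only", one_sided_alpha=0.005, seed=seed,
        )
        resolved = resolve_scenario(config)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        control, experimental = simulate_trial(resolved, rng)
        frames = [
            pd.DataFrame(
                {
                    "time": sample.times,
                    "event": sample.events.astype(int),
                    "arm": sample.label,
                }
            )
            for sample in (control, experimental)
        ]
        return pd.concat(frames, ignore_index=True)
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
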