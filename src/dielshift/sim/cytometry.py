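"""Synthetic flow-cytometry event tables with a spiked bead standard.

Cell populations follow configured diel trajectories (signal rising
through the light period and dropping after the light-to-dark
transition); the polystyrene reference beads sit at a fixed location in
every sample, so bead-relative statistics cancel instrument gain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dielshift.sim.config import SimConfig

CHANNELS = ("fals", "ssc", "red")

# relative-to-T0 trajectories over the long-exposure time course
# (hours 0, 2.5, 6, 9.5, 19.5; the last point is after the dark period)
FCM_TIMES_H = (0.0, 2.5, 6.0, 9.5, 19.5)
DEFAULT_TRAJECTORIES = {
    ("control", "fals"): (1.0, 1.35, 1.8, 2.3, 0.85),
    ("control", "red"): (1.0, 1.2, 1.5, 1.8, 0.9),
    ("HL", "fals"): (1.0, 1.3, 1.75, 2.2, 0.9),
    ("HL", "red"): (1.0, 1.05, 1.25, 1.45, 0.8),
    ("HLUV", "fals"): (1.0, 0.85, 0.7, 0.6, 0.5),
    ("HLUV", "red"): (1.0, 0.6, 0.35, 0.2, 0.07),
}


def lightshift_fcm_params(
    config: SimConfig,
    uv_red_endpoint: float = 0.07,
    base_fals: float = 500.0,
    base_red: float = 1500.0,
    replicates: int = 3,
) -> list[dict]:
    """Per-sample cell/bead location parameters for the light-shift
    time course.  ``uv_red_endpoint`` is the HL+UV red-fluorescence
    level at the final time point relative to T0 (0.07 = a 93% drop)."""
    traj = {k: list(v) for k, v in DEFAULT_TRAJECTORIES.items()}
    traj[("HLUV", "red")][-1] = uv_red_endpoint
    params = []
    for cond in ("control", "HL", "HLUV"):
        for ti, t in enumerate(FCM_TIMES_H):
            for r in range(1, replicates + 1):
                params.append(
                    {
                        "sample_id": f"{cond}.T{t:g}.r{r}",
                        "condition": cond,
                        "time_h": t,
                        "replicate": r,
                        "cell_fals": base_fals * traj[(cond, "fals")][ti],
                        "cell_red": base_red * traj[(cond, "red")][ti],
                        "cell_ssc": 300.0,
                        "n_events": config.fcm_events_per_sample,
                    }
                )
    return params


def simulate_fcm(sample_params: list[dict], config: SimConfig) -> pd.DataFrame:
    """Generate labelled cell/bead events for each sample.

    Event values are lognormal around the configured per-sample cell
    locations; bead locations are ``config.fcm_bead_mean`` in every
    sample and channel.  Returns a tidy table with columns sample_id,
    population, fals, ssc, red (plus any sample metadata provided).
    """
    if config.fcm_log_scale <= 0:
        raise ValueError("fcm_log_scale must be positive")
    rng = config.rng("fcm")
    sigma = config.fcm_log_scale
    frames = []
    for p in sample_params:
        n = int(p.get("n_events", config.fcm_events_per_sample))
        if n < 0:
            raise ValueError("n_events must be nonnegative")
        n_bead = int(round(n * config.fcm_bead_fraction))
        n_cell = n - n_bead
        meta = {k: p[k] for k in p
                if k not in ("cell_fals", "cell_red", "cell_ssc", "n_events")}
        for pop, count, locs in (
            ("cell", n_cell, {"fals": p["cell_fals"], "red": p["cell_red"],
                              "ssc": p.get("cell_ssc", 300.0)}),
            ("bead", n_bead, {c: config.fcm_bead_mean for c in CHANNELS}),
        ):
            if count == 0:
                continue
            for c, loc in locs.items():
                if loc <= 0:
                    raise ValueError(f"nonpositive location for {c}")
            df = pd.DataFrame(
                {
                    c: rng.lognormal(np.log(locs[c]), sigma, size=count)
                    for c in CHANNELS
                }
            )
            df.insert(0, "population", pop)
            for k, v in meta.items():
                df[k] = v
            frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["population", *CHANNELS, "sample_id"])
    return pd.concat(frames, ignore_index=True)
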