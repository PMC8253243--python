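"""Arena analytics: social recognition, open-field occupancy, water-maze
learning.

Reads the simulated trajectories from results/data/, computes interaction-
zone occupancy and recognition metrics for the memory trial, open-field
annulus occupancy and distance, and a per-day escape-latency learning
curve with probe-trial readouts.  Writes results/behavior_*.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phenopipe import arena, io as pio, synthgen

RESULTS = Path("results")
DATA = RESULTS / "data"
SEED = 7


def sociobox() -> None:
    zones = pio.read_zoneset(DATA / "sociobox_zones.json")
    track = pio.read_trajectory(DATA / "sociobox_track.csv")
    schedule = arena.trial_schedule("sociobox")
    memory = schedule[-1]
    t0, t1 = memory.phases[1][1:]  # interaction stage after partition lift
    occ = arena.zone_occupancy(track, zones, t0, t1)
    pd.DataFrame([r.as_dict() for r in occ.values()]).to_csv(
        RESULTS / "behavior_sociobox_occupancy.csv", index=False
    )
    rec = arena.recognition_metrics(occ, zones.roles)
    pd.DataFrame([rec.__dict__]).to_csv(
        RESULTS / "behavior_recognition.csv", index=False
    )
    print(f"recognition: stranger {rec.stranger_pct_time:.1f}% of interaction time "
          f"vs {rec.mean_stimulus_pct_time:.1f}% per acquainted stimulus "
          f"(latency to stranger {rec.latency_to_stranger:.1f} s)")


def open_field() -> None:
    zones = pio.read_zoneset(DATA / "openfield_zones.json")
    track = pio.read_trajectory(DATA / "openfield_track.csv")
    occ = arena.zone_occupancy(track, zones, 0.0, 420.0)
    df = pd.DataFrame([r.as_dict() for r in occ.values()])
    df["distance"] = arena.path_length(track, 0.0, 420.0)
    df.to_csv(RESULTS / "behavior_openfield.csv", index=False)
    total = df["total_time"].sum()
    print("open field: " + ", ".join(
        f"{row.zone} {row.total_time:.0f}s" for row in df.itertuples()
    ) + f" (sum {total:.0f}s of 420s)")


def water_maze() -> None:
    rng = np.random.default_rng(SEED)
    # improving learner: latencies shrink across 8 days, capped at 90 s
    days = 8
    latencies = np.clip(
        rng.normal(75.0 * 0.72 ** np.repeat(np.arange(days), 4), 6.0), 2.0, 90.0
    )
    curve = arena.learning_curve(latencies)
    pd.DataFrame({"day": np.arange(1, days + 1), "mean_latency_s": curve}).to_csv(
        RESULTS / "behavior_mwm_learning.csv", index=False
    )

    quadrants = arena.quadrant_zones(0.0, 0.0, 60.0, target="NE")
    probe_track = synthgen.gen_trajectory(quadrants, 90.0, 25.0, seed=SEED)
    probe = arena.probe_metrics(probe_track, quadrants, "NE")
    pd.DataFrame([probe.__dict__]).to_csv(
        RESULTS / "behavior_mwm_probe.csv", index=False
    )
    print(f"water maze: day-1 latency {curve[0]:.0f}s -> day-{days} {curve[-1]:.0f}s; "
          f"probe: {probe.time_in_target:.1f}s in target quadrant, "
          f"{probe.distance:.0f} px swum")


if __name__ == "__main__":
    RESULTS.mkdir(exist_ok=True)
    sociobox()
    open_field()
    water_maze()
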