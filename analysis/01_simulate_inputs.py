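"""Generate the synthetic study inputs used by the downstream analyses.

Small text artifacts (truth tables, signal tables, event tables, zone
layouts) go to results/data/; the bulky thermal frame stack goes to
scratch/ as a float32 TIFF with a JSON sidecar.
"""

from pathlib import Path

import pandas as pd

from phenopipe import arena, io as pio, synthgen

SEED = 7
RESULTS = Path("results/data")
SCRATCH = Path("scratch")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    # thermal session: default scene, mild camera noise
    cfg = synthgen.ThermalSceneConfig(duration=10.0, noise_sd=0.2, seed=SEED)
    session, truth = synthgen.gen_thermal_session(cfg)
    pio.write_thermal_session(
        session, SCRATCH / "thermal_frames.tif", SCRATCH / "thermal_frames.json",
        arena_center=(320.0, 240.0), arena_radius=cfg.arena_radius,
    )
    pd.DataFrame(
        {"time": session.times, "true_body_temp": truth.body_temp,
         "true_tail_temp": truth.tail_temp, "true_ci": truth.ci}
    ).to_csv(RESULTS / "thermal_truth.csv", index=False)
    print(f"thermal session: {session.n_frames} frames -> {SCRATCH}/thermal_frames.tif")

    # open-field trajectory + social-recognition arena with scripted visits
    of_zones = arena.open_field_zones(0.0, 0.0, 60.0)
    of_track = synthgen.gen_trajectory(of_zones, 420.0, 20.0, seed=SEED)
    pio.write_trajectory(of_track, RESULTS / "openfield_track.csv")
    pio.write_zoneset(of_zones, RESULTS / "openfield_zones.json")

    sb_roles = arena.trial_schedule("sociobox")[-1].insert_roles
    sb_zones = arena.sociobox_zones(0.0, 0.0, 28.0, zone_depth=5.0, roles=sb_roles)
    visits = [("insert_5", 310.0, 350.0), ("insert_1", 360.0, 380.0),
              ("insert_3", 400.0, 415.0), ("insert_5", 430.0, 460.0)]
    sb_track = synthgen.gen_trajectory(
        sb_zones, 600.0, 8.0, seed=SEED + 1, scripted_visits=visits
    )
    pio.write_trajectory(sb_track, RESULTS / "sociobox_track.csv")
    pio.write_zoneset(sb_zones, RESULTS / "sociobox_zones.json")
    print(f"trajectories -> {RESULTS}/*.csv")

    # diffusion decay replicates at SNR 50
    b, signals = synthgen.gen_ivim_signals(
        1.0, 0.10, 1e-2, 7e-4, noise_sd=0.02, seed=SEED, n_replicates=20
    )
    long = pd.DataFrame(signals, columns=b).melt(
        var_name="b", value_name="signal", ignore_index=False
    )
    long.index.name = "replicate"
    long.reset_index().to_csv(RESULTS / "ivim_signals.csv", index=False)

    # bolus-passage multi-echo series
    dsc = synthgen.gen_dsc_series(0.05, 0.01, 2.0, 3.0, 10.0, n_frames=300,
                                  noise_sd=0.02, seed=SEED)
    rows = []
    for i, t in enumerate(dsc.times):
        for j, te in enumerate(dsc.tes):
            rows.append({"t": t, "te": te, "signal": dsc.signals[i, j]})
    pd.DataFrame(rows).to_csv(RESULTS / "dsc_series.csv", index=False)
    print(f"MRI signal tables -> {RESULTS}/ivim_signals.csv, dsc_series.csv")

    # flow-cytometry event tables with truth labels
    blood = synthgen.gen_flow_events(
        "blood",
        {"t_helper": 3000, "t_cytotoxic": 2500, "b_cell": 2000, "myeloid": 1500,
         "ungated_double_positive": 1000},
        seed=SEED,
    )
    blood.to_csv(RESULTS / "flow_blood_events.csv", index=False)
    brain = synthgen.gen_flow_events(
        "brain",
        {"microglia": 4000, "macrophage": 1000, "cd4_t": 1500, "cd8_t": 1200,
         "b_cell": 800, "plasma_cell": 500, "leukocyte_other": 700,
         "ungated_negative": 300},
        seed=SEED + 1,
    )
    brain.to_csv(RESULTS / "flow_brain_events.csv", index=False)
    print(f"flow event tables -> {RESULTS}/flow_*_events.csv")

    # startle table for the prepulse-inhibition analysis
    synthgen.gen_startle_table(n_animals=12, seed=SEED).to_csv(
        RESULTS / "startle_trials.csv", index=False
    )
    print(f"startle table -> {RESULTS}/startle_trials.csv")


if __name__ == "__main__":
    main()
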