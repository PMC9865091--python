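#!/usr/bin/env python
"""Build the synthetic validation cohort.

Emulates the two acquisition sessions of the dual-site study: 19 subjects
with simultaneous hand (reference) and foot (sock) electrodermal recordings,
and 15 subjects with simultaneous finger (reference) and ankle (sock)
photoplethysmograms — 300 s per recording at 1 kHz for EDA/PPG, with a
per-subject inter-device clock offset and shared optical sync pulses so the
alignment step is exercised end to end.

Foot-EDA measurability mirrors the study's spread: 8 subjects with a fully
null foot channel, 8 with partial low-end saturation, 3 fully measurable.
Ankle PPG shares the finger's beat train (same seed) but carries more noise
and baseline wander.  Signals go to scratch/cohort/ as delimited text with
ground-truth CSVs; a config echo and per-subject manifest go to results/.
"""

import json
from pathlib import Path

import numpy as np

from socksig.io import write_events_csv, write_signal_file
from socksig.simulate import (
    EdaSimConfig,
    PpgSimConfig,
    embed_sync_events,
    simulate_ancillary,
    simulate_dual_site_eda,
    simulate_ppg,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 20230105

N_EDA, N_PPG = 19, 15
# foot-measurability strata: fully null / partially saturated / fully measurable
FOOT_PROFILE = ["null"] * 8 + ["partial"] * 8 + ["full"] * 3


def eda_config(subject: int, profile: str, seed: int) -> EdaSimConfig:
    kw = dict(duration=300.0, sampling_rate=1000.0, seed=seed)
    if profile == "null":
        return EdaSimConfig(all_zero_foot=True, **kw)
    if profile == "partial":
        # foot tonic hugs the floor so drift crosses zero intermittently
        return EdaSimConfig(foot_tonic_level=0.25, tonic_drift_sd=0.4, **kw)
    return EdaSimConfig(foot_tonic_level=1.5, **kw)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    manifest = []

    for s in range(N_EDA):
        profile = FOOT_PROFILE[s]
        cfg = eda_config(s, profile, seed=SEED + s)
        hand, foot, truth = simulate_dual_site_eda(cfg)
        acc, temp = simulate_ancillary(300.0, 100.0, seed=SEED + 500 + s)
        offset = float(rng.uniform(0.2, 5.0))
        sync_hand, sync_foot = embed_sync_events(
            hand, foot, offset, pulse_times=[10.0, 150.0, 290.0 - 5.0]
        )
        sub = OUT / f"eda_{s:02d}"
        sub.mkdir(exist_ok=True)
        write_signal_file([hand, sync_hand], sub / "hand.txt")
        write_signal_file([foot, sync_foot], sub / "foot.txt")
        write_signal_file(acc + [temp], sub / "ancillary.txt")
        rows = [
            {"site": "hand", "event_time_s": t, "shared": int(sh), "lag_s": ""}
            for t, sh in zip(truth.hand_scr_times, truth.shared_flags)
        ] + [
            {"site": "foot", "event_time_s": t, "shared": "", "lag_s": ""}
            for t in truth.foot_scr_times
        ]
        write_events_csv(sub / "truth.csv", rows,
                         ["site", "event_time_s", "shared", "lag_s"])
        np.savetxt(sub / "planted_lags.txt", truth.planted_lags)
        manifest.append(
            {"subject": s, "kind": "eda", "profile": profile,
             "device_offset_s": round(offset, 4),
             "n_hand_events": int(truth.hand_scr_times.size),
             "n_foot_events": int(truth.foot_scr_times.size)}
        )

    for s in range(N_PPG):
        base = dict(duration=300.0, sampling_rate=1000.0,
                    mean_hr=float(rng.uniform(55, 90)), hr_sd=2.5,
                    seed=SEED + 1000 + s)
        finger_cfg = PpgSimConfig(noise_sd=0.02, baseline_wander_amp=0.05, **base)
        ankle_cfg = PpgSimConfig(noise_sd=0.20, baseline_wander_amp=0.30, **base)
        finger, truth = simulate_ppg(finger_cfg)   # same seed => same beat train
        ankle, _ = simulate_ppg(ankle_cfg)
        finger = finger.copy_with(name="ppg_finger")
        ankle = ankle.copy_with(name="ppg_ankle")
        sub = OUT / f"ppg_{s:02d}"
        sub.mkdir(exist_ok=True)
        write_signal_file([finger], sub / "finger.txt")
        write_signal_file([ankle], sub / "ankle.txt")
        write_events_csv(
            sub / "beats.csv",
            [{"channel": "truth", "event_time_s": t, "label": "systolic"}
             for t in truth.beat_times],
            ["channel", "event_time_s", "label"],
        )
        manifest.append(
            {"subject": s, "kind": "ppg", "mean_hr": round(base["mean_hr"], 1),
             "n_beats": int(truth.beat_times.size)}
        )

    (RESULTS / "cohort_manifest.json").write_text(
        json.dumps({"seed": SEED, "subjects": manifest}, indent=2) + "\n"
    )
    n_eda = sum(1 for m in manifest if m["kind"] == "eda")
    n_ppg = sum(1 for m in manifest if m["kind"] == "ppg")
    print(f"wrote {n_eda} EDA and {n_ppg} PPG synthetic subjects to {OUT}")


if __name__ == "__main__":
    main()
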