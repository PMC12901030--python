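"""Simulate one synthetic session: localizer, decision epochs, gaze.

Writes the session (binary arrays + sidecars) under scratch/session/ and
a small summary under results/.  Later stages read from scratch/session/.
"""

import json
from pathlib import Path

import numpy as np

from attnrhythm.design import enumerate_design
from attnrhythm.io import save_epochs, save_events, save_gaze
from attnrhythm.synth import (
    AttentionProcessSpec,
    GazeCoupling,
    make_forward_model,
    simulate_decision_session,
    simulate_gaze,
    simulate_localizer,
)

SEED = 2024
N_SENSORS = 24
N_TRIALS = 150
SNR = 1.0

root = Path(__file__).resolve().parents[1]
session_dir = root / "scratch" / "session"
results = root / "results"
results.mkdir(exist_ok=True)

session_dir.mkdir(parents=True, exist_ok=True)

design = enumerate_design()
fm = make_forward_model(N_SENSORS, seed=SEED, snr=SNR)
np.savez(session_dir / "forward_model.npz",
         patterns=fm.patterns, noise_cov=fm.noise_cov)

localizer = simulate_localizer(fm, n_blocks=18, snr=SNR, seed=SEED + 1)
save_epochs(session_dir, localizer, name="localizer")

process = AttentionProcessSpec(osc_freq=11.0, osc_depth=0.5)
epochs, truth, _ = simulate_decision_session(
    design, fm, process, n_trials=N_TRIALS, seed=SEED + 2, snr=SNR)
save_epochs(session_dir, epochs, name="decision")
save_events(session_dir / "ground_truth_events.tsv", truth)

gaze = simulate_gaze(
    truth, N_TRIALS, 3.8,
    coupling=GazeCoupling("saccade_precedes_switch", delta=0.15, p=0.6),
    seed=SEED + 3)
save_gaze(session_dir / "gaze.tsv", gaze)

summary = dict(
    seed=SEED, n_sensors=N_SENSORS, snr=SNR,
    design_trials=design.n_trials,
    localizer_trials=localizer.n_trials,
    decision_trials=epochs.n_trials,
    planted_events=len(truth),
    planted_switch_fraction=float((truth["label"] == "switch").mean()),
    planted_saccades=int(sum(len(a) for a in gaze.planted_saccade_times)),
)
(results / "01_session_summary.json").write_text(json.dumps(summary, indent=2))
print("Simulated session:")
for k, v in summary.items():
    print(f"  {k}: {v}")
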