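"""Train the inverted encoding model on the simulated localizer.

Selects the training window by leave-one-block-out cross-validation,
fits the per-channel weights, pre-whitens them with the shrinkage
residual covariance, and verifies the g'w = 1 identity.  The model is
stored under scratch/session/; the selection table goes to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from attnrhythm.encoding import select_training_epoch, train_encoding_model
from attnrhythm.io import load_epochs

root = Path(__file__).resolve().parents[1]
session_dir = root / "scratch" / "session"
results = root / "results"

localizer = load_epochs(session_dir, name="localizer")
print(f"Localizer: {localizer.n_trials} trials, "
      f"{localizer.n_sensors} sensors at {localizer.fs:g} Hz")

candidates = [(0.10 + 0.01 * i, 0.13 + 0.01 * i) for i in range(13)]
window, scores = select_training_epoch(localizer, candidates)
table = pd.DataFrame(dict(
    window_start=[w[0] for w in sorted(candidates)],
    window_stop=[w[1] for w in sorted(candidates)],
    heldout_score=scores,
))
table.to_csv(results / "02_window_selection.csv", index=False)
print(f"Selected training window: {window[0]:.3f}-{window[1]:.3f} s "
      f"(held-out score {scores.max():.3f})")

model = train_encoding_model(localizer, training_window=window)
gw = np.einsum("sk,sk->k", model.G, model.W)
assert np.allclose(gw, 1.0, atol=1e-8), "g'w identity violated"
print(f"g'w per channel: {gw}  (identity holds)")
print(f"shrinkage intensities: {model.shrinkage.round(4)}")

np.savez(session_dir / "encoding_model.npz", W=model.W, G=model.G,
         shrinkage=model.shrinkage, centers=model.basis.centers,
         alpha=model.basis.alpha, training_window=window)
(results / "02_encoding.json").write_text(json.dumps(dict(
    training_window=list(window),
    heldout_score=float(scores.max()),
    shrinkage=[float(g) for g in model.shrinkage],
), indent=2))
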