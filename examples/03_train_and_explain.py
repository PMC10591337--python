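"""Train a small GATv2 on synthetic spectra and score its explanations.

Generates 120 synthetic molecules with planted per-carbon transitions,
trains a desk-scale attention model, then checks both prediction quality
(validation RSE against the constant mean-spectrum baseline) and
explanation quality (CAM-vs-ground-truth AUC, 0.5 = random baseline).
Runs in well under a minute on one CPU core.
"""

import numpy as np

import xasgnn as x
from xasgnn.evaluation import evaluate_model
from xasgnn.spectra import constant_mean_baseline

records = x.generate_dataset(120, seed=7)
pairs = x.training_pairs(records)
grid = pairs[0][1].grid

model = x.build_model(x.ModelConfig(
    architecture="gatv2", hidden_sizes=(32, 64), n_out=grid.n_grid, seed=1))
model, hist = x.train(model, pairs, x.TrainConfig(epochs=120, seed=2))

val = hist["val_indices"]
baseline = constant_mean_baseline(
    [pairs[i][1] for i in range(len(pairs)) if i not in set(val)])
baseline_rse = float(np.mean([x.rse(pairs[i][1], baseline) for i in val]))
print(f"validation RSE {hist['best_val_rse']:.3f} "
      f"vs mean-spectrum baseline {baseline_rse:.3f}")

report = evaluate_model(model, [records[i] for i in val], grid)
s = report.summary()
print(f"attribution AUC over {s['n_peaks']} peaks: "
      f"core mean {s['mean_auc_core']:.2f} "
      f"(median {s['median_auc_core']:.2f}), "
      f"virtual mean {s['mean_auc_virtual']:.2f} "
      f"(median {s['median_auc_virtual']:.2f})")
# AUC well above 0.5 means the model ranks the truly contributing atoms
# above the rest at the spectrum's peaks, not just fits the curve.
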