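#!/usr/bin/env python
"""Sparse feature selection, SRC classification and final metrics.

Reads scratch/features.csv and results/split.json.  On the training split:
L0 feature ranking (eta = 0.1) and 10-fold cross-validated sequential forward
selection (top-5 seed, candidates up to rank 100).  The selected features
feed the sparse-representation classifier (gamma = 0.05) on the held-out
test split.  Also reports the unsupervised 2-group clustering agreement of
the selected features on the full cohort.

Writes results/selection.json, results/classifier_outputs.csv,
results/roc_points.csv and results/metrics.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from dnrfc import cohort as coh
from dnrfc import evaluate as ev
from dnrfc import graphs
from dnrfc import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 20250925

table = graphs.read_feature_table(SCRATCH / "features.csv")
split = json.loads((RESULTS / "split.json").read_text())
train_idx = np.array(split["train"])
test_idx = np.array(split["test"])
labels = table["label"].to_numpy()

config = pl.PipelineConfig(cv_seed=SEED)
ranking, subset, outputs, metrics = pl.model_and_evaluate(
    table, train_idx, test_idx, config
)
names = [c for c in table.columns if c not in ("subject_id", "label")]
selected_names = [names[i] for i in subset.features]
n_low = sum(n.startswith("low_cc_") for n in selected_names)
print(f"selected {len(subset.features)} features "
      f"({n_low} low-order, {len(subset.features) - n_low} high-order); "
      f"training CV accuracy {subset.cv_metric:.4f}")

x = table[names].to_numpy(float)
agreement = ev.clustering_agreement(x[:, subset.features], labels)
print(f"unsupervised 2-group clustering agreement: {agreement}/{len(labels)}")

(RESULTS / "selection.json").write_text(json.dumps({
    "selected_features": subset.features,
    "selected_names": selected_names,
    "cv_accuracy": subset.cv_metric,
    "history": subset.history,
    "clustering_agreement": int(agreement),
}, indent=1))

rows = [{
    "subject_id": o.subject_id,
    "true": t,
    "predicted": o.predicted_label,
    "r_dnr": o.residuals[coh.DNR],
    "r_non": o.residuals[coh.NON_DNR],
    "score": o.score,
} for o, t in zip(outputs, labels[test_idx])]
pd.DataFrame(rows).to_csv(RESULTS / "classifier_outputs.csv", index=False)
metrics["roc"].to_csv(RESULTS / "roc_points.csv", index=False)

counts = metrics["confusion"]
summary = {k: round(float(metrics[k]), 4) for k in ("AUC", "ACC", "SEN", "SPE")}
summary["confusion"] = {"TP": counts.tp, "FN": counts.fn,
                        "TN": counts.tn, "FP": counts.fp}
(RESULTS / "metrics.json").write_text(json.dumps(summary, indent=1))
print("held-out test metrics:", summary)
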