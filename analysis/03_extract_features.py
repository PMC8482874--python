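#!/usr/bin/env python
"""Build multi-order FC networks and the 390-feature table.

Reads scratch/cohort_preprocessed/, computes per subject the 26 sliding-window
(w=90, s=1) correlation matrices, learns the 300-group edge clustering on the
training split only, builds cluster-level high-order networks, and extracts
90 + 300 weighted clustering coefficients per subject.  Also runs the
univariate screening (per-feature two-sample t-tests) on the full cohort.

Writes scratch/features.csv (bulky intermediate) plus
results/edge_clusters.{csv,json}, results/split.json and results/screening.json.
"""

import json
from pathlib import Path

import numpy as np

from dnrfc import cohort as coh
from dnrfc import evaluate as ev
from dnrfc import fc, graphs
from dnrfc import pipeline as pl

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 20250925

subjects = coh.read_cohort(SCRATCH / "cohort_preprocessed" / "manifest.csv")
labels = np.array([s.label for s in subjects])
train_idx, test_idx = ev.split_cohort(labels, ev.SplitSpec(seed=SEED))
print(f"split: {len(train_idx)} train / {len(test_idx)} test "
      f"({np.sum(labels[train_idx] == coh.DNR)} / {np.sum(labels[test_idx] == coh.DNR)} DNR)")

config = pl.PipelineConfig(window_length=90, window_step=1, n_clusters=300,
                           cluster_seed=SEED)
train_ids = [subjects[i].subject_id for i in train_idx]
table, clustering = pl.extract_features(subjects, train_ids, config)
graphs.write_feature_table(table, SCRATCH / "features.csv")
fc.save_edge_clustering(clustering, RESULTS)
(RESULTS / "split.json").write_text(json.dumps({
    "seed": SEED,
    "train": [int(i) for i in train_idx],
    "test": [int(i) for i in test_idx],
}))
print(f"feature table: {table.shape[0]} subjects x {table.shape[1] - 2} features")

x = table.drop(columns=["subject_id", "label"]).to_numpy(float)
tt = ev.feature_ttests(x, labels)
counts = ev.significance_counts(tt)
(RESULTS / "screening.json").write_text(json.dumps(
    {"p<0.05": counts[0.05], "p<0.01": counts[0.01]}
))
print(f"univariate screening: {counts[0.05]} features with p<0.05, "
      f"{counts[0.01]} with p<0.01")
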