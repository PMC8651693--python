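"""Assign proteins to compartments by k-means marker voting.

Clusters max-normalized fractionation profiles, assigns each cluster to
the location whose markers dominate it, and reports per-compartment
precision, recall and F-score — the statistics that quantify how cleanly
a fractionation protocol separates subcellular locations.
"""

from subcellflow.compartments import (assign_clusters, cluster_profiles,
                                      max_normalize, score_compartments)
from subcellflow.io import PipelineConfig
from subcellflow.pipeline import markers_from_truth, simulate_dataset
from subcellflow.preprocess import preprocess
from subcellflow.translocation import scale_profiles

cfg = PipelineConfig(seed=2, sim_n_features=600)
table, truth = simulate_dataset(cfg)
clean = preprocess(table)

profiles = scale_profiles(clean).profiles["control"].dropna()
markers = markers_from_truth(truth, per_compartment=10)
normalized = max_normalize(profiles)
labels = cluster_profiles(normalized, k=2 * 6, restarts=25, seed=cfg.seed)

report = assign_clusters(labels, markers)
scores = score_compartments(report, markers)
print(f"{labels.nunique()} clusters over {len(profiles)} proteins, "
      f"{len(markers)} markers in 6 compartments")
print("\nper-compartment scores (truncated to 2 decimals, as reported):")
print(scores[["precision_2dp", "recall_2dp", "fscore_2dp"]].to_string())
print("\nF = 1 means every marker of that location ended up in clusters "
      "assigned to it, with no foreign markers voting there.")
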