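"""Marker-based compartment assignment and scoring.

Profiles are max-normalized, grouped by k-means, and each group is
assigned to the subcellular location whose markers dominate it: if a
group holds two cytosol markers and no others, every protein in the
group is assigned to the cytosol with a precision of 1; an extra
nucleus marker drops the precision to 2/3 (reported as 0.66). Per
compartment, precision and recall over the marker proteins and their
harmonic mean (F-score) summarize how cleanly the fractionation
separates locations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "MarkerMap",
    "AssignmentReport",
    "max_normalize",
    "cluster_profiles",
    "assign_clusters",
    "score_compartments",
    "marker_centroid_correlation",
    "truncate2",
]

log = logging.getLogger(__name__)

#: feature id -> compartment label
MarkerMap = dict


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals, as assignment reports print
    2/3 as 0.66. A tiny epsilon guards against binary representation of
    exact hundredths."""
    if not np.isfinite(x):
        return x
    return math.floor(x * 100 + 1e-9) / 100


def max_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature's (linear-scale) fraction vector by its maximum.

    Entries end up in [0, 1] with the peak fraction exactly 1. All-zero
    features are dropped with a warning.
    """
    values = profiles.fillna(0.0)
    if (values.to_numpy() < 0).any():
        raise ValueError("max_normalize expects nonnegative linear-scale values")
    peaks = values.max(axis=1)
    zero = peaks <= 0
    if zero.any():
        log.warning("max_normalize: dropping %d all-zero features", int(zero.sum()))
        values, peaks = values.loc[~zero], peaks[~zero]
    return values.div(peaks, axis=0)


def cluster_profiles(
    normalized: pd.DataFrame, k: int, restarts: int = 25, seed: int = 0
) -> pd.Series:
    """Group normalized profiles with Euclidean k-means, best of
    ``restarts`` initializations by within-cluster sum of squares.
    Deterministic for a fixed seed."""
    if k > len(normalized):
        raise ValueError(f"k={k} exceeds the number of features {len(normalized)}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(normalized.to_numpy())
    return pd.Series(labels, index=normalized.index, name="cluster")


@dataclass
class AssignmentReport:
    """Cluster-to-compartment assignment by marker voting.

    ``clusters``: per cluster — assigned compartment (or None on a tie or
    with no markers), marker tally, marker count, and cluster precision
    (markers of the assigned compartment / all markers in the cluster).
    ``feature_assignments``: every feature inherits its cluster's label.
    """

    clusters: pd.DataFrame
    feature_assignments: pd.Series
    tallies: dict[int, dict[str, int]]


def assign_clusters(labels: pd.Series, markers: MarkerMap) -> AssignmentReport:
    """Assign each cluster to the compartment with the most markers in it.

    Ties and marker-free clusters stay unassigned (conservative). Cluster
    precision is the fraction of the cluster's markers that belong to the
    assigned compartment.
    """
    if not markers:
        raise ValueError("need at least one marker")
    rows, tallies = [], {}
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        tally: dict[str, int] = {}
        for feat in members:
            if feat in markers:
                tally[markers[feat]] = tally.get(markers[feat], 0) + 1
        tallies[int(cluster)] = tally
        assigned, precision = None, np.nan
        if tally:
            best = max(tally.values())
            top = [c for c, n in tally.items() if n == best]
            if len(top) == 1:
                assigned = top[0]
                precision = best / sum(tally.values())
            else:
                log.info("cluster %s: marker vote tied %s; left unassigned",
                         cluster, top)
        rows.append((int(cluster), assigned, sum(tally.values()), len(members),
                     precision))
    clusters = pd.DataFrame(
        rows, columns=["cluster", "assigned", "n_markers", "n_features", "precision"]
    ).set_index("cluster")
    assigned_of = clusters["assigned"]
    feature_assignments = labels.map(assigned_of).rename("compartment")
    return AssignmentReport(clusters, feature_assignments, tallies)


def score_compartments(
    report: AssignmentReport, markers: MarkerMap
) -> pd.DataFrame:
    """Per-compartment precision, recall and F-score over the markers.

    recall(c)    = markers of c assigned to c / all markers of c
    precision(c) = markers of c assigned to c / all markers assigned to c
    F(c)         = harmonic mean, 0 when precision + recall = 0.

    Compartments with no markers are omitted. Values are reported at full
    precision plus truncated to two decimals (2/3 prints as 0.66).
    """
    assigned = report.feature_assignments
    compartments = sorted({c for c in markers.values()})
    rows = []
    for comp in compartments:
        of_c = [f for f, c in markers.items() if c == comp]
        if not of_c:
            continue
        correct = sum(1 for f in of_c if f in assigned.index and assigned[f] == comp)
        assigned_to_c = sum(
            1 for f in markers if f in assigned.index and assigned[f] == comp
        )
        recall = correct / len(of_c)
        precision = correct / assigned_to_c if assigned_to_c else np.nan
        if np.isnan(precision) or precision + recall == 0:
            fscore = 0.0 if not np.isnan(precision) else np.nan
        else:
            fscore = 2 * precision * recall / (precision + recall)
        rows.append((comp, precision, recall, fscore,
                     truncate2(precision), truncate2(recall), truncate2(fscore)))
    return pd.DataFrame(
        rows,
        columns=["compartment", "precision", "recall", "fscore",
                 "precision_2dp", "recall_2dp", "fscore_2dp"],
    ).set_index("compartment")


def marker_centroid_correlation(
    profiles: pd.DataFrame, markers: MarkerMap
) -> pd.DataFrame:
    """Pearson correlation of each marker's profile to its compartment
    centroid (the mean profile of the compartment's markers).

    Compartments with fewer than 2 quantified markers are skipped;
    zero-variance profiles get an undefined (NaN) correlation and a flag.
    """
    rows = []
    by_comp: dict[str, list[str]] = {}
    for feat, comp in markers.items():
        if feat in profiles.index:
            by_comp.setdefault(comp, []).append(feat)
    for comp, feats in sorted(by_comp.items()):
        if len(feats) < 2:
            log.info("centroid correlation: compartment %r has <2 markers; skipped",
                     comp)
            continue
        block = profiles.loc[feats]
        centroid = block.mean(axis=0).to_numpy()
        c_center = centroid - centroid.mean()
        c_norm = np.sqrt((c_center ** 2).sum())
        for feat in feats:
            v = block.loc[feat].to_numpy(dtype=float)
            v_center = v - v.mean()
            v_norm = np.sqrt((v_center ** 2).sum())
            if v_norm == 0 or c_norm == 0:
                rows.append((feat, comp, np.nan, True))
            else:
                r = float((v_center * c_center).sum() / (v_norm * c_norm))
                rows.append((feat, comp, r, False))
    return pd.DataFrame(
        rows, columns=["feature", "compartment", "r", "zero_variance"]
    ).set_index("feature")
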