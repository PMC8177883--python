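"""Punishment-sensitivity phenotyping.

Participants are partitioned on their final-block preference ratio by
k-means (Lloyd's algorithm, 50 restarts) for k in {2, 3, 4}; the k with the
highest mean silhouette wins, ties going to the smaller k.  The cluster with
the lowest mean final ratio (strongest avoidance of the punished response)
is labelled *sensitive*, the one with the highest is *insensitive*, and any
middle cluster is *other*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

DEFAULT_K_VALUES = (2, 3, 4)
N_RESTARTS = 50


class DegenerateDataError(ValueError):
    """All input values identical: silhouettes are undefined."""


@dataclass
class ClusterResult:
    chosen_k: int
    labels: np.ndarray               # str array: sensitive / insensitive / other
    cluster_ids: np.ndarray          # raw k-means integer labels for chosen k
    mean_silhouette: dict            # k -> mean silhouette
    min_silhouette: float            # of the chosen solution
    silhouette_values: np.ndarray    # per participant, chosen solution
    cluster_means: dict              # label -> mean final ratio
    separation: float                # min adjacent mean gap / pooled within sd

    def to_frame(self, final_ratios: np.ndarray,
                 participant_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "final_ratio": np.asarray(final_ratios, dtype=float),
            "cluster_label": self.labels,
            "silhouette": self.silhouette_values,
        })
        if participant_ids is not None:
            df.insert(0, "participant_id", list(participant_ids))
        return df


def cluster_sensitivity(final_ratios, seed: int = 0,
                        k_values=DEFAULT_K_VALUES) -> ClusterResult:
    """Cluster final-block preference ratios and label the phenotypes.

    Deterministic given ``seed``; raises :class:`DegenerateDataError` when
    every value is identical and a plain ``ValueError`` for fewer than five
    finite inputs.
    """
    x = np.asarray(final_ratios, dtype=float)
    if x.ndim != 1:
        raise ValueError("final_ratios must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("final_ratios must be finite")
    if x.size < 5:
        raise ValueError("need at least 5 participants to cluster")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all final ratios identical; silhouette undefined")

    X = x.reshape(-1, 1)
    fits, sils = {}, {}
    for k in sorted(k_values):
        if k >= x.size:
            continue
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed).fit(X)
        fits[k] = km
        sils[k] = float(silhouette_score(X, km.labels_))
    if not fits:
        raise ValueError("no admissible k in k_values for this sample size")
    chosen_k = min(fits, key=lambda k: (-sils[k], k))
    km = fits[chosen_k]
    sil_values = silhouette_samples(X, km.labels_)

    means = {c: float(x[km.labels_ == c].mean()) for c in range(chosen_k)}
    order = sorted(means, key=means.get)          # ascending mean ratio
    name_of = {order[0]: "sensitive", order[-1]: "insensitive"}
    for mid in order[1:-1]:
        name_of[mid] = "other"
    labels = np.array([name_of[c] for c in km.labels_])

    # Separation index: smallest gap between adjacent cluster means in units
    # of the pooled within-cluster sd.  A unimodal sample split by k-means
    # typically lands near 2-3; well-separated modes score much higher.
    ordered = [means[c] for c in order]
    ss_within = sum(float(np.sum((x[km.labels_ == c] - means[c]) ** 2))
                    for c in range(chosen_k))
    pooled_sd = np.sqrt(ss_within / max(x.size - chosen_k, 1))
    min_gap = min(b - a for a, b in zip(ordered, ordered[1:]))
    separation = float(min_gap / pooled_sd) if pooled_sd > 0 else float("inf")

    return ClusterResult(
        chosen_k=chosen_k,
        labels=labels,
        cluster_ids=km.labels_.copy(),
        mean_silhouette=sils,
        min_silhouette=float(sil_values.min()),
        silhouette_values=sil_values,
        cluster_means={name_of[c]: means[c] for c in means},
        separation=separation,
    )


def compare_clusters(summary: pd.DataFrame, labels: pd.Series | dict) -> pd.DataFrame:
    """Join cluster labels onto a tidy per-block metric table.

    ``summary`` must have ``participant_id`` plus metric columns (long or
    wide); returns a long table keyed by (participant, cluster, metric,
    block).  Raises if any participant in ``summary`` lacks a label.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    if summary.empty:
        return pd.DataFrame(columns=["participant_id", "cluster", "metric",
                                     "block", "value"])
    missing = set(summary["participant_id"]) - set(labels.index)
    if missing:
        raise ValueError(f"no cluster label for participants: {sorted(missing)[:5]}")
    id_cols = [c for c in ("participant_id", "block", "phase") if c in summary.columns]
    long = summary.melt(id_vars=id_cols, var_name="metric", value_name="value")
    long["cluster"] = long["participant_id"].map(labels)
    if "block" not in long.columns:
        long["block"] = "all"
    return long[["participant_id", "cluster", "metric", "block", "value"]]
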