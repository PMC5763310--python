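"""Clustering evaluation: NMI, accuracy with optimal matching, silhouette.

NMI is computed from the contingency table N_{C,C*} of the two partitions:

    NMI = sum_{C,C*} N_{C,C*} log(N N_{C,C*} / (N_C N_{C*}))
          / sqrt( (sum_C N_C log(N_C/N)) (sum_{C*} N_{C*} log(N_{C*}/N)) )

(the geometric-mean normalization; the log base cancels). 0*log(0) := 0, and
if either partition has a single cluster the normalizer vanishes and NMI is
defined as 0 — the standard convention, continuous with the independent case.

ACC is the best fraction of matching labels over one-to-one relabelings of
the prediction ("a suitable class ordering"), found by optimal assignment on
the contingency table, padded to square when the cluster counts differ.

The silhouette of a sample x is s_x = (n_x - m_x) / max(m_x, n_x) with m_x
the mean Euclidean distance to its own cluster and n_x the mean distance to
the nearest other cluster; samples in singleton clusters get s_x = 0. The
package evaluates silhouettes on the spectral embedding of its own results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_samples

__all__ = ["EvaluationReport", "nmi", "acc", "silhouette", "aggregate",
           "evaluate_replicates"]


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(
            f"label vectors differ in length: {pred.size} vs {truth.size}")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)
    return table


def nmi(pred, truth) -> float:
    """Normalized mutual information between two labelings, in [0, 1]."""
    table = _contingency(pred, truth)
    N = table.sum()
    Nc = table.sum(axis=1)
    Ns = table.sum(axis=0)
    nz = table > 0
    num = float(np.sum(
        table[nz] * np.log(N * table[nz] / np.outer(Nc, Ns)[nz])))
    hc = float(np.sum(Nc * np.log(Nc / N)))
    hs = float(np.sum(Ns * np.log(Ns / N)))
    denom = np.sqrt(hc * hs)
    if denom <= 0:  # a single-cluster partition on either side
        return 0.0
    val = num / denom
    # clip roundoff just outside [0, 1]
    return float(min(max(val, 0.0), 1.0))


def acc(pred, truth) -> float:
    """Clustering accuracy under the best one-to-one label matching."""
    table = _contingency(pred, truth)
    r, c = table.shape
    size = max(r, c)
    padded = np.zeros((size, size), dtype=np.int64)
    padded[:r, :c] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum() / table.sum())


def silhouette(embedding: np.ndarray, labels) -> float:
    """Mean per-sample silhouette on Euclidean distances in the embedding."""
    labels = np.asarray(labels).ravel()
    X = np.asarray(embedding, dtype=float)
    if X.shape[0] != labels.size:
        raise ValueError("embedding rows and labels differ in length")
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(np.mean(silhouette_samples(X, labels, metric="euclidean")))


def aggregate(values) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(R), sample sd) of replicate values."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot aggregate an empty sequence")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class EvaluationReport:
    """Replicate-averaged clustering scores with standard errors."""

    nmi_mean: float
    nmi_se: float
    acc_mean: float
    acc_se: float
    per_replicate: pd.DataFrame
    silhouette_mean: float | None = None


def evaluate_replicates(
    replicate_labels: np.ndarray,
    truth,
    embedding: np.ndarray | None = None,
) -> EvaluationReport:
    """Score every k-means replicate against the truth and average the metrics.

    The reported means average the metric over replicates (labels themselves
    are never averaged). If an embedding is given, the silhouette of each
    replicate labeling is averaged as well.
    """
    reps = np.atleast_2d(np.asarray(replicate_labels))
    nmis = np.array([nmi(r, truth) for r in reps])
    accs = np.array([acc(r, truth) for r in reps])
    cols = {"replicate": np.arange(len(reps)), "nmi": nmis, "acc": accs}
    sil_mean = None
    if embedding is not None:
        sils = np.array([
            silhouette(embedding, r) if np.unique(r).size > 1 else np.nan
            for r in reps
        ])
        cols["silhouette"] = sils
        sil_mean = float(np.nanmean(sils))
    nmi_mean, nmi_se = aggregate(nmis)
    acc_mean, acc_se = aggregate(accs)
    return EvaluationReport(
        nmi_mean=nmi_mean, nmi_se=nmi_se,
        acc_mean=acc_mean, acc_se=acc_se,
        per_replicate=pd.DataFrame(cols),
        silhouette_mean=sil_mean,
    )
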