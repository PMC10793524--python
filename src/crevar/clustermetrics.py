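"""Entropy-based agreement between dissection labels and clusters.

Given the contingency table ``a_ck`` of cells by class (ground-truth
dissection/FACS label) and cluster, homogeneity ``h`` measures whether
each cluster holds a single class, completeness ``c`` whether each class
lands in a single cluster, and the V-measure ``V_beta`` is their weighted
harmonic mean, ``(1 + beta) h c / (beta h + c)``; as beta grows V
approaches c, and as beta shrinks it approaches h. Entropies use the
natural log (the base cancels in every ratio) with ``0 log 0 := 0``, and
``h`` (resp. ``c``) is defined as 1 whenever the conditional entropy
``H(C|K)`` (resp. ``H(K|C)``) is exactly zero.

Per-cluster purity is the maximum class share of the cluster,
``p_k = max_c a_ck / sum_c a_ck`` (values in ``[1/C, 1]``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ClusterContingency:
    """Classes-by-clusters cell count matrix."""

    a: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        if self.a.ndim != 2:
            raise ValueError("contingency table must be 2-D")
        if np.any(self.a < 0):
            raise ValueError("negative cell count")
        if self.a.sum() <= 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return int(self.a.sum())


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x > 0
    out[nz] = x[nz] * np.log(y[nz])
    return out


def cluster_metrics(table: ClusterContingency | np.ndarray, beta: float = 1.0):
    """Homogeneity, completeness and V_beta for a contingency table."""
    if not isinstance(table, ClusterContingency):
        table = ClusterContingency(table)
    a = table.a.astype(float)
    N = a.sum()
    class_tot = a.sum(axis=1)   # per class c
    clust_tot = a.sum(axis=0)   # per cluster k
    # H(C|K) = -sum_ck (a/N) log(a / a_.k)
    h_c_given_k = -np.sum(_xlogy(a / N, a / np.where(clust_tot == 0, 1, clust_tot)))
    h_k_given_c = -np.sum(_xlogy(a / N, (a.T / np.where(class_tot == 0, 1,
                                                        class_tot)).T))
    h_c = -np.sum(_xlogy(class_tot / N, class_tot / N))
    h_k = -np.sum(_xlogy(clust_tot / N, clust_tot / N))
    tol = 1e-12
    h = 1.0 if h_c_given_k <= tol else 1.0 - h_c_given_k / h_c
    c = 1.0 if h_k_given_c <= tol else 1.0 - h_k_given_c / h_k
    if h + c == 0:
        v = 0.0
    else:
        v = (1.0 + beta) * h * c / (beta * h + c)
    return float(h), float(c), float(v)


def cluster_purity(table: ClusterContingency | np.ndarray) -> np.ndarray:
    """Per-cluster maximum class share; empty clusters are NaN."""
    if not isinstance(table, ClusterContingency):
        table = ClusterContingency(table)
    a = table.a.astype(float)
    tot = a.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = a.max(axis=0) / tot
    p[tot == 0] = np.nan
    return p
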