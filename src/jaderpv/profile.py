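"""Drug x adverse-event profiling: ln(ROR) matrix, PCA, Ward clustering.

Each of a panel of drugs (observations) is profiled over a panel of related
adverse-event preferred terms (variables) by the natural log of its
half-corrected reporting odds ratio. A principal component analysis on the
correlation matrix summarises the event panel into a few orthogonal axes;
loadings are reported as variable–component correlations, so an event's
squared loadings over all components sum to 1. Events are then clustered by
Ward's minimum-variance method on the Euclidean geometry of their loadings
on the first three components, and the dendrogram is cut into k groups
(k = 2 separates mechanistically distinct event families).

Eigenvector signs are arbitrary; each component is oriented so that its
largest-|loading| entry is positive, which fixes plot orientation and the
loading coordinates fed to the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from sklearn.base import BaseEstimator

from .contingency import build_contingency, ror
from .errors import DegenerateDesignError, InsufficientDataError, JaderPvError


def filter_events_by_reports(cases: pd.DataFrame, events, min_reports: int = 20) -> list:
    """Keep event terms reported in at least `min_reports` cases."""
    counts = count_event_reports(cases, events)
    return [e for e in events if counts[e] >= min_reports]


def count_event_reports(cases: pd.DataFrame, events) -> dict:
    """Number of cases reporting each term."""
    counts = {e: 0 for e in events}
    wanted = set(events)
    for s in cases["events"]:
        for e in s & wanted:
            counts[e] += 1
    return counts


def build_ror_matrix(cases: pd.DataFrame, drugs, events,
                     min_reports: int = 20) -> pd.DataFrame:
    """ln(half-corrected ROR) for every drug x event pair.

    Events with fewer than `min_reports` total reports are dropped first.
    The half correction keeps every cell finite even for never-co-reported
    pairs. Raises InsufficientDataError if fewer than 2 drugs or 2 events
    remain.
    """
    kept_events = filter_events_by_reports(cases, list(events), min_reports)
    drugs = list(drugs)
    if len(drugs) < 2 or len(kept_events) < 2:
        raise InsufficientDataError(
            f"need >=2 drugs and >=2 events; got {len(drugs)} drugs, "
            f"{len(kept_events)} events after the >={min_reports}-report filter")
    values = np.empty((len(drugs), len(kept_events)))
    for j, e in enumerate(kept_events):
        for i, d in enumerate(drugs):
            point, _, _ = ror(build_contingency(cases, d, e))
            values[i, j] = np.log(point)
    return pd.DataFrame(values, index=drugs, columns=kept_events)


@dataclass
class PcaResult:
    """Correlation-matrix PCA of an observations x variables frame."""

    loadings: pd.DataFrame        # variable x component correlations
    scores: pd.DataFrame          # observation x component coordinates
    contribution_ratios: np.ndarray  # % variance per retained component
    eigenvalues: np.ndarray


def pca(matrix: pd.DataFrame) -> PcaResult:
    """PCA on the correlation matrix of `matrix` (columns = variables).

    Retains min(n_obs - 1, n_var) components (the rank bound of a
    correlation matrix); contribution ratios are 100 * eigenvalue / n_var
    and sum to 100 over the retained components. Each component's sign is
    oriented so its largest-|loading| entry is positive.
    """
    X = matrix.to_numpy(dtype=float)
    n_obs, n_var = X.shape
    if n_obs < 2 or n_var < 2:
        raise InsufficientDataError("PCA needs at least 2 rows and 2 columns")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(matrix.columns, sd) if s == 0]
        raise DegenerateDesignError(f"constant column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    k = min(n_obs - 1, n_var)
    eigval, eigvec = np.clip(eigval[:k], 0.0, None), eigvec[:, :k]

    loadings = eigvec * np.sqrt(eigval)  # variable-component correlations
    scores = Z @ eigvec
    for j in range(k):
        jmax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[jmax, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
            eigvec[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        contribution_ratios=100.0 * eigval / n_var,
        eigenvalues=eigval,
    )


@dataclass
class ClusterResult:
    """Agglomerative merge history over a set of labelled items."""

    linkage_matrix: np.ndarray
    items: list
    linkage_method: str = "ward"
    distance_metric: str = "euclidean"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def ward_cluster(loadings: pd.DataFrame) -> ClusterResult:
    """Ward minimum-variance clustering on Euclidean distances of loadings.

    `loadings` is an items x coordinates frame (typically the first three
    principal-component loadings per event). Duplicate rows merge at height
    zero; merge heights are non-decreasing.
    """
    if len(loadings) < 2:
        raise InsufficientDataError("clustering needs at least 2 items")
    Z = linkage(loadings.to_numpy(dtype=float), method="ward", metric="euclidean")
    return ClusterResult(Z, list(loadings.index))


def cut_clusters(result: ClusterResult, k: int = 2) -> pd.Series:
    """Cut the dendrogram into k groups; labels are 1..k by scipy convention."""
    if not 1 <= k <= len(result.items):
        raise JaderPvError(f"k={k} out of range 1..{len(result.items)}")
    labels = fcluster(result.linkage_matrix, t=k, criterion="maxclust")
    return pd.Series(labels, index=result.items, name="cluster")


def to_newick(result: ClusterResult) -> str:
    """Dendrogram as a Newick string with branch lengths from merge heights."""
    tree = to_tree(result.linkage_matrix)
    names = result.items

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


class EventProfiler(BaseEstimator):
    """End-to-end drug x event profiling estimator.

    fit(cases) builds the ln(ROR) matrix for the configured drugs/events,
    runs correlation-matrix PCA and Ward-clusters the events on the first
    `n_cluster_components` loadings, cutting at `k` clusters.

    Attributes: ror_matrix_, loadings_, scores_, contribution_ratios_,
    cluster_result_, labels_.
    """

    def __init__(self, drugs, event_terms, min_reports: int = 20,
                 n_cluster_components: int = 3, k: int = 2):
        self.drugs = drugs
        self.event_terms = event_terms
        self.min_reports = min_reports
        self.n_cluster_components = n_cluster_components
        self.k = k

    def fit(self, cases: pd.DataFrame, y=None):
        self.ror_matrix_ = build_ror_matrix(cases, self.drugs, self.event_terms,
                                            self.min_reports)
        res = pca(self.ror_matrix_)
        self.loadings_ = res.loadings
        self.scores_ = res.scores
        self.contribution_ratios_ = res.contribution_ratios
        self.eigenvalues_ = res.eigenvalues
        ncc = min(self.n_cluster_components, res.loadings.shape[1])
        self.cluster_result_ = ward_cluster(res.loadings.iloc[:, :ncc])
        self.labels_ = cut_clusters(self.cluster_result_, self.k)
        return self
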