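"""Partial-correlation connectome estimation and feature-space vectorization.

Connectivity between regional signals (plus the global grey-matter node) is
quantified by partial correlation — the correlation between two nodes after
removing the linear influence of all other nodes — computed from the
precision matrix Θ = Σ̂⁻¹ as pcor_ij = −Θ_ij/√(Θ_ii·Θ_jj).  The covariance
Σ̂ is Ledoit–Wolf-shrunk by default, keeping Θ well defined in the typical
frames ≲ nodes regime; the plain empirical estimator is available for exact
comparison with the regression-residual definition.

With 123 nodes (122 regions + global grey matter), the upper triangle holds
the 7503-dimensional feature space used for predictive modelling, with a
fixed bijection feature_index(i, j) = i(2n−i−1)/2 + (j−i−1) for i < j in
row-major node order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

from .preprocess import RegionalTimeseries

__all__ = [
    "ConnectivityMatrix",
    "FeatureVector",
    "partial_correlation",
    "vectorize_upper",
    "devectorize",
    "feature_index",
    "feature_pairs",
    "order_by_modules",
    "node_predictive_strength",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric node × node partial-correlation matrix, diagonal fixed to 0."""

    values: np.ndarray
    labels: list[str]
    modules: list[str] | None = None
    estimator: str = "shrinkage"
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric within 1e-10")
        self.values = v
        self.labels = list(self.labels)
        if len(self.labels) != v.shape[0]:
            raise ValueError("one label per node required")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, **kw) -> "ConnectivityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), labels=list(df.columns), **kw)


@dataclass
class FeatureVector:
    """Upper-triangle vectorization with its index ↔ node-pair map."""

    values: np.ndarray
    labels: list[str]  # node labels of the source matrix

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.size != n * (n - 1) // 2:
            raise ValueError(
                f"{self.values.size} features inconsistent with {n} nodes "
                f"(expected {n * (n - 1) // 2})"
            )

    @property
    def n_features(self) -> int:
        return self.values.size

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return feature_pairs(len(self.labels))

    def to_frame(self) -> pd.DataFrame:
        pairs = self.pairs
        return pd.DataFrame(
            {
                "feature_index": np.arange(self.n_features),
                "node_i": [self.labels[i] for i, _ in pairs],
                "node_j": [self.labels[j] for _, j in pairs],
                "value": self.values,
            }
        )


def feature_index(i: int, j: int, n_nodes: int) -> int:
    """Position of node pair (i < j) in the row-major upper-triangle order."""
    if not 0 <= i < j < n_nodes:
        raise ValueError("need 0 <= i < j < n_nodes")
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def feature_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """All (i, j) pairs with i < j in feature order."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def _empirical_precision(x: np.ndarray) -> np.ndarray:
    t, n = x.shape
    if t <= n:
        raise np.linalg.LinAlgError(
            f"empirical covariance is singular with {t} frames and {n} nodes; "
            "use the shrinkage estimator"
        )
    cov = np.cov(x, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < 1e-12 * max(eigvals.max(), 1.0):
        raise np.linalg.LinAlgError(
            "empirical covariance is numerically singular; use the shrinkage estimator"
        )
    return np.linalg.inv(cov)


def partial_correlation(
    ts: RegionalTimeseries, estimator: str = "shrinkage"
) -> ConnectivityMatrix:
    """Partial-correlation matrix over all nodes of a timeseries.

    ``estimator`` is ``"shrinkage"`` (Ledoit–Wolf, default) or
    ``"empirical"``.  The diagonal is set to 0 by convention.
    """
    x = ts.data
    if x.shape[0] <= 3:
        raise ValueError("more than 3 frames required")
    if x.shape[1] < 2:
        raise ValueError("at least 2 nodes required")
    if estimator == "shrinkage":
        # standardise nodes first so the identity shrinkage target acts on the
        # correlation matrix and the estimate stays scale-free
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xs = (x - x.mean(axis=0)) / sd
        theta = LedoitWolf().fit(xs).get_precision()
    elif estimator == "empirical":
        theta = _empirical_precision(x)
    else:
        raise ValueError("estimator must be 'shrinkage' or 'empirical'")
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    pcor = (pcor + pcor.T) / 2.0
    np.fill_diagonal(pcor, 0.0)
    return ConnectivityMatrix(
        values=pcor,
        labels=ts.labels,
        modules=ts.modules,
        estimator=estimator,
        subject_id=ts.subject_id,
    )


def vectorize_upper(conn: ConnectivityMatrix) -> FeatureVector:
    """Row-major upper-triangle (i < j) values as the feature vector."""
    iu = np.triu_indices(conn.n_nodes, k=1)
    return FeatureVector(values=conn.values[iu], labels=conn.labels)


def devectorize(vec: FeatureVector) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_upper`; diagonal is 0."""
    n = len(vec.labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = vec.values
    m = m + m.T
    return ConnectivityMatrix(values=m, labels=vec.labels)


def order_by_modules(conn: ConnectivityMatrix) -> ConnectivityMatrix:
    """Permute nodes to group them by large-scale module (stable within module).

    Module blocks appear in order of first appearance; purely a visualization
    aid — feature extraction always uses the canonical node order.
    """
    if conn.modules is None:
        raise ValueError("module labels required")
    first_seen: dict[str, int] = {}
    for m in conn.modules:
        first_seen.setdefault(m, len(first_seen))
    perm = sorted(range(conn.n_nodes), key=lambda i: (first_seen[conn.modules[i]], i))
    perm = np.asarray(perm)
    return replace(
        conn,
        values=conn.values[np.ix_(perm, perm)],
        labels=[conn.labels[i] for i in perm],
        modules=[conn.modules[i] for i in perm],
    )


def node_predictive_strength(signature, labels: list[str] | None = None) -> pd.Series:
    """Per-node sum of the signature weights of incident connections.

    Accepts a :class:`rpnsig.model.TrainedSignature`.  When ``labels`` is
    given the result covers that node universe, with 0 for nodes absent from
    the signature; otherwise only nodes appearing in entries are returned,
    ordered by descending |strength|.
    """
    strength: dict[str, float] = {}
    for e in signature.entries:
        strength[e.i_label] = strength.get(e.i_label, 0.0) + e.weight
        strength[e.j_label] = strength.get(e.j_label, 0.0) + e.weight
    s = pd.Series(strength, dtype=float)
    if labels is not None:
        s = s.reindex(labels, fill_value=0.0)
        return s
    return s.sort_values(key=np.abs, ascending=False)
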