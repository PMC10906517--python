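"""Which dimensions are preserved across datasets, and how strongly.

A dimension counts as preserved when its cross-validated scores are
significantly positively correlated between enough dataset pairs: for
every pair the partial Pearson correlation between the two datasets'
scores on that dimension is computed (each side residualized on its own
scores for all previous dimensions), p-values are BH-corrected within
the pair across dimensions, and the significant pairs form a graph over
datasets.  A dimension is retained when that graph cannot be
partitioned — by default both connected over all K datasets and with
every dataset linked to at least two others.

`preservation_score` quantifies how similar a set of per-dataset
dimension loadings is across datasets: the correlation r between each
dataset's loadings and the cross-dataset average loading (r-squared
being the fraction of loading variation preserved across datasets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .crossval import CVScores, loso_scores
from .ppca_core import ComponentModel
from .ratings_io import RatingsPanel
from .stat_tests import DegenerateResidualError, bh_fdr, partial_pearson

__all__ = [
    "SignificanceGraph",
    "PreservationReport",
    "PreservationScore",
    "pairwise_dimension_tests",
    "unipartite_criterion",
    "count_preserved",
    "preservation_score",
]


@dataclass
class SignificanceGraph:
    """Per-dimension significance graph over datasets.

    ``adjacency[a, b]`` is True when the dimension's scores in datasets
    a and b are significantly positively partially correlated after BH
    correction within the pair.  No self-edges; symmetric.
    """

    dimension: int
    datasets: list[str]
    adjacency: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    statistic: np.ndarray
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.datasets)
        k = len(self.datasets)
        for a in range(k):
            for b in range(a + 1, k):
                if self.adjacency[a, b]:
                    g.add_edge(self.datasets[a], self.datasets[b])
        return g

    def edge_list(self):
        k = len(self.datasets)
        return [
            (self.datasets[a], self.datasets[b], self.statistic[a, b],
             self.p_raw[a, b], self.p_adj[a, b])
            for a in range(k) for b in range(a + 1, k)
            if self.adjacency[a, b]
        ]


@dataclass
class PreservationReport:
    retained: list[int]
    graphs: list[SignificanceGraph]
    criterion: str
    alpha: float
    max_dims: int
    model: ComponentModel
    cv: CVScores | None = None
    preservation_r: float | None = None
    preservation_r2: float | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_json(self, path) -> None:
        payload = {
            "retained": self.retained,
            "criterion": self.criterion,
            "alpha": self.alpha,
            "max_dims": self.max_dims,
            "n_retained": self.n_retained,
            "preserved_cov": self.model.preserved_cov.tolist(),
            "loadings": self.model.loadings.tolist(),
            "concepts": self.model.concepts,
            "datasets": self.model.dataset_order,
            "graphs": [
                {
                    "dimension": g.dimension,
                    "edges": [
                        {"a": a, "b": b, "r": r, "p": p, "p_adj": q}
                        for a, b, r, p, q in g.edge_list()
                    ],
                }
                for g in self.graphs
            ],
        }
        if self.preservation_r is not None:
            payload["preservation_r"] = self.preservation_r
            payload["preservation_r2"] = self.preservation_r2
        with open(path, "w") as fh:
            json.dump(payload, fh)


def pairwise_dimension_tests(
    cv: CVScores, max_dims: int = 48, alpha: float = 0.05
) -> list[SignificanceGraph]:
    """Partial-correlation tests for every dimension and dataset pair.

    For dimension k and pair (a, b), dataset a's scores on k are
    residualized on dataset a's own scores for dimensions 0..k-1 and
    likewise for b, then the residuals are Pearson-correlated
    (one-sided, r > 0).  BH correction is applied within each pair
    across the ``max_dims`` dimensions.  Degenerate residuals are
    recorded as non-significant (p = 1) and flagged.
    """
    m = min(max_dims, cv.n_components)
    datasets = cv.datasets
    k = len(datasets)
    p_raw = np.ones((m, k, k))
    stat = np.zeros((m, k, k))
    degenerate: list[list[tuple[str, str]]] = [[] for _ in range(m)]
    for ai, bi in combinations(range(k), 2):
        za = cv.scores[datasets[ai]]
        zb = cv.scores[datasets[bi]]
        for dim in range(m):
            try:
                res = partial_pearson(
                    za[:, dim],
                    zb[:, dim],
                    covariates=za[:, :dim] if dim else None,
                    y_covariates=zb[:, :dim] if dim else None,
                    sided="one",
                )
                p_raw[dim, ai, bi] = p_raw[dim, bi, ai] = res.p_value
                stat[dim, ai, bi] = stat[dim, bi, ai] = res.statistic
            except DegenerateResidualError:
                degenerate[dim].append((datasets[ai], datasets[bi]))
    graphs = []
    p_adj = np.ones_like(p_raw)
    adj = np.zeros((m, k, k), dtype=bool)
    for ai, bi in combinations(range(k), 2):
        reject, padj = bh_fdr(p_raw[:, ai, bi], alpha=alpha)
        p_adj[:, ai, bi] = p_adj[:, bi, ai] = padj
        adj[:, ai, bi] = adj[:, bi, ai] = reject
    for dim in range(m):
        graphs.append(
            SignificanceGraph(
                dimension=dim,
                datasets=list(datasets),
                adjacency=adj[dim],
                p_raw=p_raw[dim],
                p_adj=p_adj[dim],
                statistic=stat[dim],
                degenerate_pairs=degenerate[dim],
            )
        )
    return graphs


def unipartite_criterion(graph: SignificanceGraph, mode: str = "both") -> bool:
    """Does the significance graph qualify the dimension as preserved?

    ``connected``: one connected component spanning all K datasets.
    ``min_degree_2``: every dataset significantly linked to >= 2 others.
    ``both`` (default): conjunction of the two.
    """
    g = graph.to_networkx()
    if mode not in ("connected", "min_degree_2", "both"):
        raise ValueError(f"unknown criterion mode {mode!r}")
    connected = g.number_of_nodes() > 0 and nx.is_connected(g)
    min_deg = all(d >= 2 for _, d in g.degree)
    if mode == "connected":
        return connected
    if mode == "min_degree_2":
        return min_deg
    return connected and min_deg


def count_preserved(
    panel: RatingsPanel,
    max_dims: int = 48,
    alpha: float = 0.05,
    mode: str = "both",
) -> PreservationReport:
    """Full preservation pipeline: LOSO scores -> pairwise tests -> graphs.

    Dimensions are tested in preserved-covariance order; testing stops
    at ``max_dims`` (default 48).  Returns the retained dimension
    indices with their significance graphs.
    """
    m = min(max_dims, panel.n_concepts)
    cv = loso_scores(panel, n_components=m)
    graphs = pairwise_dimension_tests(cv, max_dims=m, alpha=alpha)
    retained = [g.dimension for g in graphs if unipartite_criterion(g, mode)]
    return PreservationReport(
        retained=retained,
        graphs=graphs,
        criterion=mode,
        alpha=alpha,
        max_dims=m,
        model=cv.reference,
        cv=cv,
    )


@dataclass
class PreservationScore:
    r: float
    r2: float
    per_dimension: dict[int, float]
    per_dataset: dict[str, float]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    return float(x @ y / denom) if denom > 0 else float("nan")


def preservation_score(
    loadings_by_dataset: dict[str, np.ndarray]
) -> PreservationScore:
    """How well per-dataset dimension loadings agree with their average.

    Each dataset contributes an M x P loading slice over the same
    dimensions and concepts.  r is the Pearson correlation between the
    concatenated per-dataset loadings and the cross-dataset average
    loading repeated for each dataset; r-squared is the fraction of
    loading variation explained by the shared average.  Per-dimension
    and per-dataset sub-correlations are reported alongside.
    """
    datasets = list(loadings_by_dataset)
    if not datasets:
        raise ValueError("no datasets")
    shapes = {loadings_by_dataset[d].shape for d in datasets}
    if len(shapes) != 1:
        raise ValueError(f"mismatched loading shapes: {shapes}")
    stack = np.stack([loadings_by_dataset[d] for d in datasets])  # K x M x P
    avg = stack.mean(axis=0)  # M x P
    concat = stack.reshape(len(datasets), -1)
    tiled = np.tile(avg.ravel(), (len(datasets), 1))
    r = _pearson(concat.ravel(), tiled.ravel())
    per_dim = {
        m: _pearson(stack[:, m, :].ravel(), np.tile(avg[m], len(datasets)))
        for m in range(avg.shape[0])
    }
    per_ds = {
        d: _pearson(loadings_by_dataset[d].ravel(), avg.ravel())
        for d in datasets
    }
    return PreservationScore(r=r, r2=r * r, per_dimension=per_dim, per_dataset=per_ds)
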