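"""Principal preserved components analysis (PPCA) and its K-dataset form.

PPCA finds loading vectors alpha over a shared set of attributes such
that the projections of two datasets measuring those attributes,
X alpha and Y alpha, maximally co-vary.  Unlike PLSC or CCA it derives a
single loading vector per component, shared by both datasets, so a
component is directly interpretable as one pattern of attributes whose
variation is preserved across datasets.

For K >= 2 datasets the generalized form (G-PPCA) maximizes

    sum over unordered pairs (a, b) of Cov(X_a alpha, X_b alpha)

which equals ``alpha' M alpha`` with M the sum over pairs of the
symmetrized cross-covariance (C_ab + C_ab') / 2.  Components are the
eigenvectors of M, ordered by descending eigenvalue (total positive
pairwise covariance).  Negative-eigenvalue components are retained but
ranked last; they carry anti-preserved structure and are never treated
as preserved dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .ratings_io import RatingsPanel

__all__ = [
    "ComponentModel",
    "cross_covariance",
    "symmetrized_sum",
    "fit_gppca",
    "objective_value",
    "project_scores",
]


@dataclass
class ComponentModel:
    """Fitted (G-)PPCA components.

    ``loadings`` is a P x M matrix whose unit-norm, mutually orthogonal
    columns are the alpha vectors; ``preserved_cov`` holds the matching
    eigenvalues (summed pairwise covariance per component) in
    non-increasing order.  ``column_means`` stores the per-dataset
    training column means used for centering at projection time.
    """

    loadings: np.ndarray
    preserved_cov: np.ndarray
    column_means: dict[str, np.ndarray]
    dataset_order: list[str]
    concepts: list[str]
    pair_set: list[tuple[str, str]]
    scaled_input: bool = False
    standardized: bool = False

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.preserved_cov = np.asarray(self.preserved_cov, dtype=float)
        norms = np.linalg.norm(self.loadings, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("loading columns must have unit norm")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loading columns must be mutually orthogonal")
        if np.any(np.diff(self.preserved_cov) > 1e-10):
            raise ValueError("preserved_cov must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "preserved_cov": self.preserved_cov.tolist(),
            "column_means": {d: m.tolist() for d, m in self.column_means.items()},
            "dataset_order": self.dataset_order,
            "concepts": self.concepts,
            "pair_set": [list(p) for p in self.pair_set],
            "scaled_input": self.scaled_input,
            "standardized": self.standardized,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ComponentModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            loadings=np.array(payload["loadings"]),
            preserved_cov=np.array(payload["preserved_cov"]),
            column_means={
                d: np.array(m) for d, m in payload["column_means"].items()
            },
            dataset_order=payload["dataset_order"],
            concepts=payload["concepts"],
            pair_set=[tuple(p) for p in payload["pair_set"]],
            scaled_input=payload["scaled_input"],
            standardized=payload["standardized"],
        )


def cross_covariance(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sample cross-covariance centered X' centered Y / (N - 1).

    Both matrices are column-centered internally; rows must correspond
    to the same N >= 3 observations.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"row-count mismatch: {X.shape[0]} vs {Y.shape[0]}")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    return Xc.T @ Yc / (n - 1)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def symmetrized_sum(panel: RatingsPanel) -> np.ndarray:
    """Sum of symmetrized cross-covariances over unordered dataset pairs.

    Returns ``sum over (a, b), a < b of (C_ab + C_ab') / 2`` — the
    symmetric matrix whose eigendecomposition defines G-PPCA.  For K = 2
    this is the plain PPCA matrix.
    """
    if panel.n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    p = panel.n_concepts
    out = np.zeros((p, p))
    for a, b in combinations(panel.datasets, 2):
        c = cross_covariance(panel.values[a], panel.values[b])
        out += 0.5 * (c + c.T)
    return out


def fit_gppca(
    panel: RatingsPanel,
    n_components: int | None = None,
    standardize: bool = False,
) -> ComponentModel:
    """Fit G-PPCA by eigendecomposition of the summed symmetrized cross-covariance.

    Parameters
    ----------
    panel
        Aligned (preferably [0, 1]-scaled) panel of K >= 2 datasets.
    n_components
        Number of leading components to keep; ``None`` keeps all P.
    standardize
        Optionally z-score each concept column per dataset before
        fitting (off by default — inputs are already unit-interval
        scaled per concept per dataset).
    """
    values = {}
    for d in panel.datasets:
        mat = panel.values[d]
        if not np.all(np.isfinite(mat)):
            raise ValueError(f"non-finite values in dataset {d!r}")
        if standardize:
            sd = mat.std(axis=0, ddof=1)
            mat = (mat - mat.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        values[d] = mat
    work = RatingsPanel(
        stimuli=list(panel.stimuli),
        datasets=list(panel.datasets),
        concepts=list(panel.concepts),
        values=values,
        scaled=panel.scaled,
    )
    m_sym = symmetrized_sum(work)
    eigvals, eigvecs = np.linalg.eigh(m_sym)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = _fix_signs(eigvecs[:, order])
    if n_components is not None:
        if n_components > panel.n_concepts:
            raise ValueError("n_components exceeds number of attributes")
        eigvals = eigvals[:n_components]
        eigvecs = eigvecs[:, :n_components]
    return ComponentModel(
        loadings=eigvecs,
        preserved_cov=eigvals,
        column_means={d: values[d].mean(axis=0) for d in panel.datasets},
        dataset_order=list(panel.datasets),
        concepts=list(panel.concepts),
        pair_set=list(combinations(panel.datasets, 2)),
        scaled_input=panel.scaled,
        standardized=standardize,
    )


def objective_value(
    model: ComponentModel, panel: RatingsPanel, m: int
) -> float:
    """Summed pairwise covariance of component ``m``'s scores on a panel.

    Evaluated on the training panel this reproduces
    ``model.preserved_cov[m]``; on any other vector it is bounded above
    by the leading eigenvalue (Rayleigh bound).
    """
    if not 0 <= m < model.n_components:
        raise IndexError(f"component index {m} out of range")
    scores = project_scores(model, panel)
    total = 0.0
    for a, b in combinations(panel.datasets, 2):
        za = scores[a][:, m]
        zb = scores[b][:, m]
        total += float(np.cov(za, zb, ddof=1)[0, 1])
    return total


def project_scores(
    model: ComponentModel, panel: RatingsPanel
) -> dict[str, np.ndarray]:
    """Project each dataset's (centered) ratings onto the model's components.

    Centering uses the *training* column means stored in the model, so
    held-out stimuli are scored without re-estimating means.  Returns
    one N x M score matrix per dataset.
    """
    if list(panel.concepts) != list(model.concepts):
        raise ValueError("panel attribute order does not match model")
    out = {}
    for d in panel.datasets:
        if d not in model.column_means:
            raise KeyError(f"dataset {d!r} unknown to model")
        out[d] = (panel.values[d] - model.column_means[d]) @ model.loadings
    return out
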