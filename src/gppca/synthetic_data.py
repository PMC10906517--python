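"""Synthetic multi-dataset rating panels with planted latent structure.

Emulates the data the preservation analyses assume: K country panels
over the same stimuli, generated from ``d_shared`` latent dimensions
common to every dataset plus ``d_spec_per_dataset`` dimensions private
to each, with independent Gaussian measurement noise, optional
select-then-rate sparsity (zeroed raw cells), and per-concept [0, 1]
min-max scaling — so every pipeline stage can be checked against a
known ground truth.

Latent stimulus scores are standard Gaussian and the planted loading
rows are mutually orthonormal, the simplest structure under which the
summed pairwise-covariance objective has a known optimum: the shared
loading rows themselves, with population preserved covariance
K(K-1)/2 per shared dimension (before column scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extraction import WideMatrix
from .ratings_io import RatingsPanel, scale_unit_interval

__all__ = ["SyntheticTruth", "make_panel", "make_annotation_pair"]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel.

    ``scores`` holds the N x d_total latent stimulus scores (shared
    dimensions first, then each dataset's specific block in dataset
    order).  ``column_scale[d]`` stores the min-max range each concept
    column was divided by, so planted loadings can be mapped into the
    scaled panel's coordinates via :meth:`effective_shared_loadings`.
    """

    shared_loadings: np.ndarray                 # d_shared x P
    specific_loadings: dict[str, np.ndarray]    # dataset -> d_spec x P
    scores: np.ndarray                          # N x d_total
    noise_sd: float
    sparsity: float
    seed: int | None
    datasets: list[str]
    concepts: list[str]
    stimuli: list[str]
    column_scale: dict[str, np.ndarray]
    panel: RatingsPanel

    @property
    def d_shared(self) -> int:
        return self.shared_loadings.shape[0]

    def shared_scores(self) -> np.ndarray:
        return self.scores[:, : self.d_shared]

    def effective_shared_loadings(self, dataset: str) -> np.ndarray:
        """Shared loadings in the scaled panel's coordinates for a dataset."""
        return self.shared_loadings / self.column_scale[dataset]


def _orthonormal_rows(rng: np.random.Generator, d: int, p: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((p, d)))
    return q[:, :d].T


def _sparse_rows(
    rng: np.random.Generator, d: int, p: int, support: int
) -> np.ndarray:
    """Unit-norm rows on disjoint random supports of the given size."""
    if d * support > p:
        raise ValueError("disjoint supports exceed the number of concepts")
    cols = rng.permutation(p)
    rows = np.zeros((d, p))
    for i in range(d):
        sup = cols[i * support : (i + 1) * support]
        # same-signed, bounded-away-from-zero support entries: a planted
        # dimension is a cluster of concepts loading positively together,
        # which keeps its top-loading sign pattern well defined
        v = 0.5 + np.abs(rng.standard_normal(support))
        rows[i, sup] = v / np.linalg.norm(v)
    return rows


def make_panel(
    n_stimuli: int = 500,
    n_datasets: int = 6,
    n_concepts: int = 48,
    d_shared: int = 5,
    d_spec_per_dataset: int = 1,
    noise_sd: float = 0.3,
    sparsity: float = 0.0,
    seed: int | None = None,
    support: int | None = None,
    shared_strengths=None,
) -> tuple[RatingsPanel, SyntheticTruth]:
    """Generate a K-dataset rating panel with planted dimensions.

    ``X_a = S_shared A_shared + S_spec_a A_spec_a + noise`` with
    Gaussian latent scores, orthonormal planted loading rows (disjoint
    supports of size ``support`` per dimension when given, dense
    otherwise) and i.i.d. Gaussian(0, noise_sd^2) noise, followed by
    optional zeroing of a ``sparsity`` fraction of raw cells and
    per-concept [0, 1] scaling.  Defaults mirror a six-country panel of
    48 emotion concepts with five shared and one culture-specific
    dimension per country at moderate noise.

    Shared dimensions carry distinct strengths (latent score standard
    deviations, default geometrically spaced from 2 downward with ratio
    1/sqrt(2)) so each planted dimension is individually identifiable —
    with equal strengths the preserved-covariance eigenvalues would be
    degenerate and only the shared *subspace*, not its axes, would be
    recoverable; geometric spacing keeps the *relative* eigengap between
    adjacent dimensions constant, so identifiability does not degrade
    down the spectrum.  Specific dimensions have strength 1.
    """
    k, p = n_datasets, n_concepts
    d_total = d_shared + k * d_spec_per_dataset
    if d_total > p:
        raise ValueError(
            f"dimension budget exceeded: {d_total} latent dimensions > {p} concepts"
        )
    rng = np.random.default_rng(seed)
    if support is not None:
        rows = _sparse_rows(rng, d_total, p, support)
    else:
        rows = _orthonormal_rows(rng, d_total, p)
    a_shared = rows[:d_shared]
    datasets = [f"country_{chr(ord('A') + a)}" for a in range(k)]
    a_spec = {
        d: rows[d_shared + a * d_spec_per_dataset:
                d_shared + (a + 1) * d_spec_per_dataset]
        for a, d in enumerate(datasets)
    }
    if shared_strengths is None:
        shared_strengths = 2.0 * (0.5 ** (np.arange(d_shared) / 2.0))
    shared_strengths = np.asarray(shared_strengths, dtype=float)
    if shared_strengths.shape != (d_shared,):
        raise ValueError("shared_strengths must have one entry per shared dimension")
    strengths = np.concatenate([shared_strengths, np.ones(k * d_spec_per_dataset)])
    scores = rng.standard_normal((n_stimuli, d_total)) * strengths
    stimuli = [f"stim_{i:05d}" for i in range(n_stimuli)]

    values = {}
    for a, d in enumerate(datasets):
        block = slice(d_shared + a * d_spec_per_dataset,
                      d_shared + (a + 1) * d_spec_per_dataset)
        x = scores[:, :d_shared] @ a_shared + scores[:, block] @ a_spec[d]
        x = x + noise_sd * rng.standard_normal((n_stimuli, p))
        if sparsity > 0:
            x = np.where(rng.random((n_stimuli, p)) < sparsity, 0.0, x)
        values[d] = x
    raw = RatingsPanel(
        stimuli=stimuli, datasets=datasets, concepts=[f"concept_{j:02d}" for j in range(p)],
        values=values,
    )
    panel = scale_unit_interval(raw)
    column_scale = {
        d: raw.values[d].max(axis=0) - raw.values[d].min(axis=0)
        for d in datasets
    }
    truth = SyntheticTruth(
        shared_loadings=a_shared,
        specific_loadings=a_spec,
        scores=scores,
        noise_sd=noise_sd,
        sparsity=sparsity,
        seed=seed,
        datasets=datasets,
        concepts=list(panel.concepts),
        stimuli=stimuli,
        column_scale=column_scale,
        panel=panel,
    )
    return panel, truth


def make_annotation_pair(
    truth: SyntheticTruth,
    annotation_noise_sd: float = 0.3,
    seed: int | None = None,
) -> tuple[WideMatrix, WideMatrix]:
    """Paired wide matrices sharing exactly the planted dimensions.

    B is the generated judgment panel flattened to N x (P x K) with
    columns "concept@dataset"; A reads the same latent scores out
    through the same loadings but with independent Gaussian noise
    (sd ``annotation_noise_sd``) and its own per-column [0, 1] scaling —
    a stand-in for an annotation source (e.g. model outputs) aligned to
    the same stimuli.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.stimuli)
    d_shared = truth.d_shared
    values = {}
    for a, d in enumerate(truth.datasets):
        spec = truth.specific_loadings[d]
        d_spec = spec.shape[0]
        block = slice(d_shared + a * d_spec, d_shared + (a + 1) * d_spec)
        x = truth.scores[:, :d_shared] @ truth.shared_loadings
        if d_spec:
            x = x + truth.scores[:, block] @ spec
        values[d] = x + annotation_noise_sd * rng.standard_normal(x.shape)
    raw = RatingsPanel(
        stimuli=list(truth.stimuli),
        datasets=list(truth.datasets),
        concepts=[c for c in truth.panel.concepts],
        values=values,
    )
    A = WideMatrix.from_panel(scale_unit_interval(raw))
    B = WideMatrix.from_panel(truth.panel)
    return A, B
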