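"""Leave-one-stimulus-out cross-validated component scores.

For each stimulus the model is refitted on the remaining N - 1 stimuli
and the held-out stimulus is projected onto the refitted components, so
no stimulus contributes to the components it is scored on.  Fold
components are matched to a full-data reference model (greedy maximal
|correlation| between loading vectors, sign fixed by a positive dot
product) so that "component m" means the same dimension in every fold.

The per-fold cross-covariances are obtained by rank-one downdates of the
full-data Gram matrices rather than recomputation, which keeps the whole
sweep at one eigendecomposition per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .ppca_core import ComponentModel, fit_gppca
from .ratings_io import RatingsPanel

__all__ = ["CVScores", "loso_scores"]


@dataclass
class CVScores:
    """Held-out component scores per dataset, plus fold bookkeeping.

    ``scores[d]`` is N x M; row i was produced by a model fitted without
    stimulus i.  ``fold_alignment[i]`` records the permutation (fold
    component chosen for each reference component) and signs applied to
    fold i, and is invertible by construction.
    """

    scores: dict[str, np.ndarray]
    stimuli: list[str]
    datasets: list[str]
    reference: ComponentModel
    fold_alignment: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        if self.reference is not None:
            return self.reference.n_components
        return next(iter(self.scores.values())).shape[1]

    def to_tsv(self, path) -> None:
        rows = []
        for d in self.datasets:
            mat = self.scores[d]
            for i, s in enumerate(self.stimuli):
                for m in range(mat.shape[1]):
                    rows.append((s, d, m, mat[i, m]))
        pd.DataFrame(
            rows, columns=["stimulus_id", "dataset", "component", "score"]
        ).to_csv(path, sep="\t", index=False)


def _greedy_align(
    candidates: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match candidate loading columns to reference columns.

    Greedy on the globally largest remaining |Pearson correlation|
    between loading vectors; each candidate is used at most once.
    Returns (permutation, signs): reference column m is served by
    candidate column ``perm[m]`` flipped by ``signs[m]`` (sign of the
    dot product with the reference).
    """
    m_ref = reference.shape[1]

    def _unit_centered(a):
        a = a - a.mean(axis=0)
        norms = np.linalg.norm(a, axis=0)
        return a / np.where(norms > 0, norms, 1.0)

    corr = np.abs(_unit_centered(candidates).T @ _unit_centered(reference))
    perm = np.full(m_ref, -1, dtype=int)
    used = np.zeros(candidates.shape[1], dtype=bool)
    work = corr.copy()
    for _ in range(m_ref):
        c, r = np.unravel_index(np.argmax(work), work.shape)
        perm[r] = c
        used[c] = True
        work[c, :] = -1.0
        work[:, r] = -1.0
    dots = np.einsum("pm,pm->m", candidates[:, perm], reference)
    signs = np.where(dots >= 0, 1.0, -1.0)
    return perm, signs


def loso_scores(
    panel: RatingsPanel,
    n_components: int | None = None,
    align_extra: int = 8,
    align: str = "split",
) -> CVScores:
    """Leave-one-stimulus-out (G-)PPCA scores for every dataset.

    Parameters
    ----------
    panel
        Aligned panel with N >= 4 stimuli.
    n_components
        Components to keep (default: all P).
    align_extra
        How many fold components beyond ``n_components`` are considered
        when matching fold components to the reference model; folds can
        swap the order of nearby components, so a small buffer makes the
        greedy matching robust.
    align
        ``"split"`` (default): cross-fitted alignment — stimuli are
        split into two halves and fold i is aligned to a model fitted
        on the half *not* containing stimulus i (its component order
        matched once to the full-data reference).  ``"full"``: align
        every fold directly to the full-data reference model.

        Full-reference alignment looks natural but leaks held-out
        information: for weak, near-degenerate dimensions the fold
        eigenvector chosen is the one closest to the full-data
        eigenvector, which was itself selected using the held-out
        stimulus, so held-out scores inherit part of the full fit's
        in-sample (overfit) cross-dataset covariance.  Cross-fitted
        alignment keeps the alignment target independent of the
        held-out stimulus and restores null behaviour for noise
        dimensions.

    Folds in which some attribute is constant across the remaining
    stimuli are flagged in ``flagged_folds`` (their component set is
    still produced; the degenerate attribute simply carries no
    covariance).
    """
    n = panel.n_stimuli
    p = panel.n_concepts
    if n < 4:
        raise ValueError("need at least 4 stimuli for leave-one-out")
    if align not in ("split", "full"):
        raise ValueError("align must be 'split' or 'full'")
    reference = fit_gppca(panel, n_components)
    m = reference.n_components
    n_cand = min(p, m + align_extra)

    targets: list[np.ndarray] | None = None
    half_of: np.ndarray | None = None
    if align == "split" and n >= 8:
        half_of = np.arange(n) % 2  # deterministic, balanced
        targets = []
        for h in (0, 1):
            sub = panel.subset(np.nonzero(half_of == h)[0])
            half_model = fit_gppca(sub, None)
            cand = half_model.loadings[:, : min(p, m + align_extra)]
            perm, signs = _greedy_align(cand, reference.loadings)
            targets.append(cand[:, perm] * signs)

    datasets = list(panel.datasets)
    mats = [panel.values[d] for d in datasets]
    k = len(datasets)
    pairs = list(combinations(range(k), 2))
    col_sums = [mat.sum(axis=0) for mat in mats]
    sq_sums = [(mat**2).sum(axis=0) for mat in mats]
    grams = {(a, b): mats[a].T @ mats[b] for a, b in pairs}

    scores = {d: np.zeros((n, m)) for d in datasets}
    alignment: list[tuple[np.ndarray, np.ndarray]] = []
    flagged: list[int] = []
    for i in range(n):
        fold_means = [(col_sums[a] - mats[a][i]) / (n - 1) for a in range(k)]
        # flag attributes constant over the fold: var excluding row i == 0
        degenerate = False
        for a in range(k):
            ss = sq_sums[a] - mats[a][i] ** 2
            var = ss / (n - 1) - fold_means[a] ** 2
            if np.any(var <= 1e-14):
                degenerate = True
        if degenerate:
            flagged.append(i)

        m_sym = np.zeros((p, p))
        for a, b in pairs:
            g = grams[(a, b)] - np.outer(mats[a][i], mats[b][i])
            c = (g - (n - 1) * np.outer(fold_means[a], fold_means[b])) / (n - 2)
            m_sym += 0.5 * (c + c.T)
        eigvals, eigvecs = np.linalg.eigh(m_sym)
        order = np.argsort(eigvals)[::-1][:n_cand]
        cand = eigvecs[:, order]
        if targets is not None:
            target = targets[1 - half_of[i]]  # the half not containing i
        else:
            target = reference.loadings
        perm, signs = _greedy_align(cand, target)
        fold_loadings = cand[:, perm] * signs
        alignment.append((perm, signs))
        for a, d in enumerate(datasets):
            scores[d][i] = (mats[a][i] - fold_means[a]) @ fold_loadings
    return CVScores(
        scores=scores,
        stimuli=list(panel.stimuli),
        datasets=datasets,
        reference=reference,
        fold_alignment=alignment,
        flagged_folds=flagged,
    )
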