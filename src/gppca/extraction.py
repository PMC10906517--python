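"""Annotation-vs-judgment dimension extraction.

Given two wide matrices over the same stimuli — e.g. model annotations A
and averaged human judgments B, each with Q = concepts x datasets
columns — this pipeline finds the dimensions along which the two agree
beyond chance:

1. leave-one-stimulus-out PPCA (the K = 2 case) yields held-out score
   pairs for every stimulus and candidate dimension;
2. per dimension, the held-out A-side and B-side scores are partially
   Spearman-correlated, each side controlling for its own scores on all
   previous dimensions;
3. stimuli are resampled with replacement (default 1000 iterations) and
   the correlation step recomputed, giving a bootstrap sign p-value and
   a signal-to-noise ratio per dimension;
4. three filters — BH-FDR across the first `max_dims` dimensions,
   ForwardStop over the same ordered sequence, and SNR >= 3 — must all
   pass for a dimension to be retained;
5. retained loadings are varimax-rotated for interpretation.

`loading_significance` then asks how many of a retained dimension's
strongest attribute loadings are stable: the whole fit (PPCA + rotation)
is repeated on stimulus resamples, and the top-N loadings count as
replicated when some re-extracted dimension's loadings at those N
attributes all point in the same direction (mutually equal signs; a
dimension's global sign is arbitrary, so either orientation counts).  The number of
significant loadings is read off with ForwardStop.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .crossval import loso_scores
from .ppca_core import _fix_signs, fit_gppca
from .ratings_io import RatingsPanel
from .stat_tests import (
    DegenerateResidualError,
    bh_fdr,
    bootstrap_sign_p,
    forward_stop,
    partial_pearson,
    snr,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WideMatrix",
    "DimensionReport",
    "varimax",
    "extract_dimensions",
    "loading_significance",
]


@dataclass
class WideMatrix:
    """N stimuli x Q attributes, attribute labels "concept@dataset"."""

    stimuli: list[str]
    columns: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.stimuli), len(self.columns)):
            raise ValueError("values shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries")

    @classmethod
    def from_panel(cls, panel: RatingsPanel) -> "WideMatrix":
        cols, blocks = [], []
        for d in panel.datasets:
            cols.extend(f"{c}@{d}" for c in panel.concepts)
            blocks.append(panel.values[d])
        return cls(
            stimuli=list(panel.stimuli),
            columns=cols,
            values=np.hstack(blocks),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.stimuli, columns=self.columns)
        df.index.name = "stimulus_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "WideMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            stimuli=[str(s) for s in df.index],
            columns=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class DimensionReport:
    statistic: np.ndarray          # held-out partial Spearman per dimension
    p_boot: np.ndarray
    snr: np.ndarray
    pass_bh: np.ndarray
    pass_forward_stop: np.ndarray
    pass_snr: np.ndarray
    retained: list[int]
    loadings: np.ndarray           # Q x max_dims reference loadings
    rotated_loadings: np.ndarray   # Q x n_retained, varimax-rotated
    rotation: np.ndarray
    columns: list[str]
    params: dict = field(default_factory=dict)
    loading_counts: dict[int, int] | None = None

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_json(self, path) -> None:
        payload = {
            "statistic": self.statistic.tolist(),
            "p_boot": self.p_boot.tolist(),
            "snr": [s if np.isfinite(s) else None for s in self.snr],
            "pass_bh": self.pass_bh.tolist(),
            "pass_forward_stop": self.pass_forward_stop.tolist(),
            "pass_snr": self.pass_snr.tolist(),
            "retained": self.retained,
            "rotated_loadings": self.rotated_loadings.tolist(),
            "columns": self.columns,
            "params": self.params,
        }
        if self.loading_counts is not None:
            payload["loading_counts"] = {
                str(k): v for k, v in self.loading_counts.items()
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def rotated_to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.rotated_loadings,
            index=self.columns,
            columns=[f"dim_{i}" for i in range(self.n_retained)],
        )
        df.index.name = "attribute"
        df.to_csv(path, sep="\t")


def _varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (no Kaiser row normalization).

    Orthogonally rotates the columns of ``loadings`` to maximize the
    varimax criterion — the summed variance of squared loadings per
    factor — which concentrates each factor on few attributes.  Uses the
    SVD-based fixed-point iteration; the criterion is non-decreasing
    across accepted iterates and the best-found rotation is returned
    (with a warning if the change in the objective never dropped below
    ``tol`` within ``max_iter``).

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation``
    and ``rotation`` orthogonal.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 1:
        raise ValueError("loadings must be a Q x M matrix with M >= 1")
    q, m = L.shape
    if m == 1:
        return L.copy(), np.eye(1)
    R = np.eye(m)
    d_old = 0.0
    converged = False
    for _ in range(max_iter):
        Lr = L @ R
        grad = L.T @ (Lr**3 - Lr * (Lr**2).sum(axis=0) / q)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        d = s.sum()
        if d_old != 0 and (d - d_old) < tol * d_old:
            converged = True
            break
        d_old = d
    if not converged:
        warnings.warn("varimax did not converge; returning best-found rotation")
    return L @ R, R


def _heldout_partial_spearman(
    za: np.ndarray, zb: np.ndarray, max_dims: int
) -> np.ndarray:
    """Partial Spearman per dimension, own-side previous-score control."""
    ra = sps.rankdata(za, axis=0)
    rb = sps.rankdata(zb, axis=0)
    out = np.full(max_dims, np.nan)
    for k in range(max_dims):
        try:
            res = partial_pearson(
                ra[:, k],
                rb[:, k],
                covariates=ra[:, :k] if k else None,
                y_covariates=rb[:, :k] if k else None,
                sided="one",
            )
            out[k] = res.statistic
        except DegenerateResidualError:
            out[k] = 0.0
    return out


def _check_aligned(A: WideMatrix, B: WideMatrix) -> None:
    if A.stimuli != B.stimuli:
        raise ValueError("A and B are not aligned on the same stimuli")
    if len(A.columns) != len(B.columns):
        raise ValueError("A and B have different attribute counts")


def _pair_panel(A: WideMatrix, B: WideMatrix) -> RatingsPanel:
    return RatingsPanel(
        stimuli=list(A.stimuli),
        datasets=["A", "B"],
        concepts=list(B.columns),
        values={"A": A.values, "B": B.values},
    )


def extract_dimensions(
    A: WideMatrix,
    B: WideMatrix,
    B_boot: int = 1000,
    alpha: float = 0.05,
    snr_min: float = 3.0,
    max_dims: int = 48,
    seed: int | None = None,
) -> DimensionReport:
    """PPCA between two wide matrices with triple-filtered significance.

    See the module docstring for the pipeline.  ``seed`` drives the
    bootstrap resampling; with a fixed seed the whole report is
    reproducible bit for bit.  SNR retention is inclusive (>= snr_min).
    """
    _check_aligned(A, B)
    if B_boot < 100:
        warnings.warn(f"B_boot={B_boot} is very low; p-values will be coarse")
    panel = _pair_panel(A, B)
    max_dims = min(max_dims, len(B.columns))
    cv = loso_scores(panel, n_components=max_dims)
    za, zb = cv.scores["A"], cv.scores["B"]
    stat = _heldout_partial_spearman(za, zb, max_dims)

    rng = np.random.default_rng(seed)
    n = len(A.stimuli)
    draws = np.empty((B_boot, max_dims))
    for b in range(B_boot):
        idx = rng.integers(0, n, size=n)
        draws[b] = _heldout_partial_spearman(za[idx], zb[idx], max_dims)

    p_boot = np.array([bootstrap_sign_p(draws[:, k]) for k in range(max_dims)])
    snr_vals = np.array([snr(stat[k], draws[:, k]) for k in range(max_dims)])
    pass_bh, _ = bh_fdr(p_boot, alpha=alpha)
    k_hat = forward_stop(p_boot, alpha=alpha)
    pass_fs = np.arange(max_dims) < k_hat
    pass_snr = snr_vals >= snr_min
    retained = [int(k) for k in np.nonzero(pass_bh & pass_fs & pass_snr)[0]]
    logger.info(
        "extract_dimensions: %d of %d dimensions retained "
        "(BH %d, ForwardStop %d, SNR %d)",
        len(retained), max_dims, int(pass_bh.sum()), k_hat, int(pass_snr.sum()),
    )

    ref_loadings = cv.reference.loadings[:, :max_dims]
    if retained:
        rotated, rotation = varimax(ref_loadings[:, retained])
        rotated = _fix_signs(rotated)
    else:
        rotated = np.zeros((len(B.columns), 0))
        rotation = np.zeros((0, 0))
    return DimensionReport(
        statistic=stat,
        p_boot=p_boot,
        snr=snr_vals,
        pass_bh=pass_bh,
        pass_forward_stop=pass_fs,
        pass_snr=pass_snr,
        retained=retained,
        loadings=ref_loadings,
        rotated_loadings=rotated,
        rotation=rotation,
        columns=list(B.columns),
        params={
            "B_boot": B_boot,
            "alpha": alpha,
            "snr_min": snr_min,
            "max_dims": max_dims,
            "seed": seed,
        },
    )


def _match_depths(rot_cand: np.ndarray, order: np.ndarray) -> int:
    """Longest top-N prefix on which some candidate dimension's loadings
    all point in the same direction.

    For each candidate column the loadings at the reference-ordered
    attributes are reduced to signs; the depth is the length of the
    initial run of mutually equal signs (all positive or all negative —
    a dimension's sign is arbitrary, so both orientations count).
    Returns the maximum depth over candidates (0 if there are none).
    """
    if rot_cand.shape[1] == 0:
        return 0
    cand_signs = np.where(rot_cand[order] >= 0, 1.0, -1.0)  # N_attr x M_cand
    mismatch = cand_signs != cand_signs[0]
    depths = np.where(
        mismatch.any(axis=0), mismatch.argmax(axis=0), cand_signs.shape[0]
    )
    return int(depths.max())


def loading_significance(
    A: WideMatrix,
    B: WideMatrix,
    report: DimensionReport,
    B_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[dict[int, int], dict[int, np.ndarray]]:
    """Bootstrap significance of the top-N loadings per retained dimension.

    The PPCA fit and varimax rotation are repeated on ``B_boot``
    stimulus resamples.  For reference dimension d with attributes
    ordered by |rotated loading|, p_N is one minus the fraction of
    resamples in which *some* re-extracted dimension has mutually
    same-signed loadings on all top N attributes; p_N is non-decreasing
    in N by construction.  The significant
    loading count per dimension is the ForwardStop cut of (p_1 ... p_Q)
    at ``alpha``.

    Returns ``(counts, p_curves)`` keyed by retained dimension index.
    """
    _check_aligned(A, B)
    if not report.retained:
        return {}, {}
    n_ret = report.n_retained
    q = len(report.columns)
    orders = {
        dim: np.argsort(-np.abs(report.rotated_loadings[:, j]))
        for j, dim in enumerate(report.retained)
    }

    rng = np.random.default_rng(seed)
    n = len(A.stimuli)
    depth_hits = {dim: np.zeros(q, dtype=int) for dim in report.retained}
    for _ in range(B_boot):
        idx = rng.integers(0, n, size=n)
        # resampling duplicates stimulus ids, so rows get fresh index ids
        panel = RatingsPanel(
            stimuli=[str(i) for i in range(n)],
            datasets=["A", "B"],
            concepts=list(B.columns),
            values={"A": A.values[idx], "B": B.values[idx]},
        )
        model = fit_gppca(panel, n_components=n_ret)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rot, _ = varimax(model.loadings)
        for dim in report.retained:
            depth = _match_depths(rot, orders[dim])
            if depth > 0:
                depth_hits[dim][:depth] += 1

    counts = {}
    p_curves = {}
    for dim in report.retained:
        p_n = 1.0 - depth_hits[dim] / B_boot  # non-decreasing in N
        counts[dim] = forward_stop(p_n, alpha=alpha)
        p_curves[dim] = p_n
    return counts, p_curves
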