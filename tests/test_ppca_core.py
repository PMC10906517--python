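import numpy as np
import pytest

from gppca import (
    RatingsPanel,
    cross_covariance,
    fit_gppca,
    objective_value,
    project_scores,
    symmetrized_sum,
)
from gppca.ppca_core import ComponentModel

WORKED_X = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])


def _panel(mats: dict, stimuli=None):
    n = next(iter(mats.values())).shape[0]
    p = next(iter(mats.values())).shape[1]
    return RatingsPanel(
        stimuli=stimuli or [f"s{i}" for i in range(n)],
        datasets=list(mats),
        concepts=[f"c{j}" for j in range(p)],
        values={k: np.asarray(v, float) for k, v in mats.items()},
    )


class TestCrossCovariance:
    def test_self_covariance_hand_example(self):
        # X'X/2 with zero column means
        np.testing.assert_allclose(
            cross_covariance(WORKED_X, WORKED_X), [[1, 0.5], [0.5, 1]]
        )

    def test_linear_in_second_argument(self):
        np.testing.assert_allclose(
            cross_covariance(WORKED_X, 2 * WORKED_X), [[2, 1], [1, 2]]
        )

    def test_constant_column_gives_zero_row(self, rng):
        X = rng.random((10, 3))
        X[:, 1] = 7.0
        C = cross_covariance(X, rng.random((10, 3)))
        np.testing.assert_allclose(C[1], 0.0, atol=1e-12)

    def test_row_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            cross_covariance(rng.random((5, 2)), rng.random((6, 2)))


class TestSymmetrizedSum:
    def test_identical_copies_scale_by_pair_count(self, rng):
        X = rng.random((20, 4))
        for k in (2, 3, 5):
            panel = _panel({f"d{i}": X.copy() for i in range(k)})
            expected = k * (k - 1) / 2 * np.cov(X, rowvar=False)
            np.testing.assert_allclose(symmetrized_sum(panel), expected)

    def test_k2_reduces_to_symmetrized_cross_covariance(self, rng):
        X, Y = rng.random((15, 3)), rng.random((15, 3))
        C = cross_covariance(X, Y)
        np.testing.assert_allclose(
            symmetrized_sum(_panel({"a": X, "b": Y})), (C + C.T) / 2
        )

    def test_independent_noise_entries_vanish(self, rng):
        n = 10_000
        panel = _panel({"a": rng.standard_normal((n, 3)),
                        "b": rng.standard_normal((n, 3))})
        assert np.all(np.abs(symmetrized_sum(panel)) < 3 / np.sqrt(n))

    def test_single_dataset_rejected(self, rng):
        with pytest.raises(ValueError):
            symmetrized_sum(_panel({"a": rng.random((5, 2))}))


class TestFitGppca:
    def test_worked_example(self, worked_panel):
        model = fit_gppca(worked_panel)
        np.testing.assert_allclose(model.preserved_cov, [3.0, 1.0])
        s = 1 / np.sqrt(2)
        np.testing.assert_allclose(model.loadings[:, 0], [s, s])
        np.testing.assert_allclose(np.abs(model.loadings[:, 1]), [s, s])
        assert model.loadings[0, 1] * model.loadings[1, 1] < 0

    def test_sign_convention_largest_entry_positive(self, rng):
        panel = _panel({"a": rng.random((30, 5)), "b": rng.random((30, 5))})
        L = fit_gppca(panel).loadings
        idx = np.argmax(np.abs(L), axis=0)
        assert np.all(L[idx, np.arange(L.shape[1])] > 0)

    def test_identical_datasets_reduce_to_pca(self, rng):
        X = rng.random((40, 4))
        for k in (2, 4):
            model = fit_gppca(_panel({f"d{i}": X.copy() for i in range(k)}))
            w, v = np.linalg.eigh(np.cov(X, rowvar=False))
            order = np.argsort(w)[::-1]
            np.testing.assert_allclose(
                model.preserved_cov, k * (k - 1) / 2 * w[order], atol=1e-8
            )
            cos = np.abs(np.einsum("pm,pm->m", model.loadings, v[:, order]))
            np.testing.assert_allclose(cos, 1.0, atol=1e-8)

    def test_loadings_orthonormal(self, rng):
        panel = _panel({"a": rng.random((25, 6)), "b": rng.random((25, 6)),
                        "c": rng.random((25, 6))})
        L = fit_gppca(panel).loadings
        np.testing.assert_allclose(L.T @ L, np.eye(6), atol=1e-10)

    def test_non_finite_rejected(self, rng):
        X = rng.random((10, 3))
        Y = X.copy()
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_gppca(_panel({"a": X, "b": Y}))

    def test_k2_equals_direct_eigendecomposition(self, rng):
        X, Y = rng.random((30, 5)), rng.random((30, 5))
        panel = _panel({"a": X, "b": Y})
        model = fit_gppca(panel)
        C = cross_covariance(X, Y)
        w, v = np.linalg.eigh((C + C.T) / 2)
        order = np.argsort(w)[::-1]
        assert np.max(np.abs(model.preserved_cov - w[order])) < 1e-10
        cos = np.abs(np.einsum("pm,pm->m", model.loadings, v[:, order]))
        assert np.max(np.abs(cos - 1.0)) < 1e-10


class TestObjectiveAndScores:
    def test_training_objective_reproduces_eigenvalues(self, rng):
        panel = _panel({c: rng.random((20, 4)) for c in "abc"})
        model = fit_gppca(panel)
        for m in range(4):
            assert abs(objective_value(model, panel, m)
                       - model.preserved_cov[m]) < 1e-8

    def test_rayleigh_bound(self, rng):
        panel = _panel({c: rng.random((20, 4)) for c in "ab"})
        model = fit_gppca(panel)
        mats = [panel.values[d] - panel.values[d].mean(0) for d in panel.datasets]
        for _ in range(50):
            v = rng.standard_normal(4)
            v /= np.linalg.norm(v)
            obj = np.cov(mats[0] @ v, mats[1] @ v, ddof=1)[0, 1]
            assert obj <= model.preserved_cov[0] + 1e-10

    def test_random_search_oracle_matches_first_component(self, rng):
        # independent maximizer of the summed pairwise covariance of
        # projections, computed without the eigendecomposition path
        n, p, k = 8, 3, 3
        mats = [rng.standard_normal((n, p)) for _ in range(k)]
        panel = _panel({f"d{i}": m for i, m in enumerate(mats)})
        model = fit_gppca(panel)
        centered = [m - m.mean(0) for m in mats]

        def objective(V):  # V: (draws, p)
            total = np.zeros(V.shape[0])
            for a in range(k):
                for b in range(a + 1, k):
                    za = centered[a] @ V.T
                    zb = centered[b] @ V.T
                    total += np.sum(za * zb, axis=0) / (n - 1)
            return total

        V = rng.standard_normal((100_000, p))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        best = V[np.argmax(objective(V))]
        # polish by normalized gradient ascent on the same objective
        shift = 10.0 * np.abs(objective(best[None]))[0] + 1.0
        for _ in range(500):
            grad = np.zeros(p)
            for a in range(k):
                for b in range(a + 1, k):
                    grad += (centered[a].T @ (centered[b] @ best)
                             + centered[b].T @ (centered[a] @ best)) / (n - 1)
            best = grad / 2 + shift * best
            best /= np.linalg.norm(best)
        assert abs(best @ model.loadings[:, 0]) >= 0.999

    def test_mean_profile_scores_zero(self, worked_panel):
        model = fit_gppca(worked_panel)
        probe = RatingsPanel(
            stimuli=["m", "x", "y"], datasets=["d1", "d2"],
            concepts=["c1", "c2"],
            values={d: np.vstack([model.column_means[d]] * 3)
                    for d in ("d1", "d2")},
        )
        scores = project_scores(model, probe)
        np.testing.assert_allclose(scores["d1"], 0.0, atol=1e-12)

    def test_training_score_covariances_match_eigenvalues(self, rng):
        panel = _panel({c: rng.random((30, 3)) for c in "abc"})
        model = fit_gppca(panel)
        scores = project_scores(model, panel)
        for m in range(3):
            total = sum(
                np.cov(scores[a][:, m], scores[b][:, m], ddof=1)[0, 1]
                for i, a in enumerate(panel.datasets)
                for b in panel.datasets[i + 1:]
            )
            assert abs(total - model.preserved_cov[m]) < 1e-8

    def test_heldout_scores_hand_computed(self, worked_panel):
        model = fit_gppca(worked_panel)
        s = 1 / np.sqrt(2)
        x_new = np.array([[1.0, 1.0]])
        probe = RatingsPanel(
            stimuli=["h"], datasets=["d1", "d2"], concepts=["c1", "c2"],
            values={"d1": x_new, "d2": 2 * x_new},
        )
        z = project_scores(model, probe)
        # training means are zero, so scores are plain projections
        np.testing.assert_allclose(z["d1"][0], [2 * s, 0.0], atol=1e-12)
        np.testing.assert_allclose(z["d2"][0], [4 * s, 0.0], atol=1e-12)

    def test_component_index_out_of_range(self, worked_panel):
        model = fit_gppca(worked_panel)
        with pytest.raises(IndexError):
            objective_value(model, worked_panel, 5)


def test_model_json_round_trip(tmp_path, worked_panel):
    model = fit_gppca(worked_panel)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ComponentModel.from_json(path)
    np.testing.assert_allclose(back.loadings, model.loadings)
    np.testing.assert_allclose(back.preserved_cov, model.preserved_cov)
    assert back.dataset_order == model.dataset_order
    assert back.pair_set == model.pair_set
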