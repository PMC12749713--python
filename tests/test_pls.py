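"""PLS1 core: oracles, algebraic identities, invariances, serialization."""

import numpy as np
import pandas as pd
import pytest

from chronomodes import fit_pls, group_ttest, latent_correlation, transform
from chronomodes.pls import PLSModel, score_target_correlation


def _signed_target(rng, n):
    y = rng.choice([-1.0, 1.0], n)
    if np.unique(y).size < 2:  # pragma: no cover - vanishing probability
        y[0] = -y[0]
    return y


def test_signal_column_dominates(rng):
    y = _signed_target(rng, 1000)
    X = np.column_stack([y, rng.standard_normal(1000)])
    model = fit_pls(X, y, 1)
    assert abs(np.corrcoef(model.T[:, 0], y)[0, 1]) > 0.99


def test_first_weight_is_cross_covariance_direction(rng):
    X = rng.standard_normal((150, 25))
    y = _signed_target(rng, 150)
    model = fit_pls(X, y, 1)
    Xc = (X - model.x_center) / model.x_scale
    g = Xc.T @ (y - y.mean())
    g /= np.linalg.norm(g)
    assert abs(float(g @ model.W[:, 0])) > 1 - 1e-10


@pytest.mark.parametrize("n,p,k", [(60, 10, 3), (200, 40, 5), (50, 8, 1)])
def test_rotation_identity_and_score_orthogonality(rng, n, p, k):
    X = rng.standard_normal((n, p))
    y = _signed_target(rng, n)
    model = fit_pls(X, y, k)
    TT = model.T.T @ model.T
    off = TT - np.diag(np.diag(TT))
    assert np.abs(off).max() / np.diag(TT).max() < 1e-8
    Xc = (X - model.x_center) / model.x_scale
    assert np.abs(Xc @ model.rotation() - model.T).max() < 1e-8


def test_sign_convention_largest_weight_positive(rng):
    X = rng.standard_normal((100, 12))
    y = _signed_target(rng, 100)
    model = fit_pls(X, y, 4)
    for j in range(4):
        i = np.argmax(np.abs(model.W[:, j]))
        assert model.W[i, j] > 0


def test_joint_row_permutation_invariance(rng):
    X = rng.standard_normal((80, 15))
    y = _signed_target(rng, 80)
    perm = rng.permutation(80)
    a = fit_pls(X, y, 3)
    b = fit_pls(X[perm], y[perm], 3)
    assert np.abs(a.W - b.W).max() < 1e-10
    assert np.abs(a.P - b.P).max() < 1e-10
    assert np.abs(latent_correlation(a, y)
                  - latent_correlation(b, y[perm])).max() < 1e-10


class TestTransform:
    def test_training_matrix_reproduces_scores(self, rng):
        X = rng.standard_normal((90, 20))
        y = _signed_target(rng, 90)
        model = fit_pls(X, y, 4)
        assert np.abs(transform(model, X) - model.T).max() < 1e-8

    def test_row_at_training_mean_scores_zero(self, rng):
        X = rng.standard_normal((70, 9))
        y = _signed_target(rng, 70)
        model = fit_pls(X, y, 2)
        scores = transform(model, X.mean(axis=0, keepdims=True))
        assert np.abs(scores).max() < 1e-10

    def test_matches_explicit_linear_solve_oracle(self, rng):
        X = rng.standard_normal((100, 14))
        y = _signed_target(rng, 100)
        model = fit_pls(X, y, 3)
        X_new = rng.standard_normal((10, 14))
        Xc = (X_new - model.x_center) / model.x_scale
        # column-by-column solve of (P^T W) z = e_j, then R = W Z
        M = model.P.T @ model.W
        R = model.W @ np.column_stack(
            [np.linalg.solve(M, np.eye(3)[:, j]) for j in range(3)])
        assert np.abs(transform(model, X_new) - Xc @ R).max() < 1e-10

    def test_column_mismatch_rejected_naming_first(self, rng):
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        y = _signed_target(rng, 50)
        model = fit_pls(X, y, 1)
        bad = X.rename(columns={"b": "z"})
        with pytest.raises(ValueError, match="'z'"):
            transform(model, bad)


class TestLatentCorrelation:
    def test_score_equal_to_target_gives_one(self, rng):
        y = _signed_target(rng, 60)
        assert score_target_correlation(y[:, None], y)[0] == pytest.approx(1.0)
        assert score_target_correlation(-y[:, None], y)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        t = rng.standard_normal(100)
        y = _signed_target(rng, 100)
        got = score_target_correlation(t[:, None], y)[0]
        tc, yc = t - t.mean(), y - y.mean()
        expected = (tc @ yc) / np.sqrt((tc @ tc) * (yc @ yc))
        assert abs(got - expected) < 1e-12

    def test_zero_variance_score_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            score_target_correlation(np.ones((10, 1)),
                                     np.array([-1.0, 1.0] * 5))


class TestGroupTTest:
    def test_identical_groups_give_zero(self):
        scores = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        group = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        t, df, p = group_ttest(scores, group)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degrees_of_freedom_from_group_sizes(self, rng):
        scores = rng.standard_normal(17_995 + 9_035)
        group = np.concatenate([-np.ones(17_995), np.ones(9_035)])
        _, df, _ = group_ttest(scores, group)
        assert df == 27_028

    def test_matches_pooled_formula_oracle(self, rng):
        a = rng.standard_normal(40) + 0.3
        b = rng.standard_normal(25)
        scores = np.concatenate([a, b])
        group = np.concatenate([-np.ones(40), np.ones(25)])
        t, df, p = group_ttest(scores, group)
        sp2 = ((39 * a.var(ddof=1) + 24 * b.var(ddof=1)) / 63)
        t_oracle = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 40 + 1 / 25))
        assert abs(t - t_oracle) < 1e-10
        assert df == 63

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_ttest(np.arange(4.0), np.array([-1.0, 1.0, 1.0, 1.0]))


class TestValidation:
    def test_single_class_target_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            fit_pls(rng.standard_normal((20, 4)), np.ones(20), 1)

    def test_noncoded_target_rejected(self, rng):
        with pytest.raises(ValueError, match="-1/\\+1"):
            fit_pls(rng.standard_normal((20, 4)),
                    rng.standard_normal(20), 1)

    def test_k_beyond_dimensions_rejected(self, rng):
        with pytest.raises(ValueError, match="k="):
            fit_pls(rng.standard_normal((20, 4)), _signed_target(rng, 20), 5)

    def test_rank_exhaustion_detected(self, rng):
        z = rng.standard_normal(30)
        X = np.column_stack([z, 2 * z, 3 * z, -z])  # rank 1
        with pytest.raises(ValueError, match="rank|degenerate"):
            fit_pls(X, _signed_target(rng, 30), 3)


def test_matches_reference_implementation(rng):
    """Scores agree (up to component sign) with an independently developed
    PLS regression implementation on the same standardized data."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X = rng.standard_normal((120, 18))
    y = _signed_target(rng, 120)
    model = fit_pls(X, y, 4)
    ref = sklearn.PLSRegression(n_components=4, scale=True).fit(X, y)
    for j in range(4):
        r = np.corrcoef(ref.x_scores_[:, j], model.T[:, j])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8


def test_json_round_trip_is_lossless(tmp_path, rng):
    X = pd.DataFrame(rng.standard_normal((40, 6)),
                     columns=[f"f{i}" for i in range(6)])
    y = _signed_target(rng, 40)
    model = fit_pls(X, y, 2, blocks=["GMV"] * 3 + ["FA"] * 3)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = PLSModel.from_json(path)
    for attr in ("W", "P", "T", "y_loadings", "x_center", "x_scale"):
        assert np.array_equal(getattr(model, attr), getattr(back, attr))
    assert back.feature_names == model.feature_names
    assert back.blocks == model.blocks
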