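"""Feature-subset projection and age-bracket stratification."""

import numpy as np
import pandas as pd
import pytest

from chronomodes import (ADULT_BRACKETS_YEARS, CHILD_BRACKETS_MONTHS,
                         age_bracket_summary, build_projection, fit_pls,
                         project_cohort, transform)
from chronomodes.transfer import ProjectionModel


def _model(rng, n=120, p=16, k=3, blocks=None):
    X = rng.standard_normal((n, p))
    y = rng.choice([-1.0, 1.0], n)
    y[0] = -y[1]
    return X, y, fit_pls(X, y, k, blocks=blocks)


class TestBuildProjection:
    def test_full_subset_projection_equals_transform(self, rng):
        X, y, model = _model(rng)
        proj = build_projection(model, model.feature_names)
        scores = project_cohort(proj, X, standardize="training")
        assert np.abs(scores - model.T).max() < 1e-8
        assert np.abs(scores - transform(model, X)).max() < 1e-8

    def test_k1_rotation_is_scalar_closed_form(self, rng):
        X, y, model = _model(rng, k=1)
        proj = build_projection(model, model.feature_names[:8])
        w = model.W[:8, 0]
        p = model.P[:8, 0]
        expected = w / float(p @ w)
        assert np.abs(proj.R_sub[:, 0] - expected).max() < 1e-12

    def test_block_subset_selected_by_tag(self, rng):
        blocks = ["GMV"] * 6 + ["FA"] * 10
        X, y, model = _model(rng, blocks=blocks)
        proj = build_projection(model, "GMV")
        assert proj.feature_subset == model.feature_names[:6]
        assert proj.W_sub.shape == (6, 3)

    def test_rotation_inverse_consistency(self, rng):
        X, y, model = _model(rng)
        proj = build_projection(model, model.feature_names[:10])
        M = proj.P_sub.T @ proj.W_sub
        assert np.abs(M @ np.linalg.solve(M, np.eye(model.k))
                      - np.eye(model.k)).max() < 1e-8

    def test_singular_restriction_rejected(self, rng):
        X, y, model = _model(rng, k=2)
        with pytest.raises(ValueError, match="singular"):
            build_projection(model, model.feature_names[:1])

    def test_unknown_features_rejected(self, rng):
        X, y, model = _model(rng)
        with pytest.raises(ValueError, match="not in the model"):
            build_projection(model, ["nope"])

    def test_empty_subset_rejected(self, rng):
        X, y, model = _model(rng)
        with pytest.raises(ValueError, match="empty"):
            build_projection(model, [])


class TestProjectCohort:
    def test_matches_two_step_solve_oracle(self, rng):
        X, y, model = _model(rng)
        subset = model.feature_names[:9]
        proj = build_projection(model, subset)
        X_ext = rng.standard_normal((40, 9))
        got = project_cohort(proj, X_ext)
        center = X_ext.mean(axis=0)
        scale = X_ext.std(axis=0)
        Xs = (X_ext - center) / scale
        M = proj.P_sub.T @ proj.W_sub
        expected = Xs @ proj.W_sub @ np.linalg.solve(M, np.eye(model.k))
        assert np.abs(got - expected).max() < 1e-10

    def test_row_at_applied_center_scores_zero(self, rng):
        X, y, model = _model(rng)
        proj = build_projection(model, model.feature_names)
        one_row = proj.train_center[None, :]
        # single external row is its own center under external standardization
        assert np.abs(project_cohort(proj, one_row)).max() < 1e-12
        assert np.abs(project_cohort(proj, one_row,
                                     standardize="training")).max() < 1e-12

    def test_projection_is_linear(self, rng):
        X, y, model = _model(rng)
        proj = build_projection(model, model.feature_names[:12])
        A = rng.standard_normal((15, 12))
        B = rng.standard_normal((15, 12))
        left = project_cohort(proj, 2.0 * A + 3.0 * B, standardize="training")
        right = (2.0 * project_cohort(proj, A, standardize="training")
                 + 3.0 * project_cohort(proj, B, standardize="training")
                 + 4.0 * proj.train_center / proj.train_scale @ proj.R_sub)
        assert np.abs(left - right).max() < 1e-10

    def test_column_mismatch_rejected(self, rng):
        X, y, model = _model(rng)
        proj = build_projection(model, model.feature_names[:5])
        bad = pd.DataFrame(rng.standard_normal((5, 5)),
                           columns=["z"] + model.feature_names[1:5])
        with pytest.raises(ValueError, match="mismatch"):
            project_cohort(proj, bad)

    def test_json_round_trip(self, tmp_path, rng):
        X, y, model = _model(rng)
        proj = build_projection(model, model.feature_names[:7])
        proj.to_json(tmp_path / "proj.json")
        back = ProjectionModel.from_json(tmp_path / "proj.json")
        assert np.array_equal(back.R_sub, proj.R_sub)
        assert back.feature_subset == proj.feature_subset


class TestAgeBracketSummary:
    def test_matches_groupby_oracle(self, rng):
        ages = rng.uniform(40, 70, 300)
        scores = rng.standard_normal((300, 2))
        out = age_bracket_summary(scores, ages, ADULT_BRACKETS_YEARS)
        df = pd.DataFrame({"age": ages, "s1": scores[:, 0], "s2": scores[:, 1]})
        df["bracket"] = pd.cut(df["age"], [40, 50, 55, 60, 65, 70],
                               right=False, include_lowest=True)
        ref = df.groupby("bracket", observed=True)["s1"].agg(["mean", "std", "size"])
        got = out[out.component == 1].set_index("bracket_low")
        for (lo, _), row in zip(ADULT_BRACKETS_YEARS, ref.itertuples()):
            assert got.loc[lo, "mean"] == pytest.approx(row.mean)
            assert got.loc[lo, "sd"] == pytest.approx(row.std)
            assert got.loc[lo, "n"] == row.size

    def test_default_adult_brackets_span_40_to_70(self):
        assert len(ADULT_BRACKETS_YEARS) == 5
        assert ADULT_BRACKETS_YEARS[0][0] == 40
        assert ADULT_BRACKETS_YEARS[-1][1] == 70
        assert len(CHILD_BRACKETS_MONTHS) == 4

    def test_shared_endpoint_goes_to_upper_bracket(self):
        out = age_bracket_summary(np.array([[1.0], [2.0]]),
                                  np.array([50.0, 70.0]), ADULT_BRACKETS_YEARS)
        by = out.set_index("bracket")
        assert by.loc["50-55", "n"] == 1     # 50 is left-closed in [50, 55)
        assert by.loc["65-70", "n"] == 1     # final bracket right-closed
        assert by.loc["40-50", "n"] == 0

    def test_single_member_bracket_has_undefined_sd(self):
        out = age_bracket_summary(np.array([[0.7]]), np.array([42.0]),
                                  ADULT_BRACKETS_YEARS)
        row = out.set_index("bracket").loc["40-50"]
        assert row["mean"] == pytest.approx(0.7)
        assert np.isnan(row["sd"])

    def test_empty_bracket_emitted_with_n_zero(self):
        out = age_bracket_summary(np.array([[1.0]]), np.array([45.0]),
                                  ADULT_BRACKETS_YEARS)
        assert (out.set_index("bracket").loc["60-65", "n"] == 0)
        assert np.isnan(out.set_index("bracket").loc["60-65", "mean"])

    def test_participants_outside_brackets_counted(self):
        out = age_bracket_summary(np.array([[1.0], [2.0]]),
                                  np.array([30.0, 45.0]), ADULT_BRACKETS_YEARS)
        assert out.attrs["n_outside"] == 1

    def test_overlapping_brackets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            age_bracket_summary(np.zeros((3, 1)), np.array([41.0, 45.0, 52.0]),
                                [(40, 52), (50, 60)])
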