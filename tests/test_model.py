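"""Conjugate Normal/Inverse-Gamma regression: exact updates and marginals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neighborgrowth import (
    FocalTable,
    ModelSpec,
    PosteriorParams,
    PriorSpec,
    build_design,
    create_focal_vs_comp,
    fit_conjugate,
    posterior_marginals,
    posterior_predict,
    rmse,
)
from neighborgrowth.errors import DataError, ShapeError, ValidationError

from conftest import annotated_growth
from oracles import normal_equations_ols

UNIT_PRIOR = PriorSpec(a0=1.0, b0=1.0, mu0=np.zeros(1), lambda0=np.eye(1))


class TestModelSpec:
    spec = ModelSpec(("A", "B"), ("A", "B", "C"))

    def test_layout_dimensions(self):
        assert self.spec.p == 2 * (2 + 3)
        labels = self.spec.coefficient_labels()
        assert len(labels) == self.spec.p
        assert (labels["role"] == "competition").sum() == 2 * 3
        assert sorted(labels["coefficient"]) == list(range(self.spec.p))

    def test_column_index_is_bijective_and_stable(self):
        cols = [self.spec.intercept_col(j) for j in range(2)]
        cols += [self.spec.dbh_col(j) for j in range(2)]
        cols += [self.spec.lambda_col(j, k) for j in range(2) for k in range(3)]
        assert sorted(cols) == list(range(self.spec.p))


class TestBuildDesign:
    def test_single_group_layout(self):
        g = pd.DataFrame(
            {"stem_id": ["s1", "s2"], "sp": ["A", "A"],
             "gx": [0.0, 3.0], "gy": [0.0, 0.0],
             "dbh1": [10.0, 12.0], "growth": [0.6, 0.7],
             "basal_area": [0.3, 0.2], "buffer": False, "fold_id": 1}
        )
        g["group"] = pd.Categorical(g["sp"])
        t = create_focal_vs_comp(g, comp_dist=7.5)
        X, y = build_design(t)
        assert X.shape == (2, 3)
        assert np.allclose(X[0], [1.0, 10.0, 0.2])  # intercept, dbh, comp total
        assert np.allclose(y, [0.6, 0.7])

    def test_block_structure_zeroes_other_groups(self, focal_table):
        spec = ModelSpec.from_focal_table(focal_table)
        X, _ = build_design(focal_table, spec)
        for i, r in enumerate(focal_table.records):
            j = focal_table.focal_levels.index(r.focal_group)
            row = X[i].copy()
            row[spec.block_start(j): spec.block_start(j) + 2 + spec.K] = 0.0
            assert np.all(row == 0.0)

    def test_unknown_focal_group_rejected(self, focal_table):
        spec = ModelSpec(("X",), ("X",))
        with pytest.raises(DataError):
            build_design(focal_table, spec)


class TestFitConjugate:
    def test_worked_single_observation(self):
        """p=1, x=1, y=2 under the unit prior: closed-form hand computation."""
        post = fit_conjugate([[1.0]], [2.0], UNIT_PRIOR)
        assert post.an == pytest.approx(1.5)
        assert post.bn == pytest.approx(2.0)
        assert post.mun[0] == pytest.approx(1.0)
        assert post.lambdan[0, 0] == pytest.approx(2.0)

    def test_empty_update_returns_prior(self):
        p = 3
        prior = PriorSpec(2.0, 3.0, np.arange(p, dtype=float), np.diag([1.0, 2.0, 3.0]))
        post = fit_conjugate(np.zeros((0, p)), np.zeros(0), prior)
        assert post.an == prior.a0 and post.bn == pytest.approx(prior.b0)
        assert np.allclose(post.mun, prior.mu0)
        assert np.allclose(post.lambdan, prior.lambda0)

    def test_flat_prior_recovers_least_squares(self):
        rng = np.random.default_rng(0)
        n, p = 200, 6
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        post = fit_conjugate(X, y, PriorSpec.flat(p))
        assert np.allclose(post.mun, normal_equations_ols(X, y), atol=1e-6)

    def test_batch_equals_sequential(self):
        rng = np.random.default_rng(1)
        n, p = 20, 3
        X, y = rng.normal(size=(n, p)), rng.normal(size=n)
        prior = PriorSpec.default(p)
        batch = fit_conjugate(X, y, prior)
        running = prior
        for i in range(n):
            running = fit_conjugate(X[i: i + 1], y[i: i + 1], running).as_prior()
        assert np.allclose(running.mu0, batch.mun, atol=1e-10)
        assert np.allclose(running.lambda0, batch.lambdan, atol=1e-10)
        assert running.a0 == pytest.approx(batch.an, abs=1e-12)
        assert running.b0 == pytest.approx(batch.bn, abs=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_row_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 15, 4
        X, y = rng.normal(size=(n, p)), rng.normal(size=n)
        prior = PriorSpec.default(p)
        a = fit_conjugate(X, y, prior)
        perm = rng.permutation(n)
        b = fit_conjugate(X[perm], y[perm], prior)
        assert np.allclose(a.mun, b.mun, atol=1e-10)
        assert a.bn == pytest.approx(b.bn, rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_bn_positive_and_an_increment(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(1, 30), rng.integers(1, 5)
        X, y = rng.normal(size=(n, p)), rng.normal(size=n)
        post = fit_conjugate(X, y, PriorSpec.default(int(p)))
        assert post.bn > 0
        assert post.an == 1.0 + n / 2.0
        # lambdan - lambda0 = X'X is positive semidefinite
        eig = np.linalg.eigvalsh(post.lambdan - np.eye(int(p)) / 100.0)
        assert eig.min() > -1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            PriorSpec(1.0, 1.0, np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValidationError):
            PriorSpec(0.0, 1.0, np.zeros(1), np.eye(1))
        with pytest.raises(DataError):
            fit_conjugate([[1.0]], [np.nan], UNIT_PRIOR)
        with pytest.raises(ShapeError):
            fit_conjugate([[1.0, 2.0]], [1.0], UNIT_PRIOR)


class TestPosteriorPredict:
    post = fit_conjugate([[1.0]], [2.0], UNIT_PRIOR)

    def test_zero_row_predicts_zero(self):
        assert posterior_predict(self.post, [[0.0]])[0] == 0.0

    def test_unit_vector_extracts_coefficient(self):
        p = 4
        prior = PriorSpec(2.0, 1.0, np.array([0.5, -1.0, 2.0, 0.0]), np.eye(p))
        post = fit_conjugate(np.zeros((0, p)), np.zeros(0), prior)
        for i in range(p):
            e = np.zeros((1, p))
            e[0, i] = 1.0
            assert posterior_predict(post, e)[0] == pytest.approx(prior.mu0[i])

    def test_predictive_df_and_scale(self):
        mean, scale, df = posterior_predict(self.post, [[1.0]], return_scale=True)
        assert df == pytest.approx(3.0)  # 2 * an
        # scale^2 = (bn/an)(1 + x lambdan^-1 x') = (2/1.5)(1 + 0.5)
        assert scale[0] ** 2 == pytest.approx((2.0 / 1.5) * 1.5)

    def test_column_mismatch(self):
        with pytest.raises(ShapeError):
            posterior_predict(self.post, [[1.0, 2.0]])


class TestPosteriorMarginals:
    def test_worked_single_observation_marginal(self):
        post = fit_conjugate([[1.0]], [2.0], UNIT_PRIOR)
        marg = posterior_marginals(post)
        assert marg.loc[0, "df"] == pytest.approx(3.0)
        assert marg.loc[0, "location"] == pytest.approx(1.0)
        assert marg.loc[0, "scale"] == pytest.approx(np.sqrt((2.0 / 1.5) * 0.5))
        assert marg.attrs["sigma2_a"] == pytest.approx(1.5)
        assert marg.attrs["sigma2_b"] == pytest.approx(2.0)

    def test_no_data_centered_at_prior_mean(self):
        p = 3
        prior = PriorSpec(1.0, 1.0, np.array([1.0, -2.0, 0.5]), np.eye(p))
        post = fit_conjugate(np.zeros((0, p)), np.zeros(0), prior)
        marg = posterior_marginals(post)
        assert np.allclose(marg["location"], prior.mu0)

    def test_competition_row_count_is_J_times_K(self, focal_table):
        spec = ModelSpec.from_focal_table(focal_table)
        X, y = build_design(focal_table, spec)
        post = fit_conjugate(X, y, PriorSpec.default(spec.p), spec=spec)
        marg = posterior_marginals(post)
        assert (marg["role"] == "competition").sum() == spec.J * spec.K
        assert set(marg["role"]) == {"intercepts", "dbh_slopes", "competition"}


class TestRMSE:
    @pytest.mark.parametrize(
        "obs,pred,expected",
        [((1.0, 2.0), (1.0, 2.0), 0.0),
         ((0.0, 0.0), (1.0, 1.0), 1.0),
         ((0.0, 2.0), (0.0, 0.0), np.sqrt(2.0))],
    )
    def test_examples(self, obs, pred, expected):
        assert rmse(obs, pred) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            rmse([1.0], [1.0, 2.0])


class TestSerialization:
    def test_posterior_json_round_trip(self, focal_table):
        spec = ModelSpec.from_focal_table(focal_table)
        X, y = build_design(focal_table, spec)
        post = fit_conjugate(X, y, PriorSpec.default(spec.p), spec=spec)
        back = PosteriorParams.from_json(post.to_json())
        assert back.an == post.an and back.bn == pytest.approx(post.bn)
        assert np.allclose(back.mun, post.mun)
        assert np.allclose(back.lambdan, post.lambdan)
        assert back.spec == post.spec

    def test_scaling_equivariance(self):
        """Halving a covariate column doubles its fitted coefficient (flat prior)."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 0.01 * rng.normal(size=100)
        a = fit_conjugate(X, y, PriorSpec.flat(4))
        X2 = X.copy()
        X2[:, 2] /= 2.0
        b = fit_conjugate(X2, y, PriorSpec.flat(4))
        assert b.mun[2] == pytest.approx(2.0 * a.mun[2], rel=1e-6)
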