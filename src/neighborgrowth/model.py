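"""Species-structured Bayesian linear regression with exact conjugacy.

The growth of focal stem i of group j is modeled as

    y_ij = beta0_j + beta_dbh_j * dbh_ij + sum_k lambda_jk * x_ijk + eps_ij,
    eps_ij ~ Normal(0, sigma^2)

with a Normal/Inverse-Gamma prior: sigma^2 ~ InvGamma(a0, b0) and
beta | sigma^2 ~ Normal(mu0, sigma^2 * Lambda0^{-1}). Conjugacy gives
closed-form posteriors — no MCMC:

    Lambda_n = Lambda0 + X'X
    mu_n     = Lambda_n^{-1} (Lambda0 mu0 + X'y)
    a_n      = a0 + n/2
    b_n      = b0 + (y'y + mu0' Lambda0 mu0 - mu_n' Lambda_n mu_n) / 2

Coefficient marginals are Student-t(df=2 a_n); the posterior predictive is
Student-t(df=2 a_n, location X mu_n, scale^2 = (b_n/a_n)(1 + x Λn^{-1} x')).

One joint regression is fit with a single shared sigma^2 across all focal
groups (the single error term of the model), not per-species fits.
Coefficient ordering is j-major: for each focal level j in order, its
intercept, its dbh slope, then its K competition coefficients — p = J(2+K)
columns in all. DBH enters uncentered in cm; all-zero columns (focal x
competitor pairs never observed) are retained, kept well-posed by the proper
prior, so the coefficient index is stable across folds and shuffles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import DataError, ShapeError, ValidationError
from .neighborhoods import FocalTable

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "PriorSpec", "PosteriorParams",
    "build_design", "fit_conjugate", "posterior_predict",
    "posterior_marginals", "rmse",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed coefficient layout for the species-structured design matrix."""

    focal_levels: tuple
    comp_levels: tuple

    @property
    def J(self) -> int:
        return len(self.focal_levels)

    @property
    def K(self) -> int:
        return len(self.comp_levels)

    @property
    def p(self) -> int:
        return self.J * (2 + self.K)

    @classmethod
    def from_focal_table(cls, table: FocalTable) -> "ModelSpec":
        return cls(tuple(table.focal_levels), tuple(table.comp_levels))

    def block_start(self, j: int) -> int:
        return j * (2 + self.K)

    def intercept_col(self, j: int) -> int:
        return self.block_start(j)

    def dbh_col(self, j: int) -> int:
        return self.block_start(j) + 1

    def lambda_col(self, j: int, k: int) -> int:
        return self.block_start(j) + 2 + k

    def coefficient_labels(self) -> pd.DataFrame:
        """Tidy index: one row per coefficient with role and group labels."""
        rows = []
        for j, fj in enumerate(self.focal_levels):
            rows.append((self.intercept_col(j), "intercepts", fj, None))
            rows.append((self.dbh_col(j), "dbh_slopes", fj, None))
            for k, ck in enumerate(self.comp_levels):
                rows.append((self.lambda_col(j, k), "competition", fj, ck))
        return pd.DataFrame(
            rows, columns=["coefficient", "role", "focal_group", "competitor_group"]
        )


def build_design(table: FocalTable, spec: ModelSpec | None = None):
    """Assemble (X, y) from a focal table under the spec's coefficient layout.

    Row i (focal group j) carries 1 in its intercept column, dbh in its slope
    column, comp_totals[k] in its (j, k) competition columns, zeros elsewhere.
    """
    if spec is None:
        spec = ModelSpec.from_focal_table(table)
    focal_index = {g: j for j, g in enumerate(spec.focal_levels)}
    comp_index = {g: k for k, g in enumerate(spec.comp_levels)}
    n = len(table.records)
    X = np.zeros((n, spec.p))
    y = np.empty(n)
    for i, r in enumerate(table.records):
        if r.focal_group not in focal_index:
            raise DataError(f"focal group {r.focal_group!r} not in model spec")
        j = focal_index[r.focal_group]
        X[i, spec.intercept_col(j)] = 1.0
        X[i, spec.dbh_col(j)] = r.dbh
        if tuple(r.comp_levels) == spec.comp_levels:
            X[i, spec.block_start(j) + 2: spec.block_start(j) + 2 + spec.K] = r.comp_totals
        else:  # re-aggregate under the spec's (possibly different) level order
            for g, x in zip(r.comp_group_codes, r.comp_x):
                label = r.comp_levels[g]
                if label not in comp_index:
                    raise DataError(f"competitor group {label!r} not in model spec")
                X[i, spec.lambda_col(j, comp_index[label])] += x
        y[i] = r.growth
    return X, y


@dataclass
class PriorSpec:
    """Normal/Inverse-Gamma hyperparameters (a0, b0, mu0, Lambda0)."""

    a0: float
    b0: float
    mu0: np.ndarray
    lambda0: np.ndarray

    def __post_init__(self):
        self.mu0 = np.atleast_1d(np.asarray(self.mu0, dtype=float))
        self.lambda0 = np.atleast_2d(np.asarray(self.lambda0, dtype=float))
        p = self.mu0.shape[0]
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValidationError("a0 and b0 must be positive")
        if self.lambda0.shape != (p, p):
            raise ShapeError(f"lambda0 must be {p}x{p}, got {self.lambda0.shape}")
        if not np.allclose(self.lambda0, self.lambda0.T, atol=1e-12):
            raise ValidationError("lambda0 must be symmetric")
        try:
            np.linalg.cholesky(self.lambda0)
        except np.linalg.LinAlgError as exc:
            raise ValidationError("lambda0 must be positive definite") from exc

    @property
    def p(self) -> int:
        return self.mu0.shape[0]

    @classmethod
    def default(cls, p: int) -> "PriorSpec":
        """Weakly informative default: a0=b0=1, mu0=0, Lambda0 = I/100.

        Prior precision 0.01 puts conditional prior sd 10*sigma on every
        coefficient — diffuse on the cm/yr growth scale yet proper, so
        never-observed focal x competitor columns stay well-posed.
        """
        return cls(a0=1.0, b0=1.0, mu0=np.zeros(p), lambda0=np.eye(p) / 100.0)

    @classmethod
    def flat(cls, p: int, eps: float = 1e-10) -> "PriorSpec":
        """Near-flat prior (Lambda0 = eps*I): posterior mean -> least squares."""
        return cls(a0=1.0, b0=1.0, mu0=np.zeros(p), lambda0=np.eye(p) * eps)


@dataclass
class PosteriorParams:
    """Posterior Normal/Inverse-Gamma hyperparameters after conditioning."""

    an: float
    bn: float
    mun: np.ndarray
    lambdan: np.ndarray
    n: int
    spec: ModelSpec | None = field(default=None)

    @property
    def p(self) -> int:
        return self.mun.shape[0]

    def as_prior(self) -> PriorSpec:
        """Reuse the posterior as a prior for a further (sequential) update."""
        return PriorSpec(self.an, self.bn, self.mun.copy(), self.lambdan.copy())

    def sigma2_marginal(self) -> tuple[float, float]:
        """(shape, scale) of the Inverse-Gamma posterior of sigma^2."""
        return self.an, self.bn

    # --- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "an": self.an, "bn": self.bn, "n": self.n,
            "mun": self.mun.tolist(), "lambdan": self.lambdan.tolist(),
        }
        if self.spec is not None:
            doc["focal_levels"] = list(self.spec.focal_levels)
            doc["comp_levels"] = list(self.spec.comp_levels)
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "PosteriorParams":
        doc = json.loads(text)
        spec = None
        if "focal_levels" in doc:
            spec = ModelSpec(tuple(doc["focal_levels"]), tuple(doc["comp_levels"]))
        return cls(
            an=float(doc["an"]), bn=float(doc["bn"]),
            mun=np.asarray(doc["mun"], dtype=float),
            lambdan=np.asarray(doc["lambdan"], dtype=float),
            n=int(doc["n"]), spec=spec,
        )


def _chol(mat: np.ndarray):
    """Cholesky factor with a single logged jitter retry on failure."""
    try:
        return cho_factor(mat, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * np.trace(mat) / mat.shape[0]
        logger.warning("Cholesky failed; retrying with jitter %.3e", jitter)
        return cho_factor(mat + jitter * np.eye(mat.shape[0]), lower=True)


def fit_conjugate(
    X: np.ndarray, y: np.ndarray, prior: PriorSpec, spec: ModelSpec | None = None
) -> PosteriorParams:
    """Exact conjugate posterior update; n = 0 returns the prior unchanged.

    Solved through an SPD Cholesky factorization of Lambda_n — no explicit
    matrix inverse is formed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = y.shape[0]
    if X.shape != (n, prior.p):
        raise ShapeError(f"X must be ({n}, {prior.p}), got {X.shape}")
    if not np.all(np.isfinite(y)):
        raise DataError("response contains non-finite values")
    if not np.all(np.isfinite(X)):
        raise DataError("design matrix contains non-finite values")

    lambdan = prior.lambda0 + X.T @ X
    lambdan = (lambdan + lambdan.T) / 2.0
    rhs = prior.lambda0 @ prior.mu0 + X.T @ y
    c = _chol(lambdan)
    mun = cho_solve(c, rhs)
    an = prior.a0 + n / 2.0
    bn = prior.b0 + 0.5 * (
        float(y @ y)
        + float(prior.mu0 @ (prior.lambda0 @ prior.mu0))
        - float(mun @ (lambdan @ mun))
    )
    return PosteriorParams(an=an, bn=bn, mun=mun, lambdan=lambdan, n=n, spec=spec)


def posterior_predict(
    post: PosteriorParams, Xnew: np.ndarray, return_scale: bool = False
):
    """Posterior-predictive point predictions (and optionally scale and df).

    The predictive for a new row x is Student-t with df = 2*a_n, location
    x·mu_n and squared scale (b_n/a_n)(1 + x Λn^{-1} x'); the point
    prediction is the location.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != post.p:
        raise ShapeError(f"Xnew must have {post.p} columns, got {Xnew.shape[1]}")
    mean = Xnew @ post.mun
    if not return_scale:
        return mean
    c = _chol(post.lambdan)
    # row-wise x Λn^{-1} x' via the triangular solve
    sol = cho_solve(c, Xnew.T)
    quad = np.einsum("ij,ji->i", Xnew, sol)
    scale = np.sqrt((post.bn / post.an) * (1.0 + quad))
    return mean, scale, 2.0 * post.an


def posterior_marginals(post: PosteriorParams) -> pd.DataFrame:
    """Tidy table of coefficient marginals plus the sigma^2 density parameters.

    Each coefficient i is marginally Student-t with df = 2*a_n, location
    mu_n[i] and scale sqrt((b_n/a_n) [Λn^{-1}]_ii); rows are labeled
    "intercepts" / "dbh_slopes" / "competition" when a :class:`ModelSpec` is
    attached. The frame's ``attrs`` carry the Inverse-Gamma(a_n, b_n)
    parameters of sigma^2.
    """
    c = _chol(post.lambdan)
    inv_diag = np.einsum("ii->i", cho_solve(c, np.eye(post.p)))
    scale = np.sqrt((post.bn / post.an) * inv_diag)
    if post.spec is not None:
        table = post.spec.coefficient_labels()
    else:
        table = pd.DataFrame(
            {"coefficient": np.arange(post.p), "role": "coefficient",
             "focal_group": None, "competitor_group": None}
        )
    table = table.sort_values("coefficient").reset_index(drop=True)
    table["df"] = 2.0 * post.an
    table["location"] = post.mun[table["coefficient"].to_numpy()]
    table["scale"] = scale[table["coefficient"].to_numpy()]
    table.attrs["sigma2_a"] = post.an
    table.attrs["sigma2_b"] = post.bn
    return table


def rmse(observed, predicted) -> float:
    """Root mean squared error between two equal-length vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ShapeError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 1:
        raise ShapeError("rmse needs at least one observation")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))
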