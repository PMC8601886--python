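"""Synthetic forest plots with known ground truth.

Generates a census pair from a homogeneous Poisson point process so every
pipeline stage — growth computation, buffering, neighborhood construction,
fitting, resampling — can be exercised end to end against a known parameter
vector, with no downloads.

The generator emulates: uniform stem placement over a rectangle, multinomial
species labels, a lognormal DBH size distribution, and growth drawn from the
neighborhood-competition regression (per-group intercepts, dbh slopes, and a
J x K competition matrix acting on summed basal area within the competitive
radius) with Gaussian noise. The second census is *derived* — DBH2 = DBH1 +
growth * dt, with dt computed from the generated ISO dates exactly as the
census stage computes it (days / 365.25) — so growth round-trips bit-exactly
through the census machinery rather than bypassing it.

It does not emulate: clustered or inhibited spatial patterns, habitat
covariates, mortality, recruitment, or measurement error on DBH. Parameter
recovery on these plots therefore demonstrates correctness of the estimator
under the model's own assumptions, not robustness to their violation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace as _replace

import numpy as np
import pandas as pd

from ._seeding import child_rng
from .census import basal_area, compute_growth
from .errors import DomainError, IntegrityError
from .geometry import StudyRegion, add_buffer_flag, assign_folds, make_rectangular_partition
from .model import ModelSpec, PriorSpec, build_design, fit_conjugate, posterior_marginals
from .neighborhoods import FocalTable, create_focal_vs_comp, neighbor_pairs

__all__ = [
    "SyntheticTruth", "simulate_plot", "simulate_growth",
    "simulate_census_pair", "build_synthetic_focal_table",
    "parameter_recovery_report",
]


@dataclass
class SyntheticTruth:
    """Ground-truth scene and regression parameters for one synthetic plot.

    Defaults draw a ~300 x 300 m scene at 0.09 stems/m^2 (~8,000 stems,
    desk-scale analog of a 9-ha ForestGEO subsection), three species with
    uneven abundances, a lognormal DBH distribution with median ~10 cm,
    slightly positive diameter-growth slopes, negative (competitive)
    lambda values on the m^2 basal-area scale, and residual sd 0.1 cm/yr —
    the order of magnitude of observed annual DBH-growth error in temperate
    ForestGEO plots.
    """

    focal_levels: tuple = ("A", "B", "C")
    comp_levels: tuple = ("A", "B", "C")
    beta0: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.15, 0.10]))
    beta_dbh: np.ndarray = field(default_factory=lambda: np.array([0.004, 0.002, 0.006]))
    lam: np.ndarray = field(default_factory=lambda: np.array(
        [[-0.9, -0.3, -0.1],
         [-0.2, -0.7, -0.4],
         [-0.3, -0.2, -0.6]]
    ))
    sigma: float = 0.1                      # residual sd, cm/yr
    extent: tuple = (300.0, 300.0)          # plot side lengths, m
    intensity: float = 0.09                 # stems per m^2
    species_probs: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.3, 0.2]))
    dbh_meanlog: float = 2.3                # lognormal DBH, cm (median ~10 cm)
    dbh_sdlog: float = 0.6
    comp_dist: float = 7.5                  # competitive radius, m
    date1: str = "2008-01-01"
    date2: str = "2014-01-01"
    seed: int = 0

    def __post_init__(self):
        self.beta0 = np.asarray(self.beta0, float)
        self.beta_dbh = np.asarray(self.beta_dbh, float)
        self.lam = np.atleast_2d(np.asarray(self.lam, float))
        self.species_probs = np.asarray(self.species_probs, float)
        J, K = len(self.focal_levels), len(self.comp_levels)
        if self.lam.shape != (J, K):
            raise DomainError(f"lam must be {J}x{K}, got {self.lam.shape}")
        if self.beta0.shape != (J,) or self.beta_dbh.shape != (J,):
            raise DomainError("beta0 and beta_dbh must have one entry per focal level")
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")
        if self.extent[0] <= 0 or self.extent[1] <= 0 or self.intensity <= 0:
            raise DomainError("extent and intensity must be positive")
        if not np.isclose(self.species_probs.sum(), 1.0):
            raise DomainError("species probabilities must sum to 1")

    # --- derived -------------------------------------------------------
    @property
    def J(self) -> int:
        return len(self.focal_levels)

    @property
    def K(self) -> int:
        return len(self.comp_levels)

    @property
    def dt_years(self) -> float:
        days = (pd.Timestamp(self.date2) - pd.Timestamp(self.date1)).days
        return days / 365.25

    def region(self) -> StudyRegion:
        return StudyRegion.rectangle(0.0, 0.0, self.extent[0], self.extent[1])

    def model_spec(self) -> ModelSpec:
        return ModelSpec(tuple(self.focal_levels), tuple(self.comp_levels))

    def coefficient_vector(self) -> np.ndarray:
        """Truth laid out in the model's j-major coefficient order."""
        spec = self.model_spec()
        beta = np.zeros(spec.p)
        for j in range(self.J):
            beta[spec.intercept_col(j)] = self.beta0[j]
            beta[spec.dbh_col(j)] = self.beta_dbh[j]
            for k in range(self.K):
                beta[spec.lambda_col(j, k)] = self.lam[j, k]
        return beta

    @classmethod
    def null_identity(cls, **kw) -> "SyntheticTruth":
        """H0 scene: lambda_jk = lambda_j — competition blind to identity."""
        t = cls(**kw)
        lam_j = t.lam.mean(axis=1)
        t.lam = np.repeat(lam_j[:, None], t.K, axis=1)
        return t

    @classmethod
    def strong_identity(cls, sigma: float = 0.02, **kw) -> "SyntheticTruth":
        """HA scene: strongly species-specific competition, low noise."""
        kw.setdefault("lam", np.array(
            [[-2.0, 0.5, -0.2],
             [0.4, -1.8, 0.6],
             [-0.3, 0.7, -1.5]]
        ))
        return cls(sigma=sigma, **kw)

    def to_json(self) -> str:
        doc = asdict(self)
        for k, v in doc.items():
            if isinstance(v, np.ndarray):
                doc[k] = v.tolist()
        doc["focal_levels"] = list(self.focal_levels)
        doc["comp_levels"] = list(self.comp_levels)
        doc["extent"] = list(self.extent)
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        doc = json.loads(text)
        doc["focal_levels"] = tuple(doc["focal_levels"])
        doc["comp_levels"] = tuple(doc["comp_levels"])
        doc["extent"] = tuple(doc["extent"])
        return cls(**doc)


def simulate_plot(truth: SyntheticTruth, seed: int | None = None) -> pd.DataFrame:
    """One census of stems: Poisson count, uniform locations, multinomial labels.

    Returns the canonical census layout (DBH in cm, ISO date). Deterministic
    under (truth.seed, "plot") unless ``seed`` overrides the root.
    """
    root = truth.seed if seed is None else seed
    rng = child_rng(root, "plot")
    w, h = truth.extent
    n = int(rng.poisson(truth.intensity * w * h))
    gx = rng.uniform(0.0, w, size=n)
    gy = rng.uniform(0.0, h, size=n)
    sp = rng.choice(np.asarray(truth.focal_levels, dtype=object),
                    size=n, p=truth.species_probs)
    dbh = rng.lognormal(truth.dbh_meanlog, truth.dbh_sdlog, size=n)
    return pd.DataFrame(
        {
            "stem_id": [f"s{i:06d}" for i in range(n)],
            "tree_id": [f"t{i:06d}" for i in range(n)],
            "sp": sp.astype(str),
            "gx": gx,
            "gy": gy,
            "dbh": dbh,
            "date": pd.Timestamp(truth.date1),
            "codes": "",
            "alive": True,
        }
    )


def _growth_mean(census: pd.DataFrame, truth: SyntheticTruth) -> np.ndarray:
    """Model-mean growth for every stem, from its own neighborhood sums."""
    level_index = {g: k for k, g in enumerate(truth.comp_levels)}
    coords = census[["gx", "gy"]].to_numpy(float)
    codes = np.array([level_index[s] for s in census["sp"]], dtype=int)
    ba = basal_area(census["dbh"].to_numpy(float))
    n, K = len(census), truth.K
    totals = np.zeros((n, K))
    for i, j in neighbor_pairs(coords, truth.comp_dist):
        totals[i, codes[j]] += ba[j]
        totals[j, codes[i]] += ba[i]
    jidx = np.array([list(truth.focal_levels).index(s) for s in census["sp"]], dtype=int)
    mean = (
        truth.beta0[jidx]
        + truth.beta_dbh[jidx] * census["dbh"].to_numpy(float)
        + np.einsum("nk,nk->n", truth.lam[jidx, :], totals)
    )
    return mean


def simulate_growth(
    focal_table: FocalTable, truth: SyntheticTruth, seed: int | None = None
) -> FocalTable:
    """Fill the growth response of an existing focal table from the model.

    growth = beta0_j + beta_dbh_j * dbh + sum_k lambda_jk * comp_totals_k
    plus Normal(0, sigma^2) noise, seeded. Level sets must match the truth.
    """
    if tuple(focal_table.focal_levels) != tuple(truth.focal_levels) or \
            tuple(focal_table.comp_levels) != tuple(truth.comp_levels):
        raise IntegrityError("focal table level sets do not match the truth")
    root = truth.seed if seed is None else seed
    rng = child_rng(root, "growth")
    jidx = {g: j for j, g in enumerate(truth.focal_levels)}
    records = []
    for r in focal_table.records:
        j = jidx[r.focal_group]
        mean = (truth.beta0[j] + truth.beta_dbh[j] * r.dbh
                + float(truth.lam[j] @ r.comp_totals))
        records.append(_replace(r, growth=mean + rng.normal(0.0, truth.sigma)))
    return _replace(focal_table, records=records)


def simulate_census_pair(
    truth: SyntheticTruth, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two censuses whose implied annual growth follows the model exactly.

    Census 2 copies census 1 with DBH2 = DBH1 + growth * dt, where dt is the
    date difference in days / 365.25 — the same annualization the growth
    stage applies — and growth is the model mean plus Normal(0, sigma) noise.
    DBH2 is floored at zero (a stem cannot shrink below zero; with realistic
    parameters the floor is never hit).
    """
    root = truth.seed if seed is None else seed
    census1 = simulate_plot(truth, seed=root)
    mean = _growth_mean(census1, truth)
    rng = child_rng(root, "growth")
    growth = mean + rng.normal(0.0, truth.sigma, size=len(census1))
    census2 = census1.copy()
    census2["dbh"] = np.maximum(census1["dbh"].to_numpy(float)
                                + growth * truth.dt_years, 0.0)
    census2["date"] = pd.Timestamp(truth.date2)
    return census1, census2


def build_synthetic_focal_table(
    truth: SyntheticTruth,
    seed: int | None = None,
    nx: int = 2,
    ny: int = 2,
):
    """Full pipeline on one synthetic scene: census pair -> focal table.

    Returns (focal_table, partition, growth_table). Buffering, fold
    assignment and neighborhood construction all go through the public
    pipeline stages, so this is an end-to-end exercise of the package, not a
    shortcut.
    """
    census1, census2 = simulate_census_pair(truth, seed=seed)
    growth = compute_growth(census1, census2)
    growth["group"] = pd.Categorical(
        growth["sp"].astype(str), categories=list(truth.focal_levels)
    )
    growth["basal_area"] = basal_area(growth["dbh1"].to_numpy(float))
    region = truth.region()
    growth["buffer"] = add_buffer_flag(growth, region, truth.comp_dist)
    partition = make_rectangular_partition(region, nx, ny)
    growth["fold_id"] = assign_folds(growth, partition)
    table = create_focal_vs_comp(
        growth, comp_dist=truth.comp_dist, comp_x_var="basal_area",
        grouping="group",
    )
    return table, partition, growth


def parameter_recovery_report(
    truth: SyntheticTruth,
    n_target: int,
    reps: int,
    prior: PriorSpec | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bias / RMSE / 95%-interval coverage per coefficient over replicates.

    Each replicate simulates a fresh plot (the extent is rescaled so the
    expected focal count is roughly ``n_target``), runs the full pipeline,
    fits, and records the posterior-mean error and whether the central 95%
    marginal Student-t interval covers the truth.
    """
    from scipy import stats

    if reps < 1:
        raise DomainError("reps must be >= 1")
    root = truth.seed if seed is None else seed
    # interior focal stems are ~80% of all stems at default buffer; oversize a bit
    side = float(np.sqrt(1.3 * n_target / truth.intensity))
    spec = truth.model_spec()
    beta_true = truth.coefficient_vector()
    if prior is None:
        prior = PriorSpec.default(spec.p)

    errors = np.zeros((reps, spec.p))
    covered = np.zeros((reps, spec.p), dtype=bool)
    ns = np.zeros(reps, dtype=int)
    for rep in range(reps):
        rep_truth = SyntheticTruth(**{**_truth_kwargs(truth),
                                      "extent": (side, side),
                                      "seed": int(child_rng(root, "rep", rep)
                                                  .integers(2**31))})
        table, _, _ = build_synthetic_focal_table(rep_truth)
        X, y = build_design(table, spec)
        post = fit_conjugate(X, y, prior, spec=spec)
        marg = posterior_marginals(post)
        loc = marg["location"].to_numpy()
        scale = marg["scale"].to_numpy()
        tq = stats.t.ppf(0.975, df=2.0 * post.an)
        errors[rep] = post.mun - beta_true
        covered[rep] = np.abs(beta_true - loc) <= tq * scale
        ns[rep] = len(table)

    labels = spec.coefficient_labels()
    labels["bias"] = errors.mean(axis=0)
    labels["rmse"] = np.sqrt((errors**2).mean(axis=0))
    labels["coverage"] = covered.mean(axis=0)
    labels.attrs["mean_n"] = float(ns.mean())
    labels.attrs["reps"] = reps
    return labels


def _truth_kwargs(truth: SyntheticTruth) -> dict:
    doc = asdict(truth)
    doc["focal_levels"] = tuple(truth.focal_levels)
    doc["comp_levels"] = tuple(truth.comp_levels)
    doc["extent"] = tuple(truth.extent)
    return doc
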