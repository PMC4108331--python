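"""The LIMITS inference algorithm.

Infers a sparse interaction matrix from an abundance timeseries by fitting,
independently for each focal species *i*, the linearized discrete
Lotka-Volterra regression

    log(x_i(t+1) / x_i(t)) = sum_j c_ij (x_j(t) - xbar_j) + noise,

using forward stepwise variable selection: the self-interaction c_ii is
always in the model, and further covariate species are added greedily, one
per iteration, as long as the candidate that most reduces the held-out
(test-set) mean squared prediction error reduces it by more than a relative
threshold.  The stepwise fit is repeated on many random half/half
train-test partitions of the regression rows and the per-partition estimates
are aggregated by the elementwise MEDIAN, which stabilizes the greedy
selection while preserving exact zeros (classical bagging by the mean would
destroy sparsity).

Relative-abundance input is handled by the same code path: the sum
constraint makes the full design singular, but stepwise selection only ever
inverts sub-designs, and the recovered coefficients are interpretable up to
a common multiplicative constant (the mean total population size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dlv_sim import AbundanceTimeseries

__all__ = [
    "RegressionProblem",
    "LimitsConfig",
    "InferredNetwork",
    "EmptyProblemError",
    "estimate_equilibrium",
    "build_regression",
    "least_squares",
    "forward_stepwise",
    "limits_infer",
]

logger = logging.getLogger(__name__)


class EmptyProblemError(ValueError):
    """No usable transition rows for the focal species."""


@dataclass
class RegressionProblem:
    """Per-focal-species linear regression derived from a timeseries.

    ``design`` is ``(K, M)`` with rows ``(x_1(t) - xbar_1, ..., x_M(t) -
    xbar_M)``; ``response`` is length ``K`` with entries
    ``log(x_i(t+1) / x_i(t))`` for the focal species *i*.  Rows where the
    focal species is zero at *t* or *t+1* are excluded (the log is
    undefined); ``kept_rows`` records the surviving ``(replicate,
    timepoint)`` pairs.
    """

    design: np.ndarray
    response: np.ndarray
    focal_index: int
    kept_rows: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.design.ndim != 2 or self.response.shape != (self.design.shape[0],):
            raise ValueError("design/response shapes inconsistent")
        if not np.all(np.isfinite(self.design)) or not np.all(
            np.isfinite(self.response)
        ):
            raise ValueError("non-finite entries in regression problem")

    @property
    def n_rows(self) -> int:
        return self.design.shape[0]

    @property
    def n_species(self) -> int:
        return self.design.shape[1]


@dataclass
class LimitsConfig:
    """Tunables of the LIMITS fit.

    threshold
        Relative test-error improvement required to accept a covariate
        (0.05 means the test MSE must drop by more than 5%).
    n_bootstrap
        Number of random train/test repartitions aggregated by the median.
    seed
        Seeds all partitioning; identical config + data give identical output.
    max_covariates
        Optional cap on the active-set size (incl. the self-interaction).
    bagged
        If False, a single stepwise fit on the full data (train = test = all
        rows) is returned instead of the median over partitions.
    """

    threshold: float = 0.05
    n_bootstrap: int = 100
    seed: int = 0
    max_covariates: int | None = None
    bagged: bool = True

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class InferredNetwork:
    """Median-aggregated LIMITS estimate of the interaction matrix.

    ``coefficients[i, j]`` estimates the effect of species *j* on species
    *i*; entries never selected are exactly zero.  ``per_bootstrap`` (shape
    ``(n_bootstrap, M, M)``) holds the individual partition estimates.
    """

    coefficients: np.ndarray
    equilibrium_estimate: np.ndarray
    config: LimitsConfig
    labels: list[str] = field(default_factory=list)
    per_bootstrap: np.ndarray | None = None

    @property
    def n_species(self) -> int:
        return self.coefficients.shape[0]


def estimate_equilibrium(ts: AbundanceTimeseries) -> np.ndarray:
    """Equilibrium abundance estimate: per-species median over all samples."""
    if ts.values.size == 0:
        raise ValueError("empty timeseries")
    return np.median(ts.values.reshape(ts.n_species, -1), axis=1)


def build_regression(
    ts: AbundanceTimeseries, focal: int, equilibrium: np.ndarray
) -> RegressionProblem:
    """Assemble the design matrix and response vector for one focal species.

    One candidate row per consecutive timepoint pair within each replicate
    (never across replicate boundaries).  Rows where the focal species is
    zero at either end of the transition are dropped; zero abundances of
    other species are legal covariates (they contribute ``-xbar_j``).
    """
    m, T, R = ts.values.shape
    if not (0 <= focal < m):
        raise ValueError(f"focal index {focal} out of range for {m} species")
    if T < 2:
        raise ValueError("need at least 2 timepoints")
    equilibrium = np.asarray(equilibrium, dtype=float)
    if equilibrium.shape != (m,):
        raise ValueError("equilibrium length must match species count")

    design_blocks, response_blocks, kept = [], [], []
    for r in range(R):
        x = ts.values[:, :, r]  # (M, T)
        xf = x[focal]
        usable = (xf[:-1] > 0) & (xf[1:] > 0)
        t_idx = np.flatnonzero(usable)
        if t_idx.size == 0:
            continue
        design_blocks.append(x[:, t_idx].T - equilibrium)
        response_blocks.append(np.log(xf[t_idx + 1] / xf[t_idx]))
        kept.extend((r, int(t)) for t in t_idx)
    if not design_blocks:
        raise EmptyProblemError(
            f"no usable transitions for focal species {focal} "
            "(zero abundance at every transition)"
        )
    return RegressionProblem(
        design=np.concatenate(design_blocks),
        response=np.concatenate(response_blocks),
        focal_index=focal,
        kept_rows=kept,
    )


def least_squares(problem: RegressionProblem, active) -> np.ndarray:
    """Minimum-norm least-squares fit restricted to the active columns.

    Uses the SVD pseudo-inverse, so rank-deficient (e.g. duplicated-column)
    sub-designs yield the finite minimum-norm solution.  Returns a full
    length-``M`` coefficient row with inactive entries exactly 0.
    """
    active = list(active)
    if not active:
        raise ValueError("active set must be nonempty")
    coef, *_ = np.linalg.lstsq(problem.design[:, active], problem.response, rcond=None)
    row = np.zeros(problem.n_species)
    row[active] = coef
    return row


def _gram(design: np.ndarray, response: np.ndarray, rows: np.ndarray):
    x = design[rows]
    y = response[rows]
    return x.T @ x, x.T @ y, float(y @ y), len(rows)


def _solve_gram(g: np.ndarray, b: np.ndarray, active: list[int]) -> np.ndarray:
    ix = np.ix_(active, active)
    # pinv(X'X) X'y == pinv(X) y, so this matches the pseudo-inverse fit
    # (minimum-norm) even when the sub-design is rank deficient.
    coef, *_ = np.linalg.lstsq(g[ix], b[active], rcond=None)
    return coef


def _test_mse(
    coef: np.ndarray, active: list[int], g: np.ndarray, b: np.ndarray, yy: float, n: int
) -> float:
    ix = np.ix_(active, active)
    mse = (yy - 2.0 * coef @ b[active] + coef @ g[ix] @ coef) / n
    return max(mse, 0.0)  # guard tiny negative round-off


def forward_stepwise(
    problem: RegressionProblem,
    train_rows,
    test_rows,
    threshold: float,
    max_covariates: int | None = None,
) -> np.ndarray:
    """Greedy forward variable selection for one focal species.

    The active set starts as ``{focal}``.  Each iteration fits every
    single-candidate extension on the training rows, scores it by test-set
    MSE, picks the best candidate (ties broken by lowest species index), and
    accepts it iff ``(E_old - E_new) / E_old > threshold``; otherwise the
    loop terminates.  Returns the last accepted coefficient row (inactive
    entries exactly 0).
    """
    train_rows = np.asarray(list(train_rows), dtype=int)
    test_rows = np.asarray(list(test_rows), dtype=int)
    if train_rows.size == 0 or test_rows.size == 0:
        raise ValueError("train and test row sets must be nonempty")
    if np.intersect1d(train_rows, test_rows).size and not np.array_equal(
        np.sort(train_rows), np.sort(test_rows)
    ):
        raise ValueError("train and test row sets must be disjoint")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")

    g_tr, b_tr, _, _ = _gram(problem.design, problem.response, train_rows)
    g_te, b_te, yy_te, n_te = _gram(problem.design, problem.response, test_rows)

    m = problem.n_species
    active = [problem.focal_index]
    inactive = [j for j in range(m) if j != problem.focal_index]
    coef = _solve_gram(g_tr, b_tr, active)
    e_old = _test_mse(coef, active, g_te, b_te, yy_te, n_te)
    cap = max_covariates if max_covariates is not None else m
    # an MSE at round-off scale relative to the response is a perfect fit;
    # relative improvements below this floor are numerically meaningless
    e_floor = 1e-12 * (yy_te / n_te)

    while inactive and len(active) < cap and e_old > e_floor:
        best_j, best_e, best_coef = None, np.inf, None
        for j in inactive:  # ascending index -> deterministic tie-break
            cand = active + [j]
            c = _solve_gram(g_tr, b_tr, cand)
            e = _test_mse(c, cand, g_te, b_te, yy_te, n_te)
            if e < best_e:
                best_j, best_e, best_coef = j, e, c
        if best_j is None or (e_old - best_e) / e_old <= threshold:
            break
        active.append(best_j)
        inactive.remove(best_j)
        coef, e_old = best_coef, best_e

    row = np.zeros(m)
    row[active] = coef
    return row


def limits_infer(ts: AbundanceTimeseries, config: LimitsConfig) -> InferredNetwork:
    """Run LIMITS on a timeseries: stepwise fits bagged by the median.

    For each focal species the usable transition rows are repeatedly split
    into random halves (training gets the extra row on odd counts), forward
    stepwise selection is run on each partition, and the resulting sparse
    coefficient rows are aggregated entrywise by the median.  Works
    identically for absolute and relative abundances (relative coefficients
    are defined up to a common multiplicative constant).

    Species with fewer than 2 usable transitions get an all-zero row and a
    logged warning rather than an error.
    """
    m = ts.n_species
    rng = np.random.default_rng(config.seed)
    xbar = estimate_equilibrium(ts)
    n_fits = config.n_bootstrap if config.bagged else 1
    per_bootstrap = np.zeros((n_fits, m, m))

    for i in range(m):
        try:
            problem = build_regression(ts, i, xbar)
        except EmptyProblemError:
            logger.warning("species %s: no usable transitions; row left at zero", i)
            continue
        k = problem.n_rows
        if k < 2:
            logger.warning(
                "species %s: only %d usable transition(s); row left at zero", i, k
            )
            continue
        if k < 5 * m:
            logger.warning(
                "species %s: %d usable transitions < 5*M = %d; "
                "estimates may be unreliable",
                i, k, 5 * m,
            )
        if not config.bagged:
            rows = np.arange(k)
            per_bootstrap[0, i] = forward_stepwise(
                problem, rows, rows, config.threshold, config.max_covariates
            )
            continue
        n_train = k - k // 2  # odd counts: extra row to training
        for b in range(config.n_bootstrap):
            perm = rng.permutation(k)
            per_bootstrap[b, i] = forward_stepwise(
                problem,
                perm[:n_train],
                perm[n_train:],
                config.threshold,
                config.max_covariates,
            )

    coefficients = np.median(per_bootstrap, axis=0)
    return InferredNetwork(
        coefficients=coefficients,
        equilibrium_estimate=xbar,
        config=config,
        labels=list(ts.labels),
        per_bootstrap=per_bootstrap,
    )
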