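"""Evaluation of inferred interaction networks.

Topology metrics (sensitivity / specificity / sign errors against a known
truth), parameter-recovery R², abundance correlation matrices, the
stationary covariance of the linearized community dynamics (which shows why
abundance correlations are poor proxies for interactions), and keystone
identification by out-degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dlv_sim import InteractionMatrix, AbundanceTimeseries, dlv_jacobian
from .limits_core import InferredNetwork

__all__ = [
    "TopologyMetrics",
    "RecoveryScore",
    "topology_metrics",
    "recovery_r2",
    "correlation_matrix",
    "linearized_covariance",
    "process_noise_covariance",
    "out_degree_ranking",
]


@dataclass
class TopologyMetrics:
    """Confusion summary over the M(M-1) ordered off-diagonal species pairs.

    ``sensitivity``: fraction of truly interacting pairs detected;
    ``specificity``: fraction of truly non-interacting pairs correctly left
    out; ``sign_error_rate``: fraction of true edges that were detected but
    with the wrong sign.  ``sensitivity`` and ``sign_error_rate`` are NaN
    when there are no true edges.
    """

    sensitivity: float
    specificity: float
    sign_error_rate: float
    n_true_edges: int
    n_true_nonedges: int


@dataclass
class RecoveryScore:
    """Agreement between true and inferred coefficient matrices.

    ``r_squared`` is the squared Pearson correlation over all M² vectorized
    entries (NaN if the inferred matrix is constant); ``scale`` is the slope
    of the no-intercept least-squares fit of true on inferred, absorbing the
    arbitrary multiplicative constant of relative-abundance fits.
    """

    r_squared: float
    scale: float


def _coef(x) -> np.ndarray:
    if isinstance(x, (InteractionMatrix, InferredNetwork)):
        return np.asarray(x.coefficients, dtype=float)
    return np.asarray(x, dtype=float)


def topology_metrics(true_model, inferred, zero_tol: float = 1e-12) -> TopologyMetrics:
    """Sensitivity, specificity and sign-error rate of the inferred topology.

    Only off-diagonal entries are scored; an ordered pair counts as
    interacting iff ``|c| > zero_tol``.  Stepwise exclusion produces exact
    structural zeros, so the tolerance only guards float noise introduced by
    median aggregation.
    """
    ct = _coef(true_model)
    ci = _coef(inferred)
    if ct.shape != ci.shape:
        raise ValueError("matrix dimensions do not match")
    off = ~np.eye(ct.shape[0], dtype=bool)
    true_edge = np.abs(ct[off]) > zero_tol
    pred_edge = np.abs(ci[off]) > zero_tol

    n_edges = int(true_edge.sum())
    n_nonedges = int((~true_edge).sum())
    tp = int((true_edge & pred_edge).sum())
    tn = int((~true_edge & ~pred_edge).sum())

    sensitivity = tp / n_edges if n_edges else float("nan")
    specificity = tn / n_nonedges if n_nonedges else float("nan")
    if n_edges:
        wrong_sign = true_edge & pred_edge & (np.sign(ct[off]) != np.sign(ci[off]))
        sign_error_rate = int(wrong_sign.sum()) / n_edges
    else:
        sign_error_rate = float("nan")
    return TopologyMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        sign_error_rate=sign_error_rate,
        n_true_edges=n_edges,
        n_true_nonedges=n_nonedges,
    )


def recovery_r2(true_model, inferred) -> RecoveryScore:
    """Squared Pearson correlation between vectorized coefficient matrices."""
    ct = _coef(true_model).ravel()
    ci = _coef(inferred).ravel()
    if ct.shape != ci.shape:
        raise ValueError("matrix dimensions do not match")
    if np.ptp(ci) == 0 or np.ptp(ct) == 0:
        return RecoveryScore(r_squared=float("nan"), scale=float("nan"))
    r = np.corrcoef(ct, ci)[0, 1]
    denom = ci @ ci
    scale = float(ct @ ci / denom) if denom > 0 else float("nan")
    return RecoveryScore(r_squared=float(r**2), scale=scale)


def correlation_matrix(ts: AbundanceTimeseries) -> np.ndarray:
    """Pearson correlations of species trajectories pooled over time and
    replicates.

    Symmetric with unit diagonal; rows/columns of zero-variance species are
    NaN (flagged missing) rather than an arbitrary number.
    """
    flat = ts.values.reshape(ts.n_species, -1)
    if flat.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(flat)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    zero_var = flat.std(axis=1) == 0
    corr[zero_var, :] = np.nan
    corr[:, zero_var] = np.nan
    return corr


def process_noise_covariance(model: InteractionMatrix, sigma_process: float) -> np.ndarray:
    """Noise covariance of the linearized dynamics implied by the dLV model.

    Linearizing ``x_i exp(eta_i)`` around equilibrium turns the log-scale
    process noise into additive noise ``xbar_i * eta_i``, so the covariance
    is ``diag((xbar_i * sigma)^2)``.
    """
    return np.diag((model.equilibrium * sigma_process) ** 2)


def linearized_covariance(model: InteractionMatrix, noise_cov: np.ndarray) -> np.ndarray:
    """Stationary covariance of abundances under the linearized dynamics.

    Near equilibrium the deviations u = x - xbar follow the first-order
    vector autoregression ``u(t+1) = J u(t) + xi`` with
    ``J = I + diag(xbar) C``.  The stationary covariance solves the discrete
    Lyapunov equation ``Cov = J Cov J' + Sigma_xi``, computed here through
    the vectorization identity ``vec(Cov) = (I - J (x) J)^{-1} vec(Sigma_xi)``
    where ``(x)`` is the Kronecker product.

    Raises for an unstable model (no stationary covariance exists).
    """
    j = dlv_jacobian(model)
    m = j.shape[0]
    noise_cov = np.asarray(noise_cov, dtype=float)
    if noise_cov.shape != (m, m):
        raise ValueError("noise covariance shape must match the model")
    if not np.allclose(noise_cov, noise_cov.T, atol=1e-10):
        raise ValueError("noise covariance must be symmetric")
    radius = np.max(np.abs(np.linalg.eigvals(j)))
    if radius >= 1.0:
        raise ValueError(
            f"model is not stable (spectral radius {radius:.4f} >= 1); "
            "stationary covariance does not exist"
        )
    vec = np.linalg.solve(np.eye(m * m) - np.kron(j, j), noise_cov.ravel())
    cov = vec.reshape(m, m)
    return (cov + cov.T) / 2.0  # symmetrize round-off


def out_degree_ranking(inferred) -> tuple[list[tuple[str, int]], float]:
    """Rank species by out-degree (number of species they act on).

    The out-degree of species *j* is the count of nonzero ``c_ij`` over
    ``i != j`` — the edges j → i under the convention that ``c_ij`` is the
    effect of *j* on *i*.  Returns the list sorted by descending degree
    (ties by species index) together with the median out-degree, the
    baseline against which a keystone species stands out.
    """
    c = _coef(inferred)
    labels = getattr(inferred, "labels", None) or [f"sp{i}" for i in range(c.shape[0])]
    off = c.copy()
    np.fill_diagonal(off, 0.0)
    degrees = (off != 0).sum(axis=0)  # column j: edges j -> i
    order = sorted(range(len(degrees)), key=lambda j: (-degrees[j], j))
    ranking = [(labels[j], int(degrees[j])) for j in order]
    return ranking, float(np.median(degrees))
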