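"""Stochastic discrete-time Lotka-Volterra (Ricker) community simulation.

The generative model for a community of ``M`` species is the discrete-time
Lotka-Volterra map

.. math::

    x_i(t+1) = x_i(t) \\exp\\Big(\\sum_j c_{ij}\\,(x_j(t) - \\bar x_j)
               + \\eta_i(t)\\Big),

where ``c_ij`` is the effect of species *j* on the per-capita log-growth of
species *i*, ``xbar_j`` is the equilibrium (carrying-capacity) abundance of
species *j*, and ``eta_i(t) ~ Normal(0, sigma_process**2)`` is log-normal
multiplicative environmental noise.  The timestep is fixed to 1 (time is
measured in sampling intervals).

This module provides the simulator, a rejection-sampling generator of random
sparse stable interaction matrices, conversion of absolute abundances to
relative (compositional) abundances, and multiplicative measurement noise
emulating sequencing / OTU-assignment error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InteractionMatrix",
    "AbundanceTimeseries",
    "NoiseSpec",
    "GeneratorParams",
    "InstabilityError",
    "GenerationFailureError",
    "simulate",
    "to_relative",
    "add_measurement_noise",
    "generate_random_interactions",
    "check_stability",
    "dlv_jacobian",
]


class InstabilityError(RuntimeError):
    """The simulated trajectory diverged (non-finite state reached)."""


class GenerationFailureError(RuntimeError):
    """A stable random interaction matrix could not be generated."""


def _default_labels(m: int) -> list[str]:
    return [f"sp{i}" for i in range(m)]


@dataclass
class InteractionMatrix:
    """True or inferred interaction coefficients with equilibrium abundances.

    Attributes
    ----------
    coefficients
        ``(M, M)`` array; ``coefficients[i, j]`` is the effect of species *j*
        on the per-capita log-growth of species *i* (units:
        1/(abundance * timestep)).  Positive means *j* benefits *i*.
    equilibrium
        Length-``M`` strictly positive vector of carrying-capacity abundances.
    labels
        Species identifiers, length ``M``.
    """

    coefficients: np.ndarray
    equilibrium: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.equilibrium = np.asarray(self.equilibrium, dtype=float)
        if self.coefficients.ndim != 2 or (
            self.coefficients.shape[0] != self.coefficients.shape[1]
        ):
            raise ValueError("coefficients must be a square matrix")
        if self.equilibrium.shape != (self.coefficients.shape[0],):
            raise ValueError("equilibrium length must match coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if not np.all(np.isfinite(self.equilibrium)) or np.any(
            self.equilibrium <= 0
        ):
            raise ValueError("equilibrium abundances must be positive and finite")
        if not self.labels:
            self.labels = _default_labels(self.n_species)
        if len(self.labels) != self.n_species:
            raise ValueError("labels length must match matrix size")

    @property
    def n_species(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class AbundanceTimeseries:
    """Species x time x replicate abundance array.

    ``values`` has shape ``(M, T, R)``; ``kind`` is ``"absolute"`` or
    ``"relative"``.  For relative data every (timepoint, replicate) column
    sums to 1.  ``dt`` is the sampling interval (fixed to 1 by the model).
    """

    values: np.ndarray
    kind: str = "absolute"
    dt: float = 1.0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single replicate convenience
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must have shape (species, time, replicate)")
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"kind must be 'absolute' or 'relative', got {self.kind!r}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("abundances must be finite and nonnegative")
        if self.kind == "relative":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative abundance columns must sum to 1")
        if not self.labels:
            self.labels = _default_labels(self.n_species)
        if len(self.labels) != self.n_species:
            raise ValueError("labels length must match species count")

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]


@dataclass
class NoiseSpec:
    """Log-scale standard deviations of the two multiplicative noise sources.

    ``sigma_process`` enters the dynamics at every step (environmental
    stochasticity); ``sigma_measurement`` corrupts the observed values only
    (sequencing and OTU-assignment error).
    """

    sigma_process: float = 0.05
    sigma_measurement: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_process < 0 or self.sigma_measurement < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class GeneratorParams:
    """Tunables of the random interaction-matrix generator.

    Equilibria are log-normal with the given median and log-scale spread;
    self-limitation terms are drawn uniformly on
    ``[diag_low, diag_high] / xbar_i`` (guaranteeing each isolated
    single-species map is stable); off-diagonal couplings are drawn uniformly
    on ``[-offdiag_scale, offdiag_scale] / xbar_j`` and kept only if the full
    system stays stable.
    """

    equilibrium_median: float = 1.0
    equilibrium_sigma: float = 0.5
    diag_low: float = -1.5
    diag_high: float = -0.5
    offdiag_scale: float = 0.5
    max_attempts_per_edge: int = 100

    def __post_init__(self) -> None:
        if self.equilibrium_median <= 0 or self.equilibrium_sigma < 0:
            raise ValueError("equilibrium distribution parameters invalid")
        if not (self.diag_low <= self.diag_high < 0):
            raise ValueError("diagonal interval must be negative")
        if self.offdiag_scale <= 0 or self.max_attempts_per_edge < 1:
            raise ValueError("invalid generator parameters")


def dlv_jacobian(model: InteractionMatrix) -> np.ndarray:
    """Jacobian of the noiseless map at equilibrium: J = I + diag(xbar) @ C."""
    m = model.n_species
    return np.eye(m) + model.equilibrium[:, None] * model.coefficients


def check_stability(model: InteractionMatrix) -> bool:
    """Linear stability of the equilibrium of the noiseless discrete map.

    Returns True iff the spectral radius of ``J = I + diag(xbar) C`` is
    strictly below 1; a marginal system (radius exactly 1, e.g. ``C = 0``)
    counts as unstable.
    """
    radius = np.max(np.abs(np.linalg.eigvals(dlv_jacobian(model))))
    return bool(radius < 1.0)


def simulate(
    model: InteractionMatrix,
    T: int,
    R: int = 1,
    noise: NoiseSpec | None = None,
    initial: np.ndarray | str = "perturbed-equilibrium",
    seed: int | np.random.Generator | None = None,
) -> AbundanceTimeseries:
    """Simulate the stochastic discrete-time Lotka-Volterra map.

    Parameters
    ----------
    model
        Interaction coefficients and equilibrium abundances.
    T
        Number of timepoints per replicate (>= 2).
    R
        Number of replicates (independent initial conditions).
    noise
        Noise specification; only ``sigma_process`` is used here (apply
        measurement noise afterwards with :func:`add_measurement_noise`).
    initial
        Either an ``(M, R)`` array of strictly positive initial abundances or
        the string ``"perturbed-equilibrium"``, which draws
        ``xbar_i * exp(Uniform(-0.5, 0.5))`` independently per species and
        replicate.
    seed
        Seed or Generator; the output is deterministic given the seed.

    Returns
    -------
    AbundanceTimeseries
        Absolute abundances of shape ``(M, T, R)``, all strictly positive.

    Raises
    ------
    ValueError
        For nonpositive initial abundances or ``T < 2`` / ``R < 1``.
    InstabilityError
        If the state becomes non-finite (unstable system), naming the step.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if R < 1:
        raise ValueError("R must be >= 1")
    noise = noise if noise is not None else NoiseSpec()
    rng = np.random.default_rng(seed)
    m = model.n_species
    xbar = model.equilibrium
    c = model.coefficients

    if isinstance(initial, str):
        if initial != "perturbed-equilibrium":
            raise ValueError(f"unknown initial condition spec {initial!r}")
        x0 = xbar[:, None] * np.exp(rng.uniform(-0.5, 0.5, size=(m, R)))
    else:
        x0 = np.asarray(initial, dtype=float)
        if x0.shape == (m,):
            x0 = np.repeat(x0[:, None], R, axis=1)
        if x0.shape != (m, R):
            raise ValueError(f"initial must have shape ({m}, {R})")
        if np.any(x0 <= 0) or not np.all(np.isfinite(x0)):
            raise ValueError("initial abundances must be strictly positive")

    values = np.empty((m, T, R))
    values[:, 0, :] = x0
    x = x0.copy()
    for t in range(T - 1):
        growth = c @ (x - xbar[:, None])  # (M, R)
        if noise.sigma_process > 0:
            growth = growth + rng.normal(0.0, noise.sigma_process, size=(m, R))
        x = x * np.exp(growth)
        if not np.all(np.isfinite(x)):
            raise InstabilityError(
                f"non-finite abundance at timestep {t + 1}: the interaction "
                "matrix is unstable at this state"
            )
        values[:, t + 1, :] = x

    return AbundanceTimeseries(values=values, kind="absolute", labels=list(model.labels))


def to_relative(ts: AbundanceTimeseries) -> AbundanceTimeseries:
    """Convert absolute abundances to relative abundances y_i = x_i / N.

    Each (timepoint, replicate) column is divided by its total; zero entries
    remain zero.  Raises if the input is already relative or any column sums
    to zero.
    """
    if ts.kind != "absolute":
        raise ValueError("input timeseries is already relative")
    totals = ts.values.sum(axis=0)  # (T, R)
    if np.any(totals <= 0):
        t, r = np.argwhere(totals <= 0)[0]
        raise ValueError(f"all-zero abundance column at timepoint {t}, replicate {r}")
    return AbundanceTimeseries(
        values=ts.values / totals[None, :, :],
        kind="relative",
        dt=ts.dt,
        labels=list(ts.labels),
    )


def add_measurement_noise(
    ts: AbundanceTimeseries,
    sigma_measurement: float,
    seed: int | np.random.Generator | None = None,
) -> AbundanceTimeseries:
    """Corrupt observations with multiplicative log-normal measurement noise.

    Each value becomes ``x * exp(eps)`` with
    ``eps ~ Normal(0, sigma_measurement**2)`` drawn independently per entry;
    zeros stay zero.  Relative-abundance columns are renormalized to sum to 1
    afterwards, since sequencing counts are compositional by construction.
    """
    if sigma_measurement < 0:
        raise ValueError("sigma_measurement must be >= 0")
    if sigma_measurement == 0:
        return dataclasses.replace(ts, values=ts.values.copy())
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma_measurement, size=ts.values.shape)
    noisy = ts.values * np.exp(eps)
    if ts.kind == "relative":
        totals = noisy.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("measurement noise produced an all-zero column")
        noisy = noisy / totals[None, :, :]
    return AbundanceTimeseries(values=noisy, kind=ts.kind, dt=ts.dt, labels=list(ts.labels))


def generate_random_interactions(
    M: int,
    n_offdiag: int | None = None,
    seed: int | np.random.Generator | None = None,
    params: GeneratorParams | None = None,
) -> InteractionMatrix:
    """Generate a random sparse stable interaction matrix.

    Equilibrium abundances are drawn log-normally; diagonal (self-limitation)
    entries are drawn so each isolated single-species map is stable; exactly
    ``n_offdiag`` off-diagonal couplings (default ``2 * M``) are then added
    one at a time, each kept only if the full system remains stable
    (spectral radius of the map Jacobian < 1).

    Raises
    ------
    GenerationFailureError
        If a stable configuration cannot be found within
        ``params.max_attempts_per_edge * n_offdiag`` rejected draws.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if n_offdiag is None:
        n_offdiag = min(2 * M, M * (M - 1))
    if not (0 <= n_offdiag <= M * (M - 1)):
        raise ValueError(f"n_offdiag must be in [0, {M * (M - 1)}]")
    params = params if params is not None else GeneratorParams()
    rng = np.random.default_rng(seed)

    xbar = params.equilibrium_median * np.exp(
        rng.normal(0.0, params.equilibrium_sigma, size=M)
    )
    c = np.zeros((M, M))
    c[np.diag_indices(M)] = rng.uniform(params.diag_low, params.diag_high, size=M) / xbar

    model = InteractionMatrix(coefficients=c.copy(), equilibrium=xbar)
    if n_offdiag == 0:
        return model

    max_attempts = params.max_attempts_per_edge * n_offdiag
    attempts = 0
    added = 0
    while added < n_offdiag:
        if attempts >= max_attempts:
            raise GenerationFailureError(
                f"could not place {n_offdiag} stable off-diagonal interactions "
                f"in {max_attempts} attempts (placed {added})"
            )
        attempts += 1
        i = int(rng.integers(M))
        j = int(rng.integers(M))
        if i == j or c[i, j] != 0.0:
            continue
        value = rng.uniform(-params.offdiag_scale, params.offdiag_scale) / xbar[j]
        c[i, j] = value
        if check_stability(InteractionMatrix(coefficients=c.copy(), equilibrium=xbar)):
            added += 1
        else:
            c[i, j] = 0.0

    return InteractionMatrix(coefficients=c, equilibrium=xbar)
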