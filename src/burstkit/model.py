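"""Telegraph-model state spaces and exact steady-state mRNA distributions.

A gene is modelled as a continuous-time Markov chain over a small number of
promoter states (at most one of which is transcriptionally active) coupled to
a birth-death process for the mRNA copy number.  In the classic two-state
telegraph model the promoter switches OFF -> ON at rate ``k_on`` and
ON -> OFF at rate ``k_off``; mRNA is ejected at rate ``k_eject`` while ON and
degrades first-order at rate ``k_decay``.  The stationary mRNA distribution
is obtained by truncating the chemical master equation (CME) at a copy
number ``N`` where essentially no probability mass remains and solving for
the null space of the finite generator.

For the two-state model the stationary law has the closed Beta-Poisson form
(a Poisson distribution whose intensity is ``nu * lambda`` with
``lambda ~ Beta(alpha, beta)``, where ``alpha = k_on/k_decay``,
``beta = k_off/k_decay`` and ``nu = k_eject/k_decay``).  That closed form is
kept here as an independent cross-check of the CME route, evaluated by
adaptive quadrature.

Technical capture loss (the scRNA-seq "yield") acts as binomial thinning of
the true counts; for any generalized telegraph model thinning by ``p`` is
exactly equivalent to rescaling the eject rate ``nu -> p * nu``, so capture
loss never has to be modelled explicitly during fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.integrate
import scipy.linalg
import scipy.sparse
from scipy.integrate import quad
from scipy.special import betaln, gammaln
from scipy.stats import binom as _binom

__all__ = [
    "ModelSpec",
    "RateParameters",
    "SteadyStateDistribution",
    "TruncationError",
    "DegenerateNullSpaceError",
    "build_generator",
    "steady_state",
    "beta_poisson_pmf",
    "beta_poisson_distribution",
    "distribution_moments",
    "thin_distribution",
    "convolve_alleles",
    "switching_stationary",
    "n_free_rates",
]

#: hard cap on the adaptive mRNA-count truncation
MAX_TRUNCATION = 10_000
#: stationary mass allowed beyond the truncation boundary
TAIL_TOLERANCE = 1e-8


class TruncationError(RuntimeError):
    """The stationary distribution is not concentrated below the truncation cap."""


class DegenerateNullSpaceError(RuntimeError):
    """The truncated generator does not have a one-dimensional null space."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of a generalized telegraph model.

    Parameters
    ----------
    n_states
        Number of promoter states (1, 2 or 3).  The *last* state is the sole
        active state from which mRNA is ejected; the two-state model is one
        OFF plus one ON state, the three-state model has two OFF states in a
        serial reversible chain OFF1 <-> OFF2 <-> ON.
    n_alleles
        Independent gene copies contributing to the cellular count (default 2).
    capture_yield
        Probability ``p`` in (0, 1] that an individual mRNA molecule is
        observed (the technical yield of the protocol).
    truncation
        Optional fixed mRNA-count cutoff ``N``; ``None`` selects it
        adaptively from the model moments.
    """

    n_states: int = 2
    n_alleles: int = 2
    capture_yield: float = 1.0
    truncation: int | None = None

    def __post_init__(self) -> None:
        if self.n_states not in (1, 2, 3):
            raise ValueError(f"n_states must be 1, 2 or 3, got {self.n_states}")
        if self.n_alleles < 1:
            raise ValueError("n_alleles must be >= 1")
        if not (0.0 < self.capture_yield <= 1.0):
            raise ValueError("capture_yield must lie in (0, 1]")
        if self.truncation is not None and self.truncation < 1:
            raise ValueError("truncation must be a positive integer")


def n_free_rates(n_states: int) -> int:
    """Number of free kinetic rates (decay excluded): 1, 3 or 5."""
    return {1: 1, 2: 3, 3: 5}[n_states]


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rates of one gene, in reciprocal minutes.

    ``state_rates`` lists the promoter switching rates:

    * 1-state: empty;
    * 2-state: ``(k_on, k_off)``;
    * 3-state: ``(f1, b1, f2, b2)`` for OFF1 -f1-> OFF2 -f2-> ON with
      backward rates ``b1`` (OFF2 -> OFF1) and ``b2`` (ON -> OFF2).

    ``k_eject`` is the mRNA creation rate in the active state and
    ``k_decay`` the first-order degradation rate fixed from a measured
    half-life (``k_decay = ln 2 / half_life``).
    """

    state_rates: tuple[float, ...]
    k_eject: float
    k_decay: float

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.state_rates)
        object.__setattr__(self, "state_rates", rates)
        for r in rates + (self.k_eject, self.k_decay):
            if not math.isfinite(r) or r < 0:
                raise ValueError("rates must be finite and nonnegative")
        if self.k_decay <= 0:
            raise ValueError("k_decay must be strictly positive")
        if len(rates) not in (0, 2, 4):
            raise ValueError("state_rates must have length 0, 2 or 4")

    # -- two-state accessors -------------------------------------------------
    @property
    def k_on(self) -> float:
        if len(self.state_rates) != 2:
            raise AttributeError("k_on is defined for the two-state model only")
        return self.state_rates[0]

    @property
    def k_off(self) -> float:
        if len(self.state_rates) != 2:
            raise AttributeError("k_off is defined for the two-state model only")
        return self.state_rates[1]

    @property
    def off_time(self) -> float:
        """Mean OFF duration 1/k_on in minutes (burst frequency inverse)."""
        return 1.0 / self.k_on

    @property
    def burst_size(self) -> float:
        """Mean mRNA produced per ON period, k_eject / k_off."""
        return self.k_eject / self.k_off

    # -- decay-scaled (dimensionless) parameters ----------------------------
    @property
    def alpha(self) -> float:
        return self.k_on / self.k_decay

    @property
    def beta(self) -> float:
        return self.k_off / self.k_decay

    @property
    def nu(self) -> float:
        return self.k_eject / self.k_decay

    @property
    def exit_rate_from_on(self) -> float:
        """Rate of leaving the active state (k_off, or b2 for three states)."""
        if not self.state_rates:
            raise AttributeError("the one-state model never leaves ON")
        return self.state_rates[-1]

    @staticmethod
    def two_state(k_on: float, k_off: float, k_eject: float, k_decay: float) -> "RateParameters":
        return RateParameters((k_on, k_off), k_eject, k_decay)

    @staticmethod
    def one_state(k_eject: float, k_decay: float) -> "RateParameters":
        return RateParameters((), k_eject, k_decay)

    def with_yield(self, p: float) -> "RateParameters":
        """Rates with the eject rate rescaled by a capture probability."""
        return replace(self, k_eject=self.k_eject * p)


@dataclass
class SteadyStateDistribution:
    """Truncated probability mass function over mRNA counts 0..N."""

    probs: np.ndarray
    truncation: int = field(default=-1)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or self.probs.size < 1:
            raise ValueError("probs must be a nonempty 1-D array")
        if np.any(self.probs < -1e-10):
            raise ValueError("negative probability mass")
        self.probs = np.clip(self.probs, 0.0, None)
        total = self.probs.sum()
        if not (abs(total - 1.0) <= 1e-6):
            raise ValueError(f"probabilities sum to {total!r}, expected 1")
        self.probs = self.probs / total
        if self.truncation < 0:
            self.truncation = self.probs.size - 1

    def pmf(self, m) -> np.ndarray:
        """Probability of counts ``m`` (zero beyond the truncation)."""
        m = np.asarray(m, dtype=int)
        out = np.zeros(m.shape, dtype=float)
        inside = (m >= 0) & (m <= self.truncation)
        out[inside] = self.probs[m[inside]]
        return out

    def to_tsv(self, path) -> None:
        """Serialize as a two-column (count, probability) TSV."""
        with open(path, "w") as fh:
            fh.write("count\tprobability\n")
            for m, p in enumerate(self.probs):
                fh.write(f"{m}\t{p:.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "SteadyStateDistribution":
        counts, probs = [], []
        with open(path) as fh:
            next(fh)
            for line in fh:
                m, p = line.split("\t")
                counts.append(int(m))
                probs.append(float(p))
        if counts != list(range(len(counts))):
            raise ValueError(f"{path}: counts must enumerate 0..N")
        return cls(np.asarray(probs))

    @property
    def mean(self) -> float:
        return float(np.arange(self.probs.size) @ self.probs)

    @property
    def variance(self) -> float:
        m = np.arange(self.probs.size)
        mu = float(m @ self.probs)
        return float((m * m) @ self.probs - mu * mu)


# ---------------------------------------------------------------------------
# generator construction
# ---------------------------------------------------------------------------

def _switching_rate_matrix(n_states: int, state_rates: tuple[float, ...]) -> np.ndarray:
    """Promoter switching generator Q (column convention: Q[i, j] = rate j->i)."""
    Q = np.zeros((n_states, n_states))
    if n_states == 1:
        return Q
    if n_states == 2:
        k_on, k_off = state_rates
        Q[1, 0] = k_on
        Q[0, 1] = k_off
    else:
        f1, b1, f2, b2 = state_rates
        Q[1, 0] = f1
        Q[0, 1] = b1
        Q[2, 1] = f2
        Q[1, 2] = b2
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n_states)] = -Q.sum(axis=0)
    return Q


def switching_stationary(n_states: int, state_rates: tuple[float, ...]) -> np.ndarray:
    """Stationary distribution of the promoter switching chain alone."""
    if n_states == 1:
        return np.array([1.0])
    if n_states == 2:
        k_on, k_off = state_rates
        tot = k_on + k_off
        if tot == 0:
            return np.array([0.5, 0.5])
        return np.array([k_off, k_on]) / tot
    f1, b1, f2, b2 = state_rates
    # detailed balance along the serial chain
    w = np.array([b1 * b2, f1 * b2, f1 * f2], dtype=float)
    if w.sum() == 0:
        return np.full(3, 1.0 / 3.0)
    return w / w.sum()


def _validate_rates(spec: ModelSpec, rates: RateParameters) -> None:
    expected = {1: 0, 2: 2, 3: 4}[spec.n_states]
    if len(rates.state_rates) != expected:
        raise ValueError(
            f"{spec.n_states}-state model requires {expected} switching rates, "
            f"got {len(rates.state_rates)}"
        )


def build_generator(spec: ModelSpec, rates: RateParameters) -> scipy.sparse.csc_matrix:
    """Sparse CME generator over the joint (promoter state, mRNA count) space.

    The joint index is ``m * n_states + s`` (count-major).  Column ``j`` holds
    the outflow of state ``j``: off-diagonal entries are transition rates
    ``j -> i`` and every column sums to zero (probability conservation).
    Ejection out of the top count level ``N`` is suppressed so the truncated
    chain remains a proper generator.
    """
    _validate_rates(spec, rates)
    if spec.truncation is None:
        raise ValueError("spec.truncation must be set to build a finite generator")
    n_s = spec.n_states
    N = spec.truncation
    Q = _switching_rate_matrix(n_s, rates.state_rates)
    active = n_s - 1

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        if v != 0.0:
            rows.append(i)
            cols.append(j)
            vals.append(v)

    for m in range(N + 1):
        base = m * n_s
        for s in range(n_s):
            j = base + s
            out = 0.0
            for s2 in range(n_s):
                if s2 != s and Q[s2, s] != 0.0:
                    add(base + s2, j, Q[s2, s])
                    out += Q[s2, s]
            if s == active and m < N and rates.k_eject > 0:
                add(base + n_s + s, j, rates.k_eject)
                out += rates.k_eject
            if m > 0:
                d = m * rates.k_decay
                add(base - n_s + s, j, d)
                out += d
            add(j, j, -out)

    dim = n_s * (N + 1)
    return scipy.sparse.csc_matrix(
        (vals, (rows, cols)), shape=(dim, dim), dtype=float
    )


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def _moment_guess(spec: ModelSpec, rates: RateParameters) -> tuple[float, float]:
    """Rough stationary mean/variance used to seed the truncation."""
    pi = switching_stationary(spec.n_states, rates.state_rates)
    p_on = float(pi[-1])
    nu = rates.k_eject / rates.k_decay
    mean = nu * p_on
    if spec.n_states == 2:
        a, b = rates.alpha, rates.beta
        var = mean * (1.0 + nu * b / ((a + b) * (1.0 + a + b)))
    else:
        # Poisson part plus the (upper-bound) slow-switching mixture part
        var = mean + (nu ** 2) * p_on * (1.0 - p_on)
    return mean, var


def _initial_truncation(spec: ModelSpec, rates: RateParameters, min_truncation: int) -> int:
    mean, var = _moment_guess(spec, rates)
    n0 = 4 * math.ceil(mean) + 10 * math.ceil(math.sqrt(max(var, 0.0)))
    return int(max(n0, min_truncation, 8))


def _pin_index(spec: ModelSpec, rates: RateParameters, N: int) -> int:
    """Joint index near the stationary mode, used to anchor the null vector."""
    mean, _var = _moment_guess(spec, rates)
    m_pin = min(max(int(round(mean)), 0), N)
    pi = switching_stationary(spec.n_states, rates.state_rates)
    s_pin = int(np.argmax(pi))
    return m_pin * spec.n_states + s_pin


def _solve_banded_null(spec: ModelSpec, rates: RateParameters, N: int) -> np.ndarray:
    """Stationary vector of the truncated generator via banded elimination.

    The generator is banded with bandwidth ``n_states`` in the count-major
    ordering.  ``A p = 0`` is solved by pinning one well-scaled component
    (a joint state near the stationary mode -- pinning a tail entry whose
    true probability underflows would wreck the conditioning) to 1,
    dropping that component's redundant balance equation, and solving the
    remaining banded system; deleting a matching row/column pair never
    widens the band.  The result is renormalized.
    """
    n_s = spec.n_states
    A = build_generator(replace(spec, truncation=N), rates)
    dim = n_s * (N + 1)
    bw = n_s
    k = _pin_index(spec, rates, N)
    ab = np.zeros((2 * bw + 1, dim - 1))
    rhs = np.zeros(dim - 1)
    Ac = A.tocoo()
    for i, j, v in zip(Ac.row, Ac.col, Ac.data):
        if i == k:
            continue
        ii = i if i < k else i - 1
        if j == k:
            rhs[ii] -= v
        else:
            jj = j if j < k else j - 1
            ab[bw + ii - jj, jj] += v
    x = scipy.linalg.solve_banded((bw, bw), ab, rhs)
    p = np.concatenate([x[:k], [1.0], x[k:]])
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def _solve_nullspace(spec: ModelSpec, rates: RateParameters, N: int) -> np.ndarray:
    """Stationary vector via orthogonal factorization of the generator.

    Uses the SVD-based null space; raises if the two smallest singular
    values are not separated by a relative factor of at least 1e6 (the
    truncated generator should have a simple zero eigenvalue).
    """
    A = build_generator(replace(spec, truncation=N), rates).toarray()
    u, s, vt = scipy.linalg.svd(A)
    if s.size >= 2 and s[-2] < 1e6 * max(s[-1], np.finfo(float).tiny):
        raise DegenerateNullSpaceError(
            f"null space not one-dimensional (singular values {s[-2:]!r})"
        )
    p = vt[-1]
    if p.sum() < 0:
        p = -p
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def steady_state(
    spec: ModelSpec,
    rates: RateParameters,
    *,
    min_truncation: int = 0,
    tail_tolerance: float = TAIL_TOLERANCE,
    method: str = "banded",
) -> SteadyStateDistribution:
    """Exact stationary mRNA distribution of one allele.

    The truncation is increased (doubling) until the mass on the boundary
    level is below ``tail_tolerance``, starting from a moment-based guess and
    never below ``min_truncation``.  ``method`` selects the linear-algebra
    route: ``"banded"`` (banded elimination, fast) or ``"nullspace"``
    (orthogonal-factorization null space, reference).

    Raises
    ------
    TruncationError
        If the mass is still not concentrated at the truncation cap.
    """
    _validate_rates(spec, rates)
    solver = {"banded": _solve_banded_null, "nullspace": _solve_nullspace}[method]
    if spec.truncation is not None:
        N = int(max(spec.truncation, min_truncation))
    else:
        N = _initial_truncation(spec, rates, min_truncation)
    N = min(N, MAX_TRUNCATION)
    while True:
        p_joint = solver(spec, rates, N)
        marg = p_joint.reshape(N + 1, spec.n_states).sum(axis=1)
        if marg[-1] < tail_tolerance or spec.truncation is not None:
            break
        if N >= MAX_TRUNCATION:
            raise TruncationError(
                f"distribution not concentrated below N={MAX_TRUNCATION}"
            )
        N = min(2 * N, MAX_TRUNCATION)
    marg = marg / marg.sum()
    return SteadyStateDistribution(marg, truncation=N)


# ---------------------------------------------------------------------------
# Beta-Poisson closed form (two-state oracle)
# ---------------------------------------------------------------------------

def _beta_poisson_single(alpha: float, beta: float, nu: float, n: int) -> float:
    if nu == 0.0:
        return 1.0 if n == 0 else 0.0
    ln_norm = -betaln(alpha, beta) - gammaln(n + 1)

    def integrand(lam: float) -> float:
        if lam <= 0.0 or lam >= 1.0:
            return 0.0
        ln_f = (
            (alpha - 1.0) * math.log(lam)
            + (beta - 1.0) * math.log1p(-lam)
            + n * math.log(nu * lam)
            - nu * lam
            + ln_norm
        )
        return math.exp(ln_f) if ln_f > -745.0 else 0.0

    with warnings.catch_warnings():
        # endpoint singularities for alpha < 1 or beta < 1 are integrable;
        # quad converges but reports roundoff near the endpoints
        warnings.simplefilter("ignore", scipy.integrate.IntegrationWarning)
        val, _err = quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-13, epsrel=1e-11)
    return min(max(val, 0.0), 1.0)


def beta_poisson_pmf(alpha: float, beta: float, nu: float, n) -> float | np.ndarray:
    """Beta-Poisson pmf: Poisson(nu * lambda) with lambda ~ Beta(alpha, beta).

    This is the closed-form stationary law of the two-state telegraph model
    with decay-scaled rates ``alpha = k_on/k_decay``, ``beta = k_off/k_decay``
    and ``nu = k_eject/k_decay``.  Evaluated by adaptive quadrature of the
    normalized mixing integral in log space; serves as the independent
    cross-check of the CME solver.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    if nu < 0:
        raise ValueError("nu must be nonnegative")
    if np.isscalar(n):
        if n < 0 or int(n) != n:
            raise ValueError("n must be a nonnegative integer")
        return _beta_poisson_single(alpha, beta, nu, int(n))
    return np.array([_beta_poisson_single(alpha, beta, nu, int(k)) for k in np.asarray(n).ravel()])


def beta_poisson_distribution(
    alpha: float, beta: float, nu: float, truncation: int
) -> SteadyStateDistribution:
    """Beta-Poisson pmf tabulated on 0..truncation as a distribution object."""
    p = np.asarray(beta_poisson_pmf(alpha, beta, nu, np.arange(truncation + 1)))
    return SteadyStateDistribution(p / p.sum(), truncation=truncation)


# ---------------------------------------------------------------------------
# distribution algebra
# ---------------------------------------------------------------------------

def distribution_moments(dist: SteadyStateDistribution) -> tuple[float, float]:
    """Mean and variance of a truncated count distribution."""
    return dist.mean, dist.variance


def thin_distribution(dist: SteadyStateDistribution, p: float) -> SteadyStateDistribution:
    """Binomial thinning: each molecule independently observed with probability p.

    Returns the mixture ``P'(m) = sum_n Bin(m | n, p) P(n)``.  For any
    generalized telegraph stationary law this equals the stationary law with
    the eject rate rescaled ``nu -> p * nu``.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError("thinning probability must lie in (0, 1]")
    if p == 1.0:
        return SteadyStateDistribution(dist.probs.copy(), truncation=dist.truncation)
    n = np.arange(dist.probs.size)
    # B[m, k] = Bin(m | k, p)
    B = _binom.pmf(n[:, None], n[None, :], p)
    out = B @ dist.probs
    return SteadyStateDistribution(out / out.sum(), truncation=dist.truncation)


def convolve_alleles(dist: SteadyStateDistribution, n_alleles: int) -> SteadyStateDistribution:
    """Count distribution of ``n_alleles`` independent identical alleles."""
    if n_alleles < 1 or int(n_alleles) != n_alleles:
        raise ValueError("n_alleles must be a positive integer")
    out = dist.probs.copy()
    for _ in range(int(n_alleles) - 1):
        out = np.convolve(out, dist.probs)
    return SteadyStateDistribution(out / out.sum(), truncation=out.size - 1)
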