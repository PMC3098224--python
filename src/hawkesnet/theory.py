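"""Closed-form rates, integrated covariances and the motif power series.

For a network of linearly interacting point processes with integrated kernel
matrix ``G`` and external drive ``y0``, the stationary rates and the matrix
of integrated covariance densities are

    y = (I - G)^-1 y0
    C = (I - G)^-1 Y (I - G^T)^-1,      Y = diag(y)

``C[i, j]`` is the time integral of the spike-train cross-covariance of
neurons i and j, i.e. the large-window limit of their spike-count covariance
per unit time.  Expanding the inverses as geometric series,

    C = sum_{n, m >= 0} G^n Y (G^T)^m

maps the covariance onto network *motifs*: the (n, m) term sums all pairs of
directed paths of lengths n and m from a common source to the two target
neurons, weighted by the source rate.  Terms with n = m = 0 are the Poisson
rate contribution, terms with exactly one branch empty are chains
(direct/indirect drive), and terms with both branches nonempty are (possibly
indirect) common input.  The series converges iff the spectral radius of G
is below one; the equilibrium itself is linearly stable iff every eigenvalue
has real part below one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError, ParameterError, StabilityError
from .network import Network

__all__ = [
    "TheoryResult",
    "MotifTerm",
    "SpectrumReport",
    "equilibrium_rates",
    "integrated_covariance",
    "avg_correlation",
    "population_variance",
    "analyse_network",
    "series_terms",
    "covariance_series_sum",
    "truncation_bound",
    "order_for_tolerance",
    "average_contributions",
    "OrderContributions",
    "avg_correlation_closed_form",
    "bulk_radius",
    "mean_input",
    "spectrum_report",
]


# ---------------------------------------------------------------------------
# results containers


@dataclass
class TheoryResult:
    """Equilibrium rates and integrated covariances of one network."""

    rates: np.ndarray  # spikes/s
    covariance: np.ndarray  # integrated covariance densities, spikes^2/s
    avg_correlation: float
    population_variance: float


@dataclass
class MotifTerm:
    """One (n, m) term of the covariance power series.

    ``matrix_term`` is ``G^n Y (G^T)^m`` (may be None when only averages were
    requested); ``avg`` is its mean over all N^2 ordered node pairs.  The
    term of (m, n) is the transpose of that of (n, m).
    """

    n: int
    m: int
    avg: float
    matrix_term: np.ndarray | None = None

    @property
    def order(self) -> int:
        return self.n + self.m

    @property
    def kind(self) -> str:
        if self.n == 0 and self.m == 0:
            return "rate"
        if self.n == 0 or self.m == 0:
            return "chain"
        return "common_input"


@dataclass
class SpectrumReport:
    """Eigenvalue geometry and stability diagnostics of a connectivity matrix.

    ``predicted_mean_outlier`` is the average recurrent input per neuron,
    ``p (N_E w_E + N_I w_I)``; for large random networks one real eigenvalue
    sits there while the remaining eigenvalues fill a disc whose radius
    ``predicted_bulk_radius`` equals the per-neuron input standard deviation
    ``sqrt(p (1-p) (N_E w_E^2 + N_I w_I^2))``.
    """

    eigenvalues: np.ndarray
    spectral_radius: float
    max_real_part: float
    predicted_bulk_radius: float
    predicted_mean_outlier: float
    stable: bool
    series_convergent: bool
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# closed forms from the full matrix


def _resolvent_solve(G: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    A = np.eye(G.shape[0]) - G
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        ev = np.linalg.eigvals(G)
        raise StabilityError(
            "(I - G) is singular: eigenvalue of G at 1 "
            f"(spectral radius {np.max(np.abs(ev)):.4f}, "
            f"max real part {np.max(ev.real):.4f})"
        ) from err


def equilibrium_rates(net: Network | np.ndarray, y0: float | np.ndarray = 1.0) -> np.ndarray:
    """Stationary rate vector y = (I - G)^-1 y0.

    ``y0`` is the constant external drive (spikes/s), scalar or per-neuron.
    Negative predicted rates are kept but trigger a warning: the linear
    theory ignores rectification, which only matters for neurons driven to
    low rates by strong inhibition.
    """
    G = net.G if isinstance(net, Network) else np.asarray(net, dtype=float)
    n = G.shape[0]
    drive = np.broadcast_to(np.asarray(y0, dtype=float), (n,)).copy()
    if np.any(drive < 0):
        raise ParameterError("external drive y0 must be non-negative")
    y = _resolvent_solve(G, drive)
    if np.any(y < 0):
        warnings.warn(
            f"{int(np.sum(y < 0))} predicted rates are negative; the linear "
            "theory ignores rectification",
            stacklevel=2,
        )
    return y


def integrated_covariance(net: Network | np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Integrated covariance matrix C = (I - G)^-1 diag(rates) (I - G^T)^-1."""
    G = net.G if isinstance(net, Network) else np.asarray(net, dtype=float)
    rates = np.asarray(rates, dtype=float)
    M = _resolvent_solve(G, np.diag(rates))
    C = _resolvent_solve(G, M.T).T
    return (C + C.T) / 2.0  # symmetric by construction; remove roundoff skew


def avg_correlation(C: np.ndarray, rates: np.ndarray) -> float:
    """Average correlation: mean of C over all N^2 ordered pairs with the
    Poisson rate term of the autocovariances removed."""
    n = C.shape[0]
    return float((C.sum() - np.sum(rates)) / n**2)


def population_variance(C: np.ndarray, members: np.ndarray | None = None) -> float:
    """Population spike-count variance per unit time for a subset of neurons.

    Equals the sum of the integrated covariance matrix over the
    members x members submatrix (all of C for the full population).
    """
    C = np.asarray(C)
    if members is None:
        return float(C.sum())
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if members.size == 0:
        raise ParameterError("population subset must be non-empty")
    return float(C[np.ix_(members, members)].sum())


def analyse_network(net: Network, y0: float | np.ndarray = 1.0) -> TheoryResult:
    """Rates, covariance, average correlation and population variance."""
    y = equilibrium_rates(net, y0)
    C = integrated_covariance(net, y)
    return TheoryResult(
        rates=y,
        covariance=C,
        avg_correlation=avg_correlation(C, y),
        population_variance=population_variance(C),
    )


# ---------------------------------------------------------------------------
# motif power series


def _spectral_radius_check(G: np.ndarray) -> float:
    ev = np.linalg.eigvals(G)
    rho = float(np.max(np.abs(ev)))
    if rho >= 1.0:
        worst = ev[np.argmax(np.abs(ev))]
        raise DivergenceError(
            f"covariance series diverges: eigenvalue {worst:.4f} has "
            f"magnitude {rho:.4f} >= 1"
        )
    return rho


def series_terms(
    net: Network | np.ndarray,
    rates: np.ndarray,
    max_order: int,
    with_matrices: bool = True,
) -> list[MotifTerm]:
    """All motif terms (n, m) with n + m <= max_order.

    Averages are computed from column-sum vectors in O(N^2) per order; the
    full N x N ``matrix_term`` arrays are attached unless
    ``with_matrices=False`` (they are only needed for entrywise work).
    """
    G = net.G if isinstance(net, Network) else np.asarray(net, dtype=float)
    rates = np.asarray(rates, dtype=float)
    n_nodes = G.shape[0]
    _spectral_radius_check(G)

    # colsums[k][l] = sum_i (G^k)_{il}; avg(n,m) = colsums[n]·(y*colsums[m])/N^2
    colsums = [np.ones(n_nodes)]
    for _ in range(max_order):
        colsums.append(G.T @ colsums[-1])

    if with_matrices:
        A = [np.diag(rates)]  # A[k] = G^k Y
        R = [np.eye(n_nodes)]  # R[k] = (G^T)^k
        for _ in range(max_order):
            A.append(G @ A[-1])
            R.append(R[-1] @ G.T)

    terms = []
    for k in range(max_order + 1):
        for n in range(k + 1):
            m = k - n
            avg = float(colsums[n] @ (rates * colsums[m]) / n_nodes**2)
            mat = A[n] @ R[m] if with_matrices else None
            terms.append(MotifTerm(n=n, m=m, avg=avg, matrix_term=mat))
    return terms


def covariance_series_sum(
    net: Network | np.ndarray, rates: np.ndarray, max_order: int
) -> np.ndarray:
    """Partial sum of the power series over all (n, m) with n + m <= max_order.

    Uses the per-order recursion T_k = G T_{k-1} + Y (G^T)^k (T_0 = Y), so
    the cost is O(max_order) matrix products rather than O(max_order^2).
    """
    G = net.G if isinstance(net, Network) else np.asarray(net, dtype=float)
    rates = np.asarray(rates, dtype=float)
    _spectral_radius_check(G)
    Y = np.diag(rates)
    T = Y.copy()
    S = Y.copy()
    Gt_k = np.eye(G.shape[0])
    for _ in range(max_order):
        Gt_k = Gt_k @ G.T
        T = G @ T + Y @ Gt_k
        S += T
    return S


def truncation_bound(rates: np.ndarray, rho: float, max_order: int) -> float:
    """Norm bound on the series tail beyond ``max_order``.

    The collective weight of all motifs of order k decays like
    (k+1) rho^k, so the tail beyond K is bounded by
    ||Y|| * sum_{k>K} (k+1) rho^k with ||Y|| = max rate.
    """
    if not 0.0 <= rho < 1.0:
        raise DivergenceError(f"tail bound requires rho < 1, got {rho}")
    K = max_order
    tail = ((K + 2) * rho ** (K + 1) - (K + 1) * rho ** (K + 2)) / (1.0 - rho) ** 2
    return float(np.max(np.abs(rates)) * tail)


def order_for_tolerance(rates: np.ndarray, rho: float, tol: float) -> int:
    """Smallest truncation order whose tail bound is below ``tol``."""
    K = 0
    while truncation_bound(rates, rho, K) > tol:
        K += 1
        if K > 100_000:
            raise DivergenceError("tolerance unreachable: spectral radius too close to 1")
    return K


@dataclass
class OrderContributions:
    """Per-order averaged motif contributions to the average correlation.

    ``total[k]`` is A_k, the mean over all N^2 pairs of the summed order-k
    matrix terms (k >= 1); ``chain`` and ``common_input`` split each order by
    motif class.  ``rate_term`` is the order-0 Poisson contribution
    (mean rate / N), reported separately.
    """

    orders: np.ndarray
    total: np.ndarray
    chain: np.ndarray
    common_input: np.ndarray
    rate_term: float

    @property
    def sum(self) -> float:
        return float(self.total.sum())


def average_contributions(terms: list[MotifTerm]) -> OrderContributions:
    """Collapse motif terms into per-order averages A_k and their class split."""
    max_order = max(t.order for t in terms)
    total = np.zeros(max_order + 1)
    chain = np.zeros(max_order + 1)
    common = np.zeros(max_order + 1)
    rate_term = 0.0
    for t in terms:
        if t.kind == "rate":
            rate_term = t.avg
            continue
        total[t.order] += t.avg
        if t.kind == "chain":
            chain[t.order] += t.avg
        else:
            common[t.order] += t.avg
    return OrderContributions(
        orders=np.arange(1, max_order + 1),
        total=total[1:],
        chain=chain[1:],
        common_input=common[1:],
        rate_term=rate_term,
    )


# ---------------------------------------------------------------------------
# homogeneous closed form


def avg_correlation_closed_form(
    n: int,
    n_exc: int,
    n_inh: int,
    p: float,
    w_exc: float,
    w_inh: float,
    y0: float = 1.0,
    max_order: int = 10,
) -> tuple[np.ndarray, float]:
    """Average correlation of a homogeneous random network, in closed form.

    With uniform connection probability p, the average interaction a neuron
    pair exchanges is ``g_bar = p (N_E w_E + N_I w_I) / N`` and the average
    common input two neurons share is ``q_bar = p^2 (N_E w_E^2 + N_I w_I^2)``.
    Writing ``Gamma = N g_bar`` for the mean recurrent input per neuron, the
    homogeneous rate is ``y = y0 / (1 - Gamma)`` and the averaged order-k
    contribution to the correlation is

        A_k = y [ (k-1) q_bar Gamma^(k-2) + (2/N) Gamma^k ],   k >= 1

    (the first summand collects the k-1 common-input splits (n, m), n+m = k,
    n, m >= 1; the second the two pure chains).  Summing the geometric series
    gives the total average correlation

        c_bar = y [ q_bar / (1 - Gamma)^2 + 2 Gamma / (N (1 - Gamma)) ]

    which is exact for networks with fixed per-population out-degrees and an
    approximation (improving with N) for Bernoulli random networks.

    Returns ``(per_order, c_bar)`` with ``per_order[k-1] = A_k``.
    """
    if n <= 0 or n_exc < 0 or n_inh < 0 or n_exc + n_inh != n:
        raise ParameterError("population sizes must satisfy N_E + N_I = N")
    if not 0.0 <= p <= 1.0:
        raise ParameterError("connection probability p must lie in [0, 1]")
    gamma = p * (n_exc * w_exc + n_inh * w_inh)  # mean input N*g_bar
    q_bar = p**2 * (n_exc * w_exc**2 + n_inh * w_inh**2)  # mean common input
    if abs(gamma) >= 1.0:
        raise DivergenceError(f"mean input {gamma:.4f} outside the convergent regime |Gamma| < 1")
    y = y0 / (1.0 - gamma)
    ks = np.arange(1, max_order + 1)
    per_order = np.empty(max_order)
    per_order[0] = y * 2.0 * gamma / n
    if max_order > 1:
        k = ks[1:]
        per_order[1:] = y * ((k - 1) * q_bar * gamma ** (k - 2) + 2.0 / n * gamma**k)
    c_bar = y * (q_bar / (1.0 - gamma) ** 2 + 2.0 * gamma / (n * (1.0 - gamma)))
    return per_order, float(c_bar)


# ---------------------------------------------------------------------------
# spectrum


def mean_input(p: float, n_exc: int, n_inh: int, w_exc: float, w_inh: float) -> float:
    """Average recurrent input per neuron, p (N_E w_E + N_I w_I)."""
    return p * (n_exc * w_exc + n_inh * w_inh)


def bulk_radius(p: float, n_exc: int, n_inh: int, w_exc: float, w_inh: float) -> float:
    """Radius of the bulk eigenvalue spectrum of a random connectivity matrix.

    Equals the standard deviation of the total recurrent input of a neuron,
    ``B = sqrt(p (1-p) (N_E w_E^2 + N_I w_I^2))``.  The network is linearly
    stable only if both the mean input and B stay below one — random
    connectivity can destabilise a network through input *variance* even
    under exact excitation-inhibition balance.
    """
    return float(np.sqrt(p * (1.0 - p) * (n_exc * w_exc**2 + n_inh * w_inh**2)))


def _effective_weights(net: Network) -> tuple[float, float]:
    """Mean nonzero synaptic weight per presynaptic population."""
    exc_cols = net.G[:, net.excitatory]
    inh_cols = net.G[:, ~net.excitatory]
    w_e = float(exc_cols[exc_cols != 0].mean()) if np.any(exc_cols != 0) else 0.0
    w_i = float(inh_cols[inh_cols != 0].mean()) if np.any(inh_cols != 0) else 0.0
    return w_e, w_i


def spectrum_report(net: Network) -> SpectrumReport:
    """Eigenvalues of G plus random-matrix predictions and stability flags.

    The predictions use the realised edge density of the network as p and
    the mean nonzero weight per population, so they apply to any generator
    (for non-random architectures they describe the matched random network).
    """
    n = net.n_nodes
    ev = np.linalg.eigvals(net.G)
    p_eff = net.n_edges() / (n * (n - 1))
    w_e, w_i = _effective_weights(net)
    radius = float(np.max(np.abs(ev))) if n else 0.0
    max_re = float(np.max(ev.real)) if n else 0.0
    return SpectrumReport(
        eigenvalues=ev,
        spectral_radius=radius,
        max_real_part=max_re,
        predicted_bulk_radius=bulk_radius(p_eff, net.n_excitatory, net.n_inhibitory, w_e, w_i),
        predicted_mean_outlier=mean_input(p_eff, net.n_excitatory, net.n_inhibitory, w_e, w_i),
        stable=max_re < 1.0,
        series_convergent=radius < 1.0,
        params={"p_effective": p_eff, "w_exc": w_e, "w_inh": w_i},
    )
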