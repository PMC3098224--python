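"""Distance-dependent correlations on ring networks.

On a ring, ensemble-averaged connectivity depends only on the signed offset
d between two nodes, through the *average interaction profile*

    h(d) = sum_X  f_X * profile_X(d) * w_X        (X in {E, I})

(the probability-weighted synaptic weight a node receives from a node at
offset d) and the *average common-input profile*

    q(d) = sum_X  f_X * (h_X ∗ h_X)(d),           h_X = w_X * profile_X

where ∗ is circular convolution: two nodes at offset d share input from a
source of type X through the product of its two outgoing profiles.  (q is
not simply h ∗ h because both edges share the same source and hence the
same weight — the type enters squared.)

Averaging the covariance power series over nodes turns matrix products into
circular convolutions of these profiles, which a discrete Fourier transform
diagonalises.  With the homogeneous rate y = y0 / (1 - h_hat(0)), the
order-k contribution to the distance-dependent correlation c(d) has
transform

    c_k_hat(w) = y [ 2 h_hat(w)^k  +  (k-1) q_hat(w) h_hat(w)^(k-2) ]

(two pure chains plus k-1 common-input splits), and the full correlation
including the order-0 rate delta sums to

    c_hat(w) = y [ 1 + 2 h_hat(w) / (1 - h_hat(w)) + q_hat(w) / (1 - h_hat(w))^2 ]

The series converges iff |h_hat(w)| < 1 for every spatial frequency; modes
violating this are the large-scale oscillatory eigenmodes that destabilise
locally excitatory rings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError, ParameterError
from .network import RingProfile

__all__ = [
    "DistanceProfileSet",
    "interaction_profiles",
    "distance_correlation_analytic",
    "distance_correlation_numeric",
    "variance_vs_population_size",
    "loglog_slope",
]


@dataclass
class DistanceProfileSet:
    """Analytic distance-resolved correlation structure of a ring network.

    All length-N vectors are circular arrays indexed by offset d mod N
    (index 0 = same node, index d = d steps clockwise); profiles are
    symmetric, so index d and N-d agree.  ``c_by_order[k]`` is the order-k
    contribution c_k(d) (k = 0 is the rate delta), ``c_total`` the full
    closed-form correlation.
    """

    n: int
    h: np.ndarray
    q: np.ndarray
    rate: float
    c_by_order: np.ndarray
    c_total: np.ndarray

    def geodesic(self, vector: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Fold a circular offset array onto geodesic distances 0..N//2."""
        v = self.c_total if vector is None else vector
        dists = np.arange(self.n // 2 + 1)
        folded = np.array([(v[d] + v[(self.n - d) % self.n]) / 2.0 for d in dists])
        return dists, folded


def interaction_profiles(
    n: int,
    frac_inhib: float,
    profile_exc: RingProfile,
    profile_inh: RingProfile,
    w_exc: float,
    w_inh: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Average interaction h(d) and common-input q(d) as circular arrays."""
    d = np.arange(n)
    geo = np.minimum(d, n - d)
    f_inh = frac_inhib
    h_e = w_exc * profile_exc.probabilities(n)[geo]
    h_i = w_inh * profile_inh.probabilities(n)[geo]
    h = (1.0 - f_inh) * h_e + f_inh * h_i
    # circular autocorrelation of each symmetric per-type profile
    q_hat = (1.0 - f_inh) * np.abs(np.fft.fft(h_e)) ** 2 + f_inh * np.abs(np.fft.fft(h_i)) ** 2
    q = np.fft.ifft(q_hat).real
    return h, q


def distance_correlation_analytic(
    n: int,
    frac_inhib: float,
    profile_exc: RingProfile,
    profile_inh: RingProfile,
    w_exc: float,
    w_inh: float,
    y0: float = 1.0,
    max_order: int = 20,
) -> DistanceProfileSet:
    """Per-order and total distance-dependent correlations via the DFT.

    Uses the ensemble-averaged (annealed) profiles, so single network
    realisations match only after averaging over generator seeds.
    """
    h, q = interaction_profiles(n, frac_inhib, profile_exc, profile_inh, w_exc, w_inh)
    h_hat = np.fft.fft(h).real  # h symmetric -> real spectrum
    q_hat = np.fft.fft(q).real
    worst = int(np.argmax(np.abs(h_hat)))
    if np.abs(h_hat[worst]) >= 1.0:
        raise DivergenceError(
            f"spatial mode {worst} has |h_hat| = {np.abs(h_hat[worst]):.4f} >= 1: "
            "the corresponding oscillatory eigenmode makes the series diverge"
        )
    rate = y0 / (1.0 - h_hat[0])

    c_by_order = np.empty((max_order + 1, n))
    c_by_order[0] = np.fft.ifft(np.full(n, rate)).real  # rate delta at d = 0
    for k in range(1, max_order + 1):
        ck_hat = 2.0 * h_hat**k
        if k >= 2:
            ck_hat = ck_hat + (k - 1) * q_hat * h_hat ** (k - 2)
        c_by_order[k] = np.fft.ifft(rate * ck_hat).real

    resolvent = 1.0 / (1.0 - h_hat)
    c_hat = rate * (1.0 + 2.0 * h_hat * resolvent + q_hat * resolvent**2)
    c_total = np.fft.ifft(c_hat).real

    return DistanceProfileSet(n=n, h=h, q=q, rate=float(rate), c_by_order=c_by_order, c_total=c_total)


def distance_correlation_numeric(C: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Distance-dependent correlation c(d) from a full covariance matrix.

    ``c[d]`` is the mean over all nodes i of ``C[i+d, i]`` (indices mod N,
    nodes ordered by their ring coordinate).  Returns a circular length-N
    array comparable entrywise with the analytic ``c_total``.
    """
    C = np.asarray(C)
    n = C.shape[0]
    positions = np.asarray(positions)
    if sorted(positions.tolist()) != list(range(n)):
        raise ParameterError("positions must be a permutation of 0..N-1 (a ring)")
    order = np.argsort(positions)
    C_ring = C[np.ix_(order, order)]
    i = np.arange(n)
    rows = (i[None, :] + i[:, None]) % n  # rows[d, i] = i + d
    return C_ring[rows, i[None, :]].mean(axis=1)


def variance_vs_population_size(
    source: np.ndarray | DistanceProfileSet,
    sizes: np.ndarray,
    contiguous: bool = True,
    positions: np.ndarray | None = None,
    n_samples: int = 5,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Population spike-count variance (per unit time) versus population size.

    ``source`` is either a full covariance matrix (populations are sampled
    from it, ``n_samples`` per size, averaged) or an analytic
    :class:`DistanceProfileSet` (closed-form arc sums).  With
    ``contiguous=True`` populations are arcs of neighbouring ring positions;
    otherwise random subsets.  In locally connected rings contiguous-arc
    variance grows linearly with size, while in random networks (or for
    scattered subsets) it grows quadratically.
    """
    sizes = np.asarray(sizes, dtype=int)
    if isinstance(source, DistanceProfileSet):
        return _variance_curve_analytic(source, sizes)
    C = np.asarray(source)
    n = C.shape[0]
    if np.any(sizes > n) or np.any(sizes < 1):
        raise ParameterError("population sizes must lie in [1, N]")
    if positions is not None:
        order = np.argsort(np.asarray(positions))
        C = C[np.ix_(order, order)]
    rng = np.random.default_rng(seed)
    out = np.empty(sizes.size)
    for s_i, size in enumerate(sizes):
        acc = 0.0
        for k in range(n_samples):
            if contiguous:
                start = (k * n) // n_samples
                members = (start + np.arange(size)) % n
            else:
                members = rng.choice(n, size=size, replace=False)
            acc += C[np.ix_(members, members)].sum()
        out[s_i] = acc / n_samples
    return out


def _variance_curve_analytic(profiles: DistanceProfileSet, sizes: np.ndarray) -> np.ndarray:
    """Arc variance v(n) = sum_{|d| < n} (n - |d|) c(d) from the analytic c."""
    c = profiles.c_total
    n_ring = profiles.n
    out = np.empty(sizes.size)
    for s_i, size in enumerate(sizes):
        d = np.arange(-(size - 1), size)
        out[s_i] = np.sum((size - np.abs(d)) * c[d % n_ring])
    return out


def loglog_slope(sizes: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope of log(values) against log(sizes)."""
    x = np.log(np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(values, dtype=float))
    return float(np.polyfit(x, y, 1)[0])
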