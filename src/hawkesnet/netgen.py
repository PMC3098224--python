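"""Seeded generators for the network architectures under study.

All generators emit a :class:`~hawkesnet.network.Network` whose matrix ``G``
holds integrated kernel weights, ``G[i, j]`` being the effect of presynaptic
``j`` on postsynaptic ``i``.  Column signs follow the presynaptic type
(excitatory columns >= 0, inhibitory <= 0), self-connections are excluded,
and multi-edges are impossible by construction (all samplers draw targets
without replacement).  Identical seed and parameters give identical edge
sets.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateNetworkError, ParameterError
from .network import Network, RingProfile

__all__ = [
    "make_random",
    "make_ring",
    "make_hub_network",
    "make_patchy",
    "weighted_assortativity",
]


def _check_common(n: int, frac_inhib: float, w_exc: float, w_inh: float) -> None:
    if n <= 0:
        raise ParameterError("N must be a positive integer")
    if not 0.0 <= frac_inhib <= 1.0:
        raise ParameterError("frac_inhib must lie in [0, 1]")
    if w_exc < 0:
        raise ParameterError("excitatory weight must be >= 0")
    if w_inh > 0:
        raise ParameterError("inhibitory weight must be <= 0")


def _assign_types(n: int, frac_inhib: float, rng: np.random.Generator) -> np.ndarray:
    """Exact type counts (N_I = round(frac_inhib * N)) at random positions."""
    n_inh = int(round(frac_inhib * n))
    types = np.full(n, "E", dtype="U1")
    types[rng.choice(n, size=n_inh, replace=False)] = "I"
    return types


def _weights_by_type(types: np.ndarray, w_exc: float, w_inh: float) -> np.ndarray:
    """Per-source column weight."""
    return np.where(types == "E", w_exc, w_inh)


def make_random(
    n: int,
    frac_inhib: float,
    p: float,
    w_exc: float,
    w_inh: float,
    fixed_out_degree: bool = False,
    seed: int | np.random.Generator | None = None,
) -> Network:
    """Uniform random network: every ordered pair connected with probability p.

    With ``fixed_out_degree=True`` the network is *regular*: every source
    projects to exactly ``round(p * N_E)`` excitatory and ``round(p * N_I)``
    inhibitory targets, sampled without replacement within each type.  Fixing
    the per-population out-degree (rather than only the total) removes the
    type-mix fluctuations of Bernoulli wiring, which is what makes the
    homogeneous closed-form average correlation exact on these networks.
    """
    _check_common(n, frac_inhib, w_exc, w_inh)
    if not 0.0 <= p <= 1.0:
        raise ParameterError("connection probability p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    types = _assign_types(n, frac_inhib, rng)
    col_w = _weights_by_type(types, w_exc, w_inh)

    if fixed_out_degree:
        exc_idx = np.flatnonzero(types == "E")
        inh_idx = np.flatnonzero(types == "I")
        k_e = int(round(p * exc_idx.size))
        k_i = int(round(p * inh_idx.size))
        G = np.zeros((n, n))
        for j in range(n):
            pool_e = exc_idx[exc_idx != j]
            pool_i = inh_idx[inh_idx != j]
            if k_e > pool_e.size or k_i > pool_i.size:
                raise ParameterError("requested out-degree exceeds available pool")
            targets = np.concatenate(
                [
                    rng.choice(pool_e, size=k_e, replace=False),
                    rng.choice(pool_i, size=k_i, replace=False),
                ]
            )
            G[targets, j] = col_w[j]
    else:
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        G = mask * col_w[np.newaxis, :]

    net = Network(
        G=G,
        types=types,
        meta={
            "generator": "random",
            "params": {
                "N": n,
                "frac_inhib": frac_inhib,
                "p": p,
                "w_exc": w_exc,
                "w_inh": w_inh,
                "fixed_out_degree": fixed_out_degree,
            },
            "seed": seed if isinstance(seed, int) else None,
        },
    )
    net.validate()
    return net


def make_ring(
    n: int,
    frac_inhib: float,
    profile_exc: RingProfile,
    profile_inh: RingProfile,
    w_exc: float,
    w_inh: float,
    seed: int | np.random.Generator | None = None,
) -> Network:
    """Ring network with distance-dependent (boxcar) connectivity.

    Nodes sit on a ring at positions ``0..N-1``; the type of each node is
    Bernoulli with inhibition probability ``frac_inhib`` (so realised counts
    fluctuate, as reported in ``meta``).  A connection j -> i is realised
    with probability ``profile_X(d(i, j))`` where ``X`` is the type of the
    *source* j and ``d`` the geodesic ring distance.
    """
    _check_common(n, frac_inhib, w_exc, w_inh)
    rng = np.random.default_rng(seed)
    types = np.where(rng.random(n) < frac_inhib, "I", "E").astype("U1")
    col_w = _weights_by_type(types, w_exc, w_inh)
    positions = np.arange(n)

    # geodesic distance matrix d(i, j) and per-source probability by distance
    off = np.abs(positions[:, None] - positions[None, :])
    dist = np.minimum(off, n - off)
    prob_e = profile_exc.probabilities(n)
    prob_i = profile_inh.probabilities(n)
    p_by_source = np.where(types[None, :] == "E", prob_e[dist], prob_i[dist])
    mask = rng.random((n, n)) < p_by_source
    np.fill_diagonal(mask, False)
    G = mask * col_w[np.newaxis, :]

    net = Network(
        G=G,
        types=types,
        positions=positions,
        meta={
            "generator": "ring",
            "params": {
                "N": n,
                "frac_inhib": frac_inhib,
                "profile_exc": {"half_width": profile_exc.half_width, "height": profile_exc.height},
                "profile_inh": {"half_width": profile_inh.half_width, "height": profile_inh.height},
                "w_exc": w_exc,
                "w_inh": w_inh,
            },
            "seed": seed if isinstance(seed, int) else None,
            "realised_counts": {"N_E": int(np.sum(types == "E")), "N_I": int(np.sum(types == "I"))},
        },
    )
    net.validate()
    return net


def geometric_q(mu: float) -> float:
    """Success parameter q of the out-degree law P(k) = (1-q) q^k with mean mu."""
    if mu <= 0:
        raise ParameterError("mean out-degree mu must be positive")
    return mu / (1.0 + mu)


def make_hub_network(
    n: int,
    frac_inhib: float,
    mu: float,
    f: float,
    w_exc: float,
    w_inh: float,
    hub_threshold: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> Network:
    """Broad-degree network with a tunable hub-to-hub connection fraction.

    Out-degrees are drawn from the geometric law ``P(k) = (1-q) q^k`` on
    ``k = 0, 1, 2, ...`` with mean ``mu = q / (1-q)``.  Excitatory nodes with
    out-degree above ``hub_threshold`` (default: ``ceil(mu)``) are *hubs*.
    For each hub the number of excitatory targets is binomial with success
    probability ``N_E / N``; a fraction ``f`` of those go to other hubs, the
    rest to excitatory non-hubs, and the remaining targets to inhibitory
    nodes.  Non-hubs and inhibitory sources pick targets uniformly.  Varying
    ``f`` changes only the statistics of longer paths — the mean connectivity
    and the low-order motif statistics are independent of ``f``.
    """
    _check_common(n, frac_inhib, w_exc, w_inh)
    if not 0.0 <= f <= 1.0:
        raise ParameterError("hub-to-hub fraction f must lie in [0, 1]")
    q = geometric_q(mu)
    rng = np.random.default_rng(seed)
    types = _assign_types(n, frac_inhib, rng)
    col_w = _weights_by_type(types, w_exc, w_inh)
    threshold = int(np.ceil(mu)) if hub_threshold is None else int(hub_threshold)

    # numpy's geometric has support 1.. with P(k) = (1-p)^(k-1) p; shift to 0..
    k_out = rng.geometric(1.0 - q, size=n) - 1
    k_out = np.minimum(k_out, n - 1)

    exc = types == "E"
    hubs = exc & (k_out > threshold)
    hub_idx = np.flatnonzero(hubs)
    nonhub_exc_idx = np.flatnonzero(exc & ~hubs)
    inh_idx = np.flatnonzero(~exc)
    n_exc_total = int(exc.sum())

    G = np.zeros((n, n))
    fallback = False
    for j in range(n):
        k = int(k_out[j])
        if k == 0:
            continue
        if hubs[j]:
            k_e = int(rng.binomial(k, n_exc_total / n))
            k_i = k - k_e
            n_hub = int(round(f * k_e))
            pool_hub = hub_idx[hub_idx != j]
            pool_non = nonhub_exc_idx
            if n_hub > pool_hub.size:
                fallback = True
                pool_hub = np.concatenate([pool_hub, pool_non])
            if (k_e - min(n_hub, pool_hub.size)) > pool_non.size:
                fallback = True
            targets = _sample_split(rng, pool_hub, n_hub, pool_non, k_e - n_hub)
            if k_i > 0:
                pool_i = inh_idx[inh_idx != j]
                k_i = min(k_i, pool_i.size)
                targets = np.concatenate([targets, rng.choice(pool_i, size=k_i, replace=False)])
        else:
            pool = np.delete(np.arange(n), j)
            k = min(k, pool.size)
            targets = rng.choice(pool, size=k, replace=False)
        G[targets, j] = col_w[j]
    if fallback:
        warnings.warn(
            "hub target pool exhausted for some sources; sampled from the full "
            "excitatory pool instead",
            stacklevel=2,
        )

    net = Network(
        G=G,
        types=types,
        meta={
            "generator": "hub",
            "params": {
                "N": n,
                "frac_inhib": frac_inhib,
                "mu": mu,
                "f": f,
                "hub_threshold": threshold,
                "w_exc": w_exc,
                "w_inh": w_inh,
            },
            "seed": seed if isinstance(seed, int) else None,
            "n_hubs": int(hubs.sum()),
        },
    )
    net.validate()
    return net


def _sample_split(
    rng: np.random.Generator,
    pool_a: np.ndarray,
    k_a: int,
    pool_b: np.ndarray,
    k_b: int,
) -> np.ndarray:
    """Sample k_a from pool_a and k_b from pool_b, clipping to pool sizes."""
    k_a = min(k_a, pool_a.size)
    k_b = min(max(k_b, 0), pool_b.size)
    parts = []
    if k_a > 0:
        parts.append(rng.choice(pool_a, size=k_a, replace=False))
    if k_b > 0:
        parts.append(rng.choice(pool_b, size=k_b, replace=False))
    if not parts:
        return np.empty(0, dtype=int)
    return np.concatenate(parts)


def make_patchy(
    n: int,
    frac_inhib: float,
    patch_size: int,
    p_patch: float,
    w_exc: float,
    w_inh: float,
    separated_types: bool = False,
    seed: int | np.random.Generator | None = None,
) -> Network:
    """Ring network with patchy output connectivity.

    Each source is assigned a patch of ``patch_size`` contiguous ring
    positions at a uniformly random offset; every patch member (other than
    the source itself) becomes a target independently with probability
    ``p_patch``.  With ``separated_types=True`` all inhibitory nodes occupy
    one contiguous block of the ring; otherwise types are placed uniformly at
    random.  The expected overall connection probability
    ``patch_size * p_patch / N`` is recorded in ``meta``.
    """
    _check_common(n, frac_inhib, w_exc, w_inh)
    if not 1 <= patch_size <= n:
        raise ParameterError("patch_size must lie in [1, N]")
    if not 0.0 <= p_patch <= 1.0:
        raise ParameterError("p_patch must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_inh = int(round(frac_inhib * n))
    if separated_types:
        start = int(rng.integers(n))
        types = np.full(n, "E", dtype="U1")
        types[(start + np.arange(n_inh)) % n] = "I"
    else:
        types = _assign_types(n, frac_inhib, rng)
    col_w = _weights_by_type(types, w_exc, w_inh)
    positions = np.arange(n)

    G = np.zeros((n, n))
    for j in range(n):
        offset = int(rng.integers(n))
        members = (offset + np.arange(patch_size)) % n
        members = members[members != j]
        hit = members[rng.random(members.size) < p_patch]
        G[hit, j] = col_w[j]

    net = Network(
        G=G,
        types=types,
        positions=positions,
        meta={
            "generator": "patchy",
            "params": {
                "N": n,
                "frac_inhib": frac_inhib,
                "patch_size": patch_size,
                "p_patch": p_patch,
                "separated_types": separated_types,
                "w_exc": w_exc,
                "w_inh": w_inh,
            },
            "seed": seed if isinstance(seed, int) else None,
            "expected_connectivity": patch_size * p_patch / n,
        },
    )
    net.validate()
    return net


def weighted_assortativity(net: Network) -> float:
    """Weighted assortativity: strength correlation across directed edges.

    Generalises the degree-assortativity coefficient to weighted signed
    networks: every directed edge contributes the pair (total signed
    strength of its source, total signed strength of its target), where the
    total strength of a node is the sum of its incoming and outgoing
    weights.  The coefficient is the Pearson correlation of these end-point
    strengths with the two edge ends pooled symmetrically, each edge counted
    once.  Values lie in [-1, 1]; positive values mean high-strength nodes
    preferentially connect to each other (assortative mixing), as when
    excitatory hubs form a densely connected subnetwork.
    """
    rows, cols = np.nonzero(net.G)
    if rows.size < 2:
        raise DegenerateNetworkError("assortativity needs at least 2 edges")
    strength = net.G.sum(axis=0) + net.G.sum(axis=1)  # signed out + in strength
    x = strength[cols]  # source end
    y = strength[rows]  # target end
    # symmetric pooling of the two edge ends, each edge counted once
    mean = (x.mean() + y.mean()) / 2.0
    var = (np.mean(x**2) + np.mean(y**2)) / 2.0 - mean**2
    if var <= 0 or np.isclose(var, 0.0, atol=max(1e-15 * mean**2, 1e-30)):
        raise DegenerateNetworkError("assortativity undefined: zero strength variance")
    cov = np.mean(x * y) - mean**2
    return float(cov / var)
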