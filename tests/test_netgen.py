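"""Generator construction properties: degrees, signs, reproducibility."""

import numpy as np
import pytest

from hawkesnet import (
    DegenerateNetworkError,
    Network,
    ParameterError,
    RingProfile,
    make_hub_network,
    make_patchy,
    make_random,
    make_ring,
    weighted_assortativity,
)
from hawkesnet.netgen import geometric_q
from hawkesnet.network import ring_distance


@pytest.mark.parametrize(
    "factory",
    [
        lambda s: make_random(100, 0.2, 0.1, 0.02, -0.1, seed=s),
        lambda s: make_random(100, 0.2, 0.1, 0.02, -0.1, fixed_out_degree=True, seed=s),
        lambda s: make_ring(100, 0.2, RingProfile(10, 0.5), RingProfile(50, 0.1), 0.02, -0.1, seed=s),
        lambda s: make_hub_network(100, 0.2, 10.0, 0.5, 0.02, -0.1, seed=s),
        lambda s: make_patchy(100, 0.2, 20, 0.5, 0.02, -0.1, seed=s),
    ],
    ids=["bernoulli", "fixed_degree", "ring", "hub", "patchy"],
)
def test_generators_reproducible_and_sign_disciplined(factory):
    """Same seed gives the identical edge set; columns carry the presynaptic sign."""
    a, b = factory(3), factory(3)
    np.testing.assert_array_equal(a.G, b.G)
    np.testing.assert_array_equal(a.types, b.types)
    assert not np.array_equal(a.G, factory(4).G)
    assert np.all(np.diag(a.G) == 0)
    exc = a.excitatory
    assert np.all(a.G[:, exc] >= 0) and np.all(a.G[:, ~exc] <= 0)


def test_empty_and_fixed_degree_examples():
    net = make_random(100, 0.2, 0.0, 1.0, -1.0, seed=0)
    assert net.n_edges() == 0
    fixed = make_random(100, 0.2, 0.1, 0.02, -0.1, fixed_out_degree=True, seed=0)
    out_degrees = np.count_nonzero(fixed.G, axis=0)
    assert np.all(out_degrees == 10)  # round(0.1*80) + round(0.1*20)


def test_bernoulli_mean_out_degree_matches_binomial():
    """Across seeds the mean out-degree is within 3 SE of (N-1)p."""
    n, p, n_seeds = 300, 0.1, 30
    means = [
        np.count_nonzero(make_random(n, 0.2, p, 0.01, -0.05, seed=s).G, axis=0).mean()
        for s in range(n_seeds)
    ]
    se = np.sqrt((n - 1) * p * (1 - p) / (n * n_seeds))
    assert abs(np.mean(means) - (n - 1) * p) < 3 * se


def test_ring_respects_profile_support_and_density():
    n = 400
    net = make_ring(n, 0.2, RingProfile(5, 1.0), RingProfile(200, 0.1), 0.02, -0.1, seed=1)
    rows, cols = np.nonzero(net.G)
    d = ring_distance(rows, cols, n)
    exc_src = net.types[cols] == "E"
    assert d[exc_src].max() <= 5  # no excitatory edge beyond its half-width
    # full-width profiles at matched density behave like a uniform random net
    dens = []
    for s in range(10):
        u = make_ring(n, 0.2, RingProfile(200, 0.1), RingProfile(200, 0.1), 0.02, -0.1, seed=s)
        dens.append(u.n_edges() / (n * (n - 1)))
    # boxcar covers distances 1..N/2 on both sides => per-pair probability 0.1
    assert abs(np.mean(dens) - 0.1) < 4 * np.std(dens, ddof=1) / np.sqrt(10) + 1e-3


def test_ring_halfwidth_validation():
    with pytest.raises((ParameterError, ValueError)):
        make_ring(100, 0.2, RingProfile(60, 0.5), RingProfile(10, 0.5), 0.02, -0.1, seed=0)


def test_geometric_out_degree_mean():
    """Sampled out-degrees follow the geometric law with the requested mean."""
    mu = 50.0
    q = geometric_q(mu)
    assert np.isclose(q / (1 - q), mu)
    rng = np.random.default_rng(0)
    draws = rng.geometric(1 - q, size=100_000) - 1
    se = np.sqrt(mu * (1 + mu) / draws.size)
    assert abs(draws.mean() - mu) < 3 * se


def test_hub_network_f_controls_hub_hub_edges():
    def hub_hub_edges(f, seed=5):
        net = make_hub_network(400, 0.2, 20.0, f, 0.01, -0.05, seed=seed)
        k_out = np.count_nonzero(net.G, axis=0)
        thr = net.meta["params"]["hub_threshold"]
        hubs = (net.types == "E") & (k_out > thr)
        return np.count_nonzero(net.G[np.ix_(hubs, hubs)])

    assert hub_hub_edges(0.0) == 0
    assert hub_hub_edges(0.9) > hub_hub_edges(0.1)


def test_hub_pool_exhaustion_warns():
    # tiny network: almost no hubs, f=1 forces the fallback path
    with pytest.warns(UserWarning, match="pool"):
        make_hub_network(40, 0.2, 15.0, 1.0, 0.01, -0.05, hub_threshold=30, seed=2)


def test_patchy_targets_stay_in_patch_and_density_invariant():
    n = 400
    for s_patch in (40, 100, 400):
        p_patch = 0.1 * n / s_patch
        net = make_patchy(n, 0.2, s_patch, p_patch, 0.02, -0.1, seed=3)
        dens = net.n_edges() / (n * (n - 1))
        assert abs(dens - 0.1) < 0.02
        assert net.meta["expected_connectivity"] == pytest.approx(0.1)
    # patch membership: every realised target lies inside one arc of patch_size positions
    net = make_patchy(n, 0.2, 40, 1.0, 0.02, -0.1, seed=4)
    for j in range(0, n, 37):
        tgt = np.sort(np.flatnonzero(net.G[:, j]))
        if tgt.size > 1:
            circ_gaps = np.diff(np.append(tgt, tgt[0] + n))
            arc_span = n - circ_gaps.max() + 1
            assert arc_span <= 40


def test_separated_types_occupy_contiguous_block():
    net = make_patchy(200, 0.25, 50, 0.4, 0.02, -0.1, separated_types=True, seed=6)
    inh = np.flatnonzero(net.types == "I")
    assert inh.size == 50
    rolled = np.sort(inh)
    gaps = np.diff(rolled)
    assert np.sum(gaps > 1) <= 1  # contiguous up to one wrap-around


def test_assortativity_degenerate_and_star():
    # k-regular graph with uniform weights: zero strength variance
    G = np.zeros((6, 6))
    for i in range(6):
        G[(i + 1) % 6, i] = 0.5
        G[(i + 2) % 6, i] = 0.5
    reg = Network(G=G, types=np.array(["E"] * 6))
    with pytest.raises(DegenerateNetworkError):
        weighted_assortativity(reg)
    # out-star: high-strength hub connects only to leaves -> strongly disassortative
    star = np.zeros((8, 8))
    star[1:, 0] = 0.3
    star_net = Network(G=star, types=np.array(["E"] * 8))
    assert weighted_assortativity(star_net) < 0


def test_assortativity_increases_with_hub_interconnectivity():
    lo, hi = [], []
    for s in range(10):
        lo.append(weighted_assortativity(make_hub_network(600, 0.2, 30.0, 0.1, 0.01, -0.05, seed=s)))
        hi.append(weighted_assortativity(make_hub_network(600, 0.2, 30.0, 0.9, 0.01, -0.05, seed=s)))
    assert np.mean(hi) > np.mean(lo)
    assert all(-1 <= v <= 1 for v in lo + hi)


def test_parameter_validation():
    with pytest.raises(ParameterError):
        make_random(100, 0.2, 1.5, 0.02, -0.1)
    with pytest.raises(ParameterError):
        make_random(-5, 0.2, 0.1, 0.02, -0.1)
    with pytest.raises(ParameterError):
        make_random(100, 0.2, 0.1, -0.02, -0.1)  # wrong sign for w_exc
    with pytest.raises(ParameterError):
        make_patchy(100, 0.2, 0, 0.5, 0.02, -0.1)
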