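"""Closed forms, the motif power series, and spectral predictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hawkesnet import (
    DivergenceError,
    Network,
    ParameterError,
    StabilityError,
    analyse_network,
    average_contributions,
    avg_correlation,
    avg_correlation_closed_form,
    bulk_radius,
    covariance_series_sum,
    equilibrium_rates,
    integrated_covariance,
    make_random,
    mean_input,
    order_for_tolerance,
    population_variance,
    series_terms,
    spectrum_report,
    truncation_bound,
)


def test_rates_no_recurrence_and_single_loop():
    assert np.allclose(equilibrium_rates(np.zeros((2, 2)), 1.0), [1.0, 1.0])
    # one neuron feeding itself with integrated weight 0.5: geometric series 1/(1-g)
    assert np.isclose(equilibrium_rates(np.array([[0.5]]), 1.0)[0], 2.0)


def test_rates_and_covariance_two_neuron_chain(two_neuron_net):
    """Single edge 1->2 of weight 0.5 under unit drive, solved by hand."""
    y = equilibrium_rates(two_neuron_net, 1.0)
    np.testing.assert_allclose(y, [1.0, 1.5])
    C = integrated_covariance(two_neuron_net, y)
    np.testing.assert_allclose(C, [[1.0, 0.5], [0.5, 1.75]])


def test_covariance_of_independent_poisson_is_rate_diagonal():
    C = integrated_covariance(np.zeros((2, 2)), np.array([3.0, 4.0]))
    np.testing.assert_allclose(C, np.diag([3.0, 4.0]))


def test_negative_rates_warn_but_return():
    G = np.array([[0.0, -0.9], [0.0, 0.0]])
    with pytest.warns(UserWarning, match="negative"):
        y = equilibrium_rates(G, np.array([0.1, 1.0]))
    assert y[0] < 0


def test_singular_resolvent_raises_stability_error():
    with pytest.raises(StabilityError, match="eigenvalue"):
        equilibrium_rates(np.array([[1.0]]), 1.0)


def test_scalar_series_partial_sum():
    """Self-loop g=0.5: sum over n+m<=4 is 2*sum_(k<=4)(k+1)0.5^k = 7.125 (full: 8)."""
    G = np.array([[0.5]])
    y = equilibrium_rates(G, 1.0)
    S = covariance_series_sum(G, y, 4)
    assert np.isclose(S[0, 0], 7.125)
    assert np.isclose(integrated_covariance(G, y)[0, 0], 8.0)


def test_series_k0_is_rate_diagonal(small_random_net):
    y = equilibrium_rates(small_random_net)
    terms = series_terms(small_random_net, y, 0)
    assert len(terms) == 1 and terms[0].kind == "rate"
    np.testing.assert_allclose(terms[0].matrix_term, np.diag(y))


def test_series_converges_to_inverse_monotonically(small_random_net):
    """The truncation error of the motif series shrinks monotonically to zero."""
    y = equilibrium_rates(small_random_net)
    C = integrated_covariance(small_random_net, y)
    errs = [
        np.abs(C - covariance_series_sum(small_random_net, y, K)).max() for K in (2, 5, 10, 20)
    ]
    assert all(a >= b for a, b in zip(errs, errs[1:]))
    assert errs[-1] < 1e-3


def test_series_tail_bound_certifies_truncation(small_random_net):
    y = equilibrium_rates(small_random_net)
    rho = float(np.linalg.norm(small_random_net.G, 2))
    K = order_for_tolerance(y, rho, 1e-8)
    C = integrated_covariance(small_random_net, y)
    S = covariance_series_sum(small_random_net, y, K)
    assert np.abs(C - S).max() <= truncation_bound(y, rho, K) + 1e-12


def test_motif_term_transpose_symmetry(small_regular_net):
    y = equilibrium_rates(small_regular_net)
    terms = {(t.n, t.m): t for t in series_terms(small_regular_net, y, 3)}
    for (n, m), t in terms.items():
        np.testing.assert_allclose(t.matrix_term, terms[(m, n)].matrix_term.T, atol=1e-15)
        assert np.isclose(t.avg, terms[(m, n)].avg)
    assert terms[(1, 0)].kind == "chain" and terms[(1, 1)].kind == "common_input"


def test_divergent_series_raises_naming_eigenvalue():
    G = np.array([[0.0, 1.3], [1.3, 0.0]])
    with pytest.raises(DivergenceError, match="1.3"):
        series_terms(G, np.ones(2), 3)


def test_covariance_psd_and_symmetric_on_random_stable_nets():
    """C = (I-G)^-1 Y (I-G^T)^-1 is symmetric PSD whenever rates >= 0."""
    for s in range(20):
        net = make_random(60, 0.2, 0.1, 0.015, -0.06, seed=s)
        res = analyse_network(net)
        if np.any(res.rates < 0):
            continue
        C = res.covariance
        np.testing.assert_allclose(C, C.T, atol=1e-10)
        assert np.linalg.eigvalsh(C).min() > -1e-9


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_series_equals_inverse_on_tiny_random_matrices(seed):
    """Property: high-order partial sums reproduce the inverse formula."""
    rng = np.random.default_rng(seed)
    G = rng.normal(0, 0.08, (5, 5))
    np.fill_diagonal(G, 0)
    if np.max(np.abs(np.linalg.eigvals(G))) >= 0.9:
        return
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y = equilibrium_rates(G, 1.0)
    C = integrated_covariance(G, y)
    S = covariance_series_sum(G, y, 80)
    np.testing.assert_allclose(S, C, atol=1e-8)


def test_average_contributions_zero_graph():
    terms = series_terms(np.zeros((4, 4)), np.ones(4), 3)
    contrib = average_contributions(terms)
    assert np.allclose(contrib.total, 0.0)
    assert np.isclose(contrib.rate_term, 1.0 / 4)


def test_average_contributions_sum_to_avg_correlation(small_regular_net):
    """sum_k A_k equals (sum C - sum y)/N^2 up to the geometric tail."""
    res = analyse_network(small_regular_net)
    terms = series_terms(small_regular_net, res.rates, 30, with_matrices=False)
    contrib = average_contributions(terms)
    assert np.isclose(contrib.sum, res.avg_correlation, rtol=1e-6, atol=1e-12)


def test_closed_form_exact_on_regular_network(small_regular_net):
    p = small_regular_net.meta["params"]["p"]
    res = analyse_network(small_regular_net)
    per_order, c_bar = avg_correlation_closed_form(
        150, small_regular_net.n_excitatory, small_regular_net.n_inhibitory, p, 0.02, -0.1
    )
    assert np.isclose(c_bar, res.avg_correlation, rtol=1e-10)
    contrib = average_contributions(series_terms(small_regular_net, res.rates, 6, with_matrices=False))
    np.testing.assert_allclose(contrib.total, per_order[:6], rtol=1e-10, atol=1e-14)


def test_closed_form_zero_weights_and_divergence():
    _, c_bar = avg_correlation_closed_form(100, 80, 20, 0.1, 0.0, 0.0)
    assert c_bar == 0.0
    with pytest.raises(DivergenceError):
        avg_correlation_closed_form(100, 80, 20, 0.5, 0.5, 0.0)


def test_bulk_radius_reference_scenarios():
    """Cortical-parameter scenarios: dense subnetwork stable, sparse large net not."""
    w_e = 0.019
    assert np.isclose(bulk_radius(0.6, 2000, 500, w_e, -4 * w_e), 0.931, atol=0.001)
    assert np.isclose(bulk_radius(0.1, 12000, 3000, w_e, -4 * w_e), 1.396, atol=0.002)
    assert np.isclose(mean_input(0.1, 12000, 3000, w_e, -4 * w_e), 0.0, atol=1e-12)


def test_spectrum_report_geometry():
    # excitation-dominated regime where the mean-input outlier is well
    # separated from the bulk (mean 0.6 vs B ~ 0.27)
    net = make_random(1000, 0.2, 0.1, 0.02, -0.05, seed=13)
    rep = spectrum_report(net)
    B = rep.predicted_bulk_radius
    ev = rep.eigenvalues
    # the outlier sits near the mean input; the bulk stays inside 1.1 B
    outlier = ev[np.argmax(np.abs(ev.real))]
    assert abs(outlier.real - rep.predicted_mean_outlier) < 0.1 * abs(rep.predicted_mean_outlier)
    bulk = ev[np.abs(ev - outlier) > 1e-9]
    assert np.mean(np.abs(bulk) < 1.1 * B) >= 0.95
    assert rep.stable and rep.series_convergent


def test_zero_weight_spectrum():
    net = make_random(50, 0.2, 0.1, 0.0, 0.0, seed=1)
    rep = spectrum_report(net)
    assert rep.predicted_bulk_radius == 0.0
    assert np.allclose(rep.eigenvalues, 0.0)


def test_population_variance_identities(small_random_net):
    res = analyse_network(small_random_net)
    assert np.isclose(population_variance(res.covariance), res.covariance.sum())
    # v = sum y + N^2 c_bar identity
    n = small_random_net.n_nodes
    assert np.isclose(
        population_variance(res.covariance),
        res.rates.sum() + n**2 * avg_correlation(res.covariance, res.rates),
    )
    with pytest.raises(ParameterError):
        population_variance(res.covariance, np.array([], dtype=int))
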