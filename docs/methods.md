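# Methods

## Model and assumptions

Spike trains are modelled as a multivariate linear (Hawkes-type) point
process: neuron *i* fires as a Poisson process with instantaneous rate

    u_i(t) = y0_i + Σ_j ∫ g_ij(s) dN_j(t − s)

where the causal kernels g_ij integrate to the entries of the matrix `G`
(rows = postsynaptic targets, columns = presynaptic sources; one fixed
orientation used everywhere).  All equilibrium and integrated second-order
statistics depend on the kernels only through their integrals, so delays
and kernel shape are irrelevant to the theory and matter only in
simulation.  The theory treats `u_i` as a signed quantity; the simulator
rectifies at zero before generating spikes.  The model is therefore a
*linear approximation* whose known failure mode is strong inhibition
combined with strong synapses and weak drive, where sub-zero excursions of
`u` are clipped and low rates are over-predicted.

Key quantities (all per second unless noted):

* `y = (I−G)⁻¹ y0` — equilibrium rates; computed by dense solve (the
  package targets N ≤ a few thousand; no sparse path).
* `C = (I−G)⁻¹ Y (I−Gᵀ)⁻¹` — integrated covariance densities, equal to
  spike-count covariance per unit time for counting windows much longer
  than the kernel.
* Average correlation `c̄ = (Σ_ij C_ij − Σ_i y_i)/N²`: the mean over all N²
  ordered pairs with the Poisson rate term of the autocovariances removed.
  This convention makes the population count variance per unit time obey
  `v = Σ_i y_i + N² c̄` exactly, so `c̄` is precisely the correlation part
  of population fluctuations.

## Motif decomposition

`C = Σ_{n,m} Gⁿ Y (Gᵀ)ᵐ` is evaluated two ways: per-term (class-resolved
averages over node pairs, computed from column-sum vectors in O(N²) per
order) and as entrywise partial sums via the recursion
`T_k = G T_{k−1} + Y (Gᵀ)ᵏ` (O(K) matrix products).  Convergence is checked
with the exact spectral radius; the *certificate* for truncation error uses
the operator 2-norm ρ: the tail beyond order K is bounded by
`‖Y‖ Σ_{k>K} (k+1) ρᵏ`, which has the closed form
`‖Y‖ ((K+2)ρ^{K+1} − (K+1)ρ^{K+2})/(1−ρ)²`.  The 2-norm can exceed the
spectral radius, so the certificate is conservative; `order_for_tolerance`
inverts it numerically.

Motif classes: order 0 is the rate term; (n,0) and (0,n) are *chains*
(direct/indirect drive of one neuron by the other); n,m ≥ 1 are *common
input* through a shared, possibly distant, source.  Chain averages scale as
1/N relative to common-input averages, which is why common input dominates
order by order.

For homogeneous random networks (uniform connection probability p) the
averaged contributions have the closed form, with mean input
`Γ = p(N_E w_E + N_I w_I)` and mean common input
`q̄ = p²(N_E w_E² + N_I w_I²)`:

    A_k = y [ (k−1) q̄ Γ^(k−2) + (2/N) Γ^k ],   y = y0/(1−Γ)
    c̄  = y [ q̄/(1−Γ)² + 2Γ/(N(1−Γ)) ]

These expressions are *exact* for networks whose out-degree is fixed per
target population (`make_random(..., fixed_out_degree=True)` draws
round(p·N_E) excitatory plus round(p·N_I) inhibitory targets per source;
exactness requires p·N_X to be integers, which all shipped study conditions
satisfy) and approximate Bernoulli networks with an error that is
systematic (degree-variance driven) and shrinks with N.  Under inhibition
dominance Γ < 0 and the A_k alternate in sign — successive orders partially
cancel, the decorrelating effect of recurrent inhibition.

## Spectrum and stability

For large random E/I networks the eigenvalues of `G` form a circular bulk
of radius `B = sqrt(p(1−p)(N_E w_E² + N_I w_I²))` — the standard deviation
of a neuron's total input — plus one real outlier at the mean input
`p(N_E w_E + N_I w_I)`.  Linear stability requires max Re λ < 1, series
convergence max |λ| < 1; either the mean input or the input *variance* can
destabilise the network, even under exact E/I balance.  At measured
cortical parameters (unitary efficacy 0.019, 20% inhibition, balanced
weights) the formula gives B ≈ 0.931 for a dense subnetwork (N=2500,
p=0.6) and B ≈ 1.40 for a sparse large network (N=15000, p=0.1) — the same
connectivity statistics can sit on either side of the stability line.
`spectrum_report` estimates p and the population weights from the realised
network, so the predictions double as a matched-random-network baseline for
structured architectures.

## Ring analytics

On a ring, ensemble-averaged connectivity depends only on the signed offset
d through the average interaction `h(d) = Σ_X f_X profile_X(d) w_X` and the
common-input profile `q(d) = Σ_X f_X (h_X ∗ h_X)(d)` (convolution shares
the *same* source, so the type enters squared — q ≠ h∗h).  Averaging the
power series over nodes turns matrix products into circular convolutions;
in Fourier space, with homogeneous rate y = y0/(1 − ĥ(0)),

    ĉ_k(ω) = y [ 2 ĥ(ω)ᵏ + (k−1) q̂(ω) ĥ(ω)^(k−2) ]
    ĉ(ω)  = y [ 1 + 2ĥ/(1−ĥ) + q̂/(1−ĥ)² ]

Convergence needs |ĥ(ω)| < 1 at every spatial frequency; the modes that
violate it first are the large-scale oscillatory eigenmodes of locally
excitatory ("hat") rings.  Validation is two-sided: at ω=0 the expressions
reduce exactly to the homogeneous closed form (Parseval), and the curves
are compared against full-matrix computations averaged over generator
seeds.  The analytic pipeline is an *annealed* (ensemble-averaged)
approximation: single realisations fluctuate around it, and a small
systematic bias (growing with coupling strength) remains because paths
sharing intermediate nodes are treated as independent.  Offsets are stored
as length-N circular arrays; geodesic curves are obtained by symmetrising,
and for even N the antipodal offset is counted once.

## Synthetic study conditions (`hawkesnet.regimes`)

There is no external data: every experiment runs on generated networks.
The reference conditions, chosen once on scientific grounds:

* Common to all: 80/20 E/I, exponential kernels τ = 10 ms, delay 1 ms,
  dt = 0.1 ms, inhibition dominance g = |w_I|/w_E = 5 unless balance is the
  point.
* *Asynchronous-irregular reference* (N=1000, p=0.1, w_E=0.02, y0=10/s):
  picked so the simulation reproduces the regime the theory describes —
  rates 5–10 spikes/s, only a few % of neurons with negative predicted
  rates, ISI CV ≈ 1.05.  At much stronger coupling (bulk radius 0.8) the
  same drive puts a quarter of the rate distribution below zero and
  rectification dominates; that regime is deliberately *not* used as the
  reference.
* *Theory-recovery* (N=200, w_E=0.012, y0=20/s, 500 s, 1 s bins): weak
  coupling and strong drive make rectification negligible, so rates match
  within fractions of a percent and the covariance regression slope is
  within a few percent of one.  This isolates simulator correctness from
  the model's rectification bias.
* *Rings* (N=1000, overall connectivity 0.1 per type, local half-width 100
  at height 0.5 vs global 500 at 0.1, w_E=0.005): weak enough that all
  spatial modes satisfy |ĥ| < 1 for both hat and inverted-hat profiles.
* *Variance scaling*: dense balanced regular network (p=0.5, B≈0.7), where
  mean common input is large against the single-neuron variance and the
  quadratic growth of population variance is visible from populations of
  ~10 neurons; versus a strictly local ring (half-width 10), where
  contiguous-arc variance grows linearly.  In sparse nets near instability
  the single-neuron variance term dominates far out and masks the
  quadratic law — a real effect, not an artefact.
* *Hubs* (N=1000, geometric out-degrees with mean 50, hub threshold ⌈μ⌉,
  w_E=0.01): stable across the whole hub-interconnectivity sweep f ∈ [0,1].
  Motif comparisons across f use the homogeneous rate y0/(1−Γ) (Γ is
  f-invariant by construction), which makes the direct and common-input
  terms exactly independent of f; with realised heterogeneous rates every
  term inherits the f-dependence of the rate distribution.
* *Patches* (N=1000, patch sizes 100/200/500 at fixed overall connectivity
  0.1): separated vs mixed type placement.

What the generators deliberately do not emulate: distance-dependent
synaptic weights (only probabilities vary), conduction-delay gradients,
plasticity, non-Poisson single-neuron dynamics, and two-dimensional
geometry.  Passing tests therefore show that *structure-to-correlation
mapping* works as derived, not that the linear Poisson model captures any
particular biological dataset.

## Numerical choices and edge cases

* Dense `solve` everywhere; covariances symmetrised after the double solve
  to remove O(1e−16) roundoff skew.
* Negative predicted rates warn and are kept (the theory is used as-is);
  the simulator's spike-generation capacity is sized from the rectified
  theoretical mean rate and aborts with a diagnostic on runaway activity.
* Simulator: exact per-step decay factor exp(−dt/τ) (not Euler), at most
  one spike per neuron per step (probability u·dt, warned if > 0.1
  anywhere), delays via a ring buffer of pending increments, single global
  delay.  The discrete-time integrated kernel exceeds the nominal weight by
  a factor (dt/τ)/(1−e^(−dt/τ)) ≈ 1 + dt/2τ (0.5% at the defaults).
* Estimator: unbiased sample covariance of binned counts divided by the bin
  width; the bin should be ≥ 20 τ (the finite-window triangular weighting
  otherwise clips covariance tails).  ISI CV needs ≥ 3 spikes, else NaN.
* Generators draw targets without replacement (no multi-edges), exclude
  self-connections, and record realised type counts; ring type assignment
  is Bernoulli per node (counts fluctuate), other generators use exact
  rounded counts at random positions.
* Hub sampler falls back to the full excitatory pool (with a warning) when
  a hub requests more hub targets than exist.
* Weighted assortativity correlates total *signed* strengths (in + out)
  across directed edges, each edge counted once, with symmetric end
  pooling; degenerate (zero-variance) networks raise rather than return 0.

## Known limitations

* The rectification bias is uncontrolled analytically; the package only
  demonstrates empirically where it is negligible.
* The homogeneous closed form carries no finite-N correction for Bernoulli
  degree fluctuations; its systematic error is documented, not modelled.
* The annealed ring analytics share the same limitation for single
  realisations.
* The simulator is time-stepped (Bernoulli thinning per step), not an
  exact event-driven scheme; dt ≤ τ/10 is enforced, and statistics carry
  the O(dt/τ) discretisation factor above.
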