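"""Reference study conditions used by the test-bench and worked examples.

These are the package's canonical parameter sets for the network classes it
analyses.  They are chosen once, on scientific grounds, and shared between
the examples, the test suite and the acceptance bench so that every number
the package reports refers to the same conditions.

Conventions throughout: 80/20 excitatory/inhibitory mix, exponential
kernels with tau = 10 ms and 1 ms delay, inhibition dominance g = |w_I|/w_E
= 5 unless a regime needs exact balance, external drive normalised to give
rates in the 5-20 spikes/s range.
"""

from __future__ import annotations

# Asynchronous-irregular reference network: inhibition-dominated random
# connectivity in the regime where the linear theory predicts nearly all
# rates accurately (only a small sub-zero mass of the intrinsic variable, a
# few % of neurons with negative predicted rates) and single-neuron
# statistics are near-Poisson.  Bulk radius ~ 0.46.
ASYNC_IRREGULAR_NET = dict(n=1000, frac_inhib=0.2, p=0.1, w_exc=0.02, w_inh=-0.1)
ASYNC_IRREGULAR_SIM = dict(duration=110.0, warmup=10.0, dt=0.1, tau=10.0, delay=1.0, y0_rate=10.0)

# Regular (fixed per-population out-degree) counterpart used for the exact
# closed-form comparisons and the motif sign structure; mean input -0.2.
REGULAR_NET = dict(n=500, frac_inhib=0.2, p=0.1, w_exc=0.02, w_inh=-0.1, fixed_out_degree=True)

# Theory-recovery simulation: small network, weak coupling and strong drive
# so that rectification is negligible and the covariance estimator can be
# confronted with the closed form at the percent level.
RECOVERY_NET = dict(n=200, frac_inhib=0.2, p=0.1, w_exc=0.012, w_inh=-0.06)
RECOVERY_SIM = dict(duration=510.0, warmup=10.0, dt=0.1, tau=10.0, delay=1.0, y0_rate=20.0)
RECOVERY_BIN = 1.0  # s; 100 kernel time constants per counting window

# Ring networks, overall connectivity 0.1 for both types; "hat" = local
# excitation (half-width 100 at probability 0.5) with global inhibition,
# "inverted hat" the converse.  Weak weights keep every spatial Fourier
# mode of the average interaction below one.
RING_COMMON = dict(n=1000, frac_inhib=0.2, w_exc=0.005, w_inh=-0.025)
RING_LOCAL = dict(half_width=100, height=0.5)
RING_GLOBAL = dict(half_width=500, height=0.1)

# Population-variance scaling: a dense balanced random network (mean common
# input large against single-neuron variance, so the quadratic term is
# visible from small populations) versus a strictly local ring.
SCALING_RANDOM_NET = dict(
    n=1000, frac_inhib=0.2, p=0.5, w_exc=0.0221, w_inh=-0.0884, fixed_out_degree=True
)
SCALING_RING = dict(n=1000, frac_inhib=0.2, w_exc=0.02, w_inh=-0.08)
SCALING_RING_PROFILE = dict(half_width=10, height=1.0)

# Hub networks: geometric out-degrees with mean 50 (expected hub fraction
# ~ 0.35 above the default threshold), weights weak enough for stability
# across the whole hub-interconnectivity sweep f in [0, 1].
HUB_NET = dict(n=1000, frac_inhib=0.2, mu=50.0, w_exc=0.01, w_inh=-0.05)

# Patchy rings at fixed overall connectivity patch_size * p_patch / N = 0.1.
PATCHY_NET = dict(n=1000, frac_inhib=0.2, w_exc=0.01, w_inh=-0.05)
PATCHY_SIZES = (100, 200, 500)


def patch_probability(patch_size: int, n: int = 1000, total: float = 0.1) -> float:
    """p_patch holding the overall connection probability fixed."""
    return total * n / patch_size
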