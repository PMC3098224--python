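"""Core containers: interaction kernels, connectivity matrices, ring profiles.

A network of linearly interacting point processes is fully specified, as far
as stationary rates and integrated covariances are concerned, by the matrix
``G`` of *integrated* interaction kernels: ``G[i, j]`` is the expected number
of extra spikes in postsynaptic neuron ``i`` caused by one spike of
presynaptic neuron ``j`` (rows = targets, columns = sources).  The time
course of the kernel (shape, time constant, delay) only matters for the
simulator; delays shift kernels in time and leave all integrated quantities
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["KernelSpec", "Network", "RingProfile", "NeuronType"]


class NeuronType(str, Enum):
    """Excitatory or inhibitory presynaptic type."""

    E = "E"
    I = "I"


@dataclass(frozen=True)
class KernelSpec:
    """Causal interaction kernel of one presynaptic population.

    Parameters
    ----------
    weight : float
        Integrated kernel (dimensionless): expected number of extra
        postsynaptic spikes per presynaptic spike.  Positive for excitation,
        negative for inhibition.
    tau : float
        Decay time constant in ms.  The time-resolved kernel is
        ``(weight / tau) * exp(-(t - delay) / tau)`` for ``t >= delay``, so
        its integral equals ``weight``.
    delay : float
        Synaptic delay in ms (zero response before the delay).
    shape : str
        Kernel family; only ``"exponential"`` is implemented.
    """

    weight: float
    tau: float = 10.0
    delay: float = 1.0
    shape: str = "exponential"

    def __post_init__(self) -> None:
        if self.shape != "exponential":
            raise ValueError(f"unsupported kernel shape: {self.shape!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    @property
    def amplitude(self) -> float:
        """Jump of the intrinsic rate per incoming spike, in 1/ms."""
        return self.weight / self.tau


@dataclass(frozen=True)
class RingProfile:
    """Boxcar connection-probability profile on a ring.

    A source connects to targets at geodesic distance ``1..half_width``
    (distance 0 excluded: no self-connections) with probability ``height``,
    and never beyond ``half_width``.  The expected out-connectivity per
    source is ``height * 2 * half_width / N`` up to boundary rounding.
    """

    half_width: int
    height: float

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")
        if not 0.0 <= self.height <= 1.0:
            raise ValueError("height must be a probability in [0, 1]")

    def probabilities(self, n: int) -> np.ndarray:
        """Connection probability at geodesic distances ``0..n//2``."""
        if self.half_width > n // 2:
            raise ValueError(f"half_width {self.half_width} exceeds N/2 = {n // 2}")
        p = np.zeros(n // 2 + 1)
        p[1 : self.half_width + 1] = self.height
        return p


@dataclass
class Network:
    """Weighted directed connectivity of integrated kernels.

    Attributes
    ----------
    G : ndarray, shape (N, N)
        ``G[i, j]`` is the integrated effect of presynaptic ``j`` on
        postsynaptic ``i``.  Columns of excitatory sources are >= 0,
        inhibitory ones <= 0, and the diagonal is zero.
    types : ndarray of str, shape (N,)
        Per-node type, ``"E"`` or ``"I"``.
    positions : ndarray of int or None
        Ring coordinate per node, for spatially structured generators.
    meta : dict
        Generator name, parameter record and seed (provenance).
    """

    G: np.ndarray
    types: np.ndarray
    positions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2 or self.G.shape[0] != self.G.shape[1]:
            raise ValueError("G must be a square matrix")
        self.types = np.asarray(self.types, dtype="U1")
        if self.types.shape != (self.G.shape[0],):
            raise ValueError("types must have one entry per node")
        if not set(np.unique(self.types)) <= {"E", "I"}:
            raise ValueError("types must be 'E' or 'I'")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=int)
            if self.positions.shape != (self.G.shape[0],):
                raise ValueError("positions must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return self.G.shape[0]

    @property
    def n_excitatory(self) -> int:
        return int(np.sum(self.types == "E"))

    @property
    def n_inhibitory(self) -> int:
        return int(np.sum(self.types == "I"))

    @property
    def excitatory(self) -> np.ndarray:
        """Boolean mask of excitatory nodes."""
        return self.types == "E"

    def validate(self) -> None:
        """Check structural invariants (zero diagonal, column sign discipline)."""
        if np.any(np.diag(self.G) != 0):
            raise ValueError("self-connections are not allowed (nonzero diagonal)")
        exc = self.excitatory
        if np.any(self.G[:, exc] < 0):
            raise ValueError("excitatory columns must be non-negative")
        if np.any(self.G[:, ~exc] > 0):
            raise ValueError("inhibitory columns must be non-positive")

    def n_edges(self) -> int:
        return int(np.count_nonzero(self.G))


def ring_distance(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Geodesic ring distance min(|i-j|, N-|i-j|)."""
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n - d)
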