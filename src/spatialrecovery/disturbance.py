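"""Pulse disturbances: one-time biomass removal over part of the system.

A disturbance is described by its spatial extent ``sigma`` (fraction of the
system), local intensity ``rho`` (fraction of biomass removed where it hits),
and overall strength ``s = sigma * rho`` (total fraction of system biomass
removed).  Applied to the uniform equilibrium N = K, the disturbed region is
set to K*(1 - rho).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence

import numpy as np
import scipy.sparse.csgraph

from .model import Domain, GrowthModel, StateField

__all__ = ["Disturbance", "apply_disturbance", "disturbance_grid"]


@dataclass(frozen=True)
class Disturbance:
    """Pulse disturbance of extent sigma and intensity rho (both in (0, 1])."""

    sigma: float
    rho: float
    placement: Literal["centered", "from_edge", "random_contiguous", "site_set"] = "centered"
    sites: Optional[Sequence[int]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.sigma <= 1:
            raise ValueError(f"sigma must be in (0, 1], got {self.sigma}")
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.placement == "site_set" and self.sites is None:
            raise ValueError("placement 'site_set' requires explicit sites")

    @property
    def s(self) -> float:
        """Overall strength: fraction of total system biomass removed."""
        return self.sigma * self.rho

    def region(self, domain: Domain) -> np.ndarray:
        """Indices of the disturbed sites on ``domain``.

        The extent is rounded to whole cells/nodes; on networks a contiguous
        region is grown breadth-first from a seed node.
        """
        n = domain.n_cells
        if self.placement == "site_set":
            return np.asarray(self.sites, dtype=int)
        m = int(round(self.sigma * n))
        m = max(1, min(n, m))
        if domain.kind == "lattice1d":
            if self.placement == "centered":
                start = (n - m) // 2
            elif self.placement == "from_edge":
                start = 0
            else:  # random_contiguous
                rng = np.random.default_rng(self.seed)
                start = int(rng.integers(0, n))
            return (start + np.arange(m)) % n
        # network: BFS ball from a seed node
        if self.placement == "random_contiguous":
            rng = np.random.default_rng(self.seed)
            seed_node = int(rng.integers(0, n))
        else:
            seed_node = 0
        order = scipy.sparse.csgraph.breadth_first_order(
            domain.adjacency, seed_node, directed=False, return_predecessors=False
        )
        if len(order) < m:  # disconnected: pad with remaining nodes
            rest = np.setdiff1d(np.arange(n), order, assume_unique=False)
            order = np.concatenate([order, rest])
        return np.asarray(order[:m], dtype=int)

    def realized_sigma(self, domain: Domain) -> float:
        """Extent after rounding to whole cells."""
        return len(self.region(domain)) / domain.n_cells


def apply_disturbance(
    state_eq: StateField,
    dist: Disturbance,
    domain: Domain,
    growth: GrowthModel,
) -> StateField:
    """Remove a fraction ``rho`` of biomass on the disturbed region.

    ``state_eq`` is expected to be the uniform equilibrium N = K; the
    disturbed sites are set to K*(1 - rho), the rest left untouched.
    """
    K = growth.K
    if not np.allclose(state_eq.N, K, rtol=1e-6):
        raise ValueError("apply_disturbance expects the uniform equilibrium N = K")
    N = state_eq.N.copy()
    N[dist.region(domain)] = K * (1.0 - dist.rho)
    return StateField(N, state_eq.t)


def disturbance_grid(sigmas: Sequence[float], rhos: Sequence[float],
                     **kwargs) -> List[Disturbance]:
    """Cartesian product of extents and intensities, each carrying s = sigma*rho."""
    sigmas = list(sigmas)
    rhos = list(rhos)
    if not sigmas or not rhos:
        raise ValueError("sigma and rho grids must be non-empty")
    return [Disturbance(sg, rh, **kwargs) for sg, rh in itertools.product(sigmas, rhos)]
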