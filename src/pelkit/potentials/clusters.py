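"""Lennard-Jones atomic clusters.

Small LJ clusters are the classic proving ground for global optimisation:
their minima are exhaustively known, so basin-hopping results can be checked
against a census.  Reduced units (ε = σ = 1) by default.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import DegenerateGeometryError
from .base import CartesianSiteModel

__all__ = ["LJCluster"]


class LJCluster(CartesianSiteModel):
    """N-site Lennard-Jones cluster, V = Σ 4ε[(σ/r)¹² − (σ/r)⁶]."""

    def __init__(self, n: int, epsilon: float = 1.0, sigma: float = 1.0):
        if n < 2:
            raise ValueError("an LJ cluster needs at least 2 sites")
        self.n_sites = int(n)
        self.dimension = 3 * self.n_sites
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.name = f"lj{n}"
        self.n_zero_modes = 6
        self.parameters = {"epsilon": self.epsilon, "sigma": self.sigma}
        self.min_separation = 0.2 * self.sigma
        self.identical_sites = True  # all beads interchangeable
        self._iu = np.triu_indices(self.n_sites, k=1)

    def _pair_vectors(self, x):
        pts = x.reshape(self.n_sites, 3)
        rij = pts[self._iu[0]] - pts[self._iu[1]]
        r2 = np.einsum("ij,ij->i", rij, rij)
        return rij, r2

    def energy(self, x):
        _, r2 = self._pair_vectors(np.asarray(x, float))
        s6 = (self.sigma**2 / r2) ** 3
        return float(np.sum(4.0 * self.epsilon * (s6 * s6 - s6)))

    def gradient(self, x):
        return self.energy_gradient(np.asarray(x, float), validate=False)[1]

    def energy_gradient(self, x, validate: bool = True):
        x = np.asarray(x, dtype=float).ravel()
        if validate and (
            x.size != self.dimension or not np.all(np.isfinite(x))
        ):
            self.validate(x)  # raises with a precise message
        rij, r2 = self._pair_vectors(x)
        if validate and r2.min() < self.min_separation**2:
            raise DegenerateGeometryError(
                f"{self.name}: coincident sites "
                f"(separation {np.sqrt(r2.min()):.2e})"
            )
        s6 = (self.sigma**2 / r2) ** 3
        s12 = s6 * s6
        e = float(np.sum(4.0 * self.epsilon * (s12 - s6)))
        coeff = 24.0 * self.epsilon * (s6 - 2.0 * s12) / r2
        forces = coeff[:, None] * rij
        grad = np.zeros((self.n_sites, 3))
        np.add.at(grad, self._iu[0], forces)
        np.add.at(grad, self._iu[1], -forces)
        return e, grad.ravel()
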