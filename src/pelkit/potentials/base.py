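"""The potential-energy contract shared by every model in the toolkit.

All downstream machinery (minimisation, transition-state search, network
assembly) talks to a :class:`PotentialModel` exclusively through ``energy``,
``gradient`` and ``hessian``.  Units are kcal/mol for energies and Å for
coordinates throughout; analytic benchmark surfaces use their conventional
dimensionless units.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from ..exceptions import (
    ContractViolation,
    DegenerateGeometryError,
    PotentialEvaluationError,
)

__all__ = [
    "PotentialModel",
    "CartesianSiteModel",
    "ExternalPotential",
    "energy_gradient",
    "external_adapter",
]

FD_HESSIAN_STEP = 1e-4  # default finite-difference step, model units


class PotentialModel(ABC):
    """Energy/gradient contract for a potential-energy surface.

    Attributes
    ----------
    name : str
        Identifier used in provenance logs and database manifests.
    dimension : int
        Number of coordinates.
    n_zero_modes : int
        Count of invariant motions (overall translation/rotation) to project
        out of Hessian spectra and convergence tests.
    parameters : object
        Opaque parameter block (may be ``None``).
    """

    name: str = "potential"
    dimension: int = 0
    n_zero_modes: int = 0
    parameters: object = None

    # -- contract -----------------------------------------------------------
    @abstractmethod
    def energy(self, x: np.ndarray) -> float:
        """Potential energy V(x)."""

    def gradient(self, x: np.ndarray) -> np.ndarray:
        """∇V(x); default is centred finite differences of :meth:`energy`."""
        x = np.asarray(x, dtype=float)
        h = FD_HESSIAN_STEP
        g = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            g[i] = (self.energy(xp) - self.energy(xm)) / (2 * h)
        return g

    def energy_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = self._check(x)
        return self.energy(x), self.gradient(x)

    def hessian(self, x: np.ndarray) -> np.ndarray:
        """Hessian by centred finite differences of the gradient.

        Models with an analytic Hessian override this.  The returned matrix
        is symmetrised.
        """
        x = np.asarray(x, dtype=float)
        h = FD_HESSIAN_STEP
        n = x.size
        hess = np.empty((n, n))
        for i in range(n):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            hess[i] = (self.gradient(xp) - self.gradient(xm)) / (2 * h)
        return 0.5 * (hess + hess.T)

    # -- validation and invariant motions -----------------------------------
    def validate(self, x: np.ndarray) -> None:
        """Raise if ``x`` is not an acceptable configuration."""
        x = np.asarray(x, dtype=float)
        if x.ravel().size != self.dimension:
            raise ContractViolation(
                f"{self.name}: expected dimension {self.dimension}, "
                f"got {x.ravel().size}"
            )
        if not np.all(np.isfinite(x)):
            raise DegenerateGeometryError(f"{self.name}: non-finite coordinates")

    def _check(self, x: np.ndarray) -> np.ndarray:
        self.validate(x)
        return np.asarray(x, dtype=float).ravel()

    def zero_mode_basis(self, x: np.ndarray) -> np.ndarray:
        """Orthonormal basis (k, n) of invariant motions at ``x``; may be empty."""
        return np.zeros((0, self.dimension))

    def project_zero_modes(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Remove components of vector ``v`` along the invariant motions at ``x``."""
        basis = self.zero_mode_basis(x)
        if basis.shape[0] == 0:
            return v
        return v - basis.T @ (basis @ v)

    def projected_hessian(self, x: np.ndarray) -> np.ndarray:
        """Hessian with zero modes shifted far up the spectrum.

        The invariant subspace is assigned a large positive eigenvalue so it
        can never masquerade as the softest or a negative mode.
        """
        hess = self.hessian(x)
        basis = self.zero_mode_basis(x)
        if basis.shape[0] == 0:
            return hess
        p = np.eye(self.dimension) - basis.T @ basis
        shift = 1e6 * max(1.0, float(np.abs(hess).max()))
        return p @ hess @ p + shift * (basis.T @ basis)


class CartesianSiteModel(PotentialModel):
    """Base for models whose coordinates are 3-D interaction sites.

    Provides rigid-body zero modes (3 translations + 3 rotations) and a
    minimum-separation validity check.
    """

    n_sites: int = 0
    min_separation: float = 1e-3  # Å; coincident-site threshold

    @property
    def sites_shape(self):
        return (self.n_sites, 3)

    def sites(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float).reshape(self.n_sites, 3)

    def validate(self, x: np.ndarray) -> None:
        super().validate(x)
        pts = self.sites(np.asarray(x))
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if d2.min() < self.min_separation**2:
            i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
            raise DegenerateGeometryError(
                f"{self.name}: sites {i} and {j} are coincident "
                f"(separation {np.sqrt(d2.min()):.2e} Å)"
            )

    def zero_mode_basis(self, x: np.ndarray) -> np.ndarray:
        pts = self.sites(np.asarray(x))
        n = self.n_sites
        centred = pts - pts.mean(axis=0)
        modes = []
        for axis in range(3):  # translations
            m = np.zeros((n, 3))
            m[:, axis] = 1.0
            modes.append(m.ravel())
        for axis in range(3):  # infinitesimal rotations
            e = np.zeros(3)
            e[axis] = 1.0
            modes.append(np.cross(centred, e).ravel())
        basis = np.array(modes)
        # orthonormalise, dropping null rotations (e.g. collinear configs)
        q, r = np.linalg.qr(basis.T)
        keep = np.abs(np.diag(r)) > 1e-10
        return q.T[keep]


class ExternalPotential(PotentialModel):
    """Adapter wrapping external energy/gradient callbacks.

    Lets downstream machinery drive any external engine (an all-atom force
    field with an implicit-solvent term, for instance) through the standard
    contract.  When no gradient callback is supplied, a centred
    finite-difference gradient of the energy callback is used.
    """

    def __init__(
        self,
        energy_fn,
        gradient_fn=None,
        dimension: int = 0,
        name: str = "external",
        n_zero_modes: int = 0,
        fd_step: float = 1e-6,
    ):
        if dimension < 1:
            raise ContractViolation("external adapter needs dimension >= 1")
        self.name = name
        self.dimension = int(dimension)
        self.n_zero_modes = int(n_zero_modes)
        self._energy_fn = energy_fn
        self._gradient_fn = gradient_fn
        self._fd_step = float(fd_step)
        self.parameters = None

    def _call(self, fn, x):
        try:
            return fn(x)
        except Exception as exc:  # propagate with the configuration attached
            raise PotentialEvaluationError(
                f"{self.name}: callback raised {exc!r}", configuration=np.array(x)
            ) from exc

    def energy(self, x):
        return float(self._call(self._energy_fn, np.asarray(x, dtype=float)))

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        if self._gradient_fn is not None:
            return np.asarray(self._call(self._gradient_fn, x), dtype=float)
        h = self._fd_step
        g = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            g[i] = (self.energy(xp) - self.energy(xm)) / (2 * h)
        return g


def external_adapter(
    energy_fn, gradient_fn=None, dimension: int = 0, **kwargs
) -> ExternalPotential:
    """Wrap external callbacks behind the :class:`PotentialModel` contract."""
    return ExternalPotential(energy_fn, gradient_fn, dimension, **kwargs)


def energy_gradient(model: PotentialModel, x: np.ndarray):
    """Evaluate ``(V(x), ∇V(x))`` for any model honouring the contract."""
    return model.energy_gradient(x)
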