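"""Local minimisation and basin-hopping global optimisation.

Basin-hopping transforms the landscape into the staircase of catchment-basin
energies: each step perturbs the coordinates, minimises, and applies a
Metropolis test on the *minimised* energies.  The minima it discovers seed
the kinetic transition network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .exceptions import ConvergenceError, DegenerateGeometryError
from .geometry import align_rmsd
from .potentials import CartesianSiteModel, PotentialModel

__all__ = ["Minimum", "BasinHoppingConfig", "local_minimise", "basin_hop"]

logger = logging.getLogger(__name__)

DEFAULT_GRAD_RMS_TOL = 1e-6  # kcal/mol/Å, database-grade convergence


@dataclass
class Minimum:
    """A converged local minimum of the landscape."""

    energy: float
    coordinates: np.ndarray
    gradient_rms: float
    id: int | None = None
    discovery_count: int = 1

    def __repr__(self):
        return (
            f"Minimum(id={self.id}, E={self.energy:.6f}, "
            f"grms={self.gradient_rms:.2e})"
        )


@dataclass
class BasinHoppingConfig:
    """Hyperparameters of a basin-hopping run.

    ``temperature`` is the Metropolis temperature in kcal/mol (i.e. kT);
    ``step_size`` the half-width (Å) of the uniform coordinate displacement,
    adaptively rescaled towards ~50% acceptance when ``adaptive_step``.
    """

    n_steps: int = 500
    temperature: float = 1.0
    step_size: float = 0.4
    adaptive_step: bool = True
    rng_seed: int = 0
    minimiser_tol: float = DEFAULT_GRAD_RMS_TOL
    target_acceptance: float = 0.5
    dedup_energy_tol: float = 1e-5
    dedup_distance_tol: float = 0.1

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def _grad_rms(model: PotentialModel, x: np.ndarray, g: np.ndarray) -> float:
    g = model.project_zero_modes(x, g)
    return float(np.sqrt(np.mean(g**2)))


def local_minimise(
    model: PotentialModel,
    x0: np.ndarray,
    tol: float = DEFAULT_GRAD_RMS_TOL,
    max_iter: int = 10_000,
) -> Minimum:
    """Quasi-Newton descent to the nearest local minimum.

    L-BFGS-B followed, if needed, by Newton polishing on the projected
    Hessian to reach a gradient RMS ≤ ``tol`` (zero modes of cluster/chain
    models are projected out of the convergence test).

    Raises
    ------
    ConvergenceError
        If the tolerance is not reached; carries the trajectory tail.
    DegenerateGeometryError
        If the energy turns non-finite.
    """
    model.validate(x0)
    x0 = np.asarray(x0, dtype=float).ravel()

    def fg(x):
        # a line-search trial may transiently produce a degenerate geometry;
        # present it as an enormous-energy wall so the search backtracks
        try:
            e, g = model.energy_gradient(x)
        except DegenerateGeometryError:
            return 1e12, np.zeros_like(x)
        if not np.isfinite(e):
            raise DegenerateGeometryError("NaN/inf energy during minimisation")
        return e, g

    res = scipy_minimize(
        fg,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 0.3 * tol, "ftol": 1e-14},
    )
    x = res.x
    e, g = fg(x)
    rms = _grad_rms(model, x, g)

    # Newton polish on the projected Hessian for database-grade convergence
    tail = [x.copy()]
    for _ in range(30):
        if rms <= tol:
            break
        hess = model.projected_hessian(x)
        evals, evecs = np.linalg.eigh(hess)
        gproj = evecs.T @ model.project_zero_modes(x, g)
        safe = np.where(np.abs(evals) > 1e-10, evals, np.inf)
        if np.any(evals < -1e-8):  # not in a convex region: fall back
            step = -0.1 * model.project_zero_modes(x, g)
        else:
            step = -(evecs @ (gproj / safe))
        norm = np.linalg.norm(step)
        if norm > 0.5:
            step *= 0.5 / norm
        x_new = x + step
        e_new, g_new = fg(x_new)
        if not np.isfinite(e_new):
            break
        x, e, g = x_new, e_new, g_new
        rms = _grad_rms(model, x, g)
        tail.append(x.copy())
        if len(tail) > 8:
            tail.pop(0)
    if rms > tol:
        raise ConvergenceError(
            f"local minimisation stalled at gradient RMS {rms:.3e} > {tol:.1e}",
            trajectory_tail=tail,
        )
    e0 = model.energy(x0)
    if e > e0 + 1e-9:
        raise ConvergenceError(
            f"minimiser raised the energy ({e0:.6f} -> {e:.6f})", trajectory_tail=tail
        )
    return Minimum(energy=e, coordinates=x, gradient_rms=rms)


def _distance_fingerprint(model, x: np.ndarray) -> np.ndarray:
    pts = x.reshape(model.n_sites, 3)
    iu = np.triu_indices(model.n_sites, k=1)
    return np.sort(
        np.linalg.norm(pts[iu[0]] - pts[iu[1]], axis=1)
    )


def _same_minimum(
    model: PotentialModel, a: Minimum, b: Minimum, e_tol: float, d_tol: float
) -> bool:
    if abs(a.energy - b.energy) > e_tol:
        return False
    if isinstance(model, CartesianSiteModel) and model.n_sites >= 3:
        if getattr(model, "identical_sites", False):
            # permutation- and rotation-invariant structural fingerprint
            return bool(
                np.max(
                    np.abs(
                        _distance_fingerprint(model, a.coordinates)
                        - _distance_fingerprint(model, b.coordinates)
                    )
                )
                <= d_tol
            )
        return align_rmsd(a.coordinates, b.coordinates).rmsd <= d_tol
    return bool(
        np.linalg.norm(a.coordinates - b.coordinates)
        / np.sqrt(a.coordinates.size)
        <= d_tol
    )


def basin_hop(
    model: PotentialModel,
    x0: np.ndarray,
    config: BasinHoppingConfig,
    trace_out: list | None = None,
) -> list[Minimum]:
    """Basin-hopping global optimisation.

    Iterates perturb → minimise → Metropolis accept/reject on minimum
    energies; the walk continues from accepted minima.  Returns the
    deduplicated minima found, sorted by energy, and is fully reproducible
    for a given ``config.rng_seed``.  ``trace_out``, if given, collects one
    ``(trial_energy, accepted, current_energy)`` record per step.
    """
    rng = np.random.default_rng(config.rng_seed)
    step = float(config.step_size)
    min_step = 1e-4 * config.step_size

    current = local_minimise(model, x0, tol=config.minimiser_tol)
    found: list[Minimum] = [current]
    n_accept = 0
    stalled = False

    for it in range(config.n_steps):
        disp = rng.uniform(-step, step, size=model.dimension)
        trial_x = current.coordinates + disp
        try:
            trial = local_minimise(model, trial_x, tol=config.minimiser_tol)
        except (ConvergenceError, DegenerateGeometryError):
            continue

        de = trial.energy - current.energy
        accept = de <= 0 or rng.random() < np.exp(-de / config.temperature)
        if trace_out is not None:
            trace_out.append((trial.energy, accept, current.energy))
        if accept:
            n_accept += 1
            current = trial

        known = None
        for m in found:
            if _same_minimum(
                model, m, trial, config.dedup_energy_tol, config.dedup_distance_tol
            ):
                known = m
                break
        if known is None:
            found.append(trial)
        else:
            known.discovery_count += 1
            if accept:
                current = known

        if config.adaptive_step and (it + 1) % 50 == 0:
            rate = n_accept / (it + 1)
            factor = 1.05 if rate > config.target_acceptance else 1 / 1.05
            step = max(step * factor, min_step)
            if step == min_step and rate == 0:
                stalled = True
                break

    if stalled:
        warnings.warn(
            "basin-hopping: all moves rejected at the floored step size; "
            "returning partial result",
            RuntimeWarning,
            stacklevel=2,
        )
    found.sort(key=lambda m: m.energy)
    for i, m in enumerate(found):
        m.id = i
    return found
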