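"""Transition-state location: band interpolation, DNEB, hybrid EF refinement.

The pipeline mirrors standard landscape practice: a (doubly) nudged elastic
band between two minima yields saddle candidates at interior band maxima;
each candidate is refined to a true first-order saddle by hybrid
eigenvector-following (uphill along the lowest Hessian eigenvector,
minimisation in the orthogonal subspace); downhill descents from the saddle
identify the two minima it connects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    ConvergenceError,
    DegenerateGeometryError,
    HigherOrderSaddleError,
    InterpolationError,
    RejectedCandidateError,
)
from .optim import DEFAULT_GRAD_RMS_TOL, Minimum, local_minimise
from .potentials import CartesianSiteModel, PotentialModel

__all__ = [
    "TransitionState",
    "BandConfig",
    "interpolate",
    "dneb",
    "hybrid_ef_refine",
    "descend_from_ts",
]

logger = logging.getLogger(__name__)


@dataclass
class TransitionState:
    """A converged first-order saddle point.

    ``minus_min_id``/``plus_min_id`` are filled once downhill descents have
    identified the connected minima (see :func:`descend_from_ts`).
    """

    energy: float
    coordinates: np.ndarray
    lowest_eigenvalue: float
    eigenvector: np.ndarray
    gradient_rms: float
    id: int | None = None
    minus_min_id: int | None = None
    plus_min_id: int | None = None

    def __repr__(self):
        return (
            f"TransitionState(id={self.id}, E={self.energy:.6f}, "
            f"lambda={self.lowest_eigenvalue:.4g}, "
            f"minus={self.minus_min_id}, plus={self.plus_min_id})"
        )


@dataclass
class BandConfig:
    """Elastic-band settings.

    ``spring_k`` in (kcal/mol)/Å²; ``dneb`` switches the doubly nudged
    spring-force correction on; ``grad_rms_tol`` is the per-image RMS force
    threshold for band convergence.
    """

    n_images: int = 11
    spring_k: float = 10.0
    dneb: bool = True
    interpolation: str = "linear-clash-repair"
    grad_rms_tol: float = 1e-3
    max_iterations: int = 2000

    def __post_init__(self):
        if self.n_images < 3:
            raise ValueError("a band needs at least 3 images")


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def interpolate(
    x_a: np.ndarray,
    x_b: np.ndarray,
    n_images: int,
    scheme: str = "linear-clash-repair",
    model: PotentialModel | None = None,
    min_separation: float | None = None,
) -> np.ndarray:
    """Band of ``n_images`` configurations between two endpoints (inclusive).

    Linear Cartesian interpolation; for site-based models a repair pass
    displaces clashing sites in interior images until no pair is closer than
    ``min_separation`` (default 0.5·σ-like scale from the model, else 0.5 Å).

    Raises
    ------
    InterpolationError
        If a clash cannot be repaired; names the offending image.
    """
    x_a = np.asarray(x_a, dtype=float).ravel()
    x_b = np.asarray(x_b, dtype=float).ravel()
    if x_a.size != x_b.size:
        raise ValueError("endpoints differ in dimension")
    ts = np.linspace(0.0, 1.0, n_images)
    band = np.array([(1 - t) * x_a + t * x_b for t in ts])

    if scheme not in ("linear", "linear-clash-repair"):
        raise ValueError(f"unknown interpolation scheme {scheme!r}")
    if scheme == "linear" or not isinstance(model, CartesianSiteModel):
        return band

    if min_separation is None:
        sigma = getattr(model, "sigma", None)
        min_separation = 0.5 * sigma if sigma else 0.5
    for idx in range(1, n_images - 1):
        pts = band[idx].reshape(model.n_sites, 3)
        for _ in range(200):
            diff = pts[:, None, :] - pts[None, :, :]
            d = np.sqrt(np.sum(diff**2, axis=-1))
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(int(np.argmin(d)), d.shape)
            if d[i, j] >= min_separation:
                break
            # push the offending pair apart symmetrically
            v = pts[i] - pts[j]
            norm = np.linalg.norm(v)
            if norm < 1e-10:  # coincident: separate along a fixed axis
                v, norm = np.array([1.0, 0.0, 0.0]), 1.0
            shift = 0.5 * (min_separation - d[i, j] + 0.05) * v / norm
            pts[i] += shift
            pts[j] -= shift
        else:
            raise InterpolationError(
                f"unrepairable steric clash in band image {idx}", image=idx
            )
        band[idx] = pts.ravel()
    return band


# ---------------------------------------------------------------------------
# doubly nudged elastic band
# ---------------------------------------------------------------------------

def _band_tangents(band: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Energy-weighted upwind tangents (Henkelman's improved tangent)."""
    n = len(band)
    tangents = np.zeros_like(band)
    for i in range(1, n - 1):
        tp = band[i + 1] - band[i]
        tm = band[i] - band[i - 1]
        ep, e0, em = energies[i + 1], energies[i], energies[i - 1]
        if ep > e0 > em:
            tau = tp
        elif ep < e0 < em:
            tau = tm
        else:
            dmax = max(abs(ep - e0), abs(em - e0))
            dmin = min(abs(ep - e0), abs(em - e0))
            tau = tp * dmax + tm * dmin if ep > em else tp * dmin + tm * dmax
        norm = np.linalg.norm(tau)
        tangents[i] = tau / norm if norm > 1e-14 else tau
    return tangents


def _band_forces(
    model: PotentialModel, band: np.ndarray, config: BandConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Return (forces, energies); forces vanish on the fixed endpoints."""
    n = len(band)
    energies = np.empty(n)
    grads = np.empty_like(band)
    for i in range(n):
        energies[i], grads[i] = model.energy_gradient(band[i])
    tangents = _band_tangents(band, energies)
    forces = np.zeros_like(band)
    k = config.spring_k
    for i in range(1, n - 1):
        tau = tangents[i]
        g_perp = grads[i] - (grads[i] @ tau) * tau
        # parallel spring force
        f_spring_par = (
            k
            * (
                np.linalg.norm(band[i + 1] - band[i])
                - np.linalg.norm(band[i] - band[i - 1])
            )
            * tau
        )
        force = -g_perp + f_spring_par
        if config.dneb:
            # doubly nudged: retain the part of the perpendicular spring
            # force orthogonal to the perpendicular true gradient
            f_spring = k * ((band[i + 1] - band[i]) - (band[i] - band[i - 1]))
            f_spring_perp = f_spring - (f_spring @ tau) * tau
            gnorm = np.linalg.norm(g_perp)
            if gnorm > 1e-14:
                ghat = g_perp / gnorm
                f_spring_perp = f_spring_perp - (f_spring_perp @ ghat) * ghat
            force = force + f_spring_perp
        forces[i] = force
    return forces, energies


def _fire_relax(model, band, config):
    """FIRE relaxation of the interior band images."""
    dt, dt_max = 0.02, 0.2
    alpha0, alpha = 0.1, 0.1
    n_min, f_inc, f_dec, f_alpha = 5, 1.1, 0.5, 0.99
    v = np.zeros_like(band)
    steps_since_neg = 0
    forces, energies = _band_forces(model, band, config)
    for _ in range(config.max_iterations):
        rms = np.sqrt(
            np.mean(forces[1:-1] ** 2, axis=1)
        )  # per interior image
        if rms.max() <= config.grad_rms_tol:
            return band, energies, True
        p = float(np.sum(forces * v))
        if p > 0:
            steps_since_neg += 1
            if steps_since_neg > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
            vn = np.linalg.norm(v)
            fn = np.linalg.norm(forces)
            if fn > 1e-14:
                v = (1 - alpha) * v + alpha * vn * forces / fn
        else:
            steps_since_neg = 0
            dt *= f_dec
            alpha = alpha0
            v[:] = 0.0
        v += dt * forces
        band = band + dt * v
        band[0] = band[0]  # endpoints carry zero force by construction
        forces, energies = _band_forces(model, band, config)
    return band, energies, False


def dneb(
    model: PotentialModel,
    min_a: Minimum | np.ndarray,
    min_b: Minimum | np.ndarray,
    config: BandConfig | None = None,
) -> list[np.ndarray]:
    """Doubly nudged elastic band between two minima.

    Returns the interior images that are local energy maxima along the
    relaxed band — the transition-state candidates.  An unconverged band
    still returns its best candidates (flagged via a log warning).
    """
    config = config or BandConfig()
    x_a = min_a.coordinates if isinstance(min_a, Minimum) else np.asarray(min_a, float)
    x_b = min_b.coordinates if isinstance(min_b, Minimum) else np.asarray(min_b, float)
    if np.allclose(x_a, x_b, atol=1e-10):
        return []
    band = interpolate(
        x_a, x_b, config.n_images, scheme=config.interpolation, model=model
    )
    band, energies, converged = _fire_relax(model, band, config)
    if not converged:
        logger.warning(
            "DNEB band not converged in %d iterations; returning best candidates",
            config.max_iterations,
        )
    candidates = [
        band[i].copy()
        for i in range(1, len(band) - 1)
        if energies[i] > energies[i - 1] and energies[i] > energies[i + 1]
    ]
    return candidates


# ---------------------------------------------------------------------------
# hybrid eigenvector-following refinement
# ---------------------------------------------------------------------------

def _lowest_eigenpair(model: PotentialModel, x: np.ndarray):
    hess = model.projected_hessian(x)
    evals, evecs = np.linalg.eigh(hess)
    return evals, evecs


def hybrid_ef_refine(
    model: PotentialModel,
    x_guess: np.ndarray,
    tol: float = DEFAULT_GRAD_RMS_TOL,
    max_iter: int = 200,
    trust_radius: float = 0.3,
) -> TransitionState:
    """Refine a saddle candidate to a first-order transition state.

    Eigenvector-following steps: Newton in all modes with the sign of the
    step along the lowest eigenvector reversed, so the search walks uphill
    along the softest mode and downhill in the orthogonal subspace.  While
    the lowest eigenvalue is still positive, small uphill displacements
    along that eigenvector push the search out of the convex region.

    Raises
    ------
    RejectedCandidateError
        Converged to a stationary point with no negative eigenvalue.
    HigherOrderSaddleError
        More than one negative eigenvalue persists at convergence.
    ConvergenceError
        Gradient RMS did not fall below ``tol``.
    """
    model.validate(x_guess)
    x = np.asarray(x_guess, dtype=float).ravel().copy()
    tail = []
    for _ in range(max_iter):
        g = model.project_zero_modes(x, model.gradient(x))
        rms = float(np.sqrt(np.mean(g**2)))
        evals, evecs = _lowest_eigenpair(model, x)
        if rms <= tol:
            n_neg = int(np.sum(evals < -1e-8))
            if n_neg == 0:
                raise RejectedCandidateError(
                    f"candidate converged to a minimum (E={model.energy(x):.6f})"
                )
            if n_neg > 1:
                raise HigherOrderSaddleError(
                    f"{n_neg} negative eigenvalues persist at convergence"
                )
            e = model.energy(x)
            return TransitionState(
                energy=e,
                coordinates=x,
                lowest_eigenvalue=float(evals[0]),
                eigenvector=evecs[:, 0],
                gradient_rms=rms,
            )
        if evals[0] > -1e-8:
            # still in a convex region: walk uphill along the softest mode
            v = evecs[:, 0]
            sgn = np.sign(g @ v) or 1.0
            step = 0.5 * trust_radius * sgn * v
        else:
            coeffs = evecs.T @ g
            safe = np.where(np.abs(evals) > 1e-8, np.abs(evals), 1e-8)
            step_coeffs = -coeffs / safe
            step_coeffs[0] = -step_coeffs[0]  # reverse along the lowest mode
            # Newton step: -c_i/λ_i, i.e. uphill where λ<0 handled by |λ| + flip
            step_coeffs = np.sign(step_coeffs) * np.minimum(
                np.abs(step_coeffs), trust_radius
            )
            step = evecs @ step_coeffs
        norm = np.linalg.norm(step)
        if norm > trust_radius:
            step *= trust_radius / norm
        x = x + step
        tail.append(x.copy())
        if len(tail) > 8:
            tail.pop(0)
    raise ConvergenceError(
        f"hybrid EF did not converge below RMS {tol:.1e} in {max_iter} steps",
        trajectory_tail=tail,
    )


def descend_from_ts(
    model: PotentialModel,
    ts: TransitionState,
    displacement: float = 0.05,
    tol: float = DEFAULT_GRAD_RMS_TOL,
    max_retries: int = 4,
) -> tuple[Minimum, Minimum]:
    """Steepest-descent paths from a saddle to its two connected minima.

    Perturbs ±``displacement`` along the negative eigenvector and minimises
    both sides; the displacement is doubled on descent failure, up to
    ``max_retries`` times.  The two minima may coincide (degenerate
    rearrangement).
    """
    def steepest_descent_phase(x, max_steps=400, max_move=0.1):
        """Small-step steepest descent so the path cannot hop over a
        shallow intermediate basin before the quasi-Newton polish."""
        e = model.energy(x)
        alpha = 0.5 * max_move
        for _ in range(max_steps):
            g = model.project_zero_modes(x, model.gradient(x))
            gnorm = np.linalg.norm(g)
            if gnorm < 1e-8:
                break
            step = -min(alpha, max_move / gnorm) * g
            x_new = x + step
            try:
                e_new = model.energy(x_new)
            except DegenerateGeometryError:
                alpha *= 0.5
                continue
            if e_new < e:
                x, e = x_new, e_new
                alpha = min(alpha * 1.2, max_move)
            else:
                alpha *= 0.5
                if alpha < 1e-8:
                    break
        return x

    results = []
    for sign, side in ((-1.0, "minus"), (+1.0, "plus")):
        d = displacement
        last_exc = None
        for _ in range(max_retries + 1):
            try:
                x_start = steepest_descent_phase(
                    ts.coordinates + sign * d * ts.eigenvector
                )
                m = local_minimise(model, x_start, tol=tol)
                break
            except (ConvergenceError, DegenerateGeometryError) as exc:
                last_exc = exc
                d *= 2.0
        else:
            raise ConvergenceError(
                f"descent from TS failed on the {side} side "
                f"(last displacement {d / 2:.3g}): {last_exc}"
            )
        results.append(m)
    return results[0], results[1]
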