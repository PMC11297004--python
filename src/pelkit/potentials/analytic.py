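"""Analytic benchmark surfaces with known stationary points.

These low-dimensional surfaces exercise every landscape algorithm against
independently verifiable answers: the Müller–Brown surface has exactly three
minima and two first-order saddles, the quadratic bowl has a single minimum,
and the one-dimensional double well x⁴ − x² has minima at ±1/√2 and a saddle
at the origin.
"""

from __future__ import annotations

import numpy as np

from .base import PotentialModel

__all__ = ["MuellerBrown", "QuadraticBowl", "DoubleWell1D", "PiecewiseTwoWells"]


class MuellerBrown(PotentialModel):
    """The Müller–Brown four-Gaussian surface (standard constants).

    V(x, y) = Σ_k A_k exp(a_k (x−x_k)² + b_k (x−x_k)(y−y_k) + c_k (y−y_k)²)
    """

    name = "mueller-brown"
    dimension = 2
    n_zero_modes = 0

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, x):
        dx = x[0] - self.x0
        dy = x[1] - self.y0
        expo = self.a * dx**2 + self.b * dx * dy + self.c * dy**2
        # cap the exponent far outside the region of interest so stray
        # basin-hopping moves cannot overflow; the surface stays smooth and
        # strongly repulsive there
        return self.A * np.exp(np.minimum(expo, 200.0)), dx, dy

    def energy(self, x):
        x = np.asarray(x, dtype=float).ravel()
        t, _, _ = self._terms(x)
        return float(t.sum())

    def gradient(self, x):
        x = np.asarray(x, dtype=float).ravel()
        t, dx, dy = self._terms(x)
        gx = np.sum(t * (2 * self.a * dx + self.b * dy))
        gy = np.sum(t * (self.b * dx + 2 * self.c * dy))
        return np.array([gx, gy])

    def hessian(self, x):
        x = np.asarray(x, dtype=float).ravel()
        t, dx, dy = self._terms(x)
        u = 2 * self.a * dx + self.b * dy
        v = self.b * dx + 2 * self.c * dy
        hxx = np.sum(t * (u**2 + 2 * self.a))
        hxy = np.sum(t * (u * v + self.b))
        hyy = np.sum(t * (v**2 + 2 * self.c))
        return np.array([[hxx, hxy], [hxy, hyy]])


class QuadraticBowl(PotentialModel):
    """Convex bowl V = ½ k |x − x₀|²; single minimum at ``centre``."""

    name = "quadratic-bowl"
    n_zero_modes = 0

    def __init__(self, dimension: int = 2, k: float = 1.0, centre=None):
        self.dimension = int(dimension)
        self.k = float(k)
        self.centre = (
            np.zeros(dimension) if centre is None else np.asarray(centre, float)
        )
        self.parameters = {"k": self.k}

    def energy(self, x):
        d = np.asarray(x, float).ravel() - self.centre
        return float(0.5 * self.k * d @ d)

    def gradient(self, x):
        return self.k * (np.asarray(x, float).ravel() - self.centre)

    def hessian(self, x):
        return self.k * np.eye(self.dimension)


class DoubleWell1D(PotentialModel):
    """V(x) = x⁴ − x²; minima at ±1/√2 (V = −¼), saddle at 0 (V = 0)."""

    name = "double-well-1d"
    dimension = 1
    n_zero_modes = 0

    def energy(self, x):
        x = float(np.asarray(x).ravel()[0])
        return x**4 - x**2

    def gradient(self, x):
        x = float(np.asarray(x).ravel()[0])
        return np.array([4 * x**3 - 2 * x])

    def hessian(self, x):
        x = float(np.asarray(x).ravel()[0])
        return np.array([[12 * x**2 - 2]])


class PiecewiseTwoWells(PotentialModel):
    """Two parabolic wells meeting at a gradient-discontinuous cusp.

    V(x) = (x+1)² for x < 0 and (x−1)² for x ≥ 0.  There is no stationary
    point between the wells, so no first-order saddle exists and connection
    attempts must report the pair as unconnectable.
    """

    name = "piecewise-two-wells"
    dimension = 1
    n_zero_modes = 0

    def energy(self, x):
        x = float(np.asarray(x).ravel()[0])
        return (x + 1.0) ** 2 if x < 0 else (x - 1.0) ** 2

    def gradient(self, x):
        x = float(np.asarray(x).ravel()[0])
        return np.array([2 * (x + 1.0) if x < 0 else 2 * (x - 1.0)])
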