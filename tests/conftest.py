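"""Shared fixtures, including the independent Müller–Brown census oracle.

The census oracle implements the surface and its derivatives from scratch
(no pelkit imports) and finds all stationary points by Newton refinement of
∇V = 0 from a dense grid, classifying them by the Hessian spectrum.  The
toolkit's basin-hopping / band-search machinery is then checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

# --------------------------------------------------------------------------
# Müller–Brown, implemented independently of the package under test
# --------------------------------------------------------------------------

_A = np.array([-200.0, -100.0, -170.0, 15.0])
_a = np.array([-1.0, -1.0, -6.5, 0.7])
_b = np.array([0.0, 0.0, 11.0, 0.6])
_c = np.array([-10.0, -10.0, -6.5, 0.7])
_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def mb_energy_oracle(p):
    dx, dy = p[0] - _x0, p[1] - _y0
    return float(np.sum(_A * np.exp(_a * dx**2 + _b * dx * dy + _c * dy**2)))


def _mb_grad(p):
    dx, dy = p[0] - _x0, p[1] - _y0
    t = _A * np.exp(_a * dx**2 + _b * dx * dy + _c * dy**2)
    return np.array(
        [
            np.sum(t * (2 * _a * dx + _b * dy)),
            np.sum(t * (_b * dx + 2 * _c * dy)),
        ]
    )


def _mb_hess(p):
    dx, dy = p[0] - _x0, p[1] - _y0
    t = _A * np.exp(_a * dx**2 + _b * dx * dy + _c * dy**2)
    u = 2 * _a * dx + _b * dy
    v = _b * dx + 2 * _c * dy
    return np.array(
        [
            [np.sum(t * (u * u + 2 * _a)), np.sum(t * (u * v + _b))],
            [np.sum(t * (u * v + _b)), np.sum(t * (v * v + 2 * _c))],
        ]
    )


@dataclass(frozen=True)
class MBCensus:
    minima: tuple  # ((x, y, E), ...) sorted by energy
    saddles: tuple


def _newton_stationary(p, max_iter=100):
    p = np.array(p, dtype=float)
    for _ in range(max_iter):
        g = _mb_grad(p)
        if np.linalg.norm(g) < 1e-12:
            return p
        try:
            step = np.linalg.solve(_mb_hess(p), -g)
        except np.linalg.LinAlgError:
            return None
        if np.linalg.norm(step) > 0.5:
            step *= 0.5 / np.linalg.norm(step)
        p = p + step
        if not np.all(np.isfinite(p)) or np.abs(p).max() > 10:
            return None
    return None


@pytest.fixture(scope="session")
def mb_census() -> MBCensus:
    """All stationary points of the Müller–Brown surface by grid + Newton."""
    found = []
    for x in np.linspace(-1.8, 1.3, 40):
        for y in np.linspace(-0.6, 2.3, 40):
            p = _newton_stationary([x, y])
            if p is None:
                continue
            if not any(np.linalg.norm(p - q[:2]) < 1e-6 for q in found):
                found.append(np.array([p[0], p[1]]))
    minima, saddles = [], []
    for p in found:
        evals = np.linalg.eigvalsh(_mb_hess(p))
        entry = (p[0], p[1], mb_energy_oracle(p))
        if np.all(evals > 0):
            minima.append(entry)
        elif evals[0] < 0 < evals[1]:
            saddles.append(entry)
    minima.sort(key=lambda e: e[2])
    saddles.sort(key=lambda e: e[2])
    return MBCensus(tuple(minima), tuple(saddles))


# --------------------------------------------------------------------------
# commonly used package objects
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def mb_model():
    from pelkit.potentials import MuellerBrown

    return MuellerBrown()


@pytest.fixture()
def hand_ktn_fixture():
    from pelkit.fixtures import hand_ktn

    return hand_ktn()


@pytest.fixture(scope="session")
def pk_structure():
    from pelkit.fixtures import build_pseudoknot_structure

    return build_pseudoknot_structure()


@pytest.fixture(scope="session")
def mb_explored_ktn(mb_model):
    """Basin-hopped + fully connected Müller–Brown KTN (shared, read-only)."""
    from pelkit.ktn import KTN, connect
    from pelkit.optim import BasinHoppingConfig, basin_hop

    minima = basin_hop(
        mb_model,
        np.array([0.0, 0.0]),
        BasinHoppingConfig(n_steps=500, rng_seed=7, step_size=0.7),
    )
    ktn = KTN(mb_model.name, mb_model.dimension)
    ids = ktn.add_minima(minima)
    for a, b in zip(ids, ids[1:]):
        connect(ktn, mb_model, a, b, max_cycles=10)
    return ktn


@pytest.fixture(scope="session")
def barrier_oracle():
    """Exhaustive minimax-barrier oracle: min over simple paths of the
    maximum TS energy (independent of the union-find implementation)."""
    import networkx as nx

    def brute_force_barrier(ktn, a, b):
        g = nx.MultiGraph()
        g.add_nodes_from(ktn.minima)
        for ts in ktn.transition_states.values():
            if ts.minus_min_id != ts.plus_min_id:
                g.add_edge(ts.minus_min_id, ts.plus_min_id, energy=ts.energy)
        simple = nx.Graph(g)  # collapse parallel edges to the lowest TS
        for u, v in simple.edges:
            simple.edges[u, v]["energy"] = min(
                d["energy"] for d in g.get_edge_data(u, v).values()
            )
        best = np.inf
        for path in nx.all_simple_paths(simple, a, b):
            height = max(
                simple.edges[u, v]["energy"] for u, v in zip(path, path[1:])
            )
            best = min(best, height)
        return best

    return brute_force_barrier


@pytest.fixture(scope="session")
def toy_rna_ktn():
    """The shipped toy-RNA hairpin database (expensive; built once)."""
    from pelkit.fixtures import toy_rna_fixture_ktn

    return toy_rna_fixture_ktn()
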