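"""Kinetic transition networks: deduplicated stationary-point databases.

A KTN holds the minima and transition states of one landscape, with
structural deduplication (energy + aligned-RMSD matching), a discrete
path-sampling connection driver that grows the network until two minima are
joined by transition-state edges, representative seeding by an order
parameter, and a convergence report over database snapshots.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import networkx as nx
import numpy as np

from .exceptions import (
    ConvergenceError,
    DegenerateGeometryError,
    HigherOrderSaddleError,
    MissingRepresentativeError,
    NotAssessableError,
    RejectedCandidateError,
    UnconvergedPointError,
)
from .geometry import align_rmsd
from .optim import Minimum
from .tssearch import BandConfig, TransitionState, descend_from_ts, dneb, hybrid_ef_refine

__all__ = [
    "MatchCriteria",
    "KTN",
    "ConnectResult",
    "Representatives",
    "connect",
    "seed_representatives",
    "convergence_report",
    "ConvergenceReport",
]

logger = logging.getLogger(__name__)

DATABASE_GRAD_RMS = 1e-5  # looser than the minimiser tol, tighter than dedup


@dataclass
class MatchCriteria:
    """When two stationary points are considered the same.

    A candidate matches a stored point of the same kind if the energies
    agree within ``energy_tol`` AND the aligned structural distance is
    within ``distance_tol``.  ``permute`` enables Hungarian matching of
    identically labelled sites (for clusters of indistinguishable beads).
    """

    energy_tol: float = 1e-4  # kcal/mol
    distance_tol: float = 0.1  # Å RMSD after optimal superposition
    permute: bool = False

    def __post_init__(self):
        if self.energy_tol <= 0 or self.distance_tol <= 0:
            raise ValueError("matching tolerances must be > 0")


class KTN:
    """The stationary-point database of one landscape.

    Parameters
    ----------
    model_name
        Identifier of the potential the points belong to (provenance).
    dimension
        Coordinate count; checked on insertion.
    use_alignment
        Whether structural distances use rigid-body superposition of 3-D
        sites.  Defaults to ``dimension % 3 == 0 and dimension >= 9``.
    """

    def __init__(
        self,
        model_name: str = "",
        dimension: int | None = None,
        units: str = "kcal/mol, Å",
        use_alignment: bool | None = None,
        site_labels=None,
    ):
        self.model_name = model_name
        self.dimension = dimension
        self.units = units
        self.minima: dict[int, Minimum] = {}
        self.transition_states: dict[int, TransitionState] = {}
        self.provenance: dict = {"model": model_name, "events": []}
        self._next_min_id = 0
        self._next_ts_id = 0
        if use_alignment is None and dimension is not None:
            use_alignment = dimension % 3 == 0 and dimension >= 9
        self.use_alignment = bool(use_alignment)
        self.site_labels = site_labels

    # -- bookkeeping --------------------------------------------------------
    def log_event(self, **kv) -> None:
        self.provenance["events"].append(kv)

    def copy(self) -> "KTN":
        return _copy.deepcopy(self)

    def check_integrity(self) -> None:
        """Raise if any TS references a missing minimum or energies are bad."""
        for tid, ts in self.transition_states.items():
            for mid in (ts.minus_min_id, ts.plus_min_id):
                if mid not in self.minima:
                    raise ValueError(f"TS {tid} references missing minimum {mid}")
            if not np.isfinite(ts.energy):
                raise ValueError(f"TS {tid} has non-finite energy")
        for mid, m in self.minima.items():
            if not np.isfinite(m.energy):
                raise ValueError(f"minimum {mid} has non-finite energy")

    @property
    def global_minimum(self) -> Minimum:
        return min(self.minima.values(), key=lambda m: m.energy)

    # -- structural distance -----------------------------------------------
    def distance(self, x_a: np.ndarray, x_b: np.ndarray) -> float:
        """Aligned RMSD for site models, scaled Euclidean distance otherwise."""
        if self.use_alignment:
            return align_rmsd(x_a, x_b, labels=self.site_labels).rmsd
        x_a = np.asarray(x_a, float).ravel()
        x_b = np.asarray(x_b, float).ravel()
        return float(np.linalg.norm(x_a - x_b) / np.sqrt(x_a.size))

    def _match(self, pool: dict, point, criteria: MatchCriteria):
        for pid, stored in pool.items():
            if abs(stored.energy - point.energy) > criteria.energy_tol:
                continue
            if self.use_alignment and criteria.permute:
                d = align_rmsd(
                    stored.coordinates,
                    point.coordinates,
                    permute=True,
                    labels=self.site_labels,
                ).rmsd
            else:
                d = self.distance(stored.coordinates, point.coordinates)
            if d <= criteria.distance_tol:
                return pid
        return None

    # -- insertion ----------------------------------------------------------
    def add_stationary_point(
        self, point, criteria: MatchCriteria | None = None
    ) -> int:
        """Insert a minimum or transition state, deduplicating.

        Returns the id of the matched existing point (incrementing its
        ``discovery_count`` for minima) or the newly assigned id.

        Raises
        ------
        UnconvergedPointError
            If the point's stored gradient RMS exceeds database grade.
        """
        criteria = criteria or MatchCriteria()
        if point.gradient_rms > DATABASE_GRAD_RMS:
            raise UnconvergedPointError(
                f"gradient RMS {point.gradient_rms:.2e} exceeds database "
                f"grade {DATABASE_GRAD_RMS:.0e}"
            )
        if self.dimension is None:
            self.dimension = point.coordinates.size
            self.use_alignment = self.dimension % 3 == 0 and self.dimension >= 9
        elif point.coordinates.size != self.dimension:
            raise ValueError(
                f"point dimension {point.coordinates.size} != KTN {self.dimension}"
            )

        if isinstance(point, TransitionState):
            matched = self._match(self.transition_states, point, criteria)
            if matched is not None:
                return matched
            tid = self._next_ts_id
            self._next_ts_id += 1
            stored = _copy.deepcopy(point)
            stored.id = tid
            self.transition_states[tid] = stored
            return tid

        matched = self._match(self.minima, point, criteria)
        if matched is not None:
            self.minima[matched].discovery_count += 1
            return matched
        mid = self._next_min_id
        self._next_min_id += 1
        stored = _copy.deepcopy(point)
        stored.id = mid
        stored.discovery_count = max(1, stored.discovery_count)
        self.minima[mid] = stored
        return mid

    def add_minima(self, minima, criteria: MatchCriteria | None = None) -> list:
        return [self.add_stationary_point(m, criteria) for m in minima]

    # -- graph views --------------------------------------------------------
    def graph(self, include_degenerate: bool = False) -> nx.MultiGraph:
        """Minima as nodes, transition states as edges.

        Degenerate rearrangements (TS with identical endpoints) are stored
        in the database but excluded from path queries by default.
        """
        g = nx.MultiGraph()
        for mid, m in self.minima.items():
            g.add_node(mid, energy=m.energy)
        for tid, ts in self.transition_states.items():
            if ts.minus_min_id is None or ts.plus_min_id is None:
                continue
            if ts.minus_min_id == ts.plus_min_id and not include_degenerate:
                continue
            g.add_edge(ts.minus_min_id, ts.plus_min_id, key=tid, energy=ts.energy)
        return g

    def ts_linked(self, a_id: int, b_id: int) -> bool:
        g = self.graph()
        return nx.has_path(g, a_id, b_id) if a_id in g and b_id in g else False


class ConnectResult(NamedTuple):
    ktn: KTN
    connected: bool
    cycles_used: int
    n_ts_found: int


def _refine_candidates(ktn, model, candidates, criteria, displacement):
    """Refine DNEB candidates and insert the resulting TSs and minima."""
    n_new = 0
    for cand in candidates:
        try:
            ts = hybrid_ef_refine(model, cand)
            lo, hi = descend_from_ts(model, ts, displacement=displacement)
        except (
            ConvergenceError,
            RejectedCandidateError,
            HigherOrderSaddleError,
            DegenerateGeometryError,
        ) as exc:
            logger.debug("candidate rejected: %s", exc)
            continue
        id_lo = ktn.add_stationary_point(lo, criteria)
        id_hi = ktn.add_stationary_point(hi, criteria)
        ts.minus_min_id, ts.plus_min_id = id_lo, id_hi
        ktn.add_stationary_point(ts, criteria)
        n_new += 1
    return n_new


def connect(
    ktn: KTN,
    model,
    min_a_id: int,
    min_b_id: int,
    max_cycles: int = 20,
    band_config: BandConfig | None = None,
    criteria: MatchCriteria | None = None,
    displacement: float = 0.05,
) -> ConnectResult:
    """Grow the network until two minima are joined by TS edges.

    Each cycle runs Dijkstra on a connection graph whose TS-backed edges are
    free and whose missing edges are penalised by squared structural
    distance, then attacks the first unconnected gap on the best partial
    path with a DNEB + hybrid-EF + descent search.  Symmetric in the two
    endpoints.
    """
    if min_a_id not in ktn.minima or min_b_id not in ktn.minima:
        raise KeyError("both minima must already be in the KTN")
    band_config = band_config or BandConfig()
    criteria = criteria or MatchCriteria()
    if min_a_id == min_b_id or ktn.ts_linked(min_a_id, min_b_id):
        return ConnectResult(ktn, True, 0, 0)

    attempted: set[frozenset] = set()
    total_new = 0
    for cycle in range(1, max_cycles + 1):
        ts_graph = ktn.graph()
        g = nx.Graph()
        g.add_nodes_from(ktn.minima)
        for u, v in ts_graph.edges():
            g.add_edge(u, v, weight=1e-9, linked=True)
        ids = sorted(ktn.minima)
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                if g.has_edge(u, v) or frozenset((u, v)) in attempted:
                    continue
                d = ktn.distance(
                    ktn.minima[u].coordinates, ktn.minima[v].coordinates
                )
                g.add_edge(u, v, weight=d * d + 1e-9, linked=False)
        try:
            path = nx.dijkstra_path(g, min_a_id, min_b_id)
        except nx.NetworkXNoPath:
            break
        gaps = [
            (u, v)
            for u, v in zip(path, path[1:])
            if not g.edges[u, v]["linked"]
        ]
        if not gaps:
            return ConnectResult(ktn, True, cycle - 1, total_new)
        u, v = gaps[0]
        attempted.add(frozenset((u, v)))
        ktn.log_event(op="connect-search", pair=[int(u), int(v)], cycle=cycle)
        candidates = dneb(model, ktn.minima[u], ktn.minima[v], band_config)
        total_new += _refine_candidates(
            ktn, model, candidates, criteria, displacement
        )
        if ktn.ts_linked(min_a_id, min_b_id):
            return ConnectResult(ktn, True, cycle, total_new)
    logger.warning(
        "connect(%s, %s): unconnected after %d cycles", min_a_id, min_b_id, max_cycles
    )
    return ConnectResult(ktn, False, max_cycles, total_new)


class Representatives(NamedTuple):
    folded_id: int
    partial_id: int
    unfolded_id: int


ORDER_BANDS = {
    "folded": (0.8, 1.0),
    "partial": (0.3, 0.7),
    "unfolded": (0.0, 0.2),
}


def seed_representatives(
    ktn: KTN, order_param: Callable[[Minimum], float]
) -> Representatives:
    """Lowest-energy minima in the folded/partial/unfolded bands.

    ``order_param`` maps a minimum to [0, 1] (e.g. native-contact fraction).
    Raises :class:`MissingRepresentativeError` for an empty band.
    """
    if not ktn.minima:
        raise ValueError("KTN is empty")
    chosen = {}
    values = {mid: float(order_param(m)) for mid, m in ktn.minima.items()}
    for band_name, (lo, hi) in ORDER_BANDS.items():
        members = [
            mid for mid, q in values.items() if lo <= q <= hi
        ]
        if not members:
            raise MissingRepresentativeError(band_name, (lo, hi))
        chosen[band_name] = min(members, key=lambda mid: ktn.minima[mid].energy)
    return Representatives(chosen["folded"], chosen["partial"], chosen["unfolded"])


@dataclass
class SnapshotMetrics:
    n_minima: int
    n_ts: int
    global_min_energy: float
    funnel_count: int
    barrier_matrix: np.ndarray  # between tracked basin bottoms; NaN if unreachable
    occupation_lowest: float


@dataclass
class ConvergenceReport:
    """Topography/thermodynamics stability across database snapshots."""

    metrics: list  # SnapshotMetrics per snapshot
    tracked_minima: list  # ids of tracked basin bottoms (last snapshot)
    converged: bool
    details: dict = field(default_factory=dict)


def _rel_change(a: float, b: float) -> float:
    denom = max(abs(a), abs(b), 1e-9)
    return abs(a - b) / denom


def convergence_report(
    ktn_snapshots: list[KTN],
    delta_e: float = 1.0,
    min_depth: float | None = None,
    temperature: float = 1.0,
    rel_tol: float = 0.01,
) -> ConvergenceReport:
    """Assess convergence of an exploration from ordered KTN snapshots.

    For each snapshot: funnel count at fixed ΔE, global-minimum energy, the
    minimax-barrier matrix between tracked basin bottoms (funnel bottoms of
    the final snapshot), and the harmonic-superposition occupation
    probability of the lowest basin at ``temperature`` (kcal/mol, equal
    vibrational prefactors).  Converged when every metric is stable (rel.
    change < ``rel_tol``) over the last two snapshots.
    """
    from .dgraph import build_superbasins, identify_funnels, minimax_barrier

    if len(ktn_snapshots) < 2:
        raise NotAssessableError("need at least two snapshots to assess convergence")
    if min_depth is None:
        min_depth = 5.0 * delta_e

    final_tree = build_superbasins(ktn_snapshots[-1], delta_e)
    final_funnels = identify_funnels(final_tree, min_depth)
    tracked = [b.lowest_id for b in final_funnels]

    metrics = []
    for snap in ktn_snapshots:
        tree = build_superbasins(snap, delta_e)
        funnels = identify_funnels(tree, min_depth)
        k = len(tracked)
        bmat = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i, k):
                a, b = tracked[i], tracked[j]
                if a in snap.minima and b in snap.minima:
                    try:
                        bmat[i, j] = bmat[j, i] = minimax_barrier(snap, a, b)
                    except Exception:
                        pass
        e0 = snap.global_minimum.energy
        weights = {
            mid: np.exp(-(m.energy - e0) / temperature)
            for mid, m in snap.minima.items()
        }
        lowest_funnel = min(funnels, key=lambda b: snap.minima.get(
            b.lowest_id, snap.global_minimum
        ).energy) if funnels else None
        if lowest_funnel is not None:
            members = [m for m in lowest_funnel.member_ids if m in weights]
            occ = sum(weights[m] for m in members) / sum(weights.values())
        else:
            occ = 1.0
        metrics.append(
            SnapshotMetrics(
                n_minima=len(snap.minima),
                n_ts=len(snap.transition_states),
                global_min_energy=e0,
                funnel_count=len(funnels),
                barrier_matrix=bmat,
                occupation_lowest=float(occ),
            )
        )

    a, b = metrics[-2], metrics[-1]
    checks = {
        "funnel_count": a.funnel_count == b.funnel_count,
        "global_min_energy": _rel_change(a.global_min_energy, b.global_min_energy)
        < rel_tol,
        "occupation_lowest": _rel_change(a.occupation_lowest, b.occupation_lowest)
        < rel_tol,
    }
    both = np.isfinite(a.barrier_matrix) & np.isfinite(b.barrier_matrix)
    if both.any():
        rel = np.abs(a.barrier_matrix[both] - b.barrier_matrix[both]) / np.maximum(
            np.maximum(
                np.abs(a.barrier_matrix[both]), np.abs(b.barrier_matrix[both])
            ),
            1e-9,
        )
        checks["barriers"] = bool(rel.max() < rel_tol)
    checks["barrier_coverage"] = bool(
        np.array_equal(
            np.isfinite(a.barrier_matrix), np.isfinite(b.barrier_matrix)
        )
    )
    return ConvergenceReport(
        metrics=metrics,
        tracked_minima=tracked,
        converged=all(checks.values()),
        details=checks,
    )
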