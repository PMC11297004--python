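"""Superbasin analysis, disconnectivity graphs, funnels and barriers.

At each discrete energy level E_ref + k·ΔE, minima below the level are
grouped into superbasins by union-find over the transition states below the
level; stacking the levels gives the disconnectivity tree.  Branches merge
at the lowest discrete level at which a transition path entirely below that
level exists — the discretised counterpart of the exact minimax barrier,
which is also provided (they bracket each other within ΔE).  Funnels are
subtrees whose lowest minimum lies at least a chosen depth below the level
at which the subtree merges with any lower-energy subtree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UnreachableError

__all__ = [
    "SuperbasinNode",
    "SuperbasinTree",
    "Basin",
    "build_superbasins",
    "minimax_barrier",
    "identify_funnels",
    "render_disconnectivity",
    "tree_signature_from_layout",
]


@dataclass
class SuperbasinNode:
    id: int
    level_index: int
    level_energy: float
    member_ids: frozenset
    parent: int | None = None
    children: list = field(default_factory=list)


@dataclass
class SuperbasinTree:
    """Hierarchical merge structure of minima at discretised energy levels."""

    e_ref: float
    delta_e: float
    levels: list  # level energies, ascending
    nodes: dict  # id -> SuperbasinNode
    minima_energies: dict  # minimum id -> energy

    @property
    def top_nodes(self) -> list:
        return [n for n in self.nodes.values() if n.parent is None]

    def nodes_at(self, level_index: int) -> list:
        return [n for n in self.nodes.values() if n.level_index == level_index]

    def merge_level(self, a: int, b: int) -> float:
        """Lowest discrete level at which minima ``a`` and ``b`` share a node."""
        for n in sorted(self.nodes.values(), key=lambda n: n.level_index):
            if a in n.member_ids and b in n.member_ids:
                return n.level_energy
        raise UnreachableError(f"minima {a} and {b} never merge")


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj
            return True
        return False


def _ts_edges(ktn):
    """(energy, minus, plus) for non-degenerate TSs with valid endpoints."""
    edges = []
    for ts in ktn.transition_states.values():
        if ts.minus_min_id is None or ts.plus_min_id is None:
            continue
        if ts.minus_min_id == ts.plus_min_id:
            continue  # degenerate rearrangements carry no connectivity
        edges.append((ts.energy, ts.minus_min_id, ts.plus_min_id))
    return edges


def build_superbasins(
    ktn, delta_e: float = 1.0, e_ref: float | None = None
) -> SuperbasinTree:
    """Union-find superbasin analysis in discrete steps of ``delta_e``.

    ``e_ref`` defaults to the global-minimum energy.  At each level L,
    minima with E ≤ L joined by every transition state with E ≤ L form one
    node; nodes are linked bottom-up into a tree (a forest if the network
    is disconnected).
    """
    if delta_e <= 0:
        raise ValueError("delta_e must be > 0")
    energies = {mid: m.energy for mid, m in ktn.minima.items()}
    if not energies:
        return SuperbasinTree(0.0, delta_e, [], {}, {})
    if e_ref is None:
        e_ref = min(energies.values())
    edges = _ts_edges(ktn)
    e_top = max(
        [max(energies.values())] + [e for e, _, _ in edges] + [e_ref]
    )
    n_levels = int(np.ceil((e_top - e_ref) / delta_e - 1e-12)) + 1
    levels = [e_ref + k * delta_e for k in range(n_levels + 1)]

    tree = SuperbasinTree(e_ref, delta_e, levels, {}, dict(energies))
    next_id = 0
    prev_nodes: list[SuperbasinNode] = []
    for k, level in enumerate(levels):
        present = [mid for mid, e in energies.items() if e <= level + 1e-12]
        if not present:
            continue
        uf = _UnionFind(present)
        for e, u, v in edges:
            if e <= level + 1e-12 and u in uf.parent and v in uf.parent:
                uf.union(u, v)
        groups: dict[int, set] = {}
        for mid in present:
            groups.setdefault(uf.find(mid), set()).add(mid)
        current = []
        for members in groups.values():
            node = SuperbasinNode(next_id, k, level, frozenset(members))
            next_id += 1
            tree.nodes[node.id] = node
            current.append(node)
            for prev in prev_nodes:
                if prev.member_ids <= node.member_ids:
                    prev.parent = node.id
                    node.children.append(prev.id)
        prev_nodes = current
    return tree


def minimax_barrier(ktn, min_a_id: int, min_b_id: int) -> float:
    """Exact minimax barrier: min over paths of the max TS energy.

    Computed by Kruskal-style union-find over transition states in energy
    order, which yields the continuous-limit superbasin merge energy.  By
    the documented convention ``minimax_barrier(x, x)`` is the minimum's
    own energy.
    """
    if min_a_id not in ktn.minima or min_b_id not in ktn.minima:
        raise KeyError("both minima must be in the KTN")
    if min_a_id == min_b_id:
        return ktn.minima[min_a_id].energy
    uf = _UnionFind(list(ktn.minima))
    for e, u, v in sorted(_ts_edges(ktn)):
        uf.union(u, v)
        if uf.find(min_a_id) == uf.find(min_b_id):
            return float(e)
    raise UnreachableError(
        f"minima {min_a_id} and {min_b_id} are not connected by transition states"
    )


@dataclass
class Basin:
    """A funnel: minima draining to a common low-energy structure."""

    label: str
    member_ids: set
    lowest_id: int
    lowest_energy: float
    depth: float  # merge level with any lower-energy subtree − lowest energy

    def __post_init__(self):
        if not self.member_ids:
            raise ValueError("a basin cannot be empty")


def _subtrees_at(tree: SuperbasinTree, node: SuperbasinNode):
    """Child nodes plus pseudo-subtrees for minima first appearing here."""
    child_nodes = [tree.nodes[c] for c in node.children]
    covered = set()
    for c in child_nodes:
        covered |= c.member_ids
    singles = sorted(node.member_ids - covered)
    return child_nodes, singles


def _sub_min(tree, item):
    if isinstance(item, SuperbasinNode):
        mid = min(item.member_ids, key=lambda m: (tree.minima_energies[m], m))
        return mid, tree.minima_energies[mid]
    return item, tree.minima_energies[item]


def identify_funnels(tree: SuperbasinTree, min_depth: float) -> list[Basin]:
    """Funnels of the landscape, sorted by bottom energy, labelled A, B, ...

    A subtree forms its own funnel when its lowest minimum lies at least
    ``min_depth`` below the discrete level at which it merges with a
    lower-energy subtree; shallower subtrees are absorbed into the funnel
    they merge into.  ``min_depth`` is a required modelling choice; 5·ΔE is
    a common heuristic.
    """
    funnels: list[dict] = []

    def new_funnel(bottom_id, bottom_e, depth):
        f = {"members": set(), "lowest_id": bottom_id,
             "lowest_e": bottom_e, "depth": depth}
        funnels.append(f)
        return f

    def absorb(tree_item, funnel):
        if isinstance(tree_item, SuperbasinNode):
            funnel["members"] |= set(tree_item.member_ids)
        else:
            funnel["members"].add(tree_item)

    def descend(item, funnel):
        if not isinstance(item, SuperbasinNode):
            funnel["members"].add(item)
            return
        children, singles = _subtrees_at(tree, item)
        subtrees = children + singles
        if not subtrees:
            funnel["members"] |= set(item.member_ids)
            return
        # the subtree holding the lowest minimum continues the parent funnel
        main = min(subtrees, key=lambda s: (_sub_min(tree, s)[1], _sub_min(tree, s)[0]))
        for s in subtrees:
            if s is main:
                continue
            bottom_id, bottom_e = _sub_min(tree, s)
            depth = item.level_energy - bottom_e
            if depth >= min_depth:
                descend(s, new_funnel(bottom_id, bottom_e, depth))
            else:
                absorb(s, funnel)
        descend(main, funnel)

    for top in sorted(
        tree.top_nodes, key=lambda n: _sub_min(tree, n)[1]
    ):
        bottom_id, bottom_e = _sub_min(tree, top)
        top_span = (tree.levels[-1] if tree.levels else bottom_e) - bottom_e
        descend(top, new_funnel(bottom_id, bottom_e, max(top_span, min_depth)))

    funnels.sort(key=lambda f: (f["lowest_e"], f["lowest_id"]))
    return [
        Basin(
            label=chr(ord("A") + i) if i < 26 else f"Z{i}",
            member_ids=f["members"],
            lowest_id=f["lowest_id"],
            lowest_energy=f["lowest_e"],
            depth=f["depth"],
        )
        for i, f in enumerate(funnels)
    ]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _leaf_order(tree: SuperbasinTree) -> list:
    """Left-to-right minima order: subtree size desc, lowest energy, id."""
    order = []

    def key(s):
        if isinstance(s, SuperbasinNode):
            size = len(s.member_ids)
        else:
            size = 1
        mid, e = _sub_min(tree, s)
        return (-size, e, mid)

    def walk(item):
        if not isinstance(item, SuperbasinNode):
            order.append(item)
            return
        children, singles = _subtrees_at(tree, item)
        subtrees = sorted(children + singles, key=key)
        if not subtrees:
            for mid in sorted(item.member_ids):
                order.append(mid)
            return
        for s in subtrees:
            walk(s)

    for top in sorted(tree.top_nodes, key=lambda n: _sub_min(tree, n)[1]):
        walk(top)
    return order


def render_disconnectivity(
    tree: SuperbasinTree, layout_config: dict | None = None
) -> tuple[str, dict]:
    """Disconnectivity graph as an SVG drawing plus a JSON-able layout.

    Vertical axis is energy; each leaf branch terminates at its minimum's
    energy; children are ordered left-to-right by subtree size then lowest
    energy, giving a crossing-free drawing.  ``layout_config`` keys:
    ``width``, ``height`` (px), ``e_min``/``e_max`` (shared energy scale
    across graphs), ``highlight`` (minimum ids drawn in accent colour),
    ``title``.
    """
    cfg = {
        "width": 480,
        "height": 600,
        "margin": 50,
        "e_min": None,
        "e_max": None,
        "highlight": [],
        "title": "",
    }
    cfg.update(layout_config or {})
    if not tree.nodes:
        empty_svg = (
            '<?xml version="1.0" encoding="UTF-8"?>'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{cfg["width"]}" '
            f'height="{cfg["height"]}"></svg>'
        )
        return empty_svg, {"nodes": [], "leaves": {}, "levels": []}

    leaves = _leaf_order(tree)
    xpos = {mid: i for i, mid in enumerate(leaves)}
    e_min = cfg["e_min"]
    e_max = cfg["e_max"]
    if e_min is None:
        e_min = min(tree.minima_energies.values())
    if e_max is None:
        e_max = tree.levels[-1]
    span = max(e_max - e_min, 1e-12)
    w, h, m = cfg["width"], cfg["height"], cfg["margin"]

    def sx(x):
        n = max(len(leaves) - 1, 1)
        return m + (w - 2 * m) * (x / n if len(leaves) > 1 else 0.5)

    def sy(e):
        return m + (h - 2 * m) * (1 - (e - e_min) / span)

    node_x = {}
    for node in sorted(tree.nodes.values(), key=lambda n: n.level_index):
        node_x[node.id] = float(
            np.mean([xpos[mid] for mid in node.member_ids])
        )

    segments = []  # (x1, e1, x2, e2, leaf_id or None)
    first_node_of_min = {}
    for node in sorted(tree.nodes.values(), key=lambda n: n.level_index):
        children, singles = _subtrees_at(tree, node)
        for c in children:
            segments.append(
                (node_x[c.id], c.level_energy, node_x[node.id], node.level_energy, None)
            )
        for mid in singles:
            first_node_of_min[mid] = node.id
            segments.append(
                (
                    xpos[mid],
                    tree.minima_energies[mid],
                    node_x[node.id],
                    node.level_energy,
                    mid,
                )
            )

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f'<title>{cfg["title"] or "disconnectivity graph"}</title>',
        f'<line x1="{m}" y1="{sy(e_min)}" x2="{m}" y2="{sy(e_max)}" '
        'stroke="black" stroke-width="1"/>',
    ]
    n_ticks = 6
    for i in range(n_ticks + 1):
        e = e_min + span * i / n_ticks
        y = sy(e)
        parts.append(
            f'<line x1="{m - 4}" y1="{y}" x2="{m}" y2="{y}" stroke="black"/>'
            f'<text x="{m - 8}" y="{y + 3}" font-size="9" text-anchor="end">'
            f"{e:.1f}</text>"
        )
    highlight = set(cfg["highlight"])
    for x1, e1, x2, e2, leaf in segments:
        colour = "#d4a017" if leaf in highlight else "#333333"
        parts.append(
            f'<line x1="{sx(x1):.2f}" y1="{sy(e1):.2f}" '
            f'x2="{sx(x2):.2f}" y2="{sy(e2):.2f}" '
            f'stroke="{colour}" stroke-width="1.2"/>'
        )
    parts.append("</svg>")
    svg = "".join(parts)

    layout = {
        "e_ref": tree.e_ref,
        "delta_e": tree.delta_e,
        "levels": list(tree.levels),
        "energy_axis": [e_min, e_max],
        "nodes": [
            {
                "id": n.id,
                "level_index": n.level_index,
                "level_energy": n.level_energy,
                "members": sorted(n.member_ids),
                "parent": n.parent,
                "x": node_x[n.id],
                "y": sy(n.level_energy),
            }
            for n in sorted(tree.nodes.values(), key=lambda n: n.id)
        ],
        "leaves": {
            str(mid): {
                "x": xpos[mid],
                "y": sy(tree.minima_energies[mid]),
                "energy": tree.minima_energies[mid],
            }
            for mid in leaves
        },
    }
    return svg, layout


def tree_signature_from_layout(layout: dict) -> set:
    """Canonical topology signature {(level_index, members)} of a layout.

    ``tree_signature_from_layout(json.loads(json.dumps(layout)))`` equals
    the signature of the original tree, giving the JSON round-trip check.
    """
    return {
        (n["level_index"], tuple(sorted(n["members"]))) for n in layout["nodes"]
    }


def tree_signature(tree: SuperbasinTree) -> set:
    return {
        (n.level_index, tuple(sorted(n.member_ids))) for n in tree.nodes.values()
    }
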