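"""Superbasin trees, minimax barriers, funnels, disconnectivity rendering."""

import json

import networkx as nx
import numpy as np
import pytest

from pelkit.dgraph import (
    build_superbasins,
    identify_funnels,
    minimax_barrier,
    render_disconnectivity,
    tree_signature,
    tree_signature_from_layout,
)
from pelkit.exceptions import UnreachableError
from pelkit.fixtures import hand_ktn, random_ktn
from pelkit.ktn import KTN
from pelkit.optim import Minimum


class TestHandKtn:
    def test_merge_levels_follow_the_discrete_rule(self, hand_ktn_fixture):
        tree = build_superbasins(hand_ktn_fixture, 1.0, e_ref=0.0)
        assert tree.merge_level(1, 2) == pytest.approx(3.0)  # b–c via TS 3
        assert tree.merge_level(0, 2) == pytest.approx(5.0)  # a–c via TS 5

    def test_barriers(self, hand_ktn_fixture):
        assert minimax_barrier(hand_ktn_fixture, 0, 2) == pytest.approx(5.0)
        # barrier(x, x) is the minimum's own energy by convention
        assert minimax_barrier(hand_ktn_fixture, 1, 1) == pytest.approx(2.0)

    def test_funnels_at_min_depth(self, hand_ktn_fixture):
        tree = build_superbasins(hand_ktn_fixture, 1.0, e_ref=0.0)
        basins = identify_funnels(tree, min_depth=1.5)
        assert len(basins) == 2
        assert basins[0].label == "A" and basins[0].member_ids == {0}
        assert basins[1].label == "B" and basins[1].member_ids == {1, 2}

    def test_three_leaves_merge_into_one_root(self, hand_ktn_fixture):
        tree = build_superbasins(hand_ktn_fixture, 1.0)
        top = tree.top_nodes
        assert len(top) == 1 and top[0].member_ids == frozenset({0, 1, 2})


def test_single_minimum_tree_is_one_branch_one_funnel():
    k = KTN(dimension=1, use_alignment=False)
    k.add_stationary_point(
        Minimum(energy=-2.0, coordinates=np.array([0.0]), gradient_rms=1e-9)
    )
    tree = build_superbasins(k, 1.0)
    assert all(len(n.member_ids) == 1 for n in tree.nodes.values())
    assert len(identify_funnels(tree, min_depth=1.0)) == 1


def test_shallow_side_well_is_absorbed():
    """Two wells merging only 0.5 above the higher one form one funnel at
    min_depth 1.5."""
    k = KTN(dimension=1, use_alignment=False)
    from pelkit.fixtures import _mk_min, _mk_ts

    a = k.add_stationary_point(_mk_min(0.0, [0.0]))
    b = k.add_stationary_point(_mk_min(0.2, [4.0]))
    k.add_stationary_point(_mk_ts(0.7, [2.0], a, b))
    tree = build_superbasins(k, 1.0)
    assert len(identify_funnels(tree, min_depth=1.5)) == 1


def test_disconnected_minima_are_unreachable(hand_ktn_fixture):
    from pelkit.fixtures import _mk_min

    lone = hand_ktn_fixture.add_stationary_point(_mk_min(0.5, [99.0]))
    with pytest.raises(UnreachableError):
        minimax_barrier(hand_ktn_fixture, 0, lone)


@pytest.mark.parametrize("seed", range(30))
def test_minimax_equals_brute_force_on_random_networks(seed, barrier_oracle):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 15))
    ktn = random_ktn(n, seed)
    ids = sorted(ktn.minima)
    a, b = ids[0], ids[-1]
    assert minimax_barrier(ktn, a, b) == pytest.approx(
        barrier_oracle(ktn, a, b)
    )


@pytest.mark.parametrize("seed", range(10))
def test_discretised_merge_level_brackets_the_exact_barrier(seed):
    ktn = random_ktn(10, 100 + seed)
    delta_e = 0.7
    tree = build_superbasins(ktn, delta_e)
    ids = sorted(ktn.minima)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            exact = minimax_barrier(ktn, a, b)
            level = tree.merge_level(a, b)
            assert exact <= level + 1e-9
            assert level < exact + delta_e + 1e-9


def test_funnel_membership_partitions_assigned_minima():
    for seed in range(5):
        ktn = random_ktn(12, 200 + seed)
        tree = build_superbasins(ktn, 0.5)
        basins = identify_funnels(tree, min_depth=2.0)
        seen = [m for b in basins for m in b.member_ids]
        assert len(seen) == len(set(seen)) == len(ktn.minima)


class TestRendering:
    def test_leaves_terminate_at_their_energies(self, hand_ktn_fixture):
        tree = build_superbasins(hand_ktn_fixture, 1.0)
        svg, layout = render_disconnectivity(tree)
        assert svg.startswith('<?xml version="1.0"')
        assert len(layout["leaves"]) == 3
        for mid, leaf in layout["leaves"].items():
            assert leaf["energy"] == pytest.approx(
                hand_ktn_fixture.minima[int(mid)].energy
            )

    def test_layout_json_round_trips_the_topology(self, hand_ktn_fixture):
        tree = build_superbasins(hand_ktn_fixture, 1.0)
        _, layout = render_disconnectivity(tree)
        recovered = json.loads(json.dumps(layout))
        assert tree_signature_from_layout(recovered) == tree_signature(tree)

    def test_shared_scale_configuration_fixes_the_energy_axis(self):
        """Two networks rendered with one scale config share y-ranges."""
        t1 = build_superbasins(hand_ktn(), 1.0)
        t2 = build_superbasins(random_ktn(6, 1), 1.0)
        cfg = {"e_min": -1.0, "e_max": 12.0}
        _, l1 = render_disconnectivity(t1, cfg)
        _, l2 = render_disconnectivity(t2, cfg)
        assert l1["energy_axis"] == l2["energy_axis"] == [-1.0, 12.0]

    def test_svg_is_well_formed_xml(self, hand_ktn_fixture):
        from xml.etree import ElementTree

        tree = build_superbasins(hand_ktn_fixture, 1.0)
        svg, _ = render_disconnectivity(tree)
        ElementTree.fromstring(svg)
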