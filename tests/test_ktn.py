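"""KTN deduplication, alignment, the connection driver, seeding, convergence."""

import numpy as np
import pytest

from pelkit.exceptions import (
    MissingRepresentativeError,
    NotAssessableError,
    UnconvergedPointError,
)
from pelkit.fixtures import hand_ktn, random_ktn
from pelkit.geometry import align_rmsd, rotation_matrix
from pelkit.ktn import (
    KTN,
    MatchCriteria,
    connect,
    convergence_report,
    seed_representatives,
)
from pelkit.optim import Minimum, local_minimise
from pelkit.potentials import LJCluster, PiecewiseTwoWells
from pelkit.tssearch import TransitionState


def _min(e, coords, grms=1e-9):
    return Minimum(energy=e, coordinates=np.asarray(coords, float), gradient_rms=grms)


def _ts(e, coords, a, b):
    c = np.asarray(coords, float)
    return TransitionState(
        energy=e, coordinates=c, lowest_eigenvalue=-1.0,
        eigenvector=np.ones_like(c), gradient_rms=1e-9,
        minus_min_id=a, plus_min_id=b,
    )


class TestAlignRmsd:
    def test_rotated_translated_copy_aligns_to_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 2, (6, 3))
        rot = rotation_matrix([1, 1, 0], 1.2)
        b = a @ rot.T + np.array([5, -3, 2])
        assert align_rmsd(a.ravel(), b.ravel()).rmsd < 1e-9

    def test_single_site_displacement_bound(self):
        """Displacing one of N sites by d leaves aligned RMSD ≤ d/√N."""
        rng = np.random.default_rng(1)
        for n in (4, 7, 12):
            a = rng.normal(0, 2, (n, 3))
            b = a.copy()
            d = 0.8
            b[0] += [d, 0, 0]
            assert align_rmsd(a.ravel(), b.ravel()).rmsd <= d / np.sqrt(n) + 1e-12

    def test_chiral_mirror_image_does_not_align(self):
        """Proper rotations only: a chiral tetrahedron differs from its
        mirror image."""
        a = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.3]], dtype=float
        )
        b = a.copy()
        b[:, 2] *= -1
        assert align_rmsd(a.ravel(), b.ravel()).rmsd > 0.1

    def test_collinear_configuration_falls_back_to_translation(self):
        a = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        b = a + np.array([0, 3, 0])
        res = align_rmsd(a.ravel(), b.ravel())
        assert res.degenerate
        assert res.rmsd < 1e-9


class TestAddStationaryPoint:
    def test_duplicate_minimum_matches_and_counts(self):
        k = KTN(dimension=2, use_alignment=False)
        i1 = k.add_stationary_point(_min(1.0, [0, 0]))
        i2 = k.add_stationary_point(_min(1.0, [0, 0]))
        assert i1 == i2
        assert len(k.minima) == 1
        assert k.minima[i1].discovery_count == 2

    def test_rotated_cluster_minimum_is_matched(self):
        lj = LJCluster(7)
        rng = np.random.default_rng(4)
        m = local_minimise(lj, rng.normal(0, 1.1, 21))
        rot = rotation_matrix([0, 1, 1], 0.9)
        rotated = (m.coordinates.reshape(7, 3) @ rot.T).ravel()
        k = KTN(dimension=21)
        i1 = k.add_stationary_point(m)
        i2 = k.add_stationary_point(
            Minimum(m.energy, rotated, m.gradient_rms)
        )
        assert i1 == i2

    def test_permuted_cluster_minimum_matched_with_hungarian_pass(self):
        lj = LJCluster(5)
        rng = np.random.default_rng(6)
        m = local_minimise(lj, rng.normal(0, 1.0, 15))
        perm = m.coordinates.reshape(5, 3)[[2, 0, 4, 1, 3]].ravel()
        k = KTN(dimension=15)
        crit = MatchCriteria(permute=True)
        i1 = k.add_stationary_point(m, crit)
        i2 = k.add_stationary_point(Minimum(m.energy, perm, m.gradient_rms), crit)
        assert i1 == i2

    def test_equal_energy_distant_structures_stay_distinct(self):
        k = KTN(dimension=9)
        a = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0]], float).ravel()
        b = a + np.array([3.0, 0, 0] * 3) + np.array([0, 0, 0, 0, 2, 0, 1, 0, 2.0])
        i1 = k.add_stationary_point(_min(2.0, a))
        i2 = k.add_stationary_point(_min(2.0, b))
        assert i1 != i2

    def test_unconverged_point_is_rejected_with_reason(self):
        k = KTN(dimension=2, use_alignment=False)
        with pytest.raises(UnconvergedPointError):
            k.add_stationary_point(_min(0.0, [0, 0], grms=1e-2))


class TestConnect:
    def test_already_linked_pair_needs_no_search(self, hand_ktn_fixture):
        res = connect(hand_ktn_fixture, model=None, min_a_id=0, min_b_id=1)
        assert res.connected and res.cycles_used == 0 and res.n_ts_found == 0

    def test_mueller_brown_outer_minima_path_goes_through_the_middle(
        self, mb_model, mb_census, mb_explored_ktn
    ):
        """No direct single-saddle path exists between the outer minima:
        the discrete path must traverse the intermediate minimum."""
        import networkx as nx

        ktn = mb_explored_ktn
        assert len(ktn.minima) == 3 and len(ktn.transition_states) == 2
        by_e = sorted(ktn.minima, key=lambda i: ktn.minima[i].energy)
        lowest, middle, highest_pair = by_e[0], None, None
        g = ktn.graph()
        # outer pair = the two minima whose connecting path is longest
        path = nx.shortest_path(g, by_e[0], by_e[1])
        # identify outer minima from the census geometry instead
        coords = {i: ktn.minima[i].coordinates for i in ktn.minima}
        left = min(coords, key=lambda i: coords[i][0])
        right = max(coords, key=lambda i: coords[i][0])
        middle = ({0, 1, 2} - {left, right}).pop()
        path = nx.shortest_path(g, left, right)
        assert middle in path

    def test_endpoint_order_does_not_matter(self, mb_model):
        from pelkit.optim import BasinHoppingConfig, basin_hop

        minima = basin_hop(
            mb_model,
            np.array([0.0, 0.0]),
            BasinHoppingConfig(n_steps=300, rng_seed=2, step_size=0.7),
        )
        results = []
        for order in ((0, -1), (-1, 0)):
            ktn = KTN(mb_model.name, 2)
            ids = ktn.add_minima(minima)
            res = connect(ktn, mb_model, ids[order[0]], ids[order[1]], max_cycles=10)
            results.append(
                (res.connected, len(ktn.minima), len(ktn.transition_states))
            )
        assert results[0] == results[1]

    def test_disconnected_wells_report_unconnected(self):
        model = PiecewiseTwoWells()
        ktn = KTN(model.name, 1, use_alignment=False)
        a = ktn.add_stationary_point(
            local_minimise(model, np.array([-1.2]))
        )
        b = ktn.add_stationary_point(local_minimise(model, np.array([1.2])))
        res = connect(ktn, model, a, b, max_cycles=3)
        assert not res.connected


class TestSeeding:
    def test_trivial_bands_select_their_members(self):
        k = KTN(dimension=1, use_alignment=False)
        ids = [
            k.add_stationary_point(_min(e, [float(i)]))
            for i, e in enumerate([0.0, 1.0, 2.0])
        ]
        q = {ids[0]: 1.0, ids[1]: 0.5, ids[2]: 0.0}
        reps = seed_representatives(k, lambda m: q[m.id])
        assert reps == (ids[0], ids[1], ids[2])

    def test_missing_band_raises(self):
        k = KTN(dimension=1, use_alignment=False)
        for i in range(3):
            k.add_stationary_point(_min(float(i), [float(i)]))
        with pytest.raises(MissingRepresentativeError):
            seed_representatives(k, lambda m: 1.0)  # everything folded

    def test_toy_rna_representatives_decrease_in_order_parameter(self, toy_rna_ktn):
        from pelkit.potentials import native_contact_fraction

        model, topo, ktn = toy_rna_ktn
        reps = seed_representatives(
            ktn, lambda m: native_contact_fraction(topo, m.coordinates)
        )
        qs = [
            native_contact_fraction(topo, ktn.minima[i].coordinates)
            for i in reps
        ]
        assert qs[0] > qs[1] > qs[2]


class TestConvergenceReport:
    def test_identical_snapshots_are_converged(self, hand_ktn_fixture):
        rep = convergence_report([hand_ktn_fixture, hand_ktn_fixture.copy()])
        assert rep.converged

    def test_high_energy_minimum_inside_a_funnel_stays_converged(self):
        k1 = hand_ktn()
        k2 = k1.copy()
        new = k2.add_stationary_point(_min(4.5, [3.0]))
        k2.add_stationary_point(_ts(5.5, [2.5], 0, new))
        rep = convergence_report([k1, k2], delta_e=1.0, min_depth=3.0)
        assert rep.metrics[0].funnel_count == rep.metrics[1].funnel_count

    def test_new_deep_funnel_breaks_convergence(self):
        k1 = hand_ktn()
        k2 = k1.copy()
        new = k2.add_stationary_point(_min(0.5, [20.0]))
        k2.add_stationary_point(_ts(30.0, [15.0], 0, new))
        rep = convergence_report([k1, k2], delta_e=1.0, min_depth=3.0)
        assert rep.metrics[1].funnel_count > rep.metrics[0].funnel_count
        assert not rep.converged

    def test_single_snapshot_is_not_assessable(self, hand_ktn_fixture):
        with pytest.raises(NotAssessableError):
            convergence_report([hand_ktn_fixture])


def test_referential_integrity_under_random_operation_sequences():
    """Random insertions (minima, TSs, duplicates) never break the
    invariant that every TS references stored minima."""
    rng = np.random.default_rng(12)
    k = KTN(dimension=1, use_alignment=False)
    ids = []
    for step in range(200):
        op = rng.random()
        if op < 0.5 or not ids:
            mid = k.add_stationary_point(
                _min(float(rng.uniform(0, 5)), [float(rng.uniform(0, 100))])
            )
            ids.append(mid)
        elif op < 0.8 and len(ids) >= 2:
            a, b = rng.choice(ids, 2)
            e = max(k.minima[a].energy, k.minima[b].energy) + rng.uniform(0.1, 3)
            k.add_stationary_point(_ts(float(e), [float(rng.uniform(0, 100))], int(a), int(b)))
        else:  # duplicate an existing minimum
            mid = int(rng.choice(ids))
            m = k.minima[mid]
            k.add_stationary_point(_min(m.energy, m.coordinates.copy()))
        k.check_integrity()
    assert len(k.minima) == len(set(k.minima))
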