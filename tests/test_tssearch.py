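"""Band interpolation, DNEB candidates, hybrid-EF saddles, descents."""

import numpy as np
import pytest

from pelkit.exceptions import RejectedCandidateError
from pelkit.optim import local_minimise
from pelkit.potentials import DoubleWell1D, LJCluster, QuadraticBowl
from pelkit.tssearch import (
    BandConfig,
    descend_from_ts,
    dneb,
    hybrid_ef_refine,
    interpolate,
)


class TestInterpolate:
    def test_midpoint_is_the_coordinate_average(self):
        a, b = np.array([0.0, 0.0]), np.array([2.0, 4.0])
        band = interpolate(a, b, 3)
        assert np.allclose(band[1], [1.0, 2.0])
        assert np.array_equal(band[0], a) and np.array_equal(band[-1], b)

    def test_identical_endpoints_give_identical_images(self):
        a = np.array([1.0, -2.0, 3.0])
        band = interpolate(a, a, 5)
        assert all(np.array_equal(img, a) for img in band)

    def test_clash_repair_separates_beads_passing_through_each_other(self):
        """Swapping two LJ beads linearly makes them coincide at the
        midpoint; the repair pass restores a 0.5σ separation."""
        lj = LJCluster(2)
        a = np.array([0, 0, 0, 2, 0, 0], dtype=float)
        b = np.array([2, 0, 0, 0, 0, 0], dtype=float)
        band = interpolate(a, b, 5, model=lj)
        for img in band[1:-1]:
            pts = img.reshape(2, 3)
            assert np.linalg.norm(pts[0] - pts[1]) >= 0.5 * lj.sigma


class TestDneb:
    def test_finds_the_known_mueller_brown_saddle(self, mb_model, mb_census):
        m1 = local_minimise(mb_model, np.array([-0.55, 1.44]))
        m2 = local_minimise(mb_model, np.array([-0.05, 0.47]))
        cands = dneb(mb_model, m1, m2, BandConfig())
        assert len(cands) >= 1
        # the saddle between these minima is the higher-energy one of the two
        saddle = max(mb_census.saddles, key=lambda s: s[2])  # ≈ (−0.822, 0.624)
        best = min(cands, key=lambda c: np.hypot(c[0] - saddle[0], c[1] - saddle[1]))
        assert np.hypot(best[0] - saddle[0], best[1] - saddle[1]) < 0.15

    def test_same_minimum_yields_no_candidates(self, mb_model):
        m = local_minimise(mb_model, np.array([0.0, 0.5]))
        assert dneb(mb_model, m, m, BandConfig()) == []

    def test_convex_surface_yields_no_candidates(self):
        bowl = QuadraticBowl(dimension=2)
        a = local_minimise(bowl, np.array([1.0, 1.0]))
        assert dneb(bowl, a.coordinates + [2, 0], a.coordinates - [2, 0]) == []


class TestHybridEF:
    def test_refines_dneb_candidate_to_the_census_saddle(self, mb_model, mb_census):
        m1 = local_minimise(mb_model, np.array([-0.55, 1.44]))
        m2 = local_minimise(mb_model, np.array([-0.05, 0.47]))
        cand = dneb(mb_model, m1, m2)[0]
        ts = hybrid_ef_refine(mb_model, cand)
        sx, sy, se = max(mb_census.saddles, key=lambda s: s[2])
        assert np.hypot(ts.coordinates[0] - sx, ts.coordinates[1] - sy) < 1e-4
        assert ts.energy == pytest.approx(se, abs=1e-6)
        assert np.linalg.norm(mb_model.gradient(ts.coordinates)) < 1e-6
        assert ts.lowest_eigenvalue < 0

    def test_guess_at_a_minimum_is_rejected(self, mb_model, mb_census):
        x, y, _ = mb_census.minima[0]
        with pytest.raises(RejectedCandidateError):
            hybrid_ef_refine(mb_model, np.array([x, y]))

    def test_double_well_saddle_is_at_the_origin(self):
        dw = DoubleWell1D()
        ts = hybrid_ef_refine(dw, np.array([0.1]))
        # gradient tolerance 1e-6 near x=0 (V' ≈ −2x) bounds |x| by ~5e-7
        assert ts.coordinates[0] == pytest.approx(0.0, abs=1e-6)
        assert ts.energy == pytest.approx(0.0, abs=1e-12)

    def test_every_accepted_ts_has_one_negative_eigenvalue(self, mb_model, mb_census):
        for sx, sy, _ in mb_census.saddles:
            ts = hybrid_ef_refine(mb_model, np.array([sx + 0.02, sy - 0.02]))
            evals = np.linalg.eigvalsh(mb_model.hessian(ts.coordinates))
            assert (evals < -1e-8).sum() == 1


class TestDescend:
    def test_census_saddle_connects_the_right_minima(self, mb_model, mb_census):
        sx, sy, _ = min(mb_census.saddles, key=lambda s: s[2])  # ≈ (0.212, 0.293)
        ts = hybrid_ef_refine(mb_model, np.array([sx, sy]))
        lo, hi = descend_from_ts(mb_model, ts)
        got = {
            tuple(np.round(lo.coordinates, 2)),
            tuple(np.round(hi.coordinates, 2)),
        }
        expected_pair = {
            tuple(np.round([m[0], m[1]], 2))
            for m in mb_census.minima
            if np.hypot(m[0] - sx, m[1] - sy) < 0.6
        }
        assert got == expected_pair
        assert ts.energy >= max(lo.energy, hi.energy) - 1e-6

    def test_double_well_descends_to_both_wells(self):
        dw = DoubleWell1D()
        ts = hybrid_ef_refine(dw, np.array([0.05]))
        lo, hi = descend_from_ts(dw, ts)
        xs = sorted([lo.coordinates[0], hi.coordinates[0]])
        assert xs == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)], abs=1e-6)

    def test_ts_energy_dominates_its_minima(self, mb_model, mb_census):
        for sx, sy, se in mb_census.saddles:
            ts = hybrid_ef_refine(mb_model, np.array([sx, sy]))
            lo, hi = descend_from_ts(mb_model, ts)
            assert ts.energy >= lo.energy - 1e-6
            assert ts.energy >= hi.energy - 1e-6
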