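"""Potential models: gradients, invariances, parameter sets, adapters."""

import math

import numpy as np
import pytest

from pelkit.exceptions import (
    ConfigError,
    ContractViolation,
    DegenerateGeometryError,
    PotentialEvaluationError,
)
from pelkit.potentials import (
    DoubleWell1D,
    LJCluster,
    MuellerBrown,
    ParameterSet,
    QuadraticBowl,
    ToyRNAChain,
    build_topology,
    extended_configuration,
    external_adapter,
    get_parameter_set,
    make_toy_rna,
)


def _fd_gradient(model, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (model.energy(xp) - model.energy(xm)) / (2 * h)
    return g


def _random_configs(model, n, rng):
    """Non-degenerate random configurations appropriate for each model."""
    out = []
    while len(out) < n:
        if isinstance(model, LJCluster):
            x = rng.normal(0.0, 1.1, model.dimension)
        elif isinstance(model, ToyRNAChain):
            x = extended_configuration(model.topology) + rng.normal(
                0.0, 0.25, model.dimension
            )
        else:
            x = rng.uniform(-1.5, 1.5, model.dimension)
        try:
            model.validate(x)
        except DegenerateGeometryError:
            continue
        out.append(x)
    return out


@pytest.mark.parametrize(
    "model",
    [
        MuellerBrown(),
        QuadraticBowl(dimension=4, k=2.5, centre=[1, -1, 0.5, 2]),
        DoubleWell1D(),
        LJCluster(7),
        make_toy_rna("GGAAUCC", native_pairs=[(1, 7)])[0],
    ],
    ids=lambda m: m.name,
)
def test_gradient_matches_finite_differences(model):
    """Analytic gradients agree with centred differences at random points."""
    rng = np.random.default_rng(42)
    for x in _random_configs(model, 20, rng):
        g = model.gradient(x)
        gfd = _fd_gradient(model, x)
        scale = max(1.0, np.abs(gfd).max())
        assert np.abs(g - gfd).max() / scale < 1e-5


def test_mueller_brown_global_minimum_is_stationary(mb_model, mb_census):
    x, y, e = mb_census.minima[0]
    assert np.linalg.norm(mb_model.gradient([x, y])) < 1e-6
    assert mb_model.energy([x, y]) == pytest.approx(e, abs=1e-9)


def test_lj_dimer_minimum_is_analytic():
    """Two LJ beads at 2^(1/6)σ sit at depth −ε with zero gradient."""
    lj = LJCluster(2, epsilon=1.7, sigma=1.3)
    r = 2 ** (1 / 6) * 1.3
    x = np.array([0, 0, 0, r, 0, 0], dtype=float)
    assert lj.energy(x) == pytest.approx(-1.7, rel=1e-12)
    assert np.abs(lj.gradient(x)).max() < 1e-10


def test_harmonic_bond_at_equilibrium_is_zero_energy():
    """With every other term switched off, an equilibrium bond costs nothing."""
    params = get_parameter_set("cg-default")
    params.angles = {k: (0.0, v[1]) for k, v in params.angles.items()}
    params.torsions = {k: [] for k in params.torsions}
    params.lj = {k: (0.0, v[1]) for k, v in params.lj.items()}
    params.charges = {k: 0.0 for k in params.charges}
    params.native_strength = 0.0
    topo = build_topology("A")
    model = ToyRNAChain(topo, params)
    coords = np.zeros((3, 3))
    coords[1] = (params.bonds["P-S"][1], 0.0, 0.0)  # P–S at r0
    coords[2] = (params.bonds["P-S"][1] + params.bonds["S-B"][1], 0.0, 0.0)
    assert model.energy(coords.ravel()) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("model_name", ["lj", "chain"])
def test_rigid_body_invariance(model_name):
    """Energy unchanged and projected gradient torque-free under rigid moves."""
    from pelkit.geometry import rotation_matrix

    rng = np.random.default_rng(3)
    if model_name == "lj":
        model = LJCluster(7)
        x = rng.normal(0, 1.2, model.dimension)
        model.validate(x)
    else:
        model, topo = make_toy_rna("GGAAUCC")
        x = extended_configuration(topo)
    e0 = model.energy(x)
    rot = rotation_matrix([1, 2, 3], 0.7)
    pts = x.reshape(-1, 3) @ rot.T + np.array([3.0, -2.0, 5.0])
    assert model.energy(pts.ravel()) == pytest.approx(e0, abs=1e-9)
    # gradient has no component along the invariant motions
    g = model.gradient(x)
    basis = model.zero_mode_basis(x)
    assert np.abs(basis @ g).max() < 1e-8


class TestToyRNAFactory:
    def test_single_nucleotide_has_no_torsions(self):
        _, topo = make_toy_rna("G")
        assert topo.torsions == []

    def test_bead_count_scales_with_sequence(self):
        model, topo = make_toy_rna("GGGGUGCCUCCCCAAAAAGGC")
        assert topo.n_beads == 21 * 3
        assert model.dimension == 63 * 3

    def test_parameter_sets_share_topology_but_not_energies(self):
        m1, t1 = make_toy_rna("GGAAUCC", "cg-default")
        m2, t2 = make_toy_rna("GGAAUCC", "cg-torsion2")
        assert t1.bonds == t2.bonds and t1.torsions == t2.torsions
        x = extended_configuration(t1)
        assert m1.energy(x) != pytest.approx(m2.energy(x), abs=1e-6)

    def test_parameter_sets_rank_configurations_differently(self):
        """Two parameter sets disagree on the energy ordering of a fixed
        set of configurations — rankings are a force-field property."""
        m1, topo = make_toy_rna("GGAAUCC", "cg-default")
        m2, _ = make_toy_rna("GGAAUCC", "cg-torsion2")
        rng = np.random.default_rng(8)
        configs = [
            extended_configuration(topo) + rng.normal(0, 0.6, m1.dimension)
            for _ in range(12)
        ]
        e1 = np.array([m1.energy(x) for x in configs])
        e2 = np.array([m2.energy(x) for x in configs])
        assert not np.array_equal(np.argsort(e1), np.argsort(e2))

    def test_unknown_letter_and_parameter_set_rejected(self):
        with pytest.raises(ContractViolation):
            make_toy_rna("GGX")
        with pytest.raises(ConfigError):
            make_toy_rna("GG", "no-such-set")

    def test_torsions_are_paths_in_bond_graph(self):
        _, topo = make_toy_rna("GGGAAAUCCC")
        topo.validate()  # raises on violation


def test_parameter_set_yaml_round_trip_is_lossless():
    p = get_parameter_set("cg-torsion2")
    q = ParameterSet.from_yaml(p.to_yaml())
    assert q.to_dict() == p.to_dict()
    assert q.torsions == p.torsions


def test_dimension_mismatch_and_coincident_beads_rejected():
    lj = LJCluster(3)
    with pytest.raises(ContractViolation):
        lj.energy_gradient(np.zeros(5))
    x = np.zeros(9)
    x[3:6] = [1e-6, 0, 0]  # two coincident sites
    x[6:9] = [3, 3, 3]
    with pytest.raises(DegenerateGeometryError):
        lj.energy_gradient(x)


class TestExternalAdapter:
    def test_wraps_builtin_bitwise(self, mb_model):
        wrapped = external_adapter(
            mb_model.energy, mb_model.gradient, dimension=2
        )
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(-1, 1, 2)
            assert wrapped.energy(x) == mb_model.energy(x)
            assert np.array_equal(wrapped.gradient(x), mb_model.gradient(x))

    def test_quadratic_bowl_basin_hopping_finds_the_centre(self):
        from pelkit.optim import BasinHoppingConfig, basin_hop

        centre = np.array([0.7, -0.3, 1.1])
        wrapped = external_adapter(
            lambda x: 0.5 * np.sum((x - centre) ** 2),
            lambda x: x - centre,
            dimension=3,
        )
        mins = basin_hop(
            wrapped, np.zeros(3), BasinHoppingConfig(n_steps=20, rng_seed=1)
        )
        assert len(mins) == 1
        assert np.allclose(mins[0].coordinates, centre, atol=1e-6)

    def test_energy_only_adapter_differentiates_numerically(self):
        k = 3.0
        wrapped = external_adapter(
            lambda x: 0.5 * k * float(x @ x), dimension=4
        )
        x = np.array([0.3, -1.2, 0.9, 2.0])
        assert np.abs(wrapped.gradient(x) - k * x).max() < 1e-6

    def test_callback_errors_carry_the_configuration(self):
        def bad(x):
            raise RuntimeError("engine died")

        wrapped = external_adapter(bad, dimension=2)
        with pytest.raises(PotentialEvaluationError) as err:
            wrapped.energy(np.array([1.0, 2.0]))
        assert np.array_equal(err.value.configuration, [1.0, 2.0])
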