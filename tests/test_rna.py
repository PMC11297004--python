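"""RNA structure parsing, descriptors, pairing/stacking, dot-bracket."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelkit.exceptions import (
    BracketOverflowError,
    ContractViolation,
    EmptyStructureError,
    MissingAtomError,
    PdbParseError,
)
from pelkit.fixtures import (
    _attach_sugar,
    _ribose_template,
    base_template,
    build_pseudoknot_structure,
    ideal_stem,
    make_base_pair,
    nmr_like_ensemble,
    write_pdb,
)
from pelkit.geometry import rotation_matrix
from pelkit.rna import (
    annotate_pairs,
    annotate_stacking,
    arc_diagram,
    backbone_dihedrals,
    dot_bracket,
    ensemble_profile,
    nucleotide_descriptors,
    parse_dot_bracket,
    pucker,
    read_pdb_models,
)
from pelkit.rna.structure import NucleotideRecord, RnaStructure

PK_DB = "((((.[[[.)))).....]]]"


def _pair_structure(base1, base2, scheme, separation=0.0):
    a1, a2 = make_base_pair(base1, base2, scheme)
    if separation:
        shift = np.array([0.0, -separation, 0.0])
        a2 = {n: p + shift for n, p in a2.items()}
    return RnaStructure(
        [NucleotideRecord(1, base1, a1), NucleotideRecord(3, base2, a2)]
    )


class TestReadPdb:
    def test_single_model_file(self, tmp_path):
        p = write_pdb([ideal_stem(4)], tmp_path / "stem.pdb")
        models = read_pdb_models(p)
        assert len(models) == 1
        assert len(models[0]) == 11  # 2*4 paired + 3 loop residues

    def test_multi_model_ensemble(self, tmp_path):
        p = write_pdb(nmr_like_ensemble(seed=1), tmp_path / "ens.pdb")
        models = read_pdb_models(p)
        assert len(models) == 14
        assert all(len(m) == 21 for m in models)

    def test_protein_only_file_raises_empty_structure(self, tmp_path):
        lines = [
            "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00  0.00",
            "ATOM      2  CA  GLY A   2      12.560   7.420  -6.222  1.00  0.00",
            "END",
        ]
        p = tmp_path / "protein.pdb"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(EmptyStructureError):
            read_pdb_models(p)

    def test_malformed_atom_line_reports_line_number(self, tmp_path):
        lines = [
            "ATOM      1  C1'   G A   1       0.000   0.000   0.000  1.00  0.00",
            "ATOM      2  N9    G A   1       1.000   bad     0.000  1.00  0.00",
        ]
        p = tmp_path / "broken.pdb"
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(PdbParseError) as err:
            read_pdb_models(p)
        assert err.value.line_number == 2


class TestPucker:
    def test_numerator_zero_gives_phase_zero(self):
        """(ν4+ν1) = (ν3+ν0) with ν2 > 0 puts the phase at exactly 0°."""
        rec = NucleotideRecord(1, "A", _ribose_template(0.0, 38.0))
        phase, amplitude = pucker(rec)
        assert phase == pytest.approx(0.0, abs=1e-6)
        assert amplitude == pytest.approx(38.0, abs=1e-6)

    def test_a_form_ribose_is_c3_endo(self):
        rec = NucleotideRecord(1, "A", _ribose_template(18.0, 38.0))
        phase, _ = pucker(rec)
        assert 0.0 <= phase < 36.0  # N-type / C3'-endo window

    def test_negating_all_torsions_shifts_phase_by_180(self):
        atoms = _ribose_template(18.0, 38.0)
        mirrored = {n: p * np.array([1.0, 1.0, -1.0]) for n, p in atoms.items()}
        p0, _ = pucker(NucleotideRecord(1, "A", atoms))
        p1, _ = pucker(NucleotideRecord(1, "A", mirrored))
        assert p1 == pytest.approx((p0 + 180.0) % 360.0, abs=1e-6)

    def test_missing_ring_atom_flags_undefined(self):
        atoms = _ribose_template(18.0, 38.0)
        del atoms["O4'"]
        with pytest.raises(MissingAtomError):
            pucker(NucleotideRecord(1, "A", atoms))


class TestPairs:
    def test_ideal_gc_pair_is_canonical_with_three_hbonds(self):
        pairs = annotate_pairs(_pair_structure("G", "C", "WC"))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.category == "canonical-WC"
        assert p.edge_i == p.edge_j == "WC"
        assert p.n_hbonds == 3

    def test_separated_bases_do_not_pair(self):
        assert annotate_pairs(_pair_structure("G", "C", "WC", separation=10.0)) == []

    def test_hoogsteen_pair_is_non_canonical_on_the_hoogsteen_edge(self):
        pairs = annotate_pairs(_pair_structure("A", "U", "hoogsteen"))
        assert len(pairs) == 1
        p = pairs[0]
        assert p.category == "non-canonical"
        assert p.edge_i == "Hoogsteen"  # the adenine edge

    def test_wobble_pair_counts_as_wobble(self):
        pairs = annotate_pairs(_pair_structure("G", "U", "wobble"))
        assert len(pairs) == 1
        assert pairs[0].category == "wobble"

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_ideal_stem_annotates_exactly_k_canonical_pairs(self, k):
        pairs = annotate_pairs(ideal_stem(k))
        canonical = [p for p in pairs if p.category == "canonical-WC"]
        assert len(pairs) == len(canonical) == k
        assert {(p.i, p.j) for p in canonical} == {
            (i, 2 * k + 4 - i) for i in range(1, k + 1)
        }


class TestStacking:
    def _ring_structure(self, offset, angle_deg):
        a = base_template("A")
        rot = rotation_matrix([1, 0, 0], math.radians(angle_deg))
        b = {n: rot @ p + np.asarray(offset, float) for n, p in base_template("A").items()}
        return RnaStructure(
            [NucleotideRecord(1, "A", a), NucleotideRecord(2, "A", b)]
        )

    def test_parallel_rings_at_van_der_waals_distance_stack(self):
        s = self._ring_structure([0, 0, 3.4], 0)
        assert annotate_stacking(s) == [(1, 2)]

    def test_side_by_side_coplanar_rings_do_not_stack(self):
        s = self._ring_structure([6.0, 0, 0], 0)
        assert annotate_stacking(s) == []

    def test_perpendicular_rings_do_not_stack(self):
        s = self._ring_structure([0, 0, 3.4], 90)
        assert annotate_stacking(s) == []


class TestDotBracket:
    def test_pseudoknot_pair_set_renders_two_tiers(self):
        stems = [(1, 13), (2, 12), (3, 11), (4, 10), (6, 21), (7, 20), (8, 19)]
        assert dot_bracket(stems, 21) == PK_DB

    def test_no_pairs(self):
        assert dot_bracket([], 5) == "....."

    def test_nested_pairs_use_one_tier(self):
        assert dot_bracket([(1, 6), (2, 5)], 6) == "((..))"

    def test_five_mutually_crossing_pairs_overflow(self):
        pairs = [(i, i + 5) for i in range(1, 6)]
        with pytest.raises(BracketOverflowError):
            dot_bracket(pairs, 10)

    def test_parse_round_trip_on_the_pseudoknot(self):
        assert parse_dot_bracket(PK_DB) == {
            (1, 13), (2, 12), (3, 11), (4, 10), (6, 21), (7, 20), (8, 19),
        }

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_round_trip_property_on_random_pair_sets(self, data):
        n = data.draw(st.integers(4, 30))
        residues = list(range(1, n + 1))
        perm = data.draw(st.permutations(residues))
        n_pairs = data.draw(st.integers(0, n // 2))
        pairs = set()
        for k in range(n_pairs):
            i, j = perm[2 * k], perm[2 * k + 1]
            pairs.add((min(i, j), max(i, j)))
        try:
            s = dot_bracket(sorted(pairs), n)
        except BracketOverflowError:
            return  # >4 mutually crossing tiers: out of notation range
        assert parse_dot_bracket(s) == pairs


class TestArcDiagram:
    def test_pseudoknot_draws_seven_solid_arcs(self, pk_structure):
        pairs = annotate_pairs(pk_structure)
        data, svg = arc_diagram(pairs, 21)
        assert len(data["arcs"]) == 7
        assert all(a["style"] == "solid" for a in data["arcs"])
        assert svg.count("<path") == 7

    def test_empty_pairs_is_just_the_baseline(self):
        data, svg = arc_diagram([], 8)
        assert data["arcs"] == [] and data["unpaired"] == list(range(1, 9))
        assert "<path" not in svg

    def test_non_canonical_pair_is_dashed(self):
        pairs = annotate_pairs(_pair_structure("A", "U", "hoogsteen"))
        data, svg = arc_diagram(pairs, 4)
        assert data["arcs"][0]["style"] == "dashed"
        assert "stroke-dasharray" in svg


class TestEnsembleProfile:
    def test_single_structure_profile_has_zero_spread(self, pk_structure):
        prof = ensemble_profile([pk_structure])
        assert prof.n_structures == 1
        counts = prof.std[["n_stacking", "n_canonical_bp", "n_noncanonical_bp"]]
        assert float(counts.max().max()) == 0.0
        assert prof.dominant_fraction == 1.0

    def test_duplicate_structures_match_the_single_case(self, pk_structure):
        p1 = ensemble_profile([pk_structure])
        p2 = ensemble_profile([pk_structure, pk_structure])
        assert np.allclose(
            p1.mean.drop(columns="base").to_numpy(float),
            p2.mean.drop(columns="base").to_numpy(float),
            equal_nan=True,
        )

    def test_chi_circular_mean_wraps_correctly(self):
        """χ of +170° and −170° must average to 180°, not 0°."""

        def rotate_base(atoms, angle_deg):
            axis = atoms["N9"] - atoms["C1'"]
            rot = rotation_matrix(axis, math.radians(angle_deg))
            pivot = atoms["C1'"]
            out = dict(atoms)
            for n in set(base_template("A")) - {"C1'"}:
                out[n] = rot @ (atoms[n] - pivot) + pivot
            return out

        def one_residue_with_chi(target):
            atoms = _attach_sugar(base_template("A"), "A")
            chi = lambda a: backbone_dihedrals(
                RnaStructure([NucleotideRecord(1, "A", a)]), 1
            )["chi"]
            # probe the rotation sense, then rotate by the signed difference
            sense = 1.0 if chi(rotate_base(atoms, 1.0)) > chi(atoms) else -1.0
            moved = rotate_base(atoms, sense * (target - chi(atoms)))
            return RnaStructure([NucleotideRecord(1, "A", moved)])

        sa = one_residue_with_chi(170.0)
        sb = one_residue_with_chi(-170.0)
        assert backbone_dihedrals(sa, 1)["chi"] == pytest.approx(170.0, abs=1e-6)
        prof = ensemble_profile([sa, sb])
        assert float(prof.mean.loc[1, "chi"]) == pytest.approx(180.0, abs=1e-6)

    def test_mixed_sequences_are_rejected(self, pk_structure):
        other = RnaStructure(
            [NucleotideRecord(1, "A", _attach_sugar(base_template("A"), "A"))]
        )
        with pytest.raises(ContractViolation):
            ensemble_profile([pk_structure, other])

    def test_terminal_dihedrals_are_undefined_not_zero(self, pk_structure):
        descs = nucleotide_descriptors(pk_structure)
        assert descs[0].alpha is None  # 5' terminus has no preceding O3'


def test_descriptors_invariant_under_rigid_motion(pk_structure):
    rot = rotation_matrix([1, 2, 0.5], 1.1)
    moved = pk_structure.transformed(rot, np.array([10.0, -4.0, 2.0]))
    d0 = nucleotide_descriptors(pk_structure)
    d1 = nucleotide_descriptors(moved)
    for a, b in zip(d0, d1):
        assert a.n_stacking == b.n_stacking
        assert a.n_canonical_bp == b.n_canonical_bp
        assert a.n_noncanonical_bp == b.n_noncanonical_bp
        for field in ("pucker_phase", "chi", "delta"):
            va, vb = getattr(a, field), getattr(b, field)
            if va is None:
                assert vb is None
            else:
                assert vb == pytest.approx(va, abs=1e-9)
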