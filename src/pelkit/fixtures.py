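"""Deterministic synthetic fixtures: idealised RNA geometry, hand KTNs.

Everything here is generated programmatically so tests and examples carry
no data files.  The RNA geometry is idealised, not crystallographic:
bases are regular polygons with exocyclic donors/acceptors placed at
chemically sensible positions, pairs are posed by least-squares so the
scheme's hydrogen bonds hit their target length, riboses carry a chosen
pseudorotation phase, and helices stack pairs with A-form-like rise and
twist.  That is exactly what the geometric annotators need to be exercised
against known ground truth.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import least_squares

from .exceptions import ConfigError
from .geometry import rotation_matrix
from .ktn import KTN
from .optim import Minimum
from .rna.structure import NucleotideRecord, RnaStructure
from .tssearch import TransitionState

__all__ = [
    "base_template",
    "make_base_pair",
    "build_stem_structure",
    "build_pseudoknot_structure",
    "nmr_like_ensemble",
    "ideal_stem",
    "hand_ktn",
    "random_ktn",
    "write_pdb",
    "make_fixtures",
]

# ---------------------------------------------------------------------------
# idealised base templates (xy-plane, glycosidic nitrogen near the origin)
# ---------------------------------------------------------------------------

_RING_BOND = 1.38  # aromatic ring bond length, Å
_EXO_BOND = 1.30  # exocyclic C–N / C=O bond length, Å
_C1_BOND = 1.47  # N-glycosidic bond length, Å

_TEMPLATE_CACHE: dict[str, dict] = {}


def _hexagon():
    """Six-membered ring N1 C2 N3 C4 C5 C6, centre at origin."""
    r = _RING_BOND  # circumradius equals bond length for a regular hexagon
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    return {
        n: np.array(
            [r * math.cos(math.radians(-90 - 60 * k)),
             r * math.sin(math.radians(-90 - 60 * k)), 0.0]
        )
        for k, n in enumerate(names)
    }


def _exocyclic(ring: dict, on: str, centre=None) -> np.ndarray:
    centre = np.zeros(3) if centre is None else centre
    v = ring[on] - centre
    return ring[on] + _EXO_BOND * v / np.linalg.norm(v)


def base_template(base: str) -> dict:
    """Atom → xyz template for one base in the xy-plane.

    Purines get the fused five-membered ring (N9, C8, N7) on the C4–C5
    edge; the C1' attachment point is included so sugars can be posed.
    """
    if base in _TEMPLATE_CACHE:
        return {k: v.copy() for k, v in _TEMPLATE_CACHE[base].items()}
    atoms = _hexagon()
    if base in ("A", "G"):
        # regular pentagon sharing the C4–C5 edge, on the far side
        c4, c5 = atoms["C4"], atoms["C5"]
        mid = 0.5 * (c4 + c5)
        out = mid / np.linalg.norm(mid)  # away from the hexagon centre
        side = np.linalg.norm(c5 - c4)
        apothem = side / (2 * math.tan(math.pi / 5))
        circum = side / (2 * math.sin(math.pi / 5))
        pc = mid + apothem * out
        # pentagon vertex angles from the centre
        a4 = math.atan2(*(c4 - pc)[1::-1])
        a5 = math.atan2(*(c5 - pc)[1::-1])
        # walk from C4 away from C5: C4 → N9 → C8 → N7 → C5
        step = 2 * math.pi / 5
        # choose the rotation direction that reaches C5 in four steps
        direction = 1.0
        if abs(((a4 + 5 * step * 0 + 4 * step * direction) - a5) % (2 * math.pi)) > 1e-6:
            ang_diff = (a5 - a4) % (2 * math.pi)
            direction = 1.0 if abs(ang_diff - 4 * step) < abs(
                (2 * math.pi - ang_diff) - 4 * step
            ) else -1.0
        for k, name in enumerate(["N9", "C8", "N7"], start=1):
            ang = a4 + direction * k * step
            atoms[name] = pc + circum * np.array(
                [math.cos(ang), math.sin(ang), 0.0]
            )
        if base == "A":
            atoms["N6"] = _exocyclic(atoms, "C6")
        else:
            atoms["O6"] = _exocyclic(atoms, "C6")
            atoms["N2"] = _exocyclic(atoms, "C2")
        anchor = "N9"
        pent_centre = pc
        v = atoms[anchor] - pent_centre
    else:
        if base == "C":
            atoms["O2"] = _exocyclic(atoms, "C2")
            atoms["N4"] = _exocyclic(atoms, "C4")
        else:  # U
            atoms["O2"] = _exocyclic(atoms, "C2")
            atoms["O4"] = _exocyclic(atoms, "C4")
        anchor = "N1"
        v = atoms[anchor]  # from hexagon centre
    atoms["C1'"] = atoms[anchor] + _C1_BOND * v / np.linalg.norm(v)
    _TEMPLATE_CACHE[base] = {k: p.copy() for k, p in atoms.items()}
    return {k: p.copy() for k, p in atoms.items()}


# hydrogen-bond schemes: (atom on base 1, atom on base 2)
HBOND_SCHEMES = {
    ("G", "C", "WC"): [("O6", "N4"), ("N1", "N3"), ("N2", "O2")],
    ("A", "U", "WC"): [("N6", "O4"), ("N1", "N3")],
    ("G", "U", "wobble"): [("O6", "N3"), ("N1", "O2")],
    ("A", "U", "hoogsteen"): [("N7", "N3"), ("N6", "O4")],
}

_HB_TARGET = 2.85  # Å donor–acceptor distance


def make_base_pair(
    base1: str, base2: str, scheme: str = "WC"
) -> tuple[dict, dict]:
    """Coplanar idealised base pair; returns the two atom dictionaries.

    Base 1 keeps its template pose (xy-plane); base 2 is flipped about the
    x-axis (antiparallel strands) and posed in-plane so every hydrogen bond
    of the scheme has the target donor–acceptor distance, with a soft
    penalty keeping non-bonded atoms apart.
    """
    if (base1, base2, scheme) not in HBOND_SCHEMES:
        if (base2, base1, scheme) in HBOND_SCHEMES:
            a2, a1 = make_base_pair(base2, base1, scheme)
            return a1, a2
        raise ConfigError(f"no hydrogen-bond scheme for {base1}·{base2} {scheme!r}")
    hbonds = HBOND_SCHEMES[(base1, base2, scheme)]
    from .rna.structure import RING_ATOMS

    def edge_frame(template, base, atoms_on_edge):
        """(edge centroid, unit edge direction, unit outward normal)."""
        centroid = np.mean([template[n] for n in RING_ATOMS[base]], axis=0)
        pts = [template[a] for a in atoms_on_edge]
        c = np.mean(pts, axis=0)
        d = pts[-1] - pts[0]
        d = d / np.linalg.norm(d)
        out = c - centroid
        out = out - (out @ d) * d  # perpendicular component, away from ring
        out = out / np.linalg.norm(out)
        return c, d, out

    t1 = base_template(base1)
    t2 = base_template(base2)
    c1, d1, u1 = edge_frame(t1, base1, [a for a, _ in hbonds])
    c2, d2, u2 = edge_frame(t2, base2, [a for _, a in hbonds])

    # map the partner's edge frame onto base 1's: edge directions aligned in
    # pairing order, outward normals opposed (rings on opposite sides).  The
    # 2x2 map may be improper in-plane, i.e. the base flipped over — the
    # antiparallel arrangement.
    B = np.column_stack([d1[:2], -u1[:2]])
    C = np.column_stack([d2[:2], u2[:2]])
    A = B @ np.linalg.inv(C)
    target_c = c1 + _HB_TARGET * u1
    names2 = list(t2)
    pts2 = np.array(
        [np.r_[A @ (t2[n][:2] - c2[:2]) + target_c[:2], 0.0] for n in names2]
    )
    idx2 = {n: k for k, n in enumerate(names2)}

    # in-plane polish: rotate/translate to equalise the hydrogen bonds
    def pose_pts(params):
        tx, ty, th = params
        rot = rotation_matrix([0, 0, 1], th)
        pivot = pts2.mean(axis=0)
        return (pts2 - pivot) @ rot.T + pivot + np.array([tx, ty, 0.0])

    def residuals(params):
        moved = pose_pts(params)
        return np.array(
            [
                np.linalg.norm(t1[a1] - moved[idx2[a2]]) - _HB_TARGET
                for a1, a2 in hbonds
            ]
        )

    sol = least_squares(residuals, [0.0, 0.0, 0.0], method="trf", max_nfev=2000)
    moved = pose_pts(sol.x)
    return t1, {n: moved[idx2[n]] for n in names2}


# ---------------------------------------------------------------------------
# sugars and backbone
# ---------------------------------------------------------------------------

def _ribose_template(target_phase: float = 18.0, amplitude: float = 38.0) -> dict:
    """Five-membered ribose ring with a prescribed pseudorotation phase.

    A near-planar pentagon with out-of-plane displacements
    z_k = q·cos(4πk/5 + φ); q and φ are fitted so the Altona–Sundaralingam
    phase/amplitude computed from the ring torsions hit the targets.
    C3'-endo (phase ≈ 18°) reproduces the A-form sugar.  C5', O5' and O3'
    substituents are attached at sensible positions.
    """
    from .rna.descriptors import pucker

    names = ["C1'", "C2'", "C3'", "C4'", "O4'"]
    r = 1.18

    def ring(q, phi):
        atoms = {}
        for k, n in enumerate(names):
            ang = 2 * math.pi * k / 5
            atoms[n] = np.array(
                [
                    r * math.cos(ang),
                    r * math.sin(ang),
                    q * math.cos(2 * ang + phi),
                ]
            )
        return atoms

    def err(params):
        q, phi = params
        rec = NucleotideRecord(1, "A", ring(q, phi))
        try:
            p, amp = pucker(rec)
        except Exception:
            return [1e3, 1e3]
        dp = (p - target_phase + 180) % 360 - 180
        return [dp, amp - amplitude]

    sol = least_squares(err, [0.35, 0.0], bounds=([0.05, -math.pi], [0.8, math.pi]))
    atoms = ring(*sol.x)
    # substituents: C5' on C4', O3' on C3', O5' on C5' — placed outward and
    # out of plane, adequate for dihedral definitions
    for parent, child, length, zoff in (
        ("C4'", "C5'", 1.51, 1.1),
        ("C3'", "O3'", 1.42, -1.1),
    ):
        v = atoms[parent] / np.linalg.norm(atoms[parent])
        atoms[child] = atoms[parent] + length * (
            0.7 * v + np.array([0, 0, zoff])
        )
    v = atoms["C5'"] - atoms["C4'"]
    atoms["O5'"] = atoms["C5'"] + 1.42 * (
        v / np.linalg.norm(v) * 0.6 + np.array([0.0, 0.4, 0.5])
    )
    return atoms


def _attach_sugar(base_atoms: dict, base: str, phase: float = 18.0) -> dict:
    """Pose a ribose so its C1' sits on the base's C1' attachment point."""
    sugar = _ribose_template(phase)
    anchor = "N9" if base in ("A", "G") else "N1"
    c1 = base_atoms["C1'"]
    d = c1 - base_atoms[anchor]
    d = d / np.linalg.norm(d)
    # base-plane normal at this pose
    ring_atoms = [base_atoms[n] for n in ("N1", "C2", "N3")]
    n = np.cross(ring_atoms[1] - ring_atoms[0], ring_atoms[2] - ring_atoms[0])
    n = n / np.linalg.norm(n)
    e1 = d
    e2 = np.cross(n, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    frame = np.column_stack([e1, e2, e3])
    out = dict(base_atoms)
    sugar_c1 = sugar["C1'"]
    for name, pos in sugar.items():
        if name == "C1'":
            continue
        local = pos - sugar_c1
        out[name] = c1 + frame @ local
    return out


# ---------------------------------------------------------------------------
# stems, pseudoknot, ensembles
# ---------------------------------------------------------------------------

_RISE = 2.81  # Å per pair, A-form-like
_TWIST = math.radians(32.7)


def _pose_pair(pair_atoms, k: int, z0: float = 0.0):
    rot = rotation_matrix([0, 0, 1], k * _TWIST)
    tr = np.array([0.0, 0.0, z0 + k * _RISE])
    return {n: rot @ p + tr for n, p in pair_atoms.items()}


def build_stem_structure(
    pairings: list, n_residues: int, z0: float = 0.0, attach_sugars: bool = True
) -> dict:
    """Residue-indexed atom dicts for a stem.

    ``pairings`` is a list of (i, j, base_i, base_j[, scheme]) with i on the
    ascending strand and j on the descending strand; pair k is stacked at
    height z0 + k·rise with k·twist.  Returns {residue index: (base, atoms)}.
    Residues not in any pair are absent.
    """
    residues = {}
    for k, entry in enumerate(pairings):
        i, j, bi, bj, *rest = entry
        scheme = rest[0] if rest else "WC"
        a1, a2 = make_base_pair(bi, bj, scheme)
        if attach_sugars:
            a1 = _attach_sugar(a1, bi)
            a2 = _attach_sugar(a2, bj)
        posed1 = _pose_pair(a1, k, z0)
        posed2 = _pose_pair(a2, k, z0)
        residues[i] = (bi, posed1)
        residues[j] = (bj, posed2)
    return residues


def _add_phosphates(structure_atoms: dict) -> None:
    """Place a bridging P between consecutive residues where possible."""
    for idx in sorted(structure_atoms):
        prev = idx - 1
        if prev not in structure_atoms:
            continue
        _, atoms_prev = structure_atoms[prev]
        base, atoms = structure_atoms[idx]
        if "O3'" in atoms_prev and "O5'" in atoms:
            atoms["P"] = 0.5 * (atoms_prev["O3'"] + atoms["O5'"])


PK_SEQUENCE = "GGGGUGCCUCCCCAAAAAGGC"  # 21 nt, stems (1-4:13-10) and (6-8:21-19)
PK_STEM1 = [(1, 13), (2, 12), (3, 11), (4, 10)]
PK_STEM2 = [(6, 21), (7, 20), (8, 19)]


def build_pseudoknot_structure(sequence: str = PK_SEQUENCE) -> RnaStructure:
    """Idealised H-type pseudoknot: two coaxially stacked stems.

    Stem 1 (four pairs) sits below stem 2 (three pairs) on a common axis,
    the classic H-type arrangement; loop residues are placed on a wide
    ring well clear of all pairing/stacking cutoffs.
    """
    seq = sequence.upper()
    n = len(seq)
    pair_list = []
    for i, j in PK_STEM1:
        pair_list.append((i, j, seq[i - 1], seq[j - 1]))
    stem1 = build_stem_structure(pair_list, n, z0=0.0)
    pair_list2 = [(i, j, seq[i - 1], seq[j - 1]) for i, j in PK_STEM2]
    stem2 = build_stem_structure(pair_list2, n, z0=len(PK_STEM1) * _RISE + 1.2)

    residues_atoms = dict(stem1)
    residues_atoms.update(stem2)
    # loop residues on a wide circle, tilted so they cannot pair or stack
    loop = [i for i in range(1, n + 1) if i not in residues_atoms]
    for k, i in enumerate(loop):
        ang = 2 * math.pi * k / max(len(loop), 1)
        centre = np.array(
            [16.0 * math.cos(ang), 16.0 * math.sin(ang), 4.0 * k - 2.0]
        )
        atoms = base_template(seq[i - 1])
        atoms = _attach_sugar(atoms, seq[i - 1])
        tilt = rotation_matrix([math.cos(ang), math.sin(ang), 0.0], 0.9 + 0.4 * k)
        atoms = {nm: tilt @ p + centre for nm, p in atoms.items()}
        residues_atoms[i] = (seq[i - 1], atoms)
    _add_phosphates(residues_atoms)
    records = [
        NucleotideRecord(i, residues_atoms[i][0], residues_atoms[i][1])
        for i in sorted(residues_atoms)
    ]
    return RnaStructure(records, model_id=0)


def nmr_like_ensemble(
    n_models: int = 14, seed: int = 0, noise: float = 0.05
) -> list[RnaStructure]:
    """Ensemble of perturbed copies of the idealised pseudoknot.

    Mimics the shape of a solution-NMR deposition: 14 models of a
    21-residue chain with a 4-bp and a 3-bp stem; per-model Gaussian
    coordinate noise (``noise`` Å) is small enough that the annotation is
    stable across models.
    """
    ref = build_pseudoknot_structure()
    models = []
    for m in range(n_models):
        rng = np.random.default_rng(seed * 1000 + m)
        residues = []
        for r in ref.residues:
            atoms = {
                n: p + rng.normal(0.0, noise, 3) for n, p in r.atoms.items()
            }
            residues.append(NucleotideRecord(r.index, r.base, atoms))
        models.append(RnaStructure(residues, model_id=m + 1))
    return models


def ideal_stem(k: int, base1: str = "G", base2: str = "C") -> RnaStructure:
    """A-form-like hairpin helix of ``k`` canonical pairs plus a 3-nt loop.

    Residue i (1..k) pairs with 2k+4−i; loop residues k+1..k+3 are placed
    well outside every interaction cutoff.  Ground truth for the pair
    annotator: exactly ``k`` canonical pairs.
    """
    if k < 1:
        raise ConfigError("stem needs at least one pair")
    n = 2 * k + 3
    pairings = [(i, n + 1 - i, base1, base2) for i in range(1, k + 1)]
    residues_atoms = build_stem_structure(pairings, n)
    for m, i in enumerate(range(k + 1, k + 4)):  # loop, far from the helix
        ang = 2 * math.pi * m / 3
        centre = np.array(
            [18.0 * math.cos(ang), 18.0 * math.sin(ang), 6.0 * m]
        )
        atoms = _attach_sugar(base_template("A"), "A")
        tilt = rotation_matrix([math.cos(ang), math.sin(ang), 0.0], 1.0 + 0.5 * m)
        residues_atoms[i] = ("A", {nm: tilt @ p + centre for nm, p in atoms.items()})
    _add_phosphates(residues_atoms)
    records = [
        NucleotideRecord(i, residues_atoms[i][0], residues_atoms[i][1])
        for i in sorted(residues_atoms)
    ]
    return RnaStructure(records, model_id=0)


# ---------------------------------------------------------------------------
# hand-built and random KTNs
# ---------------------------------------------------------------------------

def _mk_min(e: float, coord) -> Minimum:
    return Minimum(
        energy=float(e),
        coordinates=np.atleast_1d(np.asarray(coord, float)),
        gradient_rms=1e-9,
    )


def _mk_ts(e: float, coord, a: int, b: int) -> TransitionState:
    return TransitionState(
        energy=float(e),
        coordinates=np.atleast_1d(np.asarray(coord, float)),
        lowest_eigenvalue=-1.0,
        eigenvector=np.ones(np.atleast_1d(np.asarray(coord)).size),
        gradient_rms=1e-9,
        minus_min_id=a,
        plus_min_id=b,
    )


TOY_RNA_SEQUENCE = "GGGAAAUCCC"


def toy_rna_fixture_ktn(
    parameter_set: str = "cg-default",
    n_steps: int = 120,
    seeds: tuple = (11, 12),
):
    """The shipped toy-RNA hairpin database.

    Basin-hopping under ``parameter_set`` from a folded (hairpin) and an
    unfolded (extended) start — the two-sided seeding that populates
    folded, partially folded and unfolded minima.  Returns
    ``(model, topology, ktn)``; deterministic for fixed seeds.
    """
    from .optim import BasinHoppingConfig, basin_hop
    from .potentials import (
        compact_configuration,
        extended_configuration,
        hairpin_native_pairs,
        make_toy_rna,
    )

    native = hairpin_native_pairs(len(TOY_RNA_SEQUENCE))
    model, topo = make_toy_rna(
        TOY_RNA_SEQUENCE, parameter_set, native_pairs=native
    )
    ktn = KTN(model.name, model.dimension)
    starts = (compact_configuration(topo), extended_configuration(topo))
    for start, seed in zip(starts, seeds):
        minima = basin_hop(
            model,
            start,
            BasinHoppingConfig(
                n_steps=n_steps, rng_seed=seed, step_size=2.0, temperature=2.0
            ),
        )
        ktn.add_minima(minima)
        ktn.log_event(op="basin-hop", seed=seed, n_steps=n_steps)
    return model, topo, ktn


def hand_ktn() -> KTN:
    """Three minima a(0), b(2), c(1) with TS a–b at 5 and b–c at 3.

    The worked example for superbasin analysis: a and c first share a
    superbasin at level 5, b and c at level 3, barrier(a, c) = 5.
    """
    k = KTN("hand-ktn", dimension=1, use_alignment=False)
    ida = k.add_stationary_point(_mk_min(0.0, [0.0]))
    idb = k.add_stationary_point(_mk_min(2.0, [4.0]))
    idc = k.add_stationary_point(_mk_min(1.0, [8.0]))
    k.add_stationary_point(_mk_ts(5.0, [2.0], ida, idb))
    k.add_stationary_point(_mk_ts(3.0, [6.0], idb, idc))
    return k


def random_ktn(
    n_minima: int, seed: int, extra_edge_fraction: float = 0.4
) -> KTN:
    """Random connected KTN with prescribed energies (barrier-oracle tests).

    A random spanning tree plus a fraction of extra TS edges; minimum
    energies uniform in [0, 5), TS energies above both endpoints.
    """
    rng = np.random.default_rng(seed)
    k = KTN(f"random-ktn-{seed}", dimension=1, use_alignment=False)
    energies = rng.uniform(0.0, 5.0, n_minima)
    ids = [
        k.add_stationary_point(_mk_min(e, [10.0 * i]))
        for i, e in enumerate(energies)
    ]
    edges = []
    for i in range(1, n_minima):
        j = int(rng.integers(0, i))
        edges.append((ids[i], ids[j]))
    n_extra = int(extra_edge_fraction * n_minima)
    for _ in range(n_extra):
        a, b = rng.choice(ids, size=2, replace=False)
        edges.append((int(a), int(b)))
    for a, b in edges:
        base = max(energies[a], energies[b])
        k.add_stationary_point(
            _mk_ts(base + float(rng.uniform(0.2, 6.0)), [5.0 + a + b], a, b)
        )
    return k


# ---------------------------------------------------------------------------
# PDB writing and the fixture entry point
# ---------------------------------------------------------------------------

def write_pdb(models: list[RnaStructure], path) -> Path:
    """Write structures as a (multi-)MODEL PDB file, 1-based numbering."""
    path = Path(path)
    lines = []
    multi = len(models) > 1
    for model in models:
        if multi:
            lines.append(f"MODEL     {model.model_id:4d}")
        serial = 1
        for res in model.residues:
            for name in sorted(res.atoms):
                x, y, z = res.atoms[name]
                pdb_name = name if len(name) == 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {res.base:>2s} A"
                    f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}"
                )
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


FIXTURE_KINDS = (
    "mueller-brown",
    "lj-cluster",
    "toy-rna",
    "ideal-stem-pdb",
    "hand-ktn",
    "nmr-like-ensemble",
)


def make_fixtures(kind: str, params: dict | None = None, seed: int = 0, out_dir=".") -> list:
    """Write deterministic fixture files; returns the paths written.

    Kinds: ``mueller-brown`` (surface constants + reference start points),
    ``lj-cluster`` (random start coordinates), ``toy-rna`` (chain config +
    start coordinates), ``ideal-stem-pdb`` (k-pair helix), ``hand-ktn``
    (three-minimum database), ``nmr-like-ensemble`` (multi-model
    pseudoknot PDB).
    """
    from .io import write_ktn
    from .potentials import (
        MuellerBrown,
        extended_configuration,
        hairpin_native_pairs,
        make_toy_rna,
    )

    params = params or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if kind == "mueller-brown":
        mb = MuellerBrown()
        doc = {
            "potential": "mueller-brown",
            "constants": {
                "A": mb.A.tolist(),
                "a": mb.a.tolist(),
                "b": mb.b.tolist(),
                "c": mb.c.tolist(),
                "x0": mb.x0.tolist(),
                "y0": mb.y0.tolist(),
            },
            "start_points": [[0.0, 0.0], [-0.5, 1.5], [0.6, 0.0]],
        }
        p = out / "mueller-brown.yaml"
        p.write_text(yaml.safe_dump(doc))
        written.append(p)
    elif kind == "lj-cluster":
        n = int(params.get("n", 7))
        rng = np.random.default_rng(seed)
        coords = rng.normal(0.0, 1.1, (n, 3))
        p = out / f"lj{n}-start.txt"
        p.write_text(
            f"# LJ{n} start coordinates (reduced units), seed {seed}\n"
            + "\n".join(" ".join(repr(v) for v in row) for row in coords)
            + "\n"
        )
        written.append(p)
    elif kind == "toy-rna":
        sequence = params.get("sequence", "GGGAAAUCCC")
        pset = params.get("parameter_set", "cg-default")
        native = hairpin_native_pairs(len(sequence))
        model, topo = make_toy_rna(sequence, pset, native_pairs=native)
        doc = {
            "sequence": sequence,
            "parameter_set": model.parameters.to_dict(),
            "native_pairs": [list(p_) for p_ in native],
            "units": "kcal/mol, Å",
        }
        p = out / "toy-rna.yaml"
        p.write_text(yaml.safe_dump(doc))
        written.append(p)
        x0 = extended_configuration(topo)
        p2 = out / "toy-rna-start.txt"
        p2.write_text("\n".join(repr(v) for v in x0) + "\n")
        written.append(p2)
    elif kind == "ideal-stem-pdb":
        k = int(params.get("k", 4))
        written.append(write_pdb([ideal_stem(k)], out / f"ideal-stem-{k}bp.pdb"))
    elif kind == "hand-ktn":
        written.append(write_ktn(hand_ktn(), out / "hand-ktn"))
    elif kind == "nmr-like-ensemble":
        models = nmr_like_ensemble(
            n_models=int(params.get("n_models", 14)), seed=seed
        )
        written.append(write_pdb(models, out / "nmr-like-ensemble.pdb"))
    else:
        raise ConfigError(
            f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}"
        )
    return written
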