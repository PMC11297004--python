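"""Per-nucleotide structural descriptors and basin-ensemble profiles.

Sugar pucker as the pseudorotation phase from the five ribose ring torsions
(Altona–Sundaralingam convention), the six backbone dihedrals plus the
glycosidic angle, geometric base-pair annotation with edge classification
(Watson–Crick / Hoogsteen / Sugar), base-stacking detection, and ensemble
averaging with circular statistics for the angular quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from ..exceptions import ContractViolation, MissingAtomError
from ..geometry import dihedral
from .structure import RING_ATOMS, SUGAR_RING, NucleotideRecord, RnaStructure

__all__ = [
    "pucker",
    "backbone_dihedrals",
    "BasePair",
    "PairingCutoffs",
    "annotate_pairs",
    "StackingCutoffs",
    "annotate_stacking",
    "NucleotideDescriptor",
    "nucleotide_descriptors",
    "EnsembleProfile",
    "ensemble_profile",
]

# ---------------------------------------------------------------------------
# sugar pucker
# ---------------------------------------------------------------------------

# endocyclic torsions ν0..ν4 of the ribose ring
_NU_ATOMS = [
    ("C4'", "O4'", "C1'", "C2'"),  # ν0
    ("O4'", "C1'", "C2'", "C3'"),  # ν1
    ("C1'", "C2'", "C3'", "C4'"),  # ν2
    ("C2'", "C3'", "C4'", "O4'"),  # ν3
    ("C3'", "C4'", "O4'", "C1'"),  # ν4
]


def pucker(residue: NucleotideRecord) -> tuple[float, float]:
    """Pseudorotation phase (deg, in [0, 360)) and amplitude (deg).

    P = atan2((ν4 + ν1) − (ν3 + ν0), 2 ν2 (sin 36° + sin 72°)), with the
    amplitude τm = ν2 / cos P.  Phases in [0°, 36°) are C3'-endo (N-type,
    A-form); around 162° is C2'-endo (S-type).

    Raises
    ------
    MissingAtomError
        If any of the five ring atoms is absent.
    """
    if not residue.has_atoms(SUGAR_RING):
        missing = [a for a in SUGAR_RING if a not in residue.atoms]
        raise MissingAtomError(
            f"residue {residue.index}: ring atoms missing {missing}"
        )
    nu = [
        dihedral(*(residue.atoms[a] for a in quad)) for quad in _NU_ATOMS
    ]
    y = (nu[4] + nu[1]) - (nu[3] + nu[0])
    x = 2.0 * nu[2] * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    p = math.degrees(math.atan2(y, x)) % 360.0
    amplitude = nu[2] / math.cos(math.radians(p))
    return p, float(amplitude)


# ---------------------------------------------------------------------------
# backbone and glycosidic dihedrals
# ---------------------------------------------------------------------------

def backbone_dihedrals(
    structure: RnaStructure, index: int
) -> dict[str, float | None]:
    """α..ζ and χ (degrees) for 1-based residue ``index``.

    Terminal residues have undefined α (5' end) or ε/ζ (3' end); those are
    returned as ``None`` rather than imputed.
    """
    res = structure.residue(index)
    prev = structure.residue_or_none(index - 1)
    nxt = structure.residue_or_none(index + 1)

    def tor(*atom_specs):
        pts = []
        for r, name in atom_specs:
            if r is None or name not in r.atoms:
                return None
            pts.append(r.atoms[name])
        return dihedral(*pts)

    chi_names = (
        ("O4'", "C1'", "N9", "C4") if res.is_purine else ("O4'", "C1'", "N1", "C2")
    )
    return {
        "alpha": tor((prev, "O3'"), (res, "P"), (res, "O5'"), (res, "C5'")),
        "beta": tor((res, "P"), (res, "O5'"), (res, "C5'"), (res, "C4'")),
        "gamma": tor((res, "O5'"), (res, "C5'"), (res, "C4'"), (res, "C3'")),
        "delta": tor((res, "C5'"), (res, "C4'"), (res, "C3'"), (res, "O3'")),
        "epsilon": tor((res, "C4'"), (res, "C3'"), (res, "O3'"), (nxt, "P")),
        "zeta": tor((res, "C3'"), (res, "O3'"), (nxt, "P"), (nxt, "O5'")),
        "chi": tor(*((res, n) for n in chi_names)),
    }


# ---------------------------------------------------------------------------
# base pairing
# ---------------------------------------------------------------------------

# hydrogen-bond donor / acceptor heavy atoms per base
_DONORS = {"A": {"N6"}, "G": {"N1", "N2"}, "C": {"N4"}, "U": {"N3"}}
_ACCEPTORS = {
    "A": {"N1", "N3", "N7"},
    "G": {"O6", "N3", "N7"},
    "C": {"N3", "O2"},
    "U": {"O2", "O4"},
}

# base-edge membership of the rim atoms (Watson–Crick / Hoogsteen / Sugar);
# atoms shared between edges list both
_EDGES = {
    "A": {"N1": {"WC"}, "N6": {"WC", "Hoogsteen"}, "N7": {"Hoogsteen"},
          "C2": {"WC", "Sugar"}, "N3": {"Sugar"}},
    "G": {"N1": {"WC"}, "N2": {"WC", "Sugar"}, "O6": {"WC", "Hoogsteen"},
          "N7": {"Hoogsteen"}, "N3": {"Sugar"}},
    "C": {"N3": {"WC"}, "N4": {"WC", "Hoogsteen"}, "O2": {"WC", "Sugar"}},
    "U": {"N3": {"WC"}, "O4": {"WC", "Hoogsteen"}, "O2": {"WC", "Sugar"}},
}

_EDGE_PRIORITY = {"WC": 0, "Hoogsteen": 1, "Sugar": 2}

_CANONICAL = {frozenset(("G", "C")), frozenset(("A", "U"))}
_WOBBLE = {frozenset(("G", "U"))}


@dataclass
class BasePair:
    """An annotated base-base interaction (i < j, 1-based residues)."""

    i: int
    j: int
    category: str  # canonical-WC | wobble | non-canonical
    edge_i: str  # WC | Hoogsteen | Sugar
    edge_j: str
    n_hbonds: int
    hbonds: list = field(default_factory=list)  # [(atom_i, atom_j, distance)]

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a base cannot pair with itself")
        if self.n_hbonds < 1:
            raise ValueError("a base pair needs at least one hydrogen bond")

    @property
    def residues(self) -> frozenset:
        return frozenset((self.i, self.j))


@dataclass
class PairingCutoffs:
    """Geometric thresholds for base-pair detection (Å / degrees)."""

    max_centre_distance: float = 7.5
    max_plane_angle: float = 35.0
    max_vertical_offset: float = 2.0  # Å along the mean normal: coplanarity
    max_hbond_distance: float = 3.5
    min_sequence_separation: int = 2  # skip i, i+1 neighbours


def _plane(coords: np.ndarray):
    """Centre and unit normal of a ring atom set (least-squares plane)."""
    centre = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centre)
    return centre, vt[2]


def _classify_edge(base: str, atoms_used) -> str:
    scores = {"WC": 0, "Hoogsteen": 0, "Sugar": 0}
    for a in atoms_used:
        for e in _EDGES[base].get(a, ()):
            scores[e] += 1
    best = max(scores.values())
    if best == 0:
        return "WC"
    return min(
        (e for e, s in scores.items() if s == best),
        key=lambda e: _EDGE_PRIORITY[e],
    )


def annotate_pairs(
    structure: RnaStructure, cutoffs: PairingCutoffs | None = None
) -> list[BasePair]:
    """Geometric base-pair annotation.

    Two bases pair when their ring centres are close, their planes are
    nearly parallel AND nearly coplanar (small offset along the normal — the
    feature separating pairing from stacking), and at least one
    donor–acceptor pair of rim heavy atoms lies within hydrogen-bond range.
    The interacting edge of each base follows from which rim atoms
    participate; the category is canonical-WC only for G·C / A·U on their
    WC edges, wobble for G·U on WC edges, non-canonical otherwise.
    """
    cutoffs = cutoffs or PairingCutoffs()
    planes = {}
    for res in structure.residues:
        rc = res.ring_coords()
        if rc is not None:
            planes[res.index] = _plane(rc)
    pairs = []
    indices = sorted(planes)
    for ii, i in enumerate(indices):
        for j in indices[ii + 1 :]:
            if j - i < cutoffs.min_sequence_separation:
                continue
            ci, ni = planes[i]
            cj, nj = planes[j]
            dvec = cj - ci
            if np.linalg.norm(dvec) > cutoffs.max_centre_distance:
                continue
            cosang = abs(ni @ nj)
            if math.degrees(math.acos(min(cosang, 1.0))) > cutoffs.max_plane_angle:
                continue
            n_mean = ni + (nj if ni @ nj >= 0 else -nj)
            n_mean /= np.linalg.norm(n_mean)
            if abs(dvec @ n_mean) > cutoffs.max_vertical_offset:
                continue
            ri, rj = structure.residue(i), structure.residue(j)
            hbonds = []
            for di_, ai_ in (
                (_DONORS[ri.base], _ACCEPTORS[rj.base]),
                (_ACCEPTORS[ri.base], _DONORS[rj.base]),
            ):
                for a in di_:
                    if a not in ri.atoms:
                        continue
                    for b in ai_:
                        if b not in rj.atoms:
                            continue
                        d = float(np.linalg.norm(ri.atoms[a] - rj.atoms[b]))
                        if d <= cutoffs.max_hbond_distance:
                            hbonds.append((a, b, d))
            if not hbonds:
                continue
            seen = set()
            unique = []
            for a, b, d in sorted(hbonds, key=lambda h: h[2]):
                if (a, b) in seen:
                    continue
                seen.add((a, b))
                unique.append((a, b, d))
            edge_i = _classify_edge(ri.base, {h[0] for h in unique})
            edge_j = _classify_edge(rj.base, {h[1] for h in unique})
            kind = frozenset((ri.base, rj.base))
            if kind in _CANONICAL and edge_i == edge_j == "WC" and len(unique) >= 2:
                category = "canonical-WC"
            elif kind in _WOBBLE and edge_i == edge_j == "WC":
                category = "wobble"
            else:
                category = "non-canonical"
            pairs.append(
                BasePair(
                    i=i,
                    j=j,
                    category=category,
                    edge_i=edge_i,
                    edge_j=edge_j,
                    n_hbonds=len(unique),
                    hbonds=unique,
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

@dataclass
class StackingCutoffs:
    """Geometric thresholds for base-stacking detection."""

    max_centre_distance: float = 4.5  # Å
    max_plane_angle: float = 30.0  # degrees
    max_lateral_offset: float = 2.5  # Å, centre offset projected on the plane


def annotate_stacking(
    structure: RnaStructure, cutoffs: StackingCutoffs | None = None
) -> list[tuple[int, int]]:
    """Stacked base pairs (i, j), i < j, by the ring-geometry criterion.

    Stacked means: ring centres within ``max_centre_distance``, planes
    within ``max_plane_angle`` of parallel, and the centre-centre vector's
    in-plane component at most ``max_lateral_offset`` (the bases sit on top
    of each other rather than side by side).
    """
    cutoffs = cutoffs or StackingCutoffs()
    planes = {}
    for res in structure.residues:
        rc = res.ring_coords()
        if rc is not None:
            planes[res.index] = _plane(rc)
    stacked = []
    indices = sorted(planes)
    for ii, i in enumerate(indices):
        for j in indices[ii + 1 :]:
            ci, ni = planes[i]
            cj, nj = planes[j]
            dvec = cj - ci
            dist = np.linalg.norm(dvec)
            if dist > cutoffs.max_centre_distance:
                continue
            cosang = abs(ni @ nj)
            if math.degrees(math.acos(min(cosang, 1.0))) > cutoffs.max_plane_angle:
                continue
            n_mean = ni + (nj if ni @ nj >= 0 else -nj)
            n_mean /= np.linalg.norm(n_mean)
            lateral = np.linalg.norm(dvec - (dvec @ n_mean) * n_mean)
            if lateral <= cutoffs.max_lateral_offset:
                stacked.append((i, j))
    return stacked


# ---------------------------------------------------------------------------
# per-nucleotide descriptors and ensemble profiles
# ---------------------------------------------------------------------------

ANGULAR_FIELDS = [
    "pucker_phase",
    "alpha",
    "beta",
    "gamma",
    "delta",
    "epsilon",
    "zeta",
    "chi",
]
COUNT_FIELDS = ["n_stacking", "n_canonical_bp", "n_noncanonical_bp"]
SCALAR_FIELDS = ["pucker_amplitude"]
ALL_FIELDS = ANGULAR_FIELDS + SCALAR_FIELDS + COUNT_FIELDS


@dataclass
class NucleotideDescriptor:
    """All per-nucleotide descriptors of one residue in one structure.

    Angular fields are degrees (``None`` when undefined, e.g. terminal α);
    counts are interaction tallies from the pairing/stacking annotation.
    """

    index: int
    base: str
    pucker_phase: float | None
    pucker_amplitude: float | None
    alpha: float | None
    beta: float | None
    gamma: float | None
    delta: float | None
    epsilon: float | None
    zeta: float | None
    chi: float | None
    n_stacking: int
    n_canonical_bp: int
    n_noncanonical_bp: int


def nucleotide_descriptors(
    structure: RnaStructure,
    pairing_cutoffs: PairingCutoffs | None = None,
    stacking_cutoffs: StackingCutoffs | None = None,
    wobble_is_canonical: bool = True,
) -> list[NucleotideDescriptor]:
    """Descriptors for every residue of one structure.

    ``wobble_is_canonical`` counts G·U wobble pairs in the canonical tally
    (the common convention for per-nucleotide pairing profiles); switch off
    to count them as non-canonical.
    """
    pairs = annotate_pairs(structure, pairing_cutoffs)
    stacks = annotate_stacking(structure, stacking_cutoffs)
    canonical_kinds = {"canonical-WC"} | (
        {"wobble"} if wobble_is_canonical else set()
    )
    n_stack = {r.index: 0 for r in structure.residues}
    n_can = dict(n_stack)
    n_non = dict(n_stack)
    for i, j in stacks:
        n_stack[i] += 1
        n_stack[j] += 1
    for p in pairs:
        tgt = n_can if p.category in canonical_kinds else n_non
        tgt[p.i] += 1
        tgt[p.j] += 1
    out = []
    for res in structure.residues:
        try:
            phase, amp = pucker(res)
        except MissingAtomError:
            phase, amp = None, None
        tors = backbone_dihedrals(structure, res.index)
        out.append(
            NucleotideDescriptor(
                index=res.index,
                base=res.base,
                pucker_phase=phase,
                pucker_amplitude=amp,
                n_stacking=n_stack[res.index],
                n_canonical_bp=n_can[res.index],
                n_noncanonical_bp=n_non[res.index],
                **tors,
            )
        )
    return out


@dataclass
class EnsembleProfile:
    """Mean and standard deviation of each descriptor over an ensemble.

    Angular fields use circular statistics; undefined values (terminal
    dihedrals, missing atoms) are excluded from the averages rather than
    imputed.  ``mean``/``std`` are residue-indexed DataFrames.
    """

    mean: pd.DataFrame
    std: pd.DataFrame
    n_structures: int
    sequence: str
    dominant_dot_bracket: str
    dominant_fraction: float


def _circular_mean_std(values_deg):
    vals = np.radians([v for v in values_deg if v is not None])
    if vals.size == 0:
        return np.nan, np.nan
    m = math.degrees(circmean(vals, high=math.pi, low=-math.pi))
    s = math.degrees(circstd(vals, high=math.pi, low=-math.pi))
    return m % 360.0 if m < 0 else m, s


def ensemble_profile(
    structures: list[RnaStructure],
    pairing_cutoffs: PairingCutoffs | None = None,
    stacking_cutoffs: StackingCutoffs | None = None,
    wobble_is_canonical: bool = True,
) -> EnsembleProfile:
    """Average per-nucleotide descriptors over a set of structures.

    All structures must share one sequence.  Also reports the dominant
    dot-bracket string of the ensemble and its frequency, a check that the
    member structures agree on the secondary structure.
    """
    from .secondary import dot_bracket

    if not structures:
        raise ContractViolation("ensemble must contain at least one structure")
    seq = structures[0].sequence
    for s in structures[1:]:
        if s.sequence != seq:
            raise ContractViolation(
                f"mixed sequences in ensemble: {seq!r} vs {s.sequence!r}"
            )

    per_structure = [
        nucleotide_descriptors(
            s, pairing_cutoffs, stacking_cutoffs, wobble_is_canonical
        )
        for s in structures
    ]
    n_res = len(seq)
    mean_rows, std_rows = [], []
    for r in range(n_res):
        mrow, srow = {"base": seq[r]}, {"base": seq[r]}
        for f in ANGULAR_FIELDS:
            vals = [getattr(d[r], f) for d in per_structure]
            mrow[f], srow[f] = _circular_mean_std(vals)
        for f in SCALAR_FIELDS + COUNT_FIELDS:
            vals = [
                getattr(d[r], f)
                for d in per_structure
                if getattr(d[r], f) is not None
            ]
            if vals:
                mrow[f] = float(np.mean(vals))
                srow[f] = float(np.std(vals))
            else:
                mrow[f] = srow[f] = np.nan
        mean_rows.append(mrow)
        std_rows.append(srow)

    brackets = [
        dot_bracket(annotate_pairs(s, pairing_cutoffs), n_res) for s in structures
    ]
    counts = pd.Series(brackets).value_counts()
    dominant = counts.index[0]
    index = pd.RangeIndex(1, n_res + 1, name="residue")
    return EnsembleProfile(
        mean=pd.DataFrame(mean_rows, index=index),
        std=pd.DataFrame(std_rows, index=index),
        n_structures=len(structures),
        sequence=seq,
        dominant_dot_bracket=dominant,
        dominant_fraction=float(counts.iloc[0] / len(structures)),
    )
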