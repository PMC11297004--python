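"""Coarse-grained RNA chain model with swappable parameter sets.

Three beads per nucleotide (phosphate P, sugar S, base B) with the classic
biomolecular functional form: harmonic bonds and angles, sinusoidal torsion
terms, a Lennard-Jones potential for excluded volume and stacking-like
attraction, and Debye–Hückel screened Coulomb electrostatics standing in for
an implicit-solvent description.  Several registered parameter sets share
the functional form and differ only in their parameters, mirroring how force
fields of one family differ; the toolkit's ranking analyses exercise these
variants.

Units: kcal/mol, Å, radians internally for angles; charges in elementary
charge units.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from ..exceptions import ConfigError, ContractViolation
from .base import CartesianSiteModel

__all__ = [
    "TorsionTerm",
    "ParameterSet",
    "ChainTopology",
    "ToyRNAChain",
    "make_toy_rna",
    "register_parameter_set",
    "get_parameter_set",
    "list_parameter_sets",
    "extended_configuration",
    "compact_configuration",
    "hairpin_native_pairs",
    "native_contact_fraction",
]

COULOMB_KCAL = 332.0636  # kcal·Å/(mol·e²)

# bead classes: P phosphate, S sugar, R purine base, Y pyrimidine base
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}


@dataclass(frozen=True)
class TorsionTerm:
    """One sinusoidal torsion term A·(1 + cos(nφ − δ))."""

    amplitude: float  # kcal/mol
    periodicity: int
    phase: float  # rad

    def __post_init__(self):
        if self.periodicity < 1 or int(self.periodicity) != self.periodicity:
            raise ConfigError("torsion periodicity must be a positive integer")


@dataclass
class ParameterSet:
    """Complete parameter block for the chain model.

    Keys for bonded terms are hyphen-joined bead-class strings with base
    classes collapsed to ``B`` (e.g. ``"P-S"``, ``"S-P-S-B"``); Lennard-Jones
    and charge entries are per concrete class (``P``, ``S``, ``R``, ``Y``).
    """

    name: str
    bonds: dict = field(default_factory=dict)  # key -> (k kcal/mol/Å², r0 Å)
    angles: dict = field(default_factory=dict)  # key -> (k kcal/mol/rad², θ0 rad)
    torsions: dict = field(default_factory=dict)  # key -> [TorsionTerm, ...]
    lj: dict = field(default_factory=dict)  # class -> (ε kcal/mol, σ Å)
    charges: dict = field(default_factory=dict)  # class -> charge (e)
    screening_length: float = 9.0  # Å, Debye length of the implicit solvent
    dielectric: float = 20.0
    native_strength: float = 0.0  # kcal/mol, Gō-like well on native pairs
    native_r0: float = 4.5  # Å, native base-base contact distance

    def __post_init__(self):
        for cls, (eps, sigma) in self.lj.items():
            if sigma <= 0:
                raise ConfigError(f"LJ sigma for class {cls} must be > 0")
        if self.screening_length <= 0:
            raise ConfigError("screening length must be > 0")

    # -- lossless config round-trip ----------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "bonds": {k: list(v) for k, v in self.bonds.items()},
            "angles": {k: list(v) for k, v in self.angles.items()},
            "torsions": {
                k: [[t.amplitude, t.periodicity, t.phase] for t in terms]
                for k, terms in self.torsions.items()
            },
            "nonbonded": {
                "lj": {k: list(v) for k, v in self.lj.items()},
                "charges": dict(self.charges),
                "screening_length": self.screening_length,
                "dielectric": self.dielectric,
                "native_strength": self.native_strength,
                "native_r0": self.native_r0,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        try:
            nb = d["nonbonded"]
            return cls(
                name=d["name"],
                bonds={k: tuple(v) for k, v in d.get("bonds", {}).items()},
                angles={k: tuple(v) for k, v in d.get("angles", {}).items()},
                torsions={
                    k: [TorsionTerm(a, int(n), p) for a, n, p in terms]
                    for k, terms in d.get("torsions", {}).items()
                },
                lj={k: tuple(v) for k, v in nb.get("lj", {}).items()},
                charges=dict(nb.get("charges", {})),
                screening_length=float(nb.get("screening_length", 9.0)),
                dielectric=float(nb.get("dielectric", 20.0)),
                native_strength=float(nb.get("native_strength", 0.0)),
                native_r0=float(nb.get("native_r0", 4.5)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed parameter-set block: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(text))

    def with_screening_length(self, value: float) -> "ParameterSet":
        """Copy of this set with a different Debye screening length."""
        other = copy.deepcopy(self)
        other.screening_length = float(value)
        other.name = f"{self.name}@lambda={value:g}"
        return other


@dataclass
class ChainTopology:
    """Bead list and bonded-term index tuples for one chain.

    All index tuples are 0-based bead indices.  ``native_pairs`` (optional)
    lists base-bead index pairs of the reference fold, used by order
    parameters, not by the energy unless the parameter set switches on a
    native (Gō-like) term.
    """

    sequence: str
    bead_classes: list  # concrete class per bead: P/S/R/Y
    bead_labels: list  # e.g. "P3", "S3", "B3" (1-based nucleotide)
    bonds: list  # [(i, j, key)]
    angles: list  # [(i, j, k, key)]
    torsions: list  # [(i, j, k, l, key)]
    native_pairs: list = field(default_factory=list)  # [(bead_i, bead_j)]

    @property
    def n_beads(self) -> int:
        return len(self.bead_classes)

    def validate(self) -> None:
        n = self.n_beads
        bond_set = {frozenset(b[:2]) for b in self.bonds}
        for tup in (
            [b[:2] for b in self.bonds]
            + [a[:3] for a in self.angles]
            + [t[:4] for t in self.torsions]
        ):
            if any(i < 0 or i >= n for i in tup):
                raise ContractViolation(f"index tuple {tup} references missing bead")
        for i, j, k, l, _ in self.torsions:
            path = [i, j, k, l]
            for a, b in zip(path, path[1:]):
                if frozenset((a, b)) not in bond_set:
                    raise ContractViolation(
                        f"torsion {path} is not a connected path in the bond graph"
                    )

    def base_bead_index(self, nt: int) -> int:
        """Bead index of the base bead of 1-based nucleotide ``nt``."""
        return 3 * (nt - 1) + 2


def _collapse(cls: str) -> str:
    return "B" if cls in ("R", "Y") else cls


def build_topology(sequence: str, native_pairs=None) -> ChainTopology:
    """Three-beads-per-nucleotide topology for ``sequence`` (letters ACGU).

    ``native_pairs`` are 1-based nucleotide index pairs; they are stored as
    base-bead index pairs.
    """
    sequence = sequence.upper()
    for ch in sequence:
        if ch not in PURINES | PYRIMIDINES:
            raise ContractViolation(f"unknown nucleotide letter {ch!r}")
    classes, labels = [], []
    for i, ch in enumerate(sequence, start=1):
        classes += ["P", "S", "R" if ch in PURINES else "Y"]
        labels += [f"P{i}", f"S{i}", f"B{i}"]

    def key(*idx):
        return "-".join(_collapse(classes[i]) for i in idx)

    n = len(sequence)
    P = lambda i: 3 * i
    S = lambda i: 3 * i + 1
    B = lambda i: 3 * i + 2

    bonds, angles, torsions = [], [], []
    for i in range(n):
        bonds.append((P(i), S(i), key(P(i), S(i))))
        bonds.append((S(i), B(i), key(S(i), B(i))))
        if i + 1 < n:
            bonds.append((S(i), P(i + 1), key(S(i), P(i + 1))))
    for i in range(n):
        angles.append((P(i), S(i), B(i), key(P(i), S(i), B(i))))
        if i + 1 < n:
            angles.append((P(i), S(i), P(i + 1), key(P(i), S(i), P(i + 1))))
            angles.append((B(i), S(i), P(i + 1), key(B(i), S(i), P(i + 1))))
            angles.append((S(i), P(i + 1), S(i + 1), key(S(i), P(i + 1), S(i + 1))))
    for i in range(n - 1):
        torsions.append(
            (B(i), S(i), P(i + 1), S(i + 1), key(B(i), S(i), P(i + 1), S(i + 1)))
        )
        torsions.append(
            (P(i), S(i), P(i + 1), S(i + 1), key(P(i), S(i), P(i + 1), S(i + 1)))
        )
        torsions.append(
            (S(i), P(i + 1), S(i + 1), B(i + 1), key(S(i), P(i + 1), S(i + 1), B(i + 1)))
        )
        if i + 2 < n:
            torsions.append(
                (S(i), P(i + 1), S(i + 1), P(i + 2), key(S(i), P(i + 1), S(i + 1), P(i + 2)))
            )

    nat = []
    for a, b in native_pairs or []:
        nat.append((B(a - 1), B(b - 1)))
    topo = ChainTopology(sequence, classes, labels, bonds, angles, torsions, nat)
    topo.validate()
    return topo


# ---------------------------------------------------------------------------
# shipped parameter sets
# ---------------------------------------------------------------------------

def _baseline_set(name: str, torsions: dict) -> ParameterSet:
    return ParameterSet(
        name=name,
        bonds={"P-S": (20.0, 3.8), "S-B": (20.0, 3.5), "S-P": (20.0, 3.9)},
        angles={
            "P-S-B": (5.0, math.radians(105.0)),
            "P-S-P": (5.0, math.radians(120.0)),
            "B-S-P": (5.0, math.radians(110.0)),
            "S-P-S": (5.0, math.radians(100.0)),
        },
        torsions=torsions,
        lj={
            "P": (0.20, 4.2),
            "S": (0.25, 4.0),
            "R": (0.60, 4.6),
            "Y": (0.60, 4.0),
        },
        charges={"P": -1.0, "S": 0.0, "R": 0.0, "Y": 0.0},
        screening_length=9.0,
        dielectric=20.0,
        native_strength=3.0,
        native_r0=4.5,
    )


_PARAMETER_SETS: dict[str, ParameterSet] = {}


def register_parameter_set(params: ParameterSet) -> None:
    _PARAMETER_SETS[params.name] = params


def get_parameter_set(name: str) -> ParameterSet:
    try:
        return copy.deepcopy(_PARAMETER_SETS[name])
    except KeyError:
        raise ConfigError(
            f"unknown parameter set {name!r}; known: {sorted(_PARAMETER_SETS)}"
        ) from None


def list_parameter_sets() -> list:
    return sorted(_PARAMETER_SETS)


register_parameter_set(
    _baseline_set(
        "cg-default",
        {
            "B-S-P-S": [TorsionTerm(1.2, 1, 0.0), TorsionTerm(0.6, 3, 0.0)],
            "P-S-P-S": [TorsionTerm(1.0, 1, 0.0), TorsionTerm(0.5, 3, 0.0)],
            "S-P-S-B": [TorsionTerm(1.2, 1, 0.0), TorsionTerm(0.6, 3, 0.0)],
            "S-P-S-P": [TorsionTerm(1.0, 1, 0.0), TorsionTerm(0.5, 3, 0.0)],
        },
    )
)
# alternative torsion parameterisation of the same functional form: shifted
# phases and stronger one-fold terms, the chain-model analogue of a dihedral
# refit within one force-field family
register_parameter_set(
    _baseline_set(
        "cg-torsion2",
        {
            "B-S-P-S": [TorsionTerm(2.0, 1, math.pi), TorsionTerm(0.8, 3, math.pi / 2)],
            "P-S-P-S": [TorsionTerm(1.6, 1, math.pi), TorsionTerm(0.4, 3, math.pi / 2)],
            "S-P-S-B": [TorsionTerm(2.0, 1, math.pi), TorsionTerm(0.8, 3, math.pi / 2)],
            "S-P-S-P": [TorsionTerm(1.6, 1, math.pi), TorsionTerm(0.4, 3, math.pi / 2)],
        },
    )
)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class ToyRNAChain(CartesianSiteModel):
    """Coarse-grained chain potential over a :class:`ChainTopology`."""

    def __init__(self, topology: ChainTopology, parameters: ParameterSet):
        self.topology = topology
        self.parameters = parameters
        self.n_sites = topology.n_beads
        self.dimension = 3 * self.n_sites
        self.n_zero_modes = 6 if self.n_sites >= 3 else 5
        self.name = f"toy-rna:{topology.sequence}:{parameters.name}"
        self.min_separation = 0.3

        p = parameters
        # precompute nonbonded tables
        n = self.n_sites
        excl = self._excluded_pairs()
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (i, j) not in excl
        ]
        self._nb_i = np.array([p_[0] for p_ in pairs], dtype=int)
        self._nb_j = np.array([p_[1] for p_ in pairs], dtype=int)
        eps = np.array([p.lj[c][0] for c in topology.bead_classes])
        sig = np.array([p.lj[c][1] for c in topology.bead_classes])
        q = np.array([p.charges[c] for c in topology.bead_classes])
        self._eps_ij = np.sqrt(eps[self._nb_i] * eps[self._nb_j])
        self._sig_ij = 0.5 * (sig[self._nb_i] + sig[self._nb_j])
        self._qq_ij = (
            COULOMB_KCAL * q[self._nb_i] * q[self._nb_j] / p.dielectric
        )
        self._native = np.array(topology.native_pairs, dtype=int).reshape(-1, 2)

        # vectorised bonded-term tables
        self._b_idx = np.array([[i, j] for i, j, _ in topology.bonds], int).reshape(-1, 2)
        self._b_k = np.array([p.bonds[key][0] for *_, key in topology.bonds])
        self._b_r0 = np.array([p.bonds[key][1] for *_, key in topology.bonds])
        self._a_idx = np.array(
            [[i, j, k] for i, j, k, _ in topology.angles], int
        ).reshape(-1, 3)
        self._a_k = np.array([p.angles[key][0] for *_, key in topology.angles])
        self._a_t0 = np.array([p.angles[key][1] for *_, key in topology.angles])
        self._t_idx = np.array(
            [[i, j, k, l] for i, j, k, l, _ in topology.torsions], int
        ).reshape(-1, 4)
        t_which, t_amp, t_per, t_phase = [], [], [], []
        for ti, (i, j, k, l, key) in enumerate(topology.torsions):
            for term in p.torsions.get(key, ()):
                t_which.append(ti)
                t_amp.append(term.amplitude)
                t_per.append(term.periodicity)
                t_phase.append(term.phase)
        self._tt_which = np.array(t_which, int)
        self._tt_amp = np.array(t_amp)
        self._tt_per = np.array(t_per, dtype=float)
        self._tt_phase = np.array(t_phase)

    def _excluded_pairs(self):
        """Pairs at bond-graph distance <= 2 (1-2 and 1-3)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_sites))
        g.add_edges_from((i, j) for i, j, _ in self.topology.bonds)
        excl = set()
        lengths = dict(nx.all_pairs_shortest_path_length(g, cutoff=2))
        for i, d in lengths.items():
            for j, dist in d.items():
                if i < j and dist <= 2:
                    excl.add((i, j))
        return excl

    # -- energy and analytic gradient ---------------------------------------
    def energy(self, x):
        e, _ = self._eval(np.asarray(x, float), want_grad=False)
        return e

    def gradient(self, x):
        _, g = self._eval(np.asarray(x, float), want_grad=True)
        return g

    def energy_gradient(self, x):
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.dimension:
            raise ContractViolation(
                f"{self.name}: expected dimension {self.dimension}, got {x.size}"
            )
        e, g = self._eval(x, want_grad=True)
        if not (np.isfinite(e) and np.all(np.isfinite(g))):
            from ..exceptions import DegenerateGeometryError

            raise DegenerateGeometryError(
                f"{self.name}: non-finite energy/gradient (degenerate geometry)"
            )
        return e, g

    def _eval(self, x, want_grad: bool):
        pts = x.reshape(self.n_sites, 3)
        p = self.parameters
        grad = np.zeros_like(pts) if want_grad else None
        e = 0.0

        # bonds (vectorised)
        if self._b_idx.size:
            d = pts[self._b_idx[:, 0]] - pts[self._b_idx[:, 1]]
            r = np.linalg.norm(d, axis=1)
            e += float(np.sum(self._b_k * (r - self._b_r0) ** 2))
            if want_grad:
                gv = (2 * self._b_k * (r - self._b_r0) / r)[:, None] * d
                np.add.at(grad, self._b_idx[:, 0], gv)
                np.add.at(grad, self._b_idx[:, 1], -gv)

        # angles (vectorised)
        if self._a_idx.size:
            u = pts[self._a_idx[:, 0]] - pts[self._a_idx[:, 1]]
            v = pts[self._a_idx[:, 2]] - pts[self._a_idx[:, 1]]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cth = np.clip(
                np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0
            )
            th = np.arccos(cth)
            e += float(np.sum(self._a_k * (th - self._a_t0) ** 2))
            if want_grad:
                sth = np.sqrt(np.maximum(1.0 - cth * cth, 1e-12))
                uh = u / nu[:, None]
                vh = v / nv[:, None]
                dth_di = (cth[:, None] * uh - vh) / (nu * sth)[:, None]
                dth_dk = (cth[:, None] * vh - uh) / (nv * sth)[:, None]
                coeff = (2 * self._a_k * (th - self._a_t0))[:, None]
                np.add.at(grad, self._a_idx[:, 0], coeff * dth_di)
                np.add.at(grad, self._a_idx[:, 2], coeff * dth_dk)
                np.add.at(grad, self._a_idx[:, 1], -coeff * (dth_di + dth_dk))

        # torsions (vectorised; IUPAC-sign dihedral, end-atom derivatives
        # along the plane normals, middle atoms by lever-arm combination)
        if self._t_idx.size and self._tt_which.size:
            b1 = pts[self._t_idx[:, 1]] - pts[self._t_idx[:, 0]]
            b2 = pts[self._t_idx[:, 2]] - pts[self._t_idx[:, 1]]
            b3 = pts[self._t_idx[:, 3]] - pts[self._t_idx[:, 2]]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            phi = np.arctan2(
                np.einsum("ij,ij->i", m1, n2), np.einsum("ij,ij->i", n1, n2)
            )
            arg = self._tt_per * phi[self._tt_which] - self._tt_phase
            e += float(np.sum(self._tt_amp * (1.0 + np.cos(arg))))
            if want_grad:
                de_dphi = np.zeros(len(self._t_idx))
                np.add.at(
                    de_dphi,
                    self._tt_which,
                    -self._tt_amp * self._tt_per * np.sin(arg),
                )
                n1sq = np.einsum("ij,ij->i", n1, n1)
                n2sq = np.einsum("ij,ij->i", n2, n2)
                dphi_di = (nb2 / n1sq)[:, None] * n1
                dphi_dl = -(nb2 / n2sq)[:, None] * n2
                s12 = np.einsum("ij,ij->i", b1, b2) / nb2**2
                s32 = np.einsum("ij,ij->i", b3, b2) / nb2**2
                dphi_dj = -(1.0 + s12)[:, None] * dphi_di + s32[:, None] * dphi_dl
                dphi_dk = s12[:, None] * dphi_di - (1.0 + s32)[:, None] * dphi_dl
                dd = de_dphi[:, None]
                np.add.at(grad, self._t_idx[:, 0], dd * dphi_di)
                np.add.at(grad, self._t_idx[:, 1], dd * dphi_dj)
                np.add.at(grad, self._t_idx[:, 2], dd * dphi_dk)
                np.add.at(grad, self._t_idx[:, 3], dd * dphi_dl)

        # nonbonded: LJ + screened Coulomb, vectorised over the pair list
        if self._nb_i.size:
            rij = pts[self._nb_i] - pts[self._nb_j]
            r2 = np.sum(rij**2, axis=1)
            r = np.sqrt(r2)
            s6 = (self._sig_ij**2 / r2) ** 3
            e_lj = 4.0 * self._eps_ij * (s6**2 - s6)
            lam = p.screening_length
            screen = np.exp(-r / lam)
            e_coul = self._qq_ij * screen / r
            e += float(np.sum(e_lj) + np.sum(e_coul))
            if want_grad:
                dlj_dr2 = 24.0 * self._eps_ij * (s6 - 2.0 * s6**2) / r2
                dcoul_dr = -self._qq_ij * screen * (1.0 / r2 + 1.0 / (lam * r))
                coeff = dlj_dr2 + dcoul_dr / r
                forces = coeff[:, None] * rij
                np.add.at(grad, self._nb_i, forces)
                np.add.at(grad, self._nb_j, -forces)

        # optional Gō-like native-contact wells between base beads
        if p.native_strength > 0 and self._native.size:
            i_, j_ = self._native[:, 0], self._native[:, 1]
            rij = pts[i_] - pts[j_]
            r2 = np.sum(rij**2, axis=1)
            # LJ form with minimum at native_r0
            sig = p.native_r0 / 2.0 ** (1.0 / 6.0)
            s6 = (sig**2 / r2) ** 3
            e += float(np.sum(4.0 * p.native_strength * (s6**2 - s6)))
            if want_grad:
                coeff = 24.0 * p.native_strength * (s6 - 2.0 * s6**2) / r2
                forces = coeff[:, None] * rij
                np.add.at(grad, i_, forces)
                np.add.at(grad, j_, -forces)

        return float(e), (grad.ravel() if want_grad else None)


def make_toy_rna(
    sequence: str, parameter_set_id: str = "cg-default", native_pairs=None
):
    """Build a coarse-grained chain model for ``sequence``.

    Parameters
    ----------
    sequence
        Nucleotide string over {A, C, G, U}.
    parameter_set_id
        Name of a registered :class:`ParameterSet`.
    native_pairs
        Optional 1-based nucleotide pairs of the reference fold.

    Returns
    -------
    (ToyRNAChain, ChainTopology)
    """
    params = get_parameter_set(parameter_set_id)
    topo = build_topology(sequence, native_pairs=native_pairs)
    return ToyRNAChain(topo, params), topo


# ---------------------------------------------------------------------------
# starting configurations and order parameters
# ---------------------------------------------------------------------------

def extended_configuration(topology: ChainTopology) -> np.ndarray:
    """Open zig-zag chain, a generic unfolded starting structure."""
    coords = np.zeros((topology.n_beads, 3))
    for i in range(len(topology.sequence)):
        xb = 5.9 * i
        coords[3 * i] = (xb, 0.0, 0.0)  # P
        coords[3 * i + 1] = (xb + 2.8, 2.2, 0.0)  # S
        coords[3 * i + 2] = (xb + 2.8, 4.2, 2.4)  # B
    return coords.ravel()


def compact_configuration(topology: ChainTopology) -> np.ndarray:
    """Loose hairpin-like fold bringing native partners near contact.

    Lays the two chain halves antiparallel ~5 Å apart with bases facing
    inward, so that minimisation under a native-biased parameter set relaxes
    into a folded reference structure.
    """
    n = len(topology.sequence)
    half = (n + 1) // 2
    coords = np.zeros((topology.n_beads, 3))
    for i in range(n):
        if i < half:  # outgoing strand along +x at y = 0
            xb, y, base_dy = 5.9 * i, 0.0, 3.2
        else:  # returning strand along −x at y ≈ 9 Å
            xb, y, base_dy = 5.9 * (n - 1 - i) + 2.0, 9.6, -3.2
        coords[3 * i] = (xb, y, 0.0)
        coords[3 * i + 1] = (xb + 2.6, y + 0.3 * base_dy, 1.2)
        coords[3 * i + 2] = (xb + 2.6, y + base_dy, 1.6)
    return coords.ravel()


def hairpin_native_pairs(n: int, n_pairs: int | None = None) -> list:
    """1-based hairpin pairs (1,n), (2,n−1), ... leaving a 3+-nt loop."""
    if n_pairs is None:
        n_pairs = max((n - 3) // 2, 0)
    return [(i, n + 1 - i) for i in range(1, n_pairs + 1)]


def native_contact_fraction(
    topology: ChainTopology, x: np.ndarray, cutoff: float = 6.0
) -> float:
    """Fraction of native base-bead pairs closer than ``cutoff`` Å.

    Serves as the folded/partially folded/unfolded order parameter in [0, 1].
    """
    if not topology.native_pairs:
        raise ContractViolation("topology declares no native pairs")
    pts = np.asarray(x, float).reshape(topology.n_beads, 3)
    hits = 0
    for i, j in topology.native_pairs:
        if np.linalg.norm(pts[i] - pts[j]) < cutoff:
            hits += 1
    return hits / len(topology.native_pairs)
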