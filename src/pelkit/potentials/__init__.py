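"""Potential-energy models and the contract they share.

Built-in models: analytic benchmark surfaces (Müller–Brown, quadratic bowl,
1-D double well), Lennard-Jones clusters, and a coarse-grained RNA chain
with swappable parameter sets.  External engines plug in through
:func:`external_adapter`.
"""

from .base import (
    CartesianSiteModel,
    ExternalPotential,
    PotentialModel,
    energy_gradient,
    external_adapter,
)
from .analytic import DoubleWell1D, MuellerBrown, PiecewiseTwoWells, QuadraticBowl
from .clusters import LJCluster
from .chain import (
    ChainTopology,
    ParameterSet,
    TorsionTerm,
    ToyRNAChain,
    build_topology,
    compact_configuration,
    extended_configuration,
    get_parameter_set,
    hairpin_native_pairs,
    list_parameter_sets,
    make_toy_rna,
    native_contact_fraction,
    register_parameter_set,
)

__all__ = [
    "PotentialModel",
    "CartesianSiteModel",
    "ExternalPotential",
    "energy_gradient",
    "external_adapter",
    "MuellerBrown",
    "QuadraticBowl",
    "DoubleWell1D",
    "PiecewiseTwoWells",
    "LJCluster",
    "ParameterSet",
    "TorsionTerm",
    "ChainTopology",
    "ToyRNAChain",
    "build_topology",
    "make_toy_rna",
    "get_parameter_set",
    "register_parameter_set",
    "list_parameter_sets",
    "extended_configuration",
    "compact_configuration",
    "hairpin_native_pairs",
    "native_contact_fraction",
    "resolve_potential",
]


def resolve_potential(spec: str) -> PotentialModel:
    """Build a model from a registry string.

    Recognised forms: ``mueller-brown``, ``quadratic-bowl[:dim]``,
    ``double-well-1d``, ``lj:N`` (e.g. ``lj:7``) and
    ``toy-rna:SEQUENCE[:parameter-set]``.
    """
    from ..exceptions import ConfigError

    parts = spec.split(":")
    head = parts[0]
    if head == "mueller-brown":
        return MuellerBrown()
    if head == "double-well-1d":
        return DoubleWell1D()
    if head == "quadratic-bowl":
        dim = int(parts[1]) if len(parts) > 1 else 2
        return QuadraticBowl(dimension=dim)
    if head == "lj":
        if len(parts) < 2:
            raise ConfigError("lj potential needs a site count, e.g. lj:7")
        return LJCluster(int(parts[1]))
    if head == "toy-rna":
        if len(parts) < 2:
            raise ConfigError("toy-rna needs a sequence, e.g. toy-rna:GGGAAAUCCC")
        pset = parts[2] if len(parts) > 2 else "cg-default"
        model, _ = make_toy_rna(parts[1], pset)
        return model
    raise ConfigError(f"unknown potential spec {spec!r}")
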