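"""Plain-text persistence for KTN databases and run configuration.

A KTN file set is a directory mirroring the min/ts database layout of
discrete path-sampling practice:

``manifest.yaml``
    units, model id, format version, tolerances, seeds (provenance).
``minima.tsv``
    one record per minimum: id, energy, gradient RMS, discovery count and
    the coordinate-block offset (line index into ``coords.dat``).
``ts.tsv``
    id, energy, lowest eigenvalue, the two connected minimum ids, offset.
``coords.dat``
    concatenated fixed-length coordinate blocks, one value per line.

Energies and coordinates are serialised as shortest round-trip decimals of
the underlying doubles, so ``read_ktn(write_ktn(k)) == k`` bit-exactly on
every numeric field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigError
from .ktn import KTN
from .optim import Minimum
from .tssearch import TransitionState

__all__ = ["write_ktn", "read_ktn", "RunConfig"]

FORMAT_VERSION = 1


def _fmt(x: float) -> str:
    return repr(float(x))


def write_ktn(ktn: KTN, path, extra_manifest: dict | None = None) -> Path:
    """Write ``ktn`` to directory ``path`` (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    coords_lines: list[str] = []

    def store(block: np.ndarray) -> int:
        offset = len(coords_lines)
        coords_lines.extend(_fmt(v) for v in np.asarray(block, float).ravel())
        return offset

    with open(path / "minima.tsv", "w") as fh:
        fh.write("# id\tenergy\tgradient_rms\tdiscovery_count\toffset\n")
        for mid in sorted(ktn.minima):
            m = ktn.minima[mid]
            fh.write(
                f"{mid}\t{_fmt(m.energy)}\t{_fmt(m.gradient_rms)}\t"
                f"{m.discovery_count}\t{store(m.coordinates)}\n"
            )
    with open(path / "ts.tsv", "w") as fh:
        fh.write(
            "# id\tenergy\tgradient_rms\tlowest_eigenvalue\tminus_id\tplus_id"
            "\toffset\teig_offset\n"
        )
        for tid in sorted(ktn.transition_states):
            ts = ktn.transition_states[tid]
            fh.write(
                f"{tid}\t{_fmt(ts.energy)}\t{_fmt(ts.gradient_rms)}\t"
                f"{_fmt(ts.lowest_eigenvalue)}\t{ts.minus_min_id}\t"
                f"{ts.plus_min_id}\t{store(ts.coordinates)}\t"
                f"{store(ts.eigenvector)}\n"
            )
    (path / "coords.dat").write_text(
        "\n".join(coords_lines) + ("\n" if coords_lines else "")
    )
    manifest = {
        "format_version": FORMAT_VERSION,
        "units": ktn.units,
        "model": ktn.model_name,
        "dimension": ktn.dimension,
        "use_alignment": ktn.use_alignment,
        "provenance": ktn.provenance,
    }
    manifest.update(extra_manifest or {})
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return path


def read_ktn(path) -> KTN:
    """Read a KTN file set written by :func:`write_ktn`."""
    path = Path(path)
    try:
        manifest = yaml.safe_load((path / "manifest.yaml").read_text())
    except FileNotFoundError:
        raise ConfigError(f"{path}: not a KTN file set (no manifest.yaml)") from None
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise ConfigError(
            f"{path}: unsupported KTN format version {version!r} "
            f"(expected {FORMAT_VERSION})"
        )
    dim = manifest["dimension"]
    coords = [
        float(line)
        for line in (path / "coords.dat").read_text().splitlines()
        if line.strip()
    ]

    def block(offset: int, size: int) -> np.ndarray:
        return np.array(coords[offset : offset + size])

    ktn = KTN(
        model_name=manifest.get("model", ""),
        dimension=dim,
        units=manifest.get("units", "kcal/mol, Å"),
        use_alignment=manifest.get("use_alignment"),
    )
    ktn.provenance = manifest.get("provenance", {})

    for line in (path / "minima.tsv").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        sid, e, grms, count, off = line.split("\t")
        m = Minimum(
            energy=float(e),
            coordinates=block(int(off), dim),
            gradient_rms=float(grms),
            id=int(sid),
            discovery_count=int(count),
        )
        ktn.minima[m.id] = m
    for line in (path / "ts.tsv").read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        sid, e, grms, lam, minus, plus, off, eoff = line.split("\t")
        ts = TransitionState(
            energy=float(e),
            coordinates=block(int(off), dim),
            lowest_eigenvalue=float(lam),
            eigenvector=block(int(eoff), dim),
            gradient_rms=float(grms),
            id=int(sid),
            minus_min_id=None if minus == "None" else int(minus),
            plus_min_id=None if plus == "None" else int(plus),
        )
        ktn.transition_states[ts.id] = ts
    ktn._next_min_id = max(ktn.minima, default=-1) + 1
    ktn._next_ts_id = max(ktn.transition_states, default=-1) + 1
    ktn.check_integrity()
    return ktn


class RunConfig:
    """Validated configuration for CLI runs.

    A flat mapping of known sections; unknown keys are rejected so typos
    fail loudly.  Every tolerance and seed is echoed into the provenance
    log of the outputs.
    """

    KNOWN_KEYS = {
        "potential",
        "seed",
        "basin_hopping",
        "band",
        "matching",
        "disconnectivity",
        "descriptors",
        "output_dir",
    }
    KNOWN_SUBKEYS = {
        "basin_hopping": {
            "n_steps",
            "temperature",
            "step_size",
            "adaptive_step",
            "minimiser_tol",
        },
        "band": {"n_images", "spring_k", "dneb", "grad_rms_tol", "max_iterations"},
        "matching": {"energy_tol", "distance_tol", "permute"},
        "disconnectivity": {"delta_e", "e_ref", "min_depth", "highlight"},
        "descriptors": {
            "max_centre_distance",
            "max_plane_angle",
            "max_vertical_offset",
            "max_hbond_distance",
            "stack_max_centre_distance",
            "stack_max_plane_angle",
            "stack_max_lateral_offset",
            "wobble_is_canonical",
        },
    }

    def __init__(self, data: dict | None = None):
        data = data or {}
        unknown = set(data) - self.KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in self.KNOWN_SUBKEYS.items():
            sub = data.get(section) or {}
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {sorted(bad)}"
                )
        self.data = data

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def section(self, name: str) -> dict:
        return dict(self.data.get(name) or {})

    def to_dict(self) -> dict:
        return dict(self.data)
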