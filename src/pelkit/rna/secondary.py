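"""Secondary-structure strings and arc diagrams, pseudoknot-aware.

Dot-bracket notation assigns each (canonical) pair to a bracket tier; pairs
that cross — the signature of a pseudoknot — go to successive tiers
``()``, ``[]``, ``{}``, ``<>`` by greedy page assignment on the crossing
graph.  Arc diagrams draw every pair (including non-canonical ones) as an
arc over the 1..n baseline with a style class per category.
"""

from __future__ import annotations

import logging

from ..exceptions import BracketOverflowError, ContractViolation
from .descriptors import BasePair

__all__ = ["dot_bracket", "parse_dot_bracket", "arc_diagram"]

logger = logging.getLogger(__name__)

BRACKETS = ["()", "[]", "{}", "<>"]

_PAIRABLE = {"canonical-WC", "wobble"}


def _as_index_pairs(pairs):
    """Normalise to sorted (i, j) tuples; accepts BasePair or tuples."""
    out = []
    for p in pairs:
        if isinstance(p, BasePair):
            out.append((min(p.i, p.j), max(p.i, p.j), p))
        else:
            i, j = p
            out.append((min(i, j), max(i, j), None))
    return out


def _resolve_conflicts(pairs):
    """One partner per residue: keep the pair with the most hydrogen bonds."""
    ranked = sorted(
        pairs,
        key=lambda t: (-(t[2].n_hbonds if t[2] else 1), t[0], t[1]),
    )
    used, kept = set(), []
    for i, j, bp in ranked:
        if i in used or j in used:
            logger.info("dot-bracket: dropping conflicting pair (%d, %d)", i, j)
            continue
        used.update((i, j))
        kept.append((i, j))
    return sorted(kept)


def _crossing(a, b) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def dot_bracket(pairs, n_residues: int) -> str:
    """Dot-bracket string for a pair set over ``n_residues``.

    Only canonical-WC and wobble pairs enter; residues claimed by several
    pairs keep the pair with the most hydrogen bonds (conflicts logged).
    Crossing pairs are pushed to successive bracket tiers by first-fit page
    assignment; more than four tiers raises
    :class:`BracketOverflowError`.  The output round-trips through
    :func:`parse_dot_bracket`.
    """
    typed = _as_index_pairs(pairs)
    typed = [
        t for t in typed if t[2] is None or t[2].category in _PAIRABLE
    ]
    for i, j, _ in typed:
        if not (1 <= i <= n_residues and 1 <= j <= n_residues):
            raise ContractViolation(f"pair ({i}, {j}) outside 1..{n_residues}")
    kept = _resolve_conflicts(typed)

    pages: dict[tuple, int] = {}
    for p in kept:  # first-fit in 5' order
        taken = {
            pages[q] for q in pages if _crossing(p, q)
        }
        page = 0
        while page in taken:
            page += 1
        if page >= len(BRACKETS):
            raise BracketOverflowError(
                f"pair set needs more than {len(BRACKETS)} bracket tiers"
            )
        pages[p] = page

    chars = ["."] * n_residues
    for (i, j), page in pages.items():
        chars[i - 1] = BRACKETS[page][0]
        chars[j - 1] = BRACKETS[page][1]
    return "".join(chars)


def parse_dot_bracket(s: str) -> set[tuple[int, int]]:
    """Pairs (i, j), 1-based, from a dot-bracket string (all four tiers)."""
    stacks: dict[int, list] = {k: [] for k in range(len(BRACKETS))}
    opener = {b[0]: k for k, b in enumerate(BRACKETS)}
    closer = {b[1]: k for k, b in enumerate(BRACKETS)}
    pairs = set()
    for pos, ch in enumerate(s, start=1):
        if ch == ".":
            continue
        if ch in opener:
            stacks[opener[ch]].append(pos)
        elif ch in closer:
            k = closer[ch]
            if not stacks[k]:
                raise ContractViolation(
                    f"unbalanced {ch!r} at position {pos}"
                )
            pairs.add((stacks[k].pop(), pos))
        else:
            raise ContractViolation(f"unexpected character {ch!r} at {pos}")
    for k, st in stacks.items():
        if st:
            raise ContractViolation(
                f"unclosed {BRACKETS[k][0]!r} at positions {st}"
            )
    return pairs


def arc_diagram(
    pairs, n_residues: int, exterior_residues=(), width: int = 600
) -> tuple[dict, str]:
    """Arc-diagram drawing data (JSON-able dict) and an SVG rendering.

    Every pair becomes an arc over the 1..n baseline with a style class
    from its category (canonical pairs solid, non-canonical dashed);
    ``exterior_residues`` marks bases pointing away from the fold with an
    outward arrow glyph.
    """
    typed = _as_index_pairs(pairs)
    arcs = []
    for i, j, bp in typed:
        category = bp.category if bp else "canonical-WC"
        arcs.append(
            {
                "i": i,
                "j": j,
                "category": category,
                "style": "dashed" if category == "non-canonical" else "solid",
            }
        )
    paired = {a["i"] for a in arcs} | {a["j"] for a in arcs}
    data = {
        "n_residues": n_residues,
        "arcs": arcs,
        "unpaired": sorted(set(range(1, n_residues + 1)) - paired),
        "exterior": sorted(exterior_residues),
    }

    margin, baseline = 20, 40
    step = (width - 2 * margin) / max(n_residues - 1, 1)

    def x(i):
        return margin + (i - 1) * step

    height = int(baseline + max((a["j"] - a["i"] for a in arcs), default=1) * step / 2 + 30)
    y0 = height - baseline
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        f'<line x1="{margin}" y1="{y0}" x2="{width - margin}" y2="{y0}" '
        'stroke="black" stroke-width="1"/>',
    ]
    for i in range(1, n_residues + 1):
        parts.append(
            f'<circle cx="{x(i):.1f}" cy="{y0}" r="2" fill="black"/>'
        )
    for a in arcs:
        xi, xj = x(a["i"]), x(a["j"])
        r = (xj - xi) / 2
        dash = ' stroke-dasharray="4 3"' if a["style"] == "dashed" else ""
        colour = "#c0392b" if a["style"] == "dashed" else "#2c5aa0"
        parts.append(
            f'<path d="M {xi:.1f} {y0} A {r:.1f} {r:.1f} 0 0 1 {xj:.1f} {y0}" '
            f'fill="none" stroke="{colour}" stroke-width="1.5" '
            f'class="{a["category"]}"{dash}/>'
        )
    for i in data["exterior"]:
        parts.append(
            f'<line x1="{x(i):.1f}" y1="{y0}" x2="{x(i):.1f}" y2="{y0 + 14}" '
            'stroke="#27823b" stroke-width="1.5" class="exterior"/>'
        )
    parts.append("</svg>")
    return data, "".join(parts)
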