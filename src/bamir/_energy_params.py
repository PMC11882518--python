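"""Nearest-neighbour free-energy parameters for RNA:RNA duplexes at 37 °C.

Stack free energies (kcal/mol) in the Turner-2004 parameter set, covering
the Watson-Crick pairs and G:U wobbles, rounded to 0.1 kcal/mol as in the
standard parameter distribution, plus the intermolecular duplex
initiation term and the terminal AU/GU penalty.

A stack key ``(x1, x2, y1, y2)`` denotes

    5'-x1 x2-3'
    3'-y1 y2-5'

with x1:y1 and x2:y2 the two base pairs.  Rotating a stack by 180 degrees
(reading both strands from the other end) maps ``(x1,x2,y1,y2)`` to
``(y2,y1,x2,x1)`` and leaves the energy unchanged; the matrix below is
symmetric, so the derived table has that property by construction.
"""

from __future__ import annotations

DUPLEX_INITIATION = 4.09  # kcal/mol, intermolecular helix initiation
TERMINAL_AU_PENALTY = 0.45  # per helix end closed by an A:U or G:U pair

WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
ALL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

_PAIR_ORDER = [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")]

# rows: outer pair (x1:y1); columns: inner pair read 3'->5' on the top
# strand, i.e. column pair (r, s) contributes x2 = s, y2 = r
_STACK_MATRIX = [
    #  CG     GC     GU     UG     AU     UA
    [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
    [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
    [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],  # GU
    [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],  # UG
    [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
    [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
]


def _build_table() -> dict[tuple[str, str, str, str], float]:
    table: dict[tuple[str, str, str, str], float] = {}
    for i, (p, q) in enumerate(_PAIR_ORDER):
        for j, (r, s) in enumerate(_PAIR_ORDER):
            table[(p, s, q, r)] = _STACK_MATRIX[i][j]
    return table


STACK_ENERGIES: dict[tuple[str, str, str, str], float] = _build_table()
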