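"""Nearest-neighbor free-energy parameters for RNA hairpin folding at 37 degC.

Terminator windows are handled in the DNA alphabet (T standing for U); the
energies below are RNA parameters, since the folding element is the nascent
transcript.  Watson-Crick stack free energies follow Xia et al. (1998,
Biochemistry 37:14719); hairpin/bulge/internal-loop initiation terms follow the
Turner 1999/2004 rule set, with Jacobson-Stockmayer log extrapolation beyond
the tabulated sizes.  G:U wobble stack values are approximate Turner-style
constants; structures rather than energies are the quantitative surface of
this package (see docs/methods.md), so sub-kcal accuracy of the wobble set is
not load-bearing.

All values are kcal/mol; negative is stabilizing.
"""

from __future__ import annotations

import math

RT37 = 0.6163  # kcal/mol at 310.15 K

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}


def is_pair(x: str, y: str, wobble: bool = True) -> bool:
    """True when (x, y) can base-pair (Watson-Crick, optionally G:T wobble)."""
    return (x, y) in WC_PAIRS or (wobble and (x, y) in WOBBLE_PAIRS)


# Stack of pair (x1,y1) over inner pair (x2,y2): motif 5'-x1 x2-3' / 3'-y1 y2-5'.
# Keys are the 4-mer x1 + x2 + y1 + y2 (DNA letters, T == U).
_STACKS_UNIQUE = {
    # Watson-Crick / Watson-Crick (Xia et al. 1998)
    "AATT": -0.93,  # 5'AA/3'UU
    "ATTA": -1.10,  # 5'AU/3'UA
    "TAAT": -1.33,  # 5'UA/3'AU
    "CTGA": -2.08,  # 5'CU/3'GA
    "CAGT": -2.11,  # 5'CA/3'GU
    "GTCA": -2.24,  # 5'GU/3'CA
    "GACT": -2.35,  # 5'GA/3'CU
    "CGGC": -2.36,  # 5'CG/3'GC
    "GGCC": -3.26,  # 5'GG/3'CC
    "GCCG": -3.42,  # 5'GC/3'CG
    # stacks containing one or two G:U wobbles (approximate Turner-style)
    "AGTT": -0.55,  # 5'AG/3'UU
    "ATTG": -1.36,  # 5'AU/3'UG
    "CGGT": -1.41,  # 5'CG/3'GU
    "CTGG": -2.11,  # 5'CU/3'GG
    "GGCT": -1.53,  # 5'GG/3'CU
    "GTCG": -2.51,  # 5'GU/3'CG
    "TGAT": -1.27,  # 5'UG/3'AU
    "TTAG": -1.00,  # 5'UU/3'AG
    "GGTT": -0.50,  # 5'GG/3'UU
    "GTTG": +1.29,  # 5'GU/3'UG
    "TGGT": +0.30,  # 5'UG/3'GU
    "TTGG": -0.74,  # 5'UU/3'GG
}


def _build_stack_table() -> dict[str, float]:
    table: dict[str, float] = {}
    for key, dg in _STACKS_UNIQUE.items():
        x1, x2, y1, y2 = key
        table[key] = dg
        # reading the same stack from the other strand: 5'y2 y1/3'x2 x1
        sym = y2 + y1 + x2 + x1
        table.setdefault(sym, dg)
    return table


STACK_TABLE = _build_stack_table()


def stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    """Free energy of stacking ``inner`` pair directly on ``outer`` pair.

    ``outer`` is the pair closer to the helix bottom (5' partner more 5').
    """
    key = outer[0] + inner[0] + outer[1] + inner[1]
    try:
        return STACK_TABLE[key]
    except KeyError as exc:  # non-pairing combination
        raise ValueError(f"no stack energy for motif {key}") from exc


# Loop initiation penalties (Turner), indexed by unpaired length.
HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4, 10: 6.5,
                11: 6.6, 12: 6.7}
BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_INIT = {2: 1.5, 3: 1.8, 4: 2.0, 5: 2.2, 6: 2.5}
_ASYMMETRY = 0.5  # kcal/mol per unit of internal-loop asymmetry


def _extrapolate(table: dict[int, float], n: int) -> float:
    m = max(table)
    if n <= m:
        return table[max(min(table), n)]
    return table[m] + 1.75 * RT37 * math.log(n / m)


def hairpin_penalty(loop_len: int) -> float:
    if loop_len < 3:
        raise ValueError("hairpin loops shorter than 3 nt are sterically forbidden")
    return _extrapolate(HAIRPIN_INIT, loop_len)


def bulge_penalty(size: int) -> float:
    if size < 1:
        raise ValueError("bulge size must be >= 1")
    return _extrapolate(BULGE_INIT, size)


def internal_penalty(n5: int, n3: int) -> float:
    """Internal-loop penalty for ``n5``/``n3`` unpaired nt on the two sides."""
    if n5 < 1 or n3 < 1:
        raise ValueError("internal loop needs unpaired nt on both sides")
    total = n5 + n3
    return _extrapolate(INTERNAL_INIT, total) + _ASYMMETRY * abs(n5 - n3)
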