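"""Brute-force folding oracle: exhaustive recursive enumeration of every legal
stem-loop decomposition, independent of the production search strategy."""

from haloterm.hairpin_fold import FoldParams, structure_energy
from haloterm.nn_energy import WC_PAIRS, is_pair


def _grow(w, p, pairs, events):
    if len(pairs) >= p.min_stem:
        yield sorted(pairs)
    i, j = pairs[-1]
    if i - 1 >= 0 and j + 1 < len(w) and is_pair(w[i - 1], w[j + 1], p.wobble):
        yield from _grow(w, p, pairs + [(i - 1, j + 1)], events)
    if events < p.max_interruptions:
        for a in range(p.max_interruption_side + 1):
            for b in range(p.max_interruption_side + 1):
                if not (1 <= a + b <= p.max_interruption_total):
                    continue
                ni, nj = i - 1 - a, j + 1 + b
                if ni >= 0 and nj < len(w) and is_pair(w[ni], w[nj], p.wobble):
                    yield from _grow(w, p, pairs + [(ni, nj)], events + 1)


def enumerate_structures(w: str, p: FoldParams):
    n = len(w)
    for loop_len in range(p.min_loop, p.max_loop + 1):
        for i0 in range(n - loop_len - 1):
            j0 = i0 + loop_len + 1
            if not is_pair(w[i0], w[j0], p.wobble):
                continue
            if p.wc_closing and (w[i0], w[j0]) not in WC_PAIRS:
                continue
            yield from _grow(w, p, [(i0, j0)], 0)


def oracle_mfe(w: str, p: FoldParams | None = None) -> float | None:
    """Minimum free energy over the exhaustively enumerated structures."""
    p = p or FoldParams()
    best = None
    for pairs in enumerate_structures(w, p):
        e = structure_energy(w, pairs)
        if best is None or e < best:
            best = e
    return best
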