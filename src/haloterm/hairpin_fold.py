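"""Constrained minimum-free-energy stem-loop folding of terminator windows.

An intrinsic terminator transcript folds into a single hairpin: a
double-helical stem (optionally interrupted by one bulge or internal loop)
closed by a short terminal loop, flanked upstream by an A-tract and downstream
by a U-tract.  This module searches all such decompositions of a window,
returns the lowest-free-energy one, and separates tract pairing from genuine
stem pairing ("tract trimming"), yielding the three energies used downstream:

* ``dG_W`` -- free energy of the untrimmed constrained fold of the whole window,
* ``dG_H`` -- free energy of the trimmed stem-loop alone,
* ``dG_B`` -- summed stacking free energy of the bottom pair-steps of the
  trimmed stem (default three steps).

Tract trimming
--------------
Terminal A:U pairing between the A-tract and the U-tract stabilises the
untrimmed fold but is not part of the hairpin stem; it is the substrate of the
``match_pattern`` feature instead.  The trimmer therefore (a) peels bottom
pairs of tract type (A paired with T, in either orientation) and (b) discards
a short residual block (< ``min_stem`` pairs) of non-tract pairs at the helix
bottom together with the contiguous run of tract pairs directly above it,
provided the run contains at least one A:T pair (5' partner A) and the
remaining stem stays >= ``min_stem``.  Rule (b) covers flank-to-flank pairs
that close over the tracts and would otherwise leave the tracts enclosed in
the stem.  On the characterized *H. bluephagenesis* terminator set this
reproduces the annotated stem/loop decompositions of all simple-hairpin parts
except three whose published annotation is not an MFE structure (see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core_io import normalize_sequence
from .nn_energy import (
    bulge_penalty,
    hairpin_penalty,
    internal_penalty,
    is_pair,
    stack_energy,
)

Pair = tuple[int, int]


@dataclass(frozen=True)
class FoldParams:
    """Knobs of the constrained hairpin folder.

    min_loop/max_loop : allowed terminal-loop size range (nt)
    min_stem          : minimum retained stem length (bp)
    max_interruptions : bulge/internal-loop events allowed in the stem (0 or 1)
    max_interruption_side / max_interruption_total : size caps (nt) on one
        interruption event
    wobble            : permit G:T (G:U) wobble pairs in the stem
    wc_closing        : require the loop-closing (innermost) pair to be
        Watson-Crick -- a wobble pair is too weak to nucleate the hairpin
        against the entropic cost of a tight terminal loop
    k_bottom          : pair-steps summed into dG_B
    max_window        : reject absurdly long windows
    """

    min_loop: int = 3
    max_loop: int = 12
    min_stem: int = 4
    max_interruptions: int = 1
    max_interruption_side: int = 8
    max_interruption_total: int = 8
    wobble: bool = True
    wc_closing: bool = True
    k_bottom: int = 3
    max_window: int = 200


@dataclass
class HairpinStructure:
    """Tract/stem/loop decomposition of one window.

    ``pairs`` is ordered bottom (outermost) to top (innermost); each element
    is ``(i, j)`` with ``i < j`` and ``window[i]`` pairing ``window[j]``.
    """

    window: str
    pairs: list[Pair]
    dG_W: float
    dG_H: float
    dG_B: float
    dG_B_steps: int
    params: FoldParams
    trimmed: bool = False
    trimmed_pairs: list[Pair] = field(default_factory=list)

    # -- derived geometry ---------------------------------------------------
    @property
    def n_H(self) -> int:
        return len(self.pairs)

    @property
    def stem5_span(self) -> tuple[int, int]:
        return self.pairs[0][0], self.pairs[-1][0] + 1

    @property
    def stem3_span(self) -> tuple[int, int]:
        return self.pairs[-1][1], self.pairs[0][1] + 1

    @property
    def stem5(self) -> str:
        return "".join(self.window[i] for i, _ in self.pairs)

    @property
    def stem3(self) -> str:
        return "".join(self.window[j] for _, j in reversed(self.pairs))

    @property
    def loops(self) -> list[tuple[int, str]]:
        """Unpaired segments inside the stem region: terminal loop first,
        then any bulge/internal-loop segments, as (start, subsequence)."""
        ti, tj = self.pairs[-1]
        out = [(ti + 1, self.window[ti + 1 : tj])]
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            if i2 > i1 + 1:
                out.append((i1 + 1, self.window[i1 + 1 : i2]))
            if j2 < j1 - 1:
                out.append((j2 + 1, self.window[j2 + 1 : j1]))
        return out

    @property
    def loop_sizes(self) -> list[int]:
        """Terminal loop size, then total unpaired nt of each interruption."""
        sizes = [self.pairs[-1][1] - self.pairs[-1][0] - 1]
        for (i1, j1), (i2, j2) in zip(self.pairs, self.pairs[1:]):
            gap = (i2 - i1 - 1) + (j1 - j2 - 1)
            if gap:
                sizes.append(gap)
        return sizes

    @property
    def loop_count(self) -> int:
        return len(self.loop_sizes)

    @property
    def a_tract(self) -> str:
        i0 = self.pairs[0][0]
        s = i0
        while s > 0 and self.window[s - 1] == "A":
            s -= 1
        return self.window[s:i0]

    @property
    def u_tract(self) -> str:
        j0 = self.pairs[0][1]
        e = j0 + 1
        while e < len(self.window) and self.window[e] == "T":
            e += 1
        return self.window[j0 + 1 : e]

    @property
    def five_tail(self) -> str:
        return self.window[: self.pairs[0][0] - len(self.a_tract)]

    @property
    def three_tail(self) -> str:
        return self.window[self.pairs[0][1] + 1 + len(self.u_tract) :]

    @property
    def downstream_of_stem(self) -> str:
        """Everything 3' of the stem (U-tract first)."""
        return self.window[self.pairs[0][1] + 1 :]

    def segments(self) -> list[tuple[str, int, int]]:
        """Ordered named spans covering the whole window (reconstruction)."""
        i0, j0 = self.pairs[0]
        a_len, u_len = len(self.a_tract), len(self.u_tract)
        spans = [("five_tail", 0, i0 - a_len), ("a_tract", i0 - a_len, i0)]
        run_start = i0
        prev = None
        for i, _ in self.pairs:
            if prev is not None and i > prev + 1:
                spans.append(("stem5", run_start, prev + 1))
                spans.append(("loop", prev + 1, i))
                run_start = i
            prev = i
        spans.append(("stem5", run_start, prev + 1))
        ti, tj = self.pairs[-1]
        spans.append(("loop", ti + 1, tj))
        run_start = tj
        prev = None
        for _, j in reversed(self.pairs):
            if prev is not None and j > prev + 1:
                spans.append(("stem3", run_start, prev + 1))
                spans.append(("loop", prev + 1, j))
                run_start = j
            prev = j
        spans.append(("stem3", run_start, prev + 1))
        spans.append(("u_tract", j0 + 1, j0 + 1 + u_len))
        spans.append(("three_tail", j0 + 1 + u_len, len(self.window)))
        return [(n, s, e) for n, s, e in spans if e > s]

    def dot_bracket(self) -> str:
        db = ["."] * len(self.window)
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)


# ---------------------------------------------------------------------------
# Energy of a fixed decomposition
# ---------------------------------------------------------------------------

def structure_energy(window: str, pairs: list[Pair]) -> float:
    """Free energy (kcal/mol) of a hairpin decomposition.

    Terminal-loop initiation + helix stacking + one bulge/internal-loop
    penalty per interruption.  A single-nt bulge keeps the stack across it.
    """
    if not pairs:
        raise ValueError("structure has no pairs")
    ti, tj = pairs[-1]
    dg = hairpin_penalty(tj - ti - 1)
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a = i2 - i1 - 1
        b = j1 - j2 - 1
        p1 = (window[i1], window[j1])
        p2 = (window[i2], window[j2])
        if a == 0 and b == 0:
            dg += stack_energy(p1, p2)
        elif a == 0 or b == 0:
            dg += bulge_penalty(a + b)
            if a + b == 1:
                dg += stack_energy(p1, p2)
        else:
            dg += internal_penalty(a, b)
    return dg


# ---------------------------------------------------------------------------
# MFE search
# ---------------------------------------------------------------------------

class _Folder:
    """Enumerates all constrained stem-loop decompositions of one window."""

    def __init__(self, window: str, params: FoldParams):
        self.w = window
        self.p = params
        self._runs: dict[Pair, tuple[int, list[float]]] = {}

    def _run(self, i: int, j: int) -> tuple[int, list[float]]:
        """Maximal contiguous helix starting at pair (i, j) growing outward,
        with cumulative stacking energy prefix (prefix[k] = energy of the
        first k+1 pairs' internal stacks)."""
        key = (i, j)
        got = self._runs.get(key)
        if got is not None:
            return got
        w, wob = self.w, self.p.wobble
        if i < 0 or j >= len(w) or not is_pair(w[i], w[j], wob):
            res = (0, [])
        else:
            prefix = [0.0]
            ii, jj = i - 1, j + 1
            while ii >= 0 and jj < len(w) and is_pair(w[ii], w[jj], wob):
                prefix.append(prefix[-1] + stack_energy((w[ii], w[jj]), (w[ii + 1], w[jj - 1])))
                ii -= 1
                jj += 1
            res = (len(prefix), prefix)
        self._runs[key] = res
        return res

    def best(self) -> tuple[float, list[Pair]] | None:
        """Lowest-energy decomposition; ties broken by more pairs, smaller
        terminal loop, leftmost 5' stem start."""
        w, p = self.w, self.p
        n = len(w)
        best_key: tuple | None = None
        best_pairs: list[Pair] | None = None

        from .nn_energy import WC_PAIRS

        for loop_len in range(p.min_loop, p.max_loop + 1):
            for li in range(1, n - loop_len):
                i0, j0 = li - 1, li + loop_len  # innermost pair
                if p.wc_closing and j0 < n and (w[i0], w[j0]) not in WC_PAIRS:
                    continue
                m1, pre1 = self._run(i0, j0)
                if m1 == 0:
                    continue
                hp = hairpin_penalty(loop_len)
                for k1 in range(1, m1 + 1):
                    e1 = hp + pre1[k1 - 1]
                    bi, bj = i0 - (k1 - 1), j0 + (k1 - 1)  # outermost of helix 1
                    if k1 >= p.min_stem:
                        key = (round(e1, 6), -k1, loop_len, bi)
                        if best_key is None or key < best_key:
                            best_key = key
                            best_pairs = [(i0 - t, j0 + t) for t in range(k1)]
                    if p.max_interruptions < 1:
                        continue
                    for a in range(0, p.max_interruption_side + 1):
                        for b in range(0, p.max_interruption_side + 1):
                            if a + b < 1 or a + b > p.max_interruption_total:
                                continue
                            si, sj = bi - 1 - a, bj + 1 + b
                            m2, pre2 = self._run(si, sj)
                            if m2 == 0:
                                continue
                            if a == 0 or b == 0:
                                gap = bulge_penalty(a + b)
                                if a + b == 1:
                                    gap += stack_energy((w[si], w[sj]), (w[bi], w[bj]))
                            else:
                                gap = internal_penalty(a, b)
                            for k2 in range(1, m2 + 1):
                                if k1 + k2 < p.min_stem:
                                    continue
                                e = e1 + gap + pre2[k2 - 1]
                                key = (round(e, 6), -(k1 + k2), loop_len, si - (k2 - 1))
                                if best_key is None or key < best_key:
                                    best_key = key
                                    best_pairs = [(i0 - t, j0 + t) for t in range(k1)] + [
                                        (si - t, sj + t) for t in range(k2)
                                    ]
        if best_pairs is None:
            return None
        best_pairs = sorted(best_pairs)
        return structure_energy(w, best_pairs), best_pairs


def _bottom_energy(window: str, pairs: list[Pair], k: int) -> tuple[float, int]:
    """Sum stacking energies of up to ``k`` bottom-most contiguous pair-steps."""
    dg, steps = 0.0, 0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if steps >= k:
            break
        if i2 == i1 + 1 and j2 == j1 - 1:
            dg += stack_energy((window[i1], window[j1]), (window[i2], window[j2]))
            steps += 1
        else:
            break
    return dg, steps


def fold_hairpin(window: str, params: FoldParams | None = None) -> HairpinStructure | None:
    """Fold a window into its MFE single stem-loop and trim tract pairing.

    Returns ``None`` when the window is shorter than the smallest possible
    hairpin, when no decomposition with negative free energy exists, or when
    trimming leaves fewer than ``min_stem`` pairs.
    """
    p = params or FoldParams()
    w = normalize_sequence(window)
    if len(w) > p.max_window:
        raise ValueError(f"window of {len(w)} nt exceeds max_window={p.max_window}")
    if len(w) < 2 * p.min_stem + p.min_loop:
        return None
    res = _Folder(w, p).best()
    if res is None:
        return None
    _, pairs = res
    pairs = sorted(pairs)  # bottom (outermost) -> top (innermost)
    dg_w = structure_energy(w, pairs)
    if dg_w >= 0:
        return None
    dg_b, steps = _bottom_energy(w, pairs, p.k_bottom)
    untrimmed = HairpinStructure(
        window=w, pairs=pairs, dG_W=dg_w, dG_H=dg_w, dG_B=dg_b,
        dG_B_steps=steps, params=p, trimmed=False,
    )
    trimmed = trim_tract_pairs(untrimmed)
    if trimmed.n_H < p.min_stem or trimmed.dG_H >= 0:
        return None
    return trimmed


def fold_untrimmed(window: str, params: FoldParams | None = None) -> HairpinStructure | None:
    """MFE constrained fold without tract trimming (mainly for inspection)."""
    p = params or FoldParams()
    w = normalize_sequence(window)
    if len(w) < 2 * p.min_stem + p.min_loop:
        return None
    res = _Folder(w, p).best()
    if res is None:
        return None
    _, pairs = res
    pairs = sorted(pairs)
    dg_w = structure_energy(w, pairs)
    if dg_w >= 0:
        return None
    dg_b, steps = _bottom_energy(w, pairs, p.k_bottom)
    return HairpinStructure(
        window=w, pairs=pairs, dG_W=dg_w, dG_H=dg_w, dG_B=dg_b,
        dG_B_steps=steps, params=p, trimmed=False,
    )


def _is_tract_pair(w: str, pair: Pair) -> bool:
    x, y = w[pair[0]], w[pair[1]]
    return (x == "A" and y == "T") or (x == "T" and y == "A")


def trim_tract_pairs(h: HairpinStructure) -> HairpinStructure:
    """Reassign tract pairing at the stem bottom to the A-/U-tracts.

    See the module docstring for the exact rule.  Never touches the terminal
    loop; never increases ``n_H``.
    """
    w, p = h.window, h.params
    pairs = list(h.pairs)  # bottom -> top
    removed: list[Pair] = []
    while pairs:
        if _is_tract_pair(w, pairs[0]):
            removed.append(pairs.pop(0))
            continue
        f = 0
        while f < len(pairs) and not _is_tract_pair(w, pairs[f]):
            f += 1
        if f == len(pairs):
            break  # no tract pairs anywhere above the bottom block
        r = f
        while r < len(pairs) and _is_tract_pair(w, pairs[r]):
            r += 1
        run = pairs[f:r]
        has_at = any(w[i] == "A" and w[j] == "T" for i, j in run)
        if f < p.min_stem and has_at and (len(pairs) - r) >= p.min_stem:
            removed.extend(pairs[:r])
            pairs = pairs[r:]
            continue
        break
    if not pairs:
        return replace(h, pairs=[], dG_H=0.0, dG_B=0.0, dG_B_steps=0,
                       trimmed=True, trimmed_pairs=removed)
    dg_h = structure_energy(w, pairs)
    dg_b, steps = _bottom_energy(w, pairs, p.k_bottom)
    return replace(h, pairs=pairs, dG_H=dg_h, dG_B=dg_b, dG_B_steps=steps,
                   trimmed=True, trimmed_pairs=removed)


def energy_whole(window: str, params: FoldParams | None = None) -> float | None:
    """dG_W: MFE of the untrimmed constrained fold of the whole window."""
    h = fold_untrimmed(window, params)
    return None if h is None else h.dG_W


def energy_bottom(h: HairpinStructure, k: int = 3) -> tuple[float, int]:
    """dG_B: stacking of the ``k`` bottom-most pair-steps of the (trimmed)
    stem.  Returns (energy, steps actually used); fewer steps than ``k``
    signals a short or interrupted stem bottom."""
    if h.n_H < 2:
        return 0.0, 0
    return _bottom_energy(h.window, h.pairs, k)
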