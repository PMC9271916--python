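import numpy as np
import pytest

from haloterm import catalog
from haloterm.core_io import reverse_complement
from haloterm.hairpin_fold import (
    FoldParams,
    energy_bottom,
    energy_whole,
    fold_hairpin,
    fold_untrimmed,
    trim_tract_pairs,
)
from haloterm.nn_energy import STACK_TABLE

from helpers_fold import oracle_mfe

# Annotated decompositions reproducible under whole-window MFE + tract
# trimming.  A05/A06/A09 are excluded: their published annotation is not an
# MFE structure of the full window (A05/A06 admit a much longer wobble-rich
# helix; A09's published stem length counts the bottom A:T tract pairs that
# the trimming rule must remove to reproduce A01).
REPRODUCIBLE = [
    "A01", "A02", "A03", "A04", "A07", "A08", "A10",
    "G01", "G02", "G03", "G04", "G05", "G06", "D01", "D02", "D03",
]


@pytest.mark.parametrize("name", REPRODUCIBLE)
def test_catalog_decomposition_reproduced(name):
    """Fold + trim of each published sequence gives the annotated stem length
    and terminal loop size."""
    h = fold_hairpin(catalog.get(name).seq)
    stem, loops = catalog.ANNOTATED_STRUCTURE[name]
    assert h is not None
    assert h.n_H == stem
    assert h.loop_sizes[0] == loops[0]


def test_a02_loop_sequence():
    h = fold_hairpin(catalog.get("A02").seq)
    assert h.n_H == 8
    assert h.loops[0][1] == "GATTT"


def test_g01_loop_is_atgac():
    h = fold_hairpin(catalog.get("G01").seq)
    assert h.loops[0][1] == "ATGAC"


def test_no_complementarity_gives_none():
    assert fold_hairpin("A" * 24) is None


def test_window_below_minimum_hairpin_size_gives_none():
    assert fold_hairpin("GCGCGCGCT") is None  # < 2*min_stem + min_loop


def test_trimming_never_increases_stem_and_keeps_loop():
    for name in catalog.SEQUENCES:
        raw = fold_untrimmed(catalog.get(name).seq)
        if raw is None:
            continue
        trimmed = trim_tract_pairs(raw)
        assert trimmed.n_H <= raw.n_H
        if trimmed.pairs:
            assert trimmed.pairs[-1] == raw.pairs[-1]  # terminal loop unchanged


def test_trimming_examples_from_annotated_parts():
    """A01 sheds its tract pairing down to a 6-bp core; a G:C-bottom stem
    (D02 after its A:T pairs) is left unchanged by further trimming."""
    a01_raw = fold_untrimmed(catalog.get("A01").seq)
    a01 = trim_tract_pairs(a01_raw)
    assert a01_raw.n_H > 6  # the untrimmed fold pairs the tracts with each other
    assert a01.n_H == 6
    assert a01.loop_sizes == [5]
    d02 = fold_hairpin(catalog.get("D02").seq)
    assert trim_tract_pairs(d02).n_H == d02.n_H  # idempotent on G:C bottom


def test_segments_reconstruct_window():
    for name in ("A01", "A04", "A07", "D01"):
        h = fold_hairpin(catalog.get(name).seq)
        joined = "".join(h.window[s:e] for _, s, e in h.segments())
        assert joined == h.window


def test_pairs_are_nested_and_legal():
    for name in catalog.SEQUENCES:
        h = fold_hairpin(catalog.get(name).seq)
        if h is None:
            continue
        for (i1, j1), (i2, j2) in zip(h.pairs, h.pairs[1:]):
            assert i1 < i2 < j2 < j1  # nested, no pseudoknots
        assert h.dG_H < 0


def test_whole_window_energy_bounds_trimmed_hairpin():
    for name in ("A01", "A02", "D01", "G01"):
        seq = catalog.get(name).seq
        h = fold_hairpin(seq)
        assert energy_whole(seq) <= h.dG_H + 1e-9


def test_gc_stack_deepens_stem_energy_monotonically():
    """Appending G:C pairs to a stem never raises dG_H."""
    prev = 0.0
    for k in range(4, 9):
        stem5 = "G" * k
        seq = stem5 + "ATAA" + reverse_complement(stem5)
        h = fold_hairpin(seq)
        assert h is not None and h.dG_H <= prev
        prev = h.dG_H


def test_bottom_stacking_energy_hand_sum_for_d01():
    """dG_B of the D01 stem bottom: GG/CC + GC/CG + CC/GG steps."""
    h = fold_hairpin(catalog.get("D01").seq)
    expected = STACK_TABLE["GGCC"] + STACK_TABLE["GCCG"] + STACK_TABLE["CCGG"]
    dg, steps = energy_bottom(h, k=3)
    assert steps == 3
    assert dg == pytest.approx(expected, abs=1e-9)
    assert dg == pytest.approx(-9.94, abs=1e-9)


def test_gc_rich_bottom_stacks_deeper_than_at_rich():
    gc = fold_hairpin("GGCGCGCC" + "ATAA" + reverse_complement("GGCGCGCC"))
    at = fold_hairpin("CATATATA" + "ATAA" + reverse_complement("CATATATA"))
    assert gc.dG_B < at.dG_B


def test_short_stem_uses_available_bottom_steps():
    h = fold_hairpin("GCTA" + "ATAA" + reverse_complement("GCTA"))
    dg, steps = energy_bottom(h, k=3)
    assert steps == min(3, h.n_H - 1)


@pytest.mark.parametrize("gc", [0.3, 0.5, 0.7])
def test_mfe_matches_bruteforce_enumeration(gc):
    """For random windows <= 30 nt the production search equals exhaustive
    enumeration of all legal decompositions."""
    rng = np.random.default_rng(42)
    p = FoldParams()
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for _ in range(70):
        n = int(rng.integers(20, 31))
        w = "".join(rng.choice(["A", "C", "G", "T"], size=n, p=probs))
        expected = oracle_mfe(w, p)
        got = fold_untrimmed(w, p)
        if expected is None or expected >= 0:
            assert got is None
        else:
            assert got is not None
            assert got.dG_W == pytest.approx(expected, abs=1e-6)
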