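"""Design operators for terminator engineering.

The "main contributor" strategy edits exactly one structural determinant at a
time — the terminal loop, the flanks, one tract, or the stem — while leaving
every other segment untouched; the de novo constructor assembles a terminator
from scratch (A-tract + GC-rich stem + stable loop + U-tract).  Every product
is validated by refolding rather than trusted by construction, because
flanking context can create alternative structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import NucleotideSequence, normalize_sequence, reverse_complement
from .hairpin_fold import FoldParams, HairpinStructure, fold_hairpin


class DesignError(ValueError):
    """A design operation is invalid or its product fails refold validation."""


def _fold_or_raise(t: NucleotideSequence, params: FoldParams | None) -> HairpinStructure:
    h = fold_hairpin(t.seq, params)
    if h is None:
        raise DesignError(f"record {t.id!r} does not fold into a hairpin")
    return h


def set_loop(
    t: NucleotideSequence, new_loop: str, params: FoldParams | None = None
) -> NucleotideSequence:
    """Replace the terminal loop; tracts and stem untouched.

    The product must refold with the intended loop.
    """
    params = params or FoldParams()
    new_loop = normalize_sequence(new_loop)
    if not (params.min_loop <= len(new_loop) <= params.max_loop):
        raise DesignError(
            f"loop of {len(new_loop)} nt outside [{params.min_loop}, {params.max_loop}]"
        )
    h = _fold_or_raise(t, params)
    ti, tj = h.pairs[-1]
    seq = h.window[: ti + 1] + new_loop + h.window[tj:]
    out = NucleotideSequence(t.id + f"_loop{new_loop}", seq, t.description)
    h2 = fold_hairpin(out.seq, params)
    if h2 is None or h2.loops[0][1] != new_loop:
        raise DesignError(
            f"product of set_loop({t.id}, {new_loop}) does not refold with that loop"
        )
    return out


def truncate_flanks(
    t: NucleotideSequence, cut5: int, cut3: int, params: FoldParams | None = None
) -> NucleotideSequence:
    """Remove ``cut5``/``cut3`` nt from the two ends; cuts must not invade
    the stem."""
    if cut5 < 0 or cut3 < 0:
        raise DesignError("cuts must be >= 0")
    h = _fold_or_raise(t, params)
    i0, j0 = h.pairs[0]
    avail5 = i0                       # 5' tail + A-tract (and trimmed pairing)
    avail3 = len(h.window) - j0 - 1   # U-tract + 3' tail
    if cut5 > avail5 or cut3 > avail3:
        raise DesignError(
            f"cut5={cut5}/cut3={cut3} invade the stem (available {avail5}/{avail3})"
        )
    seq = h.window[cut5 : len(h.window) - cut3]
    return NucleotideSequence(t.id + f"_trunc{cut5}_{cut3}", seq, t.description)


def mutate_tract(
    t: NucleotideSequence, side: str, pattern: str, params: FoldParams | None = None
) -> NucleotideSequence:
    """Replace the A-tract (side='a') or U-tract (side='u') with ``pattern``
    of the same length; the stem and loop must survive refolding unchanged."""
    if side not in ("a", "u"):
        raise DesignError("side must be 'a' or 'u'")
    pattern = normalize_sequence(pattern)
    h = _fold_or_raise(t, params)
    i0, j0 = h.pairs[0]
    if side == "a":
        tract = h.a_tract
        start = i0 - len(tract)
        end = i0
    else:
        tract = h.u_tract
        start = j0 + 1
        end = j0 + 1 + len(tract)
    if not tract:
        raise DesignError(f"record {t.id!r} has an empty {side}-tract")
    if len(pattern) != len(tract):
        raise DesignError(
            f"pattern length {len(pattern)} != {side}-tract length {len(tract)}"
        )
    seq = h.window[:start] + pattern + h.window[end:]
    out = NucleotideSequence(t.id + f"_{side}tract", seq, t.description)
    h2 = fold_hairpin(out.seq, params)
    if h2 is None or h2.loops[0][1] != h.loops[0][1] or h2.n_H != h.n_H:
        raise DesignError(
            f"mutate_tract({t.id}, {side}) changed the stem/loop on refolding"
        )
    return out


def _sample_stem(rng: np.random.Generator, length: int, gc: float) -> str:
    n_gc = int(round(gc * length))
    bases = [str(rng.choice(["G", "C"])) for _ in range(n_gc)] + [
        str(rng.choice(["A", "T"])) for _ in range(length - n_gc)
    ]
    rng.shuffle(bases)
    return "".join(bases)


def mutate_stem(
    t: NucleotideSequence,
    new_len: int,
    new_gc: float,
    seed: int,
    params: FoldParams | None = None,
    max_tries: int = 100,
) -> NucleotideSequence:
    """Replace the stem by a freshly sampled one of ``new_len`` bp at GC
    fraction ``new_gc``; both strands are co-edited so complementarity is
    preserved.  Requires a simple (uninterrupted) hairpin."""
    params = params or FoldParams()
    if new_len < params.min_stem:
        raise DesignError(f"stem of {new_len} bp below min_stem={params.min_stem}")
    h = _fold_or_raise(t, params)
    if h.loop_count != 1:
        raise DesignError("mutate_stem requires a simple (single-loop) hairpin")
    i0, j0 = h.pairs[0]
    ti, tj = h.pairs[-1]
    loop = h.window[ti + 1 : tj]
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        stem5 = _sample_stem(rng, new_len, new_gc)
        seq = h.window[:i0] + stem5 + loop + reverse_complement(stem5) + h.window[j0 + 1 :]
        out = NucleotideSequence(
            t.id + f"_stem{new_len}", seq, f"{t.description} stem seed={seed}".strip()
        )
        h2 = fold_hairpin(out.seq, params)
        if h2 is not None and h2.n_H == new_len and h2.loops[0][1] == loop:
            return out
    raise DesignError(
        f"could not realize a {new_len}-bp stem at GC={new_gc} for {t.id!r} "
        f"within {max_tries} samples"
    )


@dataclass
class DesignSpec:
    """De novo terminator blueprint."""

    a_len: int
    u_len: int
    stem_len: int
    stem_gc: float
    loop_seq: str
    flank5: str = ""
    flank3: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stem_len < 4:
            raise DesignError("stem_len must be >= 4")
        if not (3 <= len(self.loop_seq) <= 12):
            raise DesignError("loop must be 3-12 nt")
        if self.a_len < 0 or self.u_len < 0:
            raise DesignError("tract lengths must be >= 0")
        if not (0.0 <= self.stem_gc <= 1.0):
            raise DesignError("stem_gc must be a fraction in [0, 1]")


def de_novo_design(
    spec: DesignSpec, params: FoldParams | None = None, max_tries: int = 100
) -> NucleotideSequence:
    """Construct flank5 + A^a + stem5 + loop + revcomp(stem5) + T^u + flank3,
    sampling the stem at the target GC until the product refolds to the
    specified stem length and loop (bounded retries, then error)."""
    params = params or FoldParams()
    loop = normalize_sequence(spec.loop_seq)
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_tries):
        stem5 = _sample_stem(rng, spec.stem_len, spec.stem_gc)
        seq = (
            spec.flank5
            + "A" * spec.a_len
            + stem5
            + loop
            + reverse_complement(stem5)
            + "T" * spec.u_len
            + spec.flank3
        )
        rec = NucleotideSequence(
            f"denovo_s{spec.stem_len}_gc{spec.stem_gc:g}_seed{spec.seed}",
            seq,
            f"de novo design seed={spec.seed}",
        )
        h = fold_hairpin(rec.seq, params)
        if (
            h is not None
            and h.n_H == spec.stem_len
            and h.loop_count == 1
            and h.loops[0][1] == loop
        ):
            return rec
    raise DesignError(f"unsatisfiable design spec after {max_tries} samples: {spec}")
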