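"""Sequence features of a folded terminator: the regressors of the TE model
(Uscore, dG_H/n_H, match_pattern, dG_B) plus auxiliary descriptors.

Uscore weights T content immediately 3' of the trimmed stem with a geometric
positional decay, so proximal U's (the pause-inducing ones) dominate; it is
normalized to [0, 1].  match_pattern counts A:U pairings between the A-tract
(read 3'->5' from the stem base) and the U-tract (read 5'->3' from the stem
base) over a canonical ~8-nt tract window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .core_io import NucleotideSequence, gc_fraction
from .hairpin_fold import FoldParams, HairpinStructure, fold_hairpin


@dataclass
class FeatureParams:
    uscore_window: int = 15
    uscore_decay: float = 0.9
    match_window: int = 8
    fold: FoldParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fold is None:
            self.fold = FoldParams()


@dataclass
class TerminatorFeatures:
    """Feature row for one terminator record.

    ``folded`` is False (and numeric fields NaN) for records that do not fold
    into a hairpin.
    """

    name: str
    folded: bool
    uscore: float = math.nan
    dG_H: float = math.nan
    n_H: int = 0
    dG_H_per_nH: float = math.nan
    match_pattern: int = 0
    dG_B: float = math.nan
    dG_W: float = math.nan
    stem_gc: float = math.nan
    loop_count: int = 0
    loop_sizes: tuple[int, ...] = ()
    a_tract_len: int = 0
    u_tract_len: int = 0

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["loop_sizes"] = ";".join(str(s) for s in self.loop_sizes)
        return d


def compute_uscore(downstream: str, L: int = 15, decay: float = 0.9) -> float:
    """Positionally weighted U(T) content of the ``L`` nt 3' of the stem.

    uscore = sum_i [base_i == T] * decay^(i-1) / sum_i decay^(i-1), position 1
    adjacent to the stem; sequences shorter than ``L`` are padded with non-T.
    """
    if L < 1:
        raise ValueError("uscore window must be >= 1")
    if not (0 < decay <= 1):
        raise ValueError("decay must be in (0, 1]")
    s = downstream.upper().replace("U", "T")[:L]
    num = sum(decay ** i for i, base in enumerate(s) if base == "T")
    den = sum(decay ** i for i in range(L))
    return num / den


def compute_match_pattern(a_tract: str, u_tract: str, W: int = 8) -> int:
    """Number of A:U pairings between the tracts at mirrored distances from
    the stem base: positions i <= W with a_tract[i] == A and u_tract[i] == T,
    counting stopping at the shorter tract."""
    a = a_tract.upper()[::-1]  # read 3'->5' from the stem base
    u = u_tract.upper().replace("U", "T")
    return sum(
        1 for x, y in zip(a[:W], u[:W]) if x == "A" and y == "T"
    )


def features_from_structure(
    name: str, h: HairpinStructure, params: FeatureParams | None = None
) -> TerminatorFeatures:
    p = params or FeatureParams()
    uscore = compute_uscore(h.downstream_of_stem, p.uscore_window, p.uscore_decay)
    stem = h.stem5 + h.stem3
    return TerminatorFeatures(
        name=name,
        folded=True,
        uscore=uscore,
        dG_H=h.dG_H,
        n_H=h.n_H,
        dG_H_per_nH=h.dG_H / h.n_H,
        match_pattern=compute_match_pattern(h.a_tract, h.u_tract, p.match_window),
        dG_B=h.dG_B,
        dG_W=h.dG_W,
        stem_gc=gc_fraction(stem) if stem else math.nan,
        loop_count=h.loop_count,
        loop_sizes=tuple(h.loop_sizes),
        a_tract_len=len(h.a_tract),
        u_tract_len=len(h.u_tract),
    )


def extract_features(
    rec: NucleotideSequence, params: FeatureParams | None = None
) -> TerminatorFeatures:
    """Fold a record and compute all features; non-folding records yield a
    flagged all-null row."""
    p = params or FeatureParams()
    h = fold_hairpin(rec.seq, p.fold)
    if h is None:
        return TerminatorFeatures(name=rec.id, folded=False)
    return features_from_structure(rec.id, h, p)


def feature_table(records, params: FeatureParams | None = None):
    """Feature rows for a collection of records, as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([extract_features(r, params).as_dict() for r in records])
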