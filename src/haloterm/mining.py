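"""Genome-wide mining of intrinsic terminator candidates.

One 60-nt window is taken immediately downstream of each gene's stop codon
(gene-strand orientation); each window is folded, featurized and scored by a
primary rating combining the poly-U signal (weight 0.6) with a hairpin score
(weight 0.4) built from min-max-normalized -dG_W and stem GC content; the
top-N candidates are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import GeneModel, GenomicInterval, NucleotideSequence, reverse_complement
from .features import FeatureParams, TerminatorFeatures, extract_features


@dataclass
class RatingConfig:
    """Weights and normalization bounds of the primary rating.

    By default -dG_W is min-max-normalized over the mined cohort
    (cohort-relative scaling); explicit bounds may be supplied instead.
    """

    w_polyU: float = 0.6
    w_hairpin: float = 0.4
    neg_dG_W_bounds: tuple[float, float] | None = None  # (lo, hi) for minmax

    def __post_init__(self) -> None:
        if abs(self.w_polyU + self.w_hairpin - 1.0) > 1e-9:
            raise ValueError("rating weights must sum to 1")


@dataclass
class CandidateWindow:
    gene_id: str
    interval: GenomicInterval
    window_seq: str
    features: TerminatorFeatures | None = None
    rating: float = 0.0
    rank: int = 0
    truncated: bool = False


def extract_candidate_windows(
    genome: list[NucleotideSequence],
    genes: list[GeneModel],
    L: int = 60,
) -> list[CandidateWindow]:
    """One window per gene, starting at the stop codon end on the gene strand,
    truncated at contig boundaries."""
    contigs = {c.id: c.seq for c in genome}
    out = []
    for g in genes:
        iv = g.interval
        if iv.contig not in contigs:
            raise ValueError(f"gene {g.gene_id!r} references missing contig {iv.contig!r}")
        seq = contigs[iv.contig]
        sce = g.stop_codon_end
        if iv.strand == "+":
            start, end = sce, min(sce + L, len(seq))
            window = seq[start:end]
        else:
            start, end = max(sce - L, 0), sce
            window = reverse_complement(seq[start:end]) if end > start else ""
        if not window:
            continue
        out.append(
            CandidateWindow(
                gene_id=g.gene_id,
                interval=GenomicInterval(iv.contig, start, end, iv.strand),
                window_seq=window,
                truncated=len(window) < L,
            )
        )
    return out


def _minmax(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return 0.5
    return min(max((x - lo) / (hi - lo), 0.0), 1.0)


def rate_candidate(
    f: TerminatorFeatures | None, cfg: RatingConfig, neg_dG_W_bounds: tuple[float, float]
) -> float:
    """rating = 0.6 * uscore + 0.4 * mean(minmax(-dG_W), stem_gc), in [0, 1]."""
    if f is None or not f.folded:
        return 0.0
    lo, hi = cfg.neg_dG_W_bounds or neg_dG_W_bounds
    hairpin_score = 0.5 * (_minmax(-f.dG_W, lo, hi) + f.stem_gc)
    rating = cfg.w_polyU * f.uscore + cfg.w_hairpin * hairpin_score
    return min(max(rating, 0.0), 1.0)


def rank_and_select(
    candidates: list[CandidateWindow], top_n: int = 10
) -> list[CandidateWindow]:
    """Stable sort by rating desc, ties by lower dG_W then gene_id; ranks 1..N."""

    def key(c: CandidateWindow):
        dgw = c.features.dG_W if (c.features and c.features.folded) else 0.0
        return (-c.rating, dgw, c.gene_id)

    ranked = sorted(candidates, key=key)[: max(top_n, 0)]
    for i, c in enumerate(ranked, start=1):
        c.rank = i
    return ranked


def mine_genome(
    genome: list[NucleotideSequence],
    genes: list[GeneModel],
    top_n: int = 10,
    L: int = 60,
    cfg: RatingConfig | None = None,
    feature_params: FeatureParams | None = None,
) -> tuple[list[CandidateWindow], list[CandidateWindow]]:
    """Full mining pass: returns (all candidates, top-N ranked)."""
    cfg = cfg or RatingConfig()
    candidates = extract_candidate_windows(genome, genes, L)
    for c in candidates:
        c.features = extract_features(
            NucleotideSequence(c.gene_id, c.window_seq), feature_params
        )
    folded = [c.features for c in candidates if c.features.folded]
    if folded:
        vals = [-f.dG_W for f in folded]
        bounds = (min(vals), max(vals))
    else:
        bounds = (0.0, 1.0)
    for c in candidates:
        c.rating = rate_candidate(c.features, cfg, bounds)
    return candidates, rank_and_select(list(candidates), top_n)


def candidates_table(candidates: list[CandidateWindow]) -> pd.DataFrame:
    """Report table (1-based inclusive coordinates for human reading)."""
    rows = []
    for c in candidates:
        row = {
            "gene_id": c.gene_id,
            "contig": c.interval.contig,
            "start_1based": c.interval.start + 1,
            "end_1based": c.interval.end,
            "strand": c.interval.strand,
            "window_seq": c.window_seq,
            "rating": c.rating,
            "rank": c.rank,
            "truncated": c.truncated,
        }
        if c.features is not None:
            row.update(c.features.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
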