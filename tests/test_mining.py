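import math

import pytest

from haloterm import catalog
from haloterm.core_io import GeneModel, GenomicInterval, NucleotideSequence, reverse_complement
from haloterm.features import TerminatorFeatures
from haloterm.mining import (
    CandidateWindow,
    RatingConfig,
    extract_candidate_windows,
    mine_genome,
    rank_and_select,
    rate_candidate,
)
from haloterm.synthetic_data import SynthGenomeConfig, synth_genome


def _feat(uscore, dG_W=-10.0, stem_gc=0.5):
    return TerminatorFeatures(
        name="x", folded=True, uscore=uscore, dG_H=dG_W, n_H=6,
        dG_H_per_nH=dG_W / 6, match_pattern=0, dG_B=-5.0, dG_W=dG_W,
        stem_gc=stem_gc, loop_count=1, loop_sizes=(4,),
    )


def test_window_extraction_plus_and_minus_strand():
    seq = "".join("ACGT"[(i * 7) % 4] for i in range(1000))
    genome = [NucleotideSequence("c", seq)]
    genes = [
        GeneModel("plus", GenomicInterval("c", 100, 400, "+")),
        GeneModel("minus", GenomicInterval("c", 100, 400, "-")),
    ]
    wins = {w.gene_id: w for w in extract_candidate_windows(genome, genes, L=60)}
    assert (wins["plus"].interval.start, wins["plus"].interval.end) == (400, 460)
    assert wins["plus"].window_seq == seq[400:460]
    assert wins["minus"].window_seq == reverse_complement(seq[40:100])


def test_window_truncated_at_contig_end():
    genome = [NucleotideSequence("c", "ACGT" * 30)]  # 120 nt
    genes = [GeneModel("g", GenomicInterval("c", 10, 100, "+"))]
    (w,) = extract_candidate_windows(genome, genes, L=60)
    assert len(w.window_seq) == 20
    assert w.truncated


def test_missing_contig_names_gene():
    genome = [NucleotideSequence("c", "ACGT" * 30)]
    genes = [GeneModel("lost", GenomicInterval("other", 0, 50, "+"))]
    with pytest.raises(ValueError, match="lost"):
        extract_candidate_windows(genome, genes)


def test_rating_weights_and_extremes():
    cfg = RatingConfig()
    bounds = (0.0, 20.0)
    # uscore 1, hairpin score 1 (max -dG_W and all-GC stem)
    assert rate_candidate(_feat(1.0, dG_W=-20.0, stem_gc=1.0), cfg, bounds) == pytest.approx(1.0)
    # uscore 1, hairpin score 0
    assert rate_candidate(_feat(1.0, dG_W=0.0, stem_gc=0.0), cfg, bounds) == pytest.approx(0.6)
    assert rate_candidate(_feat(0.0, dG_W=0.0, stem_gc=0.0), cfg, bounds) == 0.0
    assert rate_candidate(None, cfg, bounds) == 0.0
    with pytest.raises(ValueError):
        RatingConfig(w_polyU=0.7, w_hairpin=0.4)


def test_rating_monotone_in_uscore():
    cfg = RatingConfig()
    bounds = (0.0, 20.0)
    ratings = [rate_candidate(_feat(u), cfg, bounds) for u in (0.0, 0.3, 0.6, 1.0)]
    assert ratings == sorted(ratings)


def _cand(gene_id, rating, dgw=0.0):
    c = CandidateWindow(gene_id, GenomicInterval("c", 0, 60), "A" * 60)
    c.rating = rating
    c.features = _feat(0.5, dG_W=dgw)
    return c


def test_ranking_tie_rules_and_topn():
    cands = [_cand("b", 0.5), _cand("a", 0.5), _cand("c", 0.9)]
    ranked = rank_and_select(cands, top_n=10)
    assert [c.gene_id for c in ranked] == ["c", "a", "b"]  # ties: lexicographic
    assert [c.rank for c in ranked] == [1, 2, 3]
    lower_dgw = [_cand("x", 0.5, dgw=-15.0), _cand("y", 0.5, dgw=-5.0)]
    assert [c.gene_id for c in rank_and_select(lower_dgw, 2)] == ["x", "y"]
    assert len(rank_and_select(cands, top_n=99)) == 3


def test_mining_is_strand_consistent():
    """Mining the reverse-complemented genome with flipped annotations yields
    identical window sequences."""
    cfg = SynthGenomeConfig(seed=5, genome_len=8000, n_genes=10,
                            planted=[(2, catalog.get("A02"))])
    genome, genes = synth_genome(cfg)
    n = len(genome[0].seq)
    flipped_genome = [genome[0].reverse_complement()]
    flipped_genes = [
        GeneModel(
            g.gene_id,
            GenomicInterval(
                "chr", n - g.interval.end, n - g.interval.start,
                "-" if g.interval.strand == "+" else "+",
            ),
        )
        for g in genes
    ]
    w1 = {w.gene_id: w.window_seq for w in extract_candidate_windows(genome, genes)}
    w2 = {w.gene_id: w.window_seq
          for w in extract_candidate_windows(flipped_genome, flipped_genes)}
    assert w1 == w2


def test_planted_terminator_ranks_first():
    """A strong planted part beats 50 background windows."""
    cfg = SynthGenomeConfig(seed=3, genome_len=30000, n_genes=50,
                            planted=[(7, catalog.get("A02"))])
    genome, genes = synth_genome(cfg)
    _, top = mine_genome(genome, genes, top_n=10)
    assert top[0].gene_id == "gene0007"
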