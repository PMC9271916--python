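"""Synthetic inputs for every pipeline stage.

Three generators, all pure functions of (configuration, seed):

* a genome (FASTA + gene models) with terminators planted verbatim downstream
  of chosen genes in i.i.d. background sequence of configurable GC;
* fluorescence plates simulated from true TE values under multiplicative
  Gaussian noise (plate-reader-like, CV-parameterized, floored at 0);
* feature-TE training libraries drawn from the linear TE model plus Gaussian
  noise, with regressor ranges bracketing the characterized terminator cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomicInterval, NucleotideSequence, reverse_complement
from .te_model import DEFAULT_MODEL, LinearTEModel, predict_te_from_values


@dataclass
class SynthGenomeConfig:
    seed: int
    genome_len: int = 50_000
    n_genes: int = 50
    background_gc: float = 0.5
    gene_len: int = 300
    spacing: int = 120  # intergenic room; must exceed the 60-nt window
    planted: list[tuple[int, NucleotideSequence]] = field(default_factory=list)


def synth_genome(cfg: SynthGenomeConfig) -> tuple[list[NucleotideSequence], list[GeneModel]]:
    """Background genome with non-overlapping genes on both strands and
    terminators planted at their genes' stop-codon ends."""
    rng = np.random.default_rng(cfg.seed)
    slot = cfg.gene_len + cfg.spacing
    if cfg.n_genes * slot + cfg.spacing > cfg.genome_len:
        raise ValueError(
            f"{cfg.n_genes} genes of {cfg.gene_len} nt with {cfg.spacing} nt "
            f"spacing do not fit in {cfg.genome_len} nt"
        )
    p_gc = cfg.background_gc / 2.0
    p_at = (1.0 - cfg.background_gc) / 2.0
    seq = rng.choice(
        np.array(["A", "C", "G", "T"]), size=cfg.genome_len,
        p=[p_at, p_gc, p_gc, p_at],
    )
    genes: list[GeneModel] = []
    for k in range(cfg.n_genes):
        start = cfg.spacing + k * slot
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                f"gene{k:04d}",
                GenomicInterval("chr", start, start + cfg.gene_len, strand),
            )
        )
    for idx, term in cfg.planted:
        g = genes[idx]
        sce = g.stop_codon_end
        t = term.seq
        if g.interval.strand == "+":
            if sce + len(t) > cfg.genome_len:
                raise ValueError(f"planted terminator overflows contig at gene {idx}")
            seq[sce : sce + len(t)] = list(t)
        else:
            if sce - len(t) < 0:
                raise ValueError(f"planted terminator overflows contig at gene {idx}")
            seq[sce - len(t) : sce] = list(reverse_complement(t))
    genome = [NucleotideSequence("chr", "".join(seq), f"synthetic seed={cfg.seed}")]
    return genome, genes


def synth_plate(
    true_te: dict[str, float],
    nc_ratio: float = 1.0,
    gfp_level: float = 1000.0,
    cv: float = 0.05,
    seed: int = 0,
    n_rep: int = 3,
    od600: float = 2.0,
    blank_level: float = 50.0,
) -> pd.DataFrame:
    """Simulated plate in the assay schema, from programmed TE values.

    Per replicate, normalized GFP = gfp_level*(1+eps), normalized
    RFP = GFP*nc_ratio*(1 - te/100)*(1+eps'), eps ~ N(0, cv), floored at 0;
    raw readings are back-transformed (times OD600, plus blank).  The NC
    group is generated with te = 0; blank rows are included.
    """
    if gfp_level <= 0:
        raise ValueError("gfp_level must be > 0")
    for s, te in true_te.items():
        if not (-100.0 <= te <= 100.0):
            raise ValueError(f"true TE for {s!r} outside [-100, 100]")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        rows.append(
            {"sample": "blank", "role": "blank", "replicate": rep,
             "gfp": blank_level, "rfp": blank_level, "od600": 0.0}
        )
    samples = [("NC", "negative_control", 0.0)] + [
        (s, "test", te) for s, te in sorted(true_te.items())
    ]
    for name, role, te in samples:
        for rep in range(1, n_rep + 1):
            g = max(gfp_level * (1.0 + rng.normal(0.0, cv)), 0.0)
            r = max(g * nc_ratio * (1.0 - te / 100.0) * (1.0 + rng.normal(0.0, cv)), 0.0)
            rows.append(
                {"sample": name, "role": role, "replicate": rep,
                 "gfp": blank_level + g * od600, "rfp": blank_level + r * od600,
                 "od600": od600}
            )
    return pd.DataFrame(rows)


# regressor ranges bracketing the characterized terminator cohort
LIBRARY_RANGES = {
    "uscore": (0.0, 1.0),
    "neg_dG_H_per_nH": (0.0, 4.0),   # kcal/mol/bp
    "match_pattern": (0, 8),
    "dG_B": (-6.0, 0.0),             # kcal/mol
}


def synth_training_library(
    n: int,
    model: LinearTEModel = DEFAULT_MODEL,
    te_noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-TE table with regressors sampled uniformly in the cohort
    ranges and TE = linear model + N(0, te_noise_sd)."""
    if n < 10:
        raise ValueError("library needs n >= 10 rows")
    rng = np.random.default_rng(seed)
    uscore = rng.uniform(*LIBRARY_RANGES["uscore"], size=n)
    energy = rng.uniform(*LIBRARY_RANGES["neg_dG_H_per_nH"], size=n)
    match = rng.integers(
        LIBRARY_RANGES["match_pattern"][0], LIBRARY_RANGES["match_pattern"][1] + 1, size=n
    ).astype(float)
    dgb = rng.uniform(*LIBRARY_RANGES["dG_B"], size=n)
    te = np.array(
        [
            predict_te_from_values(u, e, m, b, model)
            for u, e, m, b in zip(uscore, energy, match, dgb)
        ]
    )
    if te_noise_sd > 0:
        te = te + rng.normal(0.0, te_noise_sd, size=n)
    return pd.DataFrame(
        {
            "uscore": uscore,
            "neg_dG_H_per_nH": energy,
            "match_pattern": match,
            "dG_B": dgb,
            "te": te,
        }
    )
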