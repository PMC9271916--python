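"""Characterized intrinsic terminator parts for *Halomonas bluephagenesis* TD01.

Nineteen published terminator sequences (GenBank ON646277-ON646295): ten
native parts mined from the genome (A01-A10), six rational redesigns of the
A04 scaffold (G01-G06) and three de novo designs (D01-D03), together with
their measured termination efficiencies from the dual-fluorescent-reporter
characterization and the annotated stem/loop decomposition of each part.
These printed sequences are the reference inputs for the folding and feature
pipeline.
"""

from __future__ import annotations

from .core_io import NucleotideSequence

# name -> (sequence 5'->3', GenBank accession)
SEQUENCES: dict[str, tuple[str, str]] = {
    # native screened terminators
    "A01": ("CTTCATGACCTGAAACAAAAGGCGCCCGTGTGGCGCCTTTTGCTTGGTGTGAGGGGT", "ON646277"),
    "A02": ("CCCACGTTAAAGAAACGCCGCCCGATTTGGGCGGCGTCTATGTTGGCGCTA", "ON646278"),
    "A03": ("GAGACCACTAAAAAAGCAGTGGAAACTGCTAAGCAATAAACGCT", "ON646279"),
    "A04": ("AATTGATAGATAAAATGCCGCACCGTCATCATCAGGTGCGGCATTTTTTTGTTTACAC", "ON646280"),
    "A05": ("ATCGAATAGAAGCGTTGTGGACGTCAGGCGCCGTTGATATGGCGTCTGACGTTTACGTGGTTGGCTCTTATA", "ON646281"),
    "A06": ("TAGAAGCGTTGTGGACGTCAGGCGCCGTTGATATGGCGTCTGACGTTTACGTGGTTGGCTAGCG", "ON646282"),
    "A07": ("GCTCTATAAACCAAAGCGCCCGCAAGACCTGCAGAAGGGGCCGCGGGCGCTTTTTTATTGGCGTG", "ON646283"),
    "A08": ("TGAACTGATTTAATACGGCGCGTCGTTAGACGCGCCGTTTGCTGGCAGTTAC", "ON646284"),
    "A09": ("AACGTTAGATAGAAAGGCGGGCACCAGGAGCGCCCGCCTTTAGAGCCGAAACT", "ON646285"),
    "A10": ("TTAGCTAAATACAAAGGCCGGTGGCACTATCTGTGCTACCGGCCTTTTTGTTAAATAGT", "ON646286"),
    # rationally designed terminators based on A04
    "G01": ("GTGTAAACAAAAAAAGCCGCACCATGACGGTGCGGCTTTTATCTATCAATT", "ON646287"),
    "G02": ("GTGTAAATATTGCTTGCCGCACCATGACGGTGCGGCTTTTATCTATCAATT", "ON646288"),
    "G03": ("GTGTAAACAAAAAAAGCCGCACCATGACGGTGCGGCTCCACAACTATCAATT", "ON646289"),
    "G04": ("AAAAAAAGCCGCACCATGACGGTGCGGCTTTTATC", "ON646290"),
    "G05": ("GTGTAAACAAAAAAACTACACCATGACGGTGCTAGTCCACAACTATCAATT", "ON646291"),
    "G06": ("GTGTAAACAAAAAAACGCCGCCGCACCATGACGGTGCGGCGGCGTCCACAACTATCAATT", "ON646292"),
    # de novo designed terminators
    "D01": ("AAAAAAAAAAGGCCTCCCGTTAGGGAGGCCTTTTTTTTTT", "ON646293"),
    "D02": ("ATCAATAAAAAACGCCGCCCGATTTGGGCGGCGTTATTGTTCGTC", "ON646294"),
    "D03": ("GCTATAAAAAAAGGCCGCTTTCGCGGCCTTTTTTCGAAAA", "ON646295"),
}

# measured termination efficiency (%) from the dual-reporter assay
MEASURED_TE: dict[str, float] = {
    "A01": 96.9, "A02": 97.6, "A03": 24.4, "A04": -24.8, "A05": 16.6,
    "A06": 27.9, "A07": 83.6, "A08": -29.2, "A09": 51.4, "A10": 36.5,
    "G01": 50.1, "G02": 39.1, "G03": 32.8, "G04": 81.2, "G05": -33.9,
    "G06": -15.7, "D01": 94.7, "D02": 88.1, "D03": 89.8, "T7": 75.3,
}

# annotated decomposition: name -> (stem bp, [terminal loop nt, ...])
ANNOTATED_STRUCTURE: dict[str, tuple[int, list[int]]] = {
    "A01": (6, [5]), "A02": (8, [5]), "A03": (5, [4]), "A04": (8, [10]),
    "A05": (11, [4]), "A06": (11, [4]), "A07": (11, [5, 9]), "A08": (9, [4]),
    "A09": (10, [9]), "A10": (12, [5]),
    "G01": (8, [5]), "G02": (8, [5]), "G03": (8, [5]), "G04": (8, [5]),
    "G05": (4, [5]), "G06": (12, [5]),
    "D01": (8, [4]), "D02": (8, [5]), "D03": (6, [4]),
}

# poly U / poly A regularity labels from the characterization
REGULARITY: dict[str, str] = {
    "A01": "perfect", "A02": "perfect", "A03": "perfect", "A04": "perfect",
    "A05": "poor", "A06": "poor", "A07": "perfect", "A08": "moderate",
    "A09": "moderate", "A10": "perfect",
    "G01": "perfect", "G02": "poor", "G03": "poor", "G04": "perfect",
    "G05": "poor", "G06": "poor",
    "D01": "perfect", "D02": "poor", "D03": "perfect",
}


def get(name: str) -> NucleotideSequence:
    seq, acc = SEQUENCES[name]
    return NucleotideSequence(name, seq, description=acc)


def all_terminators() -> list[NucleotideSequence]:
    return [get(name) for name in SEQUENCES]
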