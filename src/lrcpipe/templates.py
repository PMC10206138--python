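"""Synthetic sequence building blocks for LRC-like loci.

Every planted gene is assembled from a small set of exemplar exon
peptides: a cleavable signal peptide (SP), an immunoglobulin-superfamily
(Ig) domain consensus, a transmembrane (TM) segment with or without the
arginine typical of activating receptors, and short or long (ITIM-bearing)
cytoplasmic tails.  The peptides are synthetic paralogs of a generic
Ig-receptor vocabulary, not real Felis catus sequence, so the package is
fully self-contained.  DNA is obtained by back-translation with a fixed
preferred-codon table; controlled divergence (substitutions between Ig
paralogs, synonymous jitter elsewhere) mimics within-family homology
while preserving the encoded protein features exactly where truth labels
depend on them.
"""

from __future__ import annotations

import random

# Kyte-Doolittle hydropathy scale.
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "*": 0.0,
}

CHARGED = set("RKDEH")

# --- exemplar exon peptides -------------------------------------------------

# Signal peptide: <=5-residue n-region, hydrophobic h-region, small-residue
# c-region ending in Ala (the -1 position of the cleavage site).
SP_AA = "MKTLLILLLVAAASA"

# TM segments, 23 aa.  The activating variant carries a single arginine in
# the membrane-spanning stretch; the inhibitory variant has no charged
# residue at all.
TM_B_AA = "VSLIALGLFLLLVGIIAAFILSW"
TM_A_AA = "VSLIALGLFLLRVGIIAAFILSW"

# Cytoplasmic tails.  The long tail carries up to two ITIM hexamers
# ([S/I/V/L]xYxx[I/V/L]); disabling a slot swaps the tyrosine for
# phenylalanine so the motif count is exact.  No tyrosine occurs outside
# the slots, so planted ITIM counts are unambiguous.
TAIL_SHORT_AA = "GHQKRSTDPENQ"
_TAIL_PRE = "QEGDRHQPSE"
_TAIL_MID = "GDKPQESTNRPDHQ"
_TAIL_POST = "PQDSGERQQPNSTRDNSESA"
_ITIM_SLOTS = ("SVYAQL", "SIYATL")

# Ig-superfamily domain consensus, 97 aa: two cysteines, scattered aromatic
# and hydrophobic residues but no 19-residue stretch hydrophobic enough to
# be mistaken for a TM segment, and an N-terminus that cannot satisfy the
# signal-peptide heuristic.
IG_AA = (
    "GPKPTLSALPSPVVTSGGNVTLQCRSQLGFDRFALYKEGDSAPLQRLQSEHQGGQYQAEF"
    "PMSPVTSAHAGTYRCYGSYSSNPHLLSHPSDPLELVVT"
)

# Replacement alphabet used when deriving family paralogs at the protein
# level; deliberately hydrophilic so divergence can never create TM-like
# stretches or destroy the "no signal peptide" property of the Ig block.
_SAFE_AA = "ARNDQEGHKPST"


def long_tail_aa(itim_count: int) -> str:
    """Long cytoplasmic tail with exactly ``itim_count`` intact ITIMs (0-2)."""
    if not 0 <= itim_count <= 2:
        raise ValueError("long tail supports 0-2 ITIM slots")
    slots = []
    for i, hexamer in enumerate(_ITIM_SLOTS):
        if i < itim_count:
            slots.append(hexamer)
        else:
            slots.append(hexamer.replace("Y", "F"))
    return _TAIL_PRE + slots[0] + _TAIL_MID + slots[1] + _TAIL_POST


def mutate_protein(aa: str, rate: float, seed: int) -> str:
    """Derive a diverged paralog of a peptide (deterministic in ``seed``)."""
    rng = random.Random(seed)
    out = []
    for ch in aa:
        if rng.random() < rate:
            repl = rng.choice(_SAFE_AA)
            while repl == ch:
                repl = rng.choice(_SAFE_AA)
            out.append(repl)
        else:
            out.append(ch)
    return "".join(out)


# Family-specific G domain paralogs: the KIR and the novel Ig-like gene are
# recognisable by their divergence from the LILR consensus.
IG_FAMILY = {
    "LILR": IG_AA,
    "KIR": mutate_protein(IG_AA, 0.25, seed=101),
    "NOVEL": mutate_protein(IG_AA, 0.25, seed=202),
}

# --- back-translation -------------------------------------------------------

_PREFERRED = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAG", "G": "GGC", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAG", "M": "ATG", "F": "TTC", "P": "CCT",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTG",
}

_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAC", "AAT"], "D": ["GAC", "GAT"], "C": ["TGC", "TGT"],
    "Q": ["CAG", "CAA"], "E": ["GAG", "GAA"],
    "G": ["GGC", "GGT", "GGA", "GGG"], "H": ["CAC", "CAT"],
    "I": ["ATC", "ATT", "ATA"],
    "L": ["CTG", "CTC", "CTT", "CTA", "TTG", "TTA"],
    "K": ["AAG", "AAA"], "M": ["ATG"], "F": ["TTC", "TTT"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["AGC", "AGT", "TCT", "TCC", "TCA", "TCG"],
    "T": ["ACC", "ACT", "ACA", "ACG"], "W": ["TGG"],
    "Y": ["TAC", "TAT"], "V": ["GTG", "GTC", "GTT", "GTA"],
}

STOPS = {"TAA", "TAG", "TGA"}


def backtranslate(aa: str) -> str:
    """Peptide -> DNA using the fixed preferred-codon table."""
    return "".join(_PREFERRED[ch] for ch in aa)


def synonymous_jitter(dna: str, rate: float, rng: random.Random) -> str:
    """Swap codons for single-base synonyms with per-codon probability
    ``rate``.

    The encoded protein is untouched, so truth features carried by SP/TM/
    tail exons survive exactly while the DNA still varies between
    paralogs.  Only synonyms one substitution away are used, keeping the
    per-nucleotide divergence at rate/3.
    """
    from Bio.Seq import Seq

    codons = [dna[i:i + 3] for i in range(0, len(dna), 3)]
    out = []
    for codon in codons:
        aa = str(Seq(codon).translate())
        near = [c for c in _SYNONYMS.get(aa, [])
                if c != codon and sum(x != y for x, y in zip(c, codon)) == 1]
        if near and rng.random() < rate:
            out.append(rng.choice(near))
        else:
            out.append(codon)
    return "".join(out)


def diverge_dna(dna: str, rate: float, rng: random.Random) -> str:
    """Random substitutions at per-base probability ``rate``, stop-free.

    Any substitution creating an in-frame stop codon is redrawn, so clean
    template exons stay translatable; used for the Ig paralog divergence.
    """
    seq = list(dna)
    for i in range(len(seq)):
        if rng.random() >= rate:
            continue
        original = seq[i]
        choices = [b for b in "ACGT" if b != original]
        rng.shuffle(choices)
        codon_start = (i // 3) * 3
        for b in choices:
            seq[i] = b
            codon = "".join(seq[codon_start:codon_start + 3])
            if len(codon) < 3 or codon not in STOPS:
                break
        else:
            seq[i] = original
    return "".join(seq)


def random_dna(length: int, gc: float, rng: random.Random) -> str:
    """Random sequence at the requested G+C fraction."""
    out = []
    for _ in range(length):
        if rng.random() < gc:
            out.append(rng.choice("GC"))
        else:
            out.append(rng.choice("AT"))
    return "".join(out)
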