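"""Synthetic Leukocyte Receptor Complex loci with known truth.

Generates desk-scale genomic contigs that emulate the architecture of a
carnivore LRC: two clusters of multi-exon LILR genes in mixed
orientations flanked by framing-gene markers (TTYH1, RPS9, LAIR1, GP6,
RDH13, ...), a KIR pseudogene, a novel Ig-like gene between GP6 and
RDH13, lesioned pseudogenes and Ig fragments.  Every planted gene is
recorded in a truth set (exon coordinates, classification label, lesion
list, spliced CDS) so each downstream stage of the pipeline can be
tested against known answers.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  Minus-strand genes are emitted reverse-complemented with
truth coordinates on the forward strand.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio.Seq import Seq

from . import templates as T

DEFAULT_IG_DIVERGENCE = 0.10    # substitutions/bp between planted Ig paralogs
SYN_JITTER_RATE = 0.30          # per-codon synonymous swap rate, non-Ig exons
INTRON_RANGE = (200, 2000)      # bp, uniform
INTERGENIC_RANGE = (6000, 10000)
FRAMING_LENGTH = 2000

LESION_KINDS = {
    "frameshift_ins", "frameshift_del", "nonsense", "splice_disruption",
    "domain_deletion", "compensated_double_frameshift",
}


@dataclass
class LesionSpec:
    """A planned gene-inactivating (or tolerated) sequence lesion.

    ``target_exon`` indexes exons in coding order (for splice_disruption it
    indexes the intron following that exon).  ``offset`` is in bp from the
    exon start; ``span`` is the indel length in bp, except for the
    compensated double frameshift where it is the number of codons affected
    between the two compensating deletions.
    """

    kind: str
    target_exon: int = 1
    offset: int = 30
    span: int = 1

    def __post_init__(self):
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind: {self.kind}")


@dataclass
class GenePlan:
    """Blueprint for one planted receptor gene."""

    name: str
    strand: str = "+"
    receptor_type: str = "B"          # A | B | AB | neither
    ig_count: int = 4
    has_sp: bool = True
    has_tm: Optional[bool] = None     # derived from receptor_type if None
    tm_charged: Optional[bool] = None
    tail: Optional[str] = None        # short | long | absent
    itim_count: Optional[int] = None
    lesions: list[LesionSpec] = field(default_factory=list)
    is_fragment: bool = False
    family: str = "LILR"              # LILR | KIR | NOVEL
    duplicate_of: Optional[str] = None

    def normalized(self) -> "GenePlan":
        """Fill type-derived defaults: A = short tail + charged TM,
        B = long ITIM tail, AB = both, neither = no TM and no tail."""
        p = replace(self)
        if p.receptor_type == "A":
            p.has_tm = True if p.has_tm is None else p.has_tm
            p.tm_charged = True if p.tm_charged is None else p.tm_charged
            p.tail = p.tail or "short"
            p.itim_count = 0 if p.itim_count is None else p.itim_count
        elif p.receptor_type == "B":
            p.has_tm = True if p.has_tm is None else p.has_tm
            p.tm_charged = False if p.tm_charged is None else p.tm_charged
            p.tail = p.tail or "long"
            p.itim_count = 2 if p.itim_count is None else p.itim_count
        elif p.receptor_type == "AB":
            p.has_tm = True if p.has_tm is None else p.has_tm
            p.tm_charged = True if p.tm_charged is None else p.tm_charged
            p.tail = p.tail or "long"
            p.itim_count = 2 if p.itim_count is None else p.itim_count
        elif p.receptor_type == "neither":
            p.has_tm = False if p.has_tm is None else p.has_tm
            p.tail = p.tail or "absent"
            p.tm_charged = False if p.tm_charged is None else p.tm_charged
            p.itim_count = 0 if p.itim_count is None else p.itim_count
        else:
            raise ValueError(f"receptor_type: {p.receptor_type}")
        if p.itim_count > 0 and p.tail != "long":
            raise ValueError("itim_count > 0 requires a long tail")
        if p.ig_count not in (1, 2, 3, 4, 6):
            raise ValueError("ig_count must be one of 1 (fragments), 2, 3, 4, 6")
        return p


@dataclass
class FramingGene:
    """Annotation-only marker for a conserved framing gene."""

    name: str
    length: int = FRAMING_LENGTH


@dataclass
class LocusSpec:
    species_label: str
    contig_length: int
    gene_plan: list  # ordered GenePlan / FramingGene elements
    intergenic_gc: float = 0.45
    seed: int = 0
    ig_divergence: float = DEFAULT_IG_DIVERGENCE


@dataclass
class GeneTruth:
    name: str
    strand: str
    label: str
    residual_type: str
    functional: bool
    ig_count: int
    family: str
    start: int
    end: int
    exons: list          # [(start, end, exon_class)] forward order
    coding_exons: list   # [(start, end, exon_class)] coding order
    lesions: list
    cds: str
    protein: str
    at_novel_locus: bool = False
    duplicate_of: Optional[str] = None


@dataclass
class TruthSet:
    species: str
    contig: str
    length: int
    genes: list
    framing: list        # [(name, start, end)]
    sequence: str = ""


# --- gene assembly ----------------------------------------------------------

def exon_peptides(plan: GenePlan) -> list[tuple[str, str]]:
    """Ordered (exon_class, peptide) blocks for a normalized plan."""
    ig = T.IG_FAMILY[plan.family]
    blocks: list[tuple[str, str]] = []
    if plan.has_sp:
        blocks.append(("SP", T.SP_AA))
    n_ig = 1 if plan.is_fragment else plan.ig_count
    for _ in range(n_ig):
        blocks.append(("IG", ig))
    if not plan.is_fragment:
        if plan.has_tm:
            blocks.append(("TM", T.TM_A_AA if plan.tm_charged else T.TM_B_AA))
        if plan.tail == "short":
            blocks.append(("TAIL", T.TAIL_SHORT_AA))
        elif plan.tail == "long":
            blocks.append(("TAIL", T.long_tail_aa(plan.itim_count)))
    return blocks


def inject_lesion(template_cds: str, lesion: LesionSpec,
                  rng: random.Random) -> str:
    """Apply exactly one lesion to a DNA sequence (coding orientation).

    The compensated double frameshift deletes 1 bp at ``offset`` and 2 bp
    ``3*span`` bp downstream, so the reading frame is disrupted and then
    restored with ``span`` codons affected.
    """
    seq = template_cds
    off = lesion.offset
    if off < 0 or off >= len(seq):
        raise ValueError("lesion offset outside sequence")
    if lesion.kind == "frameshift_ins":
        ins = "".join(rng.choice("ACGT") for _ in range(lesion.span))
        return seq[:off] + ins + seq[off:]
    if lesion.kind == "frameshift_del":
        return seq[:off] + seq[off + lesion.span:]
    if lesion.kind == "nonsense":
        c = off - off % 3
        return seq[:c] + "TAA" + seq[c + 3:]
    if lesion.kind == "compensated_double_frameshift":
        second = off + 3 * lesion.span
        if second + 2 > len(seq):
            raise ValueError("compensated lesion does not fit in sequence")
        seq = seq[:second] + seq[second + 2:]
        return seq[:off] + seq[off + 1:]
    raise ValueError(f"{lesion.kind} does not apply to a bare CDS")


def _build_gene(plan: GenePlan, rng: random.Random,
                ig_divergence: float) -> tuple[str, list, str]:
    """Assemble gene DNA (coding orientation, introns included).

    Returns (gene_dna, coding-order exon offsets [(off, len, class)], cds).
    """
    blocks = exon_peptides(plan)
    exon_dna = []
    for cls, aa in blocks:
        dna = T.backtranslate(aa)
        if cls == "IG":
            dna = T.diverge_dna(dna, ig_divergence, rng)
        else:
            dna = T.synonymous_jitter(dna, SYN_JITTER_RATE, rng)
        exon_dna.append([cls, dna])
    exon_dna[-1][1] += "TAA"  # terminal stop

    deleted: list[int] = []
    disrupted_introns: set[int] = set()
    for lesion in plan.lesions:
        idx = lesion.target_exon
        if lesion.kind == "domain_deletion":
            deleted.append(idx)
        elif lesion.kind == "splice_disruption":
            disrupted_introns.add(idx)
        else:
            if not 0 <= idx < len(exon_dna):
                raise ValueError("lesion target exon out of range")
            exon_dna[idx][1] = inject_lesion(exon_dna[idx][1], lesion, rng)
    for idx in sorted(set(deleted), reverse=True):
        if not 0 <= idx < len(exon_dna):
            raise ValueError("deletion target exon out of range")
        del exon_dna[idx]

    parts = []
    offsets = []
    pos = 0
    for i, (cls, dna) in enumerate(exon_dna):
        parts.append(dna)
        offsets.append((pos, len(dna), cls))
        pos += len(dna)
        if i < len(exon_dna) - 1:
            ilen = rng.randint(*INTRON_RANGE)
            donor = "GC" if i in disrupted_introns else "GT"
            intron = donor + T.random_dna(ilen - 4, 0.4, rng) + "AG"
            parts.append(intron)
            pos += len(intron)
    cds = "".join(dna for _, dna in exon_dna)
    return "".join(parts), offsets, cds


def _truth_for(plan: GenePlan) -> tuple[str, str, bool]:
    """(label, residual_type, functional) implied by a normalized plan."""
    deleted_classes = set()
    blocks = exon_peptides(replace(plan, lesions=[]))
    for lesion in plan.lesions:
        if lesion.kind == "domain_deletion":
            deleted_classes.add(blocks[lesion.target_exon][0])
    has_tm = plan.has_tm and "TM" not in deleted_classes
    tail = plan.tail if "TAIL" not in deleted_classes else "absent"
    act_struct = bool(has_tm and plan.tm_charged)
    inh_struct = tail == "long"
    if act_struct and inh_struct:
        residual = "AB"
    elif act_struct:
        residual = "A"
    elif inh_struct:
        residual = "B"
    else:
        residual = "neither"

    if plan.is_fragment:
        return ("fragment" if plan.has_sp else "lone_ig"), "neither", False

    untolerated = False
    for lesion in plan.lesions:
        if lesion.kind in ("frameshift_ins", "frameshift_del"):
            untolerated |= lesion.span % 3 != 0
        elif lesion.kind in ("nonsense", "splice_disruption"):
            untolerated = True
        elif lesion.kind == "compensated_double_frameshift":
            untolerated |= lesion.span > 5
    intact = (plan.has_sp and plan.ig_count >= 2 and has_tm
              and tail in ("short", "long"))
    act = act_struct
    inh = tail == "long" and (plan.itim_count or 0) >= 1
    functional = intact and not untolerated and (act or inh)

    if plan.family == "KIR":
        return "non_LILR", residual, functional
    if plan.family == "NOVEL":
        return "novel_ig_like", residual, functional
    if not functional:
        return "LILR_pseudogene", residual, False
    if act and inh:
        return "LILRAB", "AB", True
    if act:
        return "LILRA", "A", True
    return "LILRB", "B", True


# --- locus generation -------------------------------------------------------

def generate_locus(spec: LocusSpec) -> TruthSet:
    """Emit the genomic sequence and truth set for a locus specification.

    The same spec and seed always produce byte-identical output.  Genes are
    laid out left to right in plan order with random intergenic spacers; a
    contig too short for the plan raises ``ValueError``.
    """
    rng = random.Random(spec.seed)
    contig = f"{spec.species_label}_LRC"
    cursor = rng.randint(2000, 4000)
    chunks: list[tuple[int, str]] = []
    genes: list[GeneTruth] = []
    framing: list[tuple[str, int, int]] = []

    for element in spec.gene_plan:
        if isinstance(element, FramingGene):
            seq = T.random_dna(element.length, 0.5, rng)
            chunks.append((cursor, seq))
            framing.append((element.name, cursor, cursor + element.length))
            cursor += element.length
        else:
            plan = element.normalized()
            gene_dna, offsets, cds = _build_gene(plan, rng, spec.ig_divergence)
            glen = len(gene_dna)
            if plan.strand == "-":
                placed = str(Seq(gene_dna).reverse_complement())
            else:
                placed = gene_dna
            chunks.append((cursor, placed))
            coding_exons = []
            for off, length, cls in offsets:
                if plan.strand == "+":
                    s = cursor + off
                else:
                    s = cursor + glen - off - length
                coding_exons.append((s, s + length, cls))
            exons = sorted(coding_exons)
            label, residual, functional = _truth_for(plan)
            protein = str(Seq(cds[:len(cds) - len(cds) % 3]).translate())
            genes.append(GeneTruth(
                name=plan.name, strand=plan.strand, label=label,
                residual_type=residual, functional=functional,
                ig_count=plan.ig_count, family=plan.family,
                start=cursor, end=cursor + glen,
                exons=exons, coding_exons=coding_exons,
                lesions=[replace(l) for l in plan.lesions],
                cds=cds, protein=protein,
                duplicate_of=plan.duplicate_of,
            ))
            cursor += glen
        cursor += rng.randint(*INTERGENIC_RANGE)

    last_end = max((pos + len(seq) for pos, seq in chunks), default=0)
    if last_end > spec.contig_length:
        raise ValueError(
            f"contig too short: need {last_end} bp, have {spec.contig_length}")
    for (s1, q1), (s2, _q2) in zip(chunks, chunks[1:]):
        if s1 + len(q1) > s2:
            raise ValueError("overlapping gene intervals in plan")

    background = T.random_dna(spec.contig_length, spec.intergenic_gc, rng)
    seq = list(background)
    for pos, chunk in chunks:
        seq[pos:pos + len(chunk)] = chunk
    sequence = "".join(seq)

    # mark genes at the novel Ig-like locus (between GP6 and RDH13)
    bounds = {name: (s, e) for name, s, e in framing}
    if "GP6" in bounds and "RDH13" in bounds:
        lo = min(bounds["GP6"][1], bounds["RDH13"][1])
        hi = max(bounds["GP6"][0], bounds["RDH13"][0])
        for g in genes:
            g.at_novel_locus = lo <= g.start and g.end <= hi

    return TruthSet(species=spec.species_label, contig=contig,
                    length=spec.contig_length, genes=genes,
                    framing=framing, sequence=sequence)


# --- emission ---------------------------------------------------------------

def write_fasta(truth: TruthSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f">{truth.contig} {truth.species}\n")
        for i in range(0, len(truth.sequence), 60):
            fh.write(truth.sequence[i:i + 60] + "\n")


def emit_truth(truth: TruthSet, gff_path, tsv_path) -> None:
    """Write truth annotation (GFF3, 1-based inclusive) and class table."""
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        gff.write(f"##sequence-region {truth.contig} 1 {truth.length}\n")
        for g in truth.genes:
            attrs = f"ID={g.name};label={g.label};family={g.family}"
            gff.write("\t".join([
                truth.contig, "lrcpipe_sim", "gene", str(g.start + 1),
                str(g.end), ".", g.strand, ".", attrs]) + "\n")
            gff.write("\t".join([
                truth.contig, "lrcpipe_sim", "mRNA", str(g.start + 1),
                str(g.end), ".", g.strand, ".",
                f"ID={g.name}.t1;Parent={g.name}"]) + "\n")
            phase = 0
            cum = 0
            rows = []
            for s, e, cls in g.coding_exons:
                phase = (3 - cum % 3) % 3 if cum % 3 else 0
                rows.append((s, e, cls, phase))
                cum += e - s
            for s, e, cls, ph in sorted(rows):
                gff.write("\t".join([
                    truth.contig, "lrcpipe_sim", "exon", str(s + 1), str(e),
                    ".", g.strand, ".",
                    f"Parent={g.name}.t1;exon_class={cls}"]) + "\n")
                gff.write("\t".join([
                    truth.contig, "lrcpipe_sim", "CDS", str(s + 1), str(e),
                    ".", g.strand, str(ph),
                    f"Parent={g.name}.t1"]) + "\n")
    with open(tsv_path, "w") as tsv:
        tsv.write("name\tstrand\tlabel\tresidual_type\tfunctional\tig_count\t"
                  "family\tstart\tend\tn_lesions\tat_novel_locus\n")
        for g in truth.genes:
            tsv.write("\t".join(map(str, [
                g.name, g.strand, g.label, g.residual_type,
                int(g.functional), g.ig_count, g.family, g.start, g.end,
                len(g.lesions), int(g.at_novel_locus)])) + "\n")


def write_framing(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcontig\tstart\tend\tstrand\n")
        for name, s, e in truth.framing:
            fh.write(f"{name}\t{truth.contig}\t{s}\t{e}\t+\n")


# --- presets ----------------------------------------------------------------

def cat_like_locus_spec(seed: int = 0) -> LocusSpec:
    """A Felis catus style LRC: seven functional LILRs in two clusters in
    mixed orientations, a KIR pseudogene, and a functional novel Ig-like
    gene plus an Ig fragment between GP6 and RDH13."""
    plan = [
        FramingGene("TTYH1"),
        GenePlan("g_b1", strand="-", receptor_type="B", ig_count=4),
        FramingGene("RPS9"),
        GenePlan("g_b2", receptor_type="B", ig_count=4),
        GenePlan("g_a3", receptor_type="A", ig_count=4),
        GenePlan("g_a4", receptor_type="A", ig_count=2),
        GenePlan("g_b5", receptor_type="B", ig_count=4),
        FramingGene("LAIR1"),
        FramingGene("CDC42EP5"),
        GenePlan("g_b6", receptor_type="B", ig_count=2),
        GenePlan("g_a7", receptor_type="A", ig_count=6),
        GenePlan("g_kir", receptor_type="B", ig_count=2, family="KIR",
                 lesions=[LesionSpec("nonsense", target_exon=1, offset=60)]),
        FramingGene("GP6"),
        GenePlan("g_novel", receptor_type="B", ig_count=2, family="NOVEL"),
        GenePlan("g_novel_frag", receptor_type="B", ig_count=1,
                 family="NOVEL", is_fragment=True),
        FramingGene("RDH13"),
        FramingGene("FCAR"),
    ]
    return LocusSpec(species_label="synthetic_cat", contig_length=260_000,
                     gene_plan=plan, seed=seed)


def single_gene_locus(plan: GenePlan, seed: int = 0,
                      contig_length: int = 40_000) -> LocusSpec:
    """Minimal one-gene locus used for classifier grids and unit tests."""
    return LocusSpec(species_label="synthetic_single",
                     contig_length=contig_length,
                     gene_plan=[plan], seed=seed)
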