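"""Gene-model assembly: hit clustering, spliced alignment, ORF assessment.

Domain hits are chained into candidate loci by proximity, then each locus
is resolved into gene models by spliced alignment of gold-standard
reference models: every reference exon is located in the genomic window
in order, introns between mapped exons are checked for canonical GT-AG
dinucleotides, and the exon-level alignments are concatenated into a CDS.
Frameshifts (with compensation tracking), premature stops, splice-site
disruptions and missing domains are read off the exon alignments - the
functionality verdict itself lives in the classifier.

Exons are located by fast infix edit-distance search (edlib) and then
realigned with an affine-gap nucleotide aligner that prefers
substitutions over spurious indel pairs, so indel events in the final
alignment reflect real insertions and deletions.  All genomic
coordinates are 0-based half-open on the forward strand; gene models on
the minus strand are aligned in coding orientation and reported with
forward-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
from Bio import Align
from Bio.Seq import Seq

from . import templates as T
from .scan import DomainHit, detect_signal_peptide, kyte_doolittle_tm
from .synth import GenePlan, exon_peptides

DEFAULT_MAX_GAP = 15_000       # bp between member hits of one locus
MAX_INTRON_SEARCH = 5_000      # bp of intron allowed between adjacent exons
WINDOW_FLANK = 2_000           # bp of flank added around a candidate locus
EXON_ACCEPT_FRAC = 0.30        # max normalized edit distance for a mapped exon
SHORT_EXON_ACCEPT_FRAC = 0.25  # stricter for short exons (SP, TM, tails)
SHORT_EXON_LEN = 120
ANCHOR_PAD = 60                # bp of slack around a seed hit when anchoring


@dataclass
class ReferenceModel:
    """A gold-standard CDS with its exon structure."""

    name: str
    family: str                  # LILR | KIR | NOVEL
    cds: str
    exons: list                  # [(offset, length, exon_class)] in CDS order
    ig_count: int
    tail_kind: str               # short | long

    def __post_init__(self):
        total = sum(l for _, l, _ in self.exons)
        if total != len(self.cds):
            raise ValueError("exon offsets do not partition the CDS")


def _reference_from_plan(name: str, plan: GenePlan) -> ReferenceModel:
    plan = plan.normalized()
    blocks = exon_peptides(plan)
    exons = []
    parts = []
    off = 0
    for i, (cls, aa) in enumerate(blocks):
        dna = T.backtranslate(aa)
        if i == len(blocks) - 1:
            dna += "TAA"
        parts.append(dna)
        exons.append((off, len(dna), cls))
        off += len(dna)
    return ReferenceModel(name=name, family=plan.family, cds="".join(parts),
                          exons=exons, ig_count=plan.ig_count,
                          tail_kind=plan.tail)


def reference_models() -> dict[str, ReferenceModel]:
    """The packaged gold-standard set: LILR archetypes over Ig counts and
    tail kinds, plus KIR and novel-Ig-like references.

    References use the inhibitory TM segment; the single-codon difference
    of the activating variant is absorbed by the alignment, and the
    arginine call is made from the gene's own translation.
    """
    refs = {}
    for ig in (2, 3, 4, 6):
        for tail, code in (("long", "L"), ("short", "S")):
            name = f"LILR_ref_{ig}Ig_{code}"
            refs[name] = _reference_from_plan(
                name, GenePlan(name, receptor_type="B", ig_count=ig,
                               tm_charged=False, tail=tail,
                               itim_count=2 if tail == "long" else 0))
    refs["KIR_ref"] = _reference_from_plan(
        "KIR_ref", GenePlan("KIR_ref", receptor_type="B", ig_count=2,
                            family="KIR"))
    refs["NOVEL_ref"] = _reference_from_plan(
        "NOVEL_ref", GenePlan("NOVEL_ref", receptor_type="B", ig_count=2,
                              family="NOVEL"))
    return refs


def write_references(refs: dict[str, ReferenceModel], fasta_path,
                     exon_table_path) -> None:
    with open(fasta_path, "w") as fa:
        for ref in refs.values():
            fa.write(f">{ref.name} family={ref.family}\n")
            for i in range(0, len(ref.cds), 60):
                fa.write(ref.cds[i:i + 60] + "\n")
    with open(exon_table_path, "w") as tsv:
        tsv.write("reference\tfamily\tig_count\ttail_kind\toffset\tlength\t"
                  "exon_class\n")
        for ref in refs.values():
            for off, length, cls in ref.exons:
                tsv.write(f"{ref.name}\t{ref.family}\t{ref.ig_count}\t"
                          f"{ref.tail_kind}\t{off}\t{length}\t{cls}\n")


def read_references(fasta_path, exon_table_path) -> dict[str, ReferenceModel]:
    seqs: dict[str, str] = {}
    meta: dict[str, dict] = {}
    with open(fasta_path) as fa:
        name = None
        for line in fa:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line
    exons: dict[str, list] = {}
    with open(exon_table_path) as tsv:
        next(tsv)
        for line in tsv:
            ref, family, ig, tail, off, length, cls = \
                line.rstrip("\n").split("\t")
            exons.setdefault(ref, []).append((int(off), int(length), cls))
            meta[ref] = {"family": family, "ig_count": int(ig),
                         "tail_kind": tail}
    return {name: ReferenceModel(name=name, family=meta[name]["family"],
                                 cds=seqs[name], exons=exons[name],
                                 ig_count=meta[name]["ig_count"],
                                 tail_kind=meta[name]["tail_kind"])
            for name in seqs}


# --- candidate loci ---------------------------------------------------------

@dataclass
class FramingContext:
    upstream: Optional[tuple[str, int]] = None    # (name, distance bp)
    downstream: Optional[tuple[str, int]] = None

    def between(self, a: str, b: str) -> bool:
        names = {self.upstream[0] if self.upstream else None,
                 self.downstream[0] if self.downstream else None}
        return a in names and b in names


@dataclass
class CandidateLocus:
    contig: str
    strand: str
    start: int
    end: int
    member_hits: list
    context: Optional[FramingContext] = None


def framing_context(contig: str, start: int, end: int,
                    framing: Sequence[tuple]) -> FramingContext:
    """Nearest framing gene up- and downstream of a genomic interval.

    ``framing`` rows are (name, contig, start, end) tuples.
    """
    up = down = None
    for row in framing:
        name, fcontig, fs, fe = row[0], row[1], int(row[2]), int(row[3])
        if fcontig != contig:
            continue
        if fe <= start:
            d = start - fe
            if up is None or d < up[1]:
                up = (name, d)
        elif fs >= end:
            d = fs - end
            if down is None or d < down[1]:
                down = (name, d)
    return FramingContext(upstream=up, downstream=down)


def cluster_hits(hits: Sequence[DomainHit], max_gap: int = DEFAULT_MAX_GAP,
                 framing: Sequence[tuple] = ()) -> list[CandidateLocus]:
    """Chain same-contig, same-strand hits within ``max_gap`` of each other
    into candidate loci; isolated Ig hits become singleton loci (candidate
    lone Ig domains)."""
    loci: list[CandidateLocus] = []
    groups: dict[tuple, list] = {}
    for h in hits:
        groups.setdefault((h.contig, h.strand), []).append(h)
    for (contig, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: h.start)
        chain = [members[0]]
        for h in members[1:]:
            if h.start - chain[-1].end <= max_gap:
                chain.append(h)
            else:
                loci.append(CandidateLocus(contig, strand, chain[0].start,
                                           chain[-1].end, chain))
                chain = [h]
        loci.append(CandidateLocus(contig, strand, chain[0].start,
                                   chain[-1].end, chain))
    for locus in loci:
        locus.context = framing_context(locus.contig, locus.start, locus.end,
                                        framing)
    loci.sort(key=lambda l: (l.contig, l.start))
    return loci


# --- spliced alignment ------------------------------------------------------

@dataclass
class ExonAlignment:
    exon_class: str
    ref_index: int               # ordinal in the reference exon list
    ref_length: int
    w_start: int                 # coding-oriented window coordinates
    w_end: int
    events: list                 # [(offset_in_exon, indel_delta_bp)]
    edit_distance: int


@dataclass
class Lesion:
    kind: str                    # frameshift | premature_stop |
    #                              splice_disruption | missing_domain
    position: int = 0            # CDS bp (frameshift), codon index (stop),
    #                              intron index, or exon ordinal
    restored_within_codons: Optional[int] = None
    domain_class: Optional[str] = None
    exon_index: Optional[int] = None

    def sort_key(self):
        return (self.position, self.kind)


@dataclass
class GeneModel:
    contig: str
    strand: str
    reference: ReferenceModel
    exons: list                  # [(g_start, g_end, exon_class)] forward
    exon_alignments: list        # ExonAlignment, coding order
    splice_sites: list           # [(donor, acceptor)] per intron
    cds: str
    protein: str
    features: dict = field(default_factory=dict)
    lesions: list = field(default_factory=list)
    w_span: tuple = (0, 0)       # coding-window span, used by the builder

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.exons)

    @property
    def total_edit_distance(self) -> int:
        return sum(a.edit_distance for a in self.exon_alignments)


def _nt_realigner() -> Align.PairwiseAligner:
    # Infix alignment of a full reference exon inside a genomic segment:
    # target end gaps free, substitutions cheaper than an indel pair so
    # divergence does not masquerade as compensated frameshifts.
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.match_score = 1
    aln.mismatch_score = -2
    # an indel must cost clearly more than the mismatches it could absorb
    # (otherwise divergent exons acquire phantom compensated frameshifts),
    # but cheap enough that two nearby compensating deletions are not
    # merged into one in-frame gap
    aln.open_gap_score = -7
    aln.extend_gap_score = -2
    # unmatched genomic bases flanking the exon are free
    aln.open_left_deletion_score = 0
    aln.extend_left_deletion_score = 0
    aln.open_right_deletion_score = 0
    aln.extend_right_deletion_score = 0
    return aln


_NT_ALIGNER = _nt_realigner()


def _find_exon(exon_seq: str, window: str, lo: int, hi: int
               ) -> Optional[tuple[int, int, list, int]]:
    """Locate and realign one reference exon inside window[lo:hi].

    Returns (w_start, w_end, indel_events, edit_distance) or None when the
    best placement exceeds the acceptance threshold.  Events are
    (offset, delta) pairs with offset relative to the mapped exon start
    and delta the signed indel length (positive = genomic insertion).
    """
    lo = max(0, lo)
    hi = min(len(window), hi)
    if hi - lo < len(exon_seq) // 2:
        return None
    frac = (SHORT_EXON_ACCEPT_FRAC if len(exon_seq) <= SHORT_EXON_LEN
            else EXON_ACCEPT_FRAC)
    limit = max(2, int(frac * len(exon_seq)))
    # leftmost acceptable placement: edlib reports the best-scoring
    # location, so shrink the search range until no earlier placement
    # passes the threshold (paralogous exons downstream must not shadow
    # the next exon in gene order).
    best = None
    search_hi = hi
    while True:
        res = edlib.align(exon_seq, window[lo:search_hi], mode="HW",
                          task="locations", k=limit)
        if res["editDistance"] < 0:
            break
        s, e = res["locations"][0]
        best = (s, e)
        search_hi = lo + s + len(exon_seq) // 2
        if search_hi - lo < len(exon_seq) - limit:
            break
    if best is None:
        return None
    s, e = best
    seg_lo = max(lo, lo + s - 6)
    seg_hi = min(hi, lo + e + 1 + 6)
    segment = window[seg_lo:seg_hi]
    a = _NT_ALIGNER.align(segment, exon_seq)[0]
    tspans, qspans = a.aligned
    w_start = seg_lo + int(tspans[0][0])
    w_end = seg_lo + int(tspans[-1][1])
    events = []
    mismatches = 0
    indel_bp = 0
    if int(qspans[0][0]) > 0:  # exon start missing from the genome
        events.append((0, -int(qspans[0][0])))
        indel_bp += int(qspans[0][0])
    for k, ((t0, t1), (q0, q1)) in enumerate(zip(tspans, qspans)):
        mismatches += sum(x != y for x, y in zip(segment[t0:t1],
                                                 exon_seq[q0:q1]))
        if k + 1 < len(tspans):
            dt = int(tspans[k + 1][0]) - int(t1)
            dq = int(qspans[k + 1][0]) - int(q1)
            pos = int(t1) + seg_lo - w_start
            if dt:
                events.append((pos, dt))
                indel_bp += dt
            if dq:
                events.append((pos, -dq))
                indel_bp += dq
    if int(qspans[-1][1]) < len(exon_seq):  # exon end missing
        tail = len(exon_seq) - int(qspans[-1][1])
        events.append((w_end - w_start, -tail))
        indel_bp += tail
    nm = mismatches + indel_bp
    if nm > limit:
        return None
    return w_start, w_end, events, nm


def spliced_align(reference: ReferenceModel, window: str,
                  window_offset: int, strand: str, contig: str,
                  anchor_lo: int = 0, anchor_hi: Optional[int] = None,
                  floor: int = 0,
                  max_intron: int = MAX_INTRON_SEARCH) -> Optional[GeneModel]:
    """Map every reference exon, in order, inside a genomic window.

    ``window`` is the forward-strand sequence of the candidate region;
    minus-strand models are aligned against its reverse complement and
    reported with forward-strand coordinates.  The first Ig exon of the
    reference anchors the model inside [anchor_lo, anchor_hi) (coding
    orientation); preceding exons are searched upstream of the anchor
    (not below ``floor``) and following exons downstream, each within an
    intron-sized range.  Unmapped reference exons become missing_domain
    lesions.  Returns None when the anchor cannot be placed (the locus
    stays a fragment candidate)."""
    work = window if strand == "+" else str(Seq(window).reverse_complement())
    n = len(work)
    if anchor_hi is None:
        anchor_hi = n

    ig_indices = [i for i, (_, _, cls) in enumerate(reference.exons)
                  if cls == "IG"]
    anchor_idx = ig_indices[0] if ig_indices else 0
    off, length, cls = reference.exons[anchor_idx]
    anchor_seq = reference.cds[off:off + length]
    anchor = _find_exon(anchor_seq, work, anchor_lo, anchor_hi)
    if anchor is None:
        return None

    placed: dict[int, ExonAlignment] = {
        anchor_idx: ExonAlignment(cls, anchor_idx, length, anchor[0],
                                  anchor[1], anchor[2], anchor[3])}
    cursor = anchor[0]
    for i in range(anchor_idx - 1, -1, -1):
        off, length, cls = reference.exons[i]
        seq = reference.cds[off:off + length]
        hit = _find_exon(seq, work,
                         max(floor, cursor - max_intron - length - 50),
                         cursor)
        if hit is None:
            continue
        placed[i] = ExonAlignment(cls, i, length, hit[0], hit[1], hit[2],
                                  hit[3])
        cursor = hit[0]
    cursor = anchor[1]
    for i in range(anchor_idx + 1, len(reference.exons)):
        off, length, cls = reference.exons[i]
        seq = reference.cds[off:off + length]
        hit = _find_exon(seq, work, cursor, cursor + max_intron + length + 50)
        if hit is None:
            continue
        placed[i] = ExonAlignment(cls, i, length, hit[0], hit[1], hit[2],
                                  hit[3])
        cursor = hit[1]

    order = sorted(placed)
    alignments = [placed[i] for i in order]
    splice_sites = []
    for a, b in zip(alignments, alignments[1:]):
        donor = work[a.w_end:a.w_end + 2]
        acceptor = work[b.w_start - 2:b.w_start]
        splice_sites.append((donor, acceptor))

    cds = "".join(work[a.w_start:a.w_end] for a in alignments)
    protein = str(Seq(cds[:len(cds) - len(cds) % 3]).translate())

    def to_forward(ws, we):
        if strand == "+":
            return window_offset + ws, window_offset + we
        return window_offset + n - we, window_offset + n - ws

    exons = []
    for a in alignments:
        gs, ge = to_forward(a.w_start, a.w_end)
        exons.append((gs, ge, a.exon_class))
    exons.sort()

    model = GeneModel(contig=contig, strand=strand, reference=reference,
                      exons=exons, exon_alignments=alignments,
                      splice_sites=splice_sites, cds=cds, protein=protein,
                      w_span=(alignments[0].w_start, alignments[-1].w_end))
    model.lesions = assess_orf(model, reference)
    model.features = annotate_features(model)
    return model


def assess_orf(model: GeneModel, reference: ReferenceModel) -> list[Lesion]:
    """Exhaustive, position-ordered lesion list for a gene model.

    Frameshifts are indel runs (relative to the reference exons) whose
    summed length is not a multiple of three; a later compensating indel
    that restores the frame within k codons is recorded as
    ``restored_within_codons = k``.  In-frame premature stops, non-GT-AG
    introns and unmapped reference exons complete the list.  Stops inside
    frame-shifted stretches are not double-reported: the frameshift is
    the lesion.
    """
    lesions: list[Lesion] = []
    mapped = {a.ref_index for a in model.exon_alignments}
    for i, (_, _, cls) in enumerate(reference.exons):
        if i not in mapped:
            lesions.append(Lesion("missing_domain", position=i,
                                  domain_class=cls, exon_index=i))

    events = []  # (cds_pos, delta, ref_exon_index)
    cds_pos = 0
    for a in model.exon_alignments:
        for pos, delta in a.events:
            events.append((cds_pos + pos, delta, a.ref_index))
        cds_pos += a.w_end - a.w_start

    shift = 0
    open_lesion = None
    for pos, delta, ref_index in events:
        prev = shift
        shift = (shift + delta) % 3
        if prev == 0 and shift != 0:
            open_lesion = Lesion("frameshift", position=pos,
                                 exon_index=ref_index)
            lesions.append(open_lesion)
        elif prev != 0 and shift == 0 and open_lesion is not None:
            span_bp = pos - open_lesion.position
            open_lesion.restored_within_codons = max(1, -(-span_bp // 3))
            open_lesion = None

    # premature stops, assessed in each exon's own reading frame
    # (reference exons are phase 0, so a frameshift confined to one exon
    # cannot hide a nonsense mutation in another)
    from Bio.Seq import Seq

    cds_pos = 0
    terminal_codon_start = len(model.cds) - 3
    for a in model.exon_alignments:
        seg = model.cds[cds_pos:cds_pos + (a.w_end - a.w_start)]
        shift = 0
        ei = 0
        local_events = sorted(a.events)
        for p in range(0, len(seg) - 2, 3):
            while ei < len(local_events) and local_events[ei][0] <= p:
                shift = (shift + local_events[ei][1]) % 3
                ei += 1
            if shift != 0:
                continue
            codon = seg[p:p + 3]
            if codon in ("TAA", "TAG", "TGA") \
                    and cds_pos + p < terminal_codon_start:
                lesions.append(Lesion("premature_stop",
                                      position=(cds_pos + p) // 3,
                                      exon_index=a.ref_index))
        cds_pos += a.w_end - a.w_start

    for i, (donor, acceptor) in enumerate(model.splice_sites):
        if donor != "GT" or acceptor != "AG":
            left = model.exon_alignments[i].ref_index
            lesions.append(Lesion("splice_disruption", position=i,
                                  exon_index=left))
    lesions.sort(key=Lesion.sort_key)
    return lesions


def annotate_features(model: GeneModel) -> dict:
    """Per-exon receptor features, robust to lesions elsewhere in the gene.

    Each mapped exon is translated in its own frame (reference exons are
    phase 0), so a frameshift in one exon does not erase the evidence
    carried by the others - mirroring domain-by-domain assessment.
    """
    feats = {"sp_present": False, "ig_count": 0, "tm_present": False,
             "tm_has_arginine": False, "tm_charged_residues": [],
             "tail_kind": "absent", "itim_positions": [], "tail_seq": ""}
    pos = 0
    for a in model.exon_alignments:
        seg = model.cds[pos:pos + (a.w_end - a.w_start)]
        pos += a.w_end - a.w_start
        aa = str(Seq(seg[:len(seg) - len(seg) % 3]).translate())
        if a.exon_class == "SP":
            probe = (aa + "DDDDDD")[:30]
            try:
                flag, _ = detect_signal_peptide(probe)
            except ValueError:
                flag = False
            feats["sp_present"] = feats["sp_present"] or flag
        elif a.exon_class == "IG":
            feats["ig_count"] += 1
        elif a.exon_class == "TM":
            calls = kyte_doolittle_tm(aa) if len(aa) >= 19 else []
            if calls:
                feats["tm_present"] = True
                charged = [c for call in calls for c in call.charged_residues]
                feats["tm_charged_residues"] = charged
                feats["tm_has_arginine"] = any(r == "R" for _, r in charged)
        elif a.exon_class == "TAIL":
            tail_aa = aa.rstrip("*")
            feats["tail_seq"] = tail_aa
            feats["tail_kind"] = "long" if len(tail_aa) >= 30 else "short"
    return feats


def extract_cds(model: GeneModel, record_id: str = "gene"):
    """Spliced CDS of a model as a SeqRecord (minus-strand models are
    already in coding orientation)."""
    from Bio.SeqRecord import SeqRecord

    if not model.exons:
        raise ValueError("model has no exons")
    return SeqRecord(Seq(model.cds), id=record_id, description="")


# --- locus resolution -------------------------------------------------------

def _coding_span(g0: int, g1: int, strand: str, w_off: int,
                 w_len: int) -> tuple[int, int]:
    if strand == "+":
        return g0 - w_off, g1 - w_off
    return w_off + w_len - g1, w_off + w_len - g0


def build_gene_models(locus: CandidateLocus, genome: dict[str, str],
                      references: dict[str, ReferenceModel],
                      flank: int = WINDOW_FLANK) -> list[GeneModel]:
    """Resolve a candidate locus into gene models, one per receptor gene.

    Each Ig-domain hit of the locus seeds one anchoring attempt in coding
    order; every reference is spliced-aligned at that anchor and the
    best-fitting model (most exons mapped, then lowest divergence, then
    reference name) is kept.  Hits consumed by an emitted model do not
    seed again, so multi-gene clusters resolve into one model per gene.
    """
    seq = genome[locus.contig]
    w_start = max(0, locus.start - flank)
    w_end = min(len(seq), locus.end + flank)
    window = seq[w_start:w_end]
    w_len = len(window)

    seeds = []
    for h in locus.member_hits:
        if h.domain_class != "IG":
            continue
        lo, hi = _coding_span(h.start, h.end, locus.strand, w_start, w_len)
        seeds.append((lo, hi))
    seeds.sort()

    models: list[GeneModel] = []
    consumed = 0
    for lo, hi in seeds:
        if lo < consumed:
            continue
        candidates = []
        for name in sorted(references):
            model = spliced_align(references[name], window, w_start,
                                  locus.strand, locus.contig,
                                  anchor_lo=max(consumed, lo - ANCHOR_PAD),
                                  anchor_hi=hi + ANCHOR_PAD,
                                  floor=consumed)
            if model is not None:
                candidates.append(model)
        if not candidates:
            continue
        best = min(candidates,
                   key=lambda m: (-len(m.exon_alignments),
                                  m.total_edit_distance, m.reference.name))
        models.append(best)
        consumed = best.w_span[1]
    return models
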