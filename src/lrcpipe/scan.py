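"""Protein-domain evidence on genomic DNA.

Re-creates the translated-search stage of an immunoreceptor annotation:
each protein query (Ig domain consensus, cytoplasmic tail) is aligned
against all six reading frames of every contig with an exhaustive
Smith-Waterman (BLOSUM62, affine gaps), which is exact at desk scale and
needs no external search binary.  Signal peptides and transmembrane
segments are called with documented sequence heuristics (an n/h/c-region
rule and Kyte-Doolittle hydropathy) in place of neural predictors.

Alignments that span a stop codon are kept but flagged: pseudogene exons
must still be located, lesion classification happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .templates import KD, CHARGED, IG_AA, long_tail_aa

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class ProteinQuery:
    id: str
    domain_class: str  # IG | TAIL_LONG | TAIL_SHORT | SP_REF
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty query sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"non-amino-acid symbols in query: {bad}")


@dataclass
class DomainHit:
    """One translated local-alignment match on a contig.

    ``start``/``end`` are forward-strand genomic coordinates (0-based,
    half-open) of the codon span covered by the aligned subject segment.
    """

    query_id: str
    domain_class: str
    contig: str
    strand: str
    frame: int
    start: int
    end: int
    score: float
    pct_identity: float
    subject_aa: str
    has_internal_stop: bool


@dataclass
class TmCall:
    protein_start: int
    protein_end: int
    mean_hydropathy: float
    charged_residues: list = field(default_factory=list)


@dataclass
class ScanParams:
    """Reporting thresholds for the translated scan.

    A hit must reach ``min_score_frac`` of the query self-score, at least
    ``min_identity`` percent identity, and cover ``min_query_frac`` of the
    query length.  The score fraction is set low enough that Ig domains of
    related receptor families (KIR, the novel Ig-like gene) are still
    recovered by a LILR query, while remaining far above the score
    attainable against random sequence.
    """

    min_score_frac: float = 0.35
    min_identity: float = 35.0
    min_query_frac: float = 0.5
    gap_open: int = 11
    gap_extend: int = 1
    max_hits_per_frame: int = 60


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner(params: ScanParams) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = _BLOSUM62
    # gap of length k costs open + k * extend (BLAST protein convention)
    aln.open_gap_score = -(params.gap_open + params.gap_extend)
    aln.extend_gap_score = -params.gap_extend
    return aln


@dataclass
class LocalAlignment:
    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def n_identical(self) -> int:
        return sum(a == b for a, b in zip(self.aligned_query,
                                          self.aligned_subject))


def smith_waterman(query: str, subject: str,
                   gap_open: int = 11, gap_extend: int = 1,
                   matrix=None) -> LocalAlignment:
    """Optimal local alignment under affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend``.  When no
    positive-scoring alignment exists the empty alignment (score 0) is
    returned.  Ties between co-optimal alignments are broken
    deterministically by taking the engine's first-reported traceback.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    score = aln.score(query, subject)
    if score <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, "", "")
    a = aln.align(query, subject)[0]
    (qspans, sspans) = a.aligned
    qs, qe = int(qspans[0][0]), int(qspans[-1][1])
    ss, se = int(sspans[0][0]), int(sspans[-1][1])
    lines = str(a).splitlines()
    # reconstruct aligned strings from the aligned coordinate blocks
    aq, asub = [], []
    prev_q, prev_s = qs, ss
    for (q0, q1), (s0, s1) in zip(qspans, sspans):
        if q0 > prev_q:
            aq.append(query[prev_q:q0])
            asub.append("-" * (q0 - prev_q))
        if s0 > prev_s:
            aq.append("-" * (s0 - prev_s))
            asub.append(subject[prev_s:s0])
        aq.append(query[q0:q1])
        asub.append(subject[s0:s1])
        prev_q, prev_s = q1, s1
    return LocalAlignment(float(score), qs, qe, ss, se,
                          "".join(aq), "".join(asub))


def sixframe_translate(dna: str) -> list[dict]:
    """All six reading frames with genomic coordinate maps.

    Returns one record per frame: ``strand`` (+/-), ``frame`` (0-2),
    ``protein``, and ``to_genomic(i, j)`` mapping a protein slice to the
    forward-strand codon span (0-based half-open).  Codons containing
    ambiguity translate to X; stops render as ``*``.
    """
    if not dna:
        raise ValueError("empty input sequence")
    dna = dna.upper()
    length = len(dna)
    rc = str(Seq(dna).reverse_complement())
    frames = []
    for strand, seq in (("+", dna), ("-", rc)):
        for f in range(3):
            sub = seq[f:f + 3 * ((length - f) // 3)]
            protein = str(Seq(sub).translate())
            if strand == "+":
                def to_genomic(i, j, f=f):
                    return (f + 3 * i, f + 3 * j)
            else:
                def to_genomic(i, j, f=f, L=length):
                    return (L - f - 3 * j, L - f - 3 * i)
            frames.append({"strand": strand, "frame": f,
                           "protein": protein, "to_genomic": to_genomic})
    return frames


def query_self_score(query: ProteinQuery, matrix=None) -> float:
    m = matrix if matrix is not None else _BLOSUM62
    return float(sum(m[ch, ch] for ch in query.sequence))


def scan_domains(genome: Iterable[tuple[str, str]],
                 queries: Sequence[ProteinQuery],
                 params: Optional[ScanParams] = None) -> list[DomainHit]:
    """Translated scan of every query against all six frames of each contig.

    Hits passing the thresholds are reported on both strands with
    forward-strand coordinates; overlapping hits of the same query are
    merged to the best-scoring one.  Repeated matches within one frame are
    found by iterative masking of already-reported subject segments.
    """
    queries = list(queries)
    if not queries:
        raise ValueError("no queries supplied")
    params = params or ScanParams()
    aligner = _aligner(params)
    hits: list[DomainHit] = []
    for contig, seq in genome:
        frames = sixframe_translate(seq)
        for query in queries:
            self_score = query_self_score(query)
            threshold = params.min_score_frac * self_score
            for fr in frames:
                subject = fr["protein"]
                masked = list(subject)
                for _ in range(params.max_hits_per_frame):
                    res = smith_waterman(query.sequence, "".join(masked),
                                         params.gap_open, params.gap_extend)
                    if res.score < threshold or res.n_columns == 0:
                        break
                    for k in range(res.subject_start, res.subject_end):
                        masked[k] = "X"
                    identity = 100.0 * res.n_identical / res.n_columns
                    coverage = (res.query_end - res.query_start) / len(
                        query.sequence)
                    if identity < params.min_identity:
                        continue
                    if coverage < params.min_query_frac:
                        continue
                    g0, g1 = fr["to_genomic"](res.subject_start,
                                              res.subject_end)
                    segment = subject[res.subject_start:res.subject_end]
                    hits.append(DomainHit(
                        query_id=query.id, domain_class=query.domain_class,
                        contig=contig, strand=fr["strand"],
                        frame=fr["frame"], start=g0, end=g1,
                        score=res.score, pct_identity=round(identity, 2),
                        subject_aa=segment,
                        has_internal_stop="*" in segment))
    return merge_overlapping(hits)


def merge_overlapping(hits: list[DomainHit]) -> list[DomainHit]:
    """Keep only the best-scoring hit among genomically overlapping hits
    of the same query on the same contig and strand."""
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.contig, h.start)):
        clash = any(
            k.query_id == hit.query_id and k.contig == hit.contig
            and k.strand == hit.strand
            and k.start < hit.end and hit.start < k.end
            for k in kept)
        if not clash:
            kept.append(hit)
    kept.sort(key=lambda h: (h.contig, h.start))
    return kept


def kyte_doolittle_tm(protein: str, window: int = 19,
                      threshold: float = 1.6) -> list[TmCall]:
    """Transmembrane segments as maximal runs of 19-residue windows whose
    mean Kyte-Doolittle hydropathy reaches the threshold.

    Charged residues (R, K, D, E, H) inside each span are listed - the
    arginine typical of activating-receptor TM regions is read from here.
    Proteins shorter than the window yield no calls.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = len(protein)
    if n < window:
        return []
    vals = [KD.get(ch, 0.0) for ch in protein]
    half = window // 2
    means = []
    for c in range(half, n - half):
        means.append(sum(vals[c - half:c + half + 1]) / window)
    calls: list[TmCall] = []
    run_start = None
    for i, m in enumerate(means + [-99.0]):
        if m >= threshold and run_start is None:
            run_start = i
        elif m < threshold and run_start is not None:
            c0, c1 = run_start + half, i - 1 + half
            s, e = c0 - half, c1 + half + 1
            peak = max(means[run_start:i])
            charged = [(p, protein[p]) for p in range(s, e)
                       if protein[p] in CHARGED]
            calls.append(TmCall(s, e, round(peak, 3), charged))
            run_start = None
    return calls


SMALL_C_RESIDUES = set("AGSC")


def detect_signal_peptide(protein_n_terminus: str
                          ) -> tuple[bool, Optional[int]]:
    """n/h/c-region signal-peptide heuristic.

    True when a hydrophobic h-region of >= 7 residues with mean
    hydropathy >= 2.0 starts within the first 5 residues and lies inside
    the first 25, followed within 6 positions by a small residue
    (A/G/S/C) marking the -1 position of the cleavage site.
    """
    seq = protein_n_terminus
    if len(seq) < 15:
        raise ValueError("supply at least 15 N-terminal residues")
    vals = [KD.get(ch, 0.0) for ch in seq]
    for s in range(0, 6):
        for e in range(s + 7, min(25, len(seq)) + 1):
            if sum(vals[s:e]) / (e - s) < 2.0:
                continue
            for p in range(e, min(e + 6, len(seq))):
                if seq[p] in SMALL_C_RESIDUES:
                    return True, p
    return False, None


def default_queries() -> list[ProteinQuery]:
    """The standard query set: the Ig-domain consensus and the long
    ITIM-bearing cytoplasmic tail of the exemplar inhibitory receptor."""
    return [
        ProteinQuery("IG_consensus", "IG", IG_AA),
        ProteinQuery("LILRB_long_tail", "TAIL_LONG", long_tail_aa(2)),
    ]


HITS_COLUMNS = ["qid", "domain_class", "contig", "pident", "length",
                "qstart", "qend", "sstart", "send", "frame", "strand",
                "score", "stop_flag", "subject_aa"]


def write_hits(hits: list[DomainHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.domain_class, h.contig, h.pct_identity,
                len(h.subject_aa), 0, len(h.subject_aa), h.start, h.end,
                h.frame, h.strand, h.score, int(h.has_internal_stop),
                h.subject_aa])) + "\n")


def read_hits(path) -> list[DomainHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(DomainHit(
                query_id=f[idx["qid"]], domain_class=f[idx["domain_class"]],
                contig=f[idx["contig"]], strand=f[idx["strand"]],
                frame=int(f[idx["frame"]]), start=int(f[idx["sstart"]]),
                end=int(f[idx["send"]]), score=float(f[idx["score"]]),
                pct_identity=float(f[idx["pident"]]),
                subject_aa=f[idx["subject_aa"]],
                has_internal_stop=bool(int(f[idx["stop_flag"]]))))
    return hits
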