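"""End-to-end orchestration of the annotation stages.

Chains simulation (optional) -> translated domain scan -> gene-model
building -> classification -> per-species summary -> phylogenetics,
writing every artifact plus a manifest (inputs, seed, thresholds,
checksums).  Each stage is also callable on its own with file-based
inputs and outputs, which is what the command-line interface wraps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from . import classify as C
from . import models as M
from . import phylo as P
from . import scan as S
from . import summary as SU
from . import synth


@dataclass
class PipelineConfig:
    out_dir: str
    species: str = "synthetic_cat"
    preset: str = "cat_like"          # locus preset for the sim stage
    seed: int = 0
    genome: Optional[str] = None      # skip sim when given
    queries: Optional[str] = None     # FASTA; packaged defaults when None
    framing: Optional[str] = None     # TSV name/contig/start/end/strand
    min_score_frac: float = 0.35
    min_identity: float = 35.0
    max_gap: int = M.DEFAULT_MAX_GAP
    tail_long_min: int = 30
    tolerated_frameshift_codons: int = 5
    lenient_tail: bool = False
    lysine_charged: bool = False
    phylo_model: str = "tamura3"
    bootstrap: int = 100
    run_phylo: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in data:
            raise ValueError("config must set out_dir")
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.min_score_frac <= 1:
            raise ValueError("min_score_frac must be in (0, 1]")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be a percentage")
        if self.genome is not None and not Path(self.genome).exists():
            raise ValueError(f"genome not found: {self.genome}")
        if self.queries is not None and not Path(self.queries).exists():
            raise ValueError(f"queries not found: {self.queries}")


def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_queries(path) -> list[S.ProteinQuery]:
    queries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cls = "IG"
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
        queries.append(S.ProteinQuery(rec.id, cls, str(rec.seq)))
    return queries


def read_framing(path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            name, contig, start, end, *_ = line.rstrip("\n").split("\t")
            rows.append((name, contig, int(start), int(end)))
    return rows


def classify_models(gene_models: list[M.GeneModel], framing: list[tuple],
                    config: Optional[C.ClassifyConfig] = None,
                    species: str = "") -> list[C.Classification]:
    """Classify and name every gene model of one species."""
    config = config or C.ClassifyConfig()
    calls = []
    for i, model in enumerate(sorted(gene_models,
                                     key=lambda m: (m.contig, m.start))):
        ctx = M.framing_context(model.contig, model.start, model.end, framing)
        call = C.classify_gene(model, ctx, config, gene_id=f"locus_{i + 1}")
        call.species = species
        calls.append(call)
    return C.assign_names(calls)


def exon_anchored_msa(gene_models: list[tuple[str, M.GeneModel]],
                      alphabet: str = "nucleotide") -> P.Msa:
    """Block alignment of receptor CDS by shared exon architecture.

    Stands in for a multiple-alignment program on synthetic loci: every
    exon class occupies a fixed alignment block (Ig slots one to six, TM,
    tail), padded with gaps where a gene lacks the block or where a
    lesion shortens it.  Adequate for distance-based trees of templated
    synthetic genes; real data should be aligned with a proper MSA tool.
    """
    slots = [("SP", 45)] + [("IG", 294)] * 6 + [("TM", 69), ("TAIL", 171)]
    rows = []
    labels = []
    for label, model in gene_models:
        per_class: dict[str, list[str]] = {}
        pos = 0
        for a in model.exon_alignments:
            seg = model.cds[pos:pos + (a.w_end - a.w_start)]
            pos += a.w_end - a.w_start
            per_class.setdefault(a.exon_class, []).append(seg)
        parts = []
        ig_used = 0
        for cls, width in slots:
            if cls == "IG":
                segs = per_class.get("IG", [])
                seg = segs[ig_used] if ig_used < len(segs) else ""
                ig_used += 1
            else:
                segs = per_class.get(cls, [])
                seg = segs[0] if segs else ""
            seg = seg[:width]
            parts.append(seg + "-" * (width - len(seg)))
        labels.append(label)
        rows.append("".join(parts))
    return P.Msa(labels, rows, alphabet)


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    calls: list
    species_summary: SU.SpeciesSummary
    artifacts: dict = field(default_factory=dict)
    tree_newick: Optional[str] = None
    counts: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write artifacts plus a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def emit(name, path):
        artifacts[name] = str(path)

    # --- simulation (or user genome) ---
    framing: list[tuple]
    if config.genome is None:
        if config.preset != "cat_like":
            raise ValueError(f"unknown locus preset: {config.preset}")
        spec = synth.cat_like_locus_spec(seed=config.seed)
        spec.species_label = config.species
        truth = synth.generate_locus(spec)
        genome_path = out / "genome.fa"
        synth.write_fasta(truth, genome_path)
        synth.emit_truth(truth, out / "truth.gff3", out / "truth.tsv")
        synth.write_framing(truth, out / "framing.tsv")
        emit("genome", genome_path)
        emit("truth_gff3", out / "truth.gff3")
        emit("truth_tsv", out / "truth.tsv")
        emit("framing", out / "framing.tsv")
        genome = {truth.contig: truth.sequence}
        framing = [(n, truth.contig, s, e) for n, s, e in truth.framing]
    else:
        genome = read_genome(config.genome)
        framing = read_framing(config.framing) if config.framing else []

    # --- scan ---
    queries = (read_queries(config.queries) if config.queries
               else S.default_queries())
    params = S.ScanParams(min_score_frac=config.min_score_frac,
                          min_identity=config.min_identity)
    hits = S.scan_domains(genome.items(), queries, params)
    S.write_hits(hits, out / "hits.tsv")
    emit("hits", out / "hits.tsv")

    # --- build ---
    refs = M.reference_models()
    loci = M.cluster_hits(hits, max_gap=config.max_gap, framing=framing)
    gene_models: list[M.GeneModel] = []
    for locus in loci:
        gene_models.extend(M.build_gene_models(locus, genome, refs))

    # --- classify ---
    cconf = C.ClassifyConfig(
        tail_long_min=config.tail_long_min,
        lenient_tail=config.lenient_tail,
        lysine_charged=config.lysine_charged,
        tolerated_frameshift_codons=config.tolerated_frameshift_codons)
    calls = classify_models(gene_models, framing, cconf,
                            species=config.species)
    C.write_calls(calls, out / "calls.tsv")
    emit("calls", out / "calls.tsv")

    # --- summarize ---
    species_summary = SU.tabulate_species(calls, config.species)
    SU.write_summary_tsv([species_summary], out / "summary.tsv")
    emit("summary", out / "summary.tsv")

    # --- CDS extraction + phylogenetics ---
    by_span = {(m.contig, m.start, m.end): m for m in gene_models}
    named = []
    with open(out / "cds.fa", "w") as fh:
        for call in calls:
            model = by_span.get((call.contig, call.start, call.end))
            if model is None:
                continue
            rec_id = f"{config.species}_{call.assigned_name}"
            fh.write(f">{rec_id}\n{model.cds}\n")
            if call.functional:
                named.append((rec_id, model, call))
    emit("cds", out / "cds.fa")

    tree_newick = None
    if config.run_phylo and len(named) >= 4:
        msa = exon_anchored_msa([(rid, m) for rid, m, _ in named])
        boot = P.bootstrap_support(msa, config.bootstrap, seed=config.seed,
                                   distance_kind=config.phylo_model)
        tree = boot.tree
        outgroup = [rid for rid, _, call in named
                    if call.label == "novel_ig_like"]
        if outgroup and len(outgroup) < len(named):
            try:
                tree = P.root_tree(tree, outgroup)
            except ValueError:
                pass  # outgroup not a clade: leave unrooted
        tree_newick = P.write_newick(tree, out / "tree.nwk")
        P.distance_matrix(msa, config.phylo_model).write_tsv(
            out / "distances.tsv")
        emit("tree", out / "tree.nwk")
        emit("distances", out / "distances.tsv")

    counts = {"queries": len(queries), "hits": len(hits), "loci": len(loci),
              "gene_models": len(gene_models), "calls": len(calls),
              "functional": sum(c.functional for c in calls)}
    manifest = {
        "seed": config.seed,
        "species": config.species,
        "thresholds": {
            "min_score_frac": config.min_score_frac,
            "min_identity": config.min_identity,
            "max_gap": config.max_gap,
            "tail_long_min": config.tail_long_min,
            "tolerated_frameshift_codons":
                config.tolerated_frameshift_codons,
        },
        "flags": {"lenient_tail": config.lenient_tail,
                  "lysine_charged": config.lysine_charged},
        "counts": counts,
        "artifacts": {name: {"path": path, "sha256": sha256(path)}
                      for name, path in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(calls=calls, species_summary=species_summary,
                          artifacts=artifacts, tree_newick=tree_newick,
                          counts=counts)
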