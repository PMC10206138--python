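"""Receptor functionality classification and nomenclature.

Implements the functionality rule for LILR genes: a putatively
functional receptor requires a signal peptide, two or more Ig domains
and a transmembrane domain, all free of frameshift and nonsense
mutations, plus either a short cytoplasmic tail with an arginine in the
TM region (activating, LILRA) or a long tail carrying at least one
intact ITIM (inhibitory, LILRB); genes satisfying both tail criteria are
LILRAB.  Everything else is a pseudogene, a gene fragment, or a lone Ig
domain.  A frameshift whose reading frame is restored within a few
codons is tolerated - a gene disrupted and restored with three residues
affected still counts as putatively functional.

Names follow the family nomenclature of sequential numbering along the
locus (clade numbers omitted): LILRA<n>/LILRB<n>/LILRAB<n> by type,
LILR_<n> for pseudogenes with neither activating nor inhibitory
features, and a plus suffix for copies arising from block duplications.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import FramingContext, GeneModel

ITIM_PATTERN = re.compile(r"(?=([SIVL].Y..[IVL]))")

LABELS = {"LILRA", "LILRB", "LILRAB", "LILR_pseudogene", "fragment",
          "lone_ig", "novel_ig_like", "non_LILR"}


@dataclass
class ItimSite:
    position: int          # 1-based start within the cytoplasmic tail
    matched_hexamer: str
    intact: bool = True


@dataclass
class ClassifyConfig:
    """Tunable thresholds of the functionality rule.

    ``tail_long_min`` separates short (activating-style) from long
    (inhibitory-style) cytoplasmic tails, in residues.  ``lenient_tail``
    accepts a long tail whose ITIMs are all mutated as still inhibitory
    (the questionable-LILRB6 behaviour); the strict default calls such a
    gene a pseudogene.  ``lysine_charged`` additionally accepts lysine as
    the charged TM residue; the rule names arginine only, so this
    defaults off.  ``tolerated_frameshift_codons`` is the largest
    disrupted-and-restored span still considered functional.
    ``fragment_max_ig`` bounds the Ig count of a partial locus called a
    fragment / lone Ig domain rather than a gene.
    """

    tail_long_min: int = 30
    lenient_tail: bool = False
    lysine_charged: bool = False
    tolerated_frameshift_codons: int = 5
    fragment_max_ig: int = 1


@dataclass
class Classification:
    gene_id: str
    label: str
    residual_type: str           # A | B | AB | neither
    ig_count: int
    functional: bool
    assigned_name: str = ""
    rationale: list = field(default_factory=list)
    contig: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    at_novel_locus: bool = False
    duplicate_of: Optional[str] = None
    species: str = ""


def find_itims(tail: str) -> list[ItimSite]:
    """All (possibly overlapping) ITIM consensus matches in a tail,
    reported left to right with 1-based positions."""
    if not tail:
        raise ValueError("empty tail sequence")
    sites = []
    for m in ITIM_PATTERN.finditer(tail):
        hexamer = m.group(1)
        sites.append(ItimSite(position=m.start() + 1,
                              matched_hexamer=hexamer,
                              intact="*" not in hexamer))
    return sites


def _dispensable_ig_ordinals(model: GeneModel) -> set[int]:
    """Reference-exon ordinals of Ig domains beyond the fourth.

    Six-Ig receptors are classified on their first four intact Ig
    domains; lesions confined to the fifth and sixth Ig exons do not by
    themselves pseudogenize the gene.
    """
    ig_ordinals = [a.ref_index for a in model.exon_alignments
                   if a.exon_class == "IG"]
    missing_ig = [l.exon_index for l in model.lesions
                  if l.kind == "missing_domain" and l.domain_class == "IG"]
    ordered = sorted(ig_ordinals + missing_ig)
    return set(ordered[4:])


def untolerated_lesions(model: GeneModel,
                        config: ClassifyConfig) -> list:
    """Lesions that break the functionality rule (tolerated compensated
    frameshifts and lesions in dispensable fifth/sixth Ig exons are
    excluded; missing-domain records are judged separately)."""
    dispensable = _dispensable_ig_ordinals(model)
    bad = []
    for lesion in model.lesions:
        if lesion.kind == "missing_domain":
            continue
        if lesion.exon_index in dispensable:
            continue
        if lesion.kind == "frameshift":
            k = lesion.restored_within_codons
            if k is not None and k <= config.tolerated_frameshift_codons:
                continue
            bad.append(lesion)
        elif lesion.kind in ("premature_stop", "splice_disruption"):
            bad.append(lesion)
    return bad


def classify_gene(model: GeneModel,
                  context: Optional[FramingContext] = None,
                  config: Optional[ClassifyConfig] = None,
                  gene_id: str = "gene") -> Classification:
    """Apply the functionality rule to one gene model.

    Decision order: receptor family (KIR and other non-LILR Ig genes are
    set aside; a gene between GP6 and RDH13 matching the novel Ig-like
    reference is the novel gene), then fragment / lone-Ig calls for
    partial structures, then lesion screening, then the
    activating/inhibitory typing.
    """
    if not model.features:
        raise ValueError("model features not populated")
    config = config or ClassifyConfig()
    f = model.features
    rationale = []

    tail = f.get("tail_seq", "")
    itims = [s for s in find_itims(tail)] if tail else []
    intact_itims = [s for s in itims if s.intact]
    f["itim_positions"] = [s.position for s in itims]

    charged_ok = f["tm_has_arginine"] or (
        config.lysine_charged
        and any(r == "K" for _, r in f.get("tm_charged_residues", [])))
    act = f["tm_present"] and charged_ok
    tail_kind = f["tail_kind"]
    if tail and len(tail) >= config.tail_long_min:
        tail_kind = "long"
    inh_structural = tail_kind == "long"
    inh = inh_structural and (bool(intact_itims) or config.lenient_tail)

    if act and inh_structural:
        residual = "AB"
    elif act:
        residual = "A"
    elif inh_structural:
        residual = "B"
    else:
        residual = "neither"

    at_novel = bool(context and context.between("GP6", "RDH13"))
    family = model.reference.family

    base = dict(gene_id=gene_id, ig_count=f["ig_count"],
                contig=model.contig, start=model.start, end=model.end,
                strand=model.strand, at_novel_locus=at_novel,
                rationale=rationale)

    # partial structure: fragment or lone Ig domain
    structural = f["tm_present"] or tail_kind != "absent"
    if f["ig_count"] <= config.fragment_max_ig and not structural:
        if f["sp_present"]:
            rationale.append("partial_locus_with_sp")
            return Classification(label="fragment", residual_type="neither",
                                  functional=False, **base)
        rationale.append("ig_evidence_only")
        return Classification(label="lone_ig", residual_type="neither",
                              functional=False, **base)

    bad = untolerated_lesions(model, config)
    requirements = (f["sp_present"] and f["ig_count"] >= 2
                    and f["tm_present"] and tail_kind != "absent")
    for lesion in bad:
        rationale.append(f"lesion:{lesion.kind}@{lesion.position}")
    if not requirements:
        rationale.append("missing_required_domain")
    functional = requirements and not bad and (act or inh)

    if family == "KIR":
        rationale.append("kir_reference_match")
        return Classification(label="non_LILR", residual_type=residual,
                              functional=functional, **base)
    if family == "NOVEL":
        rationale.append("novel_ig_like_reference_match")
        if at_novel:
            return Classification(label="novel_ig_like",
                                  residual_type=residual,
                                  functional=functional, **base)
        return Classification(label="non_LILR", residual_type=residual,
                              functional=functional, **base)

    if not functional:
        if requirements and not bad and not (act or inh):
            rationale.append("no_activating_or_inhibitory_features")
        return Classification(label="LILR_pseudogene", residual_type=residual,
                              functional=False, **base)

    if act and inh:
        rationale.append("arginine_tm_and_intact_itim")
        return Classification(label="LILRAB", residual_type="AB",
                              functional=True, **base)
    if act:
        rationale.append("short_tail_arginine_tm")
        return Classification(label="LILRA", residual_type="A",
                              functional=True, **base)
    rationale.append("long_tail_intact_itim"
                     if intact_itims else "long_tail_lenient")
    return Classification(label="LILRB", residual_type="B",
                          functional=True, **base)


def assign_names(classifications: Sequence[Classification],
                 family_prefix: str = "LILR") -> list[Classification]:
    """Sequential names in genomic order along the reference orientation.

    LILR genes and pseudogenes share one running index; pseudogenes are
    named by their residual type, type-less pseudogenes become
    ``LILR_<n>``.  Copies marked as block duplicates take their cognate's
    name with a plus suffix and do not consume an index.  Novel Ig-like
    genes, fragments, lone Ig domains and non-LILR genes are named by
    category.  Input order does not matter; sorting is internal.
    """
    ordered = sorted(classifications, key=lambda c: (c.contig, c.start))
    rank = 0
    counters = {"novel": 0, "fragment": 0, "lone": 0, "non": 0}
    by_id = {c.gene_id: c for c in ordered}
    deferred = []
    for c in ordered:
        if c.label in ("LILRA", "LILRB", "LILRAB", "LILR_pseudogene"):
            if c.duplicate_of:
                deferred.append(c)
                continue
            rank += 1
            if c.label == "LILR_pseudogene":
                if c.residual_type == "neither":
                    c.assigned_name = f"{family_prefix}_{rank}"
                else:
                    c.assigned_name = \
                        f"{family_prefix}{c.residual_type}{rank}"
            else:
                suffix = c.label[len("LILR"):]
                c.assigned_name = f"{family_prefix}{suffix}{rank}"
        elif c.label == "novel_ig_like":
            counters["novel"] += 1
            n = counters["novel"]
            c.assigned_name = ("novel_Ig_like" if n == 1
                               else f"novel_Ig_like_{n}")
        elif c.label == "fragment":
            counters["fragment"] += 1
            c.assigned_name = f"fragment_{counters['fragment']}"
        elif c.label == "lone_ig":
            counters["lone"] += 1
            c.assigned_name = f"Ig_{counters['lone']}"
        else:
            counters["non"] += 1
            c.assigned_name = f"nonLILR_{counters['non']}"
    for c in deferred:
        cognate = by_id.get(c.duplicate_of)
        if cognate is not None and cognate.assigned_name:
            c.assigned_name = cognate.assigned_name + "+"
        else:
            rank += 1
            c.assigned_name = f"{family_prefix}?{rank}+"
    return ordered


CALLS_COLUMNS = ["gene_id", "label", "residual_type", "ig_count",
                 "functional", "name", "contig", "start", "end", "strand",
                 "at_novel_locus", "species", "rationale"]


def write_calls(calls: Sequence[Classification], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join(map(str, [
                c.gene_id, c.label, c.residual_type, c.ig_count,
                int(c.functional), c.assigned_name, c.contig, c.start,
                c.end, c.strand, int(c.at_novel_locus), c.species,
                ";".join(c.rationale)])) + "\n")


def read_calls(path) -> list[Classification]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(Classification(
                gene_id=f[idx["gene_id"]], label=f[idx["label"]],
                residual_type=f[idx["residual_type"]],
                ig_count=int(f[idx["ig_count"]]),
                functional=bool(int(f[idx["functional"]])),
                assigned_name=f[idx["name"]], contig=f[idx["contig"]],
                start=int(f[idx["start"]]), end=int(f[idx["end"]]),
                strand=f[idx["strand"]],
                at_novel_locus=bool(int(f[idx["at_novel_locus"]])),
                species=f[idx["species"]],
                rationale=f[idx["rationale"]].split(";")
                if f[idx["rationale"]] else []))
    return calls
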