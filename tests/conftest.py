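import pytest

from lrcpipe import models as M
from lrcpipe import scan as S
from lrcpipe import synth


@pytest.fixture(scope="session")
def cat_truth():
    return synth.generate_locus(synth.cat_like_locus_spec(seed=1))


@pytest.fixture(scope="session")
def cat_hits(cat_truth):
    return S.scan_domains([(cat_truth.contig, cat_truth.sequence)],
                          S.default_queries())


@pytest.fixture(scope="session")
def references():
    return M.reference_models()


@pytest.fixture(scope="session")
def cat_models(cat_truth, cat_hits, references):
    framing = [(n, cat_truth.contig, s, e) for n, s, e in cat_truth.framing]
    loci = M.cluster_hits(cat_hits, framing=framing)
    genome = {cat_truth.contig: cat_truth.sequence}
    out = []
    for locus in loci:
        out.extend(M.build_gene_models(locus, genome, references))
    return out


def best_reference_model(truth, references, strand="+"):
    """Spliced-align every reference against a whole single-gene contig
    and return the best-fitting model (test-side helper mirroring the
    builder's selection rule)."""
    candidates = []
    for name in sorted(references):
        m = M.spliced_align(references[name], truth.sequence, 0, strand,
                            truth.contig)
        if m is not None:
            candidates.append(m)
    assert candidates, "no reference mapped"
    return min(candidates, key=lambda m: (-len(m.exon_alignments),
                                          m.total_edit_distance,
                                          m.reference.name))
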