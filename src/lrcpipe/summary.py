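"""Per-species gene-content tables and family-level statistics.

Builds the standard comparative table for a species - putatively
functional genes and pseudogenes per receptor type (activating LILRA /
inhibitory LILRB) and Ig-domain count, type-less pseudogenes, gene
fragments, lone Ig domains and the novel Ig-like locus - and derives
family summaries: the percentage of functional LILRs among all LILR
(pseudo)genes and the mean number of functional LILRs per species.

The published carnivore tables ship as TSV fixtures (one column per
assembly; the wolf is present twice, with and without its duplicated
block, mirroring the parenthetical presentation).  Six-Ig receptors are
counted in the 4-Ig row, as the published felid tables do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

COUNT_ROWS = [("A", 4), ("B", 4), ("AB", 4), ("A", 3), ("B", 3), ("AB", 3),
              ("A", 2), ("B", 2), ("AB", 2)]


class FixtureError(ValueError):
    """Malformed summary fixture, with row/column location."""


@dataclass
class SpeciesSummary:
    species: str
    variant: str = ""
    counts: dict = field(default_factory=lambda: {
        row: (0, 0) for row in COUNT_ROWS})
    neither_pseudogenes: int = 0
    fragments: int = 0
    lone_ig: int = 0
    novel_ig_like: tuple = (0, 0, 0)   # functional, pseudogene, fragment

    @property
    def functional_total(self) -> int:
        return sum(f for f, _ in self.counts.values())

    @property
    def pseudogene_total(self) -> int:
        return (sum(p for _, p in self.counts.values())
                + self.neither_pseudogenes)

    @property
    def totals(self) -> tuple[int, int]:
        return self.functional_total, self.pseudogene_total


@dataclass
class FamilySummary:
    family: str
    members: list
    functional_ratio_pct: float
    mean_functional: float
    min_max_functional: tuple
    min_max_pseudogene: tuple


def _ig_row(ig_count: int) -> int:
    """Published tables have 2/3/4-Ig rows; 6-Ig receptors count as 4-Ig."""
    if ig_count >= 4:
        return 4
    return max(2, ig_count)


def tabulate_species(calls: Sequence, species: str) -> SpeciesSummary:
    """Fold one species' classifications into a gene-content summary.

    Each call lands in exactly one cell: functional LILRs and typed
    pseudogenes by (type, Ig row); type-less pseudogenes, fragments and
    lone Ig domains in their own tallies; novel Ig-like calls and
    fragments at the novel locus in the novel triple.  Non-LILR genes
    (KIR and other Ig-domain genes of the region) are not counted.
    """
    s = SpeciesSummary(species=species)
    counts = {row: [0, 0] for row in COUNT_ROWS}
    novel = [0, 0, 0]
    for c in calls:
        if c.label in ("LILRA", "LILRB", "LILRAB"):
            row = (c.label[4:], _ig_row(c.ig_count))
            counts[row][0] += 1
        elif c.label == "LILR_pseudogene":
            if c.residual_type == "neither":
                s.neither_pseudogenes += 1
            else:
                counts[(c.residual_type, _ig_row(c.ig_count))][1] += 1
        elif c.label == "fragment":
            if c.at_novel_locus:
                novel[2] += 1
            else:
                s.fragments += 1
        elif c.label == "lone_ig":
            s.lone_ig += 1
        elif c.label == "novel_ig_like":
            if c.functional:
                novel[0] += 1
            else:
                novel[1] += 1
        elif c.label == "non_LILR":
            pass
        else:
            raise ValueError(f"unknown classification label: {c.label}")
    s.counts = {row: tuple(v) for row, v in counts.items()}
    s.novel_ig_like = tuple(novel)
    return s


def round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(10) ** -places
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def family_stats(summaries: Sequence[SpeciesSummary],
                 family: str) -> FamilySummary:
    """Family-level statistics over per-species summaries.

    functional_ratio_pct = 100 * sum(functional) / (sum(functional) +
    sum(pseudogene)), reported to two decimals (half-up, matching the
    published precision); mean_functional = sum(functional) / n_species.
    """
    if not summaries:
        raise ValueError("at least one species summary required")
    func = [s.functional_total for s in summaries]
    pseudo = [s.pseudogene_total for s in summaries]
    total = sum(func) + sum(pseudo)
    if total == 0:
        raise ZeroDivisionError(
            f"family {family}: no genes counted, ratio undefined")
    ratio = round_half_up(100.0 * sum(func) / total, 2)
    return FamilySummary(
        family=family, members=list(summaries),
        functional_ratio_pct=ratio,
        mean_functional=sum(func) / len(summaries),
        min_max_functional=(min(func), max(func)),
        min_max_pseudogene=(min(pseudo), max(pseudo)))


# --- fixtures ---------------------------------------------------------------

PACKAGED_TABLES = {
    "Felidae": "table2_felidae.tsv",
    "Canidae": "table3_canidae.tsv",
    "Mustelidae": "table4_mustelidae.tsv",
}


def packaged_table_path(family: str) -> Path:
    try:
        fname = PACKAGED_TABLES[family]
    except KeyError:
        raise KeyError(f"no packaged table for family {family!r}; "
                       f"known: {sorted(PACKAGED_TABLES)}")
    return Path(resources.files("lrcpipe.data") / fname)


def _parse_pair(cell: str, where: str) -> tuple[int, int]:
    parts = cell.split("/")
    if len(parts) != 2:
        raise FixtureError(f"expected 'f/p' pair at {where}, got {cell!r}")
    return int(parts[0]), int(parts[1])


def load_paper_tables(path) -> list[SpeciesSummary]:
    """Parse a published gene-content table fixture.

    Columns are species (a ``name|variant`` header carries footnote
    variants such as the wolf duplication); rows are category labels.
    The stated totals row is checked against the category sums so a
    mistyped fixture cannot silently misreport the published numbers.
    """
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    header = lines[0].split("\t")
    if header[0] != "category":
        raise FixtureError(f"{path}: first column must be 'category'")
    columns = header[1:]
    summaries = []
    for name in columns:
        species, _, variant = name.partition("|")
        summaries.append(SpeciesSummary(species=species, variant=variant))
    counts = [dict.fromkeys(COUNT_ROWS, (0, 0)) for _ in columns]
    stated_totals: list[Optional[tuple]] = [None] * len(columns)
    for line in lines[1:]:
        cells = line.split("\t")
        row_label, values = cells[0], cells[1:]
        if len(values) != len(columns):
            raise FixtureError(
                f"{path}: row {row_label!r} has {len(values)} cells, "
                f"expected {len(columns)}")
        for j, cell in enumerate(values):
            where = f"{path} row {row_label!r} column {columns[j]!r}"
            if row_label.startswith("LILR") and "_" in row_label:
                rtype = row_label[4:row_label.index("_")]
                ig = int(row_label[row_label.index("_") + 1:-2])
                counts[j][(rtype, ig)] = _parse_pair(cell, where)
            elif row_label == "neither_pseudogenes":
                summaries[j].neither_pseudogenes = int(cell)
            elif row_label == "total":
                stated_totals[j] = _parse_pair(cell, where)
            elif row_label == "novel_ig_like":
                parts = cell.split("/")
                if len(parts) != 3:
                    raise FixtureError(
                        f"expected 'f/p/frag' triple at {where}")
                summaries[j].novel_ig_like = tuple(int(x) for x in parts)
            elif row_label == "fragments":
                summaries[j].fragments = int(cell)
            elif row_label == "lone_ig":
                summaries[j].lone_ig = int(cell)
            else:
                raise FixtureError(f"{path}: unknown row {row_label!r}")
    for j, s in enumerate(summaries):
        s.counts = counts[j]
        if stated_totals[j] is not None and stated_totals[j] != s.totals:
            raise FixtureError(
                f"{path} column {columns[j]!r}: stated totals "
                f"{stated_totals[j]} != computed {s.totals}")
    return summaries


def load_family(family: str,
                wolf_variant: str = "with_dup") -> list[SpeciesSummary]:
    """Packaged family table with one column per species.

    For the Canidae the wolf appears as two fixture variants; exactly one
    is selected (``with_dup`` by default, ``without_dup`` to discount the
    duplicated block as an assembly artifact).
    """
    summaries = load_paper_tables(packaged_table_path(family))
    return [s for s in summaries if not s.variant or s.variant == wolf_variant]


def format_summary(s: SpeciesSummary) -> str:
    lines = [f"{s.species}" + (f" [{s.variant}]" if s.variant else "")]
    for (rtype, ig), (f, p) in s.counts.items():
        if f or p:
            lines.append(f"  LILR{rtype} {ig}-Ig functional/pseudogenes: "
                         f"{f}/{p}")
    if s.neither_pseudogenes:
        lines.append(f"  pseudogenes with neither type: "
                     f"{s.neither_pseudogenes}")
    lines.append("  total functional/pseudogenes: "
                 f"{s.functional_total}/{s.pseudogene_total}")
    lines.append("  novel Ig-like functional/pseudogene/fragment: "
                 "{}/{}/{}".format(*s.novel_ig_like))
    lines.append(f"  other fragments: {s.fragments}; "
                 f"Ig loci without signal peptide: {s.lone_ig}")
    return "\n".join(lines)


def write_summary_tsv(summaries: Sequence[SpeciesSummary], path) -> None:
    with open(path, "w") as fh:
        cols = ["species", "variant"] + [
            f"LILR{t}_{ig}Ig" for t, ig in COUNT_ROWS] + [
            "neither_pseudogenes", "total", "novel_ig_like", "fragments",
            "lone_ig"]
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            row = [s.species, s.variant]
            row += ["{}/{}".format(*s.counts[r]) for r in COUNT_ROWS]
            row.append(str(s.neither_pseudogenes))
            row.append("{}/{}".format(*s.totals))
            row.append("{}/{}/{}".format(*s.novel_ig_like))
            row += [str(s.fragments), str(s.lone_ig)]
            fh.write("\t".join(row) + "\n")
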