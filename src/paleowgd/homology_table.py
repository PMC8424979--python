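"""Event-related multi-genome collinear gene table.

One row per reference gene, in genome order. The reference contributes three
columns (the gene itself plus its two hexaploidy-derived paralogs); every
other species contributes, for each of those three reference columns, as many
ortholog columns as its post-hexaploidy multiplicity (1 for an unduplicated
diploid, 2 for a lineage that underwent an extra tetraploidization). For the
grape/cacao/tetraploid trio this yields the 12-column layout. Missing
collinear genes — lost or translocated — are recorded as a dot.

Column filling is driven entirely by labeled collinear blocks: hexaploidy
(paralog) self-blocks of the reference, speciation (ortholog) cross-blocks,
and the tetraploid's own self-blocks for sibling-column phasing. Paralogous
and co-orthologous regions are separated by clustering block footprints;
conflicts are resolved deterministically, preferring longer blocks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .collinearity import CollinearBlock
from .genome_io import MISSING, Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TableSpec:
    reference_tag: str
    # (species tag, post-hexaploidy multiplicity), table column order
    others: tuple[tuple[str, int], ...]

    @property
    def n_columns(self) -> int:
        return 3 + 3 * sum(m for _, m in self.others)

    def column_names(self) -> list[str]:
        ref = self.reference_tag
        cols = [ref, f"{ref}-p1", f"{ref}-p2"]
        for sp, mult in self.others:
            for slot in range(3):
                base = f"{sp}-o" if slot == 0 else f"{sp}-p{slot}"
                if mult == 1:
                    cols.append(base)
                else:
                    cols.extend(f"{base}{chr(ord('a') + c)}" for c in range(mult))
        return cols

    def columns_for(self, species: str, slot: int) -> list[str]:
        """Column names of one species for one reference slot (0=self, 1/2=paralog)."""
        names = self.column_names()
        if species == self.reference_tag:
            return [names[slot]]
        return [n for n in names if _col_species_slot(n, self) == (species, slot)]


def _col_species_slot(name: str, spec: TableSpec) -> tuple[str, int] | None:
    if "-" not in name:
        return None
    sp, suffix = name.split("-", 1)
    if suffix.startswith("o"):
        return sp, 0
    if suffix.startswith("p"):
        return sp, int(suffix[1])
    return None


@dataclass
class HomologyTable:
    spec: TableSpec
    data: pd.DataFrame  # index: reference gene ids in genome order; "." missing
    provenance: pd.DataFrame  # block id per filled cell, -1 elsewhere
    reference_chromosome: pd.Series  # chromosome of each reference row
    conflicts: int = 0

    @property
    def n_rows(self) -> int:
        return len(self.data)


# ------------------------------------------------------------ footprints


@dataclass
class _Entry:
    """One directed view of a block: reference side -> partner side."""

    block: CollinearBlock
    ref_chrom: str
    ref_lo: int
    ref_hi: int
    partner_chrom: str
    partner_lo: int
    partner_hi: int
    pairs: list[tuple[str, str, int]]  # (ref gene, partner gene, ref rank)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _directed_entries(
    blocks: list[CollinearBlock], ref_tag: str, both_directions: bool
) -> list[_Entry]:
    entries = []
    for b in blocks:
        if b.genome_a == ref_tag:
            entries.append(
                _Entry(b, b.chrom_a, *b.footprint_a(), b.chrom_b, *b.footprint_b(),
                       [(ga, gb, ra) for (ga, gb), ra in zip(b.pairs, b.ranks_a)])
            )
        if b.genome_b == ref_tag and (both_directions or b.genome_a != ref_tag):
            entries.append(
                _Entry(b, b.chrom_b, *b.footprint_b(), b.chrom_a, *b.footprint_a(),
                       [(gb, ga, rb) for (ga, gb), rb in zip(b.pairs, b.ranks_b)])
            )
    return entries


def _overlap(lo1: int, hi1: int, lo2: int, hi2: int) -> bool:
    return lo1 <= hi2 and lo2 <= hi1


def _cluster_entries(entries: list[_Entry]) -> list[list[_Entry]]:
    """Cluster directed entries into homologous-region groups.

    Entries join a cluster when their partner footprints overlap on the
    same chromosome, or when they look like fragments of one broken chain:
    same partner chromosome and essentially disjoint reference intervals.
    Two genuinely distinct paralogous/co-orthologous regions on one
    chromosome cover the same reference interval twice and stay separate.
    """
    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i], entries[j]
            if a.partner_chrom != b.partner_chrom:
                continue
            if _overlap(a.partner_lo, a.partner_hi, b.partner_lo, b.partner_hi):
                parent[find(i)] = find(j)
                continue
            ov = min(a.ref_hi, b.ref_hi) - max(a.ref_lo, b.ref_lo) + 1
            shorter = min(a.ref_hi - a.ref_lo, b.ref_hi - b.ref_lo) + 1
            if ov < 0.5 * shorter:  # fragments of one chain, not stacked copies
                parent[find(i)] = find(j)
    groups: dict[int, list[_Entry]] = {}
    for i, e in enumerate(entries):
        groups.setdefault(find(i), []).append(e)
    clusters = list(groups.values())
    clusters.sort(
        key=lambda c: (
            -sum(e.n_pairs for e in c),
            c[0].partner_chrom,
            min(e.partner_lo for e in c),
        )
    )
    return clusters


def _ref_components(entries: list[_Entry]) -> list[list[_Entry]]:
    """Group entries into reference segments: connected components under
    reference-footprint overlap on the same reference chromosome."""
    parent = list(range(len(entries)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i], entries[j]
            if a.ref_chrom == b.ref_chrom and _overlap(a.ref_lo, a.ref_hi, b.ref_lo, b.ref_hi):
                parent[find(i)] = find(j)
    groups: dict[int, list[_Entry]] = {}
    for i, e in enumerate(entries):
        groups.setdefault(find(i), []).append(e)
    comps = list(groups.values())
    comps.sort(key=lambda c: (c[0].ref_chrom, min(e.ref_lo for e in c)))
    return comps


# ------------------------------------------------------------ build


class _Filler:
    """Tracks cell/column occupancy with deterministic conflict resolution:
    the candidate from the longer block wins; ties keep the first placed
    (entries are processed longest-block-first)."""

    def __init__(self, table: pd.DataFrame, prov: pd.DataFrame):
        self.table = table
        self.prov = prov
        self.strength: dict[tuple[str, str], int] = {}  # (row, col) -> block pairs
        self.used: dict[tuple[str, str], str] = {}  # (col, gene) -> row
        self.conflicts = 0

    def place(self, row: str, col: str, gene: str, block: CollinearBlock) -> bool:
        if row not in self.table.index:
            return False
        key_cell = (row, col)
        key_gene = (col, gene)
        if self.used.get(key_gene, row) != row:
            self.conflicts += 1
            return False
        current = self.table.at[row, col]
        if current != MISSING:
            if current == gene:
                return True
            self.conflicts += 1
            if self.strength.get(key_cell, 0) >= block.n_pairs:
                return False
            old_gene = current
            self.used.pop((col, old_gene), None)
        self.table.at[row, col] = gene
        self.prov.at[row, col] = block.id
        self.strength[key_cell] = block.n_pairs
        self.used[key_gene] = row
        return True


def build_table(
    spec: TableSpec,
    reference: Genome,
    blocks: dict[tuple[str, str], list[CollinearBlock]],
    paralog_event: str = "ECH",
    wgd_event: str = "AST",
) -> HomologyTable:
    """Assemble the event-related gene table from labeled blocks.

    ``blocks`` maps species-tag pairs to their labeled block lists; the
    reference self-comparison must carry ``paralog_event`` labels, the
    cross comparisons ``ortholog:*`` labels, and (for multiplicity-2
    species) that species' self-comparison ``wgd_event`` labels used for
    sibling-region phasing diagnostics.
    """
    ref = spec.reference_tag
    rows: list[str] = []
    chroms: list[str] = []
    for chrom in reference.chromosomes:
        for g in reference.genes_on(chrom):
            rows.append(g.id)
            chroms.append(chrom)
    columns = spec.column_names()
    data = pd.DataFrame(MISSING, index=rows, columns=columns, dtype=object)
    prov = pd.DataFrame(-1, index=rows, columns=columns, dtype=int)
    data[ref] = rows
    filler = _Filler(data, prov)

    # 1) reference hexaploidy-paralog columns
    self_blocks = [
        b for b in blocks.get((ref, ref), []) if b.event == paralog_event
    ]
    entries = _directed_entries(self_blocks, ref, both_directions=True)
    # paralog gene -> every (row, slot) cell it anchors (a gene from region 2
    # may sit in p1 of a region-1 row and in p2 of a region-3 row)
    slot_of_gene: dict[str, list[tuple[str, int]]] = {}
    for comp in _ref_components(entries):
        clusters = _cluster_entries(comp)
        if len(clusters) > 2:
            logger.info(
                "reference segment %s:%d has %d paralogous region clusters; "
                "keeping the two largest",
                comp[0].ref_chrom, min(e.ref_lo for e in comp), len(clusters),
            )
        kept = clusters[:2]

        def ech_placements(cluster, slot):
            col = f"{ref}-p{slot}"
            for entry in sorted(cluster, key=lambda e: (-e.n_pairs, e.block.id)):
                for row_gene, partner_gene, _ in entry.pairs:
                    yield row_gene, col, partner_gene, entry.block

        assignment = _choose_assignment(filler, kept, [1, 2], ech_placements)
        for cluster, slot in assignment:
            for row_gene, col, partner_gene, block in ech_placements(cluster, slot):
                if filler.place(row_gene, col, partner_gene, block):
                    slot_of_gene.setdefault(partner_gene, []).append((row_gene, slot))

    # 2) ortholog columns per other species
    for sp, mult in spec.others:
        key = (ref, sp) if (ref, sp) in blocks else (sp, ref)
        ortho = [
            b for b in blocks.get(key, []) if b.event.startswith("ortholog")
        ]
        entries = _directed_entries(ortho, ref, both_directions=False)
        for comp in _ref_components(entries):
            clusters = _cluster_entries(comp)
            if mult == 1:
                clusters = [[e for c in clusters for e in c]]
            elif len(clusters) > mult:
                logger.info(
                    "reference segment %s:%d has %d co-orthologous clusters "
                    "for %s; keeping the %d largest",
                    comp[0].ref_chrom, min(e.ref_lo for e in comp),
                    len(clusters), sp, mult,
                )
            kept = clusters[:mult]

            def ortho_placements(cluster, copy_idx, sp=sp, mult=mult):
                for entry in sorted(cluster, key=lambda e: (-e.n_pairs, e.block.id)):
                    for row_gene, target_gene, _ in entry.pairs:
                        for row, slot in _resolve_slots(row_gene, slot_of_gene):
                            cols = spec.columns_for(sp, slot)
                            col = cols[copy_idx] if mult > 1 else cols[0]
                            yield row, col, target_gene, entry.block

            assignment = _choose_assignment(
                filler, kept, list(range(mult)), ortho_placements)
            for cluster, copy_idx in assignment:
                for row, col, target_gene, block in ortho_placements(cluster, copy_idx):
                    filler.place(row, col, target_gene, block)

    table = HomologyTable(
        spec=spec, data=data, provenance=prov,
        reference_chromosome=pd.Series(chroms, index=rows),
        conflicts=filler.conflicts,
    )
    _check_wgd_phasing(table, blocks, spec, wgd_event)
    return table


def _choose_assignment(filler: "_Filler", clusters, values, placements):
    """Map each region cluster to a column value (paralog slot or sibling
    copy index), choosing the permutation that collides least with genes
    already occupying those columns from neighbouring segments — the
    arrangement that lets one paralog sit in p1 of one row group and p2 of
    another. Ties keep size order (largest cluster, first value)."""
    k = min(len(clusters), len(values))
    best_perm, best_score = None, None
    for perm in itertools.permutations(values, k):
        score = 0
        for cluster, value in zip(clusters, perm):
            for row, col, gene, _ in placements(cluster, value):
                if filler.used.get((col, gene), row) != row:
                    score += 1
        if best_score is None or score < best_score:
            best_perm, best_score = perm, score
    return list(zip(clusters, best_perm or []))


def _resolve_slots(ref_gene: str, slot_of_gene) -> list[tuple[str, int]]:
    """Rows/slots where a reference gene anchors columns: its own row (slot 0)
    plus every paralog cell it occupies (slots 1-2)."""
    return [(ref_gene, 0)] + slot_of_gene.get(ref_gene, [])


def _check_wgd_phasing(table, blocks, spec, wgd_event) -> None:
    """Diagnostic: sibling columns should separate the tetraploid's own
    duplication partners — a gene and its WGD partner belong to sibling
    cells of the same row, not to the same column."""
    for sp, mult in spec.others:
        if mult < 2:
            continue
        self_blocks = [b for b in blocks.get((sp, sp), []) if b.event == wgd_event]
        partners = {}
        for b in self_blocks:
            for ga, gb in b.pairs:
                partners[ga] = gb
                partners[gb] = ga
        if not partners:
            continue
        cols = [c for c in table.data.columns if _col_species_slot(c, spec) is not None
                and c.split("-")[0] == sp]
        same = split = 0
        for col in cols:
            placed = {g: r for r, g in table.data[col].items() if g != MISSING}
            for g, row in placed.items():
                p = partners.get(g)
                if p is None:
                    continue
                if p in placed:
                    same += 1
                else:
                    split += 1
        if same:
            logger.warning(
                "%s: %d WGD partner pairs share a column (vs %d split) — "
                "sibling phasing imperfect", sp, same // 2, split,
            )


# ------------------------------------------------------------ statistics


def column_stats(table: HomologyTable) -> pd.DataFrame:
    """Filled counts and retention fraction per column, plus co-retention
    between sibling column pairs (both filled in the same row)."""
    out = []
    for col in table.data.columns:
        filled = int((table.data[col] != MISSING).sum())
        out.append({"column": col, "filled": filled,
                    "retention": filled / table.n_rows if table.n_rows else 0.0})
    df = pd.DataFrame(out).set_index("column")
    return df


def sibling_co_retention(table: HomologyTable) -> pd.DataFrame:
    """For each sibling column pair of a multiplicity-2 species: fraction of
    rows with both, either, and neither sibling present."""
    rows = []
    for sp, mult in table.spec.others:
        if mult < 2:
            continue
        for slot in range(3):
            cols = table.spec.columns_for(sp, slot)
            a = table.data[cols[0]] != MISSING
            b = table.data[cols[1]] != MISSING
            rows.append({
                "species": sp, "slot": slot, "col_a": cols[0], "col_b": cols[1],
                "both": float((a & b).mean()),
                "either": float((a | b).mean()),
                "neither": float((~a & ~b).mean()),
            })
    return pd.DataFrame(rows)


def export_alignment_graph(table: HomologyTable, layout: str = "circular") -> pd.DataFrame:
    """Tick records for a circular or linear rendering of the table: one row
    per filled cell with its track (column), reference rank, and the source
    chromosome of the placed gene as a color key."""
    if layout not in {"circular", "linear"}:
        raise ValueError("layout must be 'circular' or 'linear'")
    records = []
    for rank, row in enumerate(table.data.index):
        ref_chrom = table.reference_chromosome[row]
        for track, col in enumerate(table.data.columns):
            gene = table.data.at[row, col]
            if gene == MISSING:
                continue
            records.append({
                "layout": layout, "track": track, "column": col,
                "reference_rank": rank, "reference_chromosome": ref_chrom,
                "gene": gene,
            })
    return pd.DataFrame(records)


def write_table(table: HomologyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(table.data.columns) + "\n")
        table.data.to_csv(fh, sep="\t", header=False)


def write_provenance(table: HomologyTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(table.provenance.columns) + "\n")
        table.provenance.to_csv(fh, sep="\t", header=False)
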