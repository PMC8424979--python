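"""Genome, gene-model, and homology-hit I/O.

Reads gene annotations from GFF3 or a 4-column gene bed (id, chromosome,
start, end), attaches CDS/protein sequences from FASTA, and loads BLAST
outfmt-6 style homology tables. All tabular writers emit TSV with one
commented header line so every output re-parses with the readers here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MISSING = "."


@dataclass
class GeneModel:
    """One gene: coordinates are 1-based inclusive, rank is the 0-based
    position among the genes of its chromosome ordered by start."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"
    rank: int = -1
    cds: str | None = None
    protein: str | None = None
    cds_valid: bool = True  # False when the CDS cannot back an estimate of Ks

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")


@dataclass
class Genome:
    species_tag: str
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chromosomes: list[str] = field(default_factory=list)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        out = [g for g in self.genes.values() if g.chromosome == chromosome]
        out.sort(key=lambda g: g.rank)
        return out

    def by_rank(self) -> dict[str, list[GeneModel]]:
        return {c: self.genes_on(c) for c in self.chromosomes}

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class HomologyHit:
    query_gene: str
    subject_gene: str
    evalue: float
    bitscore: float


def _assign_ranks(genome: Genome) -> None:
    for chrom in genome.chromosomes:
        for rank, gene in enumerate(
            sorted(
                (g for g in genome.genes.values() if g.chromosome == chrom),
                key=lambda g: (g.start, g.end, g.id),
            )
        ):
            gene.rank = rank


def _trim_cds(gene_id: str, seq: str) -> str:
    """Trim trailing bases so the CDS is a whole number of codons."""
    extra = len(seq) % 3
    if extra:
        logger.warning("gene %s: CDS length %d not divisible by 3, trimming %d nt",
                       gene_id, len(seq), extra)
        seq = seq[: len(seq) - extra]
    return seq


def attach_sequences(genome: Genome, fasta_path: str | Path) -> None:
    """Attach CDS (and translated protein) to genes by FASTA record id.

    A CDS with an internal stop codon is kept but flagged invalid for Ks.
    """
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gene = genome.genes.get(record.id)
        if gene is None:
            continue
        cds = _trim_cds(gene.id, str(record.seq).upper())
        gene.cds = cds
        protein = str(Seq(cds).translate())
        if protein.endswith("*"):
            protein = protein[:-1]
        if "*" in protein:
            logger.warning("gene %s: internal stop codon, excluded from Ks", gene.id)
            gene.cds_valid = False
        gene.protein = protein


def load_genome(
    annotation_path: str | Path,
    fasta_path: str | Path | None = None,
    species_tag: str | None = None,
) -> Genome:
    """Load a genome from GFF3 or 4-column gene bed, with optional CDS FASTA.

    Genes are sorted by (chromosome, start) and given dense 0-based ranks
    per chromosome. Duplicate gene ids are a hard error.
    """
    annotation_path = Path(annotation_path)
    tag = species_tag or annotation_path.stem.split(".")[0]
    genome = Genome(species_tag=tag)
    text = annotation_path.read_text()
    is_gff = annotation_path.suffix.lower() in {".gff", ".gff3"} or "##gff" in text[:200]
    for line_no, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if is_gff:
            parsed = _parse_gff_line(fields, line_no)
            if parsed is None:
                continue
        else:
            if len(fields) < 4:
                raise ValueError(f"{annotation_path}:{line_no}: expected 4 columns")
            parsed = GeneModel(
                id=fields[0], chromosome=fields[1],
                start=int(fields[2]), end=int(fields[3]),
                strand=fields[4] if len(fields) > 4 else "?",
            )
        if parsed.id in genome.genes:
            raise ValueError(f"duplicate gene id: {parsed.id}")
        genome.genes[parsed.id] = parsed
        if parsed.chromosome not in genome.chromosomes:
            genome.chromosomes.append(parsed.chromosome)
    _assign_ranks(genome)
    if fasta_path is not None:
        attach_sequences(genome, fasta_path)
    return genome


def _parse_gff_line(fields: Sequence[str], line_no: int) -> GeneModel | None:
    if len(fields) < 9:
        return None
    ftype = fields[2]
    if ftype not in {"gene", "mRNA"}:
        return None
    attrs = dict(
        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
    )
    gene_id = attrs.get("ID")
    if gene_id is None:
        raise ValueError(f"line {line_no}: {ftype} feature without ID attribute")
    return GeneModel(
        id=gene_id, chromosome=fields[0],
        start=int(fields[3]), end=int(fields[4]),
        strand=fields[6] if fields[6] in "+-" else "?",
    )


def write_genome(genome: Genome, path: str | Path) -> None:
    """Write the gene-bed dialect (round-trips through load_genome)."""
    with open(path, "w") as fh:
        fh.write("#id\tchromosome\tstart\tend\tstrand\trank\n")
        for chrom in genome.chromosomes:
            for gene in genome.genes_on(chrom):
                fh.write(
                    f"{gene.id}\t{gene.chromosome}\t{gene.start}\t{gene.end}"
                    f"\t{gene.strand}\t{gene.rank}\n"
                )


def load_hits(
    path: str | Path,
    evalue_cutoff: float = 1e-5,
    top_n: int = 5,
) -> list[HomologyHit]:
    """Load a tab-delimited homology hit table (BLAST outfmt-6, or a
    3-column query/subject/evalue dialect).

    Self-hits and hits above the E-value cutoff are removed; at most
    ``top_n`` subjects are kept per query, best bitscore first
    (``top_n=0`` disables the thinning). Malformed rows are skipped with
    a warning.
    """
    raw: list[HomologyHit] = []
    n_bad = n_total = 0
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        n_total += 1
        fields = line.split("\t")
        try:
            if len(fields) >= 12:
                hit = HomologyHit(fields[0], fields[1], float(fields[10]), float(fields[11]))
            elif len(fields) == 4:  # the package's own writer dialect
                hit = HomologyHit(fields[0], fields[1], float(fields[2]), float(fields[3]))
            elif len(fields) == 3:
                hit = HomologyHit(fields[0], fields[1], float(fields[2]), 0.0)
            else:
                raise ValueError("too few columns")
        except ValueError:
            n_bad += 1
            logger.warning("%s:%d: malformed hit row skipped", path, line_no)
            continue
        raw.append(hit)
    if n_bad:
        logger.warning("%s: skipped %d of %d rows", path, n_bad, n_total)
    return filter_hits(raw, evalue_cutoff=evalue_cutoff, top_n=top_n)


def filter_hits(
    hits: Iterable[HomologyHit],
    evalue_cutoff: float = 1e-5,
    top_n: int = 5,
) -> list[HomologyHit]:
    """Apply the E-value cutoff, drop self-hits, keep best top_n per query.

    Idempotent: filtering the output again returns it unchanged.
    """
    per_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        if h.query_gene == h.subject_gene or h.evalue > evalue_cutoff:
            continue
        per_query.setdefault(h.query_gene, []).append(h)
    out: list[HomologyHit] = []
    for query in per_query:
        ranked = sorted(per_query[query], key=lambda h: (-h.bitscore, h.evalue, h.subject_gene))
        if top_n > 0:
            ranked = ranked[:top_n]
        out.extend(ranked)
    if not out:
        logger.warning("no hits survived filtering")
    return out


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#query\tsubject\tevalue\tbitscore\n")
        for h in hits:
            fh.write(f"{h.query_gene}\t{h.subject_gene}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n")
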