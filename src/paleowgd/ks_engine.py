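"""Synonymous/nonsynonymous substitution rates for collinear gene pairs.

Protein-guided codon alignment followed by the Nei–Gojobori (NG86) method:
synonymous site fractions from the standard genetic code, pathway-averaged
difference counts for multi-hit codons (stop-codon pathways excluded), and
the Jukes–Cantor multiple-hit correction

    Ks = -(3/4) ln(1 - (4/3) ps),   ps = Sd / S

with the analogous form for Ka. A proportion of differences at or beyond
3/4 cannot be corrected and is reported as saturated rather than raised.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from . import _codon
from .collinearity import CollinearBlock
from .genome_io import Genome

SATURATED = float("nan")


@dataclass(frozen=True)
class AlignedCodonPair:
    codon_a: str
    codon_b: str
    position: int


@dataclass(frozen=True)
class KsResult:
    ks: float
    ka: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    status: str  # "ok", "saturated_ks", "saturated_ka", "saturated_both"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def codon_align(
    cds_a: str,
    cds_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> list[AlignedCodonPair]:
    """Globally align two CDS at the protein level and back-thread to codons.

    Alignment columns containing a gap are dropped. Internal stop codons
    are an error; trailing stop codons are trimmed.
    """
    codons = []
    for label, cds in (("a", cds_a), ("b", cds_b)):
        if len(cds) % 3:
            raise ValueError(f"cds_{label}: length not divisible by 3")
        prot = str(Seq(cds).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
            cds = cds[:-3]
        if "*" in prot:
            raise ValueError(f"cds_{label}: internal stop codon at position {prot.index('*')}")
        if not prot:
            raise ValueError(f"cds_{label}: empty protein after translation")
        codons.append((prot, [cds[i : i + 3] for i in range(0, len(cds), 3)]))
    (prot_a, codons_a), (prot_b, codons_b) = codons
    aligner = aligner or _default_aligner()
    alignment = aligner.align(prot_a, prot_b)[0]
    out: list[AlignedCodonPair] = []
    pos = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            out.append(AlignedCodonPair(codons_a[i], codons_b[j], pos))
            pos += 1
    return out


def ng86(pairs: list[AlignedCodonPair]) -> KsResult:
    """Nei–Gojobori Ka/Ks over a gap-free codon alignment."""
    if not pairs:
        raise ValueError("empty codon alignment")
    sd_tab, nd_tab = _codon.pair_tables()
    s_a = s_b = 0.0
    sd = nd = 0.0
    for p in pairs:
        ia = _codon.encode_codon(p.codon_a)
        ib = _codon.encode_codon(p.codon_b)
        if _codon.IS_STOP[ia] or _codon.IS_STOP[ib]:
            raise ValueError(f"stop codon at alignment position {p.position}")
        s_a += _codon.SYN_SITES[ia]
        s_b += _codon.SYN_SITES[ib]
        sd += sd_tab[ia, ib]
        nd += nd_tab[ia, ib]
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    if s_sites <= 0:
        raise ValueError("zero synonymous sites: degenerate input")
    ps = sd / s_sites
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    status = "ok"
    if math.isnan(ks) and math.isnan(ka):
        status = "saturated_both"
    elif math.isnan(ks):
        status = "saturated_ks"
    elif math.isnan(ka):
        status = "saturated_ka"
    return KsResult(ks=ks, ka=ka, s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd, status=status)


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return SATURATED
    if p <= 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def pair_ks(cds_a: str, cds_b: str) -> KsResult:
    """Convenience: codon-align two CDS and run NG86."""
    return ng86(codon_align(cds_a, cds_b))


def annotate_block_ks(
    blocks: list[CollinearBlock],
    genomes: dict[str, Genome],
) -> list[CollinearBlock]:
    """Fill per-pair Ks and the block median in place.

    Saturated or failed pairs are excluded from the median; a block is
    flagged when more than half its pairs were excluded (or none remain,
    in which case the median stays undefined).
    """
    cache: dict[tuple[str, str], KsResult | None] = {}
    for block in blocks:
        ga = genomes[block.genome_a]
        gb = genomes[block.genome_b]
        values: list[float] = []
        block.ks = []
        results: list[KsResult | None] = []
        for ida, idb in block.pairs:
            key = (ida, idb) if ida <= idb else (idb, ida)
            if key not in cache:
                cache[key] = _safe_pair_ks(ga.genes[ida], gb.genes[idb])
            res = cache[key]
            results.append(res)
            if res is not None and not math.isnan(res.ks):
                block.ks.append(res.ks)
                values.append(res.ks)
            else:
                block.ks.append(None)
        block.ks_results = results  # full KsResult per pair for the TSV writer
        n_excluded = block.n_pairs - len(values)
        block.flagged = n_excluded * 2 > block.n_pairs or not values
        block.median_ks = statistics.median(values) if values else None
    return blocks


def _safe_pair_ks(gene_a, gene_b) -> KsResult | None:
    if gene_a.cds is None or gene_b.cds is None:
        return None
    if not (gene_a.cds_valid and gene_b.cds_valid):
        return None
    try:
        return pair_ks(gene_a.cds, gene_b.cds)
    except ValueError:
        return None


def write_ks_table(blocks: list[CollinearBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\tblock_id\tka\tks\ts_sites\tn_sites\tstatus\n")
        for b in blocks:
            results = getattr(b, "ks_results", [None] * b.n_pairs)
            for (ga, gb), res in zip(b.pairs, results):
                if res is None:
                    fh.write(f"{ga}\t{gb}\t{b.id}\tNA\tNA\tNA\tNA\texcluded\n")
                    continue
                ka = "NA" if math.isnan(res.ka) else f"{res.ka:.4f}"
                ks = "NA" if math.isnan(res.ks) else f"{res.ks:.4f}"
                fh.write(
                    f"{ga}\t{gb}\t{b.id}\t{ka}\t{ks}\t{res.s_sites:.2f}"
                    f"\t{res.n_sites:.2f}\t{res.status}\n"
                )
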