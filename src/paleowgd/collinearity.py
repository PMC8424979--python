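"""Collinear (syntenic) block detection by chaining homologous gene pairs.

Hits are placed on the rank×rank plane of a chromosome pair and chained into
maximal runs with strictly monotonic ranks on both axes (co-directional or
inverted) and a bounded rank gap between consecutive members. The best chain
(most pairs; ties broken by smaller total gap, then by first gene id) is
extracted, its hits removed, and the scan repeated — the classic greedy
block-scanning scheme used for whole-genome-duplication dotplots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome, HomologyHit

DEFAULT_MAX_GAP = 50
DEFAULT_MIN_PAIRS = 4


@dataclass
class CollinearBlock:
    id: int
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    pairs: list[tuple[str, str]]
    ranks_a: list[int]
    ranks_b: list[int]
    orientation: str  # "+" co-directional, "-" inverted
    ks: list[float | None] = field(default_factory=list)  # per pair, None = no estimate
    median_ks: float | None = None
    flagged: bool = False
    event: str = "unassigned"

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def footprint_a(self) -> tuple[int, int]:
        return min(self.ranks_a), max(self.ranks_a)

    def footprint_b(self) -> tuple[int, int]:
        return min(self.ranks_b), max(self.ranks_b)


@dataclass(frozen=True)
class BlockSummary:
    threshold: int
    n_blocks: int
    n_pairs: int
    mean_pairs_per_block: float | None  # None when no block reaches the threshold


def detect_blocks(
    hits: list[HomologyHit],
    genome_a: Genome,
    genome_b: Genome,
    max_gap: int = DEFAULT_MAX_GAP,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[CollinearBlock]:
    """Chain homologous gene pairs into collinear blocks.

    ``max_gap`` bounds the number of intervening genes (rank difference
    minus one) between consecutive chain members, on both axes. Blocks
    shorter than ``min_pairs`` are not reported. In a self-comparison
    (``genome_a is genome_b`` or equal tags) the trivial diagonal is
    excluded and each paralogous block is reported once, on the side with
    chrom_a < chrom_b (or the lower start rank on one chromosome).
    """
    self_mode = genome_a.species_tag == genome_b.species_tag
    plane: dict[tuple[str, str], dict[tuple[int, int], tuple[str, str]]] = {}
    for h in hits:
        ga = genome_a.genes.get(h.query_gene)
        gb = genome_b.genes.get(h.subject_gene)
        if ga is None or gb is None:  # hit tables may carry either direction
            ga = genome_a.genes.get(h.subject_gene)
            gb = genome_b.genes.get(h.query_gene)
        if ga is None or gb is None:
            raise ValueError(
                f"hit {h.query_gene}/{h.subject_gene} references a gene "
                "absent from the genomes"
            )
        ca, ra, ia = ga.chromosome, ga.rank, ga.id
        cb, rb, ib = gb.chromosome, gb.rank, gb.id
        if self_mode:
            if ia == ib:
                continue
            if (ca, ra) > (cb, rb):  # canonical side only (merges mirrors)
                ca, ra, ia, cb, rb, ib = cb, rb, ib, ca, ra, ia
        plane.setdefault((ca, cb), {})[(ra, rb)] = (ia, ib)

    blocks: list[CollinearBlock] = []
    next_id = 0
    for (ca, cb) in sorted(plane):
        points = plane[(ca, cb)]
        while True:
            chain = _best_chain(points, max_gap)
            if chain is None or len(chain[0]) < min_pairs:
                break
            coords, orientation = chain
            pairs = [points[c] for c in coords]
            for c in coords:
                del points[c]
            blocks.append(
                CollinearBlock(
                    id=next_id,
                    genome_a=genome_a.species_tag,
                    genome_b=genome_b.species_tag,
                    chrom_a=ca,
                    chrom_b=cb,
                    pairs=pairs,
                    ranks_a=[c[0] for c in coords],
                    ranks_b=[c[1] for c in coords],
                    orientation=orientation,
                    ks=[None] * len(pairs),
                )
            )
            next_id += 1
    return blocks


def _best_chain(
    points: dict[tuple[int, int], tuple[str, str]], max_gap: int
) -> tuple[list[tuple[int, int]], str] | None:
    """Best single chain over the remaining points, or None if empty."""
    if not points:
        return None
    best: tuple[int, int, str, str] | None = None  # (len, -gap, first_gene, orient)
    best_chain: list[tuple[int, int]] | None = None
    for orientation in "+-":
        chain = _chain_dp(points, max_gap, orientation)
        if chain is None:
            continue
        gap = _total_gap(chain)
        key = (len(chain), -gap, points[chain[0]][0], orientation)
        # maximize length, then minimize gap, then lexicographic first gene id,
        # preferring "+" on full ties
        if best is None or (key[0], key[1]) > (best[0], best[1]) or (
            (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]
        ):
            best = key
            best_chain = chain
    if best_chain is None:
        return None
    return best_chain, best[3]


def _chain_dp(
    points: dict[tuple[int, int], tuple[str, str]], max_gap: int, orientation: str
) -> list[tuple[int, int]] | None:
    coords = sorted(points)
    n = len(coords)
    if n == 0:
        return None
    ra = np.array([c[0] for c in coords])
    rb = np.array([c[1] for c in coords])
    if orientation == "-":
        rb = -rb  # inverted chains become increasing after reflection
    length = np.ones(n, dtype=np.int64)
    gap_sum = np.zeros(n, dtype=np.int64)
    parent = np.full(n, -1, dtype=np.int64)
    step = max_gap + 1
    for j in range(n):
        da = ra[j] - ra[:j]
        db = rb[j] - rb[:j]
        ok = (da > 0) & (db > 0) & (da <= step) & (db <= step)
        if not ok.any():
            continue
        cand = np.flatnonzero(ok)
        gaps = (da[cand] - 1) + (db[cand] - 1)
        score = length[cand] * 10**9 - (gap_sum[cand] + gaps)
        k = cand[int(np.argmax(score))]
        g = (ra[j] - ra[k] - 1) + (rb[j] - rb[k] - 1)
        length[j] = length[k] + 1
        gap_sum[j] = gap_sum[k] + g
        parent[j] = k
    end = int(np.argmax(length * 10**9 - gap_sum))
    chain_idx = []
    while end != -1:
        chain_idx.append(end)
        end = int(parent[end])
    chain_idx.reverse()
    return [coords[i] for i in chain_idx]


def _total_gap(chain: list[tuple[int, int]]) -> int:
    g = 0
    for (a0, b0), (a1, b1) in zip(chain, chain[1:]):
        g += abs(a1 - a0) - 1 + abs(b1 - b0) - 1
    return g


def summarize_blocks(
    blocks: list[CollinearBlock], thresholds: list[int] = [4, 10, 20, 50]
) -> list[BlockSummary]:
    """Tally blocks with at least ``threshold`` pairs for each threshold.

    The mean pairs per block is reported to two decimals; with zero
    qualifying blocks it is None.
    """
    out = []
    for t in thresholds:
        qualifying = [b for b in blocks if b.n_pairs >= t]
        n_pairs = sum(b.n_pairs for b in qualifying)
        mean = round(n_pairs / len(qualifying), 2) if qualifying else None
        out.append(BlockSummary(t, len(qualifying), n_pairs, mean))
    return out


def write_blocks(blocks: list[CollinearBlock], path) -> None:
    """Block TSV: one commented header line per block, then its pair rows."""
    with open(path, "w") as fh:
        fh.write("#block_id\tgenome_a\tgenome_b\tchrom_a\tchrom_b\tn_pairs\torientation\tmedian_ks\tevent\n")
        for b in blocks:
            mks = f"{b.median_ks:.4f}" if b.median_ks is not None else "NA"
            fh.write(
                f"#{b.id}\t{b.genome_a}\t{b.genome_b}\t{b.chrom_a}\t{b.chrom_b}"
                f"\t{b.n_pairs}\t{b.orientation}\t{mks}\t{b.event}\n"
            )
            for (ga, gb), ra, rb, ks in zip(b.pairs, b.ranks_a, b.ranks_b, b.ks):
                ks_s = f"{ks:.4f}" if ks is not None and np.isfinite(ks) else "NA"
                fh.write(f"{ga}\t{gb}\t{ra}\t{rb}\t{ks_s}\n")
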