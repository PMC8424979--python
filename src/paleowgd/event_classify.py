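"""Assign collinear blocks to polyploidy/speciation events by median Ks and
infer polyploidy multiplicity from ortholog depth.

A genome that underwent only the shared hexaploidization shows one wave of
paralogous blocks; an extra tetraploidization adds a younger wave and doubles
the number of orthologous regions matching each region of an unduplicated
reference (a 1:2 depth ratio). Blocks are grouped by explicit Ks windows —
supplied by the user or suggested from a 1-D Gaussian mixture over block
medians — replacing by-eye dotplot rectangles with a reproducible rule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .collinearity import CollinearBlock
from .genome_io import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventLabel:
    name: str
    low: float
    high: float

    def contains(self, value: float) -> bool:
        return self.low <= value < self.high


@dataclass
class DepthProfile:
    reference_tag: str
    # (chromosome, window start rank, window end rank inclusive, depth)
    records: list[tuple[str, int, int, int]]

    def depths(self) -> np.ndarray:
        return np.array([r[3] for r in self.records], dtype=int)


@dataclass(frozen=True)
class PloidyCall:
    multiplicity: int
    support: float  # share of nonzero windows at the modal depth
    n_windows: int
    interpretation: str


def partition_blocks(
    blocks: list[CollinearBlock], windows: list[EventLabel]
) -> list[CollinearBlock]:
    """Label each block by the unique Ks window containing its median.

    Blocks with no defined median, flagged blocks, and medians falling
    between windows stay "unassigned". Overlapping windows are a
    configuration error.
    """
    ordered = sorted(windows, key=lambda w: w.low)
    for w1, w2 in zip(ordered, ordered[1:]):
        if w2.low < w1.high:
            raise ValueError(f"overlapping Ks windows: {w1.name} and {w2.name}")
    for block in blocks:
        block.event = "unassigned"
        if block.flagged or block.median_ks is None:
            continue
        for w in ordered:
            if w.contains(block.median_ks):
                block.event = w.name
                break
    return blocks


def suggest_windows(
    median_ks: list[float],
    n_components: int,
    names: list[str] | None = None,
    seed: int = 0,
    n_sigma: float = 3.0,
) -> list[EventLabel]:
    """Suggest event windows from a 1-D Gaussian mixture over log block
    medians (event-related Ks scatter is close to log-normal).

    Windows span mean ± ``n_sigma`` sd per component on the log scale,
    back-transformed, truncated where neighbouring windows would overlap
    (at the sd-weighted midpoint of the log means). If two component
    means land closer than 0.1 in Ks the mixture has collapsed: a warning
    is logged and a single window covering everything is returned.
    """
    values = np.asarray(median_ks, dtype=float)
    values = values[values > 0]
    if len(values) < 10:
        raise ValueError("need at least 10 positive block medians to suggest windows")
    log_values = np.log(values)
    spread = log_values.std()
    names = names or [f"peak{i + 1}" for i in range(n_components)]
    if n_components == 1 or spread < 1e-12:
        mu, sd = log_values.mean(), max(spread, 1e-6)
        return [EventLabel(names[0], float(np.exp(mu - n_sigma * sd)),
                           float(np.exp(mu + n_sigma * sd)))]
    gm = GaussianMixture(n_components=n_components, random_state=seed, n_init=5)
    gm.fit(log_values.reshape(-1, 1))
    mus = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(mus)
    mus, sds = mus[order], sds[order]
    if np.min(np.diff(np.exp(mus))) < 0.1:
        logger.warning(
            "mixture components collapsed (means %s); returning a single window",
            np.exp(mus),
        )
        return [EventLabel(names[0], float(values.min()) - 1e-9,
                           float(values.max()) + 1e-9)]
    weights = gm.weights_.ravel()[order]
    lows = mus - n_sigma * sds
    highs = mus + n_sigma * sds
    for i in range(len(mus) - 1):
        if highs[i] > lows[i + 1]:  # truncate at the mixture decision boundary
            cut = _density_boundary(mus[i], sds[i], weights[i],
                                    mus[i + 1], sds[i + 1], weights[i + 1])
            highs[i] = min(highs[i], cut)
            lows[i + 1] = max(lows[i + 1], cut)
    return [
        EventLabel(names[i], float(np.exp(lows[i])), float(np.exp(highs[i])))
        for i in range(len(mus))
    ]


def _density_boundary(m1, s1, w1, m2, s2, w2) -> float:
    """Equal-posterior point of two weighted Gaussians between their means
    (falls back to the sd-weighted midpoint if no root lies between)."""
    a = 0.5 * (1.0 / s2**2 - 1.0 / s1**2)
    b = m1 / s1**2 - m2 / s2**2
    c = (0.5 * (m2**2 / s2**2 - m1**2 / s1**2)
         + np.log((w1 * s2) / (w2 * s1)))
    roots = np.roots([a, b, c]) if abs(a) > 1e-12 else np.array([-c / b])
    real = [float(r.real) for r in np.atleast_1d(roots)
            if abs(r.imag) < 1e-9 and m1 < r.real < m2]
    if real:
        return min(real, key=lambda r: abs(r - (m1 + m2) / 2))
    return (m1 * s2 + m2 * s1) / (s1 + s2)


def depth_profile(
    reference: Genome,
    blocks: list[CollinearBlock],
    window_genes: int = 100,
    event: str | None = None,
) -> DepthProfile:
    """Count, per reference window, the distinct collinear block footprints
    from the target genome that overlap it.

    ``blocks`` should be the orthologous (speciation-labeled) blocks of one
    reference/target comparison; pass ``event`` to filter by label. The
    reference side of each block is recognised by species tag.
    """
    if event is not None:
        blocks = [b for b in blocks if b.event == event]
    footprints: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for b in blocks:
        if b.genome_a == reference.species_tag:
            chrom, lo_hi, target = b.chrom_a, b.footprint_a(), b.chrom_b
        elif b.genome_b == reference.species_tag:
            chrom, lo_hi, target = b.chrom_b, b.footprint_b(), b.chrom_a
        else:
            raise ValueError(f"block {b.id} does not involve {reference.species_tag}")
        footprints.setdefault(chrom, {}).setdefault(target, []).append(lo_hi)
    records = []
    for chrom in reference.chromosomes:
        regions = []
        for target in sorted(footprints.get(chrom, {})):
            regions.extend(_chain_layers(footprints[chrom][target]))
        n = len(reference.genes_on(chrom))
        for start in range(0, n, window_genes):
            end = min(start + window_genes, n) - 1
            depth = sum(1 for lo, hi in regions if lo <= end and hi >= start)
            records.append((chrom, start, end, depth))
    return DepthProfile(reference_tag=reference.species_tag, records=records)


def _chain_layers(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge non-overlapping footprints from one target chromosome into
    chains (fragments of a single broken collinear run); footprints that
    stack on the same reference interval are genuinely distinct regions
    and stay in separate layers. Returns one spanning interval per layer."""
    layers: list[list[tuple[int, int]]] = []
    for lo, hi in sorted(intervals):
        for layer in layers:
            if layer[-1][1] < lo:
                layer.append((lo, hi))
                break
        else:
            layers.append([(lo, hi)])
    return [(layer[0][0], max(h for _, h in layer)) for layer in layers]


def infer_ploidy(profile: DepthProfile) -> PloidyCall:
    """Modal ortholog depth over nonzero windows, with its supporting share.

    Against an unduplicated reference, depth 1 means no extra polyploidy,
    depth 2 a tetraploidization after the shared event, depth 3 a
    hexaploidization.
    """
    depths = [d for d in profile.depths() if d > 0]
    if not depths:
        raise ValueError("no reference window has orthologous coverage")
    if len(depths) < 10:
        logger.warning("only %d nonzero windows; ploidy call may be unstable", len(depths))
    counts = Counter(depths)
    top = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    multiplicity = int(top[0])
    interpretation = {
        1: "no extra polyploidy",
        2: "tetraploidization after the shared event",
        3: "hexaploidization",
    }.get(multiplicity, f"{multiplicity}-fold multiplication")
    return PloidyCall(
        multiplicity=multiplicity,
        support=top[1] / len(depths),
        n_windows=len(depths),
        interpretation=interpretation,
    )


def write_depth_profile(profile: DepthProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chromosome\twindow_start_rank\twindow_end_rank\tdepth\n")
        for chrom, lo, hi, depth in profile.records:
            fh.write(f"{chrom}\t{lo}\t{hi}\t{depth}\n")
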