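"""Standard-genetic-code lookup tables shared by the Ks engine and the simulator.

All tables are indexed by codon index 0..63 (base-4 encoding of the codon with
A=0, C=1, G=2, T=3 at each position). Pathway-averaged difference counts for
codon pairs follow the Nei–Gojobori convention: minimal mutational pathways are
weighted uniformly, pathways passing through a stop codon are excluded.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CODONS: list[str] = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: amino acid per codon, "*" for stops
AA: list[str] = [
    "*" if c in STOP_CODONS else standard_dna_table.forward_table[c] for c in CODONS
]

IS_STOP = np.array([a == "*" for a in AA], dtype=bool)
SENSE_INDICES = np.flatnonzero(~IS_STOP)


def encode_codon(codon: str) -> int:
    return (
        16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]
    )


def _mutate(codon: str, pos: int, base: str) -> str:
    return codon[:pos] + base + codon[pos + 1 :]


def _synonymous_fraction(codon: str) -> float:
    """NG86 synonymous site count for one codon.

    Each position contributes the fraction of its 3 possible single-base
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    aa = AA[CODON_INDEX[codon]]
    s = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = _mutate(codon, pos, base)
            if AA[CODON_INDEX[alt]] == aa:  # stops never match a sense aa
                s += 1.0
    return s / 3.0


#: synonymous sites per codon (nonsynonymous = 3 - SYN_SITES); 0.0 for stops
SYN_SITES = np.array(
    [0.0 if AA[i] == "*" else _synonymous_fraction(c) for i, c in enumerate(CODONS)]
)


@lru_cache(maxsize=None)
def pair_differences(i: int, j: int) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two codons.

    Uses a dynamic program over subsets of the differing positions: a state is
    the set of positions already switched to the target base, and the DP
    accumulates, over every valid mutation ordering, the number of orderings
    and the summed synonymous/nonsynonymous step counts. Orderings whose
    intermediate codons are stops are invalid. If every ordering is invalid
    (cannot occur for sense-to-sense pairs under the standard code) all
    orderings are used as a fallback.
    """
    a, b = CODONS[i], CODONS[j]
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    return _subset_dp(a, b, tuple(diff), skip_stops=True) or _subset_dp(
        a, b, tuple(diff), skip_stops=False
    )


def _subset_dp(
    a: str, b: str, diff: tuple[int, ...], skip_stops: bool
) -> tuple[float, float] | None:
    k = len(diff)
    full = (1 << k) - 1
    # state -> (n_orderings, sum_sd, sum_nd); intermediate stop states dropped
    states: dict[int, tuple[int, float, float]] = {0: (1, 0.0, 0.0)}
    for _ in range(k):
        nxt: dict[int, tuple[int, float, float]] = {}
        for mask, (n, sd, nd) in states.items():
            cur = _apply_mask(a, b, diff, mask)
            cur_aa = AA[CODON_INDEX[cur]]
            for t in range(k):
                if mask & (1 << t):
                    continue
                new_mask = mask | (1 << t)
                new = _apply_mask(a, b, diff, new_mask)
                new_aa = AA[CODON_INDEX[new]]
                if skip_stops and new_aa == "*" and new_mask != full:
                    continue
                syn = 1.0 if new_aa == cur_aa else 0.0
                pn, psd, pnd = nxt.get(new_mask, (0, 0.0, 0.0))
                nxt[new_mask] = (pn + n, psd + sd + n * syn, pnd + nd + n * (1.0 - syn))
        states = nxt
    if full not in states:
        return None
    n, sd, nd = states[full]
    return sd / n, nd / n


def _apply_mask(a: str, b: str, diff: tuple[int, ...], mask: int) -> str:
    out = list(a)
    for t, p in enumerate(diff):
        if mask & (1 << t):
            out[p] = b[p]
    return "".join(out)


def _build_pair_tables() -> tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i in SENSE_INDICES:
        for j in SENSE_INDICES:
            if i <= j:
                s, n = pair_differences(int(i), int(j))
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = n
    return sd, nd


_PAIR_TABLES: tuple[np.ndarray, np.ndarray] | None = None


def pair_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 (sd, nd) lookup tables over sense-codon pairs (lazily built)."""
    global _PAIR_TABLES
    if _PAIR_TABLES is None:
        _PAIR_TABLES = _build_pair_tables()
    return _PAIR_TABLES


def encode_cds(cds: str) -> np.ndarray:
    """Encode an in-frame CDS as an array of codon indices."""
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    arr = np.frombuffer(cds.upper().encode(), dtype="S1")
    idx = np.zeros(arr.shape, dtype=np.int64)
    for base, val in _BASE_INDEX.items():
        idx[arr == base.encode()] = val
    unknown = ~np.isin(arr, [b.encode() for b in BASES])
    if unknown.any():
        raise ValueError(f"non-ACGT base in CDS at position {int(np.flatnonzero(unknown)[0])}")
    idx = idx.reshape(-1, 3)
    return 16 * idx[:, 0] + 4 * idx[:, 1] + idx[:, 2]


def decode_codons(indices: np.ndarray) -> str:
    return "".join(CODONS[int(i)] for i in indices)
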