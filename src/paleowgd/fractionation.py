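"""Post-polyploidy gene-loss statistics.

Fractionation removes duplicated genes in runs; along a reference genome the
missing collinear genes of a target column form runs of consecutive dots
whose length spectrum is close to geometric, P(L = l) = p(1-p)^(l-1). The
"extension parameter" p is the geometric success probability (mean run
1/p), fitted here by least squares of observed run counts against
N·p·(1-p)^(l-1), with a lack-of-fit F statistic against the multinomial
sampling variance expected under the fitted model (a large P value accepts
the geometric shape), plus a chi-square goodness of fit for cross-checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .genome_io import MISSING
from .homology_table import HomologyTable, _col_species_slot

logger = logging.getLogger(__name__)


@dataclass
class RunLengthSpectrum:
    counts: dict[int, int]  # run length (1..l_max) -> number of runs
    l_max: int
    excluded_long_runs: int = 0  # runs longer than l_max ("chromosome fragments")
    excluded_genes: int = 0  # total dots inside those excluded runs

    @property
    def n_runs(self) -> int:
        return sum(self.counts.values())

    @property
    def total_genes(self) -> int:
        return sum(l * c for l, c in self.counts.items()) + self.excluded_genes

    def mean_length(self) -> float:
        n = self.n_runs
        return sum(l * c for l, c in self.counts.items()) / n if n else float("nan")


@dataclass(frozen=True)
class GeometricFit:
    p: float  # extension parameter; mean run length = 1/p
    r2: float
    f_stat: float
    p_value: float  # lack-of-fit F test; large accepts the geometric model
    chi2: float
    chi2_p: float
    df: int
    n_runs: int


def loss_rates(table: HomologyTable) -> pd.DataFrame:
    """Per reference chromosome and target column: fraction of rows with a
    dot. Sibling column pairs additionally get a both-siblings-missing row
    (the row-wise AND of the dots).

    Complementarity with ``column_stats`` holds exactly: per column,
    loss = 1 - retention when computed over all chromosomes.
    """
    records = []
    chrom_of = table.reference_chromosome
    for chrom in chrom_of.unique():
        rows = chrom_of[chrom_of == chrom].index
        if len(rows) == 0:
            logger.warning("chromosome %s has no reference rows; skipped", chrom)
            continue
        sub = table.data.loc[rows]
        for col in table.data.columns[1:]:
            records.append({
                "chromosome": chrom, "column": col,
                "loss": float((sub[col] == MISSING).mean()), "n_rows": len(rows),
            })
        for sp, mult in table.spec.others:
            if mult < 2:
                continue
            for slot in range(3):
                cols = table.spec.columns_for(sp, slot)
                if not all(c in table.data.columns for c in cols):
                    continue
                both = (sub[cols[0]] == MISSING) & (sub[cols[1]] == MISSING)
                records.append({
                    "chromosome": chrom, "column": f"{sp}-slot{slot}-both-missing",
                    "loss": float(both.mean()), "n_rows": len(rows),
                })
    return pd.DataFrame(records)


def run_lengths(
    table: HomologyTable, column: str, l_max: int = 15
) -> RunLengthSpectrum:
    """Spectrum of maximal dot runs in one column along reference order.

    Runs never span reference chromosome boundaries; runs longer than
    ``l_max`` are counted (and their dots tallied) separately as presumed
    segmental losses rather than gene-by-gene fractionation.
    """
    values = table.data[column]
    chrom_of = table.reference_chromosome
    lengths: list[int] = []
    for chrom in chrom_of.unique():
        col = values[chrom_of[chrom_of == chrom].index]
        run = 0
        for v in col:
            if v == MISSING:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return spectrum_from_lengths(lengths, l_max=l_max)


def spectrum_from_lengths(lengths, l_max: int = 15) -> RunLengthSpectrum:
    counts: dict[int, int] = {}
    excluded = excluded_genes = 0
    for l in lengths:
        l = int(l)
        if l > l_max:
            excluded += 1
            excluded_genes += l
        elif l >= 1:
            counts[l] = counts.get(l, 0) + 1
    return RunLengthSpectrum(counts=counts, l_max=l_max,
                             excluded_long_runs=excluded, excluded_genes=excluded_genes)


def merge_spectra(spectra: list[RunLengthSpectrum]) -> RunLengthSpectrum:
    if not spectra:
        raise ValueError("no spectra to merge")
    l_max = spectra[0].l_max
    if any(s.l_max != l_max for s in spectra):
        raise ValueError("spectra have differing l_max")
    counts: dict[int, int] = {}
    for s in spectra:
        for l, c in s.counts.items():
            counts[l] = counts.get(l, 0) + c
    return RunLengthSpectrum(
        counts=counts, l_max=l_max,
        excluded_long_runs=sum(s.excluded_long_runs for s in spectra),
        excluded_genes=sum(s.excluded_genes for s in spectra),
    )


def fit_geometric(spectrum: RunLengthSpectrum, on_frequencies: bool = False) -> GeometricFit:
    """Least-squares fit of the run-length spectrum to a geometric law.

    Counts (default) or relative frequencies are fitted to
    N·p·(1-p)^(l-1) over l = 1..l_max with N fixed at the observed run
    total and p free. The lack-of-fit F statistic compares the residual
    mean square to the multinomial sampling variance expected under the
    fitted model; its upper-tail P value is large when the geometric
    shape is adequate.
    """
    n = spectrum.n_runs
    if n == 0:
        raise ValueError("empty spectrum")
    lengths = np.arange(1, spectrum.l_max + 1)
    observed = np.array([spectrum.counts.get(int(l), 0) for l in lengths], dtype=float)
    distinct = int((observed > 0).sum())
    if distinct == 1:
        return GeometricFit(p=1.0 if spectrum.counts.get(1) else 1.0, r2=1.0,
                            f_stat=0.0, p_value=1.0, chi2=0.0, chi2_p=1.0,
                            df=0, n_runs=n)
    if distinct < 3:
        logger.warning("only %d distinct run lengths; geometric fit is fragile", distinct)
    scale = 1.0 / n if on_frequencies else 1.0
    y = observed * scale

    def rss(p):
        model = n * p * (1.0 - p) ** (lengths - 1) * scale
        return float(((y - model) ** 2).sum())

    res = minimize_scalar(rss, bounds=(1e-6, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-10})
    p_hat = float(res.x)
    model = n * p_hat * (1.0 - p_hat) ** (lengths - 1)
    resid = observed - model
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    # lack-of-fit: residual mean square vs expected multinomial noise
    df = len(lengths) - 2  # one fitted parameter, N fixed
    pi = p_hat * (1.0 - p_hat) ** (lengths - 1)
    sampling_var = float((n * pi * (1.0 - pi)).mean())
    f_stat = float((resid**2).sum() / df) / sampling_var if sampling_var > 0 else np.inf
    p_value = float(stats.f.sf(f_stat, df, max(n - len(lengths), 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        chi_terms = np.where(model > 1e-12, (observed - model) ** 2 / model, 0.0)
    chi2 = float(chi_terms.sum())
    chi2_p = float(stats.chi2.sf(chi2, df))
    return GeometricFit(p=p_hat, r2=r2, f_stat=f_stat, p_value=p_value,
                        chi2=chi2, chi2_p=chi2_p, df=df, n_runs=n)


def write_spectrum(spectrum: RunLengthSpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("#run_length\tcount\n")
        for l in range(1, spectrum.l_max + 1):
            fh.write(f"{l}\t{spectrum.counts.get(l, 0)}\n")
        fh.write(f"#excluded_long_runs\t{spectrum.excluded_long_runs}\n")
        fh.write(f"#excluded_genes\t{spectrum.excluded_genes}\n")
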