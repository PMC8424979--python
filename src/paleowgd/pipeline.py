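"""End-to-end orchestration: inputs (or a simulated bundle) to reports.

Stages: load/simulate → block detection → Ks annotation → event windowing
and block labeling → ortholog depth and ploidy → homology tables (primary
and optional secondary reference) → fractionation statistics → Ks peaks,
rate correction, and dating. Every stage writes its tabular output under
the run directory and contributes to a summary JSON that is a pure
function of (inputs, configuration, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import event_classify, fractionation, homology_table, peaks_dating
from .collinearity import CollinearBlock, detect_blocks, summarize_blocks, write_blocks
from .genome_io import Genome, filter_hits, load_genome, load_hits
from .ks_engine import annotate_block_ks, write_ks_table
from .reporting import percent_increase

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str | Path = "paleowgd_run"
    reference: str = "V"  # slowest unduplicated diploid; dating reference
    secondary_reference: str | None = "T"
    polyploid: str = "A"  # lineage whose extra multiplication is inferred
    species: dict[str, dict] = field(default_factory=dict)  # tag -> annotation/cds paths
    hits: dict[str, str] = field(default_factory=dict)  # "V-T" -> hit table path
    simulate: dict | None = None  # SimConfig keywords; alternative to paths
    seed: int = 0
    evalue_cutoff: float = 1e-5
    top_n: int = 5
    max_gap: int = 50
    min_pairs: int = 4
    block_thresholds: tuple[int, ...] = (4, 10, 20, 50)
    window_genes: int = 100
    l_max: int = 15
    calibration: tuple[float, float] = peaks_dating.DEFAULT_CALIBRATION
    windows: dict[str, list] | str = "auto"  # or {"A": [["AST",lo,hi],...], "V-A": ...}

    def __post_init__(self) -> None:
        lo, hi = self.calibration
        if not lo < hi:
            raise ValueError("calibration interval must have low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, bundle=None) -> dict:
    """Run every stage and return the summary dictionary (also written to
    ``outdir/summary.json`` along with all per-stage outputs)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    summary: dict = {"config": {"seed": config.seed, "max_gap": config.max_gap,
                                "min_pairs": config.min_pairs,
                                "calibration": list(config.calibration)}}

    def emit(name: str) -> Path:
        manifest.append(name)
        return outdir / name

    # ---- stage: inputs
    try:
        genomes, hits, sim_bundle = _obtain_inputs(config, bundle)
    except StageError:
        raise
    except Exception as err:
        raise StageError("inputs", err) from err
    tags = sorted(genomes)
    summary["genomes"] = {tag: genomes[tag].n_genes for tag in tags}

    # ---- stage: collinearity
    try:
        blocks: dict[tuple[str, str], list[CollinearBlock]] = {}
        for key in sorted(hits):
            blocks[key] = detect_blocks(
                hits[key], genomes[key[0]], genomes[key[1]],
                max_gap=config.max_gap, min_pairs=config.min_pairs,
            )
        summary["blocks"] = {
            f"{a}-{b}": [s.__dict__ for s in summarize_blocks(
                blocks[(a, b)], list(config.block_thresholds))]
            for a, b in blocks
        }
    except Exception as err:
        raise StageError("collinearity", err) from err

    # ---- stage: ks
    try:
        for key in sorted(blocks):
            for g in (genomes[key[0]], genomes[key[1]]):
                _require_cds(g)
            annotate_block_ks(blocks[key], {t: genomes[t] for t in set(key)})
            write_ks_table(blocks[key], emit(f"ks_{key[0]}_{key[1]}.tsv"))
    except Exception as err:
        raise StageError("ks", err) from err

    # ---- stage: classify
    try:
        windows = _event_windows(config, blocks)
        for key in sorted(blocks):
            event_classify.partition_blocks(blocks[key], windows[_wkey(key, config)])
            write_blocks(blocks[key], emit(f"blocks_{key[0]}_{key[1]}.tsv"))
        summary["windows"] = {
            k: [[w.name, round(w.low, 4), round(w.high, 4)] for w in ws]
            for k, ws in sorted(windows.items())
        }
    except Exception as err:
        raise StageError("classify", err) from err

    # ---- stage: ploidy
    try:
        ploidy = {}
        poly = config.polyploid
        for ref_tag in [config.reference, config.secondary_reference]:
            if ref_tag is None or ref_tag == poly:
                continue
            key = _pair_key(ref_tag, poly, blocks)
            profile = event_classify.depth_profile(
                genomes[ref_tag], blocks[key], window_genes=config.window_genes,
                event=f"ortholog:{key[0]}-{key[1]}",
            )
            event_classify.write_depth_profile(profile, emit(f"depth_{ref_tag}.tsv"))
            call = event_classify.infer_ploidy(profile)
            ploidy[ref_tag] = call.__dict__
        summary["ploidy"] = ploidy
        (emit("ploidy.json")).write_text(json.dumps(ploidy, indent=1))
    except Exception as err:
        raise StageError("ploidy", err) from err

    # ---- stage: tables + fractionation
    try:
        summary["tables"] = {}
        summary["fractionation"] = {}
        for ref_tag in [config.reference, config.secondary_reference]:
            if ref_tag is None or ref_tag == poly:
                continue
            mult = ploidy.get(ref_tag, {}).get("multiplicity", 2)
            others = tuple(
                (t, mult if t == poly else 1) for t in tags if t != ref_tag
            )
            spec = homology_table.TableSpec(reference_tag=ref_tag, others=others)
            table = homology_table.build_table(spec, genomes[ref_tag], blocks)
            homology_table.write_table(table, emit(f"table_{ref_tag}.tsv"))
            homology_table.write_provenance(table, emit(f"provenance_{ref_tag}.tsv"))
            graph = homology_table.export_alignment_graph(table, "circular")
            graph.to_csv(emit(f"alignment_graph_{ref_tag}.tsv"), sep="\t", index=False)
            stats_df = homology_table.column_stats(table)
            stats_df.to_csv(emit(f"column_stats_{ref_tag}.tsv"), sep="\t")
            summary["tables"][ref_tag] = {
                "n_rows": table.n_rows, "n_columns": len(table.data.columns),
                "conflicts": table.conflicts,
                "retention": {c: round(float(r), 4)
                              for c, r in stats_df["retention"].items()},
            }
            summary["fractionation"][ref_tag] = _fractionation_stage(
                table, poly, mult, config, emit)
    except Exception as err:
        raise StageError("table/fractionation", err) from err

    # ---- stage: peaks + dating
    try:
        summary["dating"] = _dating_stage(config, blocks, windows, emit)
    except Exception as err:
        raise StageError("dating", err) from err

    if sim_bundle is not None:
        from .synthetic_data import truth_report

        (emit("truth.json")).write_text(json.dumps(truth_report(sim_bundle), indent=1))
    (outdir / "manifest.json").write_text(json.dumps(sorted(manifest), indent=1))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _require_cds(genome: Genome) -> None:
    if not any(g.cds for g in genome.genes.values()):
        raise ValueError(
            f"genome {genome.species_tag} has no CDS attached; provide a cds "
            "FASTA path to estimate Ks"
        )


def _obtain_inputs(config: PipelineConfig, bundle):
    if bundle is None and config.simulate is not None:
        from .synthetic_data import SimConfig, simulate_history

        kwargs = dict(config.simulate)
        kwargs.setdefault("seed", config.seed)
        bundle = simulate_history(SimConfig(**kwargs))
    if bundle is not None:
        genomes = bundle.genomes
        hits = {
            key: filter_hits(raw, evalue_cutoff=config.evalue_cutoff,
                             top_n=config.top_n)
            for key, raw in bundle.hits.items()
        }
        return genomes, hits, bundle
    genomes = {}
    for tag, paths in config.species.items():
        genomes[tag] = load_genome(paths["annotation"], paths.get("cds"), species_tag=tag)
    hits = {}
    for name, path in config.hits.items():
        a, b = name.split("-")
        hits[(a, b)] = load_hits(path, evalue_cutoff=config.evalue_cutoff,
                                 top_n=config.top_n)
    if not genomes or not hits:
        raise ValueError("no inputs: provide species/hits paths or a simulate block")
    return genomes, hits, None


def _wkey(key: tuple[str, str], config: PipelineConfig) -> str:
    return key[0] if key[0] == key[1] else f"{key[0]}-{key[1]}"


def _pair_key(a: str, b: str, blocks) -> tuple[str, str]:
    return (a, b) if (a, b) in blocks else (b, a)


def _event_windows(config: PipelineConfig, blocks) -> dict[str, list]:
    """Per-comparison Ks windows: user-specified, or suggested by a Gaussian
    mixture over block medians (two waves for the polyploid self-comparison
    and for cross comparisons, one for unduplicated self-comparisons)."""
    windows: dict[str, list] = {}
    if isinstance(config.windows, dict):
        for name, spec in config.windows.items():
            windows[name] = [event_classify.EventLabel(n, lo, hi) for n, lo, hi in spec]
        return windows
    for key in sorted(blocks):
        name = _wkey(key, config)
        medians = [b.median_ks for b in blocks[key]
                   if b.median_ks is not None and not b.flagged]
        if key[0] == key[1]:
            labels = (["AST", "ECH"] if key[0] == config.polyploid else ["ECH"])
        else:
            labels = [f"ortholog:{key[0]}-{key[1]}", f"outparalog:{key[0]}-{key[1]}"]
        if len(medians) < 10:
            logger.warning("%s: only %d block medians; labeling all as %s",
                           name, len(medians), labels[0])
            lo = min(medians, default=0.0) - 1e-9
            hi = max(medians, default=1.0) + 1e-9
            windows[name] = [event_classify.EventLabel(labels[0], lo, hi)]
            continue
        windows[name] = event_classify.suggest_windows(
            medians, n_components=len(labels), names=labels, seed=config.seed,
        )
    return windows


def _fractionation_stage(table, poly, mult, config, emit) -> dict:
    losses = fractionation.loss_rates(table)
    losses.to_csv(emit(f"loss_rates_{table.spec.reference_tag}.tsv"), sep="\t", index=False)
    out = {}
    poly_cols = [c for c in table.data.columns if c.split("-")[0] == poly]
    poly_losses = losses[losses["column"].isin(poly_cols)]["loss"]
    if len(poly_losses):
        out["loss_range"] = [round(float(poly_losses.min()), 4),
                             round(float(poly_losses.max()), 4)]
    spectra = [fractionation.run_lengths(table, c, l_max=config.l_max) for c in poly_cols]
    spectrum = fractionation.merge_spectra(spectra)
    fractionation.write_spectrum(spectrum, emit(f"spectrum_{table.spec.reference_tag}.tsv"))
    fit = fractionation.fit_geometric(spectrum)
    out["geometric"] = {k: (round(v, 4) if isinstance(v, float) else v)
                        for k, v in fit.__dict__.items()}
    out["mean_run_length"] = round(spectrum.mean_length(), 4)
    return out


def _dating_stage(config, blocks, windows, emit) -> dict:
    poly = config.polyploid
    tags = sorted({t for key in blocks for t in key})
    # values are selected by block event label, so the KDE range only crops
    # saturation-side outliers; the windows themselves stay out of the fit
    fit_range = (0.05, 3.5)
    ech_peaks = {}
    peak_report = {}
    for tag in tags:
        ks_values = _event_ks_values(blocks[(tag, tag)], "ECH")
        peak = peaks_dating.fit_peak(ks_values, ks_range=fit_range)
        ech_peaks[tag] = peak
        peak_report[f"ECH:{tag}"] = _peak_dict(peak)
    correction = peaks_dating.correct_rates(ech_peaks)
    ref = correction.reference_tag
    excesses = {}
    for tag in tags:
        if tag != ref:
            excesses[f"{tag}_vs_{ref}"] = round(
                peaks_dating.rate_excess(ech_peaks[tag].mu, ech_peaks[ref].mu), 2)
    mu_cal = correction.adjust_peak(ref, ech_peaks[ref].mu)

    dates = {}
    ast_values = _event_ks_values(blocks[(poly, poly)], "AST")
    if len(ast_values) >= 30:
        peak = peaks_dating.fit_peak(ast_values, ks_range=fit_range)
        peak_report[f"AST:{poly}"] = _peak_dict(peak)
        adjusted = correction.adjust_peak(poly, peak.mu)
        est = peaks_dating.date_event(adjusted, mu_cal,
                                      calibration=config.calibration, event="AST")
        dates["AST"] = _date_dict(est)
    for key in sorted(blocks):
        if key[0] == key[1]:
            continue
        label = f"ortholog:{key[0]}-{key[1]}"
        values = _event_ks_values(blocks[key], label)
        if len(values) < 30:
            continue
        peak = peaks_dating.fit_peak(values, ks_range=fit_range)
        peak_report[label] = _peak_dict(peak)
        adjusted = correction.adjust_cross_peak(key[0], key[1], peak.mu)
        est = peaks_dating.date_event(adjusted, mu_cal,
                                      calibration=config.calibration,
                                      event=f"split:{key[0]}-{key[1]}")
        dates[f"split:{key[0]}-{key[1]}"] = _date_dict(est)
    report = {
        "peaks": peak_report,
        "rate_reference": ref,
        "rate_factors": {t: round(f, 4) for t, f in correction.factors.items()},
        "rate_excess_percent": excesses,
        "dates": dates,
    }
    (emit("dating.json")).write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _event_ks_values(block_list, event: str) -> list[float]:
    values = []
    for b in block_list:
        if b.event != event:
            continue
        values.extend(v for v in b.ks if v is not None and np.isfinite(v))
    return values


def _peak_dict(peak) -> dict:
    return {"mu": round(peak.mu, 4), "sigma": round(peak.sigma, 4),
            "r2": round(peak.r2, 4), "n": peak.n}


def _date_dict(est) -> dict:
    return {"t_low": est.t_low, "t_high": est.t_high,
            "peak_ratio": round(est.peak_ratio, 4),
            "calibration": list(est.calibration)}


def export_dotplot(
    block_list: list[CollinearBlock], genome_a: Genome, genome_b: Genome,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-pair dotplot records in genome-wide rank coordinates with the
    block's event label as the color key, plus chromosome offsets so a
    plotting layer can draw boundary guides."""
    offsets_a = _chrom_offsets(genome_a)
    offsets_b = _chrom_offsets(genome_b)
    records = []
    for b in block_list:
        for (ga, gb), ra, rb, ks in zip(b.pairs, b.ranks_a, b.ranks_b, b.ks):
            records.append({
                "gene_a": ga, "gene_b": gb,
                "chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                "rank_a": ra, "rank_b": rb,
                "x": offsets_a[b.chrom_a] + ra, "y": offsets_b[b.chrom_b] + rb,
                "ks": np.nan if ks is None else ks,
                "event": b.event, "block_id": b.id,
            })
    df = pd.DataFrame(records, columns=["gene_a", "gene_b", "chrom_a", "chrom_b",
                                        "rank_a", "rank_b", "x", "y", "ks",
                                        "event", "block_id"])
    if path is not None:
        with open(path, "w") as fh:
            for chrom, off in offsets_a.items():
                fh.write(f"#boundary_a\t{chrom}\t{off}\n")
            for chrom, off in offsets_b.items():
                fh.write(f"#boundary_b\t{chrom}\t{off}\n")
            df.to_csv(fh, sep="\t", index=False)
    return df


def _chrom_offsets(genome: Genome) -> dict[str, int]:
    offsets = {}
    total = 0
    for chrom in genome.chromosomes:
        offsets[chrom] = total
        total += len(genome.genes_on(chrom))
    return offsets
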