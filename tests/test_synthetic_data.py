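import numpy as np
import pytest

from paleowgd.fractionation import fit_geometric, spectrum_from_lengths
from paleowgd.genome_io import load_genome, load_hits
from paleowgd.ks_engine import pair_ks
from paleowgd.synthetic_data import (
    LossSpec,
    SimConfig,
    mutate_cds,
    simulate_history,
    truth_report,
    write_bundle,
)
from paleowgd import _codon

TINY = dict(seed=5, ancestral_genes=140, ancestral_chromosomes=7, codons_per_gene=60)


class TestMutateCds:
    def test_zero_target_is_identity(self):
        cds = "ATGGCTGAATTGGGTCATAAGCCTTGGCTT"
        assert mutate_cds(cds, 0.0, 0.0, seed=1) == cds

    def test_recovery_within_binomial_noise(self):
        rng = np.random.default_rng(16)
        root = _codon.decode_codons(rng.choice(_codon.SENSE_INDICES, size=500))
        mutated = mutate_cds(root, 0.2, 0.02, seed=17)
        res = pair_ks(root, mutated)
        assert 0.15 <= res.ks <= 0.25
        assert res.ka < 0.06

    def test_never_creates_stop_codons(self):
        rng = np.random.default_rng(18)
        root = _codon.decode_codons(rng.choice(_codon.SENSE_INDICES, size=200))
        mutated = mutate_cds(root, 1.0, 0.1, seed=19)
        assert not _codon.IS_STOP[_codon.encode_cds(mutated)].any()

    def test_target_beyond_saturation_rejected(self):
        with pytest.raises(ValueError, match="saturation"):
            mutate_cds("ATGGCTGAA", 5.0, 0.0, seed=0)


class TestSimulateHistory:
    def test_deterministic_for_a_seed(self):
        a = simulate_history(SimConfig(**TINY))
        b = simulate_history(SimConfig(**TINY))
        assert {t: sorted(g.genes) for t, g in a.genomes.items()} == {
            t: sorted(g.genes) for t, g in b.genomes.items()}
        ga = a.genomes["A"].genes
        gb = b.genomes["A"].genes
        assert all(ga[k].cds == gb[k].cds for k in ga)
        assert a.truth.event_ks == b.truth.event_ks
        assert a.hits[("V", "A")] == b.hits[("V", "A")]

    def test_tetraploid_gene_count_matches_expectation(self, small_bundle):
        cfg = small_bundle.config
        expected = cfg.ancestral_genes * 3 * 2 * cfg.tetraploidy_loss.retention
        assert abs(small_bundle.genomes["A"].n_genes - expected) <= 0.1 * expected

    def test_full_retention_means_no_deletions(self):
        cfg = SimConfig(**{**TINY, "tetraploidy_loss": LossSpec(0.4, 1.0)})
        bundle = simulate_history(cfg)
        assert bundle.genomes["A"].n_genes == cfg.ancestral_genes * 6
        assert all(not d for d in bundle.truth.run_draws.values())
        assert all(r == 1.0 for r in bundle.truth.retention["A"].values())

    def test_unreachable_retention_rejected_before_generation(self):
        cfg = dict(TINY)
        cfg["tetraploidy_loss"] = LossSpec(p=0.01, retention=0.35)
        with pytest.raises(ValueError, match="unreachable retention"):
            simulate_history(SimConfig(**cfg))

    def test_every_gene_traces_to_one_ancestor_and_copy_sets_partition(
            self, small_bundle):
        truth = small_bundle.truth
        for tag, genome in small_bundle.genomes.items():
            seen = {}
            for gid in genome.genes:
                anc = truth.ancestor[gid]
                cs = truth.subgenome[gid]
                assert (anc, cs) not in seen, "two genes from one ancestor slot"
                seen[(anc, cs)] = gid

    def test_event_ordering_validated(self):
        cfg = dict(TINY)
        cfg["event_times"] = {"ech": 0.3, "split1": 0.4, "split2": 0.2, "wgd": 0.1}
        with pytest.raises(ValueError, match="decreasing"):
            SimConfig(**cfg)


class TestTruth:
    def test_truth_report_quantities(self, small_bundle):
        report = truth_report(small_bundle)
        assert report["depth_mode"]["V-A"] == 2
        assert report["depth_mode"]["T-A"] == 2
        spectrum = {int(k): v for k, v in report["run_length_spectrum"].items()}
        draws = [l for tag in small_bundle.truth.run_draws
                 for l in small_bundle.truth.run_draws[tag]]
        assert sum(spectrum.values()) == len(draws)

    def test_truth_spectrum_refit_recovers_p(self, small_bundle):
        draws = [l for tag in small_bundle.truth.run_draws
                 for l in small_bundle.truth.run_draws[tag]]
        fit = fit_geometric(spectrum_from_lengths(draws, l_max=15))
        p = small_bundle.config.tetraploidy_loss.p
        se = p * np.sqrt((1 - p) / len(draws))
        assert fit.p == pytest.approx(p, abs=max(0.02, 3 * se))

    def test_truth_pairs_are_superset_of_detectable_homology(self, small_bundle):
        truth_ids = {frozenset((p.gene_a, p.gene_b))
                     for p in small_bundle.truth.pairs}
        spurious = 0
        for key, bucket in small_bundle.hits.items():
            for h in bucket:
                if frozenset((h.query_gene, h.subject_gene)) not in truth_ids:
                    spurious += 1
        total = sum(len(b) for b in small_bundle.hits.values())
        # only the configured spurious fraction lies outside truth homology
        assert spurious / total < 3 * small_bundle.config.spurious_hit_rate


class TestWriteBundle:
    def test_files_roundtrip_through_the_io_layer(self, small_bundle, tmp_path):
        write_bundle(small_bundle, tmp_path)
        for tag, genome in small_bundle.genomes.items():
            loaded = load_genome(tmp_path / f"{tag}.gff3",
                                 tmp_path / f"{tag}.cds.fasta", species_tag=tag)
            assert set(loaded.genes) == set(genome.genes)
            for gid in list(genome.genes)[:50]:
                assert loaded.genes[gid].rank == genome.genes[gid].rank
                assert loaded.genes[gid].cds == genome.genes[gid].cds
        hits = load_hits(tmp_path / "V_A.hits.tsv", top_n=0)
        assert len(hits) > 0
        assert (tmp_path / "truth.json").exists()
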