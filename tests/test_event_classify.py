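import numpy as np
import pytest

from paleowgd.collinearity import CollinearBlock
from paleowgd.event_classify import (
    DepthProfile,
    EventLabel,
    depth_profile,
    infer_ploidy,
    partition_blocks,
    suggest_windows,
)
from paleowgd.genome_io import GeneModel, Genome


def stub_block(i, median, flagged=False, chrom_a="r1", chrom_b="t1",
               ranks_a=None, genome_a="R", genome_b="T"):
    ranks_a = ranks_a if ranks_a is not None else [0, 1, 2, 3]
    b = CollinearBlock(id=i, genome_a=genome_a, genome_b=genome_b,
                       chrom_a=chrom_a, chrom_b=chrom_b,
                       pairs=[("x", "y")] * len(ranks_a), ranks_a=ranks_a,
                       ranks_b=list(range(len(ranks_a))), orientation="+")
    b.median_ks = median
    b.flagged = flagged
    return b


class TestPartition:
    WINDOWS = [EventLabel("AST", 0.4, 1.2), EventLabel("ECH", 1.4, 2.6)]

    def test_blocks_fall_into_containing_window(self):
        blocks = partition_blocks([stub_block(0, 0.6), stub_block(1, 0.7)],
                                  self.WINDOWS)
        assert [b.event for b in blocks] == ["AST", "AST"]

    def test_median_between_windows_is_unassigned(self):
        blocks = partition_blocks([stub_block(0, 1.3)], self.WINDOWS)
        assert blocks[0].event == "unassigned"

    def test_flagged_or_undefined_always_unassigned(self):
        blocks = partition_blocks(
            [stub_block(0, 0.6, flagged=True), stub_block(1, None)], self.WINDOWS)
        assert [b.event for b in blocks] == ["unassigned", "unassigned"]

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            partition_blocks([], [EventLabel("a", 0.1, 1.0),
                                  EventLabel("b", 0.8, 2.0)])

    def test_every_block_gets_exactly_one_label(self):
        rng = np.random.default_rng(0)
        blocks = [stub_block(i, float(m))
                  for i, m in enumerate(rng.uniform(0, 3, size=100))]
        partition_blocks(blocks, self.WINDOWS)
        names = {w.name for w in self.WINDOWS} | {"unassigned"}
        assert all(b.event in names for b in blocks)

    def test_simulated_waves_are_classified_to_true_wave(self):
        rng = np.random.default_rng(1)
        true = (["w1"] * 100) + (["w2"] * 100)
        medians = np.concatenate([
            np.exp(rng.normal(np.log(0.7), 0.1, 100)),
            np.exp(rng.normal(np.log(1.9), 0.15, 100)),
        ])
        windows = suggest_windows(list(medians), 2, names=["w1", "w2"], seed=0)
        blocks = [stub_block(i, float(m)) for i, m in enumerate(medians)]
        partition_blocks(blocks, windows)
        correct = sum(b.event == t for b, t in zip(blocks, true))
        assert correct >= 0.9 * len(blocks)


class TestSuggestWindows:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0.7, 0.1, 100),
                                 rng.normal(1.9, 0.3, 100)])
        w1, w2 = suggest_windows(list(values[values > 0]), 2, seed=0)
        center1 = np.sqrt(w1.low * w1.high)  # log-space window center
        center2 = np.sqrt(w2.low * w2.high)
        assert abs(center1 - 0.7) < 0.1
        assert abs(center2 - 1.9) < 0.1 or w2.low <= 1.9 <= w2.high

    def test_identical_values_give_single_degenerate_window(self):
        windows = suggest_windows([1.0] * 50, 2)
        assert len(windows) == 1
        assert windows[0].low <= 1.0 <= windows[0].high

    def test_unimodal_data_collapses_to_single_window(self):
        rng = np.random.default_rng(3)
        values = rng.normal(1.0, 0.02, 200)
        windows = suggest_windows(list(values), 2, seed=0)
        assert len(windows) == 1


def reference_genome(n=300, chrom="r1"):
    g = Genome(species_tag="R", chromosomes=[chrom])
    for i in range(n):
        g.genes[f"r{i}"] = GeneModel(f"r{i}", chrom, 1 + i * 10, 9 + i * 10, rank=i)
    return g


class TestDepth:
    def test_two_stacked_coverages_give_depth_two(self):
        ref = reference_genome(300)
        blocks = [
            stub_block(0, 1.0, chrom_b="t1", ranks_a=list(range(0, 300, 3))),
            stub_block(1, 1.0, chrom_b="t2", ranks_a=list(range(1, 300, 3))),
        ]
        profile = depth_profile(ref, blocks, window_genes=100)
        assert [r[3] for r in profile.records] == [2, 2, 2]

    def test_extra_small_block_raises_one_window(self):
        ref = reference_genome(300)
        blocks = [
            stub_block(0, 1.0, chrom_b="t1", ranks_a=list(range(0, 300, 3))),
            stub_block(1, 1.0, chrom_b="t2", ranks_a=list(range(1, 300, 3))),
            stub_block(2, 1.0, chrom_b="t3", ranks_a=[120, 121, 122, 123]),
        ]
        profile = depth_profile(ref, blocks, window_genes=100)
        assert [r[3] for r in profile.records] == [2, 3, 2]

    def test_fragmented_chain_counts_once(self):
        # two non-overlapping fragments from the same target chromosome are
        # one broken run, not two stacked regions
        ref = reference_genome(200)
        blocks = [
            stub_block(0, 1.0, chrom_b="t1", ranks_a=list(range(0, 90))),
            stub_block(1, 1.0, chrom_b="t1", ranks_a=list(range(110, 200))),
        ]
        profile = depth_profile(ref, blocks, window_genes=100)
        assert [r[3] for r in profile.records] == [1, 1]

    def test_depth_invariant_under_coordinate_reversal(self):
        ref = reference_genome(300)
        n = 300
        blocks = [
            stub_block(0, 1.0, chrom_b="t1", ranks_a=list(range(0, 140))),
            stub_block(1, 1.0, chrom_b="t2", ranks_a=list(range(100, 300, 2))),
        ]
        flipped = [
            stub_block(b.id, 1.0, chrom_b=b.chrom_b,
                       ranks_a=[n - 1 - r for r in b.ranks_a])
            for b in blocks
        ]
        d1 = sorted(depth_profile(ref, blocks, window_genes=100).depths())
        d2 = sorted(depth_profile(ref, flipped, window_genes=100).depths())
        assert list(d1) == list(d2)


class TestPloidy:
    def test_modal_depth_and_support(self):
        profile = DepthProfile("R", [("r1", i, i, d) for i, d in enumerate(
            [2] * 80 + [1] * 15 + [3] * 5)])
        call = infer_ploidy(profile)
        assert call.multiplicity == 2
        assert call.support == pytest.approx(0.80)
        assert "tetraploidization" in call.interpretation

    def test_all_depth_one_means_no_extra_polyploidy(self):
        profile = DepthProfile("R", [("r1", i, i, 1) for i in range(30)])
        call = infer_ploidy(profile)
        assert call.multiplicity == 1
        assert call.interpretation == "no extra polyploidy"

    def test_no_coverage_is_an_error(self):
        with pytest.raises(ValueError, match="no reference window"):
            infer_ploidy(DepthProfile("R", [("r1", 0, 99, 0)]))

    def test_simulated_tetraploid_called_correctly(self, small_run):
        _, summary, _ = small_run
        for call in summary["ploidy"].values():
            assert call["multiplicity"] == 2
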