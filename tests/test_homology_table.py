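import pandas as pd
import pytest

from paleowgd.collinearity import CollinearBlock
from paleowgd.genome_io import MISSING, GeneModel, Genome
from paleowgd.homology_table import (
    TableSpec,
    build_table,
    column_stats,
    export_alignment_graph,
    sibling_co_retention,
)


def linear_genome(tag, chrom_genes):
    """chrom_genes: {chrom: [gene ids in order]}"""
    g = Genome(species_tag=tag, chromosomes=list(chrom_genes))
    for chrom, ids in chrom_genes.items():
        for i, gid in enumerate(ids):
            g.genes[gid] = GeneModel(gid, chrom, 1 + i * 10, 9 + i * 10, rank=i)
    return g


def block(bid, ga, gb, ca, cb, pairs, ranks_a, ranks_b, event):
    b = CollinearBlock(id=bid, genome_a=ga, genome_b=gb, chrom_a=ca, chrom_b=cb,
                       pairs=pairs, ranks_a=ranks_a, ranks_b=ranks_b,
                       orientation="+")
    b.event = event
    b.median_ks = 1.0
    return b


@pytest.fixture
def toy_trio():
    """Six reference genes with a full hexaploid paralog triple, a diploid
    ortholog run, and a tetraploid with both duplicate copies present for
    five of six genes (b4 lost)."""
    n = 6
    V = linear_genome("V", {
        "v1": [f"g{i}" for i in range(n)],
        "v2": [f"p{i}" for i in range(n)],
        "v3": [f"q{i}" for i in range(n)],
    })
    T = linear_genome("T", {"t1": [f"t{i}" for i in range(n)]})
    A = linear_genome("A", {
        "a1": [f"a{i}" for i in range(n)],
        "a2": [f"b{i}" for i in range(n) if i != 4],
    })
    ranks = list(range(n))
    blocks = {
        ("V", "V"): [
            block(0, "V", "V", "v1", "v2",
                  [(f"g{i}", f"p{i}") for i in range(n)], ranks, ranks, "ECH"),
            block(1, "V", "V", "v1", "v3",
                  [(f"g{i}", f"q{i}") for i in range(n)], ranks, ranks, "ECH"),
            block(2, "V", "V", "v2", "v3",
                  [(f"p{i}", f"q{i}") for i in range(n)], ranks, ranks, "ECH"),
        ],
        ("V", "T"): [
            block(3, "V", "T", "v1", "t1",
                  [(f"g{i}", f"t{i}") for i in range(n)], ranks, ranks,
                  "ortholog:V-T"),
        ],
        ("V", "A"): [
            block(4, "V", "A", "v1", "a1",
                  [(f"g{i}", f"a{i}") for i in range(n)], ranks, ranks,
                  "ortholog:V-A"),
            block(5, "V", "A", "v1", "a2",
                  [(f"g{i}", f"b{i}") for i in range(n) if i != 4],
                  [i for i in range(n) if i != 4], list(range(n - 1)),
                  "ortholog:V-A"),
        ],
        ("A", "A"): [
            block(6, "A", "A", "a1", "a2",
                  [(f"a{i}", f"b{i}") for i in range(n) if i != 4],
                  [i for i in range(n) if i != 4], list(range(n - 1)), "AST"),
        ],
    }
    spec = TableSpec("V", (("T", 1), ("A", 2)))
    return spec, V, blocks


class TestBuildTable:
    def test_twelve_columns_and_layout(self, toy_trio):
        spec, V, blocks = toy_trio
        assert spec.n_columns == 12
        table = build_table(spec, V, blocks)
        assert list(table.data.columns) == [
            "V", "V-p1", "V-p2", "T-o", "T-p1", "T-p2",
            "A-oa", "A-ob", "A-p1a", "A-p1b", "A-p2a", "A-p2b"]
        assert table.n_rows == 18

    def test_single_loss_leaves_exactly_one_dot_in_sibling_column(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        g_rows = table.data.loc[[f"g{i}" for i in range(6)]]
        # the a-copy run is complete; the b-copy run misses gene 4 only
        sib = g_rows[["A-oa", "A-ob"]]
        assert int((sib == MISSING).sum().sum()) == 1
        assert (sib.loc["g4"] == MISSING).sum() == 1

    def test_ast_partners_fill_sibling_columns_of_same_row(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        row = table.data.loc["g0"]
        assert {row["A-oa"], row["A-ob"]} == {"a0", "b0"}

    def test_paralog_rows_anchor_their_own_ortholog_columns(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        row = table.data.loc["g1"]
        assert {row["V-p1"], row["V-p2"]} == {"p1", "q1"}
        assert row["T-o"] == "t1"
        # the paralog rows hold the reference gene back in their own cells
        prow = table.data.loc["p1"]
        assert "g1" in {prow["V-p1"], prow["V-p2"]}

    def test_empty_blocks_give_all_dots_except_reference(self, toy_trio):
        spec, V, _ = toy_trio
        table = build_table(spec, V, {})
        assert (table.data["V"] != MISSING).all()
        assert (table.data.drop(columns="V") == MISSING).all().all()

    def test_target_gene_at_most_once_per_column(self, small_run):
        bundle, _, outdir = small_run
        data = pd.read_csv(outdir / "table_V.tsv", sep="\t", header=None,
                           skiprows=1, index_col=0)
        for col in data.columns:
            filled = data[col][data[col] != MISSING]
            assert filled.is_unique

    def test_conservation_bound(self, small_run):
        bundle, summary, outdir = small_run
        data = pd.read_csv(outdir / "table_V.tsv", sep="\t", header=None,
                           skiprows=1, index_col=0)
        # file rows carry the gene id index plus all 12 named columns
        header = open(outdir / "table_V.tsv").readline().lstrip("#").split()
        data.columns = header
        a_cols = [c for c in data.columns if c.startswith("A-")]
        placed = set()
        for c in a_cols:
            placed |= set(v for v in data[c] if v != MISSING)
        assert placed <= set(bundle.genomes["A"].genes)

    def test_secondary_reference_recovers_genes_the_primary_cannot(self, small_run):
        bundle, _, outdir = small_run

        def a_genes(path):
            table = pd.read_csv(path, sep="\t", header=None, skiprows=1,
                                index_col=0)
            out = set()
            for col in table.columns:
                out |= {v for v in table[col]
                        if isinstance(v, str) and v.startswith("A_")}
            return out

        via_v = a_genes(outdir / "table_V.tsv")
        via_t = a_genes(outdir / "table_T.tsv")
        assert via_t - via_v  # the cacao-style reference anchors extra genes


class TestStats:
    def test_retention_fractions(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        stats = column_stats(table)
        assert stats.loc["V", "retention"] == 1.0
        assert stats.loc["T-o", "filled"] == 6
        assert stats.loc["A-ob", "filled"] == 5

    def test_all_dots_column_has_zero_retention(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, {k: v for k, v in blocks.items()
                                      if k != ("V", "T")})
        stats = column_stats(table)
        assert stats.loc["T-o", "retention"] == 0.0

    def test_sibling_co_retention_rows(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        co = sibling_co_retention(table)
        assert set(co["species"]) == {"A"}
        slot0 = co[co["slot"] == 0].iloc[0]
        assert slot0["both"] == pytest.approx(5 / 18)


class TestGraphExport:
    def test_tick_totals_match_filled_counts(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        graph = export_alignment_graph(table, "circular")
        stats = column_stats(table)
        ticks = graph.groupby("column").size()
        for col in table.data.columns:
            assert ticks.get(col, 0) == stats.loc[col, "filled"]

    def test_bad_layout_rejected(self, toy_trio):
        spec, V, blocks = toy_trio
        table = build_table(spec, V, blocks)
        with pytest.raises(ValueError):
            export_alignment_graph(table, "spiral")
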