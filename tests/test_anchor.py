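import numpy as np
import pandas as pd
import pytest

from chromprint.agp import agp_to_fasta, assembly_stats, read_agp, write_agp
from chromprint.anchor import (
    ANCHORED,
    UNORDERED,
    UNORIENTED,
    Pool,
    PoolMember,
    PurgeThresholds,
    build_pools,
    join_anchored,
    purge_haplotypes,
    refine_with_nodes,
    select_unplaced,
)
from chromprint.linkage import order_markers
from chromprint.markers import PATERNAL, Marker


def _map3():
    # three markers, one recombinant apart each
    m = [
        Marker("M1", PATERNAL, "AAAAABBBBB", 5),
        Marker("M2", PATERNAL, "AAAAABBBBA", 5),
        Marker("M3", PATERNAL, "AAAAABBBAA", 5),
    ]
    return order_markers(m, "chr1")


def blocks_df(rows):
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "marker_id", "n_sites"])


class TestBuildPools:
    def test_multi_marker_scaffold_anchored(self):
        lm = _map3()
        blocks = blocks_df([
            ("s1", 0, 100, "M1", 3), ("s1", 200, 300, "M2", 3),
            ("s1", 400, 500, "M3", 3),
        ])
        pools, suspicious = build_pools(lm, blocks, {"s1": 1000})
        assert len(pools) == 1
        assert pools[0].status == ANCHORED
        assert pools[0].members[0].strand == "+"
        assert suspicious == []

    def test_orientation_from_block_positions(self):
        lm = _map3()
        blocks = blocks_df([
            ("s1", 0, 100, "M2", 3), ("s1", 400, 500, "M1", 3),
        ])
        pools, _ = build_pools(lm, blocks, {"s1": 1000})
        assert pools[0].members[0].strand == "-"

    def test_two_single_marker_scaffolds_unordered_by_length(self):
        lm = _map3()
        blocks = blocks_df([
            ("sA", 0, 100, "M2", 3), ("sB", 0, 100, "M2", 3),
        ])
        pools, _ = build_pools(lm, blocks, {"sA": 500, "sB": 900})
        assert len(pools) == 1
        assert pools[0].status == UNORDERED
        assert [m.scaffold for m in pools[0].members] == ["sB", "sA"]

    def test_non_consecutive_span_routed_to_misassembly(self):
        lm = _map3()
        blocks = blocks_df([
            ("s1", 0, 100, "M1", 3), ("s1", 400, 500, "M3", 3),
        ])
        pools, suspicious = build_pools(lm, blocks, {"s1": 1000})
        assert suspicious == ["s1"]
        assert pools == []

    def test_error_free_chain_anchors_multimarker_scaffolds(self, clean_chain):
        for lg, pool_list in clean_chain.pools.items():
            for pool in pool_list:
                if pool.status == ANCHORED:
                    assert len(pool.members) >= 1


class TestPurge:
    def nodes(self, rows):
        from chromprint.sim import NODE_COLUMNS

        return pd.DataFrame(rows, columns=NODE_COLUMNS)

    def _pools(self, lengths):
        return [
            Pool("chr1", (0, 1), [PoolMember("keep", lengths["keep"], "+")], ANCHORED),
            Pool("chr1", (1, 1), [PoolMember("cand", lengths["cand"], None)], UNORIENTED),
        ]

    def test_long_candidate_above_fifty_percent_removed(self):
        lengths = {"keep": 100_000, "cand": 12_000}
        nodes = self.nodes([
            ("keep", 0, 7200, "cand", 0, 7200, "+", 60.0, 5000.0),
        ])
        pools, log = purge_haplotypes(self._pools(lengths), nodes)
        assert list(log.scaffold) == ["cand"]
        assert list(log.rule) == ["node_contained"]

    def test_short_candidate_low_alignment_kept(self):
        lengths = {"keep": 100_000, "cand": 8000}
        nodes = self.nodes([
            ("keep", 0, 1600, "cand", 0, 1600, "+", 20.0, 1000.0),
        ])
        pools, log = purge_haplotypes(self._pools(lengths), nodes)
        assert log.empty
        assert len(pools) == 2

    def test_short_candidate_above_25_percent_removed(self):
        lengths = {"keep": 100_000, "cand": 8000}
        nodes = self.nodes([
            ("keep", 0, 2800, "cand", 0, 2800, "+", 35.0, 2000.0),
        ])
        pools, log = purge_haplotypes(self._pools(lengths), nodes)
        assert list(log.rule) == ["node_contained"]

    def test_marker_containment_rule(self):
        pools = [
            Pool("chr1", (0, 2), [PoolMember("big", 50_000, "+")], ANCHORED),
            Pool("chr1", (1, 1), [PoolMember("small", 4000, None)], UNORIENTED),
        ]
        cleaned, log = purge_haplotypes(pools, self.nodes([]))
        assert list(log.rule) == ["marker_contained"]
        assert [p.members[0].scaffold for p in cleaned] == ["big"]

    def test_offcut_colocated_with_parent_removed(self):
        pools = [
            Pool("chr1", (0, 1), [PoolMember("parent", 50_000, "+")], ANCHORED),
            Pool("chr1", (1, 1), [PoolMember("parent.off1", 3000, None)], UNORIENTED),
        ]
        cleaned, log = purge_haplotypes(
            pools, self.nodes([]), {"parent.off1": "parent"}
        )
        assert list(log.rule) == ["offcut_colocated"]

    def test_haplotig_purge_precision_recall(self, unmerged_chain, clean_assembly):
        """Planted haplotigs are removed with >= 95% precision and recall at
        the 10 kb / 50% / 25% thresholds."""
        res = unmerged_chain
        hap_truth = clean_assembly.haplotig_names()
        removed = set(res.purge_log.scaffold)
        tp = len(removed & hap_truth)
        fp = len(removed - hap_truth)
        fn = len(hap_truth - removed)
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / (tp + fn)
        assert precision >= 0.95
        assert recall >= 0.95


class TestRefineWithNodes:
    def test_end_node_orders_and_orients_pair(self):
        from chromprint.sim import NODE_COLUMNS

        pool = Pool("chr1", (2, 2), [
            PoolMember("x", 5000, None), PoolMember("y", 4000, None),
        ], UNORDERED)
        nodes = pd.DataFrame([
            ("x", 4500, 5000, "y", 0, 500, "+", 99.0, 500.0),
        ], columns=NODE_COLUMNS)
        out, conflicts = refine_with_nodes([pool], nodes, {"x": 5000, "y": 4000})
        assert out[0].status == ANCHORED
        assert [(m.scaffold, m.strand) for m in out[0].members] == [
            ("x", "+"), ("y", "+"),
        ]
        assert out[0].joins == [("x", "y")]

    def test_no_nodes_pools_unchanged(self):
        pool = Pool("chr1", (2, 2), [
            PoolMember("x", 5000, None), PoolMember("y", 4000, None),
        ], UNORDERED)
        out, _ = refine_with_nodes(
            [pool], pd.DataFrame(columns=[
                "scaffold_a", "a_start", "a_end", "scaffold_b", "b_start",
                "b_end", "strand", "pct_alignment", "score",
            ]), {"x": 5000, "y": 4000},
        )
        assert out[0].status == UNORDERED


class TestJoinAnchored:
    def seqs(self):
        return {"a": "A" * 1000, "b": "C" * 2000, "c": "G" * 3000, "u": "T" * 500}

    def test_consecutive_anchored_joined_with_100bp_gaps(self):
        pools = [
            Pool("chr1", (0, 1), [PoolMember("a", 1000, "+")], ANCHORED),
            Pool("chr1", (1, 2), [PoolMember("b", 2000, "+")], ANCHORED),
            Pool("chr1", (2, 3), [PoolMember("c", 3000, "-")], ANCHORED),
        ]
        build, new_seqs, agp = join_anchored(pools, self.seqs(), "chr1")
        joined = new_seqs["chr1_s1"]
        assert len(joined) == 1000 + 100 + 2000 + 100 + 3000
        assert joined.count("N") == 200

    def test_unoriented_element_breaks_join(self):
        pools = [
            Pool("chr1", (0, 1), [PoolMember("a", 1000, "+")], ANCHORED),
            Pool("chr1", (2, 2), [PoolMember("u", 500, None)], UNORIENTED),
            Pool("chr1", (3, 4), [PoolMember("b", 2000, "+")], ANCHORED),
        ]
        build, new_seqs, agp = join_anchored(pools, self.seqs(), "chr1")
        assert set(new_seqs) == {"a", "u", "b"}

    def test_agp_fasta_roundtrip_identity(self, tmp_path):
        pools = [
            Pool("chr1", (0, 1), [PoolMember("a", 1000, "+")], ANCHORED),
            Pool("chr1", (1, 2), [PoolMember("b", 2000, "-")], ANCHORED),
            Pool("chr1", (3, 3), [PoolMember("u", 500, None)], UNORIENTED),
        ]
        seqs = self.seqs()
        build, new_seqs, agp = join_anchored(pools, seqs, "chr1")
        path = write_agp(agp, tmp_path / "chr1.agp")
        agp2 = read_agp(path)
        components = dict(seqs)
        rebuilt = agp_to_fasta(agp2[agp2.object == "chr1_s1"], components)
        assert rebuilt["chr1_s1"] == new_seqs["chr1_s1"]
        # chromosome object reconstructs from super-scaffolds + gaps
        components.update(rebuilt)
        chrom = agp_to_fasta(agp2[agp2.object == "chr1"], components)["chr1"]
        assert len(chrom) == sum(len(s) for s in new_seqs.values()) + 100
        # writing the parsed AGP back yields identical text
        path2 = write_agp(agp2, tmp_path / "again.agp")
        assert path.read_text() == path2.read_text()


class TestSelectUnplaced:
    def test_rules(self):
        out = select_unplaced(
            ["m_only", "geneful", "bare"],
            maternal_scaffolds={"m_only"},
            paternal_scaffolds=set(),
            gene_scaffolds={"geneful"},
            print_chromosome={"m_only": "chr5"},
        )
        fates = dict(zip(out.scaffold, out.fate))
        assert fates == {
            "m_only": "chromosome_assigned",
            "geneful": "gene_bearing",
            "bare": "discarded",
        }
        assert out.set_index("scaffold").loc["m_only", "chromosome"] == "chr5"


class TestAssemblyStats:
    def test_n50_example(self):
        seqs = {f"s{i}": "A" * n for i, n in enumerate([5, 4, 3, 2, 1])}
        st = assembly_stats(seqs)
        assert st["total_length"] == 15
        assert st["scaffold_n50_length"] == 4
        assert st["scaffold_n50_number"] == 2

    def test_single_scaffold(self):
        st = assembly_stats({"s": "ACGT" * 10})
        assert st["scaffold_n50_length"] == 40
        assert st["scaffold_n50_number"] == 1

    def test_contigs_split_at_n_runs(self):
        st = assembly_stats({"s": "AAANNNAAA"})
        assert st["contigs"] == 2
        assert st["gaps"] == 1
        assert st["gap_length"] == 3

    def test_empty_assembly_rejected(self):
        with pytest.raises(ValueError):
            assembly_stats({})


def test_scaffold_partition_property(clean_chain, clean_assembly):
    """Every scaffold of the working assembly is placed, retained-unplaced,
    or logged-removed — exactly once."""
    placed = set()
    for build in clean_chain.builds.values():
        placed.update(build.placed_scaffolds())
    removed = set(clean_chain.purge_log.scaffold)
    unplaced = set(clean_chain.unplaced.scaffold)
    universe = set(clean_chain.seqs)
    assert placed | removed | unplaced == universe
    assert not placed & removed
    assert not placed & unplaced
    assert not removed & unplaced
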