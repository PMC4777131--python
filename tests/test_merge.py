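import numpy as np
import pandas as pd
import pytest

from chromprint.merge import (
    PLAN_COLUMNS,
    TRANSFER_COLUMNS,
    TransferMap,
    apply_merge_plan,
    empty_plan,
    find_end_overlaps,
    iterate_merge,
    plan_from_nodes,
    transfer_features,
    veto_nodes,
)
from chromprint.sim import NODE_COLUMNS, revcomp


def rand_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def plan_df(rows):
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


class TestApplyPlan:
    def test_empty_plan_is_identity(self):
        seqs = {"a": "ACGT" * 10, "b": "GGCC" * 5}
        new, tm = apply_merge_plan(seqs, empty_plan())
        assert new == seqs
        assert tm.map_position("a", 5) == ("a", 5, "+")

    def test_overlap_merge_length(self):
        # two scaffolds overlapping 1 kb, a's copy kept
        g = rand_seq(7000, 1)
        seqs = {"a": g[:4000], "b": g[3000:]}
        plan = plan_df([
            ("m", 0, "a", 0, 4000, "+"),
            ("m", 1, "b", 1000, 4000, "+"),
        ])
        new, tm = apply_merge_plan(seqs, plan)
        assert len(new["m"]) == 4000 + 4000 - 1000
        assert new["m"] == g

    def test_partial_use_leaves_offcut(self):
        seqs = {"a": rand_seq(1000, 2)}
        plan = plan_df([("m", 0, "a", 0, 600, "+")])
        new, tm = apply_merge_plan(seqs, plan)
        assert new["a.off1"] == seqs["a"][600:]
        piece = tm.map_interval("a", 600, 1000)[0]
        assert piece["status"] == "offcut"

    def test_overlapping_plan_intervals_rejected(self):
        seqs = {"a": rand_seq(1000, 3)}
        plan = plan_df([
            ("m", 0, "a", 0, 600, "+"),
            ("m2", 0, "a", 500, 900, "+"),
        ])
        with pytest.raises(ValueError, match="overlapping"):
            apply_merge_plan(seqs, plan)

    def test_reverse_strand_part_is_reverse_complemented(self):
        seqs = {"a": rand_seq(100, 4)}
        plan = plan_df([("m", 0, "a", 0, 100, "-")])
        new, tm = apply_merge_plan(seqs, plan)
        assert new["m"] == revcomp(seqs["a"])
        assert tm.map_position("a", 0) == ("m", 99, "-")


class TestCompose:
    def test_compose_with_identity(self):
        lengths = {"a": 100, "b": 50}
        ident = TransferMap.identity(lengths)
        plan = plan_df([("m", 0, "a", 10, 90, "-")])
        _, tm = apply_merge_plan({"a": rand_seq(100, 5), "b": rand_seq(50, 6)}, plan)
        composed = ident.compose(tm)
        for pos in (10, 50, 89):
            assert composed.map_position("a", pos) == tm.map_position("a", pos)

    def test_two_strand_flips_give_plus(self):
        seqs = {"a": rand_seq(100, 7)}
        plan1 = plan_df([("m", 0, "a", 0, 100, "-")])
        s2, t1 = apply_merge_plan(seqs, plan1)
        plan2 = plan_df([("k", 0, "m", 0, 100, "-")])
        s3, t2 = apply_merge_plan(s2, plan2)
        tm = t1.compose(t2)
        assert tm.map_position("a", 30) == ("k", 30, "+")

    def test_assembly_name_mismatch_rejected(self):
        t1 = TransferMap.identity({"a": 10}, source="v1")
        t1.target = "v2"
        t2 = TransferMap.identity({"a": 10}, source="v3")
        with pytest.raises(ValueError, match="mismatch"):
            t1.compose(t2)

    def test_composition_matches_base_level_tracker(self):
        """Five chained random merge plans: composed transfer equals a
        brute-force per-base tracker on a <100 kb genome."""
        rng = np.random.default_rng(17)
        seqs = {
            f"s{i}": rand_seq(int(rng.integers(3000, 12000)), 100 + i)
            for i in range(8)
        }
        assert sum(map(len, seqs.values())) < 100_000
        base = {n: [(n, i, "+") for i in range(len(s))] for n, s in seqs.items()}
        cur = dict(seqs)
        tm = TransferMap.identity({n: len(s) for n, s in seqs.items()})
        for it in range(5):
            plan = _random_plan(cur, rng, f"it{it}")
            new, step = apply_merge_plan(cur, plan)
            base = _track(base, cur, plan)
            cur = new
            tm = tm.compose(step)
        inv = {}
        for name, lst in base.items():
            for i, (orig, p, strand) in enumerate(lst):
                inv[(orig, p)] = (name, i, strand)
        for name, seq in seqs.items():
            for pos in range(0, len(seq), 11):
                assert tm.map_position(name, pos) == inv.get((name, pos))


def _random_plan(seqs, rng, prefix):
    parts = []
    for name, s in seqs.items():
        if rng.random() > 0.7 or len(s) < 10:
            continue
        cuts = sorted(rng.choice(range(1, len(s)), size=2, replace=False))
        bounds = [0, *cuts, len(s)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if rng.random() < 0.8:
                parts.append((name, lo, hi, "+-"[rng.integers(0, 2)]))
    rng.shuffle(parts)
    k = max(1, len(parts) // 3)
    rows = [
        (f"{prefix}n{i % k}", i, *p) for i, p in enumerate(parts)
    ]
    return pd.DataFrame(rows, columns=PLAN_COLUMNS)


def _track(base, seqs, plan):
    new_base = {}
    used = {}
    for row in plan.sort_values(["new_scaffold", "part_order"]).itertuples():
        used.setdefault(row.source_scaffold, []).append((row.start, row.end))
        seg = base[row.source_scaffold][row.start : row.end]
        if row.strand == "-":
            seg = [(a, b, "+-"[c == "+"]) for a, b, c in reversed(seg)]
        new_base.setdefault(row.new_scaffold, []).extend(seg)
    for name, s in seqs.items():
        if name not in used:
            new_base[name] = base[name]
            continue
        cur = 0
        oi = 1
        for lo, hi in sorted(used[name]) + [(len(s), len(s))]:
            if lo > cur:
                new_base[f"{name}.off{oi}"] = base[name][cur:lo]
                oi += 1
            cur = max(cur, hi)
    return new_base


class TestTransferFeatures:
    def test_identity_roundtrip(self):
        tm = TransferMap.identity({"a": 1000})
        feats = pd.DataFrame(
            [("a", 100, 300, "+", "g1")],
            columns=["scaffold", "start", "end", "strand", "gene_id"],
        )
        mapped, broken = transfer_features(feats, tm)
        assert broken.empty
        assert mapped.iloc[0].start == 100 and mapped.iloc[0].end == 300

    def test_feature_split_over_two_scaffolds_reported_broken(self):
        seqs = {"a": rand_seq(1000, 8)}
        plan = plan_df([
            ("m1", 0, "a", 0, 500, "+"),
            ("m2", 0, "a", 500, 1000, "+"),
        ])
        _, tm = apply_merge_plan(seqs, plan)
        feats = pd.DataFrame(
            [("a", 400, 600, "+", "g1")],
            columns=["scaffold", "start", "end", "strand", "gene_id"],
        )
        mapped, broken = transfer_features(feats, tm)
        assert mapped.empty
        assert set(broken.piece_new_scaffold) == {"m1", "m2"}
        assert (broken.fraction == 1.0).all()

    def test_strand_aware_coordinates(self):
        seqs = {"a": rand_seq(1000, 9)}
        plan = plan_df([("m", 0, "a", 0, 1000, "-")])
        _, tm = apply_merge_plan(seqs, plan)
        feats = pd.DataFrame(
            [("a", 100, 300, "+", "g1")],
            columns=["scaffold", "start", "end", "strand", "gene_id"],
        )
        mapped, _ = transfer_features(feats, tm)
        assert (mapped.iloc[0].start, mapped.iloc[0].end) == (700, 900)
        assert mapped.iloc[0].strand == "-"

    def test_feature_off_scaffold_end_rejected(self):
        tm = TransferMap.identity({"a": 100})
        feats = pd.DataFrame(
            [("a", 50, 200, "+", "g1")],
            columns=["scaffold", "start", "end", "strand", "gene_id"],
        )
        with pytest.raises(ValueError, match="off the end"):
            transfer_features(feats, tm)


def node_row(a, a_iv, b, b_iv, strand="+", pct=99.0, score=1000.0):
    return dict(scaffold_a=a, a_start=a_iv[0], a_end=a_iv[1],
                scaffold_b=b, b_start=b_iv[0], b_end=b_iv[1],
                strand=strand, pct_alignment=pct, score=score)


class TestVeto:
    def test_linkage_conflict_rejected(self):
        nodes = pd.DataFrame([node_row("x", (0, 100), "y", (0, 100))])
        acc, rej, swaps, rl = veto_nodes(
            nodes, {"x": "chr3", "y": "chr7"}
        )
        assert acc.empty
        assert list(rej.reason) == ["linkage_conflict"]
        assert ("x", "y") in rl

    def test_gene_breakage_triggers_swap(self):
        nodes = pd.DataFrame([node_row("x", (0, 100), "y", (900, 1000))])
        genes = pd.DataFrame(
            [("g1", "y", 850, 950, "+", True)],
            columns=["gene_id", "scaffold", "start", "end", "strand", "curated"],
        )
        acc, rej, swaps, _ = veto_nodes(
            nodes, {}, genes, {"x": 2000, "y": 1000}
        )
        assert len(acc) == 1
        assert swaps == {0: "b_part"}

    def test_gene_broken_on_both_sides_rejected(self):
        nodes = pd.DataFrame([node_row("x", (1900, 2000), "y", (900, 1000))])
        genes = pd.DataFrame(
            [
                ("g1", "y", 850, 950, "+", True),
                ("g2", "x", 1850, 1950, "+", True),
            ],
            columns=["gene_id", "scaffold", "start", "end", "strand", "curated"],
        )
        acc, rej, swaps, _ = veto_nodes(
            nodes, {}, genes, {"x": 2000, "y": 1000}
        )
        assert list(rej.reason) == ["gene_breakage"]

    def test_reject_list_persists(self):
        nodes = pd.DataFrame([node_row("x", (0, 100), "y", (0, 100))])
        acc, rej, _, _ = veto_nodes(nodes, {}, reject_list={("x", "y")})
        assert acc.empty
        assert list(rej.reason) == ["reject_list"]


class TestEndOverlaps:
    def test_exact_end_overlap_found(self):
        g = rand_seq(20_000, 11)
        seqs = {"a": g[:12_000], "b": g[10_000:]}
        nodes = find_end_overlaps(seqs, min_len=1000)
        assert len(nodes) == 1
        n = nodes.iloc[0]
        assert n.pct_alignment == 100.0
        assert n.a_end - n.a_start == 2000

    def test_reverse_complement_overlap_strand_minus(self):
        g = rand_seq(20_000, 12)
        seqs = {"a": g[:12_000], "b": revcomp(g[10_000:])}
        nodes = find_end_overlaps(seqs, min_len=1000)
        assert (nodes.strand == "-").all()

    def test_divergent_overlap_identity_reported(self):
        rng = np.random.default_rng(13)
        g = rand_seq(20_000, 13)
        ovl = list(g[10_000:12_000])
        for i in range(len(ovl)):
            if rng.random() < 0.06:
                ovl[i] = "ACGT".replace(ovl[i], "")[rng.integers(0, 3)]
        seqs = {"a": g[:10_000] + "".join(ovl), "b": g[10_000:]}
        nodes = find_end_overlaps(seqs, min_len=1000, min_identity=85)
        assert len(nodes) >= 1
        assert 91 <= nodes.iloc[0].pct_alignment <= 97


class TestIterateMerge:
    def test_haplotig_free_assembly_terminates_identity(self):
        seqs = {"a": rand_seq(5000, 14), "b": rand_seq(5000, 15)}
        res = iterate_merge(
            seqs, lambda s: pd.DataFrame(columns=NODE_COLUMNS)
        )
        assert res.seqs == seqs
        assert res.iterations == 1

    def test_collapses_planted_haplotigs(self, small_assembly):
        state = {"done": False}

        def source(cur):
            if state["done"]:
                return small_assembly.nodes.iloc[0:0]
            state["done"] = True
            nodes = small_assembly.nodes
            keep = nodes.scaffold_a.isin(cur) & nodes.scaffold_b.isin(cur)
            return nodes[keep]

        res = iterate_merge(dict(small_assembly.seqs), source)
        left = [n for n in res.seqs if n.startswith("hap")]
        assert left == []
        # haplotig intervals map inside their primary scaffold
        for node in small_assembly.nodes.itertuples():
            if not node.scaffold_b.startswith("hap"):
                continue
            mid = (node.b_start + node.b_end) // 2
            hit = res.transfer.map_position(node.scaffold_b, mid)
            assert hit is not None
            assert hit[0] == node.scaffold_a

    def test_iteration_cap_respected(self):
        seqs = {"a": rand_seq(3000, 16)}
        res = iterate_merge(
            seqs, lambda s: pd.DataFrame(columns=NODE_COLUMNS),
            max_iterations=9,
        )
        assert res.iterations <= 9


def test_base_accounting_partition(small_assembly):
    """Placed + offcut + dropped intervals partition every input scaffold."""
    nodes = small_assembly.nodes
    seqs = dict(small_assembly.seqs)
    plan, cont = plan_from_nodes(nodes, seqs)
    new, tm = apply_merge_plan(seqs, plan, cont)
    for name, seq in seqs.items():
        ivs = tm.df[tm.df.old_scaffold == name].sort_values("old_start")
        covered = 0
        prev_end = 0
        for r in ivs.itertuples():
            assert r.old_start == prev_end
            covered += r.old_end - r.old_start
            prev_end = r.old_end
        assert covered == len(seq)
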