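import itertools

import numpy as np
import pytest

from chromprint import patterns
from chromprint.linkage import (
    Correction,
    LinkageMap,
    _distance_matrix,
    _tour_cost,
    clean_pattern_errors,
    order_markers,
    propose_isolated_site_corrections,
    propose_singleton_corrections,
)
from chromprint.markers import PATERNAL, Marker, Pedigree, collapse_patterns, filter_snps


def mk(mid, pattern, support=5):
    return Marker(mid, PATERNAL, patterns.canonical(pattern), support)


def test_triangle_seriation_puts_most_distant_pair_at_ends():
    # pairwise recombinant counts 1, 2, 3: the count-3 pair must flank
    a = mk("a", "A" * 10)
    b = mk("b", "A" * 9 + "B")  # d(a,b)=1
    c = mk("c", "A" * 7 + "BBB")  # d(a,c)=3, d(b,c)=2
    lm = order_markers([a, b, c], "chrN")
    assert {lm.markers[0].marker_id, lm.markers[-1].marker_id} == {"a", "c"}
    assert lm.length_cm == pytest.approx((1 / 10 + 2 / 10) * 100)


def test_single_marker_trivial_map():
    lm = order_markers([mk("a", "ABAB")], "chrN")
    assert lm.length_cm == 0.0
    assert lm.markers[0].cm_position == 0.0


def test_reversal_leaves_length_unchanged():
    marks = [mk(f"m{i}", "A" * (10 - i) + "B" * i) for i in range(6)]
    lm = order_markers([m for m in marks], "chrN")
    rev = order_markers([m for m in reversed(marks)], "chrN")
    assert lm.length_cm == pytest.approx(rev.length_cm)


def test_heuristic_order_matches_exhaustive_optimum():
    """Above the exhaustive cutoff the heuristic must still reach the
    brute-force optimum on small instances."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        pats = []
        cur = list("AAAAABBBBB")
        pats.append("".join(cur))
        for _ in range(9):
            i = rng.integers(0, 10)
            cur[i] = "A" if cur[i] == "B" else "B"
            pats.append("".join(cur))
        marks = [mk(f"m{i}", p, 3) for i, p in enumerate(dict.fromkeys(pats))]
        lm = order_markers(marks, "chrN", exhaustive_limit=1)
        d, _ = _distance_matrix(lm.markers)
        best = min(
            _tour_cost(perm, d)
            for perm in itertools.permutations(range(len(marks)))
        )
        assert _tour_cost(range(len(lm.markers)), d) == best


def test_map_length_identity_on_error_free_simulation(small_truth):
    """Total map length = visible paternal crossovers / n x 100 cM, and
    the inferred order equals the physical class order up to reversal."""
    sites = small_truth.site_records(None)
    res = filter_snps(
        sites, small_truth.samples, Pedigree.from_samples(small_truth.samples)
    )
    marks, assignments = collapse_patterns(res.accepted)
    pos_by_chrom: dict[str, list[int]] = {}
    for sp in res.accepted:
        if sp.marker_type == PATERNAL:
            pos_by_chrom.setdefault(sp.scaffold, []).append(sp.pos)
    class_chrom = {}
    for chrom in small_truth.chrom_names:
        for q in small_truth.paternal_classes(chrom, pos_by_chrom[chrom]):
            class_chrom[q] = chrom
    n = small_truth.config.n_offspring
    total = 0.0
    for chrom in small_truth.chrom_names:
        mm = [
            m for m in marks
            if m.marker_type == PATERNAL and class_chrom.get(m.pattern) == chrom
        ]
        pos = assignments[assignments.marker_id.isin([m.marker_id for m in mm])]
        lm = order_markers(mm, chrom, pos)
        want = (
            small_truth.observable_crossovers(chrom, {chrom: pos_by_chrom[chrom]})
            / n * 100
        )
        assert lm.length_cm == pytest.approx(want, abs=1e-9)
        total += lm.length_cm
        # physical order comparison on markers with unambiguous position
        cls = small_truth.paternal_classes(chrom, pos_by_chrom[chrom])
        from collections import Counter

        unique = {p for p, k in Counter(cls).items() if k == 1}
        phys = [p for p in cls if p in unique]
        got = [m.pattern for m in lm.markers if m.pattern in unique]
        assert got == phys or got == phys[::-1]
    want_total = (
        small_truth.observable_crossovers(positions=pos_by_chrom) / n * 100
    )
    assert total == pytest.approx(want_total, abs=1e-9)


class TestCleanPatternErrors:
    def test_empty_corrections_identity(self):
        marks = [mk("a", "ABAB"), mk("b", "AABB")]
        out, log, id_map = clean_pattern_errors(marks, [])
        assert {m.marker_id for m in out} == {"a", "b"}
        assert log.empty

    def test_singleton_correction_merges_and_sums_support(self):
        a = mk("a", "ABAB", support=9)
        b = mk("b", "ABAA", support=1)
        out, log, id_map = clean_pattern_errors(
            [a, b], [Correction("b", 3, "B")]
        )
        assert len(out) == 1
        assert out[0].support == 10
        assert id_map["b"] == "a"
        assert len(log) == 1

    def test_unknown_marker_rejected(self):
        with pytest.raises(KeyError):
            clean_pattern_errors([mk("a", "AB")], [Correction("zz", 0, "A")])


def test_singleton_proposals_respect_support_ratio():
    a = mk("a", "ABABABAB", support=20)
    b = mk("b", "ABABABAA", support=1)  # error copy of a
    c = mk("c", "BABababa".upper(), support=4)  # mirror of a, low support
    props = propose_singleton_corrections([a, b, c], max_support=1)
    assert {p.marker_id for p in props} == {"b"}
    out, _, id_map = clean_pattern_errors([a, b, c], props)
    assert id_map["b"] == "a"


def test_isolated_site_proposals_use_geometry():
    import pandas as pd

    a = mk("a", "ABABABAB", support=4)
    q = mk("q", "ABABABAA", support=1)
    rows = [("s", p, "a", PATERNAL) for p in (10, 20, 40, 50)]
    rows.insert(2, ("s", 30, "q", PATERNAL))
    assignments = pd.DataFrame(
        rows, columns=["scaffold", "pos", "marker_id", "marker_type"]
    )
    props = propose_isolated_site_corrections([a, q], assignments)
    assert {p.marker_id for p in props} == {"q"}
    # a genuine class between two different markers is left alone
    b = mk("b", "AABBABAB", support=4)
    rows = [("s", 10, "a", PATERNAL), ("s", 20, "a", PATERNAL),
            ("s", 30, "q", PATERNAL), ("s", 40, "b", PATERNAL),
            ("s", 50, "b", PATERNAL)]
    assignments = pd.DataFrame(
        rows, columns=["scaffold", "pos", "marker_id", "marker_type"]
    )
    assert propose_isolated_site_corrections([a, q, b], assignments) == []


@pytest.mark.parametrize("seed", [23, 47])
def test_error_cleaning_reduces_map_inflation(seed):
    """With a 1% genotyping error rate, the automated cleaning pass (missing
    merge + isolated-site corrections + singleton absorption, followed by
    the support >= 2 mapping policy it enables) removes at least 80% of the
    map-length inflation relative to the true crossover count."""
    from chromprint.pipeline import _consolidate
    from chromprint.sim import SimConfig, simulate_pedigree

    n = 40
    cfg = SimConfig(
        n_chromosomes=1, chromosome_length_bp=150_000, n_offspring=n,
        genotype_error_rate=0.01, missing_rate=0.0, seed=seed,
    )
    truth = simulate_pedigree(cfg)
    res = filter_snps(
        truth.site_records(None), truth.samples,
        Pedigree.from_samples(truth.samples),
    )
    marks, assignments = collapse_patterns(res.accepted)

    def total_map(mlist, min_support):
        mm = [
            m for m in mlist
            if m.marker_type == PATERNAL and m.support >= min_support
        ]
        return order_markers(mm, "chr1").length_cm

    true_cm = truth.observable_crossovers() / n * 100
    raw_cm = total_map(marks, 1)  # uncleaned: every site pattern is a marker
    cleaned, _ = _consolidate(marks, assignments)
    cleaned_cm = total_map(cleaned, 2)
    raw_inflation = abs(raw_cm - true_cm)
    cleaned_inflation = abs(cleaned_cm - true_cm)
    assert raw_inflation > 10  # errors roughly double the raw map
    assert cleaned_inflation <= 0.2 * raw_inflation
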