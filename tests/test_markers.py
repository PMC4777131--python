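import numpy as np
import pytest

from chromprint import patterns
from chromprint.markers import (
    INTERCROSS,
    INVALID,
    MATERNAL,
    PATERNAL,
    UNINFORMATIVE,
    Marker,
    Pedigree,
    RmsTester,
    SnpFilterConfig,
    assign_paternal_to_chromosomes,
    classify_cross_type,
    collapse_patterns,
    derive_chromosome_prints,
    filter_snps,
    merge_missing_patterns,
)
from chromprint.vcfio import MISSING, SiteRecord


@pytest.mark.parametrize(
    "mother,father,expected",
    [
        ((0, 1), (0, 0), MATERNAL),
        ((0, 0), (0, 1), PATERNAL),
        ((0, 1), (0, 1), INTERCROSS),
        ((0, 0), (0, 0), UNINFORMATIVE),
        ((1, 1), (0, 0), UNINFORMATIVE),
        ((MISSING, MISSING), (0, 1), INVALID),
        ((0, 2), (0, 0), INVALID),  # non-biallelic parent call
    ],
)
def test_classify_cross_type(mother, father, expected):
    assert classify_cross_type(mother, father) == expected


class TestRmsTest:
    def test_statistic_zero_at_expected_ratios(self):
        t = RmsTester(alpha=0.05, reps=2000, seed=0)
        res = t.test({"A": 30, "B": 30}, MATERNAL)
        assert res.statistic == 0.0
        assert res.passed

    def test_all_heterozygous_intercross_fails(self):
        # expected 1:2:1, observed (0, n, 0): statistic is
        # sqrt((0.25^2 + 0.5^2 + 0.25^2)/3) ~ 0.354
        t = RmsTester(alpha=0.05, reps=2000, seed=0)
        res = t.test({"A": 0, "H": 60, "B": 0}, INTERCROSS)
        assert res.statistic == pytest.approx(0.3536, abs=1e-3)
        assert not res.passed

    def test_empty_counts_fail_with_flag(self):
        t = RmsTester(alpha=0.05, reps=1000, seed=0)
        res = t.test({}, MATERNAL)
        assert res.n == 0 and not res.passed

    def test_statistic_invariant_under_class_permutation(self):
        t = RmsTester()
        e = np.array([0.5, 0.5])
        assert t.statistic(np.array([40.0, 20.0]), e) == t.statistic(
            np.array([20.0, 40.0]), e
        )


def _site(gts, scaffold="s", pos=0, **kw):
    return SiteRecord(scaffold, pos, "A", "C", np.array(gts, dtype=np.int8), **kw)


def _trio_site(offspring_gts, mother=(0, 1), father=(0, 0), **kw):
    gts = [(0, 0), mother, father] + list(offspring_gts)
    return _site(gts, **kw)


SAMPLES = ["F0_GM", "F1_M", "F1_F", "OFF_01", "OFF_02", "OFF_03", "OFF_04"]
PED = Pedigree.from_samples(SAMPLES)


def test_low_gq_parent_rejected_with_reason():
    site = _trio_site([(0, 0)] * 4, gq=np.array([80, 10, 80, 80, 80, 80, 80.0]))
    res = filter_snps([site], SAMPLES, PED, SnpFilterConfig(rms_null_reps=500))
    assert res.n_accepted == 0
    assert list(res.rejected.reason) == ["GQ"]


@pytest.mark.parametrize(
    "kw,reason",
    [
        (dict(mq=10), "MQ"),
        (dict(strand_bias=99), "strand_bias"),
        (dict(dp=np.full(7, 2.0)), "depth"),
        (dict(mother=(MISSING, MISSING)), "parent_missing"),
    ],
)
def test_first_failing_filter_logged(kw, reason):
    mother = kw.pop("mother", (0, 1))
    site = _trio_site([(0, 0), (0, 1), (0, 0), (0, 1)], mother=mother, **kw)
    res = filter_snps([site], SAMPLES, PED, SnpFilterConfig(rms_null_reps=500))
    assert list(res.rejected.reason) == [reason]


def test_error_free_maternal_site_accepted_and_typed():
    site = _trio_site([(0, 0), (0, 1), (0, 1), (0, 0)])
    res = filter_snps([site], SAMPLES, PED, SnpFilterConfig(rms_null_reps=500))
    assert res.n_accepted == 1
    sp = res.accepted[0]
    assert sp.marker_type == MATERNAL
    assert sp.pattern == "ABBA"


def test_valid_site_acceptance_rate_with_one_percent_error():
    """At default thresholds >= 95% of truly informative sites survive a 1%
    genotyping error rate."""
    from chromprint.sim import SimConfig, simulate_pedigree

    cfg = SimConfig(
        n_chromosomes=4, chromosome_length_bp=150_000,
        genotype_error_rate=0.01, missing_rate=0.0, seed=13,
    )
    truth = simulate_pedigree(cfg)
    sites = truth.site_records(None)
    res = filter_snps(sites, truth.samples, Pedigree.from_samples(truth.samples))
    informative = sum(
        1 for s in sites
        if classify_cross_type(s.gts[1], s.gts[2]) in (MATERNAL, PATERNAL, INTERCROSS)
    )
    assert res.n_accepted / informative >= 0.95


def test_collapse_merges_mirror_patterns():
    sp = filter_snps(
        [
            _trio_site([(0, 0), (0, 1), (0, 1), (0, 0)], pos=1),
            _trio_site([(0, 1), (0, 0), (0, 0), (0, 1)], pos=2),  # mirror
        ],
        SAMPLES, PED, SnpFilterConfig(rms_null_reps=500),
    ).accepted
    marks, assignments = collapse_patterns(sp)
    assert len(marks) == 1
    assert marks[0].support == 2
    assert len(assignments) == 2


def test_collapse_empty_input():
    marks, assignments = collapse_patterns([])
    assert marks == [] and len(assignments) == 0


def test_support_sums_to_accepted_sites(small_filtered):
    marks, _ = collapse_patterns(small_filtered.accepted)
    assert sum(m.support for m in marks) == small_filtered.n_accepted


def test_paternal_marker_count_matches_truth_classes(small_truth):
    """Error-free chain: one paternal marker per distinct pattern class
    visible at the accepted paternal sites."""
    sites = small_truth.site_records(None)
    res = filter_snps(
        sites, small_truth.samples, Pedigree.from_samples(small_truth.samples)
    )
    marks, _ = collapse_patterns(res.accepted)
    pos = {}
    for sp in res.accepted:
        if sp.marker_type == PATERNAL:
            pos.setdefault(sp.scaffold, []).append(sp.pos)
    expected = set()
    for chrom in small_truth.chrom_names:
        expected.update(small_truth.paternal_classes(chrom, pos[chrom]))
    got = {m.pattern for m in marks if m.marker_type == PATERNAL}
    assert got == expected


class TestChromosomePrints:
    def test_prints_recovered_error_free(self, small_truth, small_filtered):
        marks, _ = collapse_patterns(small_filtered.accepted)
        maternal = [m for m in marks if m.marker_type == MATERNAL]
        ps = derive_chromosome_prints(maternal, small_truth.config.n_chromosomes)
        truth_prints = {small_truth.maternal_print(c) for c in small_truth.chrom_names}
        assert {p.pattern for p in ps.prints} == truth_prints

    def test_deficit_raises(self):
        marks = [Marker("M1", MATERNAL, "AABB", 5)]
        with pytest.raises(ValueError, match="deficit"):
            derive_chromosome_prints(marks, 3)

    def test_mirror_duplicates_collapse(self):
        # patterns identical up to mirror cannot both become prints
        marks = [
            Marker("M1", MATERNAL, patterns.canonical("AABB"), 9),
            Marker("M2", MATERNAL, patterns.canonical("BBAA"), 7),
        ]
        with pytest.raises(ValueError):
            derive_chromosome_prints(marks, 2)

    def test_noisy_print_recovery_with_assignment_accuracy(self):
        from chromprint.sim import SimConfig, simulate_pedigree

        cfg = SimConfig(
            n_chromosomes=6, chromosome_length_bp=150_000,
            genotype_error_rate=0.01, missing_rate=0.0, seed=17,
        )
        truth = simulate_pedigree(cfg)
        res = filter_snps(
            truth.site_records(None), truth.samples,
            Pedigree.from_samples(truth.samples),
        )
        marks, _ = collapse_patterns(res.accepted)
        maternal = [m for m in marks if m.marker_type == MATERNAL]
        ps = derive_chromosome_prints(maternal, 6)
        truth_prints = [truth.maternal_print(c) for c in truth.chrom_names]
        n = truth.config.n_offspring
        for p in ps.prints:
            d = min(patterns.mirror_distance(p.pattern, t) for t in truth_prints)
            # per-offspring assignment accuracy of the print itself
            assert 1 - d / n >= 0.99


def test_paternal_chromosome_assignment_and_conflicts(
    small_truth, small_assembly, small_filtered
):
    marks, assignments = collapse_patterns(small_filtered.accepted)
    maternal = [m for m in marks if m.marker_type == MATERNAL]
    ps = derive_chromosome_prints(maternal, small_truth.config.n_chromosomes)
    conflicts = assign_paternal_to_chromosomes(marks, assignments, ps)
    # map linkage groups back to true chromosomes via the prints
    lg_to_chrom = {}
    for p in ps.prints:
        for chrom in small_truth.chrom_names:
            if patterns.mirror_distance(
                p.pattern, small_truth.maternal_print(chrom)
            ) == 0:
                lg_to_chrom[p.chromosome] = chrom
    truth_class_chrom = {}
    for chrom in small_truth.chrom_names:
        for q in small_truth.paternal_classes(chrom):
            truth_class_chrom[q] = chrom
    chimeric = set(small_assembly.misassembly_truth.scaffold)
    scaffolds_of = assignments.groupby("marker_id")["scaffold"].agg(set)
    for m in marks:
        if m.marker_type != PATERNAL:
            continue
        if scaffolds_of[m.marker_id] & chimeric:
            continue  # chimera evidence: may be conflicted, checked below
        assert m.chromosome is not None
        assert lg_to_chrom[m.chromosome] == truth_class_chrom[m.pattern]
    # every conflict names at least two chromosomes
    for row in conflicts.itertuples():
        assert len(row.chromosomes.split(",")) >= 2


def test_merge_missing_absorbs_compatible_pattern():
    complete = Marker("M1", PATERNAL, patterns.canonical("ABAB"), 5)
    holey = Marker("M2", PATERNAL, patterns.canonical("AB-B"), 1)
    other = Marker("M3", PATERNAL, patterns.canonical("AAAA"), 5)
    merged, id_map = merge_missing_patterns([complete, holey, other])
    assert id_map["M2"] == "M1"
    assert {m.marker_id for m in merged} == {"M1", "M3"}
    assert next(m for m in merged if m.marker_id == "M1").support == 6


def test_merge_missing_keeps_ambiguous_pattern():
    m1 = Marker("M1", PATERNAL, patterns.canonical("ABAB"), 5)
    m2 = Marker("M2", PATERNAL, patterns.canonical("ABAA"), 5)
    holey = Marker("M3", PATERNAL, patterns.canonical("ABA-"), 1)
    merged, id_map = merge_missing_patterns([m1, m2, holey])
    assert id_map["M3"] == "M3"
    assert len(merged) == 3
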