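"""From pedigree genotypes to segregation-pattern markers and prints.

Sites are typed from the F1 parents (maternal: mother heterozygous,
father homozygous; paternal: the reverse; intercross: both heterozygous),
quality-filtered, tested for Mendelian segregation with a Monte-Carlo
root-mean-square test, recoded to offspring phase classes (A/B/H/-), and
collapsed to unique markers.  Because females do not recombine, every
marker of maternal type on one chromosome shows the same pattern up to
mirroring — the chromosome print — which identifies the chromosome for
any scaffold carrying it.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import patterns
from .vcfio import MISSING, SiteRecord

MATERNAL = "maternal"
PATERNAL = "paternal"
INTERCROSS = "intercross"
UNINFORMATIVE = "uninformative"
INVALID = "invalid"

#: Expected Mendelian genotype-class ratios per informative marker type.
#: Keys are pattern symbols; extend for additional (e.g. Z-linked) types.
EXPECTED_RATIOS: dict[str, dict[str, float]] = {
    MATERNAL: {"A": 0.5, "B": 0.5},
    PATERNAL: {"A": 0.5, "B": 0.5},
    INTERCROSS: {"A": 0.25, "H": 0.5, "B": 0.25},
}


def classify_cross_type(mother_gt: Sequence[int], father_gt: Sequence[int]) -> str:
    """Type a site from the two F1 parental genotypes (total function)."""
    def bad(gt: Sequence[int]) -> bool:
        return any(a == MISSING or a > 1 for a in gt)

    if bad(mother_gt) or bad(father_gt):
        return INVALID
    m_het = mother_gt[0] != mother_gt[1]
    f_het = father_gt[0] != father_gt[1]
    if m_het and f_het:
        return INTERCROSS
    if m_het:
        return MATERNAL
    if f_het:
        return PATERNAL
    return UNINFORMATIVE


# --------------------------------------------------------------------------
# root-mean-square segregation test


@dataclasses.dataclass
class RmsResult:
    statistic: float
    critical: float
    passed: bool
    n: int


class RmsTester:
    """Monte-Carlo-calibrated RMS test of Mendelian segregation.

    The statistic is ``sqrt(mean((obs_freq - exp_freq)^2))`` over the
    genotype classes of the marker type.  The null distribution is built
    by multinomial sampling at the expected ratios and the observed
    non-missing count.  Because the statistic is discrete, a
    deterministic cutoff cannot achieve the nominal level; the classical
    randomized decision rule is used instead: reject above the boundary
    atom always, and on the boundary atom with the probability that makes
    the overall size equal alpha.
    """

    def __init__(self, alpha: float = 0.01, reps: int = 10_000, seed: int = 0):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        self.alpha = alpha
        self.reps = reps
        self.rng = np.random.default_rng(seed)
        self._cache: dict[tuple, tuple[float, float]] = {}

    @staticmethod
    def statistic(observed: np.ndarray, expected: np.ndarray) -> float:
        n = observed.sum()
        if n == 0:
            return float("nan")
        freq = observed / n
        return float(np.sqrt(np.mean((freq - expected) ** 2)))

    def _calibrate(self, n: int, expected: tuple[float, ...]) -> tuple[float, float]:
        key = (n, expected, self.reps, self.alpha)
        if key not in self._cache:
            p = np.array(expected)
            counts = self.rng.multinomial(n, p, size=self.reps)
            stats = np.sqrt(np.mean((counts / n - p) ** 2, axis=1))
            stats = np.round(stats, 12)  # make atoms exactly comparable
            c = float(np.quantile(stats, 1 - self.alpha, method="inverted_cdf"))
            p_gt = float(np.mean(stats > c))
            p_eq = float(np.mean(stats == c))
            gamma = 0.0 if p_eq == 0 else max(0.0, (self.alpha - p_gt) / p_eq)
            self._cache[key] = (c, gamma)
        return self._cache[key]

    def test(self, observed_counts: dict[str, int], marker_type: str) -> RmsResult:
        ratios = EXPECTED_RATIOS[marker_type]
        classes = list(ratios)
        obs = np.array([observed_counts.get(k, 0) for k in classes], dtype=float)
        n = int(obs.sum())
        if n == 0:
            return RmsResult(float("nan"), float("nan"), False, 0)
        expected = np.array([ratios[k] for k in classes])
        stat = round(self.statistic(obs, expected), 12)
        c, gamma = self._calibrate(n, tuple(expected))
        if stat > c:
            reject = True
        elif stat == c:
            reject = bool(self.rng.random() < gamma)
        else:
            reject = False
        return RmsResult(stat, c, not reject, n)


# --------------------------------------------------------------------------
# site filtering and recoding


@dataclasses.dataclass
class SnpFilterConfig:
    """Site acceptance thresholds (package defaults, config-overridable)."""

    min_genotype_quality: float = 30.0
    min_mapping_quality: float = 40.0
    max_strand_bias: float = 60.0  # phred-scaled Fisher strand
    min_depth: float = 8.0
    max_depth: float = 120.0
    max_missing: float = 0.2
    rms_alpha: float = 0.01
    rms_null_reps: int = 10_000
    rms_seed: int = 0

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("rms_alpha",):
                if not 0 < v < 1:
                    raise ValueError("rms_alpha must be in (0,1)")
            elif v < 0:
                raise ValueError(f"{f.name} must be non-negative")


@dataclasses.dataclass
class SitePattern:
    scaffold: str
    pos: int
    marker_type: str
    pattern: str  # raw recoding (phase-consistent where inferable)
    canonical: str
    phased: bool


@dataclasses.dataclass
class FilterResult:
    accepted: list[SitePattern]
    rejected: pd.DataFrame  # scaffold, pos, reason

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


@dataclasses.dataclass
class Pedigree:
    """Sample roles within the VCF sample list."""

    mother: str
    father: str
    offspring: list[str]
    grandmother: str | None = None

    @classmethod
    def from_samples(cls, samples: Sequence[str]) -> "Pedigree":
        """Role assignment for the simulator's naming convention."""
        return cls(
            mother="F1_M",
            father="F1_F",
            offspring=[s for s in samples if s.startswith("OFF_")],
            grandmother="F0_GM" if "F0_GM" in samples else None,
        )

    def indices(self, samples: Sequence[str]) -> tuple[int, int, list[int], int | None]:
        lookup = {s: i for i, s in enumerate(samples)}
        for s in [self.mother, self.father] + self.offspring:
            if s not in lookup:
                raise KeyError(f"sample {s!r} missing from VCF")
        gm = lookup.get(self.grandmother) if self.grandmother else None
        return (
            lookup[self.mother],
            lookup[self.father],
            [lookup[s] for s in self.offspring],
            gm,
        )


def _recode_site(
    site: SiteRecord,
    marker_type: str,
    mi: int,
    fi: int,
    oi: list[int],
    gmi: int | None,
) -> tuple[str, bool]:
    """Offspring calls -> A/B/H/- pattern for an informative site.

    For maternal (paternal) sites ``A``/``B`` track which maternal
    (paternal) haplotype each offspring inherited: the homozygous class
    shares the homozygous parent's allele, the heterozygous class carries
    the other.  When the F0 grandmother is homozygous at the site, her
    allele fixes phase (``A`` = grandmaternal haplotype transmitted);
    otherwise the recoding is phase-free and only canonical forms are
    comparable across sites.
    """
    gts = site.gts
    het_parent, hom_parent = (mi, fi) if marker_type == MATERNAL else (fi, mi)
    calls = []
    if marker_type == INTERCROSS:
        for i in oi:
            a, b = gts[i]
            if a == MISSING or b == MISSING:
                calls.append("-")
            elif a != b:
                calls.append("H")
            else:
                calls.append("A" if a == 0 else "B")
        return "".join(calls), False

    hom_allele = int(gts[hom_parent][0])
    other = 1 - hom_allele
    phased = False
    hom_class, het_class = "A", "B"
    if gmi is not None:
        gm = gts[gmi]
        if MISSING not in gm and gm[0] == gm[1]:
            # grandmaternal allele defines class A
            phased = True
            if int(gm[0]) == hom_allele:
                hom_class, het_class = "A", "B"
            else:
                hom_class, het_class = "B", "A"
    for i in oi:
        a, b = gts[i]
        if a == MISSING or b == MISSING:
            calls.append("-")
        elif a == b == hom_allele:
            calls.append(hom_class)
        elif {int(a), int(b)} == {hom_allele, other}:
            calls.append(het_class)
        else:  # non-Mendelian (e.g. hom for the untransmitted allele)
            calls.append("-")
    return "".join(calls), phased


def filter_snps(
    sites: Iterable[SiteRecord],
    samples: Sequence[str],
    pedigree: Pedigree,
    config: SnpFilterConfig | None = None,
) -> FilterResult:
    """Quality-filter, type, RMS-test and recode sites.

    Every rejected site is logged with the first failing filter, in the
    order: biallelic SNP, parent call present, parental GQ, MQ, strand
    bias, parental depth, informative type, missingness, RMS segregation.
    """
    config = config or SnpFilterConfig()
    config.validate()
    mi, fi, oi, gmi = pedigree.indices(samples)
    tester = RmsTester(config.rms_alpha, config.rms_null_reps, config.rms_seed)

    accepted: list[SitePattern] = []
    rej: list[tuple[str, int, str]] = []
    for site in sites:
        reason = _first_failure(site, mi, fi, config)
        if reason is None:
            marker_type = classify_cross_type(site.gts[mi], site.gts[fi])
            if marker_type in (UNINFORMATIVE, INVALID):
                reason = marker_type
        if reason is None:
            gq = site.gq_or_default()
            masked = site
            low = [i for i in oi if gq[i] < config.min_genotype_quality]
            if low:
                masked = dataclasses.replace(site, gts=site.gts.copy())
                for i in low:
                    masked.gts[i] = MISSING
            pattern, phased = _recode_site(masked, marker_type, mi, fi, oi, gmi)
            miss = pattern.count("-") / len(pattern)
            if miss > config.max_missing:
                reason = "missing"
            else:
                counts = {c: pattern.count(c) for c in "ABH"}
                res = tester.test(counts, marker_type)
                if not res.passed:
                    reason = "rms"
        if reason is None:
            accepted.append(
                SitePattern(site.scaffold, site.pos, marker_type, pattern,
                            patterns.canonical(pattern), phased)
            )
        else:
            rej.append((site.scaffold, site.pos, reason))
    rejected = pd.DataFrame(rej, columns=["scaffold", "pos", "reason"])
    return FilterResult(accepted, rejected)


def _first_failure(site: SiteRecord, mi: int, fi: int, config: SnpFilterConfig) -> str | None:
    if len(site.ref) != 1 or len(site.alt) != 1 or site.alt not in "ACGT":
        return "not_biallelic_snp"
    gq = site.gq_or_default()
    dp = site.dp_or_default()
    for pi in (mi, fi):
        if MISSING in site.gts[pi]:
            return "parent_missing"
    if min(gq[mi], gq[fi]) < config.min_genotype_quality:
        return "GQ"
    if site.mq < config.min_mapping_quality:
        return "MQ"
    if site.strand_bias > config.max_strand_bias:
        return "strand_bias"
    for pi in (mi, fi):
        if not config.min_depth <= dp[pi] <= config.max_depth:
            return "depth"
    return None


# --------------------------------------------------------------------------
# markers


@dataclasses.dataclass
class Marker:
    marker_id: str
    marker_type: str
    pattern: str  # canonical
    support: int
    chromosome: str | None = None
    cm_position: float | None = None


def collapse_patterns(
    accepted: Sequence[SitePattern],
) -> tuple[list[Marker], pd.DataFrame]:
    """Collapse accepted sites to unique (canonical pattern, type) markers.

    Returns the markers (support = contributing SNPs) and a per-site
    assignment table (scaffold, pos, marker_id) preserving the position
    ranges needed for block building.
    """
    groups: dict[tuple[str, str], list[SitePattern]] = defaultdict(list)
    for sp in accepted:
        groups[(sp.marker_type, sp.canonical)].append(sp)
    keys = sorted(groups, key=lambda k: (k[0], -len(groups[k]), k[1]))
    markers: list[Marker] = []
    rows = []
    for idx, key in enumerate(keys):
        mid = f"M{idx + 1:04d}"
        sites = groups[key]
        markers.append(Marker(mid, key[0], key[1], len(sites)))
        for sp in sites:
            rows.append((sp.scaffold, sp.pos, mid, key[0]))
    assignments = pd.DataFrame(rows, columns=["scaffold", "pos", "marker_id", "marker_type"])
    return markers, assignments


def merge_missing_patterns(
    marks: Sequence[Marker],
    *,
    min_target_support: int = 1,
) -> tuple[list[Marker], dict[str, str]]:
    """Merge patterns with missing calls into compatible complete markers.

    A marker whose pattern has ``-`` calls is absorbed by a complete
    (gap-free) marker of the same type when exactly one complete marker
    with support >= ``min_target_support`` matches it on every
    non-missing offspring (mirror-aware); ambiguous or unmatched holey
    markers stay separate.  Returns the consolidated markers and the
    old->kept id mapping.
    """
    import numpy as np

    from .patterns import patterns_to_matrix

    mirror_lut = np.array([1, 0, 2, 3], dtype=np.int8)
    id_map: dict[str, str] = {m.marker_id: m.marker_id for m in marks}
    out: list[Marker] = []
    by_type: dict[str, list[Marker]] = defaultdict(list)
    for m in marks:
        by_type[m.marker_type].append(m)
    for type_marks in by_type.values():
        complete = [m for m in type_marks if "-" not in m.pattern]
        trusted = [m for m in complete if m.support >= min_target_support]
        holey = [m for m in type_marks if "-" in m.pattern]
        out.extend(complete)
        if not trusted or not holey:
            out.extend(holey)
            continue
        comp_mat = patterns_to_matrix([m.pattern for m in trusted])
        hol_mat = patterns_to_matrix([m.pattern for m in holey])
        hol_mirror = mirror_lut[hol_mat]
        for start in range(0, len(holey), 256):
            chunk = slice(start, min(start + 256, len(holey)))
            a = hol_mat[chunk][:, None, :]
            am = hol_mirror[chunk][:, None, :]
            b = comp_mat[None, :, :]
            valid = a != 3
            dist = np.minimum(
                ((a != b) & valid).sum(axis=2),
                ((am != b) & valid).sum(axis=2),
            )
            for li in range(dist.shape[0]):
                m = holey[start + li]
                hits = np.flatnonzero(dist[li] == 0)
                if len(hits) == 1:
                    tgt = trusted[int(hits[0])]
                    tgt.support += m.support
                    id_map[m.marker_id] = tgt.marker_id
                else:
                    out.append(m)
    return out, id_map


@dataclasses.dataclass
class PrintSet:
    prints: list[Marker]  # chromosome set to LG1..LGk, support order
    assignment: dict[str, str]  # maternal marker_id -> chromosome
    unassigned: list[str]


def derive_chromosome_prints(
    maternal_markers: Sequence[Marker],
    expected_k: int,
    *,
    min_distinct: int = 3,
    max_assign_dist: int = 3,
) -> PrintSet:
    """Pick the k chromosome prints and assign remaining maternal markers.

    Prints are the ``expected_k`` highest-support maternal patterns that
    are mutually distinct by more than ``min_distinct`` mirror-aware
    mismatches (so mirror images and error clouds collapse onto one
    print).  Other maternal markers join the unique print within
    ``max_assign_dist`` mismatches, else stay unassigned.
    """
    ranked = sorted(maternal_markers, key=lambda m: (-m.support, m.pattern))
    prints: list[Marker] = []
    for m in ranked:
        if len(prints) == expected_k:
            break
        if all(
            patterns.mirror_distance(m.pattern, p.pattern) > min_distinct
            for p in prints
        ):
            prints.append(m)
    if len(prints) < expected_k:
        raise ValueError(
            f"only {len(prints)} distinct maternal patterns found, "
            f"expected {expected_k} (deficit {expected_k - len(prints)})"
        )
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for i, p in enumerate(prints):
        p.chromosome = f"LG{i + 1}"
        assignment[p.marker_id] = p.chromosome
    for m in ranked:
        if m.marker_id in assignment:
            continue
        dists = [
            (patterns.mirror_distance(m.pattern, p.pattern), p.chromosome)
            for p in prints
        ]
        dists.sort()
        if dists[0][0] <= max_assign_dist and (
            len(dists) == 1 or dists[1][0] > max_assign_dist
        ):
            m.chromosome = dists[0][1]
            assignment[m.marker_id] = dists[0][1]
        else:
            unassigned.append(m.marker_id)
    return PrintSet(prints, assignment, unassigned)


def assign_paternal_to_chromosomes(
    markers: Sequence[Marker],
    assignments: pd.DataFrame,
    print_set: PrintSet,
) -> pd.DataFrame:
    """Chromosome-assign paternal markers by scaffold co-location.

    A paternal marker inherits the chromosome of the print(s) present on
    the scaffolds where its SNPs lie.  Scaffolds whose maternal markers
    disagree, or paternal markers co-locating with prints of two or more
    chromosomes, are conflicts — misassembly evidence — and stay
    unassigned.  Returns the conflict log.
    """
    by_id = {m.marker_id: m for m in markers}
    mat = assignments[assignments.marker_type == MATERNAL].copy()
    mat["chromosome"] = mat.marker_id.map(print_set.assignment)
    scaffold_chroms: dict[str, set[str]] = (
        mat.dropna(subset=["chromosome"])
        .groupby("scaffold")["chromosome"]
        .agg(set)
        .to_dict()
    )
    conflicts = []
    pat = assignments[assignments.marker_type == PATERNAL]
    for mid, grp in pat.groupby("marker_id"):
        chroms: set[str] = set()
        for scaffold in grp.scaffold.unique():
            chroms |= scaffold_chroms.get(scaffold, set())
        marker = by_id[mid]
        if len(chroms) == 1:
            marker.chromosome = chroms.pop()
        elif len(chroms) > 1:
            conflicts.append(
                (mid, ",".join(sorted(chroms)), ",".join(sorted(grp.scaffold.unique())))
            )
    return pd.DataFrame(conflicts, columns=["marker_id", "chromosomes", "scaffolds"])


def markers_to_frame(markers: Sequence[Marker]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(marker_id=m.marker_id, type=m.marker_type,
                 chromosome=m.chromosome, cm=m.cm_position,
                 support=m.support, pattern=m.pattern)
            for m in markers
        ]
    )
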