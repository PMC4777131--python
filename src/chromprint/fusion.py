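"""Chromosome-fusion detection from outgroup F1 segregation patterns.

When an outgroup cross (non-recombining mother) is genotyped against a
reference with a fused karyotype, every ancestral chromosome leaves a
distinct chromosome print along the part of the reference it maps to; a
fused reference chromosome therefore shows a transition from one print
to another, and the interval between the flanking SNPs localizes the
fusion point.  Fusion intervals from two outgroups can be compared for
containment to test whether they date the same event.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import patterns
from .vcfio import MISSING, SiteRecord


def f1_segregation_sites(
    sites: Iterable[SiteRecord],
    samples: Sequence[str],
    father: str,
    mother: str,
    offspring: Sequence[str],
    z_chromosomes: set[str] | None = None,
) -> pd.DataFrame:
    """Select informative F1 sites and recode offspring patterns.

    A site qualifies when the father is homozygous, the mother is
    heterozygous (or, on a Z chromosome, hemizygous with an allele
    different from the father's), and every offspring has a genotype.
    Offspring sharing the father's homozygous genotype are class ``A``,
    heterozygotes class ``B`` (other calls, necessarily errors, ``H``).
    """
    z_chromosomes = z_chromosomes or set()
    lookup = {s: i for i, s in enumerate(samples)}
    for s in [father, mother, *offspring]:
        if s not in lookup:
            raise KeyError(f"sample {s!r} missing from VCF")
    fi, mi = lookup[father], lookup[mother]
    oi = [lookup[s] for s in offspring]
    rows = []
    for site in sites:
        f = site.gts[fi]
        m = site.gts[mi]
        if MISSING in f or MISSING in m or f[0] != f[1]:
            continue
        if site.scaffold in z_chromosomes:
            # hemizygous mother emitted as homozygous: require an allele
            # different from the father's
            if m[0] != m[1] or m[0] == f[0]:
                continue
        else:
            if m[0] == m[1]:
                continue
        calls = []
        ok = True
        for i in oi:
            a, b = site.gts[i]
            if a == MISSING or b == MISSING:
                ok = False
                break
            if a == b == f[0]:
                calls.append("A")
            elif a != b:
                calls.append("B")
            else:
                calls.append("H")
        if not ok:
            continue
        pat = "".join(calls)
        rows.append((site.scaffold, site.pos, pat, patterns.canonical(pat)))
    return pd.DataFrame(rows, columns=["scaffold", "pos", "pattern", "canonical"])


@dataclasses.dataclass
class PrintTable:
    prints: pd.DataFrame  # print_id, pattern, support
    site_class: pd.DataFrame  # scaffold, pos, print_id, klass


def identify_prints(
    site_patterns: pd.DataFrame,
    expected_k: int,
    *,
    noise_hamming: int = 1,
    min_support: int = 2,
) -> PrintTable:
    """Pick the most common patterns (mirror-merged) as chromosome prints.

    All-homozygous patterns are excluded, and patterns within
    ``noise_hamming`` of a print are classed as genotyping-error noise
    and absorbed into that print's site set.  Fewer than ``expected_k``
    well-supported patterns triggers a warning with the achieved count.
    """
    counts = site_patterns.canonical.value_counts()
    candidates = [
        (int(n), p) for p, n in counts.items() if len(set(p.replace("-", ""))) > 1
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    prints: list[tuple[str, str, int]] = []
    for n, p in candidates:
        if len(prints) == expected_k:
            break
        if n < min_support:
            continue
        if all(
            patterns.mirror_distance(p, q) > noise_hamming for _, q, _ in prints
        ):
            prints.append((f"P{len(prints) + 1:02d}", p, n))
    if len(prints) < expected_k:
        warnings.warn(
            f"only {len(prints)} chromosome prints found "
            f"(expected {expected_k})",
            stacklevel=2,
        )
    print_df = pd.DataFrame(prints, columns=["print_id", "pattern", "support"])

    assign = {}
    for canon in counts.index:
        best = None
        for pid, p, _ in prints:
            d = patterns.mirror_distance(canon, p)
            if best is None or d < best[0]:
                best = (d, pid, p)
        if best is None:
            assign[canon] = ("", "junk")
        elif best[0] == 0:
            assign[canon] = (best[1], "print")
        elif best[0] <= noise_hamming:
            assign[canon] = (best[1], "noise")
        else:
            assign[canon] = ("", "junk")
    site_class = site_patterns.copy()
    site_class["print_id"] = site_class.canonical.map(lambda c: assign[c][0])
    site_class["klass"] = site_class.canonical.map(lambda c: assign[c][1])
    # recompute print support including absorbed noise sites
    support = (
        site_class[site_class.print_id != ""].groupby("print_id").size()
    )
    print_df["support"] = print_df.print_id.map(support).fillna(0).astype(int)
    return PrintTable(print_df, site_class[["scaffold", "pos", "print_id", "klass"]])


FUSION_COLUMNS = [
    "chromosome", "interval_start", "interval_end", "left_print", "right_print",
]


def locate_fusions(
    site_class: pd.DataFrame,
    *,
    min_run: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan per-chromosome print sequences for transitions.

    Sites classed print or noise contribute their print label in
    position order; runs shorter than ``min_run`` sites are treated as
    stray mislabels and dropped.  Each surviving transition is a fusion
    point spanning the interval from the last SNP of the left print to
    the first SNP of the right print.  Also returns per-chromosome print
    synteny (one row per retained run).
    """
    fusion_rows = []
    synteny_rows = []
    labelled = site_class[site_class.print_id != ""]
    for chrom, grp in labelled.groupby("scaffold"):
        grp = grp.sort_values("pos")
        runs: list[list] = []  # [print_id, first_pos, last_pos, n]
        for row in grp.itertuples():
            if runs and runs[-1][0] == row.print_id:
                runs[-1][2] = row.pos
                runs[-1][3] += 1
            else:
                runs.append([row.print_id, row.pos, row.pos, 1])
        runs = [r for r in runs if r[3] >= min_run]
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
                merged[-1][3] += r[3]
            else:
                merged.append(r)
        for r in merged:
            synteny_rows.append((chrom, r[0], r[1], r[2], r[3]))
        for left, right in zip(merged[:-1], merged[1:]):
            fusion_rows.append(
                (chrom, int(left[2]), int(right[1]), left[0], right[0])
            )
    fusions = pd.DataFrame(fusion_rows, columns=FUSION_COLUMNS)
    synteny = pd.DataFrame(
        synteny_rows, columns=["chromosome", "print_id", "first_pos", "last_pos", "n_sites"]
    )
    return fusions, synteny


def check_containment(
    fusions_a: pd.DataFrame, fusions_b: pd.DataFrame
) -> pd.DataFrame:
    """Verdict per fusion interval of set A against set B.

    ``contained``: A's interval lies inside B's; ``overlapping``:
    intervals intersect without containment; ``disjoint`` otherwise;
    ``unmatched`` when B has no interval on that chromosome.  Intervals
    are matched by chromosome and nearest midpoint.
    """
    def _norm(df: pd.DataFrame) -> pd.DataFrame:
        return df.rename(
            columns={"chrom": "chromosome", "start": "interval_start",
                     "end": "interval_end"}
        )

    fusions_a = _norm(fusions_a)
    fusions_b = _norm(fusions_b)
    rows = []
    b_by_chrom = dict(tuple(fusions_b.groupby("chromosome")))
    for a in fusions_a.itertuples():
        grp = b_by_chrom.get(a.chromosome)
        if grp is None or grp.empty:
            rows.append((a.chromosome, a.interval_start, a.interval_end,
                         -1, -1, "unmatched", np.nan))
            continue
        mid_a = (a.interval_start + a.interval_end) / 2
        best = min(
            grp.itertuples(),
            key=lambda b: abs((b.interval_start + b.interval_end) / 2 - mid_a),
        )
        if best.interval_start <= a.interval_start and a.interval_end <= best.interval_end:
            verdict = "contained"
        elif a.interval_start < best.interval_end and best.interval_start < a.interval_end:
            verdict = "overlapping"
        else:
            verdict = "disjoint"
        dist = max(
            0,
            best.interval_start - a.interval_start,
            a.interval_end - best.interval_end,
        )
        rows.append((a.chromosome, a.interval_start, a.interval_end,
                     best.interval_start, best.interval_end, verdict, dist))
    return pd.DataFrame(
        rows,
        columns=["chromosome", "a_start", "a_end", "b_start", "b_end",
                 "verdict", "excess_bp"],
    )
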