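"""Chimeric-scaffold detection from marker discontinuities.

A scaffold carrying blocks of markers from two chromosomes, or from
distant positions on one linkage map, is a candidate misassembly; blocks
from map-adjacent markers are crossovers.  Breakpoint intervals are
narrowed using sites rejected from map construction whose patterns still
match exactly one flanking marker, and scaffolds are split under
retention rules: break at an assembly gap where one overlaps the
breakpoint, discard short markerless fragments, keep long ones as new
scaffolds.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import pandas as pd

from . import patterns
from .linkage import LinkageMap
from .markers import Marker


@dataclasses.dataclass
class Breakpoint:
    scaffold: str
    gap_start: int
    gap_end: int
    kind: str  # 'crossover' | 'misassembly'
    left_marker: str
    right_marker: str
    resolution: str | None = None  # break_at_gap | break_in_contig | discard_contig


def build_marker_blocks(assignments: pd.DataFrame) -> pd.DataFrame:
    """Concatenate runs of same-marker sites into blocks.

    ``assignments`` needs columns scaffold, pos, marker_id.  Blocks span
    first..last site (half-open end = last + 1); the returned frame also
    carries the inter-block gap to the previous block on the scaffold.
    """
    rows = []
    for scaffold, grp in assignments.groupby("scaffold"):
        grp = grp.sort_values("pos")
        start = prev_pos = None
        cur = None
        n_sites = 0
        for pos, mid in zip(grp.pos, grp.marker_id):
            if mid != cur:
                if cur is not None:
                    rows.append((scaffold, start, prev_pos + 1, cur, n_sites))
                start, cur, n_sites = pos, mid, 0
            prev_pos = pos
            n_sites += 1
        if cur is not None:
            rows.append((scaffold, start, prev_pos + 1, cur, n_sites))
    blocks = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "marker_id", "n_sites"]
    )
    blocks["gap_before"] = blocks.start - blocks.groupby("scaffold")["end"].shift()
    return blocks


def detect_discontinuities(
    blocks: pd.DataFrame,
    marks: Sequence[Marker],
    maps: dict[str, LinkageMap],
    *,
    max_map_jump: int = 1,
    min_block_sites: int = 2,
    recomb_rate_per_bp: float | None = None,
    rate_alpha: float = 1e-4,
) -> list[Breakpoint]:
    """Classify adjacent-block transitions as crossovers or misassemblies.

    Blocks of chromosome-assigned markers of any type (a maternal print
    block identifies its chromosome directly) yield an inter-chromosomal
    misassembly wherever adjacent blocks disagree on the chromosome.
    Within one chromosome, adjacency is measured as the recombinant
    distance between the flanking marker patterns: one recombinant
    offspring is an ordinary crossover; more than ``max_map_jump``
    recombinants means several offspring appear to recombine at the same
    physical point — a misassembly.  (Counting recombinants rather than
    map-order intervals keeps the call robust where repeated pattern
    classes make the marker order locally ambiguous.)  When the per-base
    crossover rate of the cross is supplied, a jump is only called a
    misassembly if its recombinant count is also implausible for the
    physical gap between the blocks (Poisson tail below ``rate_alpha``) —
    a wide marker gap is allowed to absorb several genuine crossovers.
    Blocks of unassigned markers are ignored.
    """
    from scipy.stats import poisson
    chrom_of: dict[str, str] = {}
    pattern_of: dict[str, str] = {}
    mapped: set[str] = set()
    for m in marks:
        if not m.chromosome:
            continue
        chrom_of[m.marker_id] = m.chromosome
        pattern_of[m.marker_id] = m.pattern
        lm = maps.get(m.chromosome)
        if lm is not None and m.marker_id in lm.marker_order:
            mapped.add(m.marker_id)

    out: list[Breakpoint] = []
    ann = blocks[blocks.marker_id.isin(chrom_of)]
    for scaffold, grp in ann.groupby("scaffold"):
        grp = grp.sort_values("start")
        rows = list(grp.itertuples())
        # single-site blocks are too error-prone to anchor a breakpoint
        deep = [r for r in rows if r.n_sites >= min_block_sites]
        # inter-chromosomal transitions between same-chromosome runs
        prev = deep[0] if deep else None
        for row in deep[1:]:
            if chrom_of[row.marker_id] != chrom_of[prev.marker_id]:
                out.append(
                    Breakpoint(scaffold, int(prev.end), int(row.start),
                               "misassembly", prev.marker_id, row.marker_id)
                )
            prev = row
        # intra-chromosomal discontinuities over mapped (paternal) blocks
        prev = None
        for row in deep:
            if row.marker_id not in mapped:
                continue
            if (
                prev is not None
                and row.marker_id != prev.marker_id
                and chrom_of[row.marker_id] == chrom_of[prev.marker_id]
            ):
                _, d, _ = patterns.recombination_fraction(
                    pattern_of[prev.marker_id], pattern_of[row.marker_id]
                )
                if d <= max_map_jump:
                    kind = "crossover"
                elif recomb_rate_per_bp is not None:
                    mu = recomb_rate_per_bp * max(1, row.start - prev.end)
                    kind = (
                        "misassembly"
                        if poisson.sf(d - 1, mu) < rate_alpha
                        else "crossover"
                    )
                else:
                    kind = "misassembly"
                out.append(
                    Breakpoint(scaffold, int(prev.end), int(row.start), kind,
                               prev.marker_id, row.marker_id)
                )
            prev = row
    return out


def refine_breakpoint(
    candidate: Breakpoint,
    rejected_sites: pd.DataFrame,
    marker_patterns: dict[str, str],
    *,
    claim_dist: int = 1,
    reject_dist: int = 3,
) -> Breakpoint:
    """Shrink a breakpoint gap by claiming rejected sites for a flank.

    ``rejected_sites`` needs columns scaffold, pos, pattern (recoded
    offspring calls for sites that failed map filters).  A site inside
    the gap whose pattern is within ``claim_dist`` mirror-aware
    mismatches of exactly one flanking marker — and at least
    ``reject_dist`` from the other — moves that flank's boundary past it.
    Ambiguous sites leave the gap unchanged.
    """
    left = marker_patterns[candidate.left_marker]
    right = marker_patterns[candidate.right_marker]
    inside = rejected_sites[
        (rejected_sites.scaffold == candidate.scaffold)
        & (rejected_sites.pos >= candidate.gap_start)
        & (rejected_sites.pos < candidate.gap_end)
    ].sort_values("pos")
    gs, ge = candidate.gap_start, candidate.gap_end
    for row in inside.itertuples():
        dl = patterns.mirror_distance(row.pattern, left)
        dr = patterns.mirror_distance(row.pattern, right)
        if dl <= claim_dist and dr >= reject_dist and row.pos + 1 > gs:
            gs = row.pos + 1
        elif dr <= claim_dist and dl >= reject_dist and row.pos < ge:
            ge = row.pos
    if gs >= ge:  # contradictory claims: keep the original interval
        gs, ge = candidate.gap_start, candidate.gap_end
    return dataclasses.replace(candidate, gap_start=gs, gap_end=ge)


def _n_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"N+", seq)]


def split_scaffold(
    name: str,
    seq: str,
    breakpoints: Sequence[Breakpoint],
    blocks: pd.DataFrame | None = None,
    *,
    min_retain_bp: int = 5000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Split a scaffold at misassembly breakpoints.

    A breakpoint overlapping an assembly gap (N-run) resolves at the gap;
    a contig wholly inside the breakpoint with no marker linking it to
    either side is discarded; an in-contig breakpoint carves out the
    misassembled interval, retaining it as a new scaffold only when it is
    at least ``min_retain_bp`` long or carries a marker.  Every base of
    the input is accounted for in the returned pieces or the log.
    """
    for bp in breakpoints:
        if not (0 <= bp.gap_start <= bp.gap_end <= len(seq)):
            raise ValueError(
                f"breakpoint {bp.gap_start}-{bp.gap_end} outside {name} "
                f"(length {len(seq)})"
            )
    has_marker = _marker_coverage(name, blocks)

    # each breakpoint yields a sorted list of "separator" intervals whose
    # removal/retention splits the scaffold
    log_rows = []
    cut_intervals: list[tuple[int, int, str]] = []  # (start, end, disposition)
    for bp in sorted(breakpoints, key=lambda b: b.gap_start):
        if bp.kind != "misassembly":
            continue
        runs = [
            (s, e) for s, e in _n_runs(seq) if s < bp.gap_end and e > bp.gap_start
        ]
        if runs:
            bp.resolution = "break_at_gap"
            # drop the gap runs; contigs strictly between them inside the
            # breakpoint are discarded unless a marker links them out
            for s, e in runs:
                cut_intervals.append((s, e, "gap_removed"))
            for (s1, e1), (s2, e2) in zip(runs[:-1], runs[1:]):
                if not has_marker(e1, s2):
                    cut_intervals.append((e1, s2, "discard:contig_in_breakpoint"))
                    bp.resolution = "discard_contig"
        else:
            mid_len = bp.gap_end - bp.gap_start
            if mid_len == 0:
                # point break inside a contig
                bp.resolution = "break_in_contig"
                cut_intervals.append((bp.gap_start, bp.gap_start, "point_break"))
            elif mid_len >= min_retain_bp or has_marker(bp.gap_start, bp.gap_end):
                bp.resolution = "break_in_contig"
                cut_intervals.append((bp.gap_start, bp.gap_end, "retain"))
            else:
                bp.resolution = "discard_contig"
                cut_intervals.append((bp.gap_start, bp.gap_end, "discard:short_markerless"))

    cut_intervals.sort()
    pieces: dict[str, str] = {}
    idx = 1
    prev = 0

    def emit(start: int, end: int, disposition: str) -> None:
        nonlocal idx
        if end <= start and disposition != "point_break":
            return
        if disposition in ("keep", "retain"):
            pname = f"{name}.{idx}"
            pieces[pname] = seq[start:end]
            log_rows.append((name, start, end, f"kept:{pname}"))
            idx += 1
        else:
            log_rows.append((name, start, end, disposition))

    for s, e, disp in cut_intervals:
        emit(prev, s, "keep")
        if disp == "point_break":
            pass
        elif disp == "retain":
            emit(s, e, "retain")
        else:
            emit(s, e, disp)
        prev = e
    emit(prev, len(seq), "keep")
    if not cut_intervals:  # no misassemblies: scaffold passes through
        pieces = {name: seq}
        log_rows = [(name, 0, len(seq), f"kept:{name}")]
    log = pd.DataFrame(log_rows, columns=["scaffold", "start", "end", "disposition"])
    return pieces, log


def _marker_coverage(name: str, blocks: pd.DataFrame | None):
    if blocks is None or blocks.empty:
        return lambda s, e: False
    mine = blocks[blocks.scaffold == name]

    def has(s: int, e: int) -> bool:
        return bool(((mine.start < e) & (mine.end > s)).any())

    return has


def apply_splits(
    seqs: dict[str, str],
    breakpoints: Sequence[Breakpoint],
    blocks: pd.DataFrame | None = None,
    *,
    min_retain_bp: int = 5000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Split every scaffold with misassembly breakpoints; others pass through."""
    by_scaffold: dict[str, list[Breakpoint]] = {}
    for bp in breakpoints:
        if bp.kind == "misassembly":
            by_scaffold.setdefault(bp.scaffold, []).append(bp)
    out: dict[str, str] = {}
    logs = []
    for name, seq in seqs.items():
        if name in by_scaffold:
            pieces, log = split_scaffold(
                name, seq, by_scaffold[name], blocks, min_retain_bp=min_retain_bp
            )
            out.update(pieces)
            logs.append(log)
        else:
            out[name] = seq
    log = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(
        columns=["scaffold", "start", "end", "disposition"]
    )
    return out, log
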