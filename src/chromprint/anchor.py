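"""Ordering and orienting scaffolds along chromosomes.

Scaffolds are grouped into *pools* by the linkage-map markers they carry:
a single scaffold bridging two or more consecutive markers is *anchored*
(ordered and oriented), a single scaffold at one marker is *unoriented*,
and several scaffolds sharing one marker are *unordered* (placed, sorted
by length).  Residual haplotypes are purged by rule — markerless
offcuts, offcuts co-locating with their parent scaffold, scaffolds whose
markers are strictly surrounded by a larger scaffold's markers, and
scaffolds contained in a same-or-neighbouring-pool scaffold by overlap
nodes (>10 kb needs >50% alignment, shorter needs >25%).  Runs of
consecutive anchored scaffolds are joined with 100-bp gaps, and each
chromosome is emitted as FASTA plus AGP.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .agp import AgpComponent, AgpGap, build_agp
from .linkage import LinkageMap

ANCHORED, UNORIENTED, UNORDERED = "anchored", "unoriented", "unordered"
JOIN_GAP = 100


@dataclasses.dataclass
class PoolMember:
    scaffold: str
    length: int
    strand: str | None  # None = unoriented


@dataclasses.dataclass
class Pool:
    chromosome: str
    marker_span: tuple[int, int]  # map order indices, inclusive
    members: list[PoolMember]
    status: str
    joins: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def member_names(self) -> list[str]:
        return [m.scaffold for m in self.members]


def build_pools(
    linkage_map: LinkageMap,
    blocks: pd.DataFrame,
    lengths: dict[str, int],
) -> tuple[list[Pool], list[str]]:
    """Group one chromosome's scaffolds into ordered pools.

    ``blocks`` are marker blocks (scaffold, start, end, marker_id) for
    markers on this chromosome's map.  A scaffold whose markers skip map
    positions (non-consecutive span) is routed back to misassembly
    review rather than pooled; these are returned separately.
    """
    order = {mid: i for i, mid in enumerate(linkage_map.marker_order)}
    mine = blocks[blocks.marker_id.isin(order)]
    suspicious: list[str] = []
    spans: dict[str, tuple[int, int, dict[int, float]]] = {}
    for scaffold, grp in mine.groupby("scaffold"):
        idxs = sorted({order[m] for m in grp.marker_id})
        lo, hi = idxs[0], idxs[-1]
        if idxs != list(range(lo, hi + 1)):
            suspicious.append(scaffold)
            continue
        # mean physical position per marker index, for orientation
        mean_pos = {
            order[mid]: float((g.start + g.end).mean() / 2)
            for mid, g in grp.groupby("marker_id")
        }
        spans[scaffold] = (lo, hi, mean_pos)

    anchored: list[Pool] = []
    singles: dict[int, list[str]] = {}
    for scaffold, (lo, hi, mean_pos) in spans.items():
        if hi > lo:
            ups = sum(
                1
                for i in range(lo, hi)
                for j in range(i + 1, hi + 1)
                if i in mean_pos and j in mean_pos and mean_pos[j] > mean_pos[i]
            )
            downs = sum(
                1
                for i in range(lo, hi)
                for j in range(i + 1, hi + 1)
                if i in mean_pos and j in mean_pos and mean_pos[j] < mean_pos[i]
            )
            strand = "+" if ups >= downs else "-"
            anchored.append(
                Pool(linkage_map.chromosome, (lo, hi),
                     [PoolMember(scaffold, lengths[scaffold], strand)], ANCHORED)
            )
        else:
            singles.setdefault(lo, []).append(scaffold)

    pools = anchored[:]
    for idx, scaffolds in singles.items():
        members = sorted(
            (PoolMember(s, lengths[s], None) for s in scaffolds),
            key=lambda m: (-m.length, m.scaffold),
        )
        status = UNORIENTED if len(members) == 1 else UNORDERED
        pools.append(Pool(linkage_map.chromosome, (idx, idx), members, status))
    pools.sort(key=lambda p: (p.marker_span[0], p.marker_span[1], p.status))
    return pools, suspicious


# --------------------------------------------------------------------------
# haplotype purging


@dataclasses.dataclass
class PurgeThresholds:
    long_scaffold_bp: int = 10_000
    long_min_pct: float = 50.0
    short_min_pct: float = 25.0


def purge_haplotypes(
    pools: list[Pool],
    nodes: pd.DataFrame,
    offcut_parent: dict[str, str] | None = None,
    *,
    thresholds: PurgeThresholds | None = None,
    marker_content: pd.DataFrame | None = None,
    lengths: dict[str, int] | None = None,
    scaffold_chromosome: dict[str, str] | None = None,
) -> tuple[list[Pool], pd.DataFrame]:
    """Remove residual haplotype scaffolds from pools.

    Rules (logged with rule ids): (offcut_colocated) an offcut in the
    same or neighbouring pool as its parent scaffold; (marker_contained)
    a single-marker scaffold whose marker is strictly surrounded by an
    anchored scaffold's markers; (node_contained) a scaffold covered by
    overlap nodes in a same/neighbouring-pool scaffold above the percent
    alignment thresholds.  Markerless offcuts never reach pools; pass
    ``marker_content`` (scaffold, has_marker) to log their removal too.
    """
    thresholds = thresholds or PurgeThresholds()
    offcut_parent = offcut_parent or {}
    removals: list[tuple[str, str, str]] = []

    pool_of: dict[str, int] = {}
    for i, p in enumerate(pools):
        for m in p.members:
            pool_of[m.scaffold] = i

    def neighbouring(i: int | None, j: int | None) -> bool:
        return i is not None and j is not None and abs(i - j) <= 1

    # rule: markerless offcuts (outside any pool)
    if marker_content is not None:
        for row in marker_content.itertuples():
            if row.scaffold in offcut_parent and not row.has_marker:
                removals.append((row.scaffold, "offcut_markerless", ""))

    # rule: offcut co-located with its parent
    for scaffold, parent in offcut_parent.items():
        if neighbouring(pool_of.get(scaffold), pool_of.get(parent)):
            removals.append((scaffold, "offcut_colocated", parent))

    # rule: marker containment (scaffold B at marker m inside A's span)
    anchored_spans = [
        (p.marker_span, p.members[0].scaffold)
        for p in pools
        if p.status == ANCHORED
    ]
    for p in pools:
        if p.status == ANCHORED:
            continue
        m_idx = p.marker_span[0]
        for (lo, hi), a_name in anchored_spans:
            if lo < m_idx < hi:
                for member in p.members:
                    removals.append((member.scaffold, "marker_contained", a_name))
                break

    # rule: node containment within same/neighbouring pools, or of a
    # scaffold that never entered a pool (no mapped paternal marker) but
    # is covered by a pooled scaffold of a compatible chromosome
    lengths = lengths or {}
    scaffold_chromosome = scaffold_chromosome or {}
    member_length = {
        m.scaffold: m.length for p in pools for m in p.members
    }
    removed_so_far = {r[0] for r in removals}
    for node in nodes.itertuples():
        for cand, host, c_iv in (
            (node.scaffold_b, node.scaffold_a, (node.b_start, node.b_end)),
            (node.scaffold_a, node.scaffold_b, (node.a_start, node.a_end)),
        ):
            if cand in removed_so_far:
                continue
            ci, hi_ = pool_of.get(cand), pool_of.get(host)
            if ci is not None:
                # pooled candidate needs a pooled same/neighbouring host
                if hi_ is None or not neighbouring(ci, hi_):
                    continue
            else:
                # marker-free candidate: containment in any compatible
                # scaffold is haplotype evidence
                cc = scaffold_chromosome.get(cand)
                hc = scaffold_chromosome.get(host)
                if cc is not None and hc is not None and cc != hc:
                    continue
                if cand not in lengths:
                    continue
            cand_len = member_length.get(cand, lengths.get(cand))
            host_len = member_length.get(host, lengths.get(host))
            if cand_len is None or host_len is None:
                continue
            if cand_len >= host_len:
                continue  # only the smaller copy can be the haplotype
            covered = 100.0 * (c_iv[1] - c_iv[0]) / cand_len
            pct = min(covered, float(node.pct_alignment))
            big = cand_len > thresholds.long_scaffold_bp
            if (big and pct > thresholds.long_min_pct) or (
                not big and pct > thresholds.short_min_pct
            ):
                removals.append((cand, "node_contained", host))
                removed_so_far.add(cand)

    removed = {r[0] for r in removals}
    cleaned: list[Pool] = []
    for p in pools:
        members = [m for m in p.members if m.scaffold not in removed]
        if not members:
            continue
        status = p.status
        if status == UNORDERED and len(members) == 1:
            status = UNORIENTED
        cleaned.append(
            Pool(p.chromosome, p.marker_span, members, status, p.joins)
        )
    log = pd.DataFrame(removals, columns=["scaffold", "rule", "kept_scaffold"])
    return cleaned, log


# --------------------------------------------------------------------------
# node-based refinement


def refine_with_nodes(
    pools: list[Pool],
    nodes: pd.DataFrame,
    lengths: dict[str, int],
    *,
    end_tolerance: int = 100,
) -> tuple[list[Pool], pd.DataFrame]:
    """Order and orient unordered pool members using end-overlap nodes.

    Members of one pool (or a markerless bridge scaffold linking two of
    them) with an overlap node at facing ends are ordered and oriented
    next to each other and marked for joining with a 100-bp gap.
    Contradictory node orientations leave both members unresolved and are
    logged.
    """
    from .merge import _which_end

    conflicts = []
    out: list[Pool] = []
    for p in pools:
        if p.status != UNORDERED:
            out.append(p)
            continue
        names = set(p.member_names())
        links: dict[str, list] = {}
        used_slots: set[tuple[str, str]] = set()
        pairs = []
        for node in nodes.itertuples():
            a, b = node.scaffold_a, node.scaffold_b
            if a in names and b in names:
                side_a = _which_end(
                    node.a_start, node.a_end, lengths[a], end_tolerance
                )
                side_b = _which_end(
                    node.b_start, node.b_end, lengths[b], end_tolerance
                )
                if side_a is None or side_b is None:
                    continue
                valid = (node.strand == "+" and side_a != side_b) or (
                    node.strand == "-" and side_a == side_b
                )
                if not valid:
                    continue
                if (a, side_a) in used_slots or (b, side_b) in used_slots:
                    conflicts.append((p.chromosome, a, b, "slot_conflict"))
                    continue
                used_slots.update([(a, side_a), (b, side_b)])
                pairs.append((a, side_a, b, side_b))
        if not pairs:
            out.append(p)
            continue
        # orient and order along the first chain found
        order: list[tuple[str, str]] = []
        a, side_a, b, side_b = pairs[0]
        order = [
            (a, "+" if side_a == "right" else "-"),
            (b, "+" if side_b == "left" else "-"),
        ]
        placed = {a, b}
        extended = True
        while extended:
            extended = False
            for a2, sa, b2, sb in pairs:
                if a2 == order[-1][0] and b2 not in placed:
                    order.append((b2, "+" if sb == "left" else "-"))
                    placed.add(b2)
                    extended = True
                elif b2 == order[0][0] and a2 not in placed:
                    order.insert(0, (a2, "+" if sa == "left" else "-"))
                    placed.add(a2)
                    extended = True
        members = [
            PoolMember(s, lengths[s], strand) for s, strand in order
        ] + [m for m in p.members if m.scaffold not in placed]
        status = ANCHORED if len(placed) == len(p.members) else UNORDERED
        joins = list(zip([s for s, _ in order[:-1]], [s for s, _ in order[1:]]))
        out.append(Pool(p.chromosome, p.marker_span, members, status, joins))
    log = pd.DataFrame(
        conflicts, columns=["chromosome", "scaffold_a", "scaffold_b", "reason"]
    )
    return out, log


# --------------------------------------------------------------------------
# chromosome building


@dataclasses.dataclass
class BuildElement:
    scaffold: str
    strand: str  # '+' when unknown, recorded via status
    status: str
    joined_to_prev: bool


@dataclasses.dataclass
class ChromosomeBuild:
    chromosome: str
    elements: list[BuildElement]

    def placed_scaffolds(self) -> list[str]:
        return [e.scaffold for e in self.elements]


def join_anchored(
    pools: list[Pool], seqs: dict[str, str], chromosome: str
) -> tuple[ChromosomeBuild, dict[str, str], pd.DataFrame]:
    """Assemble a chromosome: join anchored runs, place the rest.

    Consecutive anchored scaffolds (and node-joined pool members) are
    concatenated into single super-scaffolds with 100-bp gaps; unoriented
    and unordered members are placed in order but left as their own
    scaffolds.  Returns the build, the new scaffold sequences, and the
    chromosome-level AGP.
    """
    elements: list[BuildElement] = []
    prev_anchored = False
    for p in pools:
        if p.status == ANCHORED:
            for i, m in enumerate(p.members):
                joined = (i > 0) or prev_anchored
                elements.append(
                    BuildElement(m.scaffold, m.strand or "+", ANCHORED, joined)
                )
            prev_anchored = True
        else:
            for m in p.members:
                elements.append(
                    BuildElement(m.scaffold, m.strand or "+", p.status, False)
                )
            prev_anchored = False

    new_seqs: dict[str, str] = {}
    agp_objects: dict[str, list] = {}
    run: list[BuildElement] = []
    runs: list[list[BuildElement]] = []
    for e in elements:
        if e.joined_to_prev and run:
            run.append(e)
        else:
            if run:
                runs.append(run)
            run = [e]
    if run:
        runs.append(run)

    from .sim import revcomp

    chrom_parts: list = []
    si = 1
    for r in runs:
        if len(r) == 1:
            name = r[0].scaffold
            new_seqs[name] = seqs[name]
            comp = AgpComponent(name, len(seqs[name]), r[0].strand)
        else:
            name = f"{chromosome}_s{si}"
            si += 1
            chunks = []
            parts: list = []
            for i, e in enumerate(r):
                if i:
                    chunks.append("N" * JOIN_GAP)
                    parts.append(AgpGap(JOIN_GAP))
                s = seqs[e.scaffold]
                chunks.append(revcomp(s) if e.strand == "-" else s)
                parts.append(AgpComponent(e.scaffold, len(s), e.strand))
            new_seqs[name] = "".join(chunks)
            agp_objects[name] = parts
            comp = AgpComponent(name, len(new_seqs[name]), "+")
        if chrom_parts:
            chrom_parts.append(AgpGap(JOIN_GAP, gap_type="contig", linkage="no",
                                      evidence="na"))
        chrom_parts.append(comp)
    agp_objects[chromosome] = chrom_parts
    agp = build_agp(agp_objects)
    return ChromosomeBuild(chromosome, elements), new_seqs, agp


# --------------------------------------------------------------------------
# unplaced scaffold selection


def select_unplaced(
    scaffolds: list[str],
    maternal_scaffolds: set[str],
    paternal_scaffolds: set[str],
    gene_scaffolds: set[str],
    print_chromosome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Classify leftover scaffolds: keep chromosome-assigned or gene-bearing.

    A scaffold with a maternal print but no paternal marker keeps its
    chromosome assignment (position unknown); a markerless scaffold with
    a gene is kept; everything else is discarded.
    """
    print_chromosome = print_chromosome or {}
    rows = []
    for s in scaffolds:
        if s in maternal_scaffolds and s not in paternal_scaffolds:
            rows.append((s, "chromosome_assigned", print_chromosome.get(s, "")))
        elif s in gene_scaffolds:
            rows.append((s, "gene_bearing", ""))
        else:
            rows.append((s, "discarded", ""))
    return pd.DataFrame(rows, columns=["scaffold", "fate", "chromosome"])
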