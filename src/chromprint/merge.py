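"""Assembly merging: plans, vetoes, iteration and coordinate transfer.

An overlap *node* records an alignment between two scaffolds (intervals,
strand, percent alignment).  A *merge plan* lists the parts that tile
each merged scaffold; applying it yields the merged FASTA together with a
*transfer map* that accounts for every base of the input assembly —
placed in a merged scaffold, kept as an *offcut* (the leftover of a
partially used scaffold), collapsed onto its homologous copy, or dropped
with a reason.  Transfer maps compose across successive merges, so
features and markers lift from any earlier assembly version to the
current one.  Nodes can be vetoed before planning when they contradict
linkage-map chromosome assignments or would break curated genes (with a
part swap when the alternative copy keeps the gene intact).
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .sim import NODE_COLUMNS, revcomp

PLACED, OFFCUT, DROPPED = "placed", "offcut", "dropped"

TRANSFER_COLUMNS = [
    "old_scaffold", "old_start", "old_end",
    "new_scaffold", "new_start", "new_end",
    "strand", "status", "reason",
]


class TransferMap:
    """Oriented interval mapping between two assembly versions.

    Records are 0-based half-open and length-preserving; ``strand`` '-'
    means the old interval reads reverse-complemented in the new
    coordinates.  Dropped intervals keep ``new_* = -1`` and a reason.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        source: str | None = None,
        target: str | None = None,
    ):
        df = records.reset_index(drop=True).copy()
        if "reason" not in df.columns:
            df["reason"] = ""
        self.df = df[TRANSFER_COLUMNS]
        self.source = source
        self.target = target
        self._trees: dict[str, IntervalTree] | None = None

    # ---- construction --------------------------------------------------

    @classmethod
    def identity(
        cls, lengths: dict[str, int], source: str | None = None
    ) -> "TransferMap":
        rows = [
            (name, 0, ln, name, 0, ln, "+", PLACED, "")
            for name, ln in lengths.items()
        ]
        return cls(pd.DataFrame(rows, columns=TRANSFER_COLUMNS), source, source)

    # ---- lookups -------------------------------------------------------

    def _tree(self, scaffold: str) -> IntervalTree:
        if self._trees is None:
            self._trees = defaultdict(IntervalTree)
            for rec in self.df.itertuples():
                if rec.old_end > rec.old_start:
                    self._trees[rec.old_scaffold][rec.old_start:rec.old_end] = rec
        return self._trees[scaffold]

    def map_interval(
        self, scaffold: str, start: int, end: int
    ) -> list[dict]:
        """Map an old interval; returns pieces with status annotations."""
        out = []
        for iv in sorted(self._tree(scaffold)[start:end]):
            rec = iv.data
            lo, hi = max(start, rec.old_start), min(end, rec.old_end)
            piece = dict(old_scaffold=scaffold, old_start=lo, old_end=hi,
                         status=rec.status, reason=rec.reason)
            if rec.status == DROPPED:
                piece.update(new_scaffold="", new_start=-1, new_end=-1, strand=".")
            else:
                off_lo, off_hi = lo - rec.old_start, hi - rec.old_start
                if rec.strand == "+":
                    ns = rec.new_start + off_lo
                    ne = rec.new_start + off_hi
                else:
                    ne = rec.new_end - off_lo
                    ns = rec.new_end - off_hi
                piece.update(new_scaffold=rec.new_scaffold, new_start=int(ns),
                             new_end=int(ne), strand=rec.strand)
            out.append(piece)
        return out

    def map_position(self, scaffold: str, pos: int) -> tuple[str, int, str] | None:
        pieces = [
            p for p in self.map_interval(scaffold, pos, pos + 1)
            if p["status"] != DROPPED
        ]
        if not pieces:
            return None
        p = pieces[0]
        return p["new_scaffold"], p["new_start"], p["strand"]

    # ---- algebra -------------------------------------------------------

    def compose(self, other: "TransferMap") -> "TransferMap":
        """old->mid composed with mid->new (interval algebra, strand product)."""
        if (
            self.target is not None
            and other.source is not None
            and self.target != other.source
        ):
            raise ValueError(
                f"assembly mismatch: {self.target!r} vs {other.source!r}"
            )
        rows = []
        for rec in self.df.itertuples():
            if rec.status == DROPPED:
                rows.append((rec.old_scaffold, rec.old_start, rec.old_end,
                             "", -1, -1, ".", DROPPED, rec.reason))
                continue
            pieces = other.map_interval(rec.new_scaffold, rec.new_start, rec.new_end)
            covered = []
            for p in pieces:
                mid_lo, mid_hi = p["old_start"], p["old_end"]
                covered.append((mid_lo, mid_hi))
                # back through rec to old coordinates
                if rec.strand == "+":
                    o_lo = rec.old_start + (mid_lo - rec.new_start)
                    o_hi = rec.old_start + (mid_hi - rec.new_start)
                else:
                    o_hi = rec.old_end - (mid_lo - rec.new_start)
                    o_lo = rec.old_end - (mid_hi - rec.new_start)
                if p["status"] == DROPPED:
                    rows.append((rec.old_scaffold, o_lo, o_hi, "", -1, -1,
                                 ".", DROPPED, p["reason"]))
                    continue
                strand = "+" if rec.strand == p["strand"] else "-"
                status = OFFCUT if OFFCUT in (rec.status, p["status"]) else PLACED
                rows.append((rec.old_scaffold, o_lo, o_hi, p["new_scaffold"],
                             p["new_start"], p["new_end"], strand, status,
                             p["reason"]))
            # mid intervals not covered by the second map are lost
            covered.sort()
            cur = rec.new_start
            for lo, hi in covered:
                if lo > cur:
                    o = self._back(rec, cur, lo)
                    rows.append((rec.old_scaffold, o[0], o[1], "", -1, -1,
                                 ".", DROPPED, "lost"))
                cur = max(cur, hi)
            if cur < rec.new_end:
                o = self._back(rec, cur, rec.new_end)
                rows.append((rec.old_scaffold, o[0], o[1], "", -1, -1,
                             ".", DROPPED, "lost"))
        df = pd.DataFrame(rows, columns=TRANSFER_COLUMNS)
        df = df.sort_values(["old_scaffold", "old_start"]).reset_index(drop=True)
        return TransferMap(df, self.source, other.target)

    @staticmethod
    def _back(rec, mid_lo: int, mid_hi: int) -> tuple[int, int]:
        if rec.strand == "+":
            return (rec.old_start + (mid_lo - rec.new_start),
                    rec.old_start + (mid_hi - rec.new_start))
        return (rec.old_end - (mid_hi - rec.new_start),
                rec.old_end - (mid_lo - rec.new_start))

    # ---- io ------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TransferMap":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return cls(df)


# --------------------------------------------------------------------------
# merge plans

PLAN_COLUMNS = ["new_scaffold", "part_order", "source_scaffold", "start", "end", "strand"]
CONTAINMENT_COLUMNS = [
    "scaffold_b", "b_start", "b_end", "scaffold_a", "a_start", "a_end", "strand",
]


def empty_plan() -> pd.DataFrame:
    return pd.DataFrame(columns=PLAN_COLUMNS)


def apply_merge_plan(
    seqs: dict[str, str],
    plan: pd.DataFrame,
    containments: pd.DataFrame | None = None,
) -> tuple[dict[str, str], TransferMap]:
    """Build the merged assembly and the covering transfer map.

    Plan rows tile each new scaffold from oriented source parts; source
    intervals may appear at most once across the plan.  Scaffolds not
    touched pass through under their own names; leftover portions of
    partially used scaffolds become offcut scaffolds
    (``<name>.off<i>``).  ``containments`` collapses whole regions of a
    redundant scaffold onto the homologous interval of its keeper (equal
    lengths required); their bases are mapped, not dropped.
    """
    if len(plan):
        plan = plan.sort_values(["new_scaffold", "part_order"]).reset_index(drop=True)
    used: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def mark_used(name: str, start: int, end: int) -> None:
        if name not in seqs:
            raise KeyError(f"unknown scaffold {name!r}")
        if not 0 <= start < end <= len(seqs[name]):
            raise ValueError(f"part {name}:{start}-{end} out of bounds")
        for s, e in used[name]:
            if start < e and end > s:
                raise ValueError(f"overlapping plan intervals on {name}")
        used[name].append((start, end))

    for row in plan.itertuples():
        mark_used(row.source_scaffold, row.start, row.end)
    if containments is not None:
        for c in containments.itertuples():
            if c.b_end - c.b_start != c.a_end - c.a_start:
                raise ValueError("containment intervals must be equal length")
            mark_used(c.scaffold_b, c.b_start, c.b_end)

    new_seqs: dict[str, str] = {}
    rows = []
    if len(plan):
        for name, grp in plan.groupby("new_scaffold", sort=False):
            chunks = []
            offset = 0
            for row in grp.itertuples():
                piece = seqs[row.source_scaffold][row.start : row.end]
                if row.strand == "-":
                    piece = revcomp(piece)
                chunks.append(piece)
                rows.append((row.source_scaffold, row.start, row.end, name,
                             offset, offset + len(piece), row.strand, PLACED, ""))
                offset += len(piece)
            new_seqs[name] = "".join(chunks)

    # untouched scaffolds pass through; partially used ones leave offcuts
    for name, seq in seqs.items():
        if name not in used:
            new_seqs[name] = seq
            rows.append((name, 0, len(seq), name, 0, len(seq), "+", PLACED, ""))
            continue
        ivs = sorted(used[name])
        cur = 0
        oi = 1
        for s, e in ivs + [(len(seq), len(seq))]:
            if s > cur:
                off_name = f"{name}.off{oi}"
                oi += 1
                new_seqs[off_name] = seq[cur:s]
                rows.append((name, cur, s, off_name, 0, s - cur, "+", OFFCUT, ""))
            cur = max(cur, e)

    tm = TransferMap(pd.DataFrame(rows, columns=TRANSFER_COLUMNS))

    # containment regions map through the keeper copy's own placement
    if containments is not None and len(containments):
        crows = []
        for c in containments.itertuples():
            for p in tm.map_interval(c.scaffold_a, c.a_start, c.a_end):
                # back-map the keeper piece to the contained scaffold
                lo = p["old_start"] - c.a_start
                hi = p["old_end"] - c.a_start
                if c.strand == "+":
                    b_lo, b_hi = c.b_start + lo, c.b_start + hi
                    strand = p["strand"]
                else:
                    b_lo, b_hi = c.b_end - hi, c.b_end - lo
                    strand = "." if p["strand"] == "." else (
                        "+" if p["strand"] == "-" else "-"
                    )
                if p["status"] == DROPPED:
                    crows.append((c.scaffold_b, b_lo, b_hi, "", -1, -1, ".",
                                  DROPPED, "keeper_dropped"))
                else:
                    crows.append((c.scaffold_b, b_lo, b_hi, p["new_scaffold"],
                                  p["new_start"], p["new_end"], strand, PLACED,
                                  "collapsed_haplotype"))
        tm = TransferMap(
            pd.concat(
                [tm.df, pd.DataFrame(crows, columns=TRANSFER_COLUMNS)],
                ignore_index=True,
            )
        )
    return new_seqs, tm


# --------------------------------------------------------------------------
# feature transfer


def transfer_features(
    features: pd.DataFrame, tm: TransferMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lift features (scaffold, start, end, strand, ...) through a transfer.

    Features landing wholly inside one target scaffold re-coordinate
    (strand-aware, length preserved); features split over two or more
    target scaffolds or partially lost are reported broken with the
    fraction transferred.
    """
    mapped_rows = []
    broken_rows = []
    for feat in features.itertuples():
        tree_hits = tm.map_interval(feat.scaffold, feat.start, feat.end)
        placed = [p for p in tree_hits if p["status"] != DROPPED]
        total = feat.end - feat.start
        got = sum(p["old_end"] - p["old_start"] for p in tree_hits)
        if got < total:
            raise ValueError(
                f"feature {feat.scaffold}:{feat.start}-{feat.end} off the "
                "end of its scaffold"
            )
        targets = {p["new_scaffold"] for p in placed}
        placed_len = sum(p["old_end"] - p["old_start"] for p in placed)
        if len(targets) == 1 and placed_len == total and len(placed) >= 1:
            new_scaffold = placed[0]["new_scaffold"]
            lo = min(p["new_start"] for p in placed)
            hi = max(p["new_end"] for p in placed)
            if hi - lo == total:  # contiguous on the target
                strand = getattr(feat, "strand", "+")
                flip = placed[0]["strand"] == "-"
                new_strand = (
                    strand if not flip else ("-" if strand == "+" else "+")
                )
                d = feat._asdict()
                d.pop("Index", None)
                d.update(scaffold=new_scaffold, start=lo, end=hi, strand=new_strand)
                mapped_rows.append(d)
                continue
        for p in placed:
            broken_rows.append(
                dict(scaffold=feat.scaffold, start=feat.start, end=feat.end,
                     piece_new_scaffold=p["new_scaffold"],
                     piece_new_start=p["new_start"], piece_new_end=p["new_end"],
                     fraction=placed_len / total)
            )
        if not placed:
            broken_rows.append(
                dict(scaffold=feat.scaffold, start=feat.start, end=feat.end,
                     piece_new_scaffold="", piece_new_start=-1,
                     piece_new_end=-1, fraction=0.0)
            )
    mapped = pd.DataFrame(mapped_rows)
    broken = pd.DataFrame(
        broken_rows,
        columns=["scaffold", "start", "end", "piece_new_scaffold",
                 "piece_new_start", "piece_new_end", "fraction"],
    )
    return mapped, broken


# --------------------------------------------------------------------------
# node vetoes


def veto_nodes(
    nodes: pd.DataFrame,
    scaffold_chromosome: dict[str, str],
    genes: pd.DataFrame | None = None,
    lengths: dict[str, int] | None = None,
    reject_list: set[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, str], set[tuple[str, str]]]:
    """Accept/reject nodes against linkage and curated-gene evidence.

    Returns (accepted nodes, rejected log, swap directives mapping node
    index -> part to keep, updated persistent reject list).  A node whose
    scaffolds map to different chromosomes is rejected; a node whose
    default kept part (``a``) would break a curated gene swaps to ``b``
    when that leaves all genes intact, else is rejected.  Rejected pairs
    persist across merge iterations via ``reject_list``.
    """
    reject_list = set(reject_list or ())
    genes = genes if genes is not None else pd.DataFrame(
        columns=["gene_id", "scaffold", "start", "end", "strand", "curated"]
    )
    curated = genes[genes.get("curated", True) == True]  # noqa: E712
    accepted_idx = []
    rejected = []
    swaps: dict[int, str] = {}
    for idx, node in nodes.iterrows():
        pair = (node.scaffold_a, node.scaffold_b)
        if pair in reject_list or pair[::-1] in reject_list:
            rejected.append((idx, *pair, "reject_list"))
            continue
        ca = scaffold_chromosome.get(node.scaffold_a)
        cb = scaffold_chromosome.get(node.scaffold_b)
        if ca and cb and ca != cb:
            rejected.append((idx, *pair, "linkage_conflict"))
            reject_list.add(pair)
            continue
        if len(curated):
            a_broken = _genes_broken(
                curated, node.scaffold_b, node.b_start, node.b_end, lengths
            )
            if a_broken:
                b_broken = _genes_broken(
                    curated, node.scaffold_a, node.a_start, node.a_end, lengths
                )
                if not b_broken:
                    swaps[idx] = "b_part"
                else:
                    rejected.append((idx, *pair, "gene_breakage"))
                    reject_list.add(pair)
                    continue
        accepted_idx.append(idx)
    accepted = nodes.loc[accepted_idx].copy()
    rejected_df = pd.DataFrame(
        rejected, columns=["node_index", "scaffold_a", "scaffold_b", "reason"]
    )
    return accepted, rejected_df, swaps, reject_list


def _genes_broken(
    genes: pd.DataFrame,
    scaffold: str,
    iv_start: int,
    iv_end: int,
    lengths: dict[str, int] | None,
) -> bool:
    """True if replacing [iv_start, iv_end) of scaffold cuts a gene."""
    mine = genes[genes.scaffold == scaffold]
    if mine.empty:
        return False
    length = (lengths or {}).get(scaffold)
    for b in (iv_start, iv_end):
        if b == 0 or (length is not None and b == length):
            continue  # scaffold end: nothing beyond to cut off
        if bool(((mine.start < b) & (mine.end > b)).any()):
            return True
    return False


# --------------------------------------------------------------------------
# plan construction from nodes


def plan_from_nodes(
    nodes: pd.DataFrame,
    seqs: dict[str, str],
    *,
    swaps: dict[int, str] | None = None,
    containment_frac: float = 0.9,
    end_tolerance: int = 100,
    min_score: float = 0.0,
    merged_prefix: str = "mrg",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy merge layout from accepted overlap nodes.

    Nodes covering at least ``containment_frac`` of scaffold ``b`` are
    containments: ``b`` collapses onto ``a``.  Remaining nodes at
    scaffold ends chain scaffolds end-to-end (highest score first, each
    scaffold end used once, cycles refused); the overlapping region is
    kept from the ``a`` side unless a swap directive says otherwise.
    """
    swaps = swaps or {}
    contain_rows = []
    end_nodes = []
    for idx, node in nodes.iterrows():
        if node.score < min_score:
            continue
        len_b = len(seqs[node.scaffold_b])
        len_a = len(seqs[node.scaffold_a])
        if (node.b_end - node.b_start) >= containment_frac * len_b:
            contain_rows.append(
                dict(scaffold_b=node.scaffold_b, b_start=node.b_start,
                     b_end=node.b_end, scaffold_a=node.scaffold_a,
                     a_start=node.a_start, a_end=node.a_end, strand=node.strand)
            )
            continue
        side_a = _which_end(node.a_start, node.a_end, len_a, end_tolerance)
        side_b = _which_end(node.b_start, node.b_end, len_b, end_tolerance)
        if side_a is None or side_b is None:
            continue
        valid = (node.strand == "+" and side_a != side_b) or (
            node.strand == "-" and side_a == side_b
        )
        if valid:
            end_nodes.append((idx, node, side_a, side_b))

    # greedy chaining with union-find cycle refusal
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    slot_used: set[tuple[str, str]] = set()
    links = []
    end_nodes.sort(key=lambda t: (-t[1].score, t[0]))
    for idx, node, side_a, side_b in end_nodes:
        a, b = node.scaffold_a, node.scaffold_b
        if (a, side_a) in slot_used or (b, side_b) in slot_used:
            continue
        if find(a) == find(b):
            continue
        slot_used.update([(a, side_a), (b, side_b)])
        parent[find(a)] = find(b)
        keep = swaps.get(idx, "a_part")
        links.append(dict(a=a, side_a=side_a, b=b, side_b=side_b,
                          strand=node.strand, node=node, keep=keep))

    plan_rows, junction_contain = _chains_to_plan(links, seqs, merged_prefix)
    plan = pd.DataFrame(plan_rows, columns=PLAN_COLUMNS)
    # a wholly contained scaffold cannot also chain
    whole = {c["scaffold_b"] for c in contain_rows}
    if whole and len(plan):
        drop_new = set(plan[plan.source_scaffold.isin(whole)].new_scaffold)
        dropped_srcs = set(plan[plan.new_scaffold.isin(drop_new)].source_scaffold)
        plan = plan[~plan.new_scaffold.isin(drop_new)].reset_index(drop=True)
        junction_contain = [
            c for c in junction_contain
            if c["scaffold_b"] not in dropped_srcs
            and c["scaffold_a"] not in dropped_srcs
        ]
    containments = pd.DataFrame(
        contain_rows + junction_contain, columns=CONTAINMENT_COLUMNS
    )
    return plan, containments


def _which_end(start: int, end: int, length: int, tol: int) -> str | None:
    if start <= tol and end >= length - tol:
        return None  # spans the whole scaffold: containment-like
    if end >= length - tol:
        return "right"
    if start <= tol:
        return "left"
    return None


def _chains_to_plan(
    links: list[dict], seqs: dict[str, str], prefix: str
) -> tuple[list[tuple], list[dict]]:
    by_scaffold: dict[str, list[dict]] = defaultdict(list)
    for ln in links:
        by_scaffold[ln["a"]].append(ln)
        by_scaffold[ln["b"]].append(ln)

    visited: set[str] = set()
    plan_rows: list[tuple] = []
    contain_rows: list[dict] = []
    midx = 1
    starts = sorted(
        [s for s, ls in by_scaffold.items() if len(ls) == 1]
    )
    for start in starts:
        if start in visited:
            continue
        # walk the chain
        chain: list[tuple[str, str]] = []  # (scaffold, orientation)
        trims: dict[int, int] = {}  # junction i (between chain[i], chain[i+1]) trim on which side
        junctions: list[dict] = []
        ln = by_scaffold[start][0]
        # orient start so its linked side faces chain-right
        side = ln["side_a"] if ln["a"] == start else ln["side_b"]
        orient = "+" if side == "right" else "-"
        chain.append((start, orient))
        visited.add(start)
        cur, cur_orient, cur_link = start, orient, ln
        while cur_link is not None:
            other = cur_link["b"] if cur_link["a"] == cur else cur_link["a"]
            o_side = (
                cur_link["side_b"] if cur_link["a"] == cur else cur_link["side_a"]
            )
            o_orient = "+" if o_side == "left" else "-"
            junctions.append(cur_link)
            chain.append((other, o_orient))
            visited.add(other)
            nxt = [l for l in by_scaffold[other] if l is not cur_link]
            cur, cur_orient = other, o_orient
            cur_link = nxt[0] if nxt else None

        # compute per-scaffold trims from junction overlaps
        trim_left: Counter = Counter()
        trim_right: Counter = Counter()
        for i, ln2 in enumerate(junctions):
            upstream, up_or = chain[i]
            downstream, dn_or = chain[i + 1]
            node = ln2["node"]
            keep = ln2["keep"]
            # which chain member loses its overlap copy
            keep_scaffold = node.scaffold_a if keep == "a_part" else node.scaffold_b
            lose = downstream if keep_scaffold == upstream else upstream
            if lose == node.scaffold_b:
                lose_iv = (node.b_start, node.b_end)
                keep_iv = (node.a_start, node.a_end)
            else:
                lose_iv = (node.a_start, node.a_end)
                keep_iv = (node.b_start, node.b_end)
            ovl = lose_iv[1] - lose_iv[0]
            lose_or = dn_or if lose == downstream else up_or
            # losing scaffold trims its junction-facing end
            facing_chain_left = lose == downstream
            native_left = (lose_or == "+") == facing_chain_left
            if native_left:
                trim_left[lose] += ovl
                trimmed_iv = (0, ovl)
            else:
                trim_right[lose] += ovl
                trimmed_iv = (len(seqs[lose]) - ovl, len(seqs[lose]))
            # the trimmed overlap copy maps onto the kept copy when the
            # node interval sits exactly at the trimmed end
            if (
                trimmed_iv == lose_iv
                and keep_iv[1] - keep_iv[0] == ovl
            ):
                contain_rows.append(
                    dict(scaffold_b=lose, b_start=lose_iv[0], b_end=lose_iv[1],
                         scaffold_a=keep_scaffold, a_start=keep_iv[0],
                         a_end=keep_iv[1], strand=node.strand)
                )

        name = f"{prefix}{midx:05d}"
        midx += 1
        for order, (scf, orient) in enumerate(chain):
            s = trim_left.get(scf, 0)
            e = len(seqs[scf]) - trim_right.get(scf, 0)
            plan_rows.append((name, order, scf, s, e, orient))
    return plan_rows, contain_rows


# --------------------------------------------------------------------------
# iterated merging


@dataclasses.dataclass
class MergeResult:
    seqs: dict[str, str]
    transfer: TransferMap
    iterations: int
    log: list[dict]


def iterate_merge(
    seqs: dict[str, str],
    node_source: Callable[[dict[str, str]], pd.DataFrame],
    *,
    vetoer: Callable[[pd.DataFrame], tuple[pd.DataFrame, dict[int, str]]] | None = None,
    max_iterations: int = 20,
    containment_frac: float = 0.9,
    min_score: float = 0.0,
) -> MergeResult:
    """Apply merge rounds until a round merges nothing.

    Each round asks ``node_source`` for overlap nodes on the current
    assembly, vetoes them, builds and applies a plan, and composes the
    transfer.  A round with a nonempty plan that fails to reduce the
    scaffold count aborts with diagnostics.
    """
    cumulative = TransferMap.identity({n: len(s) for n, s in seqs.items()})
    log: list[dict] = []
    for it in range(1, max_iterations + 1):
        nodes = node_source(seqs)
        if nodes is None or not len(nodes):
            log.append(dict(iteration=it, nodes=0, merged=0))
            return MergeResult(seqs, cumulative, it, log)
        swaps: dict[int, str] = {}
        if vetoer is not None:
            nodes, swaps = vetoer(nodes)
        plan, containments = plan_from_nodes(
            nodes, seqs, swaps=swaps,
            containment_frac=containment_frac, min_score=min_score,
            merged_prefix=f"mrg{it}_",
        )
        if not len(plan) and not len(containments):
            log.append(dict(iteration=it, nodes=len(nodes), merged=0))
            return MergeResult(seqs, cumulative, it, log)
        before = len(seqs)
        new_seqs, tm = apply_merge_plan(seqs, plan, containments)
        if len(new_seqs) >= before:
            raise RuntimeError(
                f"iteration {it}: scaffold count did not decrease "
                f"({before} -> {len(new_seqs)}) with a nonempty plan"
            )
        cumulative = cumulative.compose(tm)
        log.append(
            dict(iteration=it, nodes=len(nodes),
                 merged=before - len(new_seqs))
        )
        seqs = new_seqs
    return MergeResult(seqs, cumulative, max_iterations, log)


# --------------------------------------------------------------------------
# node discovery on small assemblies


def find_end_overlaps(
    seqs: dict[str, str],
    min_len: int = 500,
    min_identity: float = 90.0,
    *,
    k: int = 21,
    window: int = 20_000,
) -> pd.DataFrame:
    """Detect end-to-end overlaps between scaffolds by seeded alignment.

    Shared k-mers between one scaffold's suffix window and another's
    prefix window (forward or reverse-complement) vote for an overlap
    length; the candidate is verified by global alignment (edlib) of the
    implied end regions and emitted as a node when identity and length
    pass the thresholds.  Intended for small fixtures; production nodes
    can come from any whole-genome aligner.
    """
    import edlib

    names = sorted(seqs)
    suffix_kmers: dict[str, dict[str, list[int]]] = {}
    for n in names:
        s = seqs[n]
        w = s[-window:]
        base = len(s) - len(w)
        d: dict[str, list[int]] = defaultdict(list)
        for i in range(0, len(w) - k + 1):
            d[w[i : i + k]].append(base + i)
        suffix_kmers[n] = d

    rc_suffix_kmers: dict[str, dict[str, list[int]]] = {}
    for n in names:
        s = revcomp(seqs[n])
        w = s[-window:]
        base = len(s) - len(w)
        d: dict[str, list[int]] = defaultdict(list)
        for i in range(0, len(w) - k + 1):
            d[w[i : i + k]].append(base + i)
        rc_suffix_kmers[n] = d

    rows = []
    seen: set[tuple] = set()
    # cases: suffix(a) vs prefix(b) [right-left, '+'];
    # suffix(a) vs prefix(rc(b)) [right-right, '-'];
    # suffix(rc(a)) vs prefix(b) [left-left, '-']
    for a in names:
        for b in names:
            if a == b:
                continue
            for case in ("RL", "RR", "LL"):
                if case != "RL" and a > b:
                    continue  # '-' cases are symmetric in (a, b)
                if case == "LL":
                    kmers = rc_suffix_kmers[a]
                    a_seq = revcomp(seqs[a])
                    target = seqs[b]
                else:
                    kmers = suffix_kmers[a]
                    a_seq = seqs[a]
                    target = seqs[b] if case == "RL" else revcomp(seqs[b])
                prefix = target[:window]
                votes: Counter = Counter()
                step = max(1, k // 2)
                for j in range(0, max(1, len(prefix) - k + 1), step):
                    kmer = prefix[j : j + k]
                    for apos in kmers.get(kmer, ()):
                        L = len(a_seq) - apos + j
                        if L >= min_len:
                            votes[L] += 1
                if not votes:
                    continue
                L = votes.most_common(1)[0][0]
                L = min(L, len(a_seq), len(target))
                res = edlib.align(a_seq[-L:], target[:L], mode="NW", task="distance")
                identity = 100.0 * (1 - res["editDistance"] / L)
                if identity < min_identity:
                    continue
                len_a, len_b = len(seqs[a]), len(seqs[b])
                if case == "RL":
                    a_iv, b_iv, strand = (len_a - L, len_a), (0, L), "+"
                elif case == "RR":
                    a_iv, b_iv, strand = (len_a - L, len_a), (len_b - L, len_b), "-"
                else:  # LL
                    a_iv, b_iv, strand = (0, L), (0, L), "-"
                key = (a, b, case, L)
                if key in seen:
                    continue
                seen.add(key)
                rows.append(
                    dict(scaffold_a=a, a_start=a_iv[0], a_end=a_iv[1],
                         scaffold_b=b, b_start=b_iv[0], b_end=b_iv[1],
                         strand=strand, pct_alignment=round(identity, 2),
                         score=round(L * identity / 100.0, 1))
                )
    return pd.DataFrame(rows, columns=NODE_COLUMNS)
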