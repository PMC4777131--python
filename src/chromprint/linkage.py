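"""Per-chromosome paternal linkage maps.

Markers on one chromosome are ordered by seriation: the order minimizing
the total count of recombinant offspring between adjacent markers (the
objective a minimum-spanning-tree mapper optimizes), found by exhaustive
search on small instances and nearest-neighbour construction plus 2-opt
refinement otherwise.  Centimorgan distance between adjacent markers is
``rf x 100`` — with an F2 counting single paternal meioses and dense
markers, no mapping function is applied.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from . import patterns
from .markers import Marker

recombination_fraction = patterns.recombination_fraction


@dataclasses.dataclass
class LinkageMap:
    chromosome: str
    markers: list[Marker]  # ordered; cm_position filled
    length_cm: float
    total_recombinants: int

    @property
    def marker_order(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def index_of(self, marker_id: str) -> int:
        return self.marker_order.index(marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(chromosome=self.chromosome, cm=m.cm_position,
                     marker_id=m.marker_id, pattern=m.pattern,
                     support=m.support)
                for m in self.markers
            ]
        )


def _distance_matrix(marks: Sequence[Marker]) -> tuple[np.ndarray, np.ndarray]:
    """(recombinant count, informative count) matrices, mirror-aware."""
    k = len(marks)
    d = np.zeros((k, k), dtype=int)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            _, dij, nij = patterns.recombination_fraction(
                marks[i].pattern, marks[j].pattern
            )
            d[i, j] = d[j, i] = dij
            n[i, j] = n[j, i] = nij
    return d, n


def _tour_cost(order: Sequence[int], d: np.ndarray) -> int:
    return int(sum(d[a, b] for a, b in zip(order[:-1], order[1:])))


def _exhaustive_order(d: np.ndarray) -> list[int]:
    k = d.shape[0]
    best, best_cost = None, None
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:  # skip reversals
            continue
        cost = _tour_cost(perm, d)
        if best_cost is None or cost < best_cost:
            best, best_cost = perm, cost
    return list(best)


def _mst_backbone(d: np.ndarray) -> list[int]:
    """Initial order: depth-first walk from one end of the MST diameter."""
    from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree

    k = d.shape[0]
    mst = minimum_spanning_tree(d.astype(float) + 1e-9)
    sym = mst + mst.T
    far, _ = breadth_first_order(sym, 0, directed=False)
    start = int(far[-1])
    order, _ = breadth_first_order(sym, start, directed=False)
    return [int(i) for i in order]


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    improved = True
    while improved:
        improved = False
        cost = _tour_cost(order, d)
        k = len(order)
        for i in range(k - 1):
            for j in range(i + 1, k):
                new = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                new_cost = _tour_cost(new, d)
                if new_cost < cost:
                    order, cost = new, new_cost
                    improved = True
        # Or-opt: relocate short segments (length 1-3)
        for seg in (1, 2, 3):
            for i in range(k - seg + 1):
                chunk = order[i : i + seg]
                rest = order[:i] + order[i + seg :]
                for j in range(len(rest) + 1):
                    new = rest[:j] + chunk + rest[j:]
                    if new == order:
                        continue
                    new_cost = _tour_cost(new, d)
                    if new_cost < cost:
                        order, cost = new, new_cost
                        improved = True
    return order


def _nn_two_opt(d: np.ndarray, *, restarts: int = 4) -> list[int]:
    k = d.shape[0]
    start = int(np.argmax(d.sum(axis=1)))
    order = [start]
    free = set(range(k)) - {start}
    while free:
        last = order[-1]
        nxt = min(free, key=lambda j: (d[last, j], j))
        order.append(nxt)
        free.remove(nxt)
    candidates = [_two_opt(order, d), _two_opt(_mst_backbone(d), d)]
    # seeded double-bridge restarts escape shallow local optima
    rng = np.random.default_rng(k)
    for _ in range(restarts):
        best = min(candidates, key=lambda o: _tour_cost(o, d))
        perturbed = list(best)
        if k >= 8:
            cuts = sorted(rng.choice(range(1, k), size=3, replace=False))
            a, b, c = cuts
            perturbed = (
                perturbed[:a] + perturbed[b:c] + perturbed[a:b] + perturbed[c:]
            )
        elif k >= 4:
            i, j = sorted(rng.choice(k, size=2, replace=False))
            perturbed[i], perturbed[j] = perturbed[j], perturbed[i]
        candidates.append(_two_opt(perturbed, d))
    return min(candidates, key=lambda o: _tour_cost(o, d))


def order_markers(
    marks: Sequence[Marker],
    chromosome: str | None = None,
    positions: pd.DataFrame | None = None,
    *,
    exhaustive_limit: int = 8,
) -> LinkageMap:
    """Order one chromosome's markers and assign centimorgan positions.

    ``positions`` (scaffold, pos, marker_id) orients the map so that cM
    increases with physical position for the majority of scaffolds
    carrying two or more markers; ties and missing positions leave the
    seriation orientation, with the deterministic tie-break that the first
    marker id precedes the last.
    """
    marks = list(marks)
    if not marks:
        raise ValueError("no markers to order")
    chromosome = chromosome or marks[0].chromosome or "unknown"
    if len(marks) == 1:
        marks[0].cm_position = 0.0
        return LinkageMap(chromosome, marks, 0.0, 0)

    d, n = _distance_matrix(marks)
    if len(marks) <= exhaustive_limit:
        order = _exhaustive_order(d)
    else:
        order = _nn_two_opt(d)

    if positions is not None and len(positions):
        if _orientation_vote(order, marks, positions) < 0:
            order = order[::-1]
    elif marks[order[0]].marker_id > marks[order[-1]].marker_id:
        order = order[::-1]

    ordered = [marks[i] for i in order]
    cm = 0.0
    total_rec = 0
    ordered[0].cm_position = 0.0
    for prev, cur, i in zip(order[:-1], order[1:], range(1, len(order))):
        rf = d[prev, cur] / n[prev, cur] if n[prev, cur] else 0.0
        total_rec += int(d[prev, cur])
        cm += rf * 100.0
        ordered[i].cm_position = cm
    for m in ordered:
        m.chromosome = chromosome
    return LinkageMap(chromosome, ordered, cm, total_rec)


def _orientation_vote(
    order: Sequence[int], marks: Sequence[Marker], positions: pd.DataFrame
) -> int:
    rank = {marks[i].marker_id: r for r, i in enumerate(order)}
    votes = 0
    pos = positions[positions.marker_id.isin(rank)]
    for _, grp in pos.groupby("scaffold"):
        mean_pos = grp.groupby("marker_id")["pos"].mean()
        if len(mean_pos) < 2:
            continue
        for (m1, p1), (m2, p2) in itertools.combinations(mean_pos.items(), 2):
            if rank[m1] == rank[m2] or p1 == p2:
                continue
            votes += 1 if (rank[m1] - rank[m2]) * (p1 - p2) > 0 else -1
    return votes if votes else 1


# --------------------------------------------------------------------------
# pattern-error cleaning


@dataclasses.dataclass
class Correction:
    marker_id: str
    offspring_index: int
    corrected_call: str


def propose_singleton_corrections(
    marks: Sequence[Marker],
    *,
    max_support: int = 2,
    min_support_ratio: float = 5.0,
    max_dist: int = 2,
) -> list[Correction]:
    """Propose corrections merging low-support error patterns.

    A marker with support <= ``max_support`` lying within ``max_dist``
    mirror-aware mismatches of a unique much better supported marker
    (ratio >= ``min_support_ratio``) is taken to be a genotyping-error
    copy of it; corrections rewrite the differing calls.
    """
    out: list[Correction] = []
    by_type: dict[str, list[Marker]] = {}
    for m in marks:
        by_type.setdefault(m.marker_type, []).append(m)
    mirror_lut = np.array([1, 0, 2, 3], dtype=np.int8)
    for type_marks in by_type.values():
        low = [m for m in type_marks if m.support <= max_support]
        high = [
            m for m in type_marks
            if m.support >= min_support_ratio  # lowest useful target support
        ]
        if not low or not high:
            continue
        lo_mat = patterns.patterns_to_matrix([m.pattern for m in low])
        hi_mat = patterns.patterns_to_matrix([m.pattern for m in high])
        hi_support = np.array([m.support for m in high])
        lo_mirror = mirror_lut[lo_mat]
        for start in range(0, len(low), 256):
            chunk = slice(start, start + 256)
            a = lo_mat[chunk][:, None, :]
            am = lo_mirror[chunk][:, None, :]
            b = hi_mat[None, :, :]
            valid = (a != 3) & (b != 3)
            d_fwd = ((a != b) & valid).sum(axis=2)
            d_mir = ((am != b) & valid).sum(axis=2)
            use_mirror = d_mir < d_fwd
            dist = np.minimum(d_fwd, d_mir)
            for li in range(dist.shape[0]):
                m = low[start + li]
                ok = (dist[li] <= max_dist) & (
                    hi_support >= min_support_ratio * m.support
                )
                ok &= np.array([high[h] is not m for h in range(len(high))])
                idxs = np.flatnonzero(ok)
                if len(idxs) == 0:
                    continue
                dmin = dist[li][idxs].min()
                best = [h for h in idxs if dist[li][h] == dmin]
                best.sort(key=lambda h: (-high[h].support, high[h].marker_id))
                if len(best) > 1 and high[best[0]].support == high[best[1]].support:
                    continue  # ambiguous
                h = best[0]
                tgt = high[h].pattern
                if use_mirror[li, h]:
                    tgt = patterns.mirror(tgt)
                for i, (x, y) in enumerate(zip(m.pattern, tgt)):
                    if x != y and x != "-" and y != "-":
                        out.append(Correction(m.marker_id, i, y))
    return out


def propose_isolated_site_corrections(
    marks: Sequence[Marker],
    assignments: pd.DataFrame,
    *,
    max_dist: int = 3,
    max_run: int = 1,
) -> list[Correction]:
    """Propose corrections from site geometry.

    A genotyping error corrupts a single site, so an error marker shows
    up as an isolated site (a run of <= ``max_run`` sites) interrupting a
    run of one surrounding marker.  A marker is proposed for correction
    only when *every* occurrence of it is such an interruption with the
    same surrounding marker — a genuine short pattern class instead sits
    between two *different* classes.  ``assignments`` is the per-site
    table (scaffold, pos, marker_id).
    """
    by_id = {m.marker_id: m for m in marks}
    n_runs: dict[str, int] = {}
    isolated: dict[str, int] = {}
    targets: dict[str, set[str]] = {}
    group_cols = (
        ["scaffold", "marker_type"]
        if "marker_type" in assignments.columns
        else ["scaffold"]
    )
    for _, grp in assignments.groupby(group_cols):
        mids = grp.sort_values("pos").marker_id.tolist()
        runs: list[list] = []
        for mid in mids:
            if runs and runs[-1][0] == mid:
                runs[-1][1] += 1
            else:
                runs.append([mid, 1])
        for i, (mid, n) in enumerate(runs):
            n_runs[mid] = n_runs.get(mid, 0) + 1
            if (
                0 < i < len(runs) - 1
                and n <= max_run
                and runs[i - 1][0] == runs[i + 1][0] != mid
            ):
                isolated[mid] = isolated.get(mid, 0) + 1
                targets.setdefault(mid, set()).add(runs[i - 1][0])
    out: list[Correction] = []
    for mid, tset in sorted(targets.items()):
        if isolated.get(mid) != n_runs.get(mid) or len(tset) != 1:
            continue
        q = by_id[mid]
        t = by_id[tset.pop()]
        if q.marker_type != t.marker_type:
            continue
        if patterns.mirror_distance(q.pattern, t.pattern) > max_dist:
            continue
        tgt = t.pattern
        if patterns.hamming(q.pattern, tgt) > patterns.hamming(
            q.pattern, patterns.mirror(tgt)
        ):
            tgt = patterns.mirror(tgt)
        for i, (x, y) in enumerate(zip(q.pattern, tgt)):
            if x != y and x != "-" and y != "-":
                out.append(Correction(mid, i, y))
    return out


def clean_pattern_errors(
    marks: Sequence[Marker], corrections: Sequence[Correction]
) -> tuple[list[Marker], pd.DataFrame, dict[str, str]]:
    """Apply call corrections, re-canonicalize and re-collapse markers.

    Markers whose corrected canonical patterns coincide are merged with
    summed support (the higher-support marker keeps its id).  Returns the
    new marker list, a provenance log, and the old->kept id mapping.
    """
    by_id = {m.marker_id: m for m in marks}
    patched: dict[str, list[str]] = {}
    log = []
    for c in corrections:
        if c.marker_id not in by_id:
            raise KeyError(f"unknown marker {c.marker_id!r}")
        p = patched.setdefault(c.marker_id, list(by_id[c.marker_id].pattern))
        log.append(
            dict(marker_id=c.marker_id, offspring=c.offspring_index,
                 old=p[c.offspring_index], new=c.corrected_call)
        )
        p[c.offspring_index] = c.corrected_call
    merged: dict[tuple[str, str], Marker] = {}
    id_map: dict[str, str] = {}
    for m in sorted(marks, key=lambda m: (-m.support, m.marker_id)):
        pat = patterns.canonical(
            "".join(patched[m.marker_id]) if m.marker_id in patched else m.pattern
        )
        key = (m.marker_type, pat)
        if key in merged:
            merged[key].support += m.support
            id_map[m.marker_id] = merged[key].marker_id
        else:
            merged[key] = Marker(
                m.marker_id, m.marker_type, pat, m.support, m.chromosome
            )
            id_map[m.marker_id] = m.marker_id
    return list(merged.values()), pd.DataFrame(
        log, columns=["marker_id", "offspring", "old", "new"]
    ), id_map
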