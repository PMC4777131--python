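"""End-to-end orchestration: markers -> maps -> fixes -> merge -> anchoring.

`run_chain` drives the whole toolkit in memory from a simulated (or
loaded) pedigree and draft assembly; `run_pipeline` wraps it with a YAML
config, a run directory with serialized intermediates, resumability and
a summary JSON.  All randomness flows through the single seed in the
configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import anchor as anchor_mod
from . import misassembly as mis_mod
from .agp import assembly_stats, write_agp
from .linkage import LinkageMap, order_markers
from .markers import (
    MATERNAL,
    PATERNAL,
    Marker,
    Pedigree,
    SnpFilterConfig,
    assign_paternal_to_chromosomes,
    collapse_patterns,
    derive_chromosome_prints,
    filter_snps,
)
from .merge import TransferMap, iterate_merge, veto_nodes
from .sim import Assembly, SimConfig, TruthSet, fragment_assembly, simulate_pedigree


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    snp_filter: SnpFilterConfig = dataclasses.field(default_factory=SnpFilterConfig)
    expected_k: int | None = None  # default: sim.n_chromosomes
    do_merge: bool = True
    do_purge: bool = True
    min_retain_bp: int = 5000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_cfg = SimConfig(**raw.pop("sim", {}))
        filt = SnpFilterConfig(**raw.pop("snp_filter", {}))
        cfg = cls(sim=sim_cfg, snp_filter=filt, **raw)
        if "seed" in raw or True:
            cfg.sim.seed = cfg.seed
            cfg.snp_filter.rms_seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ChainResult:
    truth: TruthSet
    assembly: Assembly
    markers: list[Marker]
    assignments: pd.DataFrame
    rejected: pd.DataFrame
    print_set: Any
    conflicts: pd.DataFrame
    maps: dict[str, LinkageMap]
    blocks: pd.DataFrame
    breakpoints: list
    split_log: pd.DataFrame
    seqs: dict[str, str]
    transfer: TransferMap
    pools: dict[str, list]
    purge_log: pd.DataFrame
    builds: dict[str, Any]
    chromosome_seqs: dict[str, str]
    agp: pd.DataFrame
    unplaced: pd.DataFrame
    stats: dict
    summary: dict


def run_chain(
    truth: TruthSet,
    assembly: Assembly,
    *,
    snp_filter: SnpFilterConfig | None = None,
    expected_k: int | None = None,
    do_merge: bool = True,
    do_purge: bool = True,
    min_retain_bp: int = 5000,
    min_map_support: int = 2,
) -> ChainResult:
    """Run markers -> linkage -> misassembly -> merge -> anchoring."""
    expected_k = expected_k or truth.config.n_chromosomes
    sites = truth.site_records(assembly)
    pedigree = Pedigree.from_samples(truth.samples)
    fr = filter_snps(sites, truth.samples, pedigree, snp_filter)
    accepted = fr.accepted + _rescue_distorted_prints(
        fr, sites, truth.samples, pedigree, expected_k
    )
    marks, assignments = collapse_patterns(accepted)
    marks, assignments = _consolidate(marks, assignments)
    maternal = [m for m in marks if m.marker_type == MATERNAL]
    print_set = derive_chromosome_prints(maternal, expected_k)
    conflicts = assign_paternal_to_chromosomes(marks, assignments, print_set)

    paternal = [m for m in marks if m.marker_type == PATERNAL]
    maps: dict[str, LinkageMap] = {}
    for lg in sorted({m.chromosome for m in paternal if m.chromosome}):
        mm = [m for m in paternal if m.chromosome == lg and m.support >= min_map_support]
        if not mm:
            continue
        pos = assignments[assignments.marker_id.isin([m.marker_id for m in mm])]
        maps[lg] = order_markers(mm, lg, pos)

    # misassembly detection and splitting: chromosome-assigned markers of
    # both types carry the signal (maternal prints identify chromosomes
    # even where paternal markers are conflict-unassigned)
    pat_ids = {m.marker_id for m in paternal}
    assigned_ids = {m.marker_id for m in marks if m.chromosome}
    blocks = mis_mod.build_marker_blocks(
        assignments[assignments.marker_id.isin(assigned_ids)]
    )
    # self-calibrated crossover density of this cross
    total_rec = sum(lm.total_recombinants for lm in maps.values())
    primary_bp = sum(
        len(s) for n, s in assembly.seqs.items()
        if n not in assembly.haplotig_names()
    )
    rate = total_rec / primary_bp if primary_bp else None
    breakpoints = mis_mod.detect_discontinuities(
        blocks, marks, maps, recomb_rate_per_bp=rate
    )
    marker_patterns = {m.marker_id: m.pattern for m in marks}
    rejected_patterns = _rejected_patterns(fr, sites, truth, pedigree)
    breakpoints = [
        mis_mod.refine_breakpoint(bp, rejected_patterns, marker_patterns)
        if bp.kind == "misassembly"
        else bp
        for bp in breakpoints
    ]
    seqs, split_log = mis_mod.apply_splits(
        assembly.seqs, breakpoints, blocks, min_retain_bp=min_retain_bp
    )
    transfer = split_transfer(split_log, assembly.seqs)

    # haplotype merging with truth nodes, vetoed by linkage
    if do_merge:
        scaffold_chrom = _scaffold_chromosomes(assignments, print_set)
        node_state = {"done": False}

        def node_source(cur_seqs: dict[str, str]) -> pd.DataFrame:
            if node_state["done"]:
                return assembly.nodes.iloc[0:0]
            node_state["done"] = True
            nodes = assembly.nodes
            present = nodes.scaffold_a.isin(cur_seqs) & nodes.scaffold_b.isin(cur_seqs)
            return nodes[present].reset_index(drop=True)

        def vetoer(nodes: pd.DataFrame):
            accepted, _, swaps, _ = veto_nodes(
                nodes, scaffold_chrom, assembly.genes,
                {n: len(s) for n, s in seqs.items()},
            )
            return accepted, swaps

        mr = iterate_merge(seqs, node_source, vetoer=vetoer)
        seqs = mr.seqs
        transfer = transfer.compose(mr.transfer)

    # project marker sites onto the current assembly
    proj = _project_assignments(assignments, transfer)
    cur_blocks = mis_mod.build_marker_blocks(proj[proj.marker_id.isin(pat_ids)])
    lengths = {n: len(s) for n, s in seqs.items()}

    pools: dict[str, list] = {}
    purge_logs = []
    builds: dict[str, Any] = {}
    chrom_seqs: dict[str, str] = {}
    agp_frames = []
    placed: set[str] = set()
    scaffold_chrom_now = {
        s: c
        for s, c in _scaffold_chromosomes(proj, print_set).items()
    }
    raw_pools = {
        lg: anchor_mod.build_pools(lm, cur_blocks, lengths)[0]
        for lg, lm in maps.items()
    }
    # any pooled scaffold carries its pool's chromosome for the purge
    # compatibility check, even without a maternal print
    for lg, plist in raw_pools.items():
        for pool in plist:
            for member in pool.members:
                scaffold_chrom_now.setdefault(member.scaffold, lg)
    for lg, lm in maps.items():
        p = raw_pools[lg]
        if do_purge:
            nodes = assembly.nodes
            present = nodes.scaffold_a.isin(lengths) & nodes.scaffold_b.isin(lengths)
            p, plog = anchor_mod.purge_haplotypes(
                p, nodes[present], lengths=lengths,
                scaffold_chromosome=scaffold_chrom_now,
            )
            purge_logs.append(plog)
            p, _ = anchor_mod.refine_with_nodes(p, nodes[present], lengths)
        build, new_seqs, agp = anchor_mod.join_anchored(p, seqs, lg)
        pools[lg] = p
        builds[lg] = build
        chrom_seqs.update(new_seqs)
        agp_frames.append(agp)
        placed.update(build.placed_scaffolds())

    purge_log = (
        pd.concat(purge_logs, ignore_index=True)
        if purge_logs
        else pd.DataFrame(columns=["scaffold", "rule", "kept_scaffold"])
    )
    agp = (
        pd.concat(agp_frames, ignore_index=True) if agp_frames else pd.DataFrame()
    )

    # leftover scaffolds
    mat_ids = {m.marker_id for m in maternal}
    mat_scaffolds = set(proj[proj.marker_id.isin(mat_ids)].scaffold)
    pat_scaffolds = set(proj[proj.marker_id.isin(pat_ids)].scaffold)
    gene_scaffolds = set(assembly.genes.scaffold) & set(lengths)
    leftovers = [
        s for s in lengths
        if s not in placed and s not in set(purge_log.scaffold)
    ]
    unplaced = anchor_mod.select_unplaced(
        leftovers, mat_scaffolds, pat_scaffolds, gene_scaffolds
    )

    stats = assembly_stats(seqs)
    placed_bp = sum(lengths[s] for s in placed)
    anchored_bp = sum(
        lengths[e.scaffold]
        for b in builds.values()
        for e in b.elements
        if e.status == anchor_mod.ANCHORED
    )
    total_bp = sum(lengths.values())
    summary = dict(
        n_markers=len(marks),
        n_maternal=len(maternal),
        n_paternal=len(paternal),
        map_length_cm=round(sum(m.length_cm for m in maps.values()), 4),
        n_breakpoints=len([b for b in breakpoints if b.kind == "misassembly"]),
        scaffolds=stats["scaffolds"],
        total_bp=total_bp,
        placed_fraction=round(placed_bp / total_bp, 4),
        anchored_fraction=round(anchored_bp / total_bp, 4),
        n_purged=len(purge_log),
        n_unplaced_retained=int((unplaced.fate != "discarded").sum()),
        n_unplaced_discarded=int((unplaced.fate == "discarded").sum()),
    )
    return ChainResult(
        truth, assembly, marks, assignments, fr.rejected, print_set, conflicts,
        maps, blocks, breakpoints, split_log, seqs, transfer, pools, purge_log,
        builds, chrom_seqs, agp, unplaced, stats, summary,
    )


def _consolidate(
    marks: list[Marker], assignments: pd.DataFrame, passes: int = 2
) -> tuple[list[Marker], pd.DataFrame]:
    """Merge missing-call patterns and clean isolated error sites."""
    from .linkage import clean_pattern_errors, propose_isolated_site_corrections
    from .markers import merge_missing_patterns

    from .linkage import propose_singleton_corrections

    def apply(corrections):
        nonlocal marks, assignments
        marks, _, id_map = clean_pattern_errors(marks, corrections)
        assignments = assignments.assign(marker_id=assignments.marker_id.map(id_map))
        marks, id_map = merge_missing_patterns(marks)
        assignments = assignments.assign(marker_id=assignments.marker_id.map(id_map))

    marks, id_map = merge_missing_patterns(marks)
    assignments = assignments.assign(marker_id=assignments.marker_id.map(id_map))
    for _ in range(passes):
        corrections = propose_isolated_site_corrections(marks, assignments)
        if not corrections:
            break
        apply(corrections)
    # residual error patterns adjacent to other errors are never isolated;
    # absorb lone patterns into a unique, much better supported neighbour —
    # except where site geometry says the pattern is a genuine short class
    # (its nearest well-supported flanking markers differ)
    for _ in range(passes):
        vetoed = _boundary_class_veto(marks, assignments)
        candidates = [m for m in marks if m.marker_id not in vetoed]
        corrections = propose_singleton_corrections(
            candidates, max_support=1, min_support_ratio=5.0, max_dist=2
        )
        if not corrections:
            break
        apply(corrections)
    return marks, assignments


def _boundary_class_veto(
    marks: list[Marker], assignments: pd.DataFrame, trusted_support: int = 5
) -> set[str]:
    """Markers whose geometry says they are genuine short pattern classes.

    A marker q sitting between two *different* trusted markers L and R is
    a real intermediate class when the recombinant distances are additive
    (d(L,R) = d(q,L) + d(q,R): the class accounts for the switches
    between its flanks); a genotyping-error pattern violates additivity.
    Only additive cases are vetoed from singleton merging.
    """
    from . import patterns as pat

    support = {m.marker_id: m.support for m in marks}
    pattern = {m.marker_id: m.pattern for m in marks}
    veto: set[str] = set()
    group_cols = (
        ["scaffold", "marker_type"]
        if "marker_type" in assignments.columns
        else ["scaffold"]
    )
    for _, grp in assignments.groupby(group_cols):
        mids = grp.sort_values("pos").marker_id.tolist()
        trusted_idx = [
            i for i, mid in enumerate(mids)
            if support.get(mid, 0) >= trusted_support
        ]
        for i, mid in enumerate(mids):
            if support.get(mid, 0) >= trusted_support or mid in veto:
                continue
            left = [j for j in trusted_idx if j < i]
            right = [j for j in trusted_idx if j > i]
            if not (left and right):
                # scaffold-edge singleton: could be a genuine terminal
                # class, leave it alone
                veto.add(mid)
                continue
            lid, rid = mids[left[-1]], mids[right[0]]
            if lid == rid:
                continue
            _, d_lr, _ = pat.recombination_fraction(pattern[lid], pattern[rid])
            _, d_ql, _ = pat.recombination_fraction(pattern[mid], pattern[lid])
            _, d_qr, _ = pat.recombination_fraction(pattern[mid], pattern[rid])
            if d_ql + d_qr == d_lr:
                veto.add(mid)
    return veto


def _rescue_distorted_prints(
    fr, sites, samples, pedigree: Pedigree, expected_k: int
):
    """Reinstate RMS-rejected maternal sites of a distorted chromosome.

    The RMS segregation test guards against per-site genotyping
    artifacts; a pattern repeated across many independent sites is a real
    segregation pattern even when distorted (a chromosome print — or a
    paternal pattern class — is a single draw from the segregation null,
    so ~alpha of them land in the rejection tail and take all their sites
    with them).  Rejected maternal sites are rescued when their shared
    canonical pattern has support comparable to a chromosome's worth of
    accepted maternal sites; rejected paternal sites when the pattern
    recurs at many sites (genotyping errors almost never repeat).
    """
    from collections import Counter

    from .markers import (
        INVALID,
        SitePattern,
        UNINFORMATIVE,
        _recode_site,
        classify_cross_type,
    )
    from .patterns import canonical as canon

    from .markers import PATERNAL

    n_acc_maternal = sum(1 for sp in fr.accepted if sp.marker_type == MATERNAL)
    per_chrom = max(1, n_acc_maternal / max(1, expected_k))
    thresholds = {
        MATERNAL: max(20, 0.3 * per_chrom),
        PATERNAL: 5,
    }

    rej = {
        (r.scaffold, r.pos)
        for r in fr.rejected.itertuples()
        if r.reason == "rms"
    }
    if not rej:
        return []
    mi, fi, oi, gmi = pedigree.indices(samples)
    candidates: list[SitePattern] = []
    for s in sites:
        if (s.scaffold, s.pos) not in rej:
            continue
        t = classify_cross_type(s.gts[mi], s.gts[fi])
        if t not in thresholds:
            continue
        pat, phased = _recode_site(s, t, mi, fi, oi, gmi)
        candidates.append(
            SitePattern(s.scaffold, s.pos, t, pat, canon(pat), phased)
        )
    counts = Counter((sp.marker_type, sp.canonical) for sp in candidates)
    keep = {
        key for key, c in counts.items() if c >= thresholds[key[0]]
    }
    return [
        sp for sp in candidates if (sp.marker_type, sp.canonical) in keep
    ]


def _rejected_patterns(fr, sites, truth: TruthSet, pedigree: Pedigree) -> pd.DataFrame:
    """Recode rejected-but-informative sites for breakpoint refinement."""
    from .markers import INVALID, UNINFORMATIVE, _recode_site, classify_cross_type

    rej = {(r.scaffold, r.pos) for r in fr.rejected.itertuples()}
    mi, fi, oi, gmi = pedigree.indices(truth.samples)
    rows = []
    for s in sites:
        if (s.scaffold, s.pos) not in rej:
            continue
        t = classify_cross_type(s.gts[mi], s.gts[fi])
        if t in (UNINFORMATIVE, INVALID):
            continue
        pat, _ = _recode_site(s, t, mi, fi, oi, gmi)
        rows.append((s.scaffold, s.pos, pat))
    return pd.DataFrame(rows, columns=["scaffold", "pos", "pattern"])


def split_transfer(split_log: pd.DataFrame, seqs: dict[str, str]) -> TransferMap:
    """Transfer map induced by scaffold splitting."""
    from .merge import TRANSFER_COLUMNS

    rows = []
    for r in split_log.itertuples():
        if r.disposition.startswith("kept:"):
            new = r.disposition.split(":", 1)[1]
            rows.append((r.scaffold, r.start, r.end, new, 0, r.end - r.start,
                         "+", "placed", ""))
        else:
            rows.append((r.scaffold, r.start, r.end, "", -1, -1, ".",
                         "dropped", r.disposition))
    touched = set(split_log.scaffold)
    for name, seq in seqs.items():
        if name not in touched:
            rows.append((name, 0, len(seq), name, 0, len(seq), "+", "placed", ""))
    return TransferMap(pd.DataFrame(rows, columns=TRANSFER_COLUMNS))


def _scaffold_chromosomes(assignments: pd.DataFrame, print_set) -> dict[str, str]:
    mat = assignments[assignments.marker_type == MATERNAL].copy()
    mat["chromosome"] = mat.marker_id.map(print_set.assignment)
    out: dict[str, str] = {}
    for scaffold, grp in mat.dropna(subset=["chromosome"]).groupby("scaffold"):
        chroms = set(grp.chromosome)
        if len(chroms) == 1:
            out[scaffold] = chroms.pop()
    return out


def _project_assignments(
    assignments: pd.DataFrame, tm: TransferMap
) -> pd.DataFrame:
    rows = []
    for r in assignments.itertuples():
        hit = tm.map_position(r.scaffold, r.pos)
        if hit is None:
            continue
        rows.append((hit[0], hit[1], r.marker_id, r.marker_type))
    return pd.DataFrame(rows, columns=["scaffold", "pos", "marker_id", "marker_type"])


# --------------------------------------------------------------------------
# file-backed runner


def run_pipeline(config: RunConfig, outdir: str | Path, *, resume: bool = False) -> dict:
    """Run the chain against a simulated dataset, writing a run directory.

    The resolved configuration, per-stage artifacts and a summary JSON
    are written under ``outdir``; with ``resume=True`` a finished run's
    summary is returned without recomputation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_path = outdir / "summary.json"
    (outdir / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    if resume and summary_path.exists():
        return json.loads(summary_path.read_text())

    config.sim.seed = config.seed
    config.snp_filter.rms_seed = config.seed
    truth = simulate_pedigree(config.sim)
    assembly = fragment_assembly(truth)
    assembly.write_fasta(outdir / "draft.fasta")
    truth.write_vcf(outdir / "pedigree.vcf", assembly)
    assembly.write_nodes(outdir / "nodes.tsv")
    assembly.write_truth(outdir / "truth.json")
    truth.write_genes_gff(outdir / "genes.gff3", assembly.genes)

    res = run_chain(
        truth, assembly,
        snp_filter=config.snp_filter,
        expected_k=config.expected_k,
        do_merge=config.do_merge,
        do_purge=config.do_purge,
        min_retain_bp=config.min_retain_bp,
    )
    from .markers import markers_to_frame

    markers_to_frame(res.markers).to_csv(outdir / "markers.tsv", sep="\t", index=False)
    res.assignments.to_csv(outdir / "site_assignments.tsv", sep="\t", index=False)
    pd.concat([m.to_frame() for m in res.maps.values()]).to_csv(
        outdir / "linkage_maps.tsv", sep="\t", index=False
    )
    res.split_log.to_csv(outdir / "split_log.tsv", sep="\t", index=False)
    res.transfer.to_tsv(outdir / "transfer.tsv")
    res.purge_log.to_csv(outdir / "purge_log.tsv", sep="\t", index=False)
    res.unplaced.to_csv(outdir / "unplaced.tsv", sep="\t", index=False)
    if len(res.agp):
        write_agp(res.agp, outdir / "chromosomes.agp")
    with open(outdir / "chromosomes.fasta", "w") as fh:
        for name, seq in res.chromosome_seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    (outdir / "stats.json").write_text(json.dumps(res.stats, indent=1))
    summary_path.write_text(json.dumps(res.summary, indent=1, sort_keys=True))
    return res.summary


# --------------------------------------------------------------------------
# figure-style report


def report_chromosome_figure(
    maps: dict[str, LinkageMap], pools: dict[str, list]
) -> pd.DataFrame:
    """Plot table linking genetic map positions to physical pool spans.

    One row per placed scaffold: chromosome, marker cM span, running
    physical offset span, pool status (colour class), mirroring the
    standard genetic-map-vs-physical-map chromosome figure.
    """
    rows = []
    for lg, pool_list in pools.items():
        lm = maps.get(lg)
        if lm is None:
            continue
        offset = 0
        for pool in pool_list:
            lo, hi = pool.marker_span
            cm_lo = lm.markers[lo].cm_position
            cm_hi = lm.markers[hi].cm_position
            for member in pool.members:
                rows.append(
                    dict(chromosome=lg, cm_start=cm_lo, cm_end=cm_hi,
                         scaffold=member.scaffold, phys_start=offset,
                         phys_end=offset + member.length, status=pool.status)
                )
                offset += member.length + 100
    return pd.DataFrame(
        rows,
        columns=["chromosome", "cm_start", "cm_end", "scaffold",
                 "phys_start", "phys_end", "status"],
    )


def plot_chromosome_figure(table: pd.DataFrame, path: str | Path | None = None):
    """Render the report table as a per-chromosome span figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"anchored": "#2a9d2a", "unoriented": "#e8882a", "unordered": "#cc3333"}
    chroms = list(dict.fromkeys(table.chromosome))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.2 * max(1, len(chroms))),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = table[table.chromosome == chrom]
        for r in sub.itertuples():
            ax.plot([r.phys_start, r.phys_end], [0, 0],
                    color=colors.get(r.status, "gray"), lw=6, solid_capstyle="butt")
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
    return fig
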