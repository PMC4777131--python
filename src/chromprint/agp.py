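"""AGP v2.1 emission/parsing and assembly statistics.

AGP (A Golden Path) records how objects (chromosomes or super-scaffolds)
are built from components and gaps; coordinates are 1-based inclusive.
The writer/reader pair here round-trips exactly: building FASTA from an
AGP plus its component sequences and re-deriving the AGP gives identical
text.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import pandas as pd

AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "component_id", "component_beg", "component_end", "orientation",
]
# for gap rows the last four columns hold gap_length, gap_type, linkage,
# linkage_evidence per the AGP v2.1 specification


@dataclasses.dataclass
class AgpComponent:
    component_id: str
    length: int
    orientation: str  # + or -


@dataclasses.dataclass
class AgpGap:
    length: int
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"


def build_agp(objects: dict[str, list[AgpComponent | AgpGap]]) -> pd.DataFrame:
    rows = []
    for name, parts in objects.items():
        pos = 1
        for i, part in enumerate(parts, start=1):
            if isinstance(part, AgpGap):
                rows.append(
                    (name, pos, pos + part.length - 1, i,
                     "U" if part.gap_type == "contig" else "N",
                     part.length, part.gap_type, part.linkage, part.evidence)
                )
                pos += part.length
            else:
                rows.append(
                    (name, pos, pos + part.length - 1, i, "W",
                     part.component_id, 1, part.length, part.orientation)
                )
                pos += part.length
    return pd.DataFrame(rows, columns=AGP_COLUMNS)


def write_agp(agp: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for row in agp.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        df[col] = df[col].astype(int)
    return df


def agp_to_fasta(agp: pd.DataFrame, components: dict[str, str]) -> dict[str, str]:
    """Reconstruct object sequences from an AGP and component sequences."""
    from .sim import revcomp

    out: dict[str, str] = {}
    for name, grp in agp.groupby("object", sort=False):
        chunks = []
        for row in grp.sort_values("part_number").itertuples():
            if row.component_type in ("N", "U"):
                chunks.append("N" * int(row.component_id))
            else:
                seq = components[row.component_id][
                    int(row.component_beg) - 1 : int(row.component_end)
                ]
                if row.orientation == "-":
                    seq = revcomp(seq)
                chunks.append(seq)
        out[name] = "".join(chunks)
    return out


def fasta_to_agp(
    seqs: dict[str, str], component_names: dict[str, list[tuple[str, int, int, str]]]
) -> pd.DataFrame:
    """AGP for objects whose component layout is known (helper for tests)."""
    objects: dict[str, list[AgpComponent | AgpGap]] = {}
    for name, comps in component_names.items():
        parts: list[AgpComponent | AgpGap] = []
        prev_end = 0
        for cid, start, end, orient in comps:
            if start > prev_end:
                parts.append(AgpGap(start - prev_end))
            parts.append(AgpComponent(cid, end - start, orient))
            prev_end = end
        objects[name] = parts
    return build_agp(objects)


# --------------------------------------------------------------------------
# assembly statistics


def _nxx(lengths: list[int], fraction: float) -> tuple[int, int]:
    """(NXX length, NXX number) per the cumulative-coverage definition."""
    total = sum(lengths)
    acc = 0
    for i, ln in enumerate(sorted(lengths, reverse=True), start=1):
        acc += ln
        if acc >= total * fraction:
            return ln, i
    return 0, 0


def assembly_stats(seqs: dict[str, str]) -> dict:
    """Scaffold and contig statistics (contigs = maximal non-N runs)."""
    if not seqs:
        raise ValueError("empty assembly")
    scaffold_lengths = [len(s) for s in seqs.values()]
    contig_lengths: list[int] = []
    n_gaps = 0
    gap_length = 0
    for s in seqs.values():
        for m in re.finditer(r"N+", s):
            n_gaps += 1
            gap_length += m.end() - m.start()
        contig_lengths.extend(
            len(c) for c in re.split(r"N+", s) if c
        )
    stats = dict(
        scaffolds=len(scaffold_lengths),
        total_length=sum(scaffold_lengths),
        max_scaffold=max(scaffold_lengths),
        contigs=len(contig_lengths),
        contig_length=sum(contig_lengths),
        gaps=n_gaps,
        gap_length=gap_length,
    )
    for frac, tag in ((0.5, "n50"), (0.9, "n90"), (0.95, "n95")):
        ln, num = _nxx(scaffold_lengths, frac)
        stats[f"scaffold_{tag}_length"] = ln
        stats[f"scaffold_{tag}_number"] = num
    ln, num = _nxx(contig_lengths, 0.5)
    stats["contig_n50_length"] = ln
    stats["contig_n50_number"] = num
    return stats
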