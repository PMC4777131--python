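"""Synthetic genomes, pedigrees, assemblies, depth tracks and karyotypes.

Everything downstream of variant calling in the toolkit is testable
against this module: it simulates a diploid genome segregating through an
F2 cross with achiasmatic (recombination-free) female meiosis, fragments
the genome into a draft assembly with haplotype duplicates (haplotigs)
and planted chimeric scaffolds, produces GC-biased read-depth tracks with
collapsed repeats, and builds fused karyotypes with an outgroup-style F1
cross — all with the ground truth recorded before any corruption.

The default configuration mirrors the study conditions the toolkit was
designed around: 21 chromosomes, 69 F2 offspring, paternal-only
recombination below one crossover per chromosome per meiosis, and an
assembly in which roughly a third of scaffolds have haplotype duplicates
at ~94% identity.  Chromosome length and SNP density are desk-scale.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import patterns
from .vcfio import MISSING, SiteRecord, write_vcf

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# --------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class SimConfig:
    """Parameters of the pedigree + assembly simulation.

    Rates are probabilities in [0, 1]; ``paternal_recomb_rate`` is the
    expected number of crossovers per chromosome per paternal meiosis
    (Poisson, no obligate crossover).  ``maternal_recomb_rate`` must be 0:
    female Lepidoptera do not recombine, which is what makes maternal
    markers chromosome prints.
    """

    n_chromosomes: int = 21
    chromosome_length_bp: int = 300_000
    n_offspring: int = 69
    snp_density: float = 6.0  # SNPs per kb
    paternal_recomb_rate: float = 0.65  # E[crossovers]/chromosome/meiosis
    maternal_recomb_rate: float = 0.0
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.01
    founder_allele_freq: float = 0.5
    n_scaffolds_per_chromosome: int = 8
    haplotig_fraction: float = 0.3
    haplotig_divergence: float = 0.06
    n_misassemblies: int = 3
    gap_length: int = 100
    n_genes_per_chromosome: int = 4
    include_z: bool = False
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "paternal_recomb_rate": self.paternal_recomb_rate,
            "genotype_error_rate": self.genotype_error_rate,
            "missing_rate": self.missing_rate,
            "founder_allele_freq": self.founder_allele_freq,
            "haplotig_fraction": self.haplotig_fraction,
            "haplotig_divergence": self.haplotig_divergence,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= (10.0 if name == "paternal_recomb_rate" else 1.0):
                raise ValueError(f"{name}={value} out of range")
        if self.maternal_recomb_rate != 0.0:
            raise ValueError(
                "maternal_recomb_rate must be 0: females are achiasmatic"
            )
        for name in (
            "n_chromosomes",
            "chromosome_length_bp",
            "n_offspring",
            "n_scaffolds_per_chromosome",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_misassemblies < 0:
            raise ValueError("n_misassemblies must be >= 0")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")


# --------------------------------------------------------------------------
# truth containers


@dataclasses.dataclass
class ChromosomeTruth:
    name: str
    length: int
    sequence: np.ndarray  # uint8 codes 0..3 -> ACGT
    snp_pos: np.ndarray  # sorted, 0-based
    ref_allele: np.ndarray  # base chars codes (uint8 into BASES)
    alt_allele: np.ndarray
    founder_haps: np.ndarray  # (4, n_snp) 0/1: gm_a, gm_b, gf_c, gf_d
    maternal_choice: np.ndarray  # (n_offspring,) 0/1 -> mother hap
    paternal_hap: np.ndarray  # (n_offspring, n_snp) 0/1 -> father hap
    crossovers: list[np.ndarray]  # per offspring, sorted bp positions
    is_z: bool = False
    z_inherit: np.ndarray | None = None  # 1 = offspring got mother's Z

    @property
    def n_snp(self) -> int:
        return len(self.snp_pos)

    def seq_str(self) -> str:
        return BASES[self.sequence].tobytes().decode()


@dataclasses.dataclass
class TruthSet:
    """Ground truth of a simulated pedigree, recorded before corruption."""

    config: SimConfig
    chromosomes: dict[str, ChromosomeTruth]
    samples: list[str]  # F0_GM, F1_M, F1_F, OFF_...
    genotypes: dict[str, np.ndarray]  # chrom -> (n_samples, n_snp, 2) truth
    observed: dict[str, np.ndarray]  # with errors and missing injected
    gq: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def offspring(self) -> list[str]:
        return self.samples[3:]

    # ---- truth bookkeeping oracles ------------------------------------

    def maternal_print(self, chrom: str) -> str:
        """True chromosome print: maternal-haplotype inheritance vector."""
        c = self.chromosomes[chrom]
        if c.is_z:
            calls = "".join("AB"[int(v)] for v in c.z_inherit)
        else:
            calls = "".join("AB"[int(v)] for v in c.maternal_choice)
        return patterns.canonical(calls)

    def paternal_classes(
        self, chrom: str, positions: Sequence[int] | None = None
    ) -> list[str]:
        """Distinct paternal pattern classes in physical order.

        ``positions`` restricts the class sequence to the given SNP
        positions (e.g. the sites a filter actually accepted).
        """
        c = self.chromosomes[chrom]
        idx = self._snp_indices(c, positions)
        out: list[str] = []
        for j in idx:
            p = patterns.canonical(
                "".join("AB"[int(v)] for v in c.paternal_hap[:, j])
            )
            if not out or out[-1] != p:
                out.append(p)
        return out

    @staticmethod
    def _snp_indices(c: ChromosomeTruth, positions: Sequence[int] | None) -> np.ndarray:
        if positions is None:
            return np.arange(c.n_snp)
        idx = np.searchsorted(c.snp_pos, np.sort(np.asarray(positions)))
        if not np.array_equal(c.snp_pos[idx], np.sort(np.asarray(positions))):
            raise ValueError("positions are not simulated SNP positions")
        return idx

    def observable_crossovers(
        self,
        chrom: str | None = None,
        positions: dict[str, Sequence[int]] | None = None,
    ) -> int:
        """Paternal haplotype switches visible between adjacent SNPs.

        This is what a linkage map can count: crossovers outside the
        flanking SNPs, or pairs cancelling within one inter-SNP gap, are
        invisible by construction.  ``positions`` (per chromosome)
        restricts visibility to the given sites.
        """
        names = [chrom] if chrom else self.chrom_names
        total = 0
        for name in names:
            c = self.chromosomes[name]
            idx = self._snp_indices(c, (positions or {}).get(name))
            if len(idx) >= 2:
                total += int((np.diff(c.paternal_hap[:, idx], axis=1) != 0).sum())
        return total

    def mendelian_consistent(self) -> bool:
        """Brute-force per-site check of the uncorrupted genotypes."""
        for name, c in self.chromosomes.items():
            g = self.genotypes[name]
            mother, father = g[1], g[2]
            for j in range(c.n_snp):
                ma, fa = set(mother[j]), set(father[j])
                for off in g[3:]:
                    a, b = off[j]
                    if not (
                        (a in ma and b in fa) or (b in ma and a in fa)
                    ):
                        return False
        return True

    # ---- emitters ------------------------------------------------------

    def site_records(
        self, assembly: "Assembly | None" = None
    ) -> list[SiteRecord]:
        """Observed genotypes as site records.

        Without an assembly, sites are on chromosome coordinates; with
        one, sites are projected onto scaffold (and haplotig) coordinates,
        dropping SNPs that fall in planted gaps.
        """
        records: list[SiteRecord] = []
        for name, c in self.chromosomes.items():
            obs = self.observed[name]
            gq = self.gq.get(name)
            for j in range(c.n_snp):
                ref = chr(BASES[c.ref_allele[j]])
                alt = chr(BASES[c.alt_allele[j]])
                site_gq = None if gq is None else gq[:, j].copy()
                if assembly is None:
                    records.append(
                        SiteRecord(name, int(c.snp_pos[j]), ref, alt,
                                   obs[:, j].copy(), gq=site_gq)
                    )
                else:
                    for scaffold, pos, strand in assembly.project(
                        name, int(c.snp_pos[j])
                    ):
                        r, a = ref, alt
                        if strand == "-":
                            r, a = COMPLEMENT[r], COMPLEMENT[a]
                        records.append(
                            SiteRecord(scaffold, pos, r, a, obs[:, j].copy(),
                                       gq=site_gq)
                        )
        records.sort(key=lambda s: (s.scaffold, s.pos))
        return records

    def write_vcf(self, path: str | Path, assembly: "Assembly | None" = None) -> Path:
        if assembly is None:
            lengths = {n: c.length for n, c in self.chromosomes.items()}
        else:
            lengths = {n: len(s) for n, s in assembly.seqs.items()}
        return write_vcf(path, self.samples, self.site_records(assembly), lengths)

    def write_genes_gff(self, path: str | Path, genes: pd.DataFrame) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in genes.iterrows():
                fh.write(
                    f"{g.scaffold}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};curated=1\n"
                )
        return path


# --------------------------------------------------------------------------
# pedigree simulation


def simulate_pedigree(config: SimConfig) -> TruthSet:
    """Simulate an F0 -> F1 -> F2 cross and genotype the pedigree.

    The F1 mother carries one grandmaternal and one grandpaternal
    haplotype, as does the F1 father (its sibling), drawn from distinct
    founder haplotype pools.  F2 offspring inherit whole maternal
    chromosomes (no female recombination) and paternal chromosomes with a
    Poisson number of uniformly placed crossovers.  Genotyping error and
    missingness are injected after the truth is recorded.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_off = config.n_offspring
    samples = ["F0_GM", "F1_M", "F1_F"] + [
        f"OFF_{i + 1:02d}" for i in range(n_off)
    ]

    # sex only matters when a Z chromosome is simulated
    offspring_is_female = rng.random(n_off) < 0.5

    chromosomes: dict[str, ChromosomeTruth] = {}
    genotypes: dict[str, np.ndarray] = {}
    observed: dict[str, np.ndarray] = {}
    gqs: dict[str, np.ndarray] = {}
    for ci in range(config.n_chromosomes):
        name = f"chr{ci + 1}"
        is_z = config.include_z and ci == config.n_chromosomes - 1
        L = config.chromosome_length_bp
        seq = rng.integers(0, 4, size=L, dtype=np.uint8)
        n_snp = max(2, int(round(L / 1000 * config.snp_density)))
        pos = np.sort(rng.choice(L, size=n_snp, replace=False))

        # founder haplotypes; resample monomorphic sites so every site is
        # a real variant in the pedigree
        haps = (rng.random((4, n_snp)) < config.founder_allele_freq).astype(np.int8)
        mono = (haps.sum(axis=0) % 4) == 0
        while mono.any():
            haps[:, mono] = (
                rng.random((4, int(mono.sum()))) < 0.5
            ).astype(np.int8)
            mono = (haps.sum(axis=0) % 4) == 0

        ref = seq[pos]
        alt_shift = rng.integers(1, 4, size=n_snp, dtype=np.uint8)
        alt = (ref + alt_shift) % 4

        maternal_choice = rng.integers(0, 2, size=n_off, dtype=np.int8)
        z_inherit = None
        if is_z:
            # daughters receive the W, sons the maternal Z
            z_inherit = (~offspring_is_female).astype(np.int8)

        # paternal gametes
        paternal_hap = np.empty((n_off, n_snp), dtype=np.int8)
        crossovers: list[np.ndarray] = []
        for i in range(n_off):
            k = rng.poisson(config.paternal_recomb_rate)
            xpos = np.sort(rng.random(k) * L)
            start = rng.integers(0, 2)
            paternal_hap[i] = (start + np.searchsorted(xpos, pos)) % 2
            crossovers.append(xpos)

        # genotype matrix (allele codes 0=ref, 1=alt)
        g = np.zeros((len(samples), n_snp, 2), dtype=np.int8)
        g[0, :, 0] = haps[0]
        g[0, :, 1] = haps[1]
        mother = haps[[0, 2]]  # gm_a, gf_c
        father = haps[[1, 3]]  # gm_b, gf_d
        if is_z:
            # mother hemizygous: single Z emitted as homozygous call
            g[1, :, 0] = g[1, :, 1] = mother[0]
        else:
            g[1, :, 0] = mother[0]
            g[1, :, 1] = mother[1]
        g[2, :, 0] = father[0]
        g[2, :, 1] = father[1]
        for i in range(n_off):
            pat = father[paternal_hap[i], np.arange(n_snp)]
            if is_z:
                if z_inherit[i]:
                    g[3 + i, :, 0] = mother[0]
                    g[3 + i, :, 1] = pat
                else:
                    g[3 + i, :, 0] = g[3 + i, :, 1] = pat
            else:
                g[3 + i, :, 0] = mother[maternal_choice[i]]
                g[3 + i, :, 1] = pat

        obs, gq = _corrupt(g, config, rng)

        chromosomes[name] = ChromosomeTruth(
            name, L, seq, pos, ref, alt, haps, maternal_choice,
            paternal_hap, crossovers, is_z, z_inherit,
        )
        genotypes[name] = g
        observed[name] = obs
        gqs[name] = gq

    return TruthSet(config, chromosomes, samples, genotypes, observed, gqs)


def _corrupt(
    g: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Inject genotype errors and missingness (offspring calls only).

    Erroneous calls receive low genotype qualities (uniform 5..50), as a
    variant caller would assign; clean calls get GQ 80.  A GQ >= 30
    filter therefore masks roughly half of the injected errors, which is
    the point of filtering on genotype quality.
    """
    obs = g.copy()
    n_samples, n_snp, _ = g.shape
    gq = np.full((n_samples, n_snp), 80.0)
    for i in range(3, n_samples):
        err = rng.random(n_snp) < config.genotype_error_rate
        for j in np.flatnonzero(err):
            cur = tuple(sorted(obs[i, j]))
            options = [(0, 0), (0, 1), (1, 1)]
            options.remove(cur)
            obs[i, j] = options[rng.integers(0, len(options))]
            gq[i, j] = rng.integers(5, 51)
        miss = rng.random(n_snp) < config.missing_rate
        obs[i, miss] = MISSING
    return obs, gq


# --------------------------------------------------------------------------
# assembly fragmentation


@dataclasses.dataclass
class Assembly:
    """A simulated draft assembly with per-base provenance truth.

    ``segments`` has one row per scaffold segment: scaffold, scaf_start,
    scaf_end (0-based half-open), chrom, chrom_start, chrom_end, strand,
    kind ('primary' | 'gap' | 'haplotig'), source_scaffold.
    """

    seqs: dict[str, str]
    segments: pd.DataFrame
    nodes: pd.DataFrame
    misassembly_truth: pd.DataFrame
    genes: pd.DataFrame

    def scaffold_names(self) -> list[str]:
        return list(self.seqs)

    def haplotig_names(self) -> set[str]:
        seg = self.segments
        return set(seg.loc[seg.kind == "haplotig", "scaffold"])

    def _segment_index(self) -> dict[str, list[tuple]]:
        if not hasattr(self, "_seg_cache"):
            cache: dict[str, list[tuple]] = {}
            seg = self.segments[self.segments.kind != "gap"]
            for s in seg.itertuples():
                cache.setdefault(s.chrom, []).append(
                    (s.chrom_start, s.chrom_end, s.scaffold, s.scaf_start, s.strand)
                )
            object.__setattr__(self, "_seg_cache", cache)
        return self._seg_cache

    def project(self, chrom: str, pos: int) -> list[tuple[str, int, str]]:
        """Map a chromosome position to assembly coordinates.

        Returns every placement (primary plus any haplotig copy); returns
        nothing if the position fell into a planted gap.
        """
        out = []
        for cs, ce, scaffold, scaf_start, strand in self._segment_index().get(chrom, ()):
            if cs <= pos < ce:
                if strand == "+":
                    p = scaf_start + (pos - cs)
                else:
                    p = scaf_start + (ce - 1 - pos)
                out.append((scaffold, int(p), strand))
        return out

    def write_fasta(self, path: str | Path, width: int = 80) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    def write_nodes(self, path: str | Path) -> Path:
        path = Path(path)
        self.nodes.to_csv(path, sep="\t", index=False)
        return path

    def write_truth(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "segments": self.segments.to_dict(orient="records"),
            "misassemblies": self.misassembly_truth.to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1, default=int))
        return path


NODE_COLUMNS = [
    "scaffold_a", "a_start", "a_end",
    "scaffold_b", "b_start", "b_end",
    "strand", "pct_alignment", "score",
]


def fragment_assembly(
    truth: TruthSet,
    config: SimConfig | None = None,
    *,
    end_overlap_bp: int = 0,
) -> Assembly:
    """Fragment the true genome into a draft assembly.

    Each chromosome is cut into ``n_scaffolds_per_chromosome`` pieces with
    random orientations; one N-gap per scaffold replaces real sequence
    (true length recorded), ``n_misassemblies`` chimeric scaffolds join
    pieces of two different chromosomes across an N-gap, and
    ``haplotig_fraction`` of scaffolds get a divergent duplicate with a
    true containment node.  With ``end_overlap_bp`` > 0, adjacent
    scaffolds additionally share duplicated end sequence and emit true
    end-overlap nodes (for order refinement tests).
    """
    config = config or truth.config
    config.validate()
    rng = np.random.default_rng(config.seed + 104729)
    gap_n = "N" * config.gap_length

    pieces = []  # (chrom, start, end) in physical order
    for name, c in truth.chromosomes.items():
        k = config.n_scaffolds_per_chromosome
        min_len = max(2 * config.gap_length + 1000, c.length // (4 * k))
        while True:
            cuts = np.sort(rng.choice(c.length, size=k - 1, replace=False))
            bounds = np.concatenate([[0], cuts, [c.length]])
            if np.diff(bounds).min() >= min_len:
                break
        for s, e in zip(bounds[:-1], bounds[1:]):
            pieces.append((name, int(s), int(e)))

    if config.n_misassemblies > len(pieces) // 2:
        raise ValueError(
            f"n_misassemblies={config.n_misassemblies} exceeds available "
            f"scaffold pairs ({len(pieces)} pieces)"
        )

    # choose chimera partners from different chromosomes
    order = rng.permutation(len(pieces))
    chimera_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for i in order:
        if len(chimera_pairs) == config.n_misassemblies:
            break
        if i in used:
            continue
        for j in order:
            if j in used or j == i or pieces[j][0] == pieces[i][0]:
                continue
            chimera_pairs.append((int(i), int(j)))
            used.update((int(i), int(j)))
            break

    seqs: dict[str, str] = {}
    seg_rows: list[dict] = []
    mis_rows: list[dict] = []

    def piece_seq(chrom: str, start: int, end: int, strand: str) -> tuple[str, list[dict]]:
        """Sequence of one piece with one planted internal gap."""
        c = truth.chromosomes[chrom]
        raw = BASES[c.sequence[start:end]].tobytes().decode()
        glen = config.gap_length
        lo, hi = start + glen, end - 2 * glen
        segs: list[dict] = []
        if hi > lo:
            gs = int(rng.integers(lo, hi))
            raw = raw[: gs - start] + gap_n + raw[gs - start + glen :]
            parts = [(start, gs, "primary"), (gs, gs + glen, "gap"), (gs + glen, end, "primary")]
        else:
            parts = [(start, end, "primary")]
        if strand == "-":
            raw = revcomp(raw)
            parts = [(s, e, k) for s, e, k in reversed(parts)]
        off = 0
        for s, e, kind in parts:
            segs.append(
                dict(scaf_start=off, scaf_end=off + (e - s), chrom=chrom,
                     chrom_start=s, chrom_end=e, strand=strand, kind=kind)
            )
            off += e - s
        return raw, segs

    def add_scaffold(name: str, parts: list[tuple[str, int, int]]) -> None:
        """parts = list of (chrom, start, end); multiple => chimera."""
        chunks: list[str] = []
        offset = 0
        for pi, (chrom, start, end) in enumerate(parts):
            strand = "+" if rng.random() < 0.5 else "-"
            if pi > 0:
                # junction gap replaces the first gap_length bases of the
                # incoming piece so base accounting stays exact
                start_adj = start + config.gap_length
                seg_rows.append(
                    dict(scaffold=name, scaf_start=offset,
                         scaf_end=offset + config.gap_length, chrom=chrom,
                         chrom_start=start, chrom_end=start_adj,
                         strand="+", kind="gap", source_scaffold=name)
                )
                chunks.append(gap_n)
                junction = offset
                offset += config.gap_length
                start = start_adj
            raw, segs = piece_seq(chrom, start, end, strand)
            for s in segs:
                s["scaf_start"] += offset
                s["scaf_end"] += offset
                s["scaffold"] = name
                s["source_scaffold"] = name
                seg_rows.append(s)
            chunks.append(raw)
            offset += len(raw)
            if pi > 0:
                mis_rows.append(
                    dict(scaffold=name, gap_start=junction,
                         gap_end=junction + config.gap_length,
                         left_chrom=parts[0][0], right_chrom=chrom)
                )
        seqs[name] = "".join(chunks)

    plain = [i for i in range(len(pieces)) if i not in used]
    counter = 0
    for i in plain:
        add_scaffold(f"scf{counter:05d}", [pieces[i]])
        counter += 1
    for i, j in chimera_pairs:
        add_scaffold(f"scf{counter:05d}", [pieces[i], pieces[j]])
        counter += 1

    # haplotigs: divergent duplicates of non-chimeric scaffolds
    node_rows: list[dict] = []
    chimeric = {f"scf{c:05d}" for c in range(len(plain), counter)}
    candidates = [n for n in seqs if n not in chimeric]
    n_hap = int(round(config.haplotig_fraction * len(candidates)))
    hap_parents = sorted(
        rng.choice(candidates, size=n_hap, replace=False).tolist()
    )
    seg_df_tmp = pd.DataFrame(seg_rows)
    for hi, parent in enumerate(hap_parents):
        plen = len(seqs[parent])
        span = int(plen * rng.uniform(0.5, 1.0))
        a_start = int(rng.integers(0, plen - span + 1))
        a_end = a_start + span
        sub = list(seqs[parent][a_start:a_end])
        snp_scafpos = set()
        for _, s in seg_df_tmp[(seg_df_tmp.scaffold == parent) & (seg_df_tmp.kind == "primary")].iterrows():
            c = truth.chromosomes[s.chrom]
            inside = c.snp_pos[(c.snp_pos >= s.chrom_start) & (c.snp_pos < s.chrom_end)]
            for p in inside:
                if s.strand == "+":
                    snp_scafpos.add(s.scaf_start + (p - s.chrom_start))
                else:
                    snp_scafpos.add(s.scaf_start + (s.chrom_end - 1 - p))
        n_sub = 0
        for k in range(span):
            if sub[k] == "N" or (a_start + k) in snp_scafpos:
                continue
            if rng.random() < config.haplotig_divergence:
                cur = sub[k]
                sub[k] = "ACGT".replace(cur, "")[rng.integers(0, 3)]
                n_sub += 1
        hap_name = f"hap{hi:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        hap_seq = "".join(sub)
        if strand == "-":
            hap_seq = revcomp(hap_seq)
        seqs[hap_name] = hap_seq
        identity = 100.0 * (1 - n_sub / max(1, span))
        node_rows.append(
            dict(scaffold_a=parent, a_start=a_start, a_end=a_end,
                 scaffold_b=hap_name, b_start=0, b_end=span, strand=strand,
                 pct_alignment=round(identity, 2),
                 score=round(span * identity / 100.0, 1))
        )
        # haplotig provenance: same chromosome intervals as the parent slice
        for _, s in seg_df_tmp[seg_df_tmp.scaffold == parent].iterrows():
            lo = max(s.scaf_start, a_start)
            hi2 = min(s.scaf_end, a_end)
            if lo >= hi2:
                continue
            if s.strand == "+":
                cs = s.chrom_start + (lo - s.scaf_start)
                ce = cs + (hi2 - lo)
            else:
                ce = s.chrom_end - (lo - s.scaf_start)
                cs = ce - (hi2 - lo)
            if strand == "+":
                h_lo, h_hi = lo - a_start, hi2 - a_start
                seg_strand = s.strand
            else:
                h_lo, h_hi = span - (hi2 - a_start), span - (lo - a_start)
                seg_strand = "-" if s.strand == "+" else "+"
            seg_rows.append(
                dict(scaffold=hap_name, scaf_start=int(h_lo), scaf_end=int(h_hi),
                     chrom=s.chrom, chrom_start=int(cs), chrom_end=int(ce),
                     strand=seg_strand,
                     kind="gap" if s.kind == "gap" else "haplotig",
                     source_scaffold=parent)
            )

    # optional duplicated end overlaps between physically adjacent scaffolds
    if end_overlap_bp > 0:
        seg_df_tmp = pd.DataFrame(seg_rows)
        prim = seg_df_tmp[seg_df_tmp.kind == "primary"]
        spans = (
            prim.groupby("scaffold")
            .agg(chrom=("chrom", "first"), lo=("chrom_start", "min"), hi=("chrom_end", "max"))
            .reset_index()
        )
        spans = spans[~spans.scaffold.isin(chimeric)]
        spans = spans[~spans.scaffold.str.startswith("hap")]
        for chrom, grp in spans.groupby("chrom"):
            grp = grp.sort_values("lo")
            rows = grp.to_dict(orient="records")
            for a, b in zip(rows[:-1], rows[1:]):
                if a["hi"] != b["lo"]:
                    continue
                c = truth.chromosomes[chrom]
                ext = BASES[c.sequence[b["lo"] : b["lo"] + end_overlap_bp]].tobytes().decode()
                a_strand = seg_df_tmp[
                    (seg_df_tmp.scaffold == a["scaffold"]) & (seg_df_tmp.kind == "primary")
                ].iloc[0].strand
                b_strand = seg_df_tmp[
                    (seg_df_tmp.scaffold == b["scaffold"]) & (seg_df_tmp.kind == "primary")
                ].iloc[0].strand
                alen = len(seqs[a["scaffold"]])
                if a_strand == "+":
                    seqs[a["scaffold"]] = seqs[a["scaffold"]] + ext
                    a_iv = (alen, alen + end_overlap_bp)
                else:
                    seqs[a["scaffold"]] = revcomp(ext) + seqs[a["scaffold"]]
                    a_iv = (0, end_overlap_bp)
                    for s in seg_rows:
                        if s["scaffold"] == a["scaffold"]:
                            s["scaf_start"] += end_overlap_bp
                            s["scaf_end"] += end_overlap_bp
                blen_ov = end_overlap_bp
                b_iv = (0, blen_ov) if b_strand == "+" else (
                    len(seqs[b["scaffold"]]) - blen_ov, len(seqs[b["scaffold"]])
                )
                node_rows.append(
                    dict(scaffold_a=a["scaffold"], a_start=a_iv[0], a_end=a_iv[1],
                         scaffold_b=b["scaffold"], b_start=b_iv[0], b_end=b_iv[1],
                         strand="+" if a_strand == b_strand else "-",
                         pct_alignment=100.0, score=float(end_overlap_bp))
                )

    segments = pd.DataFrame(seg_rows)
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    mis = pd.DataFrame(
        mis_rows,
        columns=["scaffold", "gap_start", "gap_end", "left_chrom", "right_chrom"],
    )
    genes = _place_genes(truth, segments, config)
    return Assembly(seqs, segments, nodes, mis, genes)


def _place_genes(
    truth: TruthSet, segments: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Toy single-exon genes inside primary segments, for breakage tests."""
    rng = np.random.default_rng(config.seed + 15485863)
    rows = []
    prim = segments[segments.kind == "primary"]
    gid = 0
    for chrom in truth.chrom_names:
        segs = prim[prim.chrom == chrom]
        big = segs[(segs.scaf_end - segs.scaf_start) > 5000]
        if big.empty:
            continue
        take = big.sample(
            n=min(config.n_genes_per_chromosome, len(big)),
            random_state=int(rng.integers(0, 2**31)),
        )
        for _, s in take.iterrows():
            length = int(rng.integers(1000, 3000))
            start = int(rng.integers(s.scaf_start, s.scaf_end - length))
            rows.append(
                dict(gene_id=f"gene{gid:04d}", scaffold=s.scaffold,
                     start=start, end=start + length,
                     strand="+" if rng.random() < 0.5 else "-", curated=True)
            )
            gid += 1
    return pd.DataFrame(
        rows, columns=["gene_id", "scaffold", "start", "end", "strand", "curated"]
    )


# --------------------------------------------------------------------------
# read-depth simulation


def default_gc_bias(gc_percent: np.ndarray) -> np.ndarray:
    """Mild coverage bias peaking near the genome's typical ~35% GC."""
    f = 1.0 - 0.012 * np.abs(np.asarray(gc_percent, dtype=float) - 35.0)
    return np.clip(f, 0.3, None)


def simulate_depth(
    seqs: dict[str, str],
    *,
    global_depth: int = 30,
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = default_gc_bias,
    collapsed_fraction: float = 0.0,
    collapsed_multiple: int = 2,
    jitter: int = 1,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per-base read depth with GC bias and planted collapsed repeats.

    Depth in each 1-kb window is ``global_depth x bias(GC) x copy``, where
    ``copy`` is ``collapsed_multiple`` for a random ``collapsed_fraction``
    of windows and 1 otherwise; per-base values get integer jitter in
    ``[-jitter, jitter]``.  Returns (per-base depth arrays, truth table of
    windows with scaffold/start/end/gc/copy_number).
    """
    rng = np.random.default_rng(seed)
    depth: dict[str, np.ndarray] = {}
    rows = []
    for name, seq in seqs.items():
        arr = np.zeros(len(seq), dtype=np.int32)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        for start in range(0, len(seq) - 999, 1000):
            window = codes[start : start + 1000]
            has_gap = bool((window == ord("N")).any())
            gc = int(round(100 * np.isin(window, (ord("G"), ord("C"))).mean()))
            copy = 1
            if not has_gap and collapsed_fraction > 0 and rng.random() < collapsed_fraction:
                copy = collapsed_multiple
            bias = float(gc_bias(np.array([gc]))[0]) if gc_bias else 1.0
            base = global_depth * bias * copy
            vals = np.full(1000, round(base), dtype=np.int32)
            if jitter:
                vals = vals + rng.integers(-jitter, jitter + 1, size=1000)
            arr[start : start + 1000] = np.maximum(vals, 0)
            rows.append(
                dict(scaffold=name, start=start, end=start + 1000,
                     gc=gc, copy_number=copy, has_gap=has_gap)
            )
        # trailing partial window: low constant depth, ignored downstream
        tail = len(seq) % 1000 if len(seq) >= 1000 else len(seq)
        if tail:
            arr[len(seq) - tail :] = global_depth
        depth[name] = arr
    return depth, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fused-karyotype simulation


@dataclasses.dataclass
class FusionTruth:
    ancestral_k: int
    derived_k: int
    derived_lengths: dict[str, int]
    composition: pd.DataFrame  # derived_chrom, anc_chrom, start, end, is_z
    boundaries: pd.DataFrame  # derived_chrom, boundary, left_anc, right_anc
    transmission: dict[str, np.ndarray]  # anc_chrom -> (n_offspring,) 0/1
    samples: list[str]
    sites: list[SiteRecord]
    site_truth: pd.DataFrame  # scaffold, pos, anc_chrom, kind

    def ancestral_print(self, anc_chrom: str) -> str:
        vec = self.transmission[anc_chrom]
        return patterns.canonical("".join("AB"[int(v)] for v in vec))

    def write_vcf(self, path: str | Path) -> Path:
        return write_vcf(path, self.samples, self.sites, self.derived_lengths)

    def outgroup_intervals(self, margin: int = 200_000) -> pd.DataFrame:
        """Wider fusion intervals emulating an outgroup species' map.

        The margin is set an order of magnitude above the typical spacing
        of the cross's informative sites, emulating an outgroup whose
        fusion intervals were mapped at coarser resolution.
        """
        rows = [
            dict(chrom=b.derived_chrom,
                 start=max(0, int(b.boundary) - margin),
                 end=int(b.boundary) + margin)
            for b in self.boundaries.itertuples()
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_fusion_cross(
    ancestral_k: int = 31,
    derived_k: int = 21,
    *,
    n_offspring: int = 21,
    sites_per_chromosome: int = 60,
    ancestral_length_bp: int = 1_000_000,
    genotype_error_rate: float = 0.0,
    n_junk_sites: int = 0,
    include_z: bool = True,
    seed: int = 0,
) -> FusionTruth:
    """Simulate an outgroup F1 cross read against a fused karyotype.

    ``ancestral_k - derived_k`` fusion boundaries are planted by pairing
    ancestral chromosomes onto derived ones.  Sites follow the informative
    F1 rule (father homozygous, mother heterozygous); on the Z the mother
    is hemizygous with an allele different from the father, emitted as a
    homozygous diploid call.  Offspring patterns follow the maternal
    transmission vector of the ancestral chromosome each site sits on.
    """
    if ancestral_k <= derived_k:
        raise ValueError("ancestral_k must exceed derived_k")
    rng = np.random.default_rng(seed)
    n_fusions = ancestral_k - derived_k
    anc_names = [f"anc{i + 1}" for i in range(ancestral_k)]
    z_anc = anc_names[-1] if include_z else None

    # pair 2*n_fusions ancestral autosomes; the rest map one-to-one
    fusable = anc_names[:-1] if include_z else anc_names
    paired = rng.choice(fusable, size=2 * n_fusions, replace=False)
    pairs = [(paired[2 * i], paired[2 * i + 1]) for i in range(n_fusions)]
    singles = [a for a in anc_names if a not in set(paired)]

    anc_len = {
        a: int(ancestral_length_bp * rng.uniform(0.7, 1.3)) for a in anc_names
    }

    composition_rows = []
    boundary_rows = []
    derived_lengths = {}
    di = 0
    for left, right in pairs:
        name = f"chr{di + 1}"
        b = anc_len[left]
        composition_rows += [
            dict(derived_chrom=name, anc_chrom=left, start=0, end=b,
                 is_z=left == z_anc),
            dict(derived_chrom=name, anc_chrom=right, start=b,
                 end=b + anc_len[right], is_z=right == z_anc),
        ]
        boundary_rows.append(
            dict(derived_chrom=name, boundary=b, left_anc=left, right_anc=right)
        )
        derived_lengths[name] = b + anc_len[right]
        di += 1
    for a in singles:
        name = f"chr{di + 1}"
        composition_rows.append(
            dict(derived_chrom=name, anc_chrom=a, start=0, end=anc_len[a],
                 is_z=a == z_anc)
        )
        derived_lengths[name] = anc_len[a]
        di += 1

    # distinct transmission vectors (up to mirror) per ancestral chromosome
    transmission: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    for a in anc_names:
        while True:
            vec = rng.integers(0, 2, size=n_offspring, dtype=np.int8)
            canon = patterns.canonical("".join("AB"[int(v)] for v in vec))
            if canon not in seen and len(set(canon)) > 1:
                seen.add(canon)
                transmission[a] = vec
                break

    samples = ["FATHER", "MOTHER"] + [
        f"OFF_{i + 1:02d}" for i in range(n_offspring)
    ]
    sites: list[SiteRecord] = []
    truth_rows = []
    comp = pd.DataFrame(composition_rows)
    for seg in comp.itertuples():
        pos = np.sort(
            rng.choice(seg.end - seg.start, size=sites_per_chromosome, replace=False)
        ) + seg.start
        vec = transmission[seg.anc_chrom]
        for p in pos:
            gts = np.zeros((len(samples), 2), dtype=np.int8)
            if seg.is_z:
                gts[1] = (1, 1)  # hemizygous mother, haploid-as-homozygous
                for i, v in enumerate(vec):
                    gts[2 + i] = (0, 1) if v else (0, 0)
            else:
                gts[1] = (0, 1)
                for i, v in enumerate(vec):
                    gts[2 + i] = (0, 1) if v else (0, 0)
            if genotype_error_rate:
                for i in range(n_offspring):
                    if rng.random() < genotype_error_rate:
                        cur = tuple(gts[2 + i])
                        opts = [(0, 0), (0, 1), (1, 1)]
                        opts.remove(cur)
                        gts[2 + i] = opts[rng.integers(0, 2)]
            ref, alt = "AC"[rng.integers(0, 2)], "GT"[rng.integers(0, 2)]
            sites.append(SiteRecord(seg.derived_chrom, int(p), ref, alt, gts))
            truth_rows.append(
                dict(scaffold=seg.derived_chrom, pos=int(p),
                     anc_chrom=seg.anc_chrom, kind="print")
            )

    # junk sites: every offspring homozygous (non-segregating noise)
    for _ in range(n_junk_sites):
        chrom = list(derived_lengths)[rng.integers(0, len(derived_lengths))]
        p = int(rng.integers(0, derived_lengths[chrom]))
        gts = np.zeros((len(samples), 2), dtype=np.int8)
        gts[1] = (0, 1)
        sites.append(SiteRecord(chrom, p, "A", "T", gts))
        truth_rows.append(dict(scaffold=chrom, pos=p, anc_chrom="", kind="junk"))

    order = sorted(range(len(sites)), key=lambda i: (sites[i].scaffold, sites[i].pos))
    sites = [sites[i] for i in order]
    site_truth = pd.DataFrame([truth_rows[i] for i in order])
    return FusionTruth(
        ancestral_k, derived_k, derived_lengths, comp,
        pd.DataFrame(boundary_rows, columns=["derived_chrom", "boundary", "left_anc", "right_anc"]),
        transmission, samples, sites, site_truth,
    )
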