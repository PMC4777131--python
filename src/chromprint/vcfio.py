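"""Minimal VCF v4.2 site records for pedigree genotype data.

The toolkit consumes diploid biallelic SNP genotypes for a fixed sample
set (parents plus offspring).  Internally a site is a :class:`SiteRecord`;
files are written as plain uncompressed VCFv4.2 text (deterministic byte
output under a fixed simulation seed) and read back through :mod:`cyvcf2`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

MISSING = -1


@dataclasses.dataclass
class SiteRecord:
    """One biallelic SNP with diploid genotypes for all samples."""

    scaffold: str
    pos: int  # 0-based
    ref: str
    alt: str
    gts: np.ndarray  # (n_samples, 2) int8; MISSING (-1) for no-calls
    qual: float = 100.0
    mq: float = 60.0
    strand_bias: float = 0.0  # Fisher-strand style phred score (0 = unbiased)
    gq: np.ndarray | None = None  # per-sample genotype quality
    dp: np.ndarray | None = None  # per-sample depth

    def gq_or_default(self, default: float = 80.0) -> np.ndarray:
        if self.gq is None:
            return np.full(len(self.gts), default)
        return self.gq

    def dp_or_default(self, default: float = 30.0) -> np.ndarray:
        if self.dp is None:
            return np.full(len(self.gts), default)
        return self.dp


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _format_gt(a: int, b: int) -> str:
    if a == MISSING or b == MISSING:
        return "./."
    a, b = sorted((a, b))
    return f"{a}/{b}"


def write_vcf(
    path: str | Path,
    samples: Sequence[str],
    sites: Iterable[SiteRecord],
    contig_lengths: dict[str, int] | None = None,
) -> Path:
    """Write sites as uncompressed VCFv4.2. Sites must be position-sorted."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for s in sites:
            gq = s.gq_or_default().astype(int)
            dp = s.dp_or_default().astype(int)
            cols = [
                s.scaffold,
                str(s.pos + 1),
                ".",
                s.ref,
                s.alt,
                f"{s.qual:g}",
                "PASS",
                f"MQ={s.mq:g};FS={s.strand_bias:g}",
                "GT:GQ:DP",
            ]
            for i, (a, b) in enumerate(s.gts):
                cols.append(f"{_format_gt(int(a), int(b))}:{gq[i]}:{dp[i]}")
            fh.write("\t".join(cols) + "\n")
    return path


def read_vcf(path: str | Path) -> tuple[list[str], Iterator[SiteRecord]]:
    """Read a VCF into (sample names, site iterator) via cyvcf2.

    Multi-allelic and non-SNP records are passed through unmodified as
    records with ``alt`` holding the first alternate; downstream filters
    reject them explicitly so rejections can be logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)

    def _iter() -> Iterator[SiteRecord]:
        for v in vcf:
            gts = np.array(
                [[g[0], g[1]] for g in v.genotypes], dtype=np.int8
            )
            gq = v.format("GQ")
            dp = v.format("DP")
            yield SiteRecord(
                scaffold=v.CHROM,
                pos=v.POS - 1,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
                gts=gts,
                qual=v.QUAL if v.QUAL is not None else 100.0,
                mq=float(v.INFO.get("MQ", 60.0)),
                strand_bias=float(v.INFO.get("FS", 0.0)),
                gq=None if gq is None else gq.reshape(-1).astype(float),
                dp=None if dp is None else dp.reshape(-1).astype(float),
            )

    return samples, _iter()
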