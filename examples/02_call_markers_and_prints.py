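"""Call segregation markers from pedigree genotypes and derive prints.

Each accepted SNP is typed from the F1 parents (maternal, paternal or
intercross), Mendelian-tested, recoded to offspring classes, and
collapsed to unique markers; the most common maternal patterns are the
chromosome prints that identify each chromosome.
"""

from chromprint.markers import (
    MATERNAL,
    PATERNAL,
    Pedigree,
    collapse_patterns,
    derive_chromosome_prints,
    filter_snps,
)
from chromprint.sim import SimConfig, simulate_pedigree

cfg = SimConfig(n_chromosomes=6, chromosome_length_bp=200_000, n_offspring=30, seed=1)
truth = simulate_pedigree(cfg)

sites = truth.site_records(None)
result = filter_snps(sites, truth.samples, Pedigree.from_samples(truth.samples))
print(f"sites: {len(sites)}, accepted: {result.n_accepted}")
print("rejections:", result.rejected.reason.value_counts().to_dict())

markers, assignments = collapse_patterns(result.accepted)
maternal = [m for m in markers if m.marker_type == MATERNAL]
paternal = [m for m in markers if m.marker_type == PATERNAL]
print(f"markers: {len(markers)} ({len(maternal)} maternal, {len(paternal)} paternal)")

prints = derive_chromosome_prints(maternal, expected_k=6)
for p in prints.prints:
    print(f"  {p.chromosome}: support {p.support:4d}  {p.pattern}")
# Support is the number of SNPs sharing the pattern; with 30 offspring and
# no recombination in the mother, each chromosome yields exactly one
# maternal pattern class (up to mirroring).
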