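"""Build per-chromosome paternal linkage maps and compare with truth.

Markers are ordered by seriation (minimum total adjacent recombinants);
centimorgan distance between adjacent markers is the recombination
fraction x 100.  On error-free data the total map length equals the
number of paternal crossovers visible between SNPs / n x 100 cM.
"""

from chromprint.linkage import order_markers
from chromprint.markers import PATERNAL, Pedigree, collapse_patterns, filter_snps
from chromprint.sim import SimConfig, simulate_pedigree

cfg = SimConfig(
    n_chromosomes=4, chromosome_length_bp=200_000, n_offspring=30,
    genotype_error_rate=0.0, missing_rate=0.0, seed=2,
)
truth = simulate_pedigree(cfg)
result = filter_snps(
    truth.site_records(None), truth.samples, Pedigree.from_samples(truth.samples)
)
markers, assignments = collapse_patterns(result.accepted)

# route each paternal marker to its chromosome via the true class table
# (the pipeline normally uses print co-location; see example 02)
positions: dict[str, list[int]] = {}
for sp in result.accepted:
    if sp.marker_type == PATERNAL:
        positions.setdefault(sp.scaffold, []).append(sp.pos)
class_chrom = {}
for chrom in truth.chrom_names:
    for q in truth.paternal_classes(chrom, positions[chrom]):
        class_chrom[q] = chrom

total = 0.0
for chrom in truth.chrom_names:
    mm = [
        m for m in markers
        if m.marker_type == PATERNAL and class_chrom.get(m.pattern) == chrom
    ]
    pos = assignments[assignments.marker_id.isin([m.marker_id for m in mm])]
    lm = order_markers(mm, chrom, pos)
    total += lm.length_cm
    print(f"{chrom}: {len(mm):3d} markers, {lm.length_cm:7.2f} cM")
want = truth.observable_crossovers(positions=positions) / cfg.n_offspring * 100
print(f"total map: {total:.2f} cM; truth from crossover bookkeeping: {want:.2f} cM")
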