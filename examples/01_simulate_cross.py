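"""Simulate an F2 butterfly cross and a fragmented draft assembly.

The mother does not recombine, so each chromosome's maternal inheritance
pattern across the offspring is a fixed "chromosome print"; the father
recombines with under one crossover per chromosome per meiosis.
"""

from chromprint.sim import SimConfig, fragment_assembly, simulate_pedigree

cfg = SimConfig(
    n_chromosomes=6, chromosome_length_bp=200_000, n_offspring=30, seed=1
)
truth = simulate_pedigree(cfg)
assembly = fragment_assembly(truth)

print(f"chromosomes: {cfg.n_chromosomes}, offspring: {cfg.n_offspring}")
print(f"SNPs simulated: {sum(c.n_snp for c in truth.chromosomes.values())}")
print(f"paternal crossovers visible between SNPs: {truth.observable_crossovers()}")
print(f"chromosome print of chr1: {truth.maternal_print('chr1')}")
print(
    f"assembly: {len(assembly.seqs)} scaffolds "
    f"({len(assembly.haplotig_names())} haplotigs, "
    f"{len(assembly.misassembly_truth)} planted chimeras)"
)
# The print is one A/B call per offspring: offspring sharing a letter
# inherited the same maternal chromosome copy.
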