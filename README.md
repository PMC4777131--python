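# chromprint

Linkage-map–driven improvement of draft genome assemblies for species
whose females do not recombine (achiasmatic meiosis, as in Lepidoptera),
and detection of chromosome fusion events from cross segregation
patterns.

## The idea

In an F2 cross, every informative SNP partitions the offspring into
genotype classes. Writing one symbol per offspring (`A`/`B` homozygous
classes, `H` heterozygous) gives a *segregation pattern*; because
grandparental phase is unknown, a pattern and its *mirror* (`A`↔`B`)
are equivalent. When the mother does not recombine, every
maternally-informative SNP on a chromosome shows the *same* pattern up
to mirroring — the **chromosome print** — so a single pattern
identifies the chromosome of any scaffold that carries it. Paternal
patterns change at each paternal crossover, so collapsing accepted SNPs
to unique patterns yields dense linkage-map markers: for patterns
*p₁, p₂* over *n* informative offspring with Hamming distance *d*,

    rf = min(d, n − d) / n,      cM between adjacent markers = 100·rf

and an F2 map length is (total paternal recombinants)/n × 100 cM.

On top of this marker system the toolkit provides:

- **markers / linkage** — SNP filtering (genotype quality, mapping
  quality, strand bias, depth, Monte-Carlo RMS test of Mendelian
  segregation), pattern collapse, chromosome prints, error cleaning,
  and per-chromosome marker seriation.
- **misassembly** — chimeric scaffolds detected as marker
  discontinuities, breakpoints refined with filter-rejected SNPs,
  scaffolds split under retention rules (break at gaps, ~5 kb rule).
- **merge** — merge plans that collapse haplotype scaffolds and chain
  end-overlapping scaffolds, vetoed against the linkage map and curated
  genes, with exact coordinate **transfer maps** that compose across
  assembly versions.
- **anchor** — pools of scaffolds per map marker (anchored /
  unoriented / unordered), haplotype purging (10 kb / 50% / 25%
  containment thresholds), 100-bp-gap joins of anchored runs, AGP v2.1
  emission and N50 statistics.
- **genomesize** — GC-adjusted windowed read-depth estimation of true
  genome size with collapsed-repeat flagging.
- **fusion** — chromosome prints of an outgroup cross located along a
  fused reference karyotype; print transitions are fusion points, and
  interval containment compares fusion histories between outgroups.
- **sim** — a first-class simulator (pedigrees, fragmented assemblies
  with haplotigs and planted chimeras, GC-biased depth, fused
  karyotypes) with complete recorded truth, used by the test suite and
  the acceptance script.

## A worked example

`examples/` contains one short script per capability. For instance
fusion detection (`python examples/08_fusion_points.py`):

```
informative sites: 1860, prints: 31
fusion points found: 10 (10 planted)
  chr1: P25|P28 in 1146878-1158263 (planted at 1148334)
  ...
containment vs wider outgroup intervals: {'contained': 10}
```

A 31-chromosome outgroup cross read against a 21-chromosome reference
yields 31 chromosome prints; each of the 10 fused reference chromosomes
shows a transition between two prints, the interval between the
flanking SNPs contains the planted fusion boundary, and every interval
falls inside the wider intervals of a second, coarser outgroup — the
containment verdict that dates the fusions before the outgroups' split.

Or the full improvement chain (`python examples/06_anchor_chromosomes.py`):

```
{
 "anchored_fraction": 0.7362,
 "map_length_cm": 295.0,
 "placed_fraction": 0.844,
 ...
}
final stats: N50 31619 bp over 48 scaffolds
```

placed = assigned a chromosome position; anchored = also ordered and
oriented (spans at least two consecutive map markers).

There is also a thin CLI (`chromprint sim|markers|pipeline|genomesize|
fusion-points|stats`) wrapping the same library calls.

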