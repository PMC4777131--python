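# Methods

This note documents the models, rules and numerical choices behind
chromprint, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several reasonable options existed.

## The segregation-pattern model

An F2 pedigree (two F0 grandparents, two F1 siblings crossed, N
offspring) is genotyped at biallelic SNPs. A site is typed from the F1
parents: *maternal* (mother heterozygous, father homozygous), *paternal*
(the reverse), *intercross* (both heterozygous), *uninformative* (both
homozygous), *invalid* (a parent call missing or non-biallelic).
Offspring calls are recoded to phase classes: for maternal/paternal
sites, `A` = shares the homozygous parent's genotype, `B` =
heterozygous, so `A`/`B` track which haplotype the informative parent
transmitted; for intercross sites `A`/`H`/`B` are the three genotype
classes. When the F0 grandmother is homozygous at a site, her allele
fixes phase (`A` = grandmaternal haplotype); otherwise patterns are
compared as canonical forms, the lexicographic minimum of the pattern
and its mirror (`A`↔`B` swapped). Mirror equivalence is the central
algebra of the package: without grandparental phase, a pattern and its
mirror are the same marker.

Because the mother is achiasmatic, the maternal pattern is constant
along a chromosome — the chromosome print — and the maternal side of
the simulator transmits whole chromosomes. The father's gametes carry a
Poisson number of crossovers (no obligate crossover) placed uniformly.

## Site filtering and the RMS segregation test

Sites pass, in order: biallelic SNP; parents called; parental genotype
quality ≥ 30; mapping quality ≥ 40; phred strand bias ≤ 60; parental
depth in [8, 120]; offspring calls below GQ 30 are masked to missing,
and sites with > 20% missing offspring are dropped; finally a
root-mean-square test of Mendelian segregation. All thresholds are
package defaults, exposed in `SnpFilterConfig`.

The RMS statistic is `sqrt(mean((obs_freq − exp_freq)²))` over the
genotype classes of the marker type (1:1 for maternal/paternal, 1:2:1
for intercross). The null is Monte-Carlo: 10,000 multinomial draws at
the expected ratios and the observed non-missing count, cached per
(type, n). Because the statistic is discrete, no deterministic cutoff
attains the nominal level (at n = 69 the achievable sizes of a two-class
test near α = 0.05 are ≈ 0.030 and 0.054); the tester therefore uses the
classical randomized decision rule — always reject above the boundary
atom, reject on the atom with the probability γ that makes the overall
size exactly α. The rule is seeded and deterministic across runs. The
default α is 0.01: with millions of candidate sites, a loose α discards
too many genuine markers.

A structural caveat: a chromosome print (or a paternal pattern class)
is itself a single draw from the segregation null, so about α of them
land in the rejection tail and take *all* of their sites with them. The
pipeline rescues rejected patterns that recur at many independent sites
(≥ 30% of a chromosome's worth of maternal sites; ≥ 5 sites for
paternal patterns), since genotyping errors essentially never repeat
the same pattern while distorted-but-real classes always do.

## Marker consolidation and error cleaning

Accepted sites collapse to one marker per (type, canonical pattern)
with support = contributing SNPs. Two consolidation passes address
noise:

- *Missing-call merging.* A pattern with `-` calls merges into a
  complete marker iff exactly one complete marker matches it on every
  known call (mirror-aware). Ambiguous patterns stay separate; they are
  also excluded from map construction (support ≥ 2 required), because a
  holey pattern compatible with two adjacent classes acts as a
  zero-distance bridge and deflates the map.
- *Error-site corrections.* A genotyping error corrupts one site, so an
  error marker appears as an isolated site interrupting a single
  marker's run; such markers are rewritten to the surrounding marker
  (the automated counterpart of curating a map-error list). Residual
  lone patterns merge into a unique much-better-supported neighbour
  within two mismatches — unless geometry says they are genuine: a
  pattern between two different trusted markers L, R is kept when the
  recombinant distances are additive (d(L,R) = d(q,L) + d(q,R)), which
  is true of a real intermediate class and false of an error; patterns
  at scaffold edges are also kept.

On a simulated 1% genotyping-error rate these passes remove ≥ 80% of
map-length inflation (errors roughly double a naive map).

## Linkage maps

Markers of one chromosome are ordered by seriation: minimize the total
adjacent recombinant count, the same objective a minimum-spanning-tree
mapper optimizes. Instances of ≤ 8 markers are solved exhaustively;
larger ones by nearest-neighbour and MST-diameter starts refined with
2-opt/Or-opt moves and seeded double-bridge restarts. Distances are
mirror-aware (`min(d, n−d)`); centimorgans are `rf × 100` per adjacent
interval with no mapping function — with dense markers each interval
holds few recombinants and an F2 counts single paternal meioses
directly. Map orientation follows physical coordinates by majority vote
over scaffolds carrying ≥ 2 markers; ties break on marker id.

Two identifiability limits are inherent to the marker representation
and worth stating precisely. (i) A pattern class revisited after a
close double crossover collapses onto one marker, so the map hides at
most one recombinant per extra visit; map length equals (visible
paternal crossovers)/N × 100 cM exactly in the absence of such repeats
and is otherwise short by that bounded amount. (ii) Cost-neutral local
rearrangements (repeats, cancelling crossover pairs in one inter-SNP
gap) leave small segments of the optimal order unresolvable; marker
order matches physical order up to whole-map reversal outside them.

## Misassembly detection

Per-site marker assignments concatenate into blocks (maximal runs of
one marker). Adjacent blocks from different chromosomes are
misassemblies; maternal print blocks carry this signal even where
paternal markers were conflict-unassigned by the chimera itself. Within
a chromosome, adjacency is measured as the recombinant distance between
the flanking marker patterns (one recombinant = an ordinary crossover);
counting map-order intervals instead proved brittle exactly where
repeated classes make the local order ambiguous. A jump of several
recombinants is only called a misassembly if it is also implausible for
the physical gap between the blocks under the cross's own crossover
density (Poisson tail < 1e-4, density self-calibrated from the maps):
at realistic marker density this reduces to "more than one interval",
while at the compressed physical scale of the simulator a wide marker
gap may legitimately absorb several crossovers. Single-site blocks are
not allowed to anchor a breakpoint. Candidate calls occasionally remain
on clean compressed-scale data when a short distorted class loses its
sites; like the original workflow, calls are candidates for validation.

Breakpoints are refined by claiming filter-rejected sites for a flank
(≤ 1 mismatch to one flanking marker, ≥ 3 to the other; both
configurable). Splitting follows the retention rules: a breakpoint
overlapping an N-run breaks at the gap; a contig wholly inside the
breakpoint with no linking marker is discarded; an in-contig
misassembled interval is kept as a new scaffold at ≥ 5000 bp (or with a
marker), else discarded; all dispositions are logged and the log
partitions every base of the input.

## Merging and coordinate transfer

A merge plan lists oriented source parts tiling each merged scaffold.
Applying a plan emits the merged FASTA plus a transfer map whose
records partition every input base: placed, offcut (leftover of a
partially used scaffold, kept as its own sequence), collapsed onto the
homologous kept copy (containments — removed haplotigs and trimmed
overlap copies map onto the retained copy's coordinates), or dropped
with a reason. Coordinates are 0-based half-open; strand composes
multiplicatively. Transfer maps compose by interval algebra, and the
composition is validated in tests against a brute-force per-base
tracker over chains of random plans. Feature (gene/marker) lifting is
strand-aware and reports features split across target scaffolds with
the transferred fraction.

Nodes (scaffold overlaps) may be vetoed before planning: linkage
conflicts (scaffolds of different chromosomes) are rejected and
remembered across iterations; a node whose kept part would cut a
curated gene swaps parts when the other copy keeps all genes intact,
else is rejected. Plans are built greedily: containment nodes (≥ 90% of
the smaller scaffold covered) collapse it; end nodes chain scaffolds
end-to-end, highest score first, each scaffold end used once, cycles
refused, the overlap kept from the `a` side unless a swap directive
says otherwise. Merging iterates until a round merges nothing. A k-mer
seeded, edlib-verified end-overlap finder supplies nodes for small
fixtures; production nodes can come from any whole-genome aligner as a
TSV.

## Anchoring

Scaffolds group into pools by the map markers they carry: one scaffold
spanning ≥ 2 consecutive markers is anchored (orientation from the
cM-vs-position slope); one scaffold at one marker is unoriented;
several at one marker are unordered, sorted by length. A scaffold whose
markers skip map positions is routed back to misassembly review.
Haplotype purging removes markerless offcuts, offcuts co-located with
their parent, scaffolds whose only markers are strictly surrounded by
an anchored scaffold's markers, and scaffolds covered by an overlap
node in a same/neighbouring-pool scaffold — > 50% alignment if the
candidate exceeds 10 kb, > 25% otherwise, always requiring the
candidate to be the smaller copy. A marker-free scaffold contained in
any chromosome-compatible scaffold at those thresholds is removed by
the same logic. End nodes order and orient unordered pool members
(joined with a 100-bp gap); runs of consecutive anchored scaffolds are
joined with 100-bp gaps into super-scaffolds; AGP v2.1 (1-based,
gap type `scaffold`/`yes`/`map` for the joins) round-trips exactly
against the emitted FASTA. Leftover scaffolds are kept when they carry
a maternal print (chromosome known, position not) or a gene; otherwise
discarded. The placed/removed/retained sets partition the assembly.

## Genome-size estimation

Median read depth is computed in gap-free 1-kb windows (trailing short
windows ignored) with integer GC percent. Each window's depth is
multiplied by f = (median over all windows) / (median of windows with
the same GC percent), and true bases are estimated as
Σ len(w)·adjusted(w)/overall median, scaled by assembly length over
included length. The estimator assumes the genome-wide median depth
represents the diploid copy number (stated, not verified, by the
package); it is invariant under global depth rescaling. Windows with
adjusted depth ≥ 1.5× the median are flagged collapsed-repeat
candidates (threshold configurable).

## Fusion detection

Sites where the outgroup father is homozygous, the mother heterozygous
(on the Z: hemizygous with a different allele, emitted as a homozygous
diploid call) and all offspring called, are recoded to offspring
patterns. The most common patterns (mirror-merged, all-homozygous
excluded, ties broken lexicographically) become the outgroup's
chromosome prints; patterns within one mismatch are absorbed as
genotyping-error noise. Along each reference chromosome the print
labels form runs; runs of < 5 sites are treated as stray mislabels, and
each surviving transition is a fusion point spanning the interval from
the last left-print SNP to the first right-print SNP. Containment of
one outgroup's intervals in another's (verdicts contained / overlapping
/ disjoint / unmatched, nearest-midpoint matching) tests whether both
date the same events.

## The simulator and what it does not show

Defaults follow the study design the toolkit targets: 21 chromosomes,
69 F2 offspring, paternal crossover rate 0.65 per chromosome per
meiosis (chosen so the expected map length is ≈ 1360 cM at N = 69),
one-third of scaffolds duplicated as haplotigs at 6% divergence (≈ 94%
alignment identity, the identity used for haplotype merging), three
planted inter-chromosomal chimeras, genotyping error 0.5% per call with
low simulated GQ on erroneous calls (so a GQ ≥ 30 filter removes about
half — which is the point of quality filtering), 1% missingness, and a
desk-scale physical genome of 300 kb chromosomes at 6 SNPs/kb. The F1
parents draw whole haplotypes from four founder haplotypes with allele
frequency 0.5 per site; founder heterozygosity is a parameter, since a
real cross's founders may be inbred. Planted N-gaps replace true
sequence 1:1, so base accounting is exact. The fusion simulator pairs
random ancestral chromosomes (the Z stays unfused) and generates
RAD-density sites per ancestral chromosome; outgroup comparison
intervals are planted boundaries ± 200 kb, an order of magnitude wider
than the cross's site spacing, emulating a coarser outgroup map.

Deliberately not emulated: read-level data (FASTQ, alignment,
duplicates), indels and structural variants other than the planted
chimeras, repeat families and segmental duplications, reference bias,
and sex-chromosome dosage in the pedigree simulator (a Z chromosome is
available via `include_z` but off by default, because an F2 mother is
hemizygous on Z and a Z print cannot be derived by the mother-het rule;
the Z logic is exercised where it scientifically belongs, in the
outgroup fusion cross). Passing tests therefore demonstrate the
correctness of the marker algebra, the rules and the bookkeeping — not
robustness to alignment artifacts or repeat-driven miscalling, which
enter real data upstream of this toolkit.

Compressing chromosomes to 300 kb while keeping per-chromosome
crossover counts inflates crossover density per kb by ~50× relative to
a real genome. Two detector defaults exist because of this and are
documented above: the Poisson plausibility test for intra-chromosomal
jumps, and the identifiability bounds on map length and order. At real
densities both reduce to the naive rules.

## Numerical and procedural choices

- All randomness flows through `numpy.random.default_rng` seeded from a
  single configuration seed; emitters are byte-deterministic.
- VCF v4.2 (diploid GT, one sample per pedigree member), AGP v2.1, and
  plain TSV/JSON/FASTA are the only file dialects; the merge-plan and
  node TSVs are documented flat tables rather than any aligner's
  private format.
- Sequence handling is plain ACGTN text; haplotig divergence is
  substitution-only, so containment intervals are length-preserving.
- Pool/pool and marker/marker ties break deterministically (length,
  then name; support, then pattern).
- The pipeline prefers marker (linkage) order over node-implied order
  when they conflict, and logs the conflict.
- `run_pipeline` writes every stage artifact and the resolved
  configuration into the run directory; a finished run can be resumed
  from its summary.
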