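# Methods

## Model and assumptions

`mtblot` treats the relative abundance of reads mapping to a gene as a
proxy for that gene's copy number in the mitochondrial (mt) genome of the
sampled individual. The core assumptions are:

* **Control genes are single-copy mt loci.** The normalization factor is
  derived from genes (default *matR*, *nad7*, *nad4*) that are large,
  universally mt-encoded, and single-copy across the clade being surveyed.
  Because the factor spans three loci, it is robust to moderate
  stoichiometric shifts at any one of them; it is not robust to a readset
  in which all three deviate together (e.g. some cytoplasmic male sterile
  lines).
* **Depth separates genomic compartments.** In total-DNA readsets mt
  sequence is enriched roughly a hundredfold over nuclear sequence and
  sits a few-fold below plastid sequence, so n-fold depth near 1 indicates
  a single-copy mt locus, near 2 a duplicated mt region, ≫ 1 a plastid
  insert cross-mapped by plastid reads, and ≪ 1 a residual nuclear copy.
* **Reference exons are close enough for mapping.** Presence detection is
  sensitive only down to the mapping limit; references shorter than the
  read-filter match length (~25 bp) or highly diverged targets will not
  accumulate depth and cannot be scored.

## Normalization

The factor is the **mean of per-gene mean depths**, each control weighted
equally regardless of length. The alternative — pooling all control bases —
lets one long control dominate; gene-level averaging matches the intent of
"average depth of three genes" and is what the package implements
(`depth_norm.control_factor`). A readset whose controls are missing or
jointly zero cannot be normalized and is rejected rather than scored.

## Tier classification

The decision procedure (`presence.classify`) is, in order:

1. **Absence gate**: the fraction of positions with raw depth strictly
   greater than `absent_depth` (default 5) must reach `absent_frac`
   (default 0.5, inclusive). The gate uses raw depth, not n-fold — it is an
   absolute coverage rule, so a deeply sequenced readset cannot rescue a
   locus with no reads.
2. **First tier** (`+`): an accepted consensus (gene-wide mean depth ≥ 6)
   whose sequence is an intact reading frame. A consensus rejected for
   depth cannot support a first-tier call, since the tier means "enough
   depth to assemble the frame".
3. **Second tier** (`●`): every sliding window of `window` bp (default 25,
   the read-filter match length) keeps a mean n-fold ≥ `nfold_min`
   (0.135 = exp(−2.0) to three decimals; the comparison is inclusive).
   The window operationalises "continuous coverage across the full
   length": a per-base minimum would be hypersensitive to single-base
   dropouts that a visual assessment would ignore. Windows wider than the
   gene clamp to the gene length.
4. **Third tier** (`○`): heat value strictly greater than `heat_min`
   (0.25).
5. Otherwise **absent** (`−`) when the control factor is strictly greater
   than `control_min` (15) — the readset is deep enough that no signal
   means no gene — else **ambiguous** (`?`).

Tiers are nested by precedence, first → third; a gene meeting a tier is
called present even in a shallow readset (ambiguity applies only when no
tier is met). Strict versus inclusive comparisons follow the printed
symbols of the rules (`>5`, `>15`, `>0.25` strict; the 50% gate and the
0.135 window cutoff inclusive). `log_min` and `nfold_min` are both kept in
the configuration because users may want to set either scale; construction
warns if they disagree beyond 5×10⁻⁴.

Window means are computed with pairwise summation rather than a
cumulative-sum difference: the latter drifts in the last bit and can push
a profile sitting exactly on the 0.135 cutoff to the wrong side.

## Consensus and reading frames

The consensus caller is substitution-only (no indels), consistent with
analysing exon-concatenated references: each column's plurality base wins,
zero-depth columns give N, and ties give the IUPAC code over the tied
bases — deterministic output that downstream aligners accept. The
"minimum average depth of 6" is a per-gene mean, not a per-site floor; a
rejected consensus is still returned, only flagged. The CIGAR filter's
"minimum match length 25" is interpreted as the **sum** of M/=/X bases
(it removes short spurious local alignments); a `longest_run` mode is
available behind `cigar_mode` since the alternative reading cannot be
excluded.

A reading frame is intact when the length is a positive multiple of 3,
the first codon is in the start set (default {ATG}), exactly one stop
codon occurs and it is terminal (universal genetic code, as used by plant
mitochondria), and the ambiguous-base fraction is ≤ 0.05. Codons
containing ambiguity are never counted as stops — a conservative choice
that avoids calling frames broken on low-level noise.

## Supermatrix statistics

"Data" cells are non-gap, non-N characters: N carries no phylogenetic
signal, while partial IUPAC ambiguity does and counts as data.
Completeness is the percentage of data cells; the distinct-pattern count
treats a column as the ordered tuple of its characters, case-insensitive,
with gap and N as distinct states — the semantics phylogenetic likelihood
software uses. Taxon filtering (default ≥ 10,000 data positions) is
idempotent, and completeness is invariant under gene-order permutation.

## RNA-edit tallying

Coding candidates are C→T variants on extracted CDS references (sense
strand, so only C→T can represent a C-to-U edit); noncoding candidates
are C→T or T→C on the genomic reference outside every CDS interval
(strand unknown there). The allele-frequency floor (0.2) is inclusive. A
variant at a CDS boundary belongs to the coding partition (half-open
interval membership), so no site is double-counted. Edit *prediction*
from protein conservation is out of scope; the module tallies observed
variant evidence only.

## The simulator

`simulate.simulate_readset` emulates the coverage regimes a survey
encounters, per gene: single-copy (n-fold 1), duplicated (2), plastid
insert (20), partial pseudogene (n-fold 1 over a contiguous 5′ block
covering 60%), nuclear residual (0.01), absent (0), and a readset-level
shallow regime (control depth 8, below the 15 rule). Depth is
Poisson(control depth × target n-fold) — the simplest adequate coverage
model for threshold testing; overdispersed alternatives can be plugged in
by replacing the draw. Pileup counts come from a known intact-frame truth
CDS with a symmetric 1% base error. The partial pseudogene loses a
contiguous block rather than random positions, modelling exon-scale
deletions. A fixed seed yields byte-identical fixture bundles.

What the simulator does **not** emulate: mapping artefacts (paralogous
cross-mapping, soft-clip pileups at exon junctions), GC-driven coverage
waves, indels, or reference–target divergence. Passing tests therefore
demonstrate that the thresholds and plumbing behave as specified under the
stated stoichiometric regimes, not that the pipeline is robust to every
real-data pathology.

## Problem sizes and determinism

Validation uses genes of 600 bp, controls of 1800 bp, and control depth
40 — comfortably inside the regime the thresholds were designed for while
keeping the full suite fast. Scenario recovery is measured over 200 seeded
replicates of the seven regimes; consensus, CIGAR, and pattern-count
oracles run on 100, 576, and 20 randomized cases respectively. All
randomness flows through `numpy.random.default_rng` seeds derived from a
single user seed, so every reported number is reproducible bit-for-bit.

## Known limitations

* Read mapping is out of scope: the package consumes depth tables and
  pileups, it does not produce them. An adapter from BAM is deliberately
  not bundled to keep the test surface text-only.
* The classifier has no notion of partial-gene *presence* below the heat
  threshold; very short retained fragments (< ~100 bp of a long gene)
  fall below detection, mirroring the method's stated lower limit.
* Consensus calling assumes one haplotype; mixed mitotypes produce IUPAC
  ties rather than phased alternatives.
* ε enters only the plotting transform; classification never depends
  on it.
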