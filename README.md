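# mtblot — in silico Southern blotting for organellar gene content

Plant mitochondrial (mt) genomes gain and lose genes continually: loci are
transferred to the nucleus, decay into pseudogenes, and vanish, while
plastid-derived inserts and duplicated regions complicate any read-based
view of the genome. Assembling a complete mt genome for every species of
interest is rarely practical, but public whole-genome readsets are
abundant. `mtblot` infers whether a gene still resides in the mitochondrial
genome directly from read depth — an in silico analog of a Southern blot —
and packages the surrounding survey workflow: normalization against control
genes, tiered presence/absence calling, reference-free consensus assembly
with reading-frame checks, gap-padded supermatrix construction, and
tallying of candidate C-to-U RNA-edit sites. It is aimed at organelle
genome and plant phylogenetics researchers surveying gene content across
many taxa from archived sequencing runs.

## The method

For a readset mapped to a panel of reference gene exons, let `d_g(i)` be
the read depth at position `i` of gene `g`. Three large, consistently
mt-located control genes (by default *matR*, *nad7*, *nad4*) calibrate the
expected single-copy mt depth:

```
F = mean_g∈controls( mean_i d_g(i) )          (mean of per-gene means)
n_g(i) = d_g(i) / F                           (n-fold depth)
heat(g) = mean_i d_g(i) / F                   (heat-map value)
```

Single-copy mt loci sit near `n ≈ 1`, duplicated regions near 2, plastid
inserts far above 1, and residual nuclear copies far below (total-DNA
readsets overrepresent mt sequence roughly a hundredfold relative to the
nuclear genome). Coverage plots draw `ln(n_g(i) + ε)` (ε = 1e−5) with
horizontal bounds at `±ln 6`, separating mt signal from nuclear background.

Presence is called in five states. A locus where fewer than 50% of
positions have raw depth > 5 is automatically ineligible for a presence
tier (the absence gate). Otherwise, in order of precedence:

| tier | symbol | criterion |
|------|--------|-----------|
| first | `+` | accepted consensus (mean depth ≥ 6) assembles an intact reading frame |
| second | `●` | every 25-bp window keeps mean n-fold ≥ 0.135 (log score ≥ −2.0) |
| third | `○` | heat value > 0.25 |
| absent | `−` | gate failed while the control factor is > 15 |
| ambiguous | `?` | gate failed in a readset whose control factor is ≤ 15 |

Consensus sequences are per-column plurality calls over base counts (N at
zero depth, IUPAC codes at ties) from alignments pre-filtered to a minimum
CIGAR match length of 25. Accepted consensuses feed per-gene alignments
that are gap-padded to a common taxon list, concatenated with half-open
partitions, and filtered to taxa with ≥ 10,000 data positions; the package
reports percent completeness and the distinct alignment-pattern count.
RNA-edit candidates are tallied from variant calls at allele frequency
≥ 0.2: C→T within CDS references (coding) and C→T/T→C on the genome
outside CDS intervals (noncoding).

## Worked example

Simulate a 20-gene readset (3 controls, 10 retained single-copy genes, a
duplicated region, a plastid insert, a decaying *rpl2* pseudogene, three
lost genes, one nuclear residual) and call presence:

```bash
mtblot simulate --out bundle --seed 7
mtblot call --depth bundle/depth.tsv --models bundle/models.bed \
            --pileup bundle/pileup.tsv --readset-id example7 --out calls.tsv
```

`calls.tsv` then contains one row per gene (columns: readset, gene, tier
symbol, heat value, gate fraction, minimum window n-fold, control factor,
ORF flag). For seed 7 the query rows include (values rounded to 4 places):

```
example7  cox1         +  1.0050   1.0  0.9164   40.0259  true
example7  atp8         +  1.9877   1.0  1.8818   40.0259  true
example7  psaA_insert  +  19.9387  1.0  19.6323  40.0259  true
example7  rpl2         ○  0.5990   0.6  0.0      40.0259  false
example7  sdh3         −  0.0      0.0  0.0      40.0259  NA
example7  rps14        −  0.0089   0.0  0.0      40.0259  false
```

Read: *cox1* is single-copy (heat ≈ 1) with an intact frame; *atp8* is
duplicated (heat ≈ 2); the plastid insert cross-maps at ≈ 20×; *rpl2*
keeps 60% of its length at mt depth — a third-tier partial pseudogene;
*sdh3* is absent; *rps14* survives only as a shallow nuclear copy (heat
≈ 0.01), scored absent. `mtblot heatmap --calls calls.tsv` renders the
black→yellow matrix with tier symbols; `mtblot plot --gene rpl2 ...` draws
the log-coverage panel with the ±ln 6 bounds.

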