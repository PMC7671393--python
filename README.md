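# epilift

Coordinate liftover for epigenome data, rebuilt from first principles and
verifiable base-by-base.

When a reference genome assembly is updated (hg19 → hg38, say), existing
WGBS methylomes and ChIP-seq peak sets must either be re-aligned — slow,
and raw reads are often inaccessible — or have their coordinates *lifted
over* through a precomputed pairwise alignment, the UCSC chain file.
Liftover is fast but not harmless: the chain file partitions the source
genome into regions that convert cleanly and regions that cannot, and
intervals that straddle the wrong junctions come back silently corrupted.
`epilift` is for epigenomics analysts who want the conversion *and* the
machinery to see exactly where it can fail.

The package provides:

* **Chain I/O** — parse, validate, write and invert UCSC chain files
  (gzip detected by content). All coordinates are 0-based half-open;
  target coordinates are kept strand-oriented as the format stores them
  and converted to forward-strand on demand.
* **Gap-region decomposition** — every source base falls in exactly one
  of three categories: *ungapped* (inside an aligned block),
  *gapped-in-source* (source sequence with no target counterpart) or
  *gapped-in-both* (both assemblies unaligned at the junction). Target
  insertions (*gapped-in-target*) have zero width in source coordinates
  and are localized by 2 bp midpoint intervals around the junction. The
  decomposition is emitted as BED tracks plus a census table.
* **Two interval conversion algorithms** — *span* mode (UCSC-style
  split-and-merge: map the interval's mappable bases, report one spanning
  target interval when at least `min_match` of them map; insertions
  inside the span stretch it) and *integrity* mode
  (segment_liftover-style: accept only if the before/after width ratio is
  within [1/n, n], default n = 2, on the expected chromosome).
* **A three-step filtering guideline** — prefilter inputs by the
  gapped-in-source/gapped-in-both tracks and a blacklist; lift; then
  either drop outputs overlapping target insertions (conservative) or cut
  the 2 bp midpoints out of inputs beforehand (split), followed by
  duplication, alternative-chromosome and optional not-CG filters, with
  exact record accounting.
* **Concordance statistics** — interval Jaccard, gain/loss/overlap,
  shrink/equal/extend width classes, unweighted Cohen's kappa on binned
  coverage/methylation, per-CpG methylation deltas, a seeded
  randomization Fisher enrichment test, nearest-feature distance
  preservation and Pearson width correlation.
* **A synthetic assembly simulator** — generates an assembly pair related
  by deletions, insertions, replacements and inversions, the truth chain
  linking them and a brute-force per-base truth map, so the whole engine
  is testable exhaustively without downloading anything.

## Worked example

Simulate a 50 kb assembly pair with 2% of CpGs mutated in the target,
decompose its truth chain, and run the conservative guideline on the
simulated methylome:

```sh
epilift simulate --chrom chr1:50000 --seed 11 --cpg-mutation-rate 0.02 --out demo
epilift regions --chain demo/truth.chain --out demo/regions
```

```
                  n_blocks  n_merged  length_bp  pct_length  pct_blocks
category
ungapped                13         7      49355      98.710   56.521739
gapped_in_source         4         4        451       0.902   17.391304
gapped_in_target         4         4        796       1.592   17.391304
gapped_in_both           2         2        194       0.388    8.695652
source genome size: 50000 bp
strand-change fraction of ungapped length: 0.97%
```

98.7% of this little genome sits in aligned blocks and will convert
cleanly; 0.9% was deleted (four deletions totalling 451 bp), 0.4% was
replaced, and 796 bp of new target sequence will be inserted at four
junctions. The three source-space percentages always sum to 100: they
tile the genome. The strand-change line is the fraction of aligned bases
carried by minus-strand chains (one simulated inversion here) — positions
there convert correctly but their *sequence* is reverse-complemented in
the target, a caveat for any sequence-dependent downstream analysis.

```sh
epilift guideline --chain demo/truth.chain --in demo/methylome.tsv \
    --fasta demo/target.fa --cpg-check --out demo/guide
```

```
n_input                          4630
n_raw_lifted                     4579
n_unlifted                       0
n_removed_duplication            0
n_removed_not_cg                 98
n_filtered_final                 4481
n_removed_prefilter_gapped_in_source 38
n_removed_prefilter_gapped_in_both 13
```

Of 4630 simulated CpGs, 51 were prefiltered because they sit on deleted
or replaced sequence (they could never convert meaningfully), everything
else lifted, and 98 were dropped by the CG check because their target
dinucleotide is no longer CG — exactly the positions the simulator
mutated. The tallies always account for every input record.

The same operations are available as a library:

```python
import epilift as E

chains = E.parse_chain_file("demo/truth.chain")
idx = E.build_index(chains)
E.lift_point(idx, "chr1", 12345)
E.lift_interval_span(idx, "chr1", 1000, 2000)          # UCSC-style
E.lift_interval_integrity(idx, "chr1", 1000, 2000)     # segment_liftover-style
```

## Scope

`epilift` handles point and interval BED-like data (the WGBS/ChIP-seq
case). It does not convert SAM/BAM, VCF, GFF or Wiggle, does not build
chains from raw assemblies, and emits best-chain mappings only (no
multi-mapping output).
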