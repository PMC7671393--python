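# Methods

## The chain model

A UCSC chain describes one pairwise alignment between a source (`t`)
chromosome and a target (`q`) chromosome as ordered ungapped blocks
separated by gaps; each gap advances the source by `dt` bases and the
target by `dq` bases without aligning them. The source strand is always
`+`; target coordinates are stored on the `q_strand`-oriented sequence
and re-expressed on the forward strand as
`[q_size − end, q_size − start)` when `q_strand = '-'`. We keep this
representation losslessly at parse time and convert on demand
(`forwardize_target`), rather than normalizing at parse time, so that
`parse ∘ write` is the identity on any valid file. Chains with a minus
source strand — never produced by UCSC — are rejected at parse time.

Inversion (`invert_chain`) swaps the two roles. For a plus-strand chain
this is a plain `dt`/`dq` swap; for a minus-strand chain the block list
is reversed (the gap that preceded a block becomes the gap that follows
it) and both spans are mirrored. The operation is validated as an
involution on the induced per-base map, enumerated by brute force
(`per_base_map`), both in unit tests and property tests over random
chains.

## Gap categories

Relative to the source assembly every base belongs to exactly one of:

* **ungapped** — inside an aligned block;
* **gapped-in-source** — `dt>0, dq=0` gaps, plus all sequence covered by
  no chain (an uncovered chromosome is wholly gapped-in-source);
* **gapped-in-both** — `dt>0, dq>0` gaps (the `dt` span in source space;
  the `dq` span is also emitted as a target-space track).

**gapped-in-target** (`dt=0, dq>0`) is target-only sequence: zero width
in source coordinates. Following the midpoint construction, the junction
between the two source bases flanking the insertion is widened by 1 bp
in each direction into a 2 bp interval annotated with `dq`. Junctions at
a chromosome edge are clamped to 1 bp and flagged rather than dropped,
preserving count accounting (unreachable for chains whose gaps are
strictly interior, but kept for robustness).

Where chains overlap in source coordinates, each base is classified by
the highest-scoring chain covering it (ties broken by lowest chain id),
which makes the three source-space categories a deterministic exact
partition of the genome — property-tested on every synthetic fixture.
Two *different* chains abutting in source coordinates are not treated as
an insertion junction by default (the midpoint construction operates
within a chain's own block list); a `cross_chain_contiguity` flag
enables that interpretation, with `dq` unknown and annotated 0.

Because "number of blocks" is ambiguous between raw gap lines and merged
intervals, the census table reports both (`n_blocks`, `n_merged`).

## Conversion algorithms

Both interval modes first choose a chain: the highest-scoring chain whose
source span contains the interval start, ties by lowest id; if none
covers the start, the best chain overlapping the interval. This
best-chain rule makes output deterministic and yields at most one target
per input; many-to-many output is deliberately out of scope.

* **Span mode** computes the aligned sub-runs of the interval within the
  chosen chain and reports the single target interval spanning them
  (after forward-strand conversion). It is accepted when
  `mapped_fraction ≥ min_match`. `min_match` defaults to 0.95, the
  documented UCSC liftOver default. Target insertions inside the span
  stretch the output — the width identity
  `width_after = width_before + Σ dq(crossed insertions)` holds exactly
  for fully mapped intervals and is asserted over every junction of
  every fixture. This is precisely how a 2 bp interval straddling a
  large insertion becomes a corrupted kilobase-scale output. A
  diagnostic `emit_pieces` option reports the mapped runs separately
  instead of the single span. The verbal "merge until a gap wider than
  the input" rule sometimes attributed to the split-and-merge family is
  *not* implemented literally: observed tool behavior on midpoint
  intervals spanning multi-kb insertions is the spanning interval, and
  that is what span mode reproduces.
* **Integrity mode** computes the same spanning interval with the
  minimum-match requirement waived, then accepts only if
  `1/n ≤ width_before/width_after ≤ n` (default n = 2) *and* the target
  chromosome equals the name-mapped expectation of the source chromosome
  (identity map by default; configurable for assemblies with different
  naming). The chromosome test runs before the ratio test, so a
  cross-chromosome mapping reports `chrom_violation` even when its ratio
  is also bad. Any interval spanning an insertion with
  `dq > n · width_before` is necessarily rejected with
  `ratio_violation`, since its ratio falls below `1/(1+n) < 1/n`.

Points are 1 bp intervals internally; a CpG is represented by its C
position. Unmappable inputs are statuses (`no_chain`, `gap`,
`low_match`, `ratio_violation`, `chrom_violation`), not errors, and
batch conversion conserves record counts exactly.

## The filtering guideline

Stage order and reason precedence are fixed so every record lands in
exactly one tally: prefilter (gapped-in-source, then gapped-in-both,
then blacklist; ≥1 bp overlap removes), optional splitting, lift,
optional conservative removal, duplication, alternative chromosome,
optional not-CG. The 1 bp overlap threshold matches the package's
Jaccard/overlap convention throughout.

* **Conservative mode** excludes every lifted record overlapping the
  target-space insertion track; the guarantee
  `output ∩ gapped-in-target = ∅` is asserted on randomized inputs.
* **Split mode** subtracts the 2 bp midpoints from inputs before
  lifting; pieces carry `/s<i>` name suffixes and are *not* re-merged
  after conversion (re-merging would reconstruct exactly the corrupted
  span the cut was meant to prevent). Split pieces count as distinct
  sources in the duplication filter — splitting is that mode's purpose,
  not a duplication.
* **Duplication** removes whole collision groups: all outputs of any
  source that produced more than one record (possible only in
  diagnostic pieces mode, `/<i>` suffixes) and all records sharing an
  identical target interval with a record from a different source.
  Keep-one policies are deliberately avoided. Because input names need
  not be unique, the pipeline tags records with internal unique source
  keys and strips them before returning.
* **Alternative chromosome**: the default canonical rule is
  `chr(1..22|X|Y|M)` exactly (no `_alt`/`_random` suffixes); the pattern
  is configurable for non-human genomes.
* **not-CG** treats each record as a lifted C position. On a `+`
  mapping the target must read `CG` over `[p, p+2)`; on a `-` mapping
  the C lands on the forward-strand G of the pair, so the window is
  `[p−1, p+1)`. The format never states this strand rule, so it is
  fixed here and validated against the simulator: with a faithful
  target sequence the only failures are the positions the simulator
  mutated. Records whose window runs off the sequence end are removed
  with reason `edge`.

The report's accounting identity —
`unlifted + removals + final = input − prefiltered + split_added` —
is checked after every run and raises on any leak.

## Concordance statistics

* **Jaccard** = intersection length / union length on merged sets;
  undefined (an error) when both sets are empty.
* **Gain/loss/overlap** classifies each interval by ≥1 bp (configurable)
  overlap with the other set; the identities
  `overlap_align + loss = |alignment|` and
  `overlap_lift + gain = |liftover|` hold by construction.
* **Shrink/equal/extend**: equal iff `1/n < B/A < n` strictly, so
  boundary ratios n and 1/n classify as shrink/extend respectively
  (n = 2 by default).
* **Binning**: coverage bins [0,6), [6,12), [12,18), [18,24), [24,32]
  and methylation bins [0,0.2) … [0.8,1.0]; edges half-open with a
  closed top bin. Coverage above 32 is assigned to the top bin with a
  warning rather than rejected, since real WGBS has a long coverage
  tail.
* **Cohen's kappa**, unweighted, with the conventional verbal bands
  (≤0 none … 0.81–1.0 perfect); invariant under label permutation.
* **Methylation delta** = lift − align per shared site; significance is
  `|delta| ≥ 0.2` (the symmetric reading of the one-sided phrasing,
  since deltas in either direction are equally suspect), with a 1e-12
  tolerance so boundary values like 0.1 − 0.3 stay significant in
  binary floating point. Cross-sample recurrence counting is
  direction-agnostic by default with a `same_direction` flag.
* **Enrichment** builds a 2×2 table from query-vs-random overlap counts:
  point queries draw an equal-sized without-replacement sample from the
  point universe; interval queries place each interval uniformly,
  width-preserving, on its own chromosome (overlaps among placed
  intervals allowed). One random replicate by default; with more, the
  random count is the rounded mean. The one-sided (greater) Fisher p is
  the hypergeometric upper tail; the cross-product odds ratio gets the
  Haldane–Anscombe 0.5 correction on zero cells, flagged. Significance
  is OR ≥ 5 and p < 0.001. Everything is seeded and bit-reproducible.
* **Nearest-feature preservation** pairs every feature with its nearest
  non-covering point (covered points are skipped and counted), measures
  the edge distance before (d1) and after (d2) conversion, and reports
  the fraction of pairs with `d1 − d2 = 0`.

## The simulator

The simulator emulates how one assembly revision differs from the next:
per chromosome it places non-overlapping (≥2 bp apart) source-only
deletions (→ gapped-in-source), target-only insertions
(→ gapped-in-target), replaced segments with independent source/target
lengths (→ gapped-in-both) and inverted segments, which become separate
minus-strand chains exactly as real chain files represent inversions.
Sequence is uniform ACGT with a CpG planted every 10–40 bp (≈1 per
25 bp) so CpG-level filters have material; real genomes' CpG islands,
repeats and base composition are *not* modeled, so passing tests speak
to coordinate arithmetic and filter logic, not to biological realism of
the sequence. Optionally each aligned plus-strand CpG's target G is
mutated to A with a given probability, giving the not-CG filter known
positives recorded in the fixture.

Alongside the FASTA pair the simulator emits the truth chain (chain
score = aligned length, so best-chain choice is well-defined) and a
per-base `TruthMap` built during the same walk — an independent oracle,
not derived from the chain parser. Tests close the triangle: replaying
the chains base-by-base must reproduce the truth map, the engine must
agree with the truth map on every base, and the region decomposition
must recover the planted event footprint exactly.

The methylome model is one record per CG dinucleotide with Poisson
coverage (default mean 20, a typical WGBS depth) and a bimodal
methylation beta (Beta(0.5,8) / Beta(8,0.5) / uniform mixture at
0.4/0.5/0.1), reflecting the strongly bimodal methylation landscape of
real methylomes. Peaks are uniform-width uniform-placement intervals.

Default study conditions (`default_fixture_suite`): one genome of three
chromosomes (100/80/50 kb) with 4 deletions (20–200 bp), 4 insertions
(50–500 bp), 2 replacements (30–150 bp each side), 2 inversions
(200–1000 bp) and 2% CpG corruption per chromosome, plus a smaller
plus-strand-only genome (40/30 kb) — 300 kb of source sequence in
total, chosen so the exhaustive per-base sweep stays in seconds while
every code path (including minus strands) is exercised.

## Numerical and degenerate-input choices

* Fisher p is computed with the scipy hypergeometric survival function
  and cross-checked in tests against direct binomial-coefficient
  enumeration over every table with margins ≤ 30; the empty table gets
  p = 1.
* Pearson correlation and Jaccard raise on degenerate input (constant
  widths, two empty sets) rather than returning NaN silently.
* Inverted or empty intervals are contract errors everywhere; unmappable
  positions are statuses.
* Chain ambiguity under `chain_choice="error-on-ambiguity"` raises as
  soon as more than one chain covers an interval start.

## Known limitations

* Best-chain only: a source region genuinely duplicated in the target
  yields one mapping, so the duplication filter primarily catches
  many-to-one collisions.
* Span mode reports the spanning interval only; the split pieces are
  available diagnostically but are not emitted as primary output.
* The simulator places events independently and uniformly; clustered
  structural variation, nested events and N-gaps are not modeled.
* Reproductions of the published hg19→hg38 chain-file characteristics
  require the UCSC chain file on disk (see README); they are not
  runnable from bundled data.
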