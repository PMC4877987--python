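# Methods

## Model and procedure

covbin assigns assembly scaffolds to genomes using the differential
coverage a scaffold shows across two metagenomes of the same community.
Coverage is defined per scaffold and sample as total mapped bases divided
by scaffold length; binning operates in the plane of log₁₀ coverages
(zeros floored at a pseudo-count of 0.01×, so they stay representable).
Bins are built in a fixed three-stage order, and every inclusion or
exclusion is written to a provenance log that replays to the final
membership:

1. **Coverage selection.** Scaffolds of at least `min_scaffold_len`
   (default 1,000 bp) whose log-coverage point lies inside a selection
   region. Regions are polygons or ellipses; boundary points are
   included. `auto_seed_regions` proposes regions by DBSCAN over the
   log-coverage points of scaffolds ≥ 10 kb, weighted by length (eps =
   0.2 log units), each cluster yielding its padded bounding box. This
   automates what is conventionally drawn by eye on the coverage plot
   and is labeled as such.
2. **Composition refinement.** Each scaffold's canonical tetranucleotide
   frequency vector (136 dimensions after reverse-complement collapsing;
   windows containing ambiguous bases skipped; fractions summing to 1)
   is clustered agglomeratively (average linkage by default; complete
   available). The tree is cut at Euclidean distance 0.1 and the cluster
   with the greatest total scaffold length is kept — ties broken by
   scaffold count, then smallest scaffold ID. If the kept cluster holds
   less than `min_keep_fraction` (default 0.5) of the bin's length the
   refinement refuses to act, on the grounds that discarding most of a
   bin is more likely a mis-clustering than contamination. The exact
   scaling under which the conventional 0.1 cutoff was historically
   applied is not recoverable; vectors-as-fractions is the default and
   `percent`/`zscore` scalings are exposed as configuration. No numeric
   equivalence with any particular historical script is claimed.
3. **Paired-end rescue.** Scaffolds connected to a current member by at
   least `min_links` (default 2) read pairs join the bin if, in at least
   one sample, their coverage is no less than the bin's length-weighted
   median divided by `max_cov_fold` (default 3). Coverage *above* the
   median is always admissible because multi-copy elements legitimately
   exceed it; that asymmetry is the point of the rescue stage. The link
   threshold applies per scaffold pair — independent single chimeric
   links never add up to an admission, which is what prevents one noisy
   link from chaining a foreign genome into the bin. Rescue is monotone
   (never removes) and iterates to a fixpoint.

**Marker QC.** Completeness is the percentage of the marker set
identified in the bin; redundancy is markers present in ≥ 2 copies over
markers identified. "Duplicated" counts markers, not extra copies — the
only reading under which the standard worked examples (4/106 → 3.8 %,
2/105 → 1.9 %, 4/107 → 3.7 %, 3/106 → 2.8 %) are all consistent. Hits
are resolved best-per-gene first when scores are available, so one gene
cannot inflate two markers. Reported percentages are rounded
half-away-from-zero to one decimal; full precision is kept internally.
The packaged 107-member and 35-member marker ID lists are clearly
documented placeholders of the correct sizes (the canonical identifier
lists belong to curated marker databases); they are plain data files and
can be replaced freely.

**ANI.** Query genome cut into consecutive 1,020 bp fragments (the
classical fragment length; trailing partial fragments dropped). Each
fragment is placed by edlib's infix alignment against every target
sequence on both strands; identity = 1 − edits/fragment_length, and the
search is bounded at the edit distance corresponding to the 60 %
identity cutoff, below which a fragment would be discarded anyway.
ANI is the mean identity of retained fragments; both directions are
computed and the symmetric mean is the headline value. Identity of a
genome with itself is exactly 100 because every fragment finds itself at
distance zero. A pair with no retained fragments is flagged
indeterminate rather than given a number. Precomputed tabular alignments
can be ingested instead, where the ≥ 70 % fragment-coverage filter
applies (the internal aligner aligns fragments end-to-end by
construction).

**BBH / duplicated genes.** Filters (bitscore ≥ 70, identity ≥ 30 %,
≥ 70 % of query aligned, all inclusive) are applied before best-hit
resolution (bitscore, tie → identity, tie → lexicographically smallest
subject). A pair is shared iff the best hits agree in both directions. A
gene is duplicated iff it has any non-self hit passing the same filters.

**Species calls.** Different species below ANI 94 %, corroborated by
in-silico DDH below 70 % when a DDH value is supplied; conflicting
evidence is returned as indeterminate. DDH is never computed here.

**Expression.** RPKM = 10⁹·count/(length·library); MRPKM =
RPKM_RNA/RPKM_DNA, undefined (flagged, NaN in tables) when the DNA RPKM
is zero — a gene absent from the metagenome is not the same as a silent
gene. Bin summaries report the percentage of genes with MRPKM above a
threshold (default 0, i.e. any detected transcript). Gene-group scores
(e.g. all homolog copies of one gene) aggregate by sum by default, with
mean available, since a single reported per-genome value for a
multi-copy gene does not determine the combination rule.

## The synthetic community

The generator emulates exactly the structure the pipeline assumes:
genomes → scaffolds (≥ 1 kb, exponential lengths around 10 kb,
concatenation reproduces the genome byte-for-byte) → Poisson mapping
summaries (reads ~ Poisson(cov·len/read_len); library sizes inflate the
mapped total by 1/0.87 to model unassembled community members) → planted
markers → adjacency-based PE links (5 per adjacent pair, plus isolated
single cross-genome noise links) → per-gene DNA/RNA counts.

Composition: sequences come from an order-3 Markov chain whose
conditional base distributions are Dirichlet-perturbed per genome
(concentration 1.0) with the G+C mass of every conditional renormalized
to the genome's GC target. Pure GC-content models (order 0, also
available) of realistically spaced genomes sit only ~0.05–0.09 apart in
canonical TNF space — below the 0.1 refinement cutoff — whereas real
genomes differ in k-mer usage well beyond GC; the seeded Dirichlet bias
reproduces that, giving within-genome distances ≈ 0.02 at 5 kb and
between-genome distances ≈ 0.05–0.15.

Default conditions (four genomes + one contaminant, two samples SE/LE):

| genome | length | GC | cov SE | cov LE | active genes |
|---|---|---|---|---|---|
| g1 | 350 kb | 0.54 | 100× | 60× | 27.8 % |
| g2 | 300 kb | 0.40 | 20× | 5× | 35.4 % |
| g3 | 300 kb | 0.65 | 4× | 40× | 18.1 % |
| g4 | 250 kb | 0.54 | 400× | 4× | 1.8 % |
| contam | 16 kb | 0.30 | 100× | 60× | — |

Coverage pairs are separated at least five-fold in one sample; the
contaminant shares g1's coverage pair exactly, so only composition can
expose it. Marker dropout/duplication counts are 1/4, 2/2, 0/4 and 1/3,
the patterns of curated-bin QC worked examples. Active-gene fractions
are planted as exact counts (round(f·n) genes chosen per genome), so the
generator controls the fraction rather than sampling it binomially.
Genome sizes are two orders of magnitude below real chromosomes to keep
the full pipeline fast at desk scale; scaffold counts (≈ 120) and length
scales match the regime where per-scaffold TNF and Poisson-coverage
noise behave realistically.

What the generator does *not* model: sequencing errors and read-level
artifacts, assembly chimerism, strain microdiversity, GC-dependent
coverage bias, repeat-induced coverage inflation, and real genomic k-mer
structure (codon usage, operons). Passing the recovery tests therefore
shows the pipeline's logic is correct under its own assumptions, not
that real assemblies of this difficulty will bin this cleanly.

## Numerical choices and degenerate inputs

- Report percentages round half away from zero to one decimal (Python's
  banker's rounding would disagree on exact ties).
- TNF requires at least one valid 4-mer window; all-ambiguous sequences
  are errors. A bin of fewer than two scaffolds skips refinement.
- Refinement with every scaffold in one cluster removes nothing (valid).
- Redundancy of a bin with zero identified markers is 0.0 by convention,
  with a warning.
- Empty coverage selections are errors suggesting region widening;
  unknown scaffold IDs in mappings are errors naming offenders.
- SAM ingestion counts primary mapped records only (multi-mapped reads
  count once, at the primary placement); mapped bases are the
  reference-consuming cigar lengths M/=/X/D.
- All generator randomness derives from a single integer seed through
  per-purpose child generators, so every artifact is a pure function of
  (parameters, seed).

## Known limitations

- The keep-largest-cluster rule assumes the bin's genome dominates its
  coverage region; refinement of a region containing two genomes of
  similar total length is refused by the `min_keep_fraction` guard
  rather than resolved.
- Cutting the refinement tree at a fixed height is monotone in the
  cutoff for a dominant-cluster bin, but with balanced clusters the
  kept/removed split can change non-monotonically as clusters merge.
- ANI by bounded edit distance treats every edit equally (no affine gap
  model); for closely related genomes this matches substitution-rate
  expectations well (5 % mutations → ANI ≈ 95), but divergent pairs near
  the 60 % cutoff are better served by ingesting tabular alignments from
  a dedicated aligner.
- The two-sample workflow is fixed; the data structures allow more
  samples but selection regions are two-dimensional.
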