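# Methods

## The screen

`motiflink` implements a phylogenetic-footprinting screen for a candidate
cis-regulatory module: a SOX9 binding site and a GLI binding site, each
perfectly conserved between a reference genome (mouse) and a partner
species (human), lying close together in inter- or intragenic non-coding
sequence.  The biological motivation is chondrocyte differentiation in the
growth plate: SOX9 and the hedgehog effectors GLI2/3 act together as a
repressive module on genes expressed in hypertrophic chondrocytes, so
genes up-regulated at hypertrophy (HC genes) are expected to carry linked
SOX9–GLI sites more often than genes of proliferating chondrocytes (PC
genes) or the genome at large.

The pipeline is a filter chain with explicit stage bookkeeping:

1. **Scan** — every occurrence of each IUPAC consensus motif on both
   strands of the reference, overlapping occurrences included.  Matching
   is exact set membership per position; there is no PWM scoring.  An `N`
   in the *sequence* never matches (conservative calling on masked
   genome); degenerate codes in the *motif* match any of their bases.
2. **Conserve** — a hit survives iff its window lies inside a single
   alignment block and every column is identical between reference and
   the partner species, with no gap on either row and no partner-specific
   insertion inside the window.  An indel destroys a binding site, so a
   gap anywhere in the window breaks "perfect conservation".  Hits not
   fully contained in one block are dropped and counted in the log:
   multiz block boundaries rarely split a ≤ 9-nt motif, and stitching
   blocks would add untestable complexity.
3. **Restrict** — hits overlapping any annotated exon are removed.
   "Non-coding" is read conservatively as *everything outside exons*,
   UTRs included (`exclude=exons`); `exclude=cds` is reserved as the
   alternative.  Where genes overlap, exonic labelling takes precedence.
4. **Pair** — every SOX9 × GLI combination on a chromosome whose inner
   gap (end of the first site to start of the second) is within
   `max_spacing` becomes a linked pair.  The boundary is inclusive at the
   default 100 nt; a flag flips to strict.  Either motif may come first
   and all four strand combinations are admitted — orientation is
   reported, never filtered on.  Overlapping sites are not pairs.
5. **Annotate & call** — each pair gets (a) a descriptive conservation
   percentage over its full window across the six-species panel, (b) a
   flag for a conserved TCF site lying strictly inside its gap (the
   Wnt/β-catenin connection), and (c) a gene assignment.  A gene is
   positive once it owns at least one pair.

Two conservation notions are deliberately separate.  The **filter** is
pairwise perfect conservation against one partner species (human by
default).  The **panel percentage** — the fraction of window columns at
which every panel species present in the block matches the reference
base without a gap — is descriptive output only and is never
thresholded.  If no panel species aligns, the percentage is vacuously
100 and `species_present` names the reference alone so reports can flag
the window.

### Gene assignment

How an intergenic site is attributed to a gene is a genuinely open
design point; we use nearest gene by edge distance within a `max_flank`
of 50 kb (sites inside a gene span go to that gene; exact ties go to all
tied genes; beyond the flank, to none).  The flank default is surfaced
prominently in the CLI because results at intergenic sites depend on it.

### Motif definitions

The shipped consensus strings — SOX9 `WWCAAWG` (the COL2C1-type heptamer
of the collagen-enhancer literature), GLI `GACCACCCA`, TCF `CTTTGWW` —
are editable configuration (`--motifs`, YAML), not constants: consensus
choices of this kind vary between studies and must be auditable.  An
optional composite scan finds the dimeric SOX9 arrangement (two
heptamers head-to-head, spacer 3–5 nt, canonically 4), but the default
screen uses the single consensus.

## Statistics

Both tests are exact and directional.

* **Hypergeometric over-representation.**  For a set of `n` genes with
  `k` positives against a genome of `N` genes containing `K` positives,
  the reported p is the upper tail `P(X ≥ k)`.  `K` is a **required
  input** with no default: the genome-wide positive count depends on the
  exact alignments and annotation used and must not be silently assumed.
* **One-tailed Fisher exact test** between two sets is computed as the
  hypergeometric upper tail with the 2×2 margins (`N=a+b+c+d`, `K=a+c`,
  `n=a+b`, `k=a`); the direction is "set 1 enriched" and set order is
  explicit in the API.

Numerics: binomial-coefficient logs use a compensated sum of term logs
(`log C(n,k) = Σ_j log((n−k+j)/j)`) for lower index ≤ 5000 and log-gamma
beyond; tails accumulate with log-sum-exp and are clipped to [0, 1].
The compensated form keeps the pmf normalized to 1 within 1e−12 even at
N in the tens of thousands, where log-gamma alone drifts by ~1e−11.
No multiple-testing correction is applied; reports say so.

## Synthetic data

The generator emulates the statistical structure the screen assumes:
perfectly conserved functional sites embedded in diverged non-coding
sequence.  Each gene gets an independent locus (its own scaffold) with a
two-exon gene body in the middle 40% and intergenic flanks.  With a
per-gene plant probability, one SOX9 instance and one GLI instance
(each drawn uniformly from the sequences satisfying its consensus) are
embedded in non-exonic space, order, strands, and spacing
(uniform on [0, 100] nt) randomized.  Partner species descend from the
reference on a star phylogeny by i.i.d. per-base substitutions and
single-base indel events (a deletion gaps the partner row; an insertion
adds a reference-gap column) — no realignment, since the consumer is the
conservation checker, which only needs column structure.  One planted
pair at most per gene, because downstream positivity is boolean.

Defaults are the study conditions: an 11-gene HC-like set planted at
6/11, a 14-gene PC-like set at 2/14, the six-species mammalian panel,
loci of 3 kb at GC 0.5.  The per-species substitution rate defaults to
0.15 and the indel rate to 0.02 per base with planted motif windows
protected — divergence typical of mammalian neutral non-coding sequence
at the scale that still leaves a usable alignment, while the protected
sites mirror the premise that functional sites are perfectly conserved.
A single seeded NumPy generator drives all draws; the seed is recorded
in the truth-table header and a fixed seed reproduces every output file
byte for byte.

What the generator does **not** emulate: phylogenetically realistic
substitution processes (no tree structure beyond a star, no
transition/transversion bias, no indel length distribution), alignment
error, repeat structure, or regional GC/conservation heterogeneity.
Passing tests on this data therefore demonstrate the correctness of the
pipeline's logic and calibration of its statistics — not genome-scale
sensitivity or specificity on real alignments, which depend on
alignment quality and annotation completeness.

## Verification

* The scanner is checked for exact equivalence with a brute-force
  window-by-window set-membership oracle on random sequences and random
  IUPAC motifs, plus a strand-symmetry property.
* The hypergeometric tail is checked against exhaustive enumeration of
  all C(N, n) samples at small N, against pmf normalization at genome
  scale, and against an independent library implementation; the Fisher
  test against exhaustive fixed-margin table enumeration (totals ≤ 40)
  with exact integer weights.
* Planted-pair recovery: on noiseless protected data the pipeline
  recovers 100% of planted pairs at exact coordinates (200 loci), and
  with nothing planted the background pair count matches an analytic
  expectation (per-window match probabilities × valid placements) within
  3 SE over 500 loci.
* Null calibration: with positives assigned uniformly at random, the
  one-tailed p-value is super-uniform (empirical type-I error at
  α = 0.05 stays below 0.05 + 3·SE over 2,000 replicates) — discreteness
  of the exact test makes it conservative.

Problem sizes in the routine suite (loci of 1.5–2 kb, 200–500 loci,
2,000 calibration replicates) were chosen so the whole suite verifies
every contract in well under ten minutes on one CPU.

## Known limitations

* Published genome-scale counts for this kind of screen depend on the
  specific multiz alignments and the genome-wide positive count `K`;
  with `K` external, genome-scale p-values (e.g. against 32,120 genes)
  can be recomputed only when the user supplies `K` from their own run.
* Hits spanning alignment-block boundaries are dropped, not stitched.
* Gene attribution of intergenic sites is nearest-gene within a flank —
  one defensible choice among several; enhancers do skip genes.
* Consensus matching has no affinity model; a single mismatch is a miss.
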