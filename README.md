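# motiflink

A phylogenetic-footprinting pipeline for detecting a candidate
cis-regulatory module — **linked SOX9–GLI binding sites** — in conserved
non-coding sequence, with exact over-representation statistics.

## The problem

During endochondral ossification, growth-plate chondrocytes proliferate,
then mature into hypertrophic chondrocytes.  SOX9 together with the
hedgehog effectors GLI2/3 can act as a repressive module that keeps
hypertrophy-stage genes (e.g. *Col10a1*, *Runx2*, *Mef2c*) silent in
immature chondrocytes.  The genomic signature of this module is a SOX9
consensus site and a GLI consensus site, each perfectly conserved between
mouse and human, separated by at most 100 nt of non-coding sequence.
`motiflink` finds such linked pairs genome-wide and asks whether they are
over-represented in a gene set of interest.

The pipeline: scan the reference with IUPAC consensus motifs (both
strands, overlaps included) → keep hits perfectly conserved against a
partner species in multiz-style MAF alignments (no mismatch, no gap) →
restrict to inter-/intragenic non-coding space → pair SOX9 with GLI at
inner gap ≤ 100 nt → annotate intervening TCF sites and six-species
conservation percentage → assign pairs to genes → exact statistics.

## Statistics

For a gene set of size *n* with *k* linked-pair-positive genes, drawn
against a genome of *N* genes of which *K* are positive, enrichment is
the hypergeometric upper tail

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ k) = Σᵢ₌ₖ^min(K,n) C(K,i)·C(N−K,n−i) / C(N,n),

computed in log space (log-sum-exp over compensated log-binomials), so
genome-scale *N* never overflows.  Two gene sets are contrasted with the
one-tailed Fisher exact test — the same tail with the 2×2 table's margins.
*K* is a required input: the genome-wide positive count depends on the
alignments and annotation used and is never assumed.

## Worked example

The package ships a generator for synthetic six-species datasets with
planted, perfectly conserved SOX9–GLI pairs at controlled per-gene
frequency, so the whole pipeline runs without downloads:

```sh
python analysis/01_simulate.py --seed 1   # 11 HC-like + 14 PC-like loci
python analysis/02_scan.py                # scan -> conserve -> pair -> call
python analysis/03_enrich.py              # hypergeometric + Fisher report
```

With seed 1 this prints:

```
filter funnel (hits per motif):
motif  raw  conserved  noncoding
 SOX9   98         36         34
  GLI   10          8          8
  TCF   51         20         18
linked pairs (<=100 nt spacing): 9; 0 hits dropped at block edges
positive genes: 8 of 25

HC: 6/11 positive genes; genome reference 8/25; hypergeometric P(X >= 6) = 0.0433
PC: 2/14 positive genes; genome reference 8/25; hypergeometric P(X >= 2) = 0.996
HC (6/11) vs PC (2/14): one-tailed Fisher p = 0.0433
```

Reading it: of 98 raw SOX9 consensus matches, 36 are perfectly conserved
against the simulated human sequence and 34 of those are non-coding;
pairing with conserved GLI sites yields 9 linked pairs over 8 of 25
genes.  Six of the 11 HC-like genes are positive versus 2 of 14 PC-like
genes, and the one-tailed Fisher exact test puts that contrast at
p = 0.043 — the HC-like set is enriched, matching how the data were
simulated (plant frequencies 6/11 vs 2/14).

The same stages are available as a CLI (`motiflink synth | scan |
enrich | all`) for running on real FASTA/MAF/BED12 inputs; consensus
definitions are editable YAML (`--motifs`).

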