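"""End-to-end screen: scan -> conserve -> restrict -> pair -> call.

Stage bookkeeping is explicit: every filter logs how many hits survive,
so the funnel (raw hits -> perfectly conserved -> non-coding -> paired)
is auditable from the run log and the returned counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO

from . import alignments as aln
from . import motifs as mo
from . import pairs as pr
from . import regions as rg

log = logging.getLogger(__name__)


@dataclass
class StageCounts:
    raw_hits: dict[str, int] = field(default_factory=dict)
    cross_block_dropped: int = 0
    conserved_hits: dict[str, int] = field(default_factory=dict)
    noncoding_hits: dict[str, int] = field(default_factory=dict)
    pairs: int = 0
    pairs_assigned: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.raw_hits:
            rows.append({"motif": name,
                         "raw": self.raw_hits.get(name, 0),
                         "conserved": self.conserved_hits.get(name, 0),
                         "noncoding": self.noncoding_hits.get(name, 0)})
        return pd.DataFrame(rows)


@dataclass
class ScanResult:
    hits: list[mo.MotifHit]               # conserved, non-coding hits
    pairs: list[pr.LinkedPair]
    calls: pr.GeneCallTable
    counts: StageCounts

    def hits_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"motif": h.motif_name, "chrom": h.chrom, "start": h.start,
              "end": h.end, "strand": h.strand, "matched_seq": h.matched_seq}
             for h in self.hits])


def read_genome(path: str) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines fine) as a dict of sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def run_scan(genome: dict[str, str],
             blocks: list[aln.AlignmentBlock],
             genes: list[rg.GeneModel],
             chrom_lengths: dict[str, int],
             motifs: list[mo.MotifDef] | None = None,
             partner_species: str = "human",
             species_panel: tuple[str, ...] | None = None,
             max_spacing: int = 100,
             spacing_inclusive: bool = True,
             max_flank: int = 50_000,
             exclude: str = "exons") -> ScanResult:
    """Run the whole screen over in-memory inputs.

    ``motifs`` must contain entries named SOX9 and GLI (TCF optional);
    defaults to the shipped motif set.  ``partner_species`` is the single
    species against which perfect conservation is required; the wider
    ``species_panel`` only feeds the descriptive conservation percentage.
    """
    motifs = motifs if motifs is not None else mo.load_motifs()
    by_name = {m.name: m for m in motifs}
    if "SOX9" not in by_name or "GLI" not in by_name:
        raise ValueError("motif set must define SOX9 and GLI")
    missing = {g.chrom for g in genes} - set(genome)
    if missing:
        raise ValueError(f"annotation chromosomes absent from genome: {sorted(missing)}")

    mask = rg.build_region_mask(genes, chrom_lengths, exclude=exclude)
    index = aln.MafIndex(blocks)
    gene_index = rg.GeneIndex(genes)
    if species_panel is None:
        seen = {r.species for b in blocks for r in b.rows}
        species_panel = tuple(sorted(seen)) or ("ref",)

    counts = StageCounts()
    conserved: dict[str, list[mo.MotifHit]] = {m.name: [] for m in motifs}
    for m in motifs:
        raw = 0
        for chrom, seq in sorted(genome.items()):
            for hit in mo.scan_sequence(seq, m, chrom):
                raw += 1
                block = index.containing(chrom, hit.start, hit.end)
                if block is None:
                    counts.cross_block_dropped += 1
                    log.debug("hit %s:%d-%d not inside a single block; dropped",
                              chrom, hit.start, hit.end)
                    continue
                if aln.is_perfectly_conserved(block, hit.start, hit.end,
                                              partner_species):
                    conserved[m.name].append(
                        mo.MotifHit(hit.chrom, hit.start, hit.end, hit.strand,
                                    hit.motif_name, hit.matched_seq, True))
        counts.raw_hits[m.name] = raw
        counts.conserved_hits[m.name] = len(conserved[m.name])
        log.info("motif %s: %d raw hits, %d perfectly conserved vs %s",
                 m.name, raw, len(conserved[m.name]), partner_species)

    noncoding: dict[str, list[mo.MotifHit]] = {}
    for name, hits in conserved.items():
        kept = [h for h in hits if mask.is_noncoding(h.chrom, h.start, h.end)]
        noncoding[name] = kept
        counts.noncoding_hits[name] = len(kept)
        log.info("motif %s: %d hits in non-coding space", name, len(kept))

    pairs = pr.find_linked_pairs(noncoding["SOX9"], noncoding["GLI"],
                                 max_spacing=max_spacing,
                                 inclusive=spacing_inclusive)
    counts.pairs = len(pairs)
    log.info("%d linked pairs at max spacing %d", len(pairs), max_spacing)

    tcf_hits = noncoding.get("TCF", [])
    annotated: list[pr.LinkedPair] = []
    for p in pairs:
        p = pr.annotate_intervening_tcf(p, tcf_hits)
        block = index.containing(p.chrom, p.start, p.end)
        cons = None
        if block is not None:
            cons = aln.conservation_percentage(block, p.start, p.end,
                                               list(species_panel))
        gene_ids = tuple(gene_index.assign(p.chrom, p.start, p.end, max_flank))
        annotated.append(replace(p, conservation=cons, genes=gene_ids))
    counts.pairs_assigned = sum(1 for p in annotated if p.genes)

    calls = pr.call_genes(annotated, [g.gene_id for g in genes])
    all_hits = sorted((h for hs in noncoding.values() for h in hs),
                      key=lambda h: (h.chrom, h.start, h.strand))
    return ScanResult(hits=all_hits, pairs=annotated, calls=calls,
                      counts=counts)


def run_scan_from_files(genome_path: str, maf_path: str, annotation_path: str,
                        chrom_sizes_path: str, annotation_format: str = "bed12",
                        motifs_path: str | None = None,
                        **kwargs) -> ScanResult:
    """File-based wrapper around :func:`run_scan`."""
    return run_scan(
        genome=read_genome(genome_path),
        blocks=aln.read_maf(maf_path),
        genes=rg.read_annotation(annotation_path, annotation_format),
        chrom_lengths=rg.read_chrom_sizes(chrom_sizes_path),
        motifs=mo.load_motifs(motifs_path) if motifs_path else None,
        **kwargs)
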