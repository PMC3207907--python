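"""Synthetic multi-species datasets with planted conserved SOX9-GLI pairs.

Each gene gets its own locus (one scaffold), carrying a two-exon gene
body flanked by intergenic sequence.  With a per-gene plant probability a
perfectly conserved SOX9 instance and GLI instance are embedded in
non-exonic space at a spacing drawn uniformly from the spacing range,
random order and strands.  Partner species descend from the reference by
i.i.d. per-base substitutions and single-base indels on a star phylogeny;
planted motif windows can be protected from noise, emulating the premise
that functional sites are perfectly conserved while surrounding
non-coding sequence diverges.

Everything is driven by one seeded NumPy generator, so a fixed seed
reproduces the dataset byte for byte; the seed is recorded in the truth
table header.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .alignments import AlignmentBlock, AlignmentRow, write_maf
from .motifs import MotifDef, load_motifs, reverse_complement, validate_iupac
from .regions import GeneModel

BASES = np.array(list("ACGT"))

DEFAULT_PANEL = ("mouse", "human", "chimpanzee", "canine", "bovine", "opossum")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the screened gene sets: an 11-gene hypertrophic-
    chondrocyte-like set planted at 6/11 and a 14-gene proliferating-
    chondrocyte-like set planted at 2/14, aligned across the six-species
    mammalian panel with a 0-100 nt spacing window.
    """

    n_genes: int = 25
    n_hc: int = 11
    n_pc: int = 14
    locus_length: int = 3000
    species_panel: tuple[str, ...] = DEFAULT_PANEL
    plant_probability: float = 0.25          # background genes beyond the sets
    f_hi: float = 6 / 11                     # HC-like plant probability
    f_lo: float = 2 / 14                     # PC-like plant probability
    spacing_range: tuple[int, int] = (0, 100)
    per_species_substitution_rate: float = 0.15
    per_species_indel_rate: float = 0.02
    protect_planted: bool = True
    gc_content: float = 0.5
    seed: int = 0
    sox9: MotifDef = field(default_factory=lambda: load_motifs()[0])
    gli: MotifDef = field(default_factory=lambda: load_motifs()[1])

    def __post_init__(self) -> None:
        for name, v in (("plant_probability", self.plant_probability),
                        ("f_hi", self.f_hi), ("f_lo", self.f_lo),
                        ("substitution rate", self.per_species_substitution_rate),
                        ("indel rate", self.per_species_indel_rate),
                        ("gc_content", self.gc_content)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_hc + self.n_pc > self.n_genes:
            raise ValueError("n_hc + n_pc exceeds n_genes")
        needed = 2 * (len(self.sox9) + len(self.gli)) + self.spacing_range[1]
        if self.locus_length <= needed:
            raise ValueError(f"locus_length must exceed {needed}")

    @property
    def ref_species(self) -> str:
        return self.species_panel[0]

    def plant_prob_for(self, gene_index: int) -> float:
        if gene_index < self.n_hc:
            return self.f_hi
        if gene_index < self.n_hc + self.n_pc:
            return self.f_lo
        return self.plant_probability


@dataclass
class TruthRow:
    gene_id: str
    chrom: str
    planted: bool
    sox9_start: int = -1
    sox9_strand: str = "."
    gli_start: int = -1
    gli_strand: str = "."
    spacing: int = -1
    upstream_motif: str = "."
    n_substitutions: int = 0
    n_indels: int = 0


@dataclass
class Locus:
    chrom: str
    ref_seq: str
    block: AlignmentBlock
    gene: GeneModel
    truth: TruthRow


def _draw_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _draw_instance(rng: np.random.Generator, motif: MotifDef) -> str:
    """A concrete sequence drawn uniformly from those matching the consensus."""
    return "".join(rng.choice(sorted(s)) for s in validate_iupac(motif.consensus))


def _gene_layout(length: int) -> GeneModel:
    """Two-exon gene body occupying the middle 40% of the locus."""
    tx_start, tx_end = int(length * 0.30), int(length * 0.70)
    exon = min(100, (tx_end - tx_start) // 3)
    exons = ((tx_start, tx_start + exon), (tx_end - exon, tx_end))
    return GeneModel("placeholder", "placeholder", "+", tx_start, tx_end, exons)


def _noncoding_intervals(length: int, gene: GeneModel) -> list[tuple[int, int]]:
    ivs = [(0, gene.tx_start), (gene.exons[0][1], gene.exons[1][0]),
           (gene.tx_end, length)]
    return [(s, e) for s, e in ivs if e > s]


def generate_locus(config: SyntheticConfig, gene_index: int,
                   rng: np.random.Generator,
                   plant_probability: float | None = None) -> Locus:
    """One reference locus with its gene, alignment block, and truth row."""
    L = config.locus_length
    chrom = f"locus{gene_index:04d}"
    gene_id = f"gene{gene_index:04d}"
    f = config.plant_probability if plant_probability is None else plant_probability

    ref = _draw_sequence(rng, L, config.gc_content)
    layout = _gene_layout(L)
    gene = GeneModel(gene_id, chrom, "+", layout.tx_start, layout.tx_end,
                     layout.exons)
    truth = TruthRow(gene_id=gene_id, chrom=chrom, planted=False)
    protected: list[tuple[int, int]] = []

    if rng.random() < f:
        sox_seq = _draw_instance(rng, config.sox9)
        gli_seq = _draw_instance(rng, config.gli)
        sox_strand, gli_strand = rng.choice(["+", "-"], size=2)
        spacing = int(rng.integers(config.spacing_range[0],
                                   config.spacing_range[1] + 1))
        sox_first = bool(rng.random() < 0.5)
        first_len = len(sox_seq) if sox_first else len(gli_seq)
        second_len = len(gli_seq) if sox_first else len(sox_seq)
        window = first_len + spacing + second_len

        slots = [(s, e) for s, e in _noncoding_intervals(L, gene)
                 if e - s >= window]
        if not slots:
            raise ValueError(f"locus too short to place gene and pair "
                             f"(window {window} nt)")
        weights = np.array([e - s - window + 1 for s, e in slots], float)
        slot = slots[int(rng.choice(len(slots), p=weights / weights.sum()))]
        pos = int(rng.integers(slot[0], slot[1] - window + 1))

        first_seq, first_strand = ((sox_seq, sox_strand) if sox_first
                                   else (gli_seq, gli_strand))
        second_seq, second_strand = ((gli_seq, gli_strand) if sox_first
                                     else (sox_seq, sox_strand))
        p2 = pos + first_len + spacing
        for p, seq, strand in ((pos, first_seq, first_strand),
                               (p2, second_seq, second_strand)):
            planted = seq if strand == "+" else reverse_complement(seq)
            ref[p:p + len(seq)] = list(planted)
            protected.append((p, p + len(seq)))

        truth = TruthRow(
            gene_id=gene_id, chrom=chrom, planted=True,
            sox9_start=pos if sox_first else p2,
            sox9_strand=sox_strand,
            gli_start=p2 if sox_first else pos,
            gli_strand=gli_strand,
            spacing=spacing,
            upstream_motif="SOX9" if sox_first else "GLI")

    block, n_sub, n_ind = _build_alignment(config, chrom, ref, protected, rng)
    truth.n_substitutions, truth.n_indels = n_sub, n_ind
    return Locus(chrom=chrom, ref_seq="".join(ref), block=block,
                 gene=gene, truth=truth)


def _build_alignment(config: SyntheticConfig, chrom: str, ref: np.ndarray,
                     protected: list[tuple[int, int]],
                     rng: np.random.Generator) -> tuple[AlignmentBlock, int, int]:
    """Star-phylogeny alignment: per-species substitutions and 1-bp indels."""
    L = len(ref)
    prot = np.zeros(L, bool)
    if config.protect_planted:
        for s, e in protected:
            prot[s:e] = True

    # per species: base at each ref position ('-' = deletion) and an
    # insertion string emitted after that position
    chars: dict[str, np.ndarray] = {}
    inserts: dict[str, dict[int, str]] = {}
    n_sub_total = n_ind_total = 0
    for sp in config.species_panel[1:]:
        c = ref.copy()
        ins: dict[int, str] = {}
        sub_mask = (rng.random(L) < config.per_species_substitution_rate) & ~prot
        for i in np.flatnonzero(sub_mask):
            alt = [b for b in "ACGT" if b != ref[i]]
            c[i] = alt[int(rng.integers(3))]
        n_sub_total += int(sub_mask.sum())
        ind_mask = (rng.random(L) < config.per_species_indel_rate) & ~prot
        for i in np.flatnonzero(ind_mask):
            if rng.random() < 0.5:
                c[i] = "-"                          # deletion in this species
            else:
                ins[int(i)] = str(rng.choice(BASES))  # 1-bp insertion after i
        n_ind_total += int(ind_mask.sum())
        chars[sp] = c
        inserts[sp] = ins

    cols: dict[str, list[str]] = {sp: [] for sp in config.species_panel}
    ref_sp = config.ref_species
    for i in range(L):
        cols[ref_sp].append(ref[i])
        for sp in config.species_panel[1:]:
            cols[sp].append(str(chars[sp][i]))
        for sp in config.species_panel[1:]:
            if i in inserts[sp]:
                for other in config.species_panel:
                    cols[other].append(inserts[sp][i] if other == sp else "-")

    rows = []
    for sp in config.species_panel:
        text = "".join(cols[sp])
        size = len(text) - text.count("-")
        rows.append(AlignmentRow(species=sp, src=f"{sp}.{chrom}", start=0,
                                 size=size, strand="+",
                                 src_size=size if sp != ref_sp else L,
                                 text=text))
    return AlignmentBlock(rows), n_sub_total, n_ind_total


TRUTH_COLUMNS = ["gene_id", "chrom", "planted", "sox9_start", "sox9_strand",
                 "gli_start", "gli_strand", "spacing", "upstream_motif",
                 "n_substitutions", "n_indels"]


def generate_dataset(config: SyntheticConfig, outdir: str) -> dict[str, str]:
    """Write a complete dataset; returns the emitted file paths.

    Files: reference FASTA, MAF alignment, BED12 annotation, chrom.sizes,
    the two gene-set lists (HC-like planted at ``f_hi``, PC-like at
    ``f_lo``), and the truth table TSV (seed in its header line).
    Deterministic: the same config yields byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    loci = [generate_locus(config, i, rng, config.plant_prob_for(i))
            for i in range(config.n_genes)]

    paths = {k: os.path.join(outdir, v) for k, v in {
        "genome": "genome.fa", "maf": "alignment.maf",
        "annotation": "genes.bed", "chrom_sizes": "chrom.sizes",
        "genes_hc": "genes_hc.txt", "genes_pc": "genes_pc.txt",
        "truth": "truth.tsv"}.items()}

    with open(paths["genome"], "w") as fh:
        for loc in loci:
            fh.write(f">{loc.chrom}\n")
            for i in range(0, len(loc.ref_seq), 60):
                fh.write(loc.ref_seq[i:i + 60] + "\n")

    write_maf([loc.block for loc in loci], paths["maf"])

    with open(paths["annotation"], "w") as fh:
        for loc in loci:
            g = loc.gene
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                g.tx_start, g.tx_end, "0,0,0", len(g.exons),
                sizes, starts])) + "\n")

    with open(paths["chrom_sizes"], "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{config.locus_length}\n")

    with open(paths["genes_hc"], "w") as fh:
        for loc in loci[:config.n_hc]:
            fh.write(loc.gene.gene_id + "\n")
    with open(paths["genes_pc"], "w") as fh:
        for loc in loci[config.n_hc:config.n_hc + config.n_pc]:
            fh.write(loc.gene.gene_id + "\n")

    with open(paths["truth"], "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for loc in loci:
            t = loc.truth
            fh.write("\t".join(str(getattr(t, c)) for c in TRUTH_COLUMNS) + "\n")
    return paths


def motif_match_probability(motif: MotifDef, gc: float) -> float:
    """Per-window probability that i.i.d. sequence matches the consensus.

    Counts both strands when the motif scans both; the (tiny) inclusion-
    exclusion term for windows matching on both strands is ignored, which
    is exact for non-self-complementary consensi like the defaults.
    """
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
              "G": gc / 2, "C": gc / 2}
    def one(consensus: str) -> float:
        p = 1.0
        for allowed in validate_iupac(consensus):
            p *= sum(base_p[b] for b in allowed)
        return p
    p = one(motif.consensus)
    if motif.both_strands:
        p += one(reverse_complement(motif.consensus))
    return p


def expected_background_pairs(noncoding: list[tuple[int, int]],
                              sox9: MotifDef, gli: MotifDef,
                              max_spacing: int, gc: float) -> float:
    """Analytic expectation of background pair count in unplanted sequence.

    Sums, over every ordered placement of a SOX9 window and a GLI window
    inside the non-coding intervals with an inner gap in [0, max_spacing],
    the product of the two per-window match probabilities.  Dependence
    between overlapping windows of the same motif is ignored (second-order
    for the scanned consensus lengths).
    """
    ls, lg = len(sox9), len(gli)
    sox_starts = np.concatenate([np.arange(s, e - ls + 1)
                                 for s, e in noncoding if e - s >= ls]) \
        if noncoding else np.array([], int)
    gli_starts = np.concatenate([np.arange(s, e - lg + 1)
                                 for s, e in noncoding if e - s >= lg]) \
        if noncoding else np.array([], int)
    n_placements = 0
    for s in sox_starts:
        # SOX9 first: gap = g_start - (s + ls) in [0, max_spacing]
        n_placements += int(((gli_starts >= s + ls) &
                             (gli_starts <= s + ls + max_spacing)).sum())
        # GLI first: gap = s - (g_start + lg) in [0, max_spacing]
        n_placements += int(((gli_starts + lg <= s) &
                             (gli_starts + lg >= s - max_spacing)).sum())
    return (n_placements * motif_match_probability(sox9, gc)
            * motif_match_probability(gli, gc))
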