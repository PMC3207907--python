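"""Multi-species alignment blocks (MAF) and conservation calls.

Two distinct conservation notions are used downstream and kept separate
here, mirroring how footprinting screens report them:

* *perfect conservation* of a motif window against exactly one partner
  species (default human against a mouse reference): every aligned column
  identical, no gaps.  This is the **filter**.
* a descriptive *conservation percentage* over a window across a species
  panel: the fraction of reference columns at which every panel species
  present in the block matches the reference base without a gap.  This is
  **reported, never thresholded**.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


class MafParseError(ValueError):
    """Malformed MAF input; message carries the offending line number."""


def species_of(src: str) -> str:
    """Species id of a MAF source name: the prefix before the first dot."""
    return src.split(".", 1)[0]


@dataclass(frozen=True)
class AlignmentRow:
    species: str
    src: str            # original source name, e.g. "hg18.chr6"
    start: int          # forward-axis 0-based start on the source sequence
    size: int           # ungapped length
    strand: str         # source strand of the aligned text
    src_size: int
    text: str           # aligned characters, '-' for gaps


@dataclass
class AlignmentBlock:
    """One multiz-style block; the first row is the reference species."""

    rows: list[AlignmentRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment block has no rows")
        lens = {len(r.text) for r in self.rows}
        if len(lens) != 1:
            raise ValueError(f"rows of unequal length: {sorted(lens)}")
        ids = [r.species for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate species within block: {ids}")

    @property
    def ref(self) -> AlignmentRow:
        return self.rows[0]

    @property
    def ref_species(self) -> str:
        return self.ref.species

    @property
    def ref_chrom(self) -> str:
        src = self.ref.src
        return src.split(".", 1)[1] if "." in src else src

    @property
    def ref_start(self) -> int:
        return self.ref.start

    @property
    def ref_end(self) -> int:
        return self.ref.start + self.ref.size

    @property
    def n_columns(self) -> int:
        return len(self.ref.text)

    def row_for(self, species: str) -> AlignmentRow | None:
        for r in self.rows:
            if r.species == species:
                return r
        return None


@dataclass(frozen=True)
class ConservationRecord:
    """Descriptive window conservation across a species panel."""

    pct_identical: float
    species_present: tuple[str, ...]
    n_columns: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identical <= 100.0):
            raise ValueError("pct_identical out of [0, 100]")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")


def _diagnose_maf(path: str) -> int | None:
    """Line number (1-based) of the first malformed 's' line or ragged block."""
    block_len: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("a"):
                block_len = None
            elif line.startswith("s"):
                parts = line.split()
                if len(parts) != 7:
                    return lineno
                try:
                    int(parts[2]); int(parts[3]); int(parts[5])
                except ValueError:
                    return lineno
                if parts[4] not in "+-":
                    return lineno
                if block_len is None:
                    block_len = len(parts[6])
                elif len(parts[6]) != block_len:
                    return lineno
    return None


def read_maf(path: str) -> list[AlignmentBlock]:
    """Read a UCSC-dialect MAF file into forward-axis alignment blocks.

    The first 's' row of each block is taken as the reference species.
    Minus-strand source coordinates are converted to the forward axis.
    """
    blocks: list[AlignmentBlock] = []
    try:
        with open(path) as fh:
            for aln in AlignIO.parse(fh, "maf"):
                rows = []
                for rec in aln:
                    ann = rec.annotations
                    start, size = ann["start"], ann["size"]
                    strand = "+" if ann["strand"] == 1 else "-"
                    src_size = ann["srcSize"]
                    if strand == "-":
                        start = src_size - start - size
                    rows.append(AlignmentRow(
                        species=species_of(rec.id), src=rec.id,
                        start=start, size=size, strand=strand,
                        src_size=src_size, text=str(rec.seq)))
                blocks.append(AlignmentBlock(rows))
    except ValueError as exc:
        lineno = _diagnose_maf(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise MafParseError(f"malformed MAF {path!r}{where}: {exc}") from exc
    return blocks


def write_maf(blocks: list[AlignmentBlock], path: str) -> None:
    """Write blocks back to MAF (forward coordinates, '+' strands)."""
    alns = []
    for b in blocks:
        recs = []
        for r in b.rows:
            rec = SeqRecord(Seq(r.text), id=r.src)
            rec.annotations = {"start": r.start, "size": r.size,
                               "strand": 1, "srcSize": r.src_size}
            recs.append(rec)
        alns.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(alns, fh, "maf")


def ref_interval_to_columns(block: AlignmentBlock, start: int, end: int) -> range:
    """Alignment-column range covering reference bases [start, end).

    The returned half-open column range runs from the column of the first
    reference base to one past the column of the last; it may include
    reference-gap columns (insertions in other species) between them.
    """
    if start < block.ref_start or end > block.ref_end or start >= end:
        raise IndexError(
            f"interval [{start}, {end}) outside block reference span "
            f"[{block.ref_start}, {block.ref_end})")
    text = block.ref.text
    base_cols = [i for i, ch in enumerate(text) if ch != "-"]
    first = base_cols[start - block.ref_start]
    last = base_cols[end - 1 - block.ref_start]
    return range(first, last + 1)


def is_perfectly_conserved(block: AlignmentBlock, start: int, end: int,
                           partner_species: str) -> bool:
    """True iff [start, end) is identical and gap-free against the partner.

    Any substitution, any gap in the partner row, or any partner-specific
    insertion inside the window breaks perfect conservation; a partner
    absent from the block is non-conservation (logged), not an error.
    """
    partner = block.row_for(partner_species)
    if partner is None:
        log.debug("partner %s absent from block at %s:%d",
                  partner_species, block.ref_chrom, block.ref_start)
        return False
    cols = ref_interval_to_columns(block, start, end)
    ref_text, p_text = block.ref.text, partner.text
    for c in cols:
        r, p = ref_text[c], p_text[c]
        if r == "-" and p == "-":
            continue                      # insertion in a third species
        if r == "-" or p == "-":
            return False                  # indel between ref and partner
        if r.upper() != p.upper():
            return False
    return True


def conservation_percentage(block: AlignmentBlock, start: int, end: int,
                            species_panel: list[str]) -> ConservationRecord:
    """Panel-wide descriptive conservation of reference window [start, end).

    A reference column counts as identical when every panel species present
    in the block aligns a non-gap base equal to the reference base there.
    With no panel species aligned the percentage is vacuously 100 and
    ``species_present`` names the reference alone, so reports can flag it.
    """
    if end <= start:
        raise ValueError("zero-length window")
    if not species_panel:
        raise ValueError("empty species panel")
    cols = ref_interval_to_columns(block, start, end)
    ref_text = block.ref.text
    others = [block.row_for(sp) for sp in species_panel
              if sp != block.ref_species]
    others = [r for r in others if r is not None]

    ref_cols = [c for c in cols if ref_text[c] != "-"]
    n_ident = 0
    for c in ref_cols:
        r = ref_text[c].upper()
        if all(row.text[c] != "-" and row.text[c].upper() == r for row in others):
            n_ident += 1
    present = tuple([block.ref_species] + [
        row.species for row in others
        if all(row.text[c] != "-" for c in ref_cols)])
    return ConservationRecord(
        pct_identical=100.0 * n_ident / len(ref_cols),
        species_present=present,
        n_columns=len(ref_cols))


class MafIndex:
    """Per-chromosome interval lookup of blocks fully containing a window."""

    def __init__(self, blocks: list[AlignmentBlock]):
        self._trees: dict[str, IntervalTree] = {}
        for b in blocks:
            self._trees.setdefault(b.ref_chrom, IntervalTree()).addi(
                b.ref_start, b.ref_end, b)

    def containing(self, chrom: str, start: int, end: int) -> AlignmentBlock | None:
        """The block whose reference span fully contains [start, end), or None."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        for iv in tree.overlap(start, end):
            if iv.begin <= start and end <= iv.end:
                return iv.data
        return None
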