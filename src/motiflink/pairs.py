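"""Linked SOX9-GLI site pairing, TCF context, and per-gene calls.

A *linked pair* is a conserved SOX9 site and a conserved GLI site on the
same chromosome whose inner gap (end of the first site to start of the
second on the forward axis) is at most ``max_spacing`` nt -- 100 by
default.  Order on the axis and strand orientations are recorded, never
filtered on.  Overlapping sites are not pairs: spacing presupposes
separated sites.  A gene is called positive once it owns at least one
pair, regardless of multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .alignments import ConservationRecord
from .motifs import MotifHit


@dataclass(frozen=True)
class LinkedPair:
    sox9: MotifHit
    gli: MotifHit
    spacing: int
    upstream_motif: str                   # which motif comes first on the axis
    conservation: ConservationRecord | None = None
    genes: tuple[str, ...] = ()
    intervening_tcf: bool = False

    def __post_init__(self) -> None:
        if self.spacing < 0:
            raise ValueError("linked pair hits must not overlap")

    @property
    def chrom(self) -> str:
        return self.sox9.chrom

    @property
    def start(self) -> int:
        return min(self.sox9.start, self.gli.start)

    @property
    def end(self) -> int:
        return max(self.sox9.end, self.gli.end)

    @property
    def orientations(self) -> tuple[str, str]:
        return (self.sox9.strand, self.gli.strand)

    @property
    def gap_interval(self) -> tuple[int, int]:
        first, second = ((self.sox9, self.gli) if self.sox9.start <= self.gli.start
                         else (self.gli, self.sox9))
        return first.end, second.start


def find_linked_pairs(sox9_hits: list[MotifHit], gli_hits: list[MotifHit],
                      max_spacing: int = 100,
                      inclusive: bool = True) -> list[LinkedPair]:
    """All SOX9 x GLI combinations with inner gap in [0, max_spacing].

    Either motif may come first on the axis and any strand combination is
    admitted.  ``inclusive=False`` flips the boundary to a strict
    ``gap < max_spacing``.  Each combination is reported once; output is
    sorted by pair start.
    """
    gli_sorted = sorted(gli_hits, key=lambda h: (h.start, h.strand))
    out: list[LinkedPair] = []
    for s in sox9_hits:
        for g in gli_sorted:
            if g.chrom != s.chrom:
                continue
            if g.start >= s.end:
                gap = g.start - s.end
                first = "SOX9"
            elif s.start >= g.end:
                gap = s.start - g.end
                first = "GLI"
            else:
                continue                  # overlapping hits are not a pair
            ok = gap <= max_spacing if inclusive else gap < max_spacing
            if gap >= 0 and ok:
                out.append(LinkedPair(sox9=s, gli=g, spacing=gap,
                                      upstream_motif=first))
    out.sort(key=lambda p: (p.chrom, p.start, p.end,
                            p.sox9.start, p.gli.start))
    return out


def annotate_intervening_tcf(pair: LinkedPair,
                             tcf_hits: list[MotifHit]) -> LinkedPair:
    """Mark the pair when a conserved TCF site lies wholly inside its gap.

    "Between" is read strictly: a TCF hit overlapping either the SOX9 or
    the GLI site does not count.
    """
    gap_start, gap_end = pair.gap_interval
    has = any(t.chrom == pair.chrom and t.start >= gap_start and t.end <= gap_end
              for t in tcf_hits)
    return replace(pair, intervening_tcf=has)


@dataclass
class GeneCallTable:
    """Per-gene positivity plus the pair detail rows behind each call."""

    calls: dict[str, bool]
    details: pd.DataFrame

    def positives(self) -> list[str]:
        return sorted(g for g, v in self.calls.items() if v)

    def count_positive(self, gene_set: list[str]) -> tuple[int, list[str]]:
        """(k, unknown_ids) for a gene set against this table."""
        unknown = [g for g in gene_set if g not in self.calls]
        k = sum(1 for g in gene_set if self.calls.get(g, False))
        return k, unknown


PAIR_COLUMNS = ["gene_id", "chrom", "sox9_start", "sox9_strand",
                "gli_start", "gli_strand", "upstream_motif", "spacing",
                "pct_conservation", "species_present", "intervening_tcf"]


def pairs_to_frame(pairs: list[LinkedPair]) -> pd.DataFrame:
    """Flatten pairs to the detail table (one row per pair x assigned gene)."""
    rows = []
    for p in pairs:
        cons = p.conservation
        for gene in (p.genes or ("",)):
            rows.append({
                "gene_id": gene,
                "chrom": p.chrom,
                "sox9_start": p.sox9.start,
                "sox9_strand": p.sox9.strand,
                "gli_start": p.gli.start,
                "gli_strand": p.gli.strand,
                "upstream_motif": p.upstream_motif,
                "spacing": p.spacing,
                "pct_conservation": None if cons is None else cons.pct_identical,
                "species_present": "" if cons is None else ",".join(cons.species_present),
                "intervening_tcf": p.intervening_tcf,
            })
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def call_genes(pairs: list[LinkedPair], gene_ids: list[str]) -> GeneCallTable:
    """Boolean per-gene call table over ``gene_ids`` from assigned pairs."""
    calls = {g: False for g in gene_ids}
    for p in pairs:
        for g in p.genes:
            calls[g] = True
    return GeneCallTable(calls=calls, details=pairs_to_frame(pairs))


def pairs_to_bed6(pairs: list[LinkedPair]) -> str:
    """BED6 text of pair windows (score = spacing, strand = SOX9 strand)."""
    lines = []
    for p in pairs:
        name = ";".join(p.genes) if p.genes else "unassigned"
        lines.append("\t".join(map(str, [p.chrom, p.start, p.end,
                                         name, p.spacing, p.sox9.strand])))
    return "\n".join(lines) + ("\n" if lines else "")
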