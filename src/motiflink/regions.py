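"""Gene models, the non-coding search space, and gene assignment.

The screen runs over inter- and intragenic *non-coding* sequence: a
chromosome is tiled into exonic / intronic / intergenic intervals
(exonic taking precedence where genes overlap) and only the
intronic + intergenic remainder is searched.  An intergenic site is
attributed to its nearest gene by edge distance within a configurable
flank (ties attribute to all tied genes).
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree


class AnnotationParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"{self.gene_id}: empty transcript span")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside "
                                 f"transcript [{self.tx_start},{self.tx_end})")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted disjoint list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(base: list[tuple[int, int]],
                       cut: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference base \\ cut; both inputs sorted disjoint."""
    out: list[tuple[int, int]] = []
    cut = list(cut)
    j = 0
    for s, e in base:
        pos = s
        while j < len(cut) and cut[j][1] <= s:
            j += 1
        k = j
        while k < len(cut) and cut[k][0] < e:
            cs, ce = cut[k]
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            k += 1
        if pos < e:
            out.append((pos, e))
    return out


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise AnnotationParseError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5]
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from None
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise AnnotationParseError(f"line {lineno}: blockCount disagrees with block lists")
    exons = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
    try:
        return GeneModel(name, chrom, strand, start, end, exons)
    except ValueError as exc:
        raise AnnotationParseError(f"line {lineno}: {exc}") from None


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_annotation(path: str, fmt: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or GTF.

    Multiple transcripts of one gene id are collapsed to the union of
    their exons and the widest transcript span.  Returned sorted by
    (chrom, tx_start).
    """
    fmt = fmt.lower()
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if fmt == "bed12":
                g = _parse_bed12_line(line, lineno)
                gid, chrom, strand = g.gene_id, g.chrom, g.strand
                span = (g.tx_start, g.tx_end)
                exons = list(g.exons)
            elif fmt == "gtf":
                f = line.rstrip("\n").split("\t")
                if len(f) != 9:
                    raise AnnotationParseError(f"line {lineno}: GTF needs 9 fields")
                chrom, feature, strand = f[0], f[2], f[6]
                try:
                    start, end = int(f[3]) - 1, int(f[4])   # GTF is 1-based inclusive
                except ValueError as exc:
                    raise AnnotationParseError(f"line {lineno}: {exc}") from None
                attrs = _parse_gtf_attrs(f[8])
                gid = attrs.get("gene_id")
                if gid is None:
                    raise AnnotationParseError(f"line {lineno}: missing gene_id")
                if feature not in ("exon", "transcript", "gene"):
                    continue
                span = (start, end)
                exons = [(start, end)] if feature == "exon" else []
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
            entry = raw.setdefault(gid, {"chrom": chrom, "strand": strand,
                                         "span": span, "exons": []})
            if entry["chrom"] != chrom:
                raise AnnotationParseError(
                    f"line {lineno}: gene {gid!r} on multiple chromosomes")
            entry["span"] = (min(entry["span"][0], span[0]),
                             max(entry["span"][1], span[1]))
            entry["exons"].extend(exons)

    genes = []
    for gid, e in raw.items():
        exons = merge_intervals(e["exons"]) or [e["span"]]
        genes.append(GeneModel(gid, e["chrom"], e["strand"],
                               e["span"][0], e["span"][1], tuple(exons)))
    genes.sort(key=lambda g: (g.chrom, g.tx_start))
    return genes


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column UCSC chrom.sizes file."""
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise AnnotationParseError(f"line {lineno}: need 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_gene_set(path: str) -> list[str]:
    """Plain-text gene list, one id per line; order preserved, de-duplicated."""
    seen, out = set(), []
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if gid and not gid.startswith("#") and gid not in seen:
                seen.add(gid)
                out.append(gid)
    return out


@dataclass
class RegionMask:
    """Per-chromosome partition into exonic / intronic / intergenic intervals."""

    exonic: dict[str, list[tuple[int, int]]]
    intronic: dict[str, list[tuple[int, int]]]
    intergenic: dict[str, list[tuple[int, int]]]
    chrom_lengths: dict[str, int]

    def noncoding(self, chrom: str) -> list[tuple[int, int]]:
        """The search space: intronic plus intergenic intervals."""
        return merge_intervals(self.intronic.get(chrom, []) +
                               self.intergenic.get(chrom, []))

    def is_noncoding(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) avoids all exonic sequence."""
        for s, e in self.exonic.get(chrom, []):
            if s < end and start < e:
                return False
        return True


def build_region_mask(genes: list[GeneModel],
                      chrom_lengths: dict[str, int],
                      exclude: str = "exons") -> RegionMask:
    """Tile each chromosome into exonic / intronic / intergenic intervals.

    ``exclude='exons'`` treats every annotated exon (UTRs included) as
    coding space -- the conservative reading of "non-coding".  Where genes
    overlap, exonic takes precedence over intronic.
    """
    if exclude not in ("exons", "cds"):
        raise ValueError("exclude must be 'exons' or 'cds'")
    exonic: dict[str, list] = {}
    spans: dict[str, list] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id!r}: unknown chromosome {g.chrom!r}")
        if g.tx_end > chrom_lengths[g.chrom]:
            raise ValueError(f"gene {g.gene_id!r} extends past end of {g.chrom}")
        exonic.setdefault(g.chrom, []).extend(g.exons)
        spans.setdefault(g.chrom, []).append((g.tx_start, g.tx_end))

    ex_m, intr_m, inter_m = {}, {}, {}
    for chrom, length in chrom_lengths.items():
        ex = merge_intervals(exonic.get(chrom, []))
        sp = merge_intervals(spans.get(chrom, []))
        ex_m[chrom] = ex
        intr_m[chrom] = subtract_intervals(sp, ex)
        inter_m[chrom] = subtract_intervals([(0, length)], sp)
    return RegionMask(ex_m, intr_m, inter_m, dict(chrom_lengths))


def assign_to_gene(chrom: str, start: int, end: int,
                   genes: list[GeneModel], max_flank: int = 50_000) -> list[str]:
    """Gene id(s) an interval is attributed to.

    Inside one or more gene spans: all containing genes.  Otherwise the
    nearest gene by edge distance within ``max_flank`` nt; exact ties go
    to all tied genes; beyond the flank, none.  Deterministic and
    independent of the order genes are supplied in.
    """
    containing, nearest, best = [], [], None
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom != chrom:
            continue
        if g.tx_start < end and start < g.tx_end:
            containing.append(g.gene_id)
            continue
        # edge distance = number of bases strictly between interval and span
        d = g.tx_start - end if g.tx_start >= end else start - g.tx_end
        if d <= max_flank:
            if best is None or d < best:
                best, nearest = d, [g.gene_id]
            elif d == best:
                nearest.append(g.gene_id)
    return containing if containing else nearest


class GeneIndex:
    """Interval-tree lookup used by the pipeline for repeated assignment."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: g.gene_id)
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.tx_start, g.tx_end, g.gene_id)

    def assign(self, chrom: str, start: int, end: int,
               max_flank: int = 50_000) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is not None:
            hits = sorted(iv.data for iv in tree.overlap(start, end))
            if hits:
                return hits
        return assign_to_gene(chrom, start, end,
                              self._by_chrom.get(chrom, []), max_flank)
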