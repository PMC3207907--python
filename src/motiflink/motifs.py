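"""IUPAC consensus motifs and exhaustive both-strand scanning.

Transcription-factor binding sites are represented as IUPAC consensus
strings (e.g. the SOX9 heptamer ``WWCAAWG``).  Scanning is exact
set-membership matching per position -- no position-weight-matrix
scoring -- which mirrors the consensus-site screens used in classical
phylogenetic-footprinting studies of chondrocyte enhancers.

Coordinates are 0-based half-open on the forward reference axis
throughout; minus-strand hits are reported on the forward axis with
``strand='-'`` and ``matched_seq`` holding the forward-strand substring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import yaml

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: Default motif set.  The consensus strings are editable defaults taken
#: from the binding-site literature (COL2C1-type SOX9 heptamer, the GLI1/2/3
#: 9-mer, and the TCF/LEF core); they are configuration, not constants of
#: the method, and can be overridden via a YAML motif file.
DEFAULT_MOTIFS_YAML = """\
motifs:
  - name: SOX9
    consensus: WWCAAWG
    both_strands: true
  - name: GLI
    consensus: GACCACCCA
    both_strands: true
  - name: TCF
    consensus: CTTTGWW
    both_strands: true
"""


class IupacError(ValueError):
    """Raised for an invalid IUPAC consensus string."""


def validate_iupac(consensus: str) -> list[frozenset[str]]:
    """Return the per-position allowed-base sets of an IUPAC consensus.

    Raises
    ------
    IupacError
        If the string is empty or contains a non-IUPAC symbol; the message
        names the offending character and its 0-based position.
    """
    if not consensus:
        raise IupacError("empty consensus string")
    sets = []
    for i, ch in enumerate(consensus.upper()):
        try:
            sets.append(IUPAC_CODES[ch])
        except KeyError:
            raise IupacError(
                f"invalid IUPAC symbol {ch!r} at position {i} in {consensus!r}"
            ) from None
    return sets


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; accepts IUPAC codes, returns uppercase."""
    bad = set(seq.upper()) - set(IUPAC_CODES) - {"-"}
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)!r} in sequence")
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC consensus with its scanning policy."""

    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise IupacError(
                f"consensus for {self.name!r} shorter than 4 nt: {self.consensus!r}"
            )
        validate_iupac(self.consensus)
        object.__setattr__(self, "consensus", self.consensus.upper())

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def allowed(self) -> list[frozenset[str]]:
        return validate_iupac(self.consensus)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence on the reference, forward-axis coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_name: str = field(compare=False)
    matched_seq: str = field(compare=False)
    conserved: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.matched_seq):
            raise ValueError("matched_seq length does not equal the hit span")


def _consensus_regex(consensus: str) -> re.Pattern[str]:
    # Plain bases in the scanned sequence only; sequence N never matches,
    # so the character class is the allowed set itself (never includes N).
    parts = ["[" + "".join(sorted(s)) + "]" for s in validate_iupac(consensus)]
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_sequence(seq: str, motif: MotifDef, chrom: str, offset: int = 0) -> list[MotifHit]:
    """All occurrences of ``motif`` in ``seq``, both strands if configured.

    Overlapping occurrences are all reported.  ``offset`` is added to the
    reported coordinates so chromosome slices can be scanned in place.
    Output is sorted by start, then '+' before '-'.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    seq = seq.upper()
    hits: list[MotifHit] = []
    fwd = _consensus_regex(motif.consensus)
    for m in fwd.finditer(seq):
        s = m.start()
        hits.append(MotifHit(chrom, offset + s, offset + s + len(motif), "+",
                             motif.name, m.group(1)))
    if motif.both_strands:
        # a window matches on '-' iff its reverse complement matches the
        # consensus, i.e. the forward substring matches the reverse
        # complement of the consensus
        rev = _consensus_regex(reverse_complement(motif.consensus))
        for m in rev.finditer(seq):
            s = m.start()
            hits.append(MotifHit(chrom, offset + s, offset + s + len(motif), "-",
                                 motif.name, m.group(1)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def load_motifs(path_or_text: str | None = None) -> list[MotifDef]:
    """Load a motif set from a YAML file path (or raw YAML text); default set if None.

    The file holds ``motifs: [{name, consensus, both_strands}, ...]``.
    Names must be unique.
    """
    if path_or_text is None:
        data = yaml.safe_load(DEFAULT_MOTIFS_YAML)
    else:
        try:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        except (OSError, FileNotFoundError):
            data = yaml.safe_load(path_or_text)
    motifs = [MotifDef(d["name"], d["consensus"], bool(d.get("both_strands", True)))
              for d in data["motifs"]]
    names = [m.name for m in motifs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate motif names in set: {names}")
    return motifs


def scan_dimeric(seq: str, motif: MotifDef, chrom: str, offset: int = 0,
                 spacer_range: tuple[int, int] = (3, 5)) -> list[MotifHit]:
    """Composite scan for the dimeric SOX9 arrangement.

    SOX9 binds some enhancers as a dimer: two heptamers in head-to-head
    orientation separated by a short spacer (canonically 4 bp).  This
    optional scan reports one composite hit spanning both half-sites
    wherever a '-' half-site is followed, after ``spacer_range`` nt, by a
    '+' half-site.  The default single-consensus scan remains the primary
    mode; this exists for users screening for the paired arrangement.
    """
    singles = scan_sequence(seq, motif, chrom, offset)
    minus = [h for h in singles if h.strand == "-"]
    plus_by_start = {h.start: h for h in singles if h.strand == "+"}
    lo, hi = spacer_range
    out: list[MotifHit] = []
    for left in minus:
        for spacer in range(lo, hi + 1):
            right = plus_by_start.get(left.end + spacer)
            if right is not None:
                sub = seq[left.start - offset:right.end - offset].upper()
                out.append(MotifHit(chrom, left.start, right.end, "+",
                                    motif.name + "_dimer", sub))
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def scan_all(sequences: dict[str, str], motifs: Iterable[MotifDef]) -> list[MotifHit]:
    """Scan every motif over every sequence; sorted per chromosome."""
    hits: list[MotifHit] = []
    for chrom in sorted(sequences):
        for motif in motifs:
            hits.extend(scan_sequence(sequences[chrom], motif, chrom))
    return hits
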