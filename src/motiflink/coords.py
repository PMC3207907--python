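"""Coordinate conventions and converters at the I/O boundary.

Internally everything is 0-based half-open on the forward axis (BED
convention).  Published enhancer coordinates are usually 1-based
biological positions, often negative offsets upstream of a TSS
(e.g. an element "between -4286 and -3646 bp" of a gene); these
converters make the arithmetic explicit instead of scattering ±1s.
"""

from __future__ import annotations


def one_based_to_zero_half_open(start_1b: int, end_1b: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if start_1b < 1 or end_1b < start_1b:
        raise ValueError(f"bad 1-based interval [{start_1b}, {end_1b}]")
    return start_1b - 1, end_1b


def zero_half_open_to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"bad half-open interval [{start}, {end})")
    return start + 1, end


def upstream_region_length(minus_start: int, minus_end: int) -> int:
    """Length of a region given by upstream (negative) boundary offsets.

    Upstream boundaries published as "-A to -B bp" (A > B > 0) delimit the
    region from A bases upstream down to, but not including, the base B
    bases upstream; its length is therefore A - B.  For example boundaries
    of -4286 and -3646 delimit a 640 bp element.
    """
    if minus_start >= 0 or minus_end >= 0:
        raise ValueError("upstream offsets must be negative")
    a, b = abs(minus_start), abs(minus_end)
    if a <= b:
        raise ValueError("first offset must be farther upstream than the second")
    return a - b


def upstream_region_to_interval(tss: int, minus_start: int, minus_end: int) -> tuple[int, int]:
    """Map upstream offsets relative to a 0-based TSS to a half-open interval.

    ``tss`` is the 0-based position of the transcription start; offset -k
    denotes the base k positions 5' of it on the forward strand.
    """
    length = upstream_region_length(minus_start, minus_end)
    start = tss + minus_start
    if start < 0:
        raise ValueError("region extends past the start of the chromosome")
    return start, start + length
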