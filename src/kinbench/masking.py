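"""Damage-aware terminal read masking for ancient-DNA alignments.

Post-mortem cytosine deamination inflates C>T misincorporations at the 5'
ends of sequenced fragments and, for double-stranded library protocols, G>A
misincorporations at the 3' ends.  Two masking strategies are implemented:

* a profile-driven mask: per-position terminal misincorporation rates
  (mapDamage-style ``misincorporation.txt`` tables or a simplified
  two-column dialect) define how deep each terminal window extends -- the
  window grows outward-in while the rate stays at or above a threshold
  (default 1%) and stops at the first sub-threshold position.  Within the
  windows, positions whose aligned *reference* base is susceptible (C at the
  5' end, G at the 3' end, in fragment orientation) are replaced by N with
  base quality 0, so that downstream base-quality filters drop them.
* a fixed-window mask (trimBam-style): the first and last k bases of every
  read are replaced by N unconditionally.

Masking never changes read length or name, and is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pysam

__all__ = [
    "MisincorporationProfile",
    "ReadRecord",
    "parse_misincorporation",
    "mask_boundaries",
    "mask_read",
    "trim_fixed",
    "mask_sam",
]

logger = logging.getLogger(__name__)

MASKED_QUAL = "!"  # PHRED+33 encoding of quality 0


@dataclass(frozen=True)
class MisincorporationProfile:
    """Per-position terminal damage rates.

    ``rates5[k]`` is P(C>T) at 1-based position ``k+1`` from the 5' end;
    ``rates3[k]`` is P(G>A) at position ``k+1`` from the 3' end.
    """

    rates5: tuple[float, ...]
    rates3: tuple[float, ...]

    def __post_init__(self):
        for rates in (self.rates5, self.rates3):
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError("misincorporation rates must lie in [0, 1]")
        if not self.rates5 and not self.rates3:
            raise ValueError("empty misincorporation profile")


@dataclass(frozen=True)
class ReadRecord:
    """Minimal aligned-read view used by the masking rules.

    ``sequence``/``qualities`` are stored in reference orientation (as in
    SAM); for a reverse-strand read the fragment's 5' end is therefore the
    *right* end of the stored sequence.  ``reference`` holds the aligned
    reference bases over the read span (same length as the sequence;
    indel-free alignments only, per scope).
    """

    name: str
    is_reverse: bool
    sequence: str
    qualities: str
    reference: str | None = None

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality strings differ in length")
        if self.reference is not None and len(self.reference) != len(self.sequence):
            raise ValueError("reference context must match read length")


def parse_misincorporation(text: str, dialect: str = "simple") -> MisincorporationProfile:
    """Parse a misincorporation table.

    ``simple`` dialect: whitespace-delimited columns position, 5' C>T rate,
    3' G>A rate.  ``mapdamage`` dialect: the tab-separated
    ``misincorporation.txt`` layout with a header containing Chr, End, Std,
    Pos and per-substitution count columns; rates are computed as
    C>T count / C count on 5' rows and G>A count / G count on 3' rows,
    aggregated over chromosomes and strands.  Zero denominators yield rate 0
    with a logged warning.
    """
    if dialect == "simple":
        rows = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(
                    f"line {lineno}: expected 3 columns (pos rate5 rate3)"
                )
            rows.append((int(fields[0]), float(fields[1]), float(fields[2])))
        if not rows:
            raise ValueError("empty misincorporation table")
        rows.sort()
        return MisincorporationProfile(
            tuple(r5 for _, r5, _ in rows), tuple(r3 for _, _, r3 in rows)
        )
    if dialect == "mapdamage":
        return _parse_mapdamage(text)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _parse_mapdamage(text: str) -> MisincorporationProfile:
    header = None
    counts: dict[str, dict[int, list[float]]] = {
        "5p": {}, "3p": {},
    }  # end -> pos -> [numerator, denominator]
    for raw in text.splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if header is None:
            header = {name: k for k, name in enumerate(fields)}
            for required in ("Chr", "End", "Std", "Pos"):
                if required not in header:
                    raise ValueError(
                        f"malformed mapDamage header: missing {required!r}"
                    )
            for required in ("C", "G", "C>T", "G>A"):
                if required not in header:
                    raise ValueError(
                        f"malformed mapDamage header: missing column {required!r}"
                    )
            continue
        end = fields[header["End"]]
        if end not in counts:
            continue
        pos = int(fields[header["Pos"]])
        num_col, den_col = (("C>T", "C") if end == "5p" else ("G>A", "G"))
        acc = counts[end].setdefault(pos, [0.0, 0.0])
        acc[0] += float(fields[header[num_col]])
        acc[1] += float(fields[header[den_col]])
    if header is None or (not counts["5p"] and not counts["3p"]):
        raise ValueError("empty misincorporation table")

    def rates(end: str) -> tuple[float, ...]:
        out = []
        for pos in sorted(counts[end]):
            num, den = counts[end][pos]
            if den == 0:
                logger.warning(
                    "zero denominator at %s position %d; rate set to 0", end, pos
                )
                out.append(0.0)
            else:
                out.append(num / den)
        return tuple(out)

    return MisincorporationProfile(rates("5p"), rates("3p"))


def mask_boundaries(
    profile: MisincorporationProfile, threshold: float = 0.01
) -> tuple[int, int]:
    """Window lengths (n5, n3) to mask at each read end.

    Scanning outward-in from each end, the window extends while the rate is
    at or above ``threshold`` and stops at the first sub-threshold position.
    """

    def scan(rates: tuple[float, ...]) -> int:
        n = 0
        for rate in rates:
            if rate < threshold:
                break
            n += 1
        return n

    return scan(profile.rates5), scan(profile.rates3)


def _mask_positions(read: ReadRecord, positions: list[int]) -> ReadRecord:
    if not positions:
        return read
    seq = list(read.sequence)
    qual = list(read.qualities)
    for k in positions:
        seq[k] = "N"
        qual[k] = MASKED_QUAL
    return replace(read, sequence="".join(seq), qualities="".join(qual))


def mask_read(
    read: ReadRecord, n5: int, n3: int, mode: str = "reference"
) -> ReadRecord:
    """Mask damage-susceptible positions inside the terminal windows.

    In fragment orientation, positions within the first ``n5`` bases whose
    reference base is C, and within the last ``n3`` bases whose reference
    base is G, are set to N with quality 0.  For reverse-strand reads the
    5' end is the right end of the stored sequence and the complement rule
    applies (reference G at the 5' window, C at the 3' window).

    ``mode="read"`` is a conservative reference-free variant that tests the
    read base instead: C or T at the 5' window, G or A at the 3' window (in
    fragment orientation).
    """
    length = len(read.sequence)
    if n5 > length or n3 > length:
        raise ValueError("mask window exceeds read length")
    if mode == "reference":
        if read.reference is None:
            raise ValueError("reference context required for reference mode")
        test5 = lambda k: read.reference[k].upper() == ("G" if read.is_reverse else "C")
        test3 = lambda k: read.reference[k].upper() == ("C" if read.is_reverse else "G")
    elif mode == "read":
        test5 = lambda k: read.sequence[k].upper() in (
            "GA" if read.is_reverse else "CT"
        )
        test3 = lambda k: read.sequence[k].upper() in (
            "CT" if read.is_reverse else "GA"
        )
    else:
        raise ValueError(f"unknown masking mode: {mode!r}")
    if read.is_reverse:
        window5 = range(length - n5, length)
        window3 = range(0, n3)
    else:
        window5 = range(0, n5)
        window3 = range(length - n3, length)
    positions = [k for k in window5 if test5(k)]
    positions += [k for k in window3 if k not in window5 and test3(k)]
    return _mask_positions(read, positions)


def trim_fixed(read: ReadRecord, left: int = 10, right: int = 10) -> ReadRecord:
    """Unconditionally mask the first ``left`` and last ``right`` bases in
    fragment orientation; overlapping windows mask the entire read."""
    if left < 0 or right < 0:
        raise ValueError("window lengths must be non-negative")
    length = len(read.sequence)
    if read.is_reverse:
        left, right = right, left  # stored sequence is reference-oriented
    if left + right >= length:
        positions = list(range(length))
    else:
        positions = list(range(left)) + list(range(length - right, length))
    return _mask_positions(read, positions)


# --------------------------------------------------------------------- SAM IO

def _record_from_alignment(aln: pysam.AlignedSegment) -> ReadRecord:
    try:
        ref = aln.get_reference_sequence().upper()
    except ValueError:
        ref = None
    if aln.query_qualities is not None:
        qual = pysam.qualities_to_qualitystring(aln.query_qualities)
    else:
        qual = "!" * len(aln.query_sequence)
    return ReadRecord(
        name=aln.query_name,
        is_reverse=aln.is_reverse,
        sequence=aln.query_sequence,
        qualities=qual,
        reference=ref,
    )


def _apply_to_alignment(aln: pysam.AlignedSegment, masked: ReadRecord) -> None:
    # setting query_sequence clears qualities, so restore them afterwards
    quals = pysam.qualitystring_to_array(masked.qualities)
    aln.query_sequence = masked.sequence
    aln.query_qualities = quals


def mask_sam(
    in_path,
    out_path,
    profile: MisincorporationProfile | None = None,
    threshold: float = 0.01,
    mode: str = "pmd",
    left: int = 10,
    right: int = 10,
    base_mode: str = "reference",
) -> int:
    """Mask a SAM file; returns the number of reads processed.

    ``mode="pmd"`` applies the profile-driven mask (``profile`` required,
    reference context taken from MD tags); ``mode="fixed"`` applies the
    trimBam-style fixed-window mask.  The header is preserved verbatim;
    unmapped reads pass through untouched.
    """
    if mode == "pmd":
        if profile is None:
            raise ValueError("pmd mode requires a misincorporation profile")
        n5, n3 = mask_boundaries(profile, threshold)
    elif mode != "fixed":
        raise ValueError(f"unknown masking mode: {mode!r}")
    n_reads = 0
    with pysam.AlignmentFile(str(in_path), "r", check_sq=False) as inp, \
            pysam.AlignmentFile(str(out_path), "w", template=inp) as out:
        for aln in inp:
            if not aln.is_unmapped and aln.query_sequence:
                record = _record_from_alignment(aln)
                if mode == "pmd":
                    eff5, eff3 = min(n5, len(record.sequence)), min(
                        n3, len(record.sequence)
                    )
                    masked = mask_read(record, eff5, eff3, mode=base_mode)
                else:
                    masked = trim_fixed(record, left, right)
                _apply_to_alignment(aln, masked)
                n_reads += 1
            out.write(aln)
    return n_reads
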