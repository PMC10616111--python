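"""ORF discovery and classification on transcripts.

Enumerates ATG-initiated, in-frame-stop-terminated open reading frames in all
three frames of a transcript, classifies them relative to an annotated CDS
(mORF / uORF / dORF on protein-coding transcripts, lncORF on lncRNAs), and
assigns each ORF its operational 3'UTR.  For noncanonical ORFs the 3'UTR runs
from the stop codon to the next ATG occurrence downstream in any frame (or to
the transcript end if none exists); for the annotated main ORF it is the
canonical region from the CDS end to the transcript end.

Coordinates are 0-based half-open in transcript space throughout.  An ORF
interval includes its stop codon; ``coding_nt = end - start - 3`` excludes it,
and the peptide length in amino acids is ``coding_nt / 3`` (the initiator Met
counts, the stop does not).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

VALID_CLASSES = ("mORF", "uORF", "dORF", "lncORF", "overlapping")


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence with biotype and optional CDS annotation.

    ``cds`` is a (start, end) interval, 0-based half-open, stop codon
    included; present iff ``biotype == "protein_coding"``.
    """

    id: str
    sequence: str
    biotype: str = "lncRNA"
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = re.search(r"[^ACGT]", self.sequence)
        if bad:
            raise ValueError(
                f"{self.id}: invalid character {self.sequence[bad.start()]!r} "
                f"at position {bad.start()}"
            )
        if self.biotype not in ("protein_coding", "lncRNA"):
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")
        if self.biotype == "protein_coding":
            if self.cds is None:
                raise ValueError(f"{self.id}: protein_coding transcript requires a cds")
            s, e = self.cds
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"{self.id}: cds {self.cds} outside sequence bounds")
            if (e - s) % 3 != 0:
                raise ValueError(f"{self.id}: cds length {e - s} not divisible by 3")
        elif self.cds is not None:
            raise ValueError(f"{self.id}: lncRNA transcript must not carry a cds")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfRecord:
    """One ORF: interval (stop codon included), class, and operational 3'UTR."""

    orf_id: str
    transcript_id: str
    start: int
    end: int
    orf_class: str = "lncORF"
    utr3: Optional[tuple[int, int]] = None
    flags: set = field(default_factory=set)

    @property
    def coding_nt(self) -> int:
        return self.end - self.start - 3

    @property
    def peptide_len_aa(self) -> int:
        return self.coding_nt // 3


def orf_id_for(transcript_id: str, start: int, end: int) -> str:
    return f"{transcript_id}:{start}-{end}"


def _iter_raw_orfs(seq: str) -> Iterator[tuple[int, int]]:
    """Yield (start, end) for every ATG..stop ORF, end including the stop."""
    n = len(seq)
    # per frame: sorted stop positions, then map each ATG to the next in-frame stop
    stops_by_frame: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops_by_frame[i % 3].append(i)
    import bisect

    for m in re.finditer("ATG", seq):
        i = m.start()
        stops = stops_by_frame[i % 3]
        j = bisect.bisect_left(stops, i + 3)
        if j < len(stops):
            yield i, stops[j] + 3


def find_orfs(
    transcript: Transcript,
    min_nt: int = 9,
    max_nt: Optional[int] = None,
    collapse_nested: bool = True,
) -> list[OrfRecord]:
    """Enumerate ATG-initiated ORFs with ``min_nt <= coding_nt <= max_nt``.

    Nested ORFs sharing a stop codon are collapsed to the longest (5'-most
    ATG) unless ``collapse_nested`` is False.  Records are ordered by start
    position, then length descending.  Classification and 3'UTR assignment
    are left to :func:`classify_orf` / :func:`assign_utr3`.
    """
    if min_nt < 3 or min_nt % 3:
        raise ValueError(f"min_nt must be a positive multiple of 3, got {min_nt}")
    if max_nt is not None and max_nt < min_nt:
        raise ValueError(f"max_nt ({max_nt}) < min_nt ({min_nt})")
    raw = list(_iter_raw_orfs(transcript.sequence))
    if collapse_nested:
        by_stop: dict[int, int] = {}
        for s, e in raw:
            if e not in by_stop or s < by_stop[e]:
                by_stop[e] = s
        raw = [(s, e) for e, s in by_stop.items()]
    out = []
    for s, e in raw:
        coding = e - s - 3
        if coding < min_nt or (max_nt is not None and coding > max_nt):
            continue
        out.append(
            OrfRecord(orf_id_for(transcript.id, s, e), transcript.id, s, e)
        )
    out.sort(key=lambda o: (o.start, -(o.end - o.start)))
    return out


def classify_orf(orf: OrfRecord, transcript: Transcript) -> str:
    """Class of an ORF relative to the transcript's annotation.

    lncRNA transcripts host lncORFs; on coding transcripts an ORF equal to
    the CDS is the mORF, one ending at or before the CDS start a uORF, one
    starting at or after the CDS end a dORF, and anything else overlapping —
    catalogued but excluded from the screen.
    """
    if transcript.biotype == "lncRNA":
        return "lncORF"
    cs, ce = transcript.cds  # type: ignore[misc]
    if (orf.start, orf.end) == (cs, ce):
        return "mORF"
    if orf.end <= cs:
        return "uORF"
    if orf.start >= ce:
        return "dORF"
    return "overlapping"


def assign_utr3(orf: OrfRecord, transcript: Transcript) -> Optional[tuple[int, int]]:
    """Operational 3'UTR of an ORF.

    mORF: CDS end to transcript end.  Noncanonical ORF: stop codon to the
    next ATG at any downstream position in any frame, falling back to the
    transcript end when no downstream ATG exists.  A zero-length interval is
    returned as None with flag ``no_utr3`` set on the record.
    """
    n = len(transcript)
    if orf.orf_class == "mORF":
        lo, hi = orf.end, n
    else:
        nxt = transcript.sequence.find("ATG", orf.end)
        hi = nxt if nxt != -1 else n
        lo = orf.end
    if hi <= lo:
        orf.flags.add("no_utr3")
        return None
    return (lo, hi)


def catalog_transcript(
    transcript: Transcript,
    min_nt: int = 9,
    max_nt: Optional[int] = None,
    collapse_nested: bool = True,
) -> list[OrfRecord]:
    """find_orfs + classification + 3'UTR assignment in one pass."""
    orfs = find_orfs(transcript, min_nt=min_nt, max_nt=max_nt, collapse_nested=collapse_nested)
    # the annotated CDS is always catalogued as the mORF even if it falls
    # outside the [min_nt, max_nt] window used for noncanonical ORFs
    if transcript.biotype == "protein_coding":
        cs, ce = transcript.cds  # type: ignore[misc]
        if not any((o.start, o.end) == (cs, ce) for o in orfs):
            orfs.append(OrfRecord(orf_id_for(transcript.id, cs, ce), transcript.id, cs, ce))
            orfs.sort(key=lambda o: (o.start, -(o.end - o.start)))
    for o in orfs:
        o.orf_class = classify_orf(o, transcript)
        o.utr3 = assign_utr3(o, transcript)
    return orfs


@dataclass
class LongestPeptide:
    length_aa: int
    orf: Optional[OrfRecord]
    flag: Optional[str] = None


def longest_peptide(transcript: Transcript) -> LongestPeptide:
    """Longest ORF-encoded peptide on a transcript (ties: 5'-most start).

    Returns length 0 with flag ``no_orf`` when the transcript has no
    ATG-initiated ORF.
    """
    orfs = find_orfs(transcript, min_nt=3, max_nt=None)
    if not orfs:
        return LongestPeptide(0, None, "no_orf")
    best = max(orfs, key=lambda o: (o.coding_nt, -o.start))
    return LongestPeptide(best.peptide_len_aa, best)
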