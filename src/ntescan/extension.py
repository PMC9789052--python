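"""Theoretical N-terminal extensions: extraction, windows, filters, candidate starts.

The primary (theoretical) extension of a transcript is the maximal in-frame
region upstream of the annotated AUG, bounded by the first in-frame stop codon
(stop_bounded) or by the 5'-most complete in-frame codon of the transcript
(edge_bounded). Analysis windows are clipped to at most 50 codons abutting the
annotated start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .transcript_io import (
    ExonMap,
    GenomicInterval,
    START_CODONS,
    STOP_CODONS,
    TranscriptRecord,
    intersect_intervals,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_CODONS = 50
DEFAULT_MIN_CODONS = 20


@dataclass
class TheoreticalExtension:
    transcript_id: str
    ext_start: int
    length_codons: int
    boundary: str  # "stop_bounded" | "edge_bounded"
    genomic_blocks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.boundary not in ("stop_bounded", "edge_bounded"):
            raise ValueError(f"bad boundary {self.boundary!r}")
        if self.length_codons <= 0:
            raise ValueError("extension must be at least one codon")


@dataclass
class ExtensionWindow:
    transcript_id: str
    win_start: int
    win_codons: int
    sequence: str
    genomic_blocks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != 3 * self.win_codons:
            raise ValueError("window sequence length != 3 * win_codons")


@dataclass(frozen=True)
class CandidateStart:
    transcript_id: str
    position: int
    codon: str

    @property
    def codon_class(self) -> str:
        return "AUG" if self.codon == "ATG" else "near_cognate"


def extract_theoretical_extension(rec: TranscriptRecord, require_atg: bool = True):
    """Walk upstream from the annotated start in steps of three.

    Returns (extension, reason): the extension is None with a reason code when
    the record fails the complete-CDS/AUG gates, when there is no room upstream,
    or when the codon immediately upstream of the start is a stop ("zero_length").
    The extension never contains an in-frame stop codon.
    """
    if not rec.is_complete_cds():
        return None, "incomplete_cds"
    if require_atg and not rec.has_atg_start():
        return None, "non_atg_annotated"
    cds_start = rec.cds_start
    if cds_start < 3:
        return None, "zero_length"
    seq = rec.sequence
    pos = cds_start - 3
    boundary = "edge_bounded"
    while pos >= 0:
        if seq[pos : pos + 3] in STOP_CODONS:
            boundary = "stop_bounded"
            pos += 3
            break
        pos -= 3
    else:
        pos += 3  # 5'-most complete in-frame codon; any <3nt leftover is dropped
    if pos == cds_start:
        return None, "zero_length"
    ext = TheoreticalExtension(
        rec.transcript_id,
        ext_start=pos,
        length_codons=(cds_start - pos) // 3,
        boundary=boundary,
    )
    if rec.exons and "exon_mismatch" not in rec.flags:
        emap = ExonMap(rec.transcript_id, rec.exons)
        ext.genomic_blocks = emap.to_genome(ext.ext_start, cds_start)
    return ext, None


def clip_window(ext: TheoreticalExtension, rec: TranscriptRecord,
                max_codons: int = DEFAULT_WINDOW_CODONS) -> ExtensionWindow:
    """The up-to-``max_codons`` codons of the extension abutting the annotated start."""
    win_codons = min(max_codons, ext.length_codons)
    win_start = rec.cds_start - 3 * win_codons
    win = ExtensionWindow(
        ext.transcript_id,
        win_start=win_start,
        win_codons=win_codons,
        sequence=rec.sequence[win_start : rec.cds_start],
    )
    if rec.exons and "exon_mismatch" not in rec.flags:
        emap = ExonMap(rec.transcript_id, rec.exons)
        win.genomic_blocks = emap.to_genome(win_start, rec.cds_start)
    return win


def filter_min_length(ext: TheoreticalExtension, min_codons: int = DEFAULT_MIN_CODONS) -> bool:
    """Keep iff the theoretical extension is at least ``min_codons`` long."""
    keep = ext.length_codons >= min_codons
    logger.debug("%s length %d -> %s", ext.transcript_id, ext.length_codons,
                 "keep" if keep else "drop")
    return keep


def filter_coding_overlap(win: ExtensionWindow, coding_exons, own_transcript_id=None,
                          same_strand: bool = True):
    """Drop a window that overlaps any foreign coding exon by >= 1 base.

    ``coding_exons`` is a list of (catalog, transcript_id, GenomicInterval).
    The window transcript's own CDS exons are exempt. Returns
    (keep, offending) where offending is the first (catalog, interval) hit.
    """
    if not win.genomic_blocks:
        raise ValueError("no_structure: window lacks genomic blocks")
    own = own_transcript_id if own_transcript_id is not None else win.transcript_id
    foreign = [(cat, tid, iv) for cat, tid, iv in coding_exons if tid != own]
    subject = [iv for _, _, iv in foreign]
    hits = intersect_intervals(win.genomic_blocks, subject, same_strand=same_strand)
    if hits:
        _, j, _ = hits[0]
        return False, (foreign[j][0], foreign[j][2])
    return True, None


def enumerate_candidate_starts(win: ExtensionWindow, allowed=START_CODONS):
    """Every in-frame occurrence of an allowed start codon in the window, 5'->3'."""
    allowed = set(allowed)
    out = []
    for i in range(0, 3 * win.win_codons, 3):
        codon = win.sequence[i : i + 3]
        if codon in allowed:
            out.append(CandidateStart(win.transcript_id, win.win_start + i, codon))
    return out


def collapse_by_gene(extensions: dict[str, TheoreticalExtension],
                     records: dict[str, TranscriptRecord]) -> dict[str, str]:
    """One representative transcript per gene: the longest theoretical extension,
    ties broken by lexicographically smallest transcript_id.

    Returns gene_id -> transcript_id. Two representatives never share identical
    genomic blocks (duplicates collapse to the first by transcript id).
    """
    best: dict[str, str] = {}
    for tid, ext in sorted(extensions.items()):
        gene = records[tid].gene_id
        if gene not in best:
            best[gene] = tid
        else:
            cur = extensions[best[gene]]
            if ext.length_codons > cur.length_codons:
                best[gene] = tid
    # de-duplicate identical genomic footprints across genes (paranoid guard)
    seen_blocks = set()
    out = {}
    for gene, tid in sorted(best.items()):
        key = tuple(extensions[tid].genomic_blocks) or tid
        if key in seen_blocks:
            continue
        seen_blocks.add(key)
        out[gene] = tid
    return out
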