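"""Transcript models, annotation parsing, and transcript<->genome coordinate mapping.

All internal coordinates are 0-based half-open. External dialects (GTF and
GENCODE-style FASTA headers are 1-based inclusive, VCF is 1-based) are converted
at the I/O boundary only, so no off-by-one conversions leak into analysis code.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: AUG plus the nine near-cognate codons (one mismatch from AUG), DNA spelling.
START_CODONS = ("ATG", "CTG", "GTG", "TTG", "ATA", "ATT", "ATC", "ACG", "AGG", "AAG")
NEAR_COGNATE_CODONS = START_CODONS[1:]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TranscriptRecord:
    """A spliced transcript with its CDS span and (optionally) its exon structure.

    ``exons`` are ordered 5'->3' along the transcript: on the minus strand the
    first exon is the one with the highest genomic coordinates.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    exons: list[GenomicInterval] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not 0 <= self.cds_start < self.cds_end <= len(self.sequence):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length not a multiple of 3")
        if self.exons:
            if sum(len(e) for e in self.exons) != len(self.sequence):
                raise ValueError(f"{self.transcript_id}: exon lengths != sequence length")
            chroms = {e.chrom for e in self.exons}
            strands = {e.strand for e in self.exons}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")

    @property
    def strand(self) -> str | None:
        return self.exons[0].strand if self.exons else None

    @property
    def chrom(self) -> str | None:
        return self.exons[0].chrom if self.exons else None

    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    def has_atg_start(self) -> bool:
        return self.sequence[self.cds_start : self.cds_start + 3] == "ATG"

    def is_complete_cds(self) -> bool:
        """CDS length divisible by 3 (guaranteed) and no truncation tags."""
        return not ({"cds_start_NF", "cds_end_NF"} & self.flags)


class ExonMap:
    """Bidirectional transcript<->genome position lookup for one transcript."""

    def __init__(self, transcript_id: str, exons: list[GenomicInterval]):
        if not exons:
            raise ValueError("exon list is empty")
        self.transcript_id = transcript_id
        self.exons = list(exons)
        self.strand = exons[0].strand
        self.chrom = exons[0].chrom
        self.offsets = []  # cumulative transcript offset at the start of each exon
        total = 0
        for e in self.exons:
            self.offsets.append(total)
            total += len(e)
        self.length = total

    def to_genome(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Project a transcript interval to an ordered list of genomic blocks.

        Blocks are returned in transcript 5'->3' order, split at exon junctions;
        their lengths sum to ``t_end - t_start``.
        """
        if not 0 <= t_start < t_end <= self.length:
            raise ValueError(f"range: ({t_start},{t_end}) outside [0,{self.length})")
        blocks = []
        for exon, off in zip(self.exons, self.offsets):
            lo = max(t_start, off)
            hi = min(t_end, off + len(exon))
            if lo >= hi:
                continue
            a, b = lo - off, hi - off  # offsets within this exon
            if exon.strand == "+":
                blocks.append(GenomicInterval(exon.chrom, exon.start + a, exon.start + b, "+"))
            else:
                blocks.append(GenomicInterval(exon.chrom, exon.end - b, exon.end - a, "-"))
        assert sum(len(b) for b in blocks) == t_end - t_start
        return blocks

    def to_transcript(self, gpos: int) -> int | None:
        """Transcript position of a genomic base, or None if intronic/outside."""
        for exon, off in zip(self.exons, self.offsets):
            if exon.start <= gpos < exon.end:
                if exon.strand == "+":
                    return off + (gpos - exon.start)
                return off + (exon.end - 1 - gpos)
        return None

    def genome_positions(self, t_start: int, t_end: int) -> list[int]:
        """Per-base genomic positions in transcript order (minus strand descends)."""
        out = []
        for blk in self.to_genome(t_start, t_end):
            rng = range(blk.start, blk.end) if blk.strand == "+" else range(blk.end - 1, blk.start - 1, -1)
            out.extend(rng)
        return out


# ---------------------------------------------------------------------------
# FASTA parsing (gencode_pc header dialect and plain FASTA + sidecar TSV)
# ---------------------------------------------------------------------------

def _parse_gencode_header(description: str):
    """Pull transcript_id, gene_id, CDS:u-v and tags out of a pipe-separated header."""
    fields = description.split("|")
    transcript_id = fields[0].split()[0]
    gene_id = fields[1] if len(fields) > 1 and fields[1] else transcript_id
    cds = None
    tags = set()
    for f in fields[2:]:
        if f.startswith("CDS:"):
            try:
                u, v = f[4:].split("-")
                cds = (int(u), int(v))
            except ValueError:
                cds = None
        elif f in ("cds_start_NF", "cds_end_NF"):
            tags.add(f)
    return transcript_id, gene_id, cds, tags


def parse_transcript_fasta(fasta_path, dialect: str = "gencode_pc", sidecar_path=None):
    """Parse a transcript FASTA into TranscriptRecords.

    dialect "gencode_pc": pipe-separated headers carrying a ``CDS:u-v`` field
    with u, v 1-based inclusive. dialect "plain+sidecar": plain headers plus a
    TSV sidecar with columns transcript_id, gene_id, cds_start, cds_end already
    in 0-based half-open coordinates.

    Returns (records, skipped) where skipped is a list of (id, reason) pairs.
    Records whose annotated CDS does not begin with ATG are retained but
    flagged ``non_atg_annotated``; truncation tags become flags as well.
    """
    records, skipped = [], []
    sidecar = {}
    if dialect == "plain+sidecar":
        if sidecar_path is None:
            raise ValueError("plain+sidecar dialect requires sidecar_path")
        with open(sidecar_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                tid, gid, cs, ce = line.rstrip("\n").split("\t")[:4]
                sidecar[tid] = (gid, int(cs), int(ce))

    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(entry.seq).upper()
        if dialect == "gencode_pc":
            tid, gid, cds, tags = _parse_gencode_header(entry.description)
            if cds is None:
                skipped.append((tid, "no_cds"))
                continue
            cds_start, cds_end = cds[0] - 1, cds[1]  # 1-based inclusive -> 0-based half-open
        else:
            tid = entry.id
            if tid not in sidecar:
                skipped.append((tid, "no_cds"))
                continue
            gid, cds_start, cds_end = sidecar[tid]
            tags = set()
        if not 0 <= cds_start < cds_end <= len(seq):
            skipped.append((tid, "cds_out_of_range"))
            continue
        if (cds_end - cds_start) % 3 != 0:
            skipped.append((tid, "cds_not_triplet"))
            continue
        rec = TranscriptRecord(tid, gid, seq, cds_start, cds_end, flags=tags)
        if not rec.has_atg_start():
            rec.flags.add("non_atg_annotated")
        records.append(rec)
    for tid, reason in skipped:
        logger.info("skipped %s: %s", tid, reason)
    return records, skipped


def attach_exons(records: list[TranscriptRecord], gtf_path) -> list[TranscriptRecord]:
    """Populate exon lists from GTF exon features (1-based inclusive on disk).

    Exons are ordered 5'->3' along the transcript. Records whose exon-length sum
    disagrees with the sequence length get the ``exon_mismatch`` flag and keep
    empty exon lists (transcript-only analyses still work); transcripts missing
    from the GTF are flagged ``no_structure``.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_tx: dict[str, list] = defaultdict(list)
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        by_tx[tid].append(f)
    out = []
    for rec in records:
        feats = by_tx.get(rec.transcript_id)
        if not feats:
            rec.flags.add("no_structure")
            out.append(rec)
            continue
        strand = feats[0].strand
        feats.sort(key=lambda f: f.start, reverse=(strand == "-"))
        exons = [GenomicInterval(f.seqid, f.start - 1, f.end, f.strand) for f in feats]
        if sum(len(e) for e in exons) != len(rec.sequence):
            rec.flags.add("exon_mismatch")
            out.append(rec)
            continue
        out.append(replace(rec, exons=exons, flags=set(rec.flags)))
    return out


def coding_exons_from_records(records, catalog: str = "self"):
    """CDS genomic blocks per transcript, tagged with a catalog name.

    Returns a list of (catalog, transcript_id, GenomicInterval).
    """
    out = []
    for rec in records:
        if not rec.exons or "exon_mismatch" in rec.flags:
            continue
        emap = ExonMap(rec.transcript_id, rec.exons)
        for blk in emap.to_genome(rec.cds_start, rec.cds_end):
            out.append((catalog, rec.transcript_id, blk))
    return out


# ---------------------------------------------------------------------------
# Interval intersection
# ---------------------------------------------------------------------------

def intersect_intervals(query, subject, same_strand: bool = False):
    """All (query index, subject index, overlap length) pairs with overlap >= 1.

    With ``same_strand`` set, pairs on opposite strands are not reported.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, s in enumerate(subject):
        trees[s.chrom].addi(s.start, s.end, j)
    hits = []
    for i, q in enumerate(query):
        for iv in trees[q.chrom].overlap(q.start, q.end):
            j = iv.data
            s = subject[j]
            if same_strand and s.strand != q.strand:
                continue
            hits.append((i, j, q.overlap(s)))
    hits.sort()
    return hits


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def write_bed6(intervals, path, names=None, scores=None):
    """Write intervals as BED6 (0-based half-open, so no conversion needed)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            score = scores[i] if scores else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
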