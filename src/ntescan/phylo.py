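"""Codon-alignment window extraction from MAF and coding-evolution scoring.

The built-in scorer is a deliberately simple stand-in for full phylogenetic
coding-potential methods: it compares each species codon to the reference
pairwise over a star topology and scores substitutions by a synonymous/
nonsynonymous log-likelihood ratio between a purifying (omega < 1) and a
neutral (omega = 1) regime, with Nei-Gojobori path counting for multi-position
differences. External per-codon score tracks (e.g. from PhyloCSF) can be read
in instead; the pipeline is scorer-pluggable and every track carries a
scorer_id.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import AlignIO
from Bio.Seq import Seq

from .transcript_io import GenomicInterval, STOP_CODONS, revcomp

logger = logging.getLogger(__name__)

MISSING = "..."     # species not covered by any MAF block at this codon
BASES = "ACGT"


@dataclass
class CodonAlignmentWindow:
    transcript_id: str
    species: list[str]                   # reference assembly first
    codon_columns: list[list[str]]       # [codon index][species index] -> 3-mer/marker

    @property
    def n_codons(self) -> int:
        return len(self.codon_columns)

    def reference_codons(self) -> list[str]:
        return [col[0] for col in self.codon_columns]


@dataclass
class CodingScoreTrack:
    transcript_id: str
    per_codon: list[float]
    scorer_id: str
    flags: set[str] = field(default_factory=set)

    @property
    def total(self) -> float:
        return float(sum(self.per_codon))


@dataclass
class ScorerConfig:
    omega_coding: float = 0.1
    stop_penalty: float = -10.0
    min_species: int = 3

    def __post_init__(self):
        if not 0 < self.omega_coding < 1:
            raise ValueError("omega_coding must be in (0, 1)")


# ---------------------------------------------------------------------------
# MAF window extraction
# ---------------------------------------------------------------------------

class MafIndex:
    """Reference-anchored MAF blocks with per-column genomic positions."""

    def __init__(self, maf_path, ref_assembly: str):
        self.ref_assembly = ref_assembly
        self.blocks = []   # (chrom, gpos->column dict, {species: aligned row}, ref row)
        for msa in AlignIO.parse(str(maf_path), "maf"):
            ref = None
            rows = {}
            for rec in msa:
                assembly, _, chrom = rec.id.partition(".")
                if assembly == ref_assembly and ref is None:
                    ref = (chrom, rec)
                rows[assembly] = str(rec.seq).upper()
            if ref is None:
                continue
            chrom, rec = ref
            if rec.annotations.get("strand", 1) != 1:
                raise ValueError("reference MAF rows must be on the + strand")
            start = rec.annotations["start"]
            colmap = {}
            g = start
            for col, base in enumerate(str(rec.seq).upper()):
                if base != "-":
                    colmap[g] = col
                    g += 1
            self.blocks.append((chrom, colmap, rows))

    def column(self, chrom: str, gpos: int):
        """(block rows, column index) covering a reference base, or None."""
        for bchrom, colmap, rows in self.blocks:
            if bchrom == chrom and gpos in colmap:
                return rows, colmap[gpos]
        return None


def extract_alignment_window(maf_path, blocks: list[GenomicInterval],
                             ref_assembly: str, transcript_id: str = "",
                             window_sequence: str | None = None,
                             species_order: list[str] | None = None) -> CodonAlignmentWindow:
    """Pull the spliced codon alignment for a window's genomic blocks.

    Columns for each reference base are taken from the covering MAF block
    (reference-insertion columns in other species are dropped by construction,
    since columns are addressed by reference base), stitched across exon blocks
    in transcript order, complemented on the minus strand, and grouped into
    codons in the window's frame. Species absent from a covering block — or
    bases covered by no block — get the missing marker.
    """
    index = maf_path if isinstance(maf_path, MafIndex) else MafIndex(maf_path, ref_assembly)
    species = [ref_assembly] + [s for s in (species_order or []) if s != ref_assembly]
    per_base: list[dict[str, str]] = []   # transcript-order base columns
    comp = str.maketrans("ACGTN", "TGCAN")
    for blk in blocks:
        positions = (range(blk.start, blk.end) if blk.strand == "+"
                     else range(blk.end - 1, blk.start - 1, -1))
        for g in positions:
            hit = index.column(blk.chrom, g)
            col: dict[str, str] = {}
            if hit is not None:
                rows, ci = hit
                for assembly, row in rows.items():
                    base = row[ci]
                    if blk.strand == "-":
                        base = base.translate(comp)
                    col[assembly] = base
                    if assembly not in species:
                        species.append(assembly)
            per_base.append(col)
    total = len(per_base)
    if total % 3 != 0:
        raise ValueError("window length is not a multiple of 3")
    # bases covered by no block: reference comes from the window sequence,
    # every other species gets the missing marker there
    wseq = window_sequence.upper() if window_sequence is not None else None
    for k, col in enumerate(per_base):
        if ref_assembly not in col:
            if wseq is None:
                raise ValueError("ref_mismatch: uncovered reference base and "
                                 "no window sequence supplied")
            col[ref_assembly] = wseq[k]
    ref_bases = "".join(col[ref_assembly] for col in per_base)
    if wseq is not None and ref_bases != wseq:
        raise ValueError("ref_mismatch: MAF reference disagrees with window sequence")
    codon_columns = []
    for c in range(0, total, 3):
        cols = per_base[c : c + 3]
        col_out = []
        for sp in species:
            triplet = [cols[k].get(sp) for k in range(3)]
            if any(b is None for b in triplet):
                col_out.append(MISSING)
            else:
                col_out.append("".join(triplet))
        codon_columns.append(col_out)
    return CodonAlignmentWindow(transcript_id, species, codon_columns)


# ---------------------------------------------------------------------------
# Built-in substitution-type scorer
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def synonymous_fraction(codon: str) -> float:
    """Fraction of the 9 single-nucleotide neighbours that are synonymous.

    Neighbours that are stop codons are counted as nonsynonymous.
    """
    syn = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            q = codon[:i] + b + codon[i + 1 :]
            if q not in STOP_CODONS and _translate(q) == _translate(codon):
                syn += 1
    return syn / 9.0


@lru_cache(maxsize=None)
def path_step_counts(ref: str, alt: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) single-nucleotide step counts
    between two codons, averaged over mutation orderings (Nei-Gojobori style).

    Orderings passing through a stop-codon intermediate are excluded; if all
    orderings are blocked, all are used as a fallback.
    """
    diff = [i for i in range(3) if ref[i] != alt[i]]
    paths = []
    for strict in (True, False):
        for order in itertools.permutations(diff):
            cur = ref
            steps = []
            blocked = False
            for i in order:
                nxt = cur[:i] + alt[i] + cur[i + 1 :]
                if strict and nxt in STOP_CODONS and nxt != alt:
                    blocked = True
                    break
                steps.append(_translate(nxt) == _translate(cur))
                cur = nxt
            if not blocked:
                paths.append(steps)
        if paths:
            break
    s = sum(sum(p) for p in paths) / len(paths)
    return s, len(diff) - s


@lru_cache(maxsize=None)
def pair_score(ref: str, alt: str, omega: float, stop_penalty: float) -> float:
    """Log-likelihood-ratio contribution of one species codon vs the reference.

    Under the neutral model a single-nucleotide step from the reference codon is
    synonymous with probability f_s (the synonymous neighbour fraction); under
    the coding model nonsynonymous steps are down-weighted by omega, so
    P_coding(syn) = f_s / (f_s + omega*(1 - f_s)). Each expected step
    contributes log(P_coding / P_neutral); identical codons contribute 0 and a
    species codon that is an in-frame stop contributes the stop penalty.
    """
    if alt == ref:
        return 0.0
    if alt in STOP_CODONS:
        return stop_penalty
    if any(b not in BASES for b in alt) or any(b not in BASES for b in ref):
        return 0.0   # gap / ambiguity: absence is not evidence
    import math
    fs = synonymous_fraction(ref)
    denom = fs + omega * (1.0 - fs)
    s, n = path_step_counts(ref, alt)
    score = 0.0
    if s > 0 and fs > 0:
        score += s * math.log((fs / denom) / fs)
    if n > 0 and fs < 1:
        score += n * math.log((omega * (1.0 - fs) / denom) / (1.0 - fs))
    return score


def builtin_coding_score(win: CodonAlignmentWindow,
                         cfg: ScorerConfig | None = None) -> CodingScoreTrack:
    """Per-codon coding-evolution scores for a window under the built-in scorer.

    Species with gap or missing codons at a column are skipped there. Windows
    with fewer than ``min_species`` species present anywhere are flagged
    ``low_species`` (their total should not be used for classification).
    """
    cfg = cfg or ScorerConfig()
    per_codon = []
    present: set[str] = set()
    for col in win.codon_columns:
        ref = col[0]
        score = 0.0
        for sp, codon in zip(win.species[1:], col[1:]):
            if codon == MISSING or "-" in codon:
                continue
            present.add(sp)
            score += pair_score(ref, codon, cfg.omega_coding, cfg.stop_penalty)
        per_codon.append(score)
    track = CodingScoreTrack(win.transcript_id, per_codon, scorer_id="builtin_subst_v1")
    if len(present) + 1 < cfg.min_species:
        track.flags.add("low_species")
    return track


def classify_positive(track: CodingScoreTrack) -> bool:
    """Strictly-positive total => member of the conserved class."""
    return track.total > 0


# ---------------------------------------------------------------------------
# Score-track serialisation (external scorer interchange format)
# ---------------------------------------------------------------------------

def write_score_tracks(tracks: list[CodingScoreTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tcodon_index\tscore\n")
        for t in tracks:
            for i, s in enumerate(t.per_codon):
                fh.write(f"{t.transcript_id}\t{i}\t{s:.10g}\n")
            fh.write(f"{t.transcript_id}\ttotal\t{t.total:.10g}\n")


def read_external_scores(path, scorer_id: str = "external") -> list[CodingScoreTrack]:
    """Read per-codon score tracks; totals are cross-checked against the sums.

    A total line disagreeing with the per-codon sum by more than 1e-6 is logged
    and the per-codon sum wins.
    """
    per: dict[str, dict[int, float]] = {}
    totals: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("transcript_id"):
            raise ValueError("malformed score-track file: missing header")
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed score-track line {ln}")
            tid, idx, score = parts
            if idx == "total":
                totals[tid] = float(score)
            else:
                per.setdefault(tid, {})[int(idx)] = float(score)
    tracks = []
    for tid in sorted(per):
        scores = per[tid]
        track = CodingScoreTrack(tid, [scores[i] for i in range(len(scores))], scorer_id)
        if tid in totals and abs(totals[tid] - track.total) > 1e-6:
            logger.warning("%s: total line %.6g disagrees with per-codon sum %.6g; "
                           "sum wins", tid, totals[tid], track.total)
        tracks.append(track)
    return tracks
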