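"""Synthetic inputs with recorded ground truth.

Generates every file the pipeline consumes — transcript FASTA (pipe-separated
headers with a CDS:u-v field), GTF exon/CDS structures, P-site profile TSVs
(elongating + initiating channels), a reference-anchored MAF evolved under
coding or neutral regimes, a toy TIS-efficiency table and a variant file —
deterministically from (seed, config), together with a GroundTruth object
recording what was planted where.

The read model is intentionally minimal and matches the detector's
assumptions: counts are drawn per codon and split across the three frames
with frame-0 probability ``p_frame`` in translated regions and uniformly
elsewhere, which makes detection power analytically checkable. The alignment
simulator uses a star tree (independent branches from the reference); it
exercises the pairwise-to-reference scorer and is not a phylogeny emulator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .extension import extract_theoretical_extension
from .transcript_io import ExonMap, GenomicInterval, STOP_CODONS, TranscriptRecord, revcomp

BASES = "ACGT"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
NONSTOP_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

CHROM = "chrS1"
CHROM_SIZE = 50_000_000
REF_ASSEMBLY = "refsim"

VARIANT_CLASSES = ("Pathogenic", "Likely_pathogenic",
                   "Conflicting_interpretations_of_pathogenicity", "Benign")


@dataclass
class SimConfig:
    seed: int = 1
    n_genes: int = 500
    fraction_true_nte: float = 0.1
    # start codon palette for planted non-AUG starts (DNA spelling); the most
    # frequent near-cognate starts are CTG, then GTG and ACG
    start_codon_palette: dict = field(default_factory=lambda: {
        "CTG": 0.35, "GTG": 0.20, "ACG": 0.15, "TTG": 0.10, "ATT": 0.06,
        "ATA": 0.05, "ATC": 0.04, "AAG": 0.025, "AGG": 0.025,
    })
    ext_codons_range: tuple = (20, 120)
    cds_codons_range: tuple = (100, 300)
    utr3_range: tuple = (20, 100)
    frac_edge_bounded: float = 0.15
    frac_spliced: float = 0.3
    strong_context_prob: float = 0.8
    # profile parameters
    depth: float = 10.0              # reads per codon in translated regions
    p_frame: float = 0.8             # frame-0 probability in translated regions
    step_multiplier: float = 5.0     # translated/background density ratio
    init_peak: int = 20              # initiating reads planted at true starts
    noise_rate: float = 0.0          # extra uniform per-nt Poisson noise
    ext_background: bool = True      # background reads over untranslated extensions
    noise_only: bool = False         # calibration mode: equal frames everywhere
    # alignment parameters
    n_species: int = 10
    subs_per_codon: float = 0.3      # expected mutation events per codon per branch
    omega_coding: float = 0.1
    omega_neutral: float = 1.0
    fraction_coding: float = 0.5
    split_maf_blocks: bool = False
    # decoy counts (within n_genes)
    n_overlap_decoys: int = 10
    n_short_ext: int = 10
    n_zero_cov: int = 10
    n_untransl_rule5: int = 3
    n_untransl_rule6: int = 3
    n_untransl_rule7: int = 3
    n_untransl_boundary: int = 2
    # variants
    n_var_inside: int = 30
    n_var_outside: int = 30

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(blob.encode()).hexdigest()[:12]


@dataclass
class GeneTruth:
    gene_id: str
    transcript_id: str
    klass: str                      # true_nte | background | overlap_victim | ...
    strand: str
    spliced: bool
    cds_start: int
    cds_end: int
    ext_start: int
    ext_len_codons: int
    boundary: str
    is_true_nte: bool = False
    true_start: int | None = None   # transcript position of the planted start
    true_codon: str | None = None
    untransl_expected: str | None = None   # "pass", a rule name, or None
    regime: str | None = None              # coding | neutral (set by gen_alignments)
    species_codons: dict | None = None     # species -> codon list, transcript order
    expected_variant_hits: list = field(default_factory=list)


@dataclass
class GroundTruth:
    config: SimConfig
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    profile_totals: dict[str, dict[str, int]] = field(default_factory=dict)

    def of_transcript(self, tid: str) -> GeneTruth | None:
        for g in self.genes.values():
            if g.transcript_id == tid:
                return g
        return None


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stream])


def _random_nonstop_codons(rng, n) -> list[str]:
    return [NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), size=n)]


def _random_seq(rng, n) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def _assign_classes(cfg: SimConfig) -> list[str]:
    n_true = round(cfg.fraction_true_nte * cfg.n_genes)
    classes = (["true_nte"] * n_true
               + ["overlap_victim", "overlap_source"] * cfg.n_overlap_decoys
               + ["short_ext"] * cfg.n_short_ext
               + ["zero_cov"] * cfg.n_zero_cov
               + ["untransl_rule5"] * cfg.n_untransl_rule5
               + ["untransl_rule6"] * cfg.n_untransl_rule6
               + ["untransl_rule7"] * cfg.n_untransl_rule7
               + ["untransl_boundary_pass", "untransl_boundary_fail"]
               * (cfg.n_untransl_boundary // 2))
    if len(classes) > cfg.n_genes:
        raise ValueError("decoy counts exceed n_genes")
    classes += ["background"] * (cfg.n_genes - len(classes))
    return classes


def _build_gene(rng, cfg: SimConfig, klass: str):
    """Compose one transcript; returns (sequence, layout dict)."""
    deterministic = klass.startswith("untransl_")
    if klass == "short_ext":
        ext_len = int(rng.integers(5, 20))
    else:
        ext_len = int(rng.integers(cfg.ext_codons_range[0], cfg.ext_codons_range[1] + 1))
    if klass.startswith("untransl_boundary"):
        cds_len = 100
    else:
        cds_len = int(rng.integers(cfg.cds_codons_range[0], cfg.cds_codons_range[1] + 1))
    edge_bounded = (not deterministic) and rng.random() < cfg.frac_edge_bounded
    pad = int(rng.integers(0, 3)) if edge_bounded else int(rng.integers(0, 6))

    ext_codons = _random_nonstop_codons(rng, ext_len)
    true_start_idx = None
    true_codon = None
    if klass == "true_nte":
        lo = max(1, ext_len - 48)
        hi = ext_len - 10
        true_start_idx = int(rng.integers(lo, hi + 1))
        palette = sorted(cfg.start_codon_palette.items())
        codons, weights = zip(*palette)
        w = np.array(weights) / sum(weights)
        true_codon = codons[rng.choice(len(codons), p=w)]
        ext_codons[true_start_idx] = true_codon
        if rng.random() < cfg.strong_context_prob:
            # purine at -3 (first base of the previous codon) and G at +4
            prev = ext_codons[true_start_idx - 1]
            ext_codons[true_start_idx - 1] = ("A" if rng.random() < 0.5 else "G") + prev[1:]
            if true_start_idx + 1 < ext_len:
                nxt = ext_codons[true_start_idx + 1]
                ext_codons[true_start_idx + 1] = "G" + nxt[1:]

    cds_codons = ["ATG"] + _random_nonstop_codons(rng, cds_len - 2) + ["TAA"]
    parts = [_random_seq(rng, pad)]
    if not edge_bounded:
        parts.append("TAA")
    parts.append("".join(ext_codons))
    parts.append("".join(cds_codons))
    parts.append(_random_seq(rng, int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))))
    seq = "".join(parts)
    ext_start = pad if edge_bounded else pad + 3
    cds_start = ext_start + 3 * ext_len
    layout = {
        "ext_len": ext_len, "ext_start": ext_start,
        "cds_start": cds_start, "cds_end": cds_start + 3 * cds_len,
        "boundary": "edge_bounded" if edge_bounded else "stop_bounded",
        "true_start": None if true_start_idx is None else ext_start + 3 * true_start_idx,
        "true_codon": true_codon,
    }
    return seq, layout


def _make_exons(rng, cfg, klass, strand, gstart, txlen, spliceable=True):
    """Genomic exon layout (transcript 5'->3' order); returns (exons, genomic_end)."""
    spliced = spliceable and rng.random() < cfg.frac_spliced
    if spliced and txlen >= 60:
        n_exons = int(rng.integers(2, 4))
        cuts = sorted(rng.choice(np.arange(20, txlen - 20), size=n_exons - 1, replace=False))
        lens = np.diff([0] + [int(c) for c in cuts] + [txlen]).tolist()
    else:
        spliced = False
        lens = [txlen]
    introns = [int(rng.integers(80, 301)) for _ in range(len(lens) - 1)]
    # left-to-right genomic segments; on '-' the transcript reads right-to-left
    seg_lens = lens if strand == "+" else lens[::-1]
    segs = []
    g = gstart
    for i, L in enumerate(seg_lens):
        segs.append((g, g + L))
        g += L + (introns[i] if i < len(introns) else 0)
    gend = segs[-1][1]
    ordered = segs if strand == "+" else segs[::-1]
    exons = [GenomicInterval(CHROM, s, e, strand) for s, e in ordered]
    return exons, gend, spliced


def _untransl_expectation(klass: str, cfg: SimConfig) -> str | None:
    if klass == "true_nte":
        return "in_predicted_set"
    if klass == "overlap_victim":
        return "coding_overlap"
    if klass == "short_ext":
        return "short_extension"
    if klass in ("zero_cov", "untransl_rule6"):
        return "low_cds_coverage"
    if klass == "untransl_rule5":
        return "extension_covered"
    if klass in ("untransl_rule7", "untransl_boundary_fail"):
        return "low_cds_breadth"
    if klass in ("untransl_boundary_pass",):
        return "pass"
    if klass in ("background", "overlap_source"):
        # indeterminate when background reads may land in the extension
        return "pass" if not (cfg.ext_background or cfg.noise_rate > 0) else None
    return None


def gen_transcriptome(cfg: SimConfig, fasta_path=None, gtf_path=None):
    """Generate the synthetic transcriptome.

    Returns (records, truth); when paths are given, also writes the FASTA
    (gencode_pc-style headers) and GTF.
    """
    rng = _rng(cfg, 1)
    classes = _assign_classes(cfg)
    truth = GroundTruth(cfg)
    records: list[TranscriptRecord] = []
    cursor = 10_000
    pending_victim = None  # layout info for pairing an overlap_source to its victim

    for i, klass in enumerate(classes):
        gid = f"GENE{i:05d}"
        tid = f"TX{i:05d}"
        seq, lay = _build_gene(rng, cfg, klass)
        paired = klass in ("overlap_victim", "overlap_source")
        strand = "+" if paired else ("+" if i % 2 == 0 else "-")

        if klass == "overlap_source" and pending_victim is not None:
            # place so this gene's CDS overlaps the victim's extension window
            # by >= 1 base while its own extension stays clear of any CDS
            v = pending_victim
            gstart = v["win_gstart"] + 1 - lay["cds_start"]
            exons, gend, spliced = _make_exons(rng, cfg, klass, strand, gstart,
                                               len(seq), spliceable=False)
            pending_victim = None
        else:
            exons, gend, spliced = _make_exons(rng, cfg, klass, strand, cursor,
                                               len(seq), spliceable=not paired)
            if klass == "overlap_victim":
                win_codons = min(50, lay["ext_len"])
                pending_victim = {
                    "win_gstart": cursor + lay["cds_start"] - 3 * win_codons,
                }
        cursor = max(cursor, gend) + 1_000

        rec = TranscriptRecord(tid, gid, seq, lay["cds_start"], lay["cds_end"], exons)
        records.append(rec)
        truth.genes[gid] = GeneTruth(
            gene_id=gid, transcript_id=tid, klass=klass, strand=strand,
            spliced=spliced, cds_start=lay["cds_start"], cds_end=lay["cds_end"],
            ext_start=lay["ext_start"], ext_len_codons=lay["ext_len"],
            boundary=lay["boundary"], is_true_nte=(klass == "true_nte"),
            true_start=lay["true_start"], true_codon=lay["true_codon"],
            untransl_expected=_untransl_expectation(klass, cfg),
        )

    header_extra = f"seed:{cfg.seed}|cfg:{cfg.config_hash()}"
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for rec in records:
                u, v = rec.cds_start + 1, rec.cds_end
                fh.write(f">{rec.transcript_id}|{rec.gene_id}|{header_extra}|"
                         f"len:{len(rec.sequence)}|CDS:{u}-{v}|\n")
                for k in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[k : k + 60] + "\n")
    if gtf_path is not None:
        with open(gtf_path, "w") as fh:
            fh.write(f"#!ntescan simulation seed={cfg.seed} cfg={cfg.config_hash()}\n")
            for rec in records:
                emap = ExonMap(rec.transcript_id, rec.exons)
                attrs = (f'gene_id "{rec.gene_id}"; '
                         f'transcript_id "{rec.transcript_id}";')
                for e in rec.exons:
                    fh.write(f"{e.chrom}\tntescan_sim\texon\t{e.start + 1}\t{e.end}"
                             f"\t.\t{e.strand}\t.\t{attrs}\n")
                for b in emap.to_genome(rec.cds_start, rec.cds_end):
                    fh.write(f"{b.chrom}\tntescan_sim\tCDS\t{b.start + 1}\t{b.end}"
                             f"\t.\t{b.strand}\t.\t{attrs}\n")
    return records, truth


# ---------------------------------------------------------------------------
# Ribo-seq profiles
# ---------------------------------------------------------------------------

def _translated_codon_reads(rng, cfg) -> tuple[int, int, int]:
    n = int(rng.poisson(cfg.depth))
    if cfg.noise_only:
        p = np.array([1 / 3, 1 / 3, 1 / 3])
    else:
        p = np.array([cfg.p_frame, (1 - cfg.p_frame) / 2, (1 - cfg.p_frame) / 2])
    return tuple(rng.multinomial(n, p)) if n else (0, 0, 0)


def _background_codon_reads(rng, cfg) -> tuple[int, int, int]:
    n = int(rng.poisson(cfg.depth / cfg.step_multiplier))
    return tuple(rng.multinomial(n, [1 / 3, 1 / 3, 1 / 3])) if n else (0, 0, 0)


def gen_ribo_profiles(records, truth: GroundTruth, cfg: SimConfig,
                      elong_path=None, init_path=None):
    """Per-transcript P-site count profiles for both channels.

    Returns {transcript_id: {"elong": {pos: n}, "init": {pos: n}}} and fills
    ``truth.profile_totals``. When paths are given, writes profile TSVs.
    """
    rng = _rng(cfg, 2)
    by_tid = {r.transcript_id: r for r in records}
    out: dict[str, dict[str, dict[int, int]]] = {}
    for gid in sorted(truth.genes):
        gt = truth.genes[gid]
        rec = by_tid[gt.transcript_id]
        elong: dict[int, int] = {}
        init: dict[int, int] = {}

        def add(channel, pos, n):
            if n > 0:
                channel[pos] = channel.get(pos, 0) + int(n)

        k = gt.klass
        if k != "zero_cov":
            if k == "untransl_rule6":
                for ci, c0 in enumerate(range(gt.cds_start, gt.cds_end, 3)):
                    if ci % 2 == 0:
                        add(elong, c0, 1)
            elif k == "untransl_rule7":
                # 5 reads on the frame-0 position of ~20% of codons: in-frame
                # reads/codon >= 1 but covered-position breadth ~0.067 < 0.3
                n_codons = (gt.cds_end - gt.cds_start) // 3
                for ci in range(n_codons // 5 + 1):
                    add(elong, gt.cds_start + 3 * ci, 5)
            elif k.startswith("untransl_boundary"):
                covered = 90 if k.endswith("pass") else 89
                extra = 100 - covered
                for ci in range(covered):
                    add(elong, gt.cds_start + 3 * ci, 2 if ci < extra else 1)
            else:
                for c0 in range(gt.cds_start, gt.cds_end, 3):
                    a, b, d = _translated_codon_reads(rng, cfg)
                    add(elong, c0, a); add(elong, c0 + 1, b); add(elong, c0 + 2, d)
                add(init, gt.cds_start, cfg.init_peak)

            if k == "untransl_rule5":
                for off in (0, 7, 14):
                    add(elong, gt.ext_start + off, 1)
            elif k == "true_nte":
                for c0 in range(gt.true_start, gt.cds_start, 3):
                    a, b, d = _translated_codon_reads(rng, cfg)
                    add(elong, c0, a); add(elong, c0 + 1, b); add(elong, c0 + 2, d)
                add(init, gt.true_start, cfg.init_peak)
                if cfg.ext_background:
                    for c0 in range(gt.ext_start, gt.true_start, 3):
                        a, b, d = _background_codon_reads(rng, cfg)
                        add(elong, c0, a); add(elong, c0 + 1, b); add(elong, c0 + 2, d)
            elif k in ("background", "overlap_victim", "overlap_source", "short_ext"):
                if cfg.ext_background:
                    for c0 in range(gt.ext_start, gt.cds_start, 3):
                        if cfg.noise_only:
                            a, b, d = _translated_codon_reads(rng, cfg)
                        else:
                            a, b, d = _background_codon_reads(rng, cfg)
                        add(elong, c0, a); add(elong, c0 + 1, b); add(elong, c0 + 2, d)
            if cfg.noise_rate > 0:
                for pos in range(len(rec.sequence)):
                    add(elong, pos, rng.poisson(cfg.noise_rate))

        out[gt.transcript_id] = {"elong": elong, "init": init}
        truth.profile_totals[gt.transcript_id] = {
            "elong": sum(elong.values()), "init": sum(init.values()),
        }

    header = f"# ntescan simulation seed={cfg.seed} cfg={cfg.config_hash()}\n"
    for path, channel in ((elong_path, "elong"), (init_path, "init")):
        if path is None:
            continue
        with open(path, "w") as fh:
            fh.write(header)
            for tid in sorted(out):
                for pos in sorted(out[tid][channel]):
                    fh.write(f"{tid}\t{pos}\t{out[tid][channel][pos]}\t{channel}\n")
    return out


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _evolve_codon(rng, codon: str, t: float, omega: float, coding: bool) -> str:
    cur = codon
    for _ in range(int(rng.poisson(t))):
        i = int(rng.integers(3))
        b = BASES[int(rng.integers(4))]
        if b == cur[i]:
            continue
        nxt = cur[:i] + b + cur[i + 1 :]
        if coding and nxt in STOPS_SET:
            continue
        if _AA[nxt] != _AA[cur] and rng.random() > omega:
            continue
        cur = nxt
    return cur


from Bio.Seq import Seq as _Seq  # noqa: E402  (local import keeps module header tidy)

_AA = {c: str(_Seq(c).translate()) for c in ALL_CODONS}
STOPS_SET = STOP_CODONS


def gen_alignments(windows, records_by_tid, truth: GroundTruth, cfg: SimConfig,
                   maf_path=None):
    """Evolve each window's codons over a star tree and emit reference-anchored MAF.

    ``windows`` is a list of ExtensionWindow with genomic_blocks. The regime
    (coding, omega_coding vs neutral, omega_neutral) is drawn per gene with
    ``fraction_coding`` and recorded in the truth together with the per-species
    codons (transcript orientation). MAF blocks may be split mid-window to
    exercise stitching.
    """
    rng = _rng(cfg, 3)
    species = [f"sp{j:02d}" for j in range(1, cfg.n_species + 1)]
    blocks_out = []  # (gstart, ref_plus_text, {assembly: plus_text})
    for win in sorted(windows, key=lambda w: w.transcript_id):
        rec = records_by_tid[win.transcript_id]
        gt = truth.of_transcript(win.transcript_id)
        coding = rng.random() < cfg.fraction_coding
        omega = cfg.omega_coding if coding else cfg.omega_neutral
        codons = [win.sequence[i : i + 3] for i in range(0, len(win.sequence), 3)]
        sp_codons = {REF_ASSEMBLY: codons}
        for sp in species:
            sp_codons[sp] = [
                _evolve_codon(rng, c, cfg.subs_per_codon, omega, coding)
                for c in codons
            ]
        if gt is not None:
            gt.regime = "coding" if coding else "neutral"
            gt.species_codons = sp_codons
        seqs = {a: "".join(cs) for a, cs in sp_codons.items()}
        off = 0
        for blk in win.genomic_blocks:
            L = len(blk)
            sl = slice(off, off + L)
            pieces = {a: s[sl] for a, s in seqs.items()}
            if blk.strand == "-":
                pieces = {a: revcomp(p) for a, p in pieces.items()}
            halves = [(blk.start, pieces)]
            if cfg.split_maf_blocks and L >= 6:
                cut = L // 2
                halves = [
                    (blk.start, {a: p[:cut] for a, p in pieces.items()}),
                    (blk.start + cut, {a: p[cut:] for a, p in pieces.items()}),
                ]
            for gstart, pc in halves:
                blocks_out.append((gstart, pc))
            off += L
    blocks_out.sort(key=lambda x: x[0])

    if maf_path is not None:
        with open(maf_path, "w") as fh:
            fh.write("##maf version=1 scoring=none\n")
            fh.write(f"# ntescan simulation seed={cfg.seed} cfg={cfg.config_hash()}\n\n")
            for gstart, pieces in blocks_out:
                fh.write("a score=0.0\n")
                L = len(pieces[REF_ASSEMBLY])
                fh.write(f"s {REF_ASSEMBLY}.{CHROM} {gstart} {L} + {CHROM_SIZE} "
                         f"{pieces[REF_ASSEMBLY]}\n")
                for sp in species:
                    fh.write(f"s {sp}.chrU {gstart} {L} + {CHROM_SIZE} {pieces[sp]}\n")
                fh.write("\n")
    return blocks_out


# ---------------------------------------------------------------------------
# Variants and TIS table
# ---------------------------------------------------------------------------

def gen_variants(windows, truth: GroundTruth, cfg: SimConfig, vcf_path,
                 gene_of: dict[str, str] | None = None):
    """Plant variants inside and outside window blocks; truth records the hits."""
    rng = _rng(cfg, 4)
    windows = sorted(windows, key=lambda w: w.transcript_id)
    inside = []
    covered = [(b, w) for w in windows for b in w.genomic_blocks]
    for k in range(cfg.n_var_inside):
        blk, win = covered[int(rng.integers(len(covered)))]
        pos0 = int(rng.integers(blk.start, blk.end))
        vclass = VARIANT_CLASSES[int(rng.integers(len(VARIANT_CLASSES)))]
        inside.append((pos0, vclass, win))
    max_end = max(b.end for b, _ in covered)
    outside = []
    for k in range(cfg.n_var_outside):
        pos0 = int(rng.integers(max_end + 10_000, max_end + 100_000))
        vclass = VARIANT_CLASSES[int(rng.integers(len(VARIANT_CLASSES)))]
        outside.append((pos0, vclass))

    rows = []
    for j, (pos0, vclass, win) in enumerate(inside):
        vid = f"var_in_{j:04d}"
        rows.append((pos0, vid, vclass))
        gt = truth.of_transcript(win.transcript_id)
        gene = gt.gene_id if gt else win.transcript_id
        if gene_of:
            gene = gene_of.get(win.transcript_id, gene)
        if gt is not None:
            gt.expected_variant_hits.append((vid, vclass))
    for j, (pos0, vclass) in enumerate(outside):
        rows.append((pos0, f"var_out_{j:04d}", vclass))
    rows.sort()
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##seed={cfg.seed}\n##cfg={cfg.config_hash()}\n")
        fh.write(f"##contig=<ID={CHROM},length={CHROM_SIZE}>\n")
        fh.write('##INFO=<ID=CLNSIG,Number=.,Type=String,'
                 'Description="Synthetic clinical significance">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos0, vid, vclass in rows:
            fh.write(f"{CHROM}\t{pos0 + 1}\t{vid}\tA\tG\t.\t.\tCLNSIG={vclass}\n")
    return rows


OPTIMAL_TIS = "CACCATGG"


def gen_tis_table(cfg: SimConfig, path, extra_contexts=()):
    """Toy TIS-efficiency table: the optimal context scores 100; non-AUG
    contexts get scores in the measured 0.2-50.4 range."""
    rng = _rng(cfg, 5)
    scores = {OPTIMAL_TIS: 100.0}
    pool = set(extra_contexts)
    while len(pool) < 200:
        pool.add(_random_seq(rng, 8))
    for ctx in sorted(pool):
        if ctx == OPTIMAL_TIS:
            continue
        scores[ctx] = round(float(rng.uniform(0.2, 50.4)), 2)
    with open(path, "w") as fh:
        fh.write(f"# ntescan simulation seed={cfg.seed} cfg={cfg.config_hash()}\n")
        fh.write("context\tscore\n")
        for ctx in sorted(scores):
            fh.write(f"{ctx}\t{scores[ctx]:g}\n")
    return scores


def demo_config(seed: int = 7) -> SimConfig:
    """The bundled small demonstration cohort: 60 genes with a few of every
    decoy class; completes end to end in seconds."""
    return SimConfig(seed=seed, n_genes=60, n_overlap_decoys=3,
                     n_short_ext=3, n_zero_cov=3)


# ---------------------------------------------------------------------------
# Self-consistency helper used by tests
# ---------------------------------------------------------------------------

def verify_truth_extensions(records, truth: GroundTruth) -> bool:
    """Every true-NTE gene's extraction must agree with the planted layout."""
    by_tid = {r.transcript_id: r for r in records}
    for gt in truth.genes.values():
        rec = by_tid[gt.transcript_id]
        ext, reason = extract_theoretical_extension(rec)
        if ext is None:
            return False
        if ext.ext_start != gt.ext_start or ext.length_codons != gt.ext_len_codons:
            return False
        if gt.is_true_nte and not (gt.ext_start <= gt.true_start < gt.cds_start):
            return False
    return True
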