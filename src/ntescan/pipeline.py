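"""End-to-end orchestration: extraction -> filters -> footprint calling ->
coding-evolution scoring -> set building -> statistics, with a run report
that conserves counts at every stage.

Either evidence arm (ribo, phylo) can be disabled, mirroring the two
independent routes to candidate gene sets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import context as ctx
from . import extension as extmod
from . import phylo, ribo, sets
from . import simulate as sim
from . import transcript_io as tio

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    fasta: str = ""
    gtf: str = ""
    elong_profiles: str = ""
    init_profiles: str = ""
    maf: str = ""
    tis_table: str = ""
    vcf: str = ""
    outdir: str = "ntescan_out"
    ref_assembly: str = sim.REF_ASSEMBLY
    window_codons: int = 50
    min_ext_codons: int = 20
    top_n: int = 500
    top_n_ext: int = 5000
    rank_sweep_step: int = 500
    same_strand_overlap: bool = True
    require_atg: bool = True
    run_ribo: bool = True
    run_phylo: bool = True
    ribo: ribo.RiboConfig = dataclasses.field(default_factory=ribo.RiboConfig)
    scorer: phylo.ScorerConfig = dataclasses.field(default_factory=phylo.ScorerConfig)
    untransl: sets.UntranslConfig = dataclasses.field(default_factory=sets.UntranslConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {"ribo": ribo.RiboConfig, "scorer": phylo.ScorerConfig,
                  "untransl": sets.UntranslConfig}
        kwargs = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key, val in d.items():
            if key not in known:
                raise ValueError(f"unknown config key: {key}")
            if key in nested and isinstance(val, dict):
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                bad = set(val) - sub_known
                if bad:
                    raise ValueError(f"unknown config key: {key}.{sorted(bad)[0]}")
                val = nested[key](**val)
            kwargs[key] = val
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunReport:
    def __init__(self):
        self.stages: list[dict] = []
        self.checksums: dict[str, str] = {}
        self.config: dict = {}

    def stage(self, name: str, n_in: int, n_out: int, dropped: dict[str, int]):
        n_dropped = sum(dropped.values())
        if n_in != n_out + n_dropped:
            raise AssertionError(
                f"count conservation violated at {name}: "
                f"{n_in} != {n_out} + {n_dropped}")
        self.stages.append({"stage": name, "in": n_in, "out": n_out,
                            "dropped": dict(sorted(dropped.items()))})

    def to_dict(self) -> dict:
        return {"stages": self.stages, "checksums": self.checksums,
                "config": self.config, "version": "0.1.0"}

    def write(self, json_path: Path, text_path: Path | None = None):
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        if text_path is not None:
            with open(text_path, "w") as fh:
                for st in self.stages:
                    drops = ", ".join(f"{k}={v}" for k, v in st["dropped"].items()) or "-"
                    fh.write(f"{st['stage']}: in={st['in']} out={st['out']} "
                             f"dropped [{drops}]\n")


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run all enabled stages; artifacts land in cfg.outdir."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.config = dataclasses.asdict(cfg)

    # --- stage 1: parse and structure -------------------------------------
    records, skipped = tio.parse_transcript_fasta(cfg.fasta)
    drop = {}
    for _, reason in skipped:
        drop[reason] = drop.get(reason, 0) + 1
    report.stage("parse_fasta", len(records) + len(skipped), len(records), drop)
    records = tio.attach_exons(records, cfg.gtf)
    rec_by_tid = {r.transcript_id: r for r in records}
    gene_of = {r.transcript_id: r.gene_id for r in records}
    universe = {r.gene_id for r in records if r.is_complete_cds()}

    # --- stage 2: theoretical extensions -----------------------------------
    extensions: dict[str, extmod.TheoreticalExtension] = {}
    drop = {}
    for rec in records:
        ext, reason = extmod.extract_theoretical_extension(rec, cfg.require_atg)
        if ext is None:
            drop[reason] = drop.get(reason, 0) + 1
        else:
            extensions[rec.transcript_id] = ext
    report.stage("extract_extension", len(records), len(extensions), drop)

    # --- stage 3: length filter, windows, overlap filter --------------------
    drop = {}
    long_enough = {}
    for tid, ext in extensions.items():
        if extmod.filter_min_length(ext, cfg.min_ext_codons):
            long_enough[tid] = ext
        else:
            drop["short_extension"] = drop.get("short_extension", 0) + 1
    report.stage("min_length_filter", len(extensions), len(long_enough), drop)

    windows = {tid: extmod.clip_window(ext, rec_by_tid[tid], cfg.window_codons)
               for tid, ext in long_enough.items()}
    coding_exons = tio.coding_exons_from_records(records, catalog="annotation")
    overlap_ok: dict[str, bool] = {}
    drop = {}
    kept_windows = {}
    for tid, win in windows.items():
        if not win.genomic_blocks:
            overlap_ok[tid] = True   # transcript-only analyses may proceed
            drop["no_structure"] = drop.get("no_structure", 0) + 1
            continue
        keep, _ = extmod.filter_coding_overlap(
            win, coding_exons, same_strand=cfg.same_strand_overlap)
        overlap_ok[tid] = keep
        if keep:
            kept_windows[tid] = win
        else:
            drop["coding_overlap"] = drop.get("coding_overlap", 0) + 1
    report.stage("overlap_filter", len(windows), len(kept_windows), drop)

    win_rows = []
    for tid in sorted(kept_windows):
        w = kept_windows[tid]
        ext = long_enough[tid]
        win_rows.append(f"{tid}\t{ext.ext_start}\t{ext.length_codons}\t"
                        f"{ext.boundary}\t{w.sequence}")
    (out / "windows.tsv").write_text(
        "transcript_id\text_start\tlength_codons\tboundary\twindow_sequence\n"
        + "".join(r + "\n" for r in win_rows))
    all_blocks = [b for tid in sorted(kept_windows)
                  for b in kept_windows[tid].genomic_blocks]
    names = [tid for tid in sorted(kept_windows)
             for _ in kept_windows[tid].genomic_blocks]
    tio.write_bed6(all_blocks, out / "windows.bed", names=names)

    genesets: dict[str, sets.GeneSet] = {}
    ranked: list[ribo.NtePrediction] = []
    stats_rows: list[str] = []

    # --- stage 4b: ribo arm -------------------------------------------------
    if cfg.run_ribo:
        profiles = ribo.load_profiles(
            [p for p in (cfg.elong_profiles, cfg.init_profiles) if p])
        candidates = {tid: extmod.enumerate_candidate_starts(w)
                      for tid, w in kept_windows.items()}
        for tid, prof in profiles.items():
            if tid in rec_by_tid:
                prof.length = len(rec_by_tid[tid].sequence)
        cds_starts = {tid: rec_by_tid[tid].cds_start for tid in kept_windows}
        ranked = ribo.call_and_rank(profiles, {t: long_enough[t] for t in kept_windows},
                                    candidates, cds_starts, cfg.ribo)
        ribo.write_predictions(ranked, out / "predictions.tsv")
        report.stage("ribo_call", len(kept_windows), len(ranked),
                     {"no_passing_candidate": len(kept_windows) - len(ranked)})

        genesets["RiboSET"] = sets.build_riboset(
            ranked, gene_of, cfg.top_n, label="RiboSET")
        genesets["RiboSET_ext"] = sets.build_riboset(
            ranked, gene_of, cfg.top_n_ext, label="RiboSET_ext")
        predicted_tids = {p.transcript_id for p in ranked}
        predicted_genes = {gene_of[t] for t in predicted_tids}
        untransl, attrition, _ = sets.build_untranslset(
            rec_by_tid, long_enough, overlap_ok, profiles,
            predicted_tids, predicted_genes, cfg.untransl)
        genesets["UntranslSET"] = untransl
        report.stage("untranslset", len(long_enough),
                     len(long_enough) - sum(attrition.values()), attrition)

    # --- stage 4a: phylo arm --------------------------------------------------
    tracks: list[phylo.CodingScoreTrack] = []
    if cfg.run_phylo and cfg.maf:
        index = phylo.MafIndex(cfg.maf, cfg.ref_assembly)
        n_err = 0
        for tid in sorted(kept_windows):
            w = kept_windows[tid]
            if not w.genomic_blocks:
                n_err += 1
                continue
            win = phylo.extract_alignment_window(
                index, w.genomic_blocks, cfg.ref_assembly, tid, w.sequence)
            tracks.append(phylo.builtin_coding_score(win, cfg.scorer))
        phylo.write_score_tracks(tracks, out / "score_tracks.tsv")
        positive = {t.transcript_id for t in tracks
                    if "low_species" not in t.flags and phylo.classify_positive(t)}
        genesets["PhyloSET"] = sets.GeneSet(
            "PhyloSET", {gene_of[t] for t in positive},
            params={"scorer": tracks[0].scorer_id if tracks else "none",
                    "threshold": "total > 0"})
        report.stage("phylo_score", len(kept_windows), len(tracks),
                     {"no_structure": n_err})

    # --- stage 5: sets + statistics -----------------------------------------
    for label in sorted(genesets):
        sets.write_geneset(genesets[label], out / f"geneset_{label}.tsv",
                           out / f"geneset_{label}.params.json")

    if "RiboSET" in genesets and "PhyloSET" in genesets:
        pairs = [(genesets["RiboSET"], genesets["PhyloSET"])]
        if "UntranslSET" in genesets:
            pairs.append((genesets["UntranslSET"], genesets["PhyloSET"]))
        for r in sets.hypergeom_overlap(pairs, universe):
            stats_rows.append(f"overlap\t{r.labels[0]}~{r.labels[1]}\t{r.overlap}\t"
                              f"{r.p_raw:.6g}\t{r.p_adj:.6g}")
        ranked_genes = [gene_of[p.transcript_id] for p in ranked]
        sweep = sets.rank_sweep(ranked_genes, genesets["PhyloSET"],
                                step=cfg.rank_sweep_step)
        stats_rows.append("rank_sweep\tobserved\t"
                          + ",".join(map(str, sweep.observed_increments))
                          + f"\t{sweep.test_p:.6g}\t{sweep.method}")
    if ranked:
        dens, rks = [], []
        profiles_loaded = ribo.load_profiles(
            [p for p in (cfg.elong_profiles,) if p]) if cfg.elong_profiles else {}
        for p in ranked:
            rec = rec_by_tid[p.transcript_id]
            prof = profiles_loaded.get(p.transcript_id)
            if prof is None:
                continue
            fc = ribo.frame_counts(prof, rec.cds_start, rec.cds_end)
            if fc.total > 0:
                dens.append(fc.total / fc.L)
                rks.append(p.rank)
        if len(dens) >= 5 and len({round(d, 9) for d in dens}) > 1:
            rho, pval = sets.rank_vs_coverage(rks, dens)
            stats_rows.append(f"rank_vs_coverage\tspearman\t{len(dens)}\t"
                              f"{rho:.6g}\t{pval:.6g}")
    if cfg.vcf and kept_windows:
        hits = sets.intersect_variants(
            list(kept_windows.values()), cfg.vcf,
            classifications={"Pathogenic", "Likely_pathogenic",
                             "Conflicting_interpretations_of_pathogenicity"},
            gene_of=gene_of)
        with open(out / "variant_hits.tsv", "w") as fh:
            fh.write("gene\tvariant_id\tclassification\n")
            for gene, vid, vclass in sorted(hits):
                fh.write(f"{gene}\t{vid}\t{vclass}\n")
        stats_rows.append(f"variant_hits\tcount\t{len(hits)}\t-\t-")
    if cfg.tis_table and ranked:
        table = ctx.TisTable.from_tsv(cfg.tis_table)
        scored = []
        for p in ranked:
            rec = rec_by_tid[p.transcript_id]
            c = ctx.start_context(rec.sequence, p.start.position)
            if c is not None:
                s = ctx.tis_score(c, table)
                if s is not None:
                    scored.append(s)
        stats_rows.append(f"tis_scored_starts\tcount\t{len(scored)}\t-\t-")

    (out / "stats.tsv").write_text(
        "metric\tdetail\tvalue\tp\textra\n"
        + "".join(r + "\n" for r in stats_rows))

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in ("report.json", "report.txt"):
            report.checksums[f.name] = _sha256(f)
    report.write(out / "report.json", out / "report.txt")
    with open(out / "config.json", "w") as fh:
        json.dump(report.config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report


def simulate_inputs(cfg: sim.SimConfig, outdir) -> dict[str, str]:
    """Generate a full input bundle under ``outdir``; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: str(out / v) for k, v in {
        "fasta": "transcripts.fa", "gtf": "annotation.gtf",
        "elong_profiles": "profiles_elong.tsv", "init_profiles": "profiles_init.tsv",
        "maf": "alignment.maf", "tis_table": "tis_table.tsv", "vcf": "variants.vcf",
    }.items()}
    records, truth = sim.gen_transcriptome(cfg, paths["fasta"], paths["gtf"])
    sim.gen_ribo_profiles(records, truth, cfg, paths["elong_profiles"],
                          paths["init_profiles"])
    rec_by_tid = {r.transcript_id: r for r in records}
    windows = []
    contexts = []
    for rec in records:
        ext, _ = extmod.extract_theoretical_extension(rec)
        if ext is None or ext.length_codons < 20:
            continue
        gt = truth.genes.get(rec.gene_id)
        if gt is not None and gt.klass in ("overlap_victim", "overlap_source"):
            continue   # overlapping loci imply conflicting genomic sequence
        win = extmod.clip_window(ext, rec)
        windows.append(win)
        if gt is not None and gt.true_start is not None:
            c = ctx.start_context(rec.sequence, gt.true_start)
            if c:
                contexts.append(c)
    sim.gen_alignments(windows, rec_by_tid, truth, cfg, paths["maf"])
    sim.gen_variants(windows, truth, cfg, paths["vcf"])
    sim.gen_tis_table(cfg, paths["tis_table"], extra_contexts=contexts)
    with open(out / "truth.json", "w") as fh:
        json.dump({g: dataclasses.asdict(t) for g, t in truth.genes.items()},
                  fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
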