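"""Gene-set construction (RiboSET / RiboSET_ext / PhyloSET / UntranslSET) and
the comparison statistics between the two evidence arms.

Set building is pure: the same inputs and configuration always produce the
same members, and UntranslSET attrition attributes each transcript to exactly
the first rule it fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.stats import hypergeom, ks_2samp, mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    label: str
    members: set[str]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapTestResult:
    labels: tuple[str, str]
    overlap: int
    universe: int
    p_raw: float
    p_adj: float
    method: str = "hypergeometric+BH"


@dataclass
class RankSweepResult:
    thresholds: list[int]
    observed_increments: list[int]
    expected_increments: list[float]
    test_p: float
    method: str


# ---------------------------------------------------------------------------
# Set builders
# ---------------------------------------------------------------------------

def build_riboset(ranked, gene_of: dict[str, str], top_n: int = 500,
                  exclude_aug: bool = True, label: str = "RiboSET") -> GeneSet:
    """Gene set from the top-``top_n`` ranked extension calls.

    AUG-called starts are dropped when ``exclude_aug`` (the sets target
    non-AUG proteoforms); transcripts collapse to gene level.
    """
    if top_n > len(ranked):
        logger.warning("top_n=%d exceeds %d available ranks; using all", top_n, len(ranked))
    kept = [p for p in ranked if p.rank is not None and p.rank <= top_n]
    if exclude_aug:
        kept = [p for p in kept if not p.aug_called]
    members = {gene_of[p.transcript_id] for p in kept}
    if not members:
        logger.warning("%s is empty", label)
    return GeneSet(label, members,
                   params={"top_n": top_n, "exclude_aug": exclude_aug,
                           "n_predictions": len(kept)})


UNTRANSL_RULES = [
    "truncated_cds",        # 1: transcript must have a non-truncated CDS
    "coding_overlap",       # 2: theoretical extension free of foreign coding exons
    "short_extension",      # 3: extension >= min codons
    "in_predicted_set",     # 4: gene/transcript absent from the entire predicted set
    "extension_covered",    # 5: covered-position fraction in extension <= threshold
    "low_cds_coverage",     # 6: CDS in-frame reads per codon >= threshold
    "low_cds_breadth",      # 7: covered-position fraction in CDS >= threshold
]


@dataclass
class UntranslConfig:
    min_ext_codons: int = 20
    max_ext_covered_fraction: float = 0.0005
    min_cds_reads_per_codon: float = 1.0
    min_cds_covered_fraction: float = 0.3


def build_untranslset(records, extensions, overlap_ok: dict[str, bool],
                      profiles, predicted_transcripts: set[str],
                      predicted_genes: set[str],
                      cfg: UntranslConfig | None = None,
                      label: str = "UntranslSET"):
    """Genes with a well-translated CDS but no detectable upstream translation.

    Applies the seven rules in order; each failing transcript is attributed to
    its first failed rule. One transcript per gene is kept, the one with the
    highest CDS in-frame coverage (ties by transcript id). Returns
    (GeneSet, attrition, chosen) where attrition maps rule name -> count and
    chosen maps gene -> transcript.
    """
    cfg = cfg or UntranslConfig()
    attrition = {r: 0 for r in UNTRANSL_RULES}
    passing = []  # (gene, transcript, cds_coverage)
    for tid in sorted(extensions):
        rec = records[tid]
        ext = extensions[tid]
        if not rec.is_complete_cds():
            attrition["truncated_cds"] += 1
            continue
        if not overlap_ok.get(tid, True):
            attrition["coding_overlap"] += 1
            continue
        if ext.length_codons < cfg.min_ext_codons:
            attrition["short_extension"] += 1
            continue
        if tid in predicted_transcripts or rec.gene_id in predicted_genes:
            attrition["in_predicted_set"] += 1
            continue
        prof = profiles.get(tid)
        elong = prof.elong if prof is not None else {}
        ext_len_nt = rec.cds_start - ext.ext_start
        covered_ext = sum(1 for p in range(ext.ext_start, rec.cds_start)
                          if elong.get(p, 0) > 0)
        if covered_ext / ext_len_nt > cfg.max_ext_covered_fraction:
            attrition["extension_covered"] += 1
            continue
        cds_codons = (rec.cds_end - rec.cds_start) // 3
        inframe = sum(elong.get(p, 0)
                      for p in range(rec.cds_start, rec.cds_end, 3))
        cds_cov = inframe / cds_codons
        if cds_cov < cfg.min_cds_reads_per_codon:
            attrition["low_cds_coverage"] += 1
            continue
        covered_cds = sum(1 for p in range(rec.cds_start, rec.cds_end)
                          if elong.get(p, 0) > 0)
        if covered_cds / (rec.cds_end - rec.cds_start) < cfg.min_cds_covered_fraction:
            attrition["low_cds_breadth"] += 1
            continue
        passing.append((rec.gene_id, tid, cds_cov))

    chosen: dict[str, tuple[str, float]] = {}
    for gene, tid, cov in sorted(passing, key=lambda x: (x[0], -x[2], x[1])):
        if gene not in chosen:
            chosen[gene] = (tid, cov)
    geneset = GeneSet(label, set(chosen),
                      params={"rules": vars(cfg), "n_transcripts_passing": len(passing)})
    return geneset, attrition, {g: t for g, (t, _) in chosen.items()}


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def hypergeom_overlap(pairs, universe: set[str]) -> list[OverlapTestResult]:
    """Upper-tail hypergeometric overlap tests with BH adjustment over the family.

    ``pairs`` is a list of (GeneSet, GeneSet); all members must lie in the
    universe.
    """
    results = []
    praws = []
    for a, b in pairs:
        if not a.members <= universe or not b.members <= universe:
            raise ValueError("universe_violation: set member outside universe")
        k = len(a.members & b.members)
        M, n, N = len(universe), len(a.members), len(b.members)
        p_raw = float(hypergeom.sf(k - 1, M, n, N)) if n and N else 1.0
        praws.append(p_raw)
        results.append(OverlapTestResult((a.label, b.label), k, M, p_raw, p_raw))
    if results:
        _, p_adj, _, _ = multipletests(praws, method="fdr_bh")
        for r, pa in zip(results, p_adj):
            r.p_adj = float(max(pa, r.p_raw))
    return results


def rank_sweep(ranked_genes: list[str], reference: GeneSet, step: int = 500,
               max_rank: int | None = None) -> RankSweepResult:
    """Observed vs expected gains of reference genes per rank bin of width ``step``.

    ``ranked_genes`` lists the gene of each call in rank order (rank 1 first).
    The expected increments place the reference genes found anywhere in the
    ranking uniformly across it. The two increment lists are compared with a
    two-sided Mann-Whitney test (exact for <= 30 bins per side).
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if max_rank is None:
        max_rank = len(ranked_genes)
    max_rank = min(max_rank, len(ranked_genes))
    n_bins = (max_rank + step - 1) // step
    thresholds = [min((i + 1) * step, max_rank) for i in range(n_bins)]
    seen: set[str] = set()
    observed = []
    prev = 0
    total_ref_in_ranking = len(reference.members & set(ranked_genes[:max_rank]))
    for thr in thresholds:
        for g in ranked_genes[prev:thr]:
            if g in reference.members:
                seen.add(g)
        observed.append(len(seen))
        prev = thr
    observed_inc = [observed[0]] + [observed[i] - observed[i - 1]
                                    for i in range(1, n_bins)]
    expected_inc = [total_ref_in_ranking * (thresholds[0] / max_rank)]
    for i in range(1, n_bins):
        expected_inc.append(total_ref_in_ranking *
                            ((thresholds[i] - thresholds[i - 1]) / max_rank))
    if n_bins >= 2 and (any(observed_inc) or any(e > 0 for e in expected_inc)):
        exact = n_bins <= 30
        res = mannwhitneyu(observed_inc, expected_inc, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
        test_p = float(res.pvalue)
        method = "mannwhitney_exact" if exact else "mannwhitney_asymptotic"
    else:
        test_p, method = 1.0, "degenerate"
    return RankSweepResult(thresholds, observed_inc, expected_inc, test_p, method)


def rank_vs_coverage(ranks: list[int], cds_densities: list[float]):
    """Spearman correlation between log10 mean CDS footprint density and rank."""
    if len(ranks) != len(cds_densities) or len(ranks) < 5:
        raise ValueError("insufficient_n: need >= 5 paired observations")
    dens = np.log10(np.asarray(cds_densities, dtype=float))
    if np.all(dens == dens[0]) or len(set(ranks)) == 1:
        raise ValueError("degenerate: constant input")
    rho, p = spearmanr(dens, ranks)
    return float(rho), float(p)


def compare_score_distributions(x, y):
    """Two-sample KS test between score distributions (exact for small n)."""
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("empty sample")
    exact = max(len(x), len(y)) <= 30
    res = ks_2samp(x, y, method="exact" if exact else "asymp")
    return float(res.statistic), float(res.pvalue), ("exact" if exact else "asymp")


# ---------------------------------------------------------------------------
# Variant overlap
# ---------------------------------------------------------------------------

def intersect_variants(windows, vcf_path, classifications=None,
                       gene_of: dict[str, str] | None = None,
                       class_field: str = "CLNSIG"):
    """Variants whose position falls inside any window genomic block.

    VCF positions are 1-based; blocks are 0-based half-open. Returns a list of
    (gene, variant id, classification) filtered to the supplied classes (all
    classes pass when ``classifications`` is None).
    """
    hits = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for var in vf:
            pos0 = var.pos - 1
            raw = var.info.get(class_field, ())
            if isinstance(raw, str):
                raw = (raw,)
            vclass = ",".join(raw) if raw else ""
            if classifications is not None and vclass not in classifications:
                continue
            for win in windows:
                if any(b.chrom == var.chrom and b.start <= pos0 < b.end
                       for b in win.genomic_blocks):
                    gene = (gene_of or {}).get(win.transcript_id, win.transcript_id)
                    hits.append((gene, var.id or f"{var.chrom}:{var.pos}", vclass))
                    break
    return hits


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_geneset(gs: GeneSet, path, sidecar_path=None) -> None:
    with open(path, "w") as fh:
        fh.write("label\tgene\n")
        for gene in sorted(gs.members):
            fh.write(f"{gs.label}\t{gene}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"label": gs.label, "size": len(gs), "params": gs.params},
                      fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
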