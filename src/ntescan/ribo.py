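"""Footprint-based detection and ranking of translated N-terminal extensions.

Profiles are P-site-assigned counts per transcript position, split into an
elongating and an initiating channel. A candidate start is scored on the
region from the candidate to the annotated start with two periodicity
statistics — a read-level binomial tail on frame-0 counts, and a codon-level
tail on the number of codons whose frame-0 position holds the strict maximum —
combined into a single p-value, plus a density step score at the candidate and
an initiation-peak score. One call per transcript, ranked transcriptome-wide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import binom, chi2

from .extension import CandidateStart, TheoreticalExtension

logger = logging.getLogger(__name__)

EPS = 0.1                    # pseudocount for density ratios
UPSTREAM_CODONS = 15         # in-frame codons used for the pre-start density
MIN_INFRAME_READS = 10
EXACT_WIN_ENUM_MAX = 30      # exact trinomial enumeration bound for null win prob


@dataclass
class RiboProfile:
    transcript_id: str
    elong: dict[int, int] = field(default_factory=dict)
    init: dict[int, int] = field(default_factory=dict)
    length: int | None = None

    def channel(self, name: str) -> dict[int, int]:
        return self.elong if name == "elong" else self.init


@dataclass
class FrameCounts:
    F0: int
    F1: int
    F2: int
    occupied: int
    wins: int
    L: int
    codon_totals: tuple[int, ...] = ()  # totals of occupied codons, for the null

    @property
    def total(self) -> int:
        return self.F0 + self.F1 + self.F2


@dataclass
class NtePrediction:
    transcript_id: str
    start: CandidateStart
    phi: float       # in-frame read fraction
    p_read: float
    p_codon: float
    p_comb: float
    gamma: float     # fraction of codons with >= 1 read
    mu: float        # mean reads per codon over the scored region
    sigma: float     # density step-increase score at the candidate
    iota: float      # initiation-peak score
    rank: int | None = None

    @property
    def aug_called(self) -> bool:
        return self.start.codon == "ATG"


@dataclass
class RiboConfig:
    min_inframe_reads: int = MIN_INFRAME_READS
    min_gamma: float = 0.0          # gate is gamma > min_gamma ("non-zero coverage")
    eps: float = EPS
    upstream_codons: int = UPSTREAM_CODONS
    combiner: str = "min_bonferroni"  # or "fisher"
    use_iota_in_ranking: bool = False


# ---------------------------------------------------------------------------
# Profile loading
# ---------------------------------------------------------------------------

def load_profiles(paths) -> dict[str, RiboProfile]:
    """Aggregate profile TSVs (transcript_id, position, count, channel).

    Counts are summed across files per channel; malformed lines are skipped and
    logged; a negative count is a corrupt file and fatal.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    profiles: dict[str, RiboProfile] = {}
    n_skipped = 0
    for path in paths:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 4:
                    n_skipped += 1
                    continue
                tid, pos_s, count_s, channel = parts[:4]
                if channel not in ("elong", "init"):
                    n_skipped += 1
                    continue
                try:
                    pos, count = int(pos_s), int(count_s)
                except ValueError:
                    n_skipped += 1
                    continue
                if count < 0:
                    raise ValueError(f"corrupt_profile: negative count in {path}")
                prof = profiles.setdefault(tid, RiboProfile(tid))
                ch = prof.channel(channel)
                ch[pos] = ch.get(pos, 0) + count
    if n_skipped:
        logger.warning("load_profiles: skipped %d malformed lines", n_skipped)
    return profiles


# ---------------------------------------------------------------------------
# Periodicity statistics
# ---------------------------------------------------------------------------

def frame_counts(profile: RiboProfile, start: int, end: int,
                 channel: str = "elong") -> FrameCounts:
    """Per-frame sums and strict-max codon wins on [start, end), frame 0 at ``start``.

    A codon "wins" when its frame-0 count strictly exceeds both other frames;
    ties never count as wins.
    """
    if start >= end or (end - start) % 3 != 0:
        raise ValueError("region must be non-empty and a multiple of 3")
    counts = profile.channel(channel)
    F = [0, 0, 0]
    occupied = wins = 0
    totals = []
    for c0 in range(start, end, 3):
        a = counts.get(c0, 0)
        b = counts.get(c0 + 1, 0)
        d = counts.get(c0 + 2, 0)
        F[0] += a; F[1] += b; F[2] += d
        tot = a + b + d
        if tot > 0:
            occupied += 1
            totals.append(tot)
            if a > b and a > d:
                wins += 1
    return FrameCounts(F[0], F[1], F[2], occupied, wins, (end - start) // 3,
                       tuple(totals))


@lru_cache(maxsize=None)
def null_win_probability(c: int) -> float:
    """P(frame 0 holds the strict maximum) for c reads split uniformly over 3 frames.

    Exact trinomial enumeration for c <= 30; 1/3 beyond (the tie probability is
    negligible there).
    """
    if c <= 0:
        return 0.0
    if c > EXACT_WIN_ENUM_MAX:
        return 1.0 / 3.0
    total = 0.0
    p = (1.0 / 3.0) ** c
    for a in range(c + 1):
        for b in range(c - a + 1):
            d = c - a - b
            if a > b and a > d:
                total += math.comb(c, a) * math.comb(c - a, b) * p
    return total


def periodicity_pvalues(fc: FrameCounts) -> tuple[float, float]:
    """(p_read, p_codon) upper-tail p-values under the equal-frames null.

    p_read: P(>= F0 of F reads in frame 0), Binomial(F, 1/3).
    p_codon: P(>= wins strict-max codons of occupied), Binomial(occupied, p0)
    with p0 the mean exact null win probability at the occupied codons' totals.
    Both are 1 on an empty region.
    """
    if fc.total == 0:
        return 1.0, 1.0
    p_read = float(binom.sf(fc.F0 - 1, fc.total, 1.0 / 3.0))
    if fc.occupied == 0:
        p_codon = 1.0
    else:
        p0 = float(np.mean([null_win_probability(c) for c in fc.codon_totals]))
        p_codon = float(binom.sf(fc.wins - 1, fc.occupied, p0))
    return max(p_read, 1e-300), max(p_codon, 1e-300)


def combine_pvalues(p_read: float, p_codon: float,
                    method: str = "min_bonferroni") -> float:
    """Combine the two periodicity p-values.

    "min_bonferroni" (default): min(1, 2*min(p_read, p_codon)) — a valid bound
    under arbitrary dependence between the two statistics, which share the
    frame-0 counts. "fisher": chi-square combination assuming independence.
    """
    if method == "fisher":
        stat = -2.0 * (math.log(p_read) + math.log(p_codon))
        return float(chi2.sf(stat, 4))
    return min(1.0, 2.0 * min(p_read, p_codon))


# ---------------------------------------------------------------------------
# Start-step and initiation-peak scores
# ---------------------------------------------------------------------------

def _inframe_mean(counts: dict[int, int], start: int, end: int) -> float:
    """Mean in-frame reads per codon over [start, end), frame anchored at start."""
    n = (end - start) // 3
    if n <= 0:
        return 0.0
    return sum(counts.get(p, 0) for p in range(start, end, 3)) / n


def start_step_score(profile: RiboProfile, cand: CandidateStart,
                     ext: TheoreticalExtension, cds_start: int,
                     cfg: RiboConfig | None = None) -> tuple[float, float]:
    """(sigma, iota): density step at the candidate and initiation-peak score.

    sigma = (mu_down + eps) / (mu_up + eps), with mu_down the in-frame reads
    per codon on [cand, cds_start) and mu_up the same over the up-to-15
    in-frame codons upstream of the candidate but inside the extension (0 when
    none exist). iota = initiating reads within one codon of the candidate over
    the transcript-wide mean initiating reads per codon (plus eps).
    """
    cfg = cfg or RiboConfig()
    mu_down = _inframe_mean(profile.elong, cand.position, cds_start)
    up_start = max(ext.ext_start, cand.position - 3 * cfg.upstream_codons)
    mu_up = _inframe_mean(profile.elong, up_start, cand.position)
    sigma = (mu_down + cfg.eps) / (mu_up + cfg.eps)

    peak = sum(profile.init.get(p, 0)
               for p in range(cand.position - 3, cand.position + 6))
    length = profile.length
    if length is None:
        length = max(list(profile.elong) + list(profile.init) + [0]) + 1
    codons = max(1, length // 3)
    init_mean = sum(profile.init.values()) / codons
    iota = peak / (init_mean + cfg.eps)
    return sigma, iota


# ---------------------------------------------------------------------------
# Calling and ranking
# ---------------------------------------------------------------------------

def score_candidate(profile: RiboProfile, cand: CandidateStart,
                    ext: TheoreticalExtension, cds_start: int,
                    cfg: RiboConfig) -> NtePrediction | None:
    """Score one candidate on [cand, cds_start); None if it fails the gates."""
    fc = frame_counts(profile, cand.position, cds_start)
    if fc.F0 < cfg.min_inframe_reads:
        return None
    gamma = fc.occupied / fc.L
    if not gamma > cfg.min_gamma:
        return None
    p_read, p_codon = periodicity_pvalues(fc)
    p_comb = combine_pvalues(p_read, p_codon, cfg.combiner)
    sigma, iota = start_step_score(profile, cand, ext, cds_start, cfg)
    phi = fc.F0 / fc.total if fc.total else 0.0
    mu = fc.total / fc.L
    return NtePrediction(cand.transcript_id, cand, phi, p_read, p_codon,
                         p_comb, gamma, mu, sigma, iota)


def call_and_rank(profiles: dict[str, RiboProfile],
                  extensions: dict[str, TheoreticalExtension],
                  candidates: dict[str, list[CandidateStart]],
                  cds_starts: dict[str, int],
                  cfg: RiboConfig | None = None) -> list[NtePrediction]:
    """One call per transcript (best candidate), ranked transcriptome-wide.

    Per transcript the call is the candidate with the smallest p_comb, ties
    broken by larger sigma, then the 5'-most position. Ranks order calls by
    p_comb ascending, ties by mu descending, then transcript_id; transcripts
    with no passing candidate are absent. Zero-read transcripts are never called.
    """
    cfg = cfg or RiboConfig()
    calls = []
    for tid in sorted(extensions):
        prof = profiles.get(tid)
        if prof is None or not prof.elong:
            continue
        ext = extensions[tid]
        scored = []
        for cand in candidates.get(tid, []):
            pred = score_candidate(prof, cand, ext, cds_starts[tid], cfg)
            if pred is not None:
                scored.append(pred)
        if not scored:
            continue
        scored.sort(key=lambda p: (p.p_comb, -p.sigma,
                                   -p.iota if cfg.use_iota_in_ranking else 0.0,
                                   p.start.position))
        calls.append(scored[0])
    calls.sort(key=lambda p: (p.p_comb, -p.mu, p.transcript_id))
    for i, pred in enumerate(calls, start=1):
        pred.rank = i
    return calls


# ---------------------------------------------------------------------------
# QC and serialisation
# ---------------------------------------------------------------------------

def sample_periodicity_qc(profiles: dict[str, RiboProfile],
                          cds_bounds: dict[str, tuple[int, int]]) -> float:
    """Informational QC: overall in-frame read fraction across all CDSs."""
    inframe = total = 0
    for tid, (cs, ce) in cds_bounds.items():
        prof = profiles.get(tid)
        if prof is None:
            continue
        fc = frame_counts(prof, cs, ce)
        inframe += fc.F0
        total += fc.total
    return inframe / total if total else float("nan")


PREDICTION_COLUMNS = ["transcript_id", "position", "codon", "codon_class",
                      "phi", "p_read", "p_codon", "p_comb", "gamma", "mu",
                      "sigma", "iota", "rank", "aug_called"]


def write_predictions(calls: list[NtePrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for p in calls:
            fh.write("\t".join([
                p.transcript_id, str(p.start.position), p.start.codon,
                p.start.codon_class,
                f"{p.phi:.6g}", f"{p.p_read:.6g}", f"{p.p_codon:.6g}",
                f"{p.p_comb:.6g}", f"{p.gamma:.6g}", f"{p.mu:.6g}",
                f"{p.sigma:.6g}", f"{p.iota:.6g}",
                str(p.rank), str(int(p.aug_called)),
            ]) + "\n")
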