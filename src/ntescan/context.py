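"""Start-codon characterisation: TIS-efficiency lookup, positional context
matrices, and a sliding-window downstream-structure scan.

TIS efficiency scores are on the scale where the optimal context (CACCAUGG:
four upstream bases, the start codon, one downstream base) scores 100. The
built-in structure energy is a base-pair-maximisation stand-in (Nussinov-style
dynamic programme, minimum hairpin loop 3, G·U allowed), not a thermodynamic
model; real folding engines plug in through ``energy_fn`` and every profile
carries its energy_model_id.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

RNA_TO_DNA = str.maketrans("Uu", "Tt")
PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
MIN_LOOP = 3

#: position labels for the 8-mer context: 4 upstream, the codon (+1..+3), +4
CONTEXT_POSITIONS = (-4, -3, -2, -1, 1, 2, 3, 4)


def normalise_context(context: str) -> str:
    return context.upper().translate(RNA_TO_DNA)


@dataclass
class TisTable:
    scores: dict[str, float]

    def __post_init__(self):
        self.scores = {normalise_context(k): float(v) for k, v in self.scores.items()}
        if any(v < 0 for v in self.scores.values()):
            raise ValueError("TIS scores must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "TisTable":
        scores = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                ctx, val = line.rstrip("\n").split("\t")[:2]
                if ctx == "context":
                    continue
                scores[ctx] = float(val)
        return cls(scores)


def tis_score(context: str, table: TisTable) -> float | None:
    """Exact lookup of an 8-mer context; absent contexts are None, never imputed."""
    ctx = normalise_context(context)
    if len(ctx) != 8:
        raise ValueError(f"context must be 8 nt after normalisation, got {len(ctx)}")
    return table.scores.get(ctx)


def start_context(sequence: str, position: int) -> str | None:
    """The 8-mer context of a start at ``position``: [-4,-1] + codon + (+4).

    None when the start is too close to either transcript end.
    """
    if position < 4 or position + 4 > len(sequence):
        return None
    return sequence[position - 4 : position + 4]


# ---------------------------------------------------------------------------
# Context matrix
# ---------------------------------------------------------------------------

@dataclass
class ContextMatrix:
    positions: tuple[int, ...]
    counts: dict[int, Counter]
    n_used: int
    n_dropped: int
    purine_fraction_minus3: float = float("nan")
    g_fraction_plus4: float = float("nan")

    def frequencies(self) -> dict[int, dict[str, float]]:
        out = {}
        for pos in self.positions:
            c = self.counts[pos]
            total = sum(c.values())
            out[pos] = {b: (c[b] / total if total else 0.0) for b in "ACGT"}
        return out


def context_matrix(starts) -> ContextMatrix:
    """Per-position nucleotide counts/frequencies over start 8-mer contexts.

    ``starts`` is an iterable of (sequence, position) pairs or raw 8-mer
    strings; starts too close to a transcript end are dropped and counted.
    The Kozak-relevant positions are summarised separately: purine fraction at
    -3 and G fraction at +4.
    """
    counts = {pos: Counter() for pos in CONTEXT_POSITIONS}
    used = dropped = 0
    for item in starts:
        if isinstance(item, str):
            ctx = normalise_context(item)
            if len(ctx) != 8:
                dropped += 1
                continue
        else:
            seq, pos = item
            ctx = start_context(seq, pos)
            if ctx is None:
                dropped += 1
                continue
            ctx = normalise_context(ctx)
        used += 1
        for pos, base in zip(CONTEXT_POSITIONS, ctx):
            counts[pos][base] += 1
    m3 = counts[-3]
    p4 = counts[4]
    m3_total, p4_total = sum(m3.values()), sum(p4.values())
    return ContextMatrix(
        CONTEXT_POSITIONS, counts, used, dropped,
        purine_fraction_minus3=(m3["A"] + m3["G"]) / m3_total if m3_total else float("nan"),
        g_fraction_plus4=p4["G"] / p4_total if p4_total else float("nan"),
    )


def compare_distributions(x, y):
    """Two-sample KS comparison of TIS-score distributions.

    Returns (statistic, p, method); exact for small samples, asymptotic
    otherwise.
    """
    from .sets import compare_score_distributions
    return compare_score_distributions(x, y)


# ---------------------------------------------------------------------------
# Structure scan
# ---------------------------------------------------------------------------

def max_base_pairs(seq: str, min_loop: int = MIN_LOOP) -> int:
    """Maximum number of nested base pairs (Watson-Crick + G·U) in ``seq``."""
    n = len(seq)
    if n < min_loop + 2:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                paired = 1 if (seq[k], seq[j]) in PAIRS else 0
                if paired:
                    left = dp[i, k - 1] if k > i else 0
                    inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i, j] = best
    return int(dp[0, n - 1])


def pairing_energy(seq: str) -> float:
    """Built-in stand-in energy: minus the maximum nested pair count."""
    return -float(max_base_pairs(seq))


@dataclass
class FoldProfile:
    offsets: list[int]
    energies: list[float]
    energy_model_id: str
    truncated: bool = False


def fold_scan(sequence: str, start_pos: int, window: int = 22,
              region: tuple[int, int] = (-10, 100),
              energy_fn=None, energy_model_id: str | None = None) -> FoldProfile:
    """Window energies at 1-nt steps over ``region`` around a start codon.

    Offsets run from region[0] to region[1] - window + 1 (offset 0 is the first
    base of the start codon). Windows extending past either transcript end are
    skipped and the profile flagged truncated.
    """
    if energy_fn is None:
        energy_fn = pairing_energy
        energy_model_id = energy_model_id or "pairmax_v1"
    elif energy_model_id is None:
        raise ValueError("external energy_fn requires an energy_model_id")
    offsets, energies = [], []
    truncated = False
    for off in range(region[0], region[1] - window + 2):
        a = start_pos + off
        b = a + window
        if a < 0 or b > len(sequence):
            truncated = True
            continue
        offsets.append(off)
        energies.append(float(energy_fn(sequence[a:b])))
    return FoldProfile(offsets, energies, energy_model_id, truncated)
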