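"""Degenerate motif scanning, enrichment statistics and first-layer motif harvesting.

Motif patterns are strings over {A, C, G, T, N} with N a wildcard (e.g. the
canonical PRDM9 binding motif ``CCTCCCTNNCCAC``).  Scanning counts
*occurrences* (overlaps allowed), by default on both strands: a position
matches when the pattern or its reverse-complement pattern matches there,
counted once if both do.  Both-strand occurrence counts are therefore
invariant under reverse-complementing the scanned sequences.

Enrichment between hotspot (label 1) and coldspot (label 0) sequence sets is
summarized by the plain ratio of hot to cold occurrence counts, with a
two-sided exact binomial test (null success probability = the hot fraction
of sequences) and Bonferroni correction across the tested motif set.  A
per-sequence rate-ratio variant is available behind ``method='rate_ratio'``.

Motif harvesting reverses the network's first layer: for each RC-tied filter
pair, find the sequences that activate it most strongly, cut out the
filter-length subsequence driving each activation (reverse-complemented when
the tied partner filter fired harder), and stack the aligned subsequences
into a pseudocount-smoothed PWM.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import binomtest

from . import layers as L
from .network import LabeledDataset, Model
from .sequences import clean_sequence, rc_seq
from .simulate import PWM

_IUPAC_N = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "[ACGT]"}


def _validate_pattern(pattern: str) -> str:
    p = pattern.upper()
    if not p:
        raise ValueError("empty motif pattern")
    bad = set(p) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid pattern symbols {sorted(bad)!r}")
    return p


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("(?=" + "".join(_IUPAC_N[c] for c in pattern) + ")")


def match_positions(seq: str, pattern: str, both_strands: bool = True) -> set[int]:
    """0-based start positions where the pattern (or its RC pattern) matches."""
    p = _validate_pattern(pattern)
    s = clean_sequence(seq)
    pos = {m.start() for m in _pattern_regex(p).finditer(s)}
    if both_strands:
        pos |= {m.start() for m in _pattern_regex(rc_seq(p)).finditer(s)}
    return pos


def scan_count(seq: str, pattern: str, both_strands: bool = True) -> int:
    """Number of (overlapping) occurrence positions of a degenerate motif.

    A position matching both the pattern and its RC pattern counts once.
    """
    return len(match_positions(seq, pattern, both_strands))


# ---------------------------------------------------------------------------
# Count tables and enrichment

@dataclass
class CountTable:
    """Occurrence counts of one motif in hot (label 1) vs cold (label 0) sets."""

    motif: str
    hot_count: int
    cold_count: int
    n_hot_seqs: int
    n_cold_seqs: int
    split: str = "full"

    def __post_init__(self) -> None:
        if min(self.hot_count, self.cold_count, self.n_hot_seqs, self.n_cold_seqs) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EnrichmentResult:
    motif: str
    ratio: float
    p_raw: float
    p_bonferroni: float
    method: str = "ratio"


def count_dataset(dataset: LabeledDataset, motif: str, both_strands: bool = True, split: str = "full") -> CountTable:
    """Total occurrence counts per class, summed over sequences (both strands)."""
    hot = cold = 0
    for seq, lab in zip(dataset.sequences, dataset.labels):
        c = scan_count(seq, motif, both_strands)
        if lab == 1:
            hot += c
        else:
            cold += c
    n_hot = int((dataset.labels == 1).sum())
    return CountTable(motif, hot, cold, n_hot, len(dataset) - n_hot, split)


def enrich(table: CountTable, n_tests: int = 1, method: str = "ratio") -> EnrichmentResult:
    """Enrichment ratio plus exact binomial test with Bonferroni correction.

    ``method='ratio'`` (default): hot_count / cold_count.
    ``method='rate_ratio'``: per-sequence rates (hot_count/n_hot) / (cold_count/n_cold).
    The p-value is a two-sided exact binomial test of ``hot_count`` successes
    in ``hot_count + cold_count`` trials against the null success probability
    ``n_hot_seqs / (n_hot_seqs + n_cold_seqs)``.
    """
    total = table.hot_count + table.cold_count
    if total == 0:
        raise ValueError("zero total occurrence count; enrichment undefined")
    if method == "ratio":
        ratio = table.hot_count / table.cold_count if table.cold_count else np.inf
    elif method == "rate_ratio":
        hot_rate = table.hot_count / table.n_hot_seqs
        cold_rate = table.cold_count / table.n_cold_seqs
        ratio = hot_rate / cold_rate if cold_rate else np.inf
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    p0 = table.n_hot_seqs / (table.n_hot_seqs + table.n_cold_seqs)
    p_raw = binomtest(table.hot_count, total, p0, alternative="two-sided").pvalue
    return EnrichmentResult(table.motif, float(ratio), float(p_raw), min(1.0, n_tests * float(p_raw)), method)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding with ties away from zero (the convention of printed
    tables), unlike Python's default banker's rounding: 3.625 -> 3.63."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# PWM information content and consensus

def information_content(pwm: PWM) -> np.ndarray:
    """Per-column information in bits under a uniform background: 2 + sum p log2 p."""
    P = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    return 2.0 + plogp.sum(axis=0)


def pwm_to_consensus(pwm: PWM, ic_threshold: float = 0.5, base_prob_threshold: float = 0.75) -> str:
    """Degenerate consensus: dominant base where the column is informative, else N."""
    ic = information_content(pwm)
    out = []
    for j in range(len(pwm)):
        i = int(pwm.probs[:, j].argmax())
        if ic[j] >= ic_threshold and pwm.probs[i, j] >= base_prob_threshold:
            out.append("ACGT"[i])
        else:
            out.append("N")
    return "".join(out)


# ---------------------------------------------------------------------------
# Motif harvesting

@dataclass
class HarvestedMotif:
    pwm: PWM
    support: int
    filter_index: int
    mean_activation: float


def harvest_motifs(
    model: Model,
    sequences: list[str],
    top_k: int = 500,
    activation_quantile: float = 0.99,
    pseudocount: float = 1.0,
) -> list[HarvestedMotif]:
    """Build PWMs from the subsequences that maximally activate first-layer filters.

    For each filter (one representative per RC-tied pair in equivariant
    models): take each sequence's maximal first-layer activation and its
    position, keep the ``min(top_k, #above the activation_quantile)`` highest
    sequences, cut out the filter-length subsequence at each kept position —
    reverse-complemented when the tied partner filter produced the larger
    activation — and normalize the stacked base counts (plus pseudocount)
    into a PWM.  Filters with an empty harvest are reported and skipped.
    """
    first = model.config.layers[0]
    if first.kind != "conv":
        raise ValueError("motif harvesting requires a first-layer convolution")
    bank = model.conv_bank(0)
    f_l = bank.filter_len
    from .sequences import encode_batch

    X = encode_batch(sequences)
    A = L.conv1d_valid(X, bank, first.params["activation"])  # [B, n_f, L1]
    # Strand-flipped evaluation perturbs floating-point sums; round scores so
    # ranking/thresholding (hence the harvest) is exactly RC-invariant.
    A = np.round(A, 9)
    n_f = bank.n_filters
    paired = model.config.equivariant and n_f % 2 == 0
    reps = range(n_f // 2) if paired else range(n_f)

    results = []
    for i in reps:
        act_i = A[:, i, :]
        m1, p1 = act_i.max(axis=1), act_i.argmax(axis=1)
        if paired:
            act_j = A[:, n_f - 1 - i, :]
            m2, p2 = act_j.max(axis=1), act_j.argmax(axis=1)
            partner_won = m2 > m1
            best = np.where(partner_won, m2, m1)
            pos = np.where(partner_won, p2, p1)
        else:
            partner_won = np.zeros(len(sequences), dtype=bool)
            best, pos = m1, p1
        threshold = np.quantile(best, activation_quantile)
        above = np.flatnonzero(best >= threshold)
        n_keep = min(top_k, above.size)
        if n_keep == 0:
            warnings.warn(f"filter {i}: no sequence passed the activation threshold", stacklevel=2)
            continue
        keep = above[np.argsort(best[above], kind="stable")[::-1][:n_keep]]
        counts = np.full((4, f_l), pseudocount, dtype=np.float64)
        for b in keep:
            if paired and m1[b] == m2[b]:
                # exact strand tie: pick the lexicographically smaller
                # orientation, which is stable under RC of the input set
                cand_plus = sequences[b][p1[b] : p1[b] + f_l]
                cand_minus = rc_seq(sequences[b][p2[b] : p2[b] + f_l])
                sub = min(cand_plus, cand_minus)
            else:
                sub = sequences[b][pos[b] : pos[b] + f_l]
                if partner_won[b]:
                    sub = rc_seq(sub)
            for j, base in enumerate(sub):
                counts["ACGT".index(base), j] += 1.0
        pwm = PWM(counts / counts.sum(axis=0), f"filter{i}")
        results.append(HarvestedMotif(pwm, int(n_keep), i, float(best[keep].mean())))
    return results
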