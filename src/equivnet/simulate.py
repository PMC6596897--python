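"""PWM-injection simulator for two-motif regulatory datasets.

The generative model emulates a regulatory element bound by two proteins:
draw a binary phenotype label with probability ``label_prob``; draw an
i.i.d. background sequence; then, independently for each of the two position
weight matrices (PWMs), sample a concrete motif instance from the PWM and
inject it at a uniform random position — with probability ``p_inject_pos``
when the label is 1 and ``p_inject_neg`` when it is 0 — reverse-complementing
each injected instance with probability 1/2.  Labels are drawn first and
injections are conditioned on them, so motif presence is the *only* signal
linking sequence to label.  The defaults (40 000 sequences of length 1000,
injection probabilities 0.4 / 0.2, balanced labels, uniform background)
are deliberately noisy: motif presence is far from deterministic in either
class.

Every injection is logged (sequence id, PWM name, position, strand,
instance), giving exact ground truth for recovery tests.  The two injections
may overlap; the second simply overwrites (and both are logged).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LabeledDataset
from .sequences import clean_sequence, rc_seq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PWM:
    """Column-stochastic ``[4, L]`` base-probability matrix (rows A, C, G, T)."""

    probs: np.ndarray
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("PWM probabilities must have shape [4, L]")
        if (self.probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1 (within 1e-9)")

    def __len__(self) -> int:
        return self.probs.shape[1]

    def rc(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1], f"{self.name}_rc")


@dataclass
class SimConfig:
    n_sequences: int = 40_000
    seq_length: int = 1000
    p_inject_pos: float = 0.4
    p_inject_neg: float = 0.2
    label_prob: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_inject_pos, self.p_inject_neg, self.label_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_sequences <= 0 or self.seq_length <= 0:
            raise ValueError("counts and lengths must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")


# ---------------------------------------------------------------------------
# JASPAR PFM I/O

def read_jaspar_pfm(path: str) -> PWM:
    """Read a JASPAR-style position frequency matrix and normalize to probabilities.

    Expected format: a ``>ID NAME`` header then four rows like
    ``A  [ 4 19 0 ... ]`` in A/C/G/T order (brackets optional).
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ValueError("JASPAR PFM must start with a '>' header line")
    name = lines[0][1:].strip() or "pwm"
    rows = {}
    for ln in lines[1:5]:
        m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]+?)\s*\]?$", ln)
        if not m:
            raise ValueError(f"malformed PFM row: {ln!r}")
        rows[m.group(1)] = np.array([float(x) for x in m.group(2).split()])
    if sorted(rows) != ["A", "C", "G", "T"]:
        raise ValueError("PFM needs exactly the four rows A, C, G, T")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValueError("PFM rows have unequal lengths")
    counts = np.vstack([rows[b] for b in "ACGT"])
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("PFM has a zero-total column")
    return PWM(counts / totals, name)


def write_jaspar_pfm(path: str, pwm: PWM, scale: float = 1.0) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, b in enumerate("ACGT"):
            vals = " ".join(f"{scale * v:.6f}" for v in pwm.probs[i])
            fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Bundled toy motifs

def toy_pwms(sharp_weight: float = 0.97) -> tuple[PWM, PWM]:
    """Two bundled synthetic PWMs: a sharp 10-mer and a degenerate 8-mer.

    These are package fixtures standing in for database motifs so the
    simulator is self-contained; real JASPAR files load via
    :func:`read_jaspar_pfm`.
    """
    def sharp(consensus: str, w: float) -> np.ndarray:
        M = np.full((4, len(consensus)), (1.0 - w) / 3.0)
        for j, b in enumerate(consensus):
            M["ACGT".index(b), j] = w
        return M

    sharp10 = PWM(sharp("ACGGTCATGC", sharp_weight), "toy_sharp10")
    # degenerate 8-mer: strong flanks, near-uniform core
    deg = sharp("GTCCAAGG", 0.85)
    deg[:, 3:5] = 0.25
    deg[:, 2] = [0.4, 0.4, 0.1, 0.1]
    deg = deg / deg.sum(axis=0)
    return sharp10, PWM(deg, "toy_degenerate8")


# ---------------------------------------------------------------------------
# Sampling operations

def sample_motif(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw a concrete instance: position ``j`` from PWM column ``j``."""
    cum = np.cumsum(pwm.probs, axis=0)
    u = rng.random(len(pwm))
    idx = (u[None, :] > cum).sum(axis=0)
    return "".join("ACGT"[i] for i in idx)


def inject(seq: str, motif: str, position: int, rc_flag: bool = False) -> str:
    """Replace ``seq[position : position + len(motif)]`` by the (possibly RC'd) motif."""
    motif = clean_sequence(motif)
    if position < 0 or position + len(motif) > len(seq):
        raise ValueError(f"injection at {position} overruns sequence of length {len(seq)}")
    ins = rc_seq(motif) if rc_flag else motif
    return seq[:position] + ins + seq[position + len(motif):]


def _random_background(config: SimConfig, rng: np.random.Generator) -> list[str]:
    comp = np.asarray(config.background)
    shape = (config.n_sequences, config.seq_length)
    if np.allclose(comp, 0.25):
        codes = rng.integers(0, 4, shape, dtype=np.uint8)
    else:
        cum = np.cumsum(comp)
        codes = (rng.random(shape)[..., None] > cum[None, None, :]).sum(axis=-1).astype(np.uint8)
    chars = _BASES[codes]
    return [row.tobytes().decode("ascii") for row in chars]


def simulate_dataset(
    config: SimConfig,
    pwms: tuple[PWM, PWM] | list[PWM],
    rng: np.random.Generator | None = None,
) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate the labeled dataset plus its exact injection log.

    Returns ``(dataset, log)`` where the log has one row per injected motif
    instance: seq_id, pwm, position, strand ('+'/'-'), instance (the exact
    string written into the sequence, post-RC).
    """
    pwms = list(pwms)
    if not pwms:
        raise ValueError("at least one PWM is required")
    max_len = max(len(p) for p in pwms)
    if config.seq_length < max_len:
        raise ValueError("seq_length shorter than the longest PWM")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    labels = (rng.random(config.n_sequences) < config.label_prob).astype(np.int64)
    seqs = _random_background(config, rng)
    log_rows = []
    for i in range(config.n_sequences):
        p_inj = config.p_inject_pos if labels[i] else config.p_inject_neg
        for pwm in pwms:
            if rng.random() >= p_inj:
                continue
            motif = sample_motif(pwm, rng)
            rc_flag = bool(rng.random() < 0.5)
            pos = int(rng.integers(0, config.seq_length - len(pwm) + 1))
            seqs[i] = inject(seqs[i], motif, pos, rc_flag)
            log_rows.append(
                {
                    "seq_id": f"seq{i:06d}",
                    "pwm": pwm.name,
                    "position": pos,
                    "strand": "-" if rc_flag else "+",
                    "instance": rc_seq(motif) if rc_flag else motif,
                }
            )
    log = pd.DataFrame(log_rows, columns=["seq_id", "pwm", "position", "strand", "instance"])
    return LabeledDataset(seqs, labels), log
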