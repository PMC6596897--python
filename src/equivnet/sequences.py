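"""DNA alphabet handling, one-hot encoding and the reverse-complement group actions.

The reverse complement (RC) of a double-stranded DNA sequence is the sequence
read off the opposite strand: base order reversed and A<->T, C<->G swapped.
With the channel order fixed to (A, C, G, T), complementation is exactly a
reversal of the channel axis, so the RC action on a one-hot encoded sequence
``X`` of shape ``[4, N]`` is ``RC(X)[i, j] = X[-1 - i, -1 - j]`` (0-based;
equivalently, 1-based ``X[5 - i, N + 1 - j]``).  The same "flip both axes"
action is used on every hidden tensor of an RC-equivariant network.

All RC actions are involutions: applying any of them twice is the identity.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
ALPHABET = frozenset("ACGTN")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 lookup: ASCII code -> channel index (255 = invalid)
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


def clean_sequence(seq: str) -> str:
    """Uppercase ``seq`` and check it only uses the A/C/G/T/N alphabet."""
    s = seq.upper()
    bad = set(s) - ALPHABET
    if bad:
        raise ValueError(f"invalid DNA symbols {sorted(bad)!r}; allowed: A,C,G,T,N")
    return s


def rc_seq(seq: str) -> str:
    """String-level reverse complement; ``N`` maps to ``N``."""
    return clean_sequence(seq).translate(_COMPLEMENT)[::-1]


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA sequence as a ``[4, N]`` one-hot array (rows A, C, G, T).

    Column ``j`` is the basis vector of base ``j``; every column sums to 1.
    Sequences containing ``N`` are rejected — callers must filter them out
    beforehand (ambiguous bases carry no strand-symmetric point encoding).
    """
    s = clean_sequence(seq)
    if not s:
        raise ValueError("cannot encode an empty sequence")
    if "N" in s:
        raise ValueError("sequence contains N; filter ambiguous sequences before encoding")
    codes = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    X = np.zeros((4, len(s)), dtype=np.float64)
    X[codes, np.arange(len(s))] = 1.0
    return X


def decode_one_hot(X: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for exact one-hot input."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != 4:
        raise ValueError("expected a [4, N] tensor")
    return "".join(BASES[i] for i in X.argmax(axis=0))


def encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences into a ``[n, 4, N]`` array."""
    if not seqs:
        raise ValueError("empty sequence batch")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences must have equal length, got lengths {sorted(lengths)}")
    return np.stack([one_hot_encode(s) for s in seqs])


def rc_input(X: np.ndarray) -> np.ndarray:
    """RC action on the input space: reverse both the channel and spatial axis.

    For the (A, C, G, T) basis this equals encoding the reverse-complement
    string: ``rc_input(one_hot_encode(s)) == one_hot_encode(rc_seq(s))``.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] != 4:
        raise ValueError("rc_input expects a [4, N] tensor")
    return np.ascontiguousarray(X[::-1, ::-1])


def rc_hidden(T: np.ndarray) -> np.ndarray:
    """RC action on a hidden ``[..., C, L]`` tensor: reverse the last two axes.

    On a ``[4, N]`` tensor this coincides with :func:`rc_input` (same index
    map); leading batch axes are left untouched.
    """
    T = np.asarray(T)
    if T.ndim < 2:
        raise ValueError("rc_hidden expects at least a 2-axis tensor")
    return np.ascontiguousarray(T[..., ::-1, ::-1])


# ---------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | os.PathLike) -> list[Tuple[str, str]]:
    """Read a (possibly line-wrapped) multi-record FASTA; bases uppercased."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, clean_sequence(str(rec.seq))))
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[Tuple[str, str]]) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_genome(path: str | os.PathLike) -> Mapping[str, str]:
    """Read a FASTA genome into a ``{contig: sequence}`` mapping."""
    return dict(read_fasta(path))
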