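"""Recombination-hotspot segmentation and GC-matched coldspot extraction.

A two-state hidden Markov model with exponential emission densities
``f(x; mean) = exp(-x/mean) / mean`` segments a windowed recombination-rate
track (cM/Mb) into 'hot' and 'not hot' regions.  Parameters are set by
*Viterbi training* (hard EM): alternate Viterbi decoding with re-estimation
of each state's mean from its assigned windows and of the transition matrix
from path transition counts (add-one smoothed), until the decoded path stops
changing.  State 0 is hot by the identifiability convention
``mean_hot > mean_cold`` (enforced by swapping).

Downstream, maximal runs of hot windows are merged into hotspot intervals;
intervals longer than 4 kb are discarded as poorly localized, the centered
1 kb of the rest is extracted (sequences containing N dropped), and for each
hotspot a GC-matched control ('coldspot') window is found by a greedy
outward search within 300 kb — the first 1 kb window with GC content within
10 percentage points, mean rate below 0.5 cM/Mb, no N and no overlap with
hot intervals or previously chosen coldspots.  GC matching prevents GC
content from acting as a proxy for recombination strength.

Rates of exactly 0 are floored at ``RATE_FLOOR = 1e-6`` cM/Mb before
likelihood evaluation so that maximum-likelihood mean estimation cannot
degenerate when a state captures only zero-rate windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

RATE_FLOOR = 1e-6
HOT, COLD = 0, 1


@dataclass
class HMM2Params:
    """Exponential means (cM/Mb), 2x2 row-stochastic transitions, initial dist.

    State order is (hot, not-hot); ``mean_hot > mean_cold`` is the labeling
    convention.
    """

    mean_hot: float
    mean_cold: float
    transitions: np.ndarray
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        if self.initial is None:
            self.initial = np.array([0.5, 0.5])
        self.initial = np.asarray(self.initial, dtype=np.float64)
        if self.mean_hot <= 0 or self.mean_cold <= 0:
            raise ValueError("exponential means must be positive")
        if self.mean_hot <= self.mean_cold:
            raise ValueError("labeling convention requires mean_hot > mean_cold")
        if self.transitions.shape != (2, 2) or not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transitions must be a 2x2 row-stochastic matrix")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_hot, self.mean_cold])


# ---------------------------------------------------------------------------
# Rate-track I/O and helpers

TRACK_COLUMNS = ["chrom", "start", "end", "rate"]


def read_rate_track(path: str) -> pd.DataFrame:
    """Read a 4-column BED-like TSV (chrom, start, end, rate in cM/Mb)."""
    df = pd.read_csv(path, sep="\t", header=None, names=TRACK_COLUMNS)
    return validate_track(df)


def write_rate_track(path: str, track: pd.DataFrame) -> None:
    track[TRACK_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def validate_track(track: pd.DataFrame) -> pd.DataFrame:
    if (track["rate"] < 0).any():
        raise ValueError("rates must be non-negative")
    for _, grp in track.groupby("chrom", sort=False):
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        if (ends <= starts).any():
            raise ValueError("intervals must have positive length")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("track intervals must be sorted and non-overlapping")
    return track


def _emission_loglik(rates: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Log density of each observation under each state's exponential, [n, 2]."""
    x = np.maximum(np.asarray(rates, dtype=np.float64), RATE_FLOOR)
    return -np.log(means)[None, :] - x[:, None] / means[None, :]


# ---------------------------------------------------------------------------
# Viterbi decoding and training

def viterbi(rates: np.ndarray, params: HMM2Params) -> np.ndarray:
    """Most probable state path (log-space dynamic programming).

    Returns an int array with 0 = hot, 1 = not-hot.
    """
    rates = np.asarray(rates, dtype=np.float64)
    if rates.size == 0:
        raise ValueError("empty rate track")
    logB = _emission_loglik(rates, params.means)
    logA = np.log(params.transitions)
    logpi = np.log(params.initial)
    n = len(rates)
    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=np.int64)
    delta[0] = logpi + logB[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + logA
        psi[t] = cand.argmax(axis=0)
        delta[t] = cand.max(axis=0) + logB[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = delta[-1].argmax()
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def path_loglik(rates: np.ndarray, path: np.ndarray, params: HMM2Params) -> float:
    """Joint log-likelihood of (state path, observations)."""
    logB = _emission_loglik(rates, params.means)
    logA = np.log(params.transitions)
    ll = float(np.log(params.initial[path[0]]) + logB[np.arange(len(path)), path].sum())
    ll += float(logA[path[:-1], path[1:]].sum())
    return ll


def viterbi_train(
    rates: np.ndarray,
    init: HMM2Params,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> HMM2Params:
    """Hard-EM parameter estimation.

    Iterates {Viterbi decode; re-estimate state means as the sample mean of
    assigned (floored) rates; re-estimate transitions from path transition
    counts with add-one smoothing} until the decoded path is unchanged or the
    largest parameter change falls below ``tol``.  A state assigned zero
    windows keeps its parameters for that iteration (with a warning).  The
    returned parameters satisfy ``mean_hot > mean_cold``, swapping labels if
    estimation inverted them.
    """
    rates = np.maximum(np.asarray(rates, dtype=np.float64), RATE_FLOOR)
    params = HMM2Params(init.mean_hot, init.mean_cold, init.transitions.copy(), init.initial.copy())
    prev_path = None
    for _ in range(max_iter):
        path = viterbi(rates, params)
        means = params.means.copy()
        for s in (HOT, COLD):
            assigned = rates[path == s]
            if assigned.size == 0:
                warnings.warn(f"state {s} received zero windows; freezing its mean", stacklevel=2)
            else:
                means[s] = max(assigned.mean(), RATE_FLOOR)
        counts = np.ones((2, 2))  # add-one smoothing
        np.add.at(counts, (path[:-1], path[1:]), 1.0)
        trans = counts / counts.sum(axis=1, keepdims=True)
        if means[HOT] <= means[COLD]:  # enforce labeling convention
            means = means[::-1]
            trans = trans[::-1, ::-1]
            path = 1 - path
        delta = max(
            float(np.abs(means - params.means).max()),
            float(np.abs(trans - params.transitions).max()),
        )
        params = HMM2Params(means[HOT], means[COLD], trans, params.initial)
        if prev_path is not None and np.array_equal(path, prev_path):
            break
        if delta < tol:
            break
        prev_path = path
    return params


class ExponentialHMMSegmenter(BaseEstimator):
    """sklearn-style wrapper: ``fit`` runs Viterbi training, ``predict`` decodes.

    Parameters are the initial exponential means (cM/Mb), initial
    self-transition probability, and the hard-EM stopping controls.
    """

    def __init__(
        self,
        mean_hot: float = 10.0,
        mean_cold: float = 0.5,
        self_transition: float = 0.99,
        max_iter: int = 100,
        tol: float = 1e-6,
    ):
        self.mean_hot = mean_hot
        self.mean_cold = mean_cold
        self.self_transition = self_transition
        self.max_iter = max_iter
        self.tol = tol

    def _init_params(self) -> HMM2Params:
        a = self.self_transition
        return HMM2Params(self.mean_hot, self.mean_cold, np.array([[a, 1 - a], [1 - a, a]]))

    def fit(self, X, y=None):
        rates = np.asarray(X, dtype=np.float64).ravel()
        fitted = viterbi_train(rates, self._init_params(), self.max_iter, self.tol)
        self.params_ = fitted
        self.mean_hot_ = fitted.mean_hot
        self.mean_cold_ = fitted.mean_cold
        self.transitions_ = fitted.transitions
        return self

    def predict(self, X) -> np.ndarray:
        params = getattr(self, "params_", None) or self._init_params()
        return viterbi(np.asarray(X, dtype=np.float64).ravel(), params)


# ---------------------------------------------------------------------------
# Segmentation -> intervals -> sequences

def call_hotspots(states: np.ndarray, track: pd.DataFrame) -> pd.DataFrame:
    """Merge maximal runs of hot windows into intervals with bp length and mean rate."""
    states = np.asarray(states)
    if len(states) != len(track):
        raise ValueError("states and track lengths differ")
    rows = []
    tr = track.reset_index(drop=True)
    start_idx = None
    for i in range(len(tr) + 1):
        boundary = (
            i == len(tr)
            or states[i] != HOT
            or (i > 0 and start_idx is not None and tr.loc[i, "chrom"] != tr.loc[i - 1, "chrom"])
        )
        if start_idx is not None and boundary:
            seg = tr.iloc[start_idx:i]
            rows.append(
                {
                    "chrom": seg.iloc[0]["chrom"],
                    "start": int(seg.iloc[0]["start"]),
                    "end": int(seg.iloc[-1]["end"]),
                    "mean_rate": float(seg["rate"].mean()),
                }
            )
            start_idx = None
        if i < len(tr) and states[i] == HOT and start_idx is None:
            start_idx = i
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_rate"])


def gc_content(seq: str) -> float:
    """(#G + #C) / length; rejects empty or ambiguous sequences."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    if "N" in s:
        raise ValueError("sequence contains N")
    return (s.count("G") + s.count("C")) / len(s)


def extract_center(
    intervals: pd.DataFrame,
    genome: Mapping[str, str],
    max_len: int = 4000,
    out_len: int = 1000,
) -> pd.DataFrame:
    """Centered fixed-width windows from intervals no longer than ``max_len``.

    The center is ``floor((start + end) / 2)`` and the window
    ``[center - out_len//2, center + out_len - out_len//2)``.  Intervals longer
    than ``max_len``, windows running past a contig end (warned) and windows
    containing N are dropped.
    """
    rows = []
    for _, iv in intervals.iterrows():
        if iv["end"] - iv["start"] > max_len:
            continue
        center = (int(iv["start"]) + int(iv["end"])) // 2
        w_start = center - out_len // 2
        w_end = w_start + out_len
        contig = genome.get(iv["chrom"])
        if contig is None or w_start < 0 or w_end > len(contig):
            warnings.warn(f"window {iv['chrom']}:{w_start}-{w_end} outside contig; dropped", stacklevel=2)
            continue
        seq = contig[w_start:w_end].upper()
        if "N" in seq:
            continue
        rows.append({"chrom": iv["chrom"], "start": w_start, "end": w_end, "seq": seq})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "seq"])


class _TrackIndex:
    """Per-chromosome arrays for overlap-weighted mean rate over a window."""

    def __init__(self, track: pd.DataFrame):
        self.by_chrom = {
            c: (g["start"].to_numpy(), g["end"].to_numpy(), g["rate"].to_numpy())
            for c, g in track.groupby("chrom", sort=False)
        }

    def mean_rate(self, chrom: str, start: int, end: int) -> float:
        if chrom not in self.by_chrom:
            return np.inf  # no rate information: treat as unusable for coldspots
        starts, ends, rates = self.by_chrom[chrom]
        ov = np.minimum(ends, end) - np.maximum(starts, start)
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total == 0:
            return np.inf
        return float((ov * rates).sum() / total)


def _overlaps(start: int, end: int, occupied: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in occupied)


def match_coldspot(
    hotspot: tuple[str, int, int],
    genome: Mapping[str, str],
    track: pd.DataFrame | _TrackIndex,
    occupied: Mapping[str, list[tuple[int, int]]] | None = None,
    search_radius: int = 300_000,
    gc_tol: float = 0.10,
    rate_max: float = 0.5,
    relative_gc: bool = False,
    step: int = 1000,
) -> tuple[str, int, int, str] | None:
    """Greedy GC-matched control window for one hotspot window, or None.

    Candidate windows of width ``end - start`` are scanned outward from the
    hotspot at increasing distance, alternating right then left in ``step``
    increments.  The first candidate within the GC tolerance (absolute
    difference of fractions by default; relative ±``gc_tol``·GC_hot when
    ``relative_gc``), with mean track rate below ``rate_max``, no N, inside
    the contig and not overlapping any occupied interval is returned.
    """
    chrom, start, end = hotspot
    width = end - start
    contig = genome.get(chrom)
    if contig is None:
        return None
    gc_hot = gc_content(contig[start:end])
    index = track if isinstance(track, _TrackIndex) else _TrackIndex(track)
    occ = list((occupied or {}).get(chrom, []))
    for k in range(1, search_radius // step + 1):
        for side in (+1, -1):
            c_start = end + (k - 1) * step if side > 0 else start - k * step
            c_end = c_start + width
            if abs(c_start - start) > search_radius and abs(c_end - end) > search_radius:
                continue
            if c_start < 0 or c_end > len(contig):
                continue
            seq = contig[c_start:c_end].upper()
            if "N" in seq:
                continue
            gc = gc_content(seq)
            tol = gc_tol * gc_hot if relative_gc else gc_tol
            if abs(gc - gc_hot) > tol:
                continue
            if index.mean_rate(chrom, c_start, c_end) >= rate_max:
                continue
            if _overlaps(c_start, c_end, occ):
                continue
            return (chrom, c_start, c_end, seq)
    return None


def match_coldspots(
    hot_windows: pd.DataFrame,
    genome: Mapping[str, str],
    track: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Match every hotspot window in turn, keeping chosen coldspots disjoint
    from all hotspot windows and from each other."""
    index = _TrackIndex(track)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for _, hw in hot_windows.iterrows():
        occupied.setdefault(hw["chrom"], []).append((int(hw["start"]), int(hw["end"])))
    rows = []
    for _, hw in hot_windows.iterrows():
        hit = match_coldspot(
            (hw["chrom"], int(hw["start"]), int(hw["end"])), genome, index, occupied, **kwargs
        )
        if hit is None:
            continue
        chrom, s, e, seq = hit
        occupied.setdefault(chrom, []).append((s, e))
        rows.append(
            {
                "chrom": chrom,
                "start": s,
                "end": e,
                "seq": seq,
                "hot_chrom": hw["chrom"],
                "hot_start": int(hw["start"]),
                "hot_end": int(hw["end"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "seq", "hot_chrom", "hot_start", "hot_end"]
    )


# ---------------------------------------------------------------------------
# Synthetic fixture generator

def simulate_rate_track(
    params: HMM2Params,
    n_windows: int,
    window_bp: int = 1000,
    rng: np.random.Generator | None = None,
    chrom: str = "chrSim",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample a Markov state path and exponential rates; returns (track, true path)."""
    if rng is None:
        rng = np.random.default_rng()
    states = np.empty(n_windows, dtype=np.int64)
    states[0] = rng.choice(2, p=params.initial)
    for t in range(1, n_windows):
        states[t] = rng.choice(2, p=params.transitions[states[t - 1]])
    rates = rng.exponential(params.means[states])
    track = pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n_windows) * window_bp,
            "end": (np.arange(n_windows) + 1) * window_bp,
            "rate": rates,
        }
    )
    return track, states
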