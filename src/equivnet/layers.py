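"""RC-equivariant layer primitives: tied convolution, pooling, dropout, activations.

A layer ``F`` with input RC action ``RC_in`` and output action ``RC_out`` is
*equivariant* when ``F(RC_in(X)) == RC_out(F(X))``.  For the two-element RC
group every action here is "flip the channel axis and the spatial axis"
(:func:`equivnet.sequences.rc_hidden`) or the identity.

* A valid 1-D convolution is equivariant iff its weight bank obeys the tie
  ``W[m, n, i] = W[-1-m, -1-n, -1-i]`` (0-based; biases mirrored
  ``b[i] = b[-1-i]``).  We enforce the tie by *reparameterization*: only the
  first ``n_f/2`` filters are free parameters and the second half is their
  double flip, so the symmetry holds exactly after every gradient step.
* Spatial max-pooling (stride = pool width) is equivariant as-is.
* RC orbit pooling reduces each orbit ``{(i, j), (-1-i, -1-j)}`` along the
  filter axis (max, sum or mean), halving the channel count; RC acts as the
  identity downstream, so any later layer preserves full RC invariance.
* Dropout is equivariant when the Bernoulli mask is itself RC-symmetric:
  one draw per orbit, copied to both members.

Dropout uses the *inverted* convention: kept activations are divided by the
keep probability in training and in Monte Carlo prediction passes, so
``keep_p = 1`` reduces exactly to no dropout and expected activations are
scale-stable.  Weight-averaged (conventional) prediction applies no mask and
no scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

ACTIVATIONS = ("linear", "relu", "elu", "srelu")
ORBIT_MODES = ("max", "sum", "avg")


@dataclass
class FreeConvParams:
    """Unconstrained half-bank; the full equivariant bank is derived from it.

    ``w`` has shape ``[4, f_l, n_f/2]`` (channel, filter position, filter),
    ``b`` shape ``[n_f/2]``.
    """

    w: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.w.ndim != 3 or self.w.shape[0] != 4:
            raise ValueError("free conv weights must have shape [4, f_l, n_f/2]")
        if self.b.shape != (self.w.shape[2],):
            raise ValueError("free bias length must equal the number of free filters")

    @property
    def filter_len(self) -> int:
        return self.w.shape[1]

    @property
    def n_free(self) -> int:
        return self.w.shape[2]


@dataclass
class ConvFilterBank:
    """Full filter bank ``w: [4, f_l, n_f]``, ``b: [n_f]``.

    When produced by :func:`symmetrize` it satisfies the RC weight tie
    ``w[m, n, i] == w[3-m, f_l-1-n, n_f-1-i]`` and ``b[i] == b[n_f-1-i]``.
    """

    w: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.w.ndim != 3 or self.w.shape[0] != 4:
            raise ValueError("conv weights must have shape [4, f_l, n_f]")
        if self.b.shape != (self.w.shape[2],):
            raise ValueError("bias length must equal the number of filters")

    @property
    def filter_len(self) -> int:
        return self.w.shape[1]

    @property
    def n_filters(self) -> int:
        return self.w.shape[2]

    def is_symmetric(self) -> bool:
        return bool(
            np.array_equal(self.w, self.w[::-1, ::-1, ::-1])
            and np.array_equal(self.b, self.b[::-1])
        )


def symmetrize(free: FreeConvParams) -> ConvFilterBank:
    """Build the RC-tied bank: filter ``n_f-1-i`` is the double flip of filter ``i``."""
    w = np.concatenate([free.w, free.w[::-1, ::-1, ::-1]], axis=2)
    b = np.concatenate([free.b, free.b[::-1]])
    return ConvFilterBank(w, b)


def free_from_bank(bank: ConvFilterBank) -> FreeConvParams:
    """Extract the free half (first ``n_f/2`` filters) of a symmetric bank."""
    if bank.n_filters % 2:
        raise ValueError("symmetric banks have an even number of filters")
    h = bank.n_filters // 2
    return FreeConvParams(bank.w[:, :, :h].copy(), bank.b[:h].copy())


# ---------------------------------------------------------------------------
# Activations

def activate(z: np.ndarray, kind: str) -> np.ndarray:
    """Elementwise nonlinearity: relu ``max(0,z)``, elu ``z or exp(z)-1``, srelu ``max(z,-1)``."""
    z = np.asarray(z)
    if kind == "linear":
        return z
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "elu":
        return np.where(z > 0, z, np.expm1(np.minimum(z, 0.0)))
    if kind == "srelu":
        return np.maximum(z, -1.0)
    raise ValueError(f"unknown activation {kind!r}; choose from {ACTIVATIONS}")


def activation_grad(z: np.ndarray, kind: str) -> np.ndarray:
    """Derivative of :func:`activate` with respect to its pre-activation ``z``."""
    z = np.asarray(z)
    if kind == "linear":
        return np.ones_like(z)
    if kind == "relu":
        return (z > 0).astype(z.dtype)
    if kind == "elu":
        return np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))
    if kind == "srelu":
        return (z > -1.0).astype(z.dtype)
    raise ValueError(f"unknown activation {kind!r}")


# ---------------------------------------------------------------------------
# Convolution

def conv_patches(X: np.ndarray, f_l: int) -> np.ndarray:
    """Sliding valid-padding windows: ``[..., C, N] -> [..., L_out, C*f_l]``."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] < f_l:
        raise ValueError(f"sequence length {X.shape[-1]} shorter than filter length {f_l}")
    win = sliding_window_view(X, f_l, axis=-1)  # [..., C, L_out, f_l]
    win = np.moveaxis(win, -2, -3)              # [..., L_out, C, f_l]
    return win.reshape(*win.shape[:-2], win.shape[-2] * win.shape[-1])


def conv1d_valid(X: np.ndarray, bank: ConvFilterBank, activation: str = "linear") -> np.ndarray:
    """Valid 1-D convolution ``[.., C, N] -> [.., n_f, N - f_l + 1]``.

    Output ``(i, j)`` is ``f(sum_{m,n} X[m, j+n] w[m, n, i] + b[i])`` — bias
    added before the activation.  With a symmetric bank the layer is
    equivariant: ``conv(rc(X)) == rc_hidden(conv(X))``.
    """
    P = conv_patches(X, bank.filter_len)                      # [.., L_out, C*f_l]
    Wm = bank.w.reshape(-1, bank.n_filters)                   # [C*f_l, n_f]
    z = P @ Wm + bank.b
    return activate(np.moveaxis(z, -1, -2), activation)       # [.., n_f, L_out]


# ---------------------------------------------------------------------------
# Pooling

def spatial_max_pool(T: np.ndarray, p_l: int) -> np.ndarray:
    """Non-overlapping window maxima along the spatial axis (stride = width).

    Strict contract: ``p_l`` must divide the spatial length.
    """
    T = np.asarray(T)
    if p_l < 1:
        raise ValueError("pool width must be >= 1")
    L = T.shape[-1]
    if L % p_l:
        raise ValueError(f"pool width {p_l} does not divide spatial length {L}")
    return T.reshape(*T.shape[:-1], L // p_l, p_l).max(axis=-1)


def rc_orbit_pool(T: np.ndarray, mode: str = "max") -> np.ndarray:
    """Pool each RC orbit ``{(i, j), (-1-i, -1-j)}`` along the filter axis.

    Halves the channel count; afterwards RC acts as the identity, so the
    output is invariant: ``rc_orbit_pool(rc_hidden(T)) == rc_orbit_pool(T)``.
    """
    T = np.asarray(T)
    C = T.shape[-2]
    if C % 2:
        raise ValueError("RC orbit pooling requires an even channel count")
    h = C // 2
    a = T[..., :h, :]
    b = T[..., h:, :][..., ::-1, ::-1]
    if mode == "max":
        return np.maximum(a, b)
    if mode == "sum":
        return a + b
    if mode == "avg":
        return (a + b) / 2.0
    raise ValueError(f"unknown orbit mode {mode!r}; choose from {ORBIT_MODES}")


# ---------------------------------------------------------------------------
# Dropout

@dataclass
class DropoutMask:
    """A 0/1 mask ``eps`` of shape ``[C, L]`` with keep probability ``keep_p``.

    In equivariant mode ``eps == rc_hidden(eps)`` exactly (one Bernoulli draw
    per orbit, ``C*L/2`` free draws).
    """

    eps: np.ndarray
    keep_p: float


def sample_mask(
    shape: tuple[int, int],
    keep_p: float,
    equivariant: bool = False,
    rng: np.random.Generator | None = None,
) -> DropoutMask:
    """Sample a Bernoulli(keep_p) dropout mask, RC-symmetric if requested."""
    if not 0.0 < keep_p <= 1.0:
        raise ValueError("keep probability must lie in (0, 1]")
    C, L = shape
    if rng is None:
        rng = np.random.default_rng()
    if keep_p == 1.0:
        return DropoutMask(np.ones((C, L)), 1.0)
    if equivariant:
        if C % 2:
            raise ValueError("equivariant masks require an even channel count")
        half = (rng.random((C // 2, L)) < keep_p).astype(np.float64)
        eps = np.concatenate([half, half[::-1, ::-1]], axis=0)
    else:
        eps = (rng.random((C, L)) < keep_p).astype(np.float64)
    return DropoutMask(eps, keep_p)


def apply_dropout(T: np.ndarray, mask: DropoutMask) -> np.ndarray:
    """Hadamard product with the mask, inverted-dropout scaled by ``1/keep_p``."""
    T = np.asarray(T)
    if T.shape[-2:] != mask.eps.shape:
        raise ValueError(f"mask shape {mask.eps.shape} does not match tensor {T.shape[-2:]}")
    return T * (mask.eps / mask.keep_p)
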