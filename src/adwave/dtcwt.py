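"""2-D dual-tree complex wavelet transform (DTCWT).

Two parallel real wavelet filter-bank trees are run over rows and columns
of an image.  Combining the four resulting real subbands per detail type
into complex pairs yields, at every decomposition level, six complex
subbands that are directionally selective (orientations +/-15, +/-45,
+/-75 degrees) and whose magnitudes are approximately invariant to small
translations of the input -- the two properties that the plain decimated
DWT lacks.

Conventions
-----------
* Analysis uses circular (periodic) convolution with even-phase
  decimation: ``y[n] = sum_m f[m] x[(2n - m) mod N]``.  Circular
  filtering makes every single-tree stage an exactly invertible linear
  map, so the inverse transform reconstructs to machine precision at any
  depth.
* Tree B's first-stage filters are tree A's delayed by one sample, which
  realises the required half-sample offset between trees at level 1.
  From level 2 on, Q-shift filters are used: tree B is the time reverse
  of tree A, giving a quarter-sample delay each relative to the filter
  midpoint.
* The pyramid is normalised so that total coefficient energy (squared
  magnitudes of the six oriented subbands over all levels plus the
  packed low-pass) equals the energy of the input image exactly whenever
  no filter wrap-around occurs (every intermediate extent >= filter
  length).
* Orientation order of the subband axis is ``(+15, +45, +75, -15, -45,
  -75)`` degrees, where the angle is the direction of intensity
  variation measured from the column (x) axis towards the row (y) axis.

Odd image extents are handled by edge-replicating one row/column before
a level; the padding is recorded in the pyramid and undone on inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.fft as sfft

__all__ = [
    "FilterSet",
    "SubbandPyramid",
    "ORIENTATIONS",
    "default_filter_set",
    "qmf_highpass",
    "dwt_analysis_level",
    "forward",
    "inverse",
    "coefficient_energy",
]

#: Orientation labels (degrees) of the six complex subbands, in storage order.
ORIENTATIONS = (15, 45, 75, -15, -45, -75)

_SQRT2 = np.sqrt(2.0)

# Daubechies least-asymmetric ("symlet") 10-tap low-pass filter.  A
# published orthonormal filter with near-linear phase, used for the first
# decomposition stage of both trees (tree B delayed by one sample).
_SYM5_LO = np.array(
    [
        0.027333068345077982,
        0.029519490925774643,
        -0.039134249302383094,
        0.199397533977393960,
        0.723407690402420560,
        0.633978963458211900,
        0.016602105764522319,
        -0.175328089908450440,
        -0.021101834024758855,
        0.019538882735286728,
    ]
)

# 14-tap orthonormal Q-shift low-pass filter used from level 2 on.
# Designed for this package on the paraunitary lattice (orthonormality and
# the Nyquist zero hold to machine precision by construction) by jointly
# minimising (i) the energy of the iterated dual-tree complex wavelets on
# the wrong side of the spectrum (non-analyticity) at levels 2-5 and
# (ii) the shift-dependence of decimated subband energy, with a mild
# stop-band penalty.  See scripts/design_qshift.py for the generator.
_QSHIFT14_LO = np.array(
    [
        -1.4772714610406128e-04,
        1.3908008925354539e-03,
        6.6303525431293774e-03,
        -3.1153486330480790e-02,
        -1.0321993822238983e-01,
        2.5459690524344919e-01,
        7.6401982060877816e-01,
        5.7223739929002182e-01,
        2.2513478135093336e-03,
        -1.0228887689424708e-01,
        4.1062432464899525e-02,
        1.2694685060319337e-02,
        -3.4895068752751816e-03,
        -3.7064607505043156e-04,
    ]
)

# Level-1 filters are deployed time-reversed (the symlet's synthesis
# orientation): with this Q-shift design the group delays of the two
# stages then combine so that a centred impulse's subband energy is
# nearly unchanged under one-pixel shifts.


def qmf_highpass(lowpass: np.ndarray) -> np.ndarray:
    """Conjugate-quadrature high-pass: alternating-sign reverse of `lowpass`."""
    g = np.asarray(lowpass, dtype=float)[::-1].copy()
    g[1::2] *= -1.0
    return g


@dataclass(frozen=True)
class FilterSet:
    """The four analysis filter pairs of the dual tree.

    ``level1_*`` filters are used at the first stage, ``qshift_*`` from the
    second stage on.  All are real 1-D tap arrays.  High-pass filters are
    the alternating-sign reverses of their low-pass partners, tree B's
    level-1 pair is tree A's delayed by one sample, and the Q-shift pairs
    of the two trees are time reverses of each other.
    """

    level1_low_a: np.ndarray
    level1_high_a: np.ndarray
    level1_low_b: np.ndarray
    level1_high_b: np.ndarray
    qshift_low_a: np.ndarray
    qshift_high_a: np.ndarray
    qshift_low_b: np.ndarray
    qshift_high_b: np.ndarray
    name: str = "custom"

    def level1_pair(self, tree: str) -> tuple[np.ndarray, np.ndarray]:
        if tree == "a":
            return self.level1_low_a, self.level1_high_a
        return self.level1_low_b, self.level1_high_b

    def qshift_pair(self, tree: str) -> tuple[np.ndarray, np.ndarray]:
        if tree == "a":
            return self.qshift_low_a, self.qshift_high_a
        return self.qshift_low_b, self.qshift_high_b

    @property
    def max_length(self) -> int:
        return max(
            len(self.level1_low_a), len(self.level1_low_b), len(self.qshift_low_a)
        )


def default_filter_set() -> FilterSet:
    """Symlet-10 first stage plus the package's 14-tap Q-shift filters."""
    la = _SYM5_LO[::-1].copy()  # synthesis orientation, see note above
    # delay by one sample; padded to even length so the alternating-sign
    # reverse remains a valid conjugate-quadrature partner
    lb = np.concatenate([[0.0], la, [0.0]])
    qa = _QSHIFT14_LO.copy()
    qb = qa[::-1].copy()
    return FilterSet(
        level1_low_a=la,
        level1_high_a=qmf_highpass(la),
        level1_low_b=lb,
        level1_high_b=qmf_highpass(lb),
        qshift_low_a=qa,
        qshift_high_a=qmf_highpass(qa),
        qshift_low_b=qb,
        qshift_high_b=qmf_highpass(qb),
        name="sym5 level-1 / lattice-designed qshift-14",
    )


@dataclass
class SubbandPyramid:
    """Multi-level DTCWT coefficients of one image (or a batch of images).

    Attributes
    ----------
    lowpass:
        Complex array of shape ``(..., 2*r, c)`` packing the four real
        final-scale low-pass images: even rows hold row-tree A, odd rows
        row-tree B; the real part is column-tree A, the imaginary part
        column-tree B.  Scaled by 1/2 (see module docstring on energy
        normalisation).
    levels:
        ``levels[j]`` is a complex array of shape ``(..., 6, r_j, c_j)``
        holding the six oriented subbands of level ``j + 1`` in
        :data:`ORIENTATIONS` order.
    input_shape:
        ``(rows, cols)`` of the original image.
    """

    lowpass: np.ndarray
    levels: list[np.ndarray]
    input_shape: tuple[int, int]
    # pre-padding shape of every level's input, needed for exact inversion
    level_shapes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def nlevels(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# circular filtering primitives (vectorised over leading batch axes)
# ---------------------------------------------------------------------------


def _wrap_filter(f: np.ndarray, n: int) -> np.ndarray:
    """Filter taps folded onto length `n` (circular convolution)."""
    f = np.asarray(f, dtype=float)
    if len(f) > n:
        reps = -(-len(f) // n)
        buf = np.zeros(reps * n)
        buf[: len(f)] = f
        f = buf.reshape(reps, n).sum(axis=0)
    elif len(f) < n:
        f = np.concatenate([f, np.zeros(n - len(f))])
    return f


def _wrapped_dft(f: np.ndarray, n: int) -> np.ndarray:
    """DFT of filter `f` folded onto length `n` (circular convolution)."""
    return np.fft.fft(_wrap_filter(f, n))


def _reshape_for(axis: int, n: int, ndim: int) -> list[int]:
    shape = [1] * ndim
    shape[axis] = n
    return shape


def _filter_down_multi(
    x: np.ndarray, filters: Sequence[np.ndarray], axis: int
) -> list[np.ndarray]:
    """Circular convolution with several filters plus even-phase decimation.

    The input spectrum is computed once; decimation is folded into the
    frequency domain so each output needs only a half-length inverse FFT.
    """
    n = x.shape[axis]
    m = n // 2
    xf = sfft.rfft(x, axis=axis)  # bins 0 .. n/2
    # aliasing of even decimation in the half spectrum:
    # folded[k] = (V[k] + conj(V[m-k])) / 2 for k = 0 .. m/2
    kb = m // 2 + 1  # rfft bin count of the decimated signal
    lo_sl = [slice(None)] * x.ndim
    hi_sl = [slice(None)] * x.ndim
    lo_sl[axis] = slice(0, kb)
    hi_sl[axis] = slice(m - kb + 1, m + 1)
    rev = [slice(None)] * x.ndim
    rev[axis] = slice(None, None, -1)
    out = []
    for f in filters:
        fr = np.fft.rfft(_wrap_filter(f, n))
        v = xf * fr.reshape(_reshape_for(axis, len(fr), x.ndim))
        folded = (v[tuple(lo_sl)] + np.conj(v[tuple(hi_sl)][tuple(rev)])) * 0.5
        out.append(sfft.irfft(folded, n=m, axis=axis))
    return out


def _pair_down(
    x: np.ndarray, lo: np.ndarray, hi: np.ndarray, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    a, b = _filter_down_multi(x, (lo, hi), axis)
    return a, b


def _pair_up(
    ylo: np.ndarray,
    yhi: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    axis: int,
    n: int,
) -> np.ndarray:
    """Exact inverse of :func:`_pair_down` along `axis` (output extent `n`).

    Solves the 2x2 polyphase system per frequency, which stays exact even
    when the filters wrap around signals shorter than the filter length.
    """
    m = n // 2
    g = _wrapped_dft(lo, n)
    h = _wrapped_dft(hi, n)
    g1, g2 = g[:m], g[m:]
    h1, h2 = h[:m], h[m:]
    det = g1 * h2 - g2 * h1
    shape = _reshape_for(axis, m, ylo.ndim)
    yl = np.fft.fft(ylo, axis=axis)
    yh = np.fft.fft(yhi, axis=axis)
    x1 = (h2.reshape(shape) * yl - g2.reshape(shape) * yh) * (2.0 / det.reshape(shape))
    x2 = (g1.reshape(shape) * yh - h1.reshape(shape) * yl) * (2.0 / det.reshape(shape))
    xf = np.concatenate([x1, x2], axis=axis)
    return np.fft.ifft(xf, axis=axis).real


def _analysis_2d(x, row_pair, col_pair):
    lo_r, hi_r = row_pair
    lo_c, hi_c = col_pair
    low, high = _pair_down(x, lo_r, hi_r, axis=-2)
    ll, lh = _pair_down(low, lo_c, hi_c, axis=-1)
    hl, hh = _pair_down(high, lo_c, hi_c, axis=-1)
    return ll, lh, hl, hh


def _synthesis_2d(ll, lh, hl, hh, row_pair, col_pair, shape):
    lo_r, hi_r = row_pair
    lo_c, hi_c = col_pair
    low = _pair_up(ll, lh, lo_c, hi_c, axis=-1, n=shape[1])
    high = _pair_up(hl, hh, lo_c, hi_c, axis=-1, n=shape[1])
    return _pair_up(low, high, lo_r, hi_r, axis=-2, n=shape[0])


# ---------------------------------------------------------------------------
# plain DWT analysis step (shift-variance reference)
# ---------------------------------------------------------------------------


def dwt_analysis_level(signal_2d: np.ndarray, filters: FilterSet):
    """One level of the ordinary separable decimated DWT.

    Row- and column-filters the input with tree A's first-stage
    conjugate-quadrature pair and decimates by two along each axis,
    returning the four real subbands ``(LL, LH, HL, HH)``.  ``LH`` is
    low-pass along rows / high-pass along columns, ``HL`` the converse.
    This is the shift-variant transform that the dual tree improves on;
    it is kept for side-by-side comparisons.
    """
    x = np.asarray(signal_2d, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={x.ndim}")
    flen = max(len(filters.level1_low_a), len(filters.level1_high_a))
    if min(x.shape) < flen:
        raise ValueError(
            f"image extent {x.shape} too small: both dimensions must be >= "
            f"the filter length {flen}"
        )
    if any(s % 2 for s in x.shape):
        raise ValueError(f"image extents must be even for decimation, got {x.shape}")
    pair = filters.level1_pair("a")
    ll, lh, hl, hh = _analysis_2d(x, pair, pair)
    return ll, lh, hl, hh


# ---------------------------------------------------------------------------
# forward / inverse DTCWT
# ---------------------------------------------------------------------------

_TREES = (("a", "a"), ("a", "b"), ("b", "a"), ("b", "b"))

# subband scale making total coefficient energy equal image energy
_BAND_SCALE = 1.0 / (2.0 * _SQRT2)


def _edge_pad(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    pr = x.shape[-2] % 2
    pc = x.shape[-1] % 2
    if pr or pc:
        pad = [(0, 0)] * (x.ndim - 2) + [(0, pr), (0, pc)]
        x = np.pad(x, pad, mode="edge")
    return x, (pr, pc)


def _mix(uaa, uab, uba, ubb):
    """Four real tree subbands -> the two oriented complex subbands."""
    z1 = ((uaa - ubb) + 1j * (uab + uba)) * _BAND_SCALE
    z2 = ((uaa + ubb) + 1j * (uba - uab)) * _BAND_SCALE
    return z1, z2

def _unmix(z1, z2):
    s = 1.0 / (2.0 * _BAND_SCALE)
    uaa = (z1.real + z2.real) * s
    ubb = (z2.real - z1.real) * s
    uab = (z1.imag - z2.imag) * s
    uba = (z1.imag + z2.imag) * s
    return uaa, uab, uba, ubb


# storage index of (detail-type, mix-output) -> ORIENTATIONS slot; detail
# types are 0=LH (row-low/col-high), 1=HL, 2=HH.  Established by measuring
# which subband responds to oriented gratings (see tests).
_ORIENT_SLOT = {
    (0, 0): 0,   # +15
    (0, 1): 3,   # -15
    (1, 0): 2,   # +75
    (1, 1): 5,   # -75
    (2, 0): 1,   # +45
    (2, 1): 4,   # -45
}


def forward(image: np.ndarray, levels: int, filters: FilterSet | None = None) -> SubbandPyramid:
    """Multi-level 2-D DTCWT of `image` (leading batch axes allowed).

    Returns a :class:`SubbandPyramid` with six oriented complex subbands
    per level.  Requires ``levels >= 1`` and both trailing extents of the
    image to be at least ``2**levels``.
    """
    if filters is None:
        filters = default_filter_set()
    x = np.asarray(image, dtype=float)
    if x.ndim < 2:
        raise ValueError("image must have at least 2 dimensions")
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    rows, cols = x.shape[-2:]
    if rows < 2 ** levels or cols < 2 ** levels:
        raise ValueError(
            f"image of extent {(rows, cols)} is too small for {levels} "
            f"levels: needs at least {2 ** levels} in each dimension"
        )

    low = {t: x for t in _TREES}
    out_levels: list[np.ndarray] = []
    level_shapes: list[tuple[int, int]] = []
    for j in range(levels):
        pick = filters.level1_pair if j == 0 else filters.qshift_pair
        level_shapes.append(low[("a", "a")].shape[-2:])
        details = {}
        if j == 0:
            # all four trees share the input: one row-stage FFT serves both
            # trees, and each row output is column-filtered for both trees
            img, _ = _edge_pad(x)
            fa, fb = pick("a"), pick("b")
            quad = (fa[0], fa[1], fb[0], fb[1])
            r_la, r_ha, r_lb, r_hb = _filter_down_multi(img, quad, axis=-2)
            row_out = {"a": (r_la, r_ha), "b": (r_lb, r_hb)}
            col_out = {
                (r, part): _filter_down_multi(arr, quad, axis=-1)
                for r in ("a", "b")
                for part, arr in zip(("low", "high"), row_out[r])
            }
            for (r, c) in _TREES:
                ci = 0 if c == "a" else 2
                low[(r, c)] = col_out[(r, "low")][ci]
                details[(r, c)] = (
                    col_out[(r, "low")][ci + 1],
                    col_out[(r, "high")][ci],
                    col_out[(r, "high")][ci + 1],
                )
        else:
            for (r, c) in _TREES:
                img, _ = _edge_pad(low[(r, c)])
                ll, lh, hl, hh = _analysis_2d(img, pick(r), pick(c))
                low[(r, c)] = ll
                details[(r, c)] = (lh, hl, hh)
        bands = [None] * 6
        for k in range(3):
            z1, z2 = _mix(
                details[("a", "a")][k],
                details[("a", "b")][k],
                details[("b", "a")][k],
                details[("b", "b")][k],
            )
            bands[_ORIENT_SLOT[(k, 0)]] = z1
            bands[_ORIENT_SLOT[(k, 1)]] = z2
        out_levels.append(np.stack(bands, axis=-3))

    laa, lab, lba, lbb = (low[t] for t in _TREES)
    r, c = laa.shape[-2:]
    packed = np.empty(laa.shape[:-2] + (2 * r, c), dtype=complex)
    packed[..., 0::2, :] = (laa + 1j * lab) * 0.5
    packed[..., 1::2, :] = (lba + 1j * lbb) * 0.5
    return SubbandPyramid(
        lowpass=packed,
        levels=out_levels,
        input_shape=(rows, cols),
        level_shapes=level_shapes,
    )


def inverse(pyramid: SubbandPyramid, filters: FilterSet | None = None) -> np.ndarray:
    """Reconstruct the image from a :class:`SubbandPyramid`.

    Exact (machine precision) for pyramids produced by :func:`forward`
    with the same filter set; linear in the coefficients, so modified
    pyramids invert to correspondingly modified images.
    """
    if filters is None:
        filters = default_filter_set()
    nlev = pyramid.nlevels
    if nlev == 0:
        raise ValueError("pyramid has no detail levels")
    if not pyramid.level_shapes or len(pyramid.level_shapes) != nlev:
        raise ValueError("pyramid is missing per-level shape bookkeeping")

    packed = pyramid.lowpass * 2.0
    rec = {
        ("a", "a"): packed[..., 0::2, :].real,
        ("a", "b"): packed[..., 0::2, :].imag,
        ("b", "a"): packed[..., 1::2, :].real,
        ("b", "b"): packed[..., 1::2, :].imag,
    }
    for j in range(nlev - 1, -1, -1):
        pick = filters.level1_pair if j == 0 else filters.qshift_pair
        bands = pyramid.levels[j]
        if bands.shape[-3] != 6:
            raise ValueError(
                f"level {j + 1} has {bands.shape[-3]} subbands, expected 6"
            )
        details = {}
        for k in range(3):
            z1 = bands[..., _ORIENT_SLOT[(k, 0)], :, :]
            z2 = bands[..., _ORIENT_SLOT[(k, 1)], :, :]
            uaa, uab, uba, ubb = _unmix(z1, z2)
            details[k] = {("a", "a"): uaa, ("a", "b"): uab, ("b", "a"): uba, ("b", "b"): ubb}
        tr, tc = pyramid.level_shapes[j]
        padded = (tr + tr % 2, tc + tc % 2)
        for (r, c) in _TREES:
            ll = rec[(r, c)]
            if ll.shape[-2:] != bands.shape[-2:]:
                raise ValueError(
                    f"low-pass extent {ll.shape[-2:]} inconsistent with level "
                    f"{j + 1} subband extent {bands.shape[-2:]}"
                )
            img = _synthesis_2d(
                ll, details[0][(r, c)], details[1][(r, c)], details[2][(r, c)],
                pick(r), pick(c), padded,
            )
            rec[(r, c)] = img[..., : tr, : tc]
    out = (rec[("a", "a")] + rec[("a", "b")] + rec[("b", "a")] + rec[("b", "b")]) / 4.0
    return out


def coefficient_energy(pyramid: SubbandPyramid) -> float:
    """Total squared magnitude of all pyramid coefficients.

    Equals the input image's energy exactly when no filter wrap-around
    occurred during analysis (every intermediate extent >= filter length).
    """
    e = sum(float((np.abs(b) ** 2).sum()) for b in pyramid.levels)
    return e + float((np.abs(pyramid.lowpass) ** 2).sum())
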