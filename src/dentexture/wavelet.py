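"""Multilevel 2D discrete wavelet transform and texture-map assembly.

The analysis step computes, for an orthonormal scaling filter l and its
quadrature-mirror highpass h,

    a[k] = sum_m l[m] x[2k + m]        (approximation)
    d[k] = sum_m h[m] x[2k + m]        (detail)

with a periodized circular extension, so every subband has exactly
ceil(n/2) coefficients, the transform is orthogonal on even lengths
(energy conservation to machine precision), and the inverse filter bank
reconstructs the input exactly. Odd lengths are padded by edge replication
to even before the circular step, as non-expansive periodization requires.

The 2D transform is separable (rows, then columns) and is applied
recursively to the approximation band. The level-2 subband mosaic — the
standard pyramid layout with the deepest approximation in the top-left
tile — is the texture image handed to the classifier.

Filter coefficients for haar/db2/db4 come from PyWavelets; the transform
itself is implemented here so the analysis/synthesis convention is pinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .errors import ParameterError

_FAMILIES = ("haar", "db2", "db4")


def _qmf_pair(family: str) -> tuple[np.ndarray, np.ndarray]:
    if family not in _FAMILIES:
        raise ParameterError(f"family must be one of {_FAMILIES}, got {family!r}")
    l = np.asarray(pywt.Wavelet(family).filter_bank[0], dtype=np.float64)[::-1]
    # alternating-flip quadrature mirror: h[m] = (-1)^m l[L-1-m]
    h = l[::-1].copy()
    h[1::2] *= -1.0
    return l, h


@dataclass(frozen=True)
class WaveletSpec:
    """Orthonormal wavelet family and decomposition depth (1-3)."""

    family: str = "haar"
    level: int = 2
    lowpass: np.ndarray = field(init=False, repr=False)
    highpass: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise ParameterError(f"level must be in {{1,2,3}}, got {self.level}")
        l, h = _qmf_pair(self.family)
        object.__setattr__(self, "lowpass", l)
        object.__setattr__(self, "highpass", h)


def _pad_even(x: np.ndarray, axis: int) -> np.ndarray:
    if x.shape[axis] % 2 == 0:
        return x
    pad = [(0, 0)] * x.ndim
    pad[axis] = (0, 1)
    return np.pad(x, pad, mode="edge")


def _analysis_axis(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Circular correlation with `filt` followed by dyadic downsampling."""
    x = _pad_even(np.asarray(x, dtype=np.float64), axis)
    n = x.shape[axis]
    k = np.arange(n // 2)
    idx = (2 * k[:, None] + np.arange(len(filt))[None, :]) % n
    xt = np.moveaxis(x, axis, -1)
    out = np.einsum("...km,m->...k", xt[..., idx], filt)
    return np.moveaxis(out, -1, axis)


def _synthesis_axis(a: np.ndarray, d: np.ndarray, spec: WaveletSpec, axis: int, n_out: int) -> np.ndarray:
    """Adjoint of the analysis step; truncates padding for odd n_out."""
    n = 2 * a.shape[axis]
    l, h = spec.lowpass, spec.highpass
    k = np.arange(n // 2)
    idx = (2 * k[:, None] + np.arange(len(l))[None, :]) % n
    at = np.moveaxis(np.asarray(a, dtype=np.float64), axis, -1)
    dt = np.moveaxis(np.asarray(d, dtype=np.float64), axis, -1)
    out = np.zeros(at.shape[:-1] + (n,))
    np.add.at(out, (..., idx), at[..., :, None] * l)
    np.add.at(out, (..., idx), dt[..., :, None] * h)
    out = np.moveaxis(out, -1, axis)
    if n_out < n:
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(0, n_out)
        out = out[tuple(sl)]
    return out


def dwt_step_1d(signal, spec: WaveletSpec) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step on a 1D signal -> (approximation, detail).

    Output lengths are ceil(n/2). The signal must be at least as long as
    the filter.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("dwt_step_1d expects a 1D signal")
    if len(x) < len(spec.lowpass):
        raise ParameterError(
            f"signal length {len(x)} shorter than filter length {len(spec.lowpass)}"
        )
    return (
        _analysis_axis(x, spec.lowpass, 0),
        _analysis_axis(x, spec.highpass, 0),
    )


@dataclass(frozen=True)
class DetailBands:
    horizontal: np.ndarray  # lowpass along rows, highpass along columns
    vertical: np.ndarray  # highpass along rows, lowpass along columns
    diagonal: np.ndarray


@dataclass(frozen=True)
class SubbandSet:
    """Approximation plus per-level detail triples of a multilevel 2D DWT.

    ``details[0]`` is level 1 (finest), ``details[-1]`` the deepest level.
    """

    approximation: np.ndarray
    details: tuple[DetailBands, ...]
    source_shape: tuple[int, int]
    spec: WaveletSpec

    @property
    def level(self) -> int:
        return len(self.details)


def _dwt2_step(img: np.ndarray, spec: WaveletSpec):
    lo = _analysis_axis(img, spec.lowpass, 1)
    hi = _analysis_axis(img, spec.highpass, 1)
    ll = _analysis_axis(lo, spec.lowpass, 0)
    lh = _analysis_axis(lo, spec.highpass, 0)
    hl = _analysis_axis(hi, spec.lowpass, 0)
    hh = _analysis_axis(hi, spec.highpass, 0)
    return ll, DetailBands(horizontal=lh, vertical=hl, diagonal=hh)


def decompose(img, spec: WaveletSpec = WaveletSpec()) -> SubbandSet:
    """Separable multilevel 2D DWT of a grayscale image."""
    a = np.asarray(img, dtype=np.float64)
    if a.ndim != 2:
        raise ParameterError("decompose expects a 2D image")
    if min(a.shape) < 2**spec.level:
        raise ParameterError(
            f"image {a.shape} smaller than 2^level = {2 ** spec.level}"
        )
    details = []
    approx = a
    for _ in range(spec.level):
        approx, bands = _dwt2_step(approx, spec)
        details.append(bands)
    return SubbandSet(approx, tuple(details), a.shape, spec)


def reconstruct(sb: SubbandSet, spec: WaveletSpec | None = None) -> np.ndarray:
    """Inverse filter bank; returns an image of ``source_shape``."""
    spec = spec or sb.spec
    if spec.family != sb.spec.family or spec.level != sb.spec.level:
        raise ParameterError("spec does not match the one used for decomposition")
    shapes = [sb.source_shape]
    for _ in range(sb.level - 1):
        h, w = shapes[-1]
        shapes.append(((h + 1) // 2, (w + 1) // 2))
    approx = sb.approximation
    for bands, (h, w) in zip(reversed(sb.details), reversed(shapes)):
        lo = _synthesis_axis(approx, bands.horizontal, spec, 0, n_out=(h + 1) // 2 * 2)
        hi = _synthesis_axis(bands.vertical, bands.diagonal, spec, 0, n_out=(h + 1) // 2 * 2)
        lo = lo[:h]
        hi = hi[:h]
        approx = _synthesis_axis(lo, hi, spec, 1, n_out=w)
    return approx


@dataclass(frozen=True)
class TextureMap:
    """Pyramid mosaic of all subbands, pixel values in [0, 1]."""

    pixels: np.ndarray
    layout: dict  # subband id -> (r0, c0, r1, c1) half-open tile rectangle


def _fit(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Edge-replicate to the requested shape (grows by at most one pixel)."""
    pr, pc = shape[0] - a.shape[0], shape[1] - a.shape[1]
    if pr == 0 and pc == 0:
        return a
    return np.pad(a, ((0, max(pr, 0)), (0, max(pc, 0))), mode="edge")


def _minmax(a: np.ndarray) -> np.ndarray:
    rng = np.ptp(a)
    if rng == 0:
        return np.zeros_like(a)
    return (a - a.min()) / rng


def texture_map(sb: SubbandSet, normalize: str = "per_subband_minmax") -> TextureMap:
    """Assemble the standard pyramid mosaic.

    The deepest approximation occupies the top-left tile; each level's
    detail bands fill the adjacent right (vertical), below (horizontal) and
    diagonal tiles. Detail coefficients are signed, so their magnitudes are
    rescaled to [0,1] — per subband by default, or jointly with
    ``normalize="global"``.
    """
    if normalize not in ("per_subband_minmax", "global"):
        raise ParameterError(f"unknown normalization {normalize!r}")
    if normalize == "global":
        all_abs = np.concatenate(
            [np.abs(b).ravel() for bands in sb.details for b in (bands.horizontal, bands.vertical, bands.diagonal)]
        )
        peak = all_abs.max() if all_abs.size and all_abs.max() > 0 else 1.0

    def norm_detail(a):
        if normalize == "global":
            return np.abs(a) / peak
        return _minmax(np.abs(a))

    canvas = _minmax(sb.approximation)
    layout = {f"a{sb.level}": (0, 0, *canvas.shape)}
    for lvl in range(sb.level, 0, -1):
        bands = sb.details[lvl - 1]
        v = norm_detail(bands.vertical)
        h = norm_detail(bands.horizontal)
        d = norm_detail(bands.diagonal)
        r, c = canvas.shape
        # odd source dims leave the assembled quadrant one pixel larger than
        # the next level's detail bands; replicate edges so tiles still abut
        v = _fit(v, (r, v.shape[1]))
        h = _fit(h, (h.shape[0], c))
        d = _fit(d, (h.shape[0], v.shape[1]))
        top = np.hstack([canvas, v])
        bottom = np.hstack([h, d])
        layout[f"v{lvl}"] = (0, c, v.shape[0], c + v.shape[1])
        layout[f"h{lvl}"] = (r, 0, r + h.shape[0], h.shape[1])
        layout[f"d{lvl}"] = (r, c, r + d.shape[0], c + d.shape[1])
        # shift nested layout is already absolute: tiles accumulated top-left
        canvas = np.vstack([top, bottom])
    return TextureMap(canvas, layout)


def subband_energies(sb: SubbandSet) -> np.ndarray:
    """Mean-square energy per subband — a compact texture descriptor."""
    feats = [float(np.mean(sb.approximation**2))]
    for bands in sb.details:
        for b in (bands.horizontal, bands.vertical, bands.diagonal):
            feats.append(float(np.mean(np.asarray(b) ** 2)))
    return np.asarray(feats)
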