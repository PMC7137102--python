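"""Real-to-complex Fourier transforms and frequency-domain resizing.

Conventions, fixed globally:

* forward transform is unnormalized (the DC coefficient equals the sum of
  the real-space values); the inverse applies the 1/N factor;
* spectra are stored in half-spectrum layout — the x axis keeps only the
  non-negative frequencies, ``x//2 + 1`` bins for even x;
* :func:`spectral_resize` keeps (downscale) or zero-pads (upscale) the
  centred low-frequency block, taking each new Nyquist bin from the source
  bin of frequency ``-N/2``, rescales by ``new N / old N`` so the inverse
  preserves the real-space mean exactly, and enforces Hermitian symmetry so
  the result is a valid spectrum of a real image.

Fourier cropping is the ideal (sinc-interpolation) way to downsample
band-limited EM images: it discards high frequencies without introducing
new aliasing, which is why the image-scaling processor is built on it.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .dtypes import Dims4D, Image
from .errors import EmkitError


class Spectrum:
    """Half-spectrum complex coefficients tied to their real-space geometry.

    ``coeffs`` has shape ``(z, y, x//2 + 1)`` for the 3-D item described by
    ``source_dims`` (``z == 1`` for 2-D images).
    """

    def __init__(self, coeffs: np.ndarray, source_dims: Dims4D) -> None:
        dims = Dims4D(*source_dims).validate()
        if dims.n != 1:
            raise EmkitError("a Spectrum describes a single item (n == 1)")
        coeffs = np.asarray(coeffs, dtype=np.complex128)
        expect = (dims.z, dims.y, dims.x // 2 + 1)
        if coeffs.shape != expect:
            raise EmkitError(
                f"coefficient shape {coeffs.shape} inconsistent with "
                f"source dims {tuple(dims)} (expected {expect})"
            )
        self.coeffs = coeffs
        self.source_dims = dims

    @property
    def dc(self) -> complex:
        return complex(self.coeffs[0, 0, 0])


def forward(img: Image) -> Spectrum:
    """Unnormalized real-to-complex transform of a single 2-D/3-D item."""
    if img.n_items != 1:
        raise EmkitError("forward() takes a single item; loop over the stack")
    if not img.dtype.is_float:
        raise EmkitError(
            f"forward() requires a float image, got {img.dtype.name}; "
            "cast first"
        )
    arr = img.data[0].astype(np.float64)
    return Spectrum(np.fft.rfftn(arr), img.dims)


def inverse(spec: Spectrum) -> Image:
    """Inverse transform (applies 1/N); returns a float64 image."""
    dims = spec.source_dims
    arr = np.fft.irfftn(spec.coeffs, s=dims.item_shape, axes=(0, 1, 2))
    return Image(arr.reshape(tuple(dims)))


def _full_spectrum(spec: Spectrum) -> np.ndarray:
    """Reconstruct the full complex spectrum from the half layout."""
    real = np.fft.irfftn(spec.coeffs, s=spec.source_dims.item_shape,
                         axes=(0, 1, 2))
    return np.fft.fftn(real)


def _hermitian_symmetrize(full: np.ndarray) -> np.ndarray:
    """Average F with conj(F[-k]) so the inverse transform is real."""
    rev = full
    for ax in range(full.ndim):
        rev = np.roll(np.flip(rev, axis=ax), 1, axis=ax)
    return 0.5 * (full + np.conj(rev))


def spectral_resize(spec: Spectrum, new_dims: Sequence[int]) -> Spectrum:
    """Crop or zero-pad the centred frequency block to new spatial dims.

    ``new_dims`` is ``(y, x)`` or ``(z, y, x)``; every axis being resized
    must be even and >= 2.  Coefficients are rescaled by the size ratio so
    the real-space mean is preserved.
    """
    old = spec.source_dims
    new_dims = tuple(int(v) for v in new_dims)
    if len(new_dims) == 2:
        new_dims = (old.z, *new_dims) if old.z == 1 else None
        if new_dims is None:
            raise EmkitError("3-D source needs a (z, y, x) target")
    if len(new_dims) != 3:
        raise EmkitError("target dims must be (y, x) or (z, y, x)")
    for axis_old, axis_new in zip(old.item_shape, new_dims):
        if axis_new == axis_old:
            continue
        if axis_new < 2 or axis_new % 2 or axis_old % 2:
            raise EmkitError(
                "resized axes must be even and >= 2 "
                f"(got {axis_old} -> {axis_new})"
            )
    full = _full_spectrum(spec)
    shifted = np.fft.fftshift(full)
    out = shifted
    for ax, (n_old, n_new) in enumerate(zip(old.item_shape, new_dims)):
        if n_new < n_old:
            start = n_old // 2 - n_new // 2
            out = np.take(out, range(start, start + n_new), axis=ax)
        elif n_new > n_old:
            pad = [(0, 0)] * out.ndim
            left = (n_new - n_old) // 2
            pad[ax] = (left, n_new - n_old - left)
            out = np.pad(out, pad)
    out = np.fft.ifftshift(out)
    ratio = int(np.prod(new_dims)) / old.item_shape[0] / old.item_shape[1] \
        / old.item_shape[2]
    out = _hermitian_symmetrize(out * ratio)
    half = out[..., : new_dims[2] // 2 + 1]
    return Spectrum(half, Dims4D(1, *new_dims))
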