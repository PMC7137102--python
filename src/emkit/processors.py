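"""Parameterized, composable image transforms.

Every processor is a named parameter set plus a ``process(image)`` method.
Processing is strictly out-of-place (the input image is never mutated) and
applies per item across stacks: ``process(stack).item(i)`` equals
``process(stack.item(i))`` for every concrete processor.

Arithmetic runs in float64 regardless of the input element type and the
result is cast back with round-clamp narrowing, so integer images never
overflow silently.
"""

from __future__ import annotations

import math
from types import MappingProxyType
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from . import fourier
from .dtypes import (
    FLOAT32, FLOAT64, Dims4D, DType, Image, dtype_cast, stack_items,
)
from .errors import EmkitError


class Processor:
    """Base class: a name, an immutable parameter mapping, a process()."""

    name = "processor"

    def __init__(self, **params) -> None:
        self._params = MappingProxyType(dict(params))

    @property
    def params(self) -> Mapping:
        return self._params

    def process(self, img: Image) -> Image:
        items = [self._process_item(img.item(i)) for i in range(img.n_items)]
        out = stack_items(items) if len(items) > 1 else items[0]
        if out.pixel_size is None and img.pixel_size is not None:
            out.pixel_size = img.pixel_size
        return out

    def _process_item(self, item: Image) -> Image:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        inner = ", ".join(f"{k}={v!r}" for k, v in self._params.items())
        return f"{type(self).__name__}({inner})"


class MathProc(Processor):
    """Element-wise scalar arithmetic: add, subtract, multiply or divide."""

    name = "math"
    OPS = ("add", "subtract", "multiply", "divide")

    def __init__(self, op: str, operand: float) -> None:
        if op not in self.OPS:
            raise EmkitError(f"unknown arithmetic op {op!r}")
        operand = float(operand)
        if not math.isfinite(operand):
            raise EmkitError("operand must be finite")
        if op == "divide" and operand == 0:
            raise EmkitError("division by zero")
        super().__init__(op=op, operand=operand)

    def _process_item(self, item: Image) -> Image:
        op = self._params["op"]
        c = self._params["operand"]
        vals = item.data.astype(np.float64)
        if op == "add":
            vals = vals + c
        elif op == "subtract":
            vals = vals - c
        elif op == "multiply":
            vals = vals * c
        else:
            vals = vals / c
        out = dtype_cast(vals, FLOAT64, item.dtype, "round-clamp")
        return Image(out.reshape(vals.shape), pixel_size=item.pixel_size)


class ScaleProc(Processor):
    """Fourier-cropping rescale, by isotropic factor or explicit target dims.

    The factor form rounds each spatial extent to the nearest even integer
    (``round(extent * factor / 2) * 2``).  Output keeps float64 input as
    float64 and yields float32 otherwise; the pixel size grows or shrinks
    inversely with the geometric change.
    """

    name = "scale"

    def __init__(self, factor: Optional[float] = None,
                 dims: Optional[Sequence[int]] = None) -> None:
        if (factor is None) == (dims is None):
            raise EmkitError("give exactly one of factor= or dims=")
        if factor is not None and not factor > 0:
            raise EmkitError(f"scale factor must be > 0, got {factor}")
        super().__init__(factor=factor,
                         dims=tuple(int(v) for v in dims) if dims else None)

    def _target_dims(self, item: Image) -> Tuple[int, int, int]:
        z, y, x = item.dims.item_shape
        if self._params["dims"] is not None:
            d = self._params["dims"]
            if len(d) == 2:
                return (z, d[0], d[1])
            if len(d) == 3:
                return d
            raise EmkitError("dims must be (y, x) or (z, y, x)")
        f = self._params["factor"]

        def even(v: int) -> int:
            out = int(round(v * f / 2.0)) * 2
            return out

        tz = even(z) if z > 1 else 1
        return (tz, even(y), even(x))

    def _process_item(self, item: Image) -> Image:
        target = self._target_dims(item)
        out_dt = FLOAT64 if item.dtype == FLOAT64 else FLOAT32
        spec = fourier.forward(item.astype(FLOAT64))
        resized = fourier.inverse(fourier.spectral_resize(spec, target))
        out = resized.astype(out_dt)
        if item.pixel_size is not None:
            out.pixel_size = item.pixel_size * item.dims.x / target[2]
        return out


class WindowProc(Processor):
    """Real-space centred crop or pad to new dims, filling with a constant.

    For an extent change of Δ on an axis the left/top margin is floor(Δ/2),
    so padding then cropping back is the identity.
    """

    name = "window"

    def __init__(self, dims: Sequence[int], fill: float = 0) -> None:
        dims = tuple(int(v) for v in dims)
        if len(dims) not in (2, 3) or any(v < 1 for v in dims):
            raise EmkitError(f"window dims must be 2 or 3 extents >= 1: {dims}")
        super().__init__(dims=dims, fill=float(fill))

    def _process_item(self, item: Image) -> Image:
        z, y, x = item.dims.item_shape
        d = self._params["dims"]
        target = (z, *d) if len(d) == 2 else d
        fill_cell = dtype_cast(np.asarray([self._params["fill"]]),
                               FLOAT64, item.dtype, "round-clamp")[0]
        out = np.full(target, fill_cell, dtype=item.dtype.numpy)
        src = item.data[0]
        src_slices, dst_slices = [], []
        for n_old, n_new in zip((z, y, x), target):
            take = min(n_old, n_new)
            src_off = (n_old - take) // 2
            dst_off = (n_new - take) // 2
            src_slices.append(slice(src_off, src_off + take))
            dst_slices.append(slice(dst_off, dst_off + take))
        out[tuple(dst_slices)] = src[tuple(src_slices)]
        return Image(out, pixel_size=item.pixel_size)


class LowpassProc(Processor):
    """Raised-cosine low-pass filter in digital frequency units.

    The mask is 1 below ``cutoff - edge_width``, 0 at and above ``cutoff``,
    with a half-cosine roll-off between.  Frequency magnitude is the
    max-norm over the per-axis digital frequencies, so the passband is the
    full grid when cutoff reaches the 0.5 Nyquist limit.  DC is always
    inside the passband: the image mean is preserved.
    """

    name = "lowpass"

    def __init__(self, cutoff: float, edge_width: float = 0.02) -> None:
        if not 0 < cutoff <= 0.5:
            raise EmkitError(f"cutoff must be in (0, 0.5], got {cutoff}")
        if not 0 <= edge_width < 0.5:
            raise EmkitError(f"edge width must be in [0, 0.5), got {edge_width}")
        super().__init__(cutoff=float(cutoff), edge_width=float(edge_width))

    def _mask(self, item_shape: Tuple[int, int, int]) -> np.ndarray:
        z, y, x = item_shape
        fz = np.abs(np.fft.fftfreq(z)) if z > 1 else np.zeros(1)
        fy = np.abs(np.fft.fftfreq(y))
        fx = np.abs(np.fft.rfftfreq(x))
        r = np.maximum.reduce(np.meshgrid(fz, fy, fx, indexing="ij"))
        c = self._params["cutoff"]
        w = self._params["edge_width"]
        if w == 0:
            return (r <= c).astype(np.float64)
        mask = np.zeros_like(r)
        mask[r <= c - w] = 1.0
        band = (r > c - w) & (r < c)
        mask[band] = 0.5 * (1 + np.cos(np.pi * (r[band] - (c - w)) / w))
        return mask

    def _process_item(self, item: Image) -> Image:
        out_dt = item.dtype if item.dtype.is_float else FLOAT32
        spec = fourier.forward(item.astype(FLOAT64))
        spec.coeffs *= self._mask(item.dims.item_shape)
        out = fourier.inverse(spec).astype(out_dt)
        out.pixel_size = item.pixel_size
        return out


# Spec-level constructor aliases -----------------------------------------

def math_proc(op: str, operand: float) -> MathProc:
    return MathProc(op, operand)


def scale_proc(factor_or_dims: Union[float, Sequence[int]]) -> ScaleProc:
    if isinstance(factor_or_dims, (int, float)):
        return ScaleProc(factor=float(factor_or_dims))
    return ScaleProc(dims=factor_or_dims)


def window_proc(dims: Sequence[int], fill: float = 0) -> WindowProc:
    return WindowProc(dims, fill)


def lowpass_proc(cutoff: float, edge_width: float = 0.02) -> LowpassProc:
    return LowpassProc(cutoff, edge_width)
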