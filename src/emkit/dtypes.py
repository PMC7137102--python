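"""Element-type system and the 4-D image container.

Every image in the library is a dense 4-D array with axes ``(n, z, y, x)``
where ``n`` counts 2-D/3-D items in a stack and ``x`` is the fastest-varying
axis (the MRC "column" axis).  A small closed set of element types with
explicit cast semantics keeps file I/O deterministic: widening casts are
value-exact, narrowing casts either round-and-clamp or raise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Union

import numpy as np

from .errors import CastError, EmkitError


class Kind(enum.Enum):
    """Element-type family."""

    SIGNED_INT = "signed-int"
    UNSIGNED_INT = "unsigned-int"
    FLOAT = "float"


@dataclass(frozen=True)
class DType:
    """Descriptor of a supported element type: a (kind, bit-width) pair.

    The supported set is closed: int8, int16, int32, uint8, uint16,
    float32 and float64.  Use :func:`dtype` or the module-level constants
    (``INT8`` ...) rather than constructing arbitrary pairs.
    """

    kind: Kind
    bits: int

    def __post_init__(self) -> None:
        if (self.kind, self.bits) not in _CANONICAL:
            raise EmkitError(
                f"unsupported element type: {self.kind.value}{self.bits}"
            )

    @property
    def name(self) -> str:
        return _CANONICAL[(self.kind, self.bits)]

    @property
    def numpy(self) -> np.dtype:
        """Native-endian numpy dtype for in-memory buffers."""
        return np.dtype(self.name)

    @property
    def is_float(self) -> bool:
        return self.kind is Kind.FLOAT

    @property
    def is_integer(self) -> bool:
        return not self.is_float

    def widens_to(self, other: "DType") -> bool:
        """True if every value of self is exactly representable in other."""
        return other.name in _WIDENS[self.name]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DType({self.name})"


_CANONICAL = {
    (Kind.SIGNED_INT, 8): "int8",
    (Kind.SIGNED_INT, 16): "int16",
    (Kind.SIGNED_INT, 32): "int32",
    (Kind.UNSIGNED_INT, 8): "uint8",
    (Kind.UNSIGNED_INT, 16): "uint16",
    (Kind.FLOAT, 32): "float32",
    (Kind.FLOAT, 64): "float64",
}

_BY_NAME = {name: DType(kind, bits) for (kind, bits), name in _CANONICAL.items()}

INT8 = _BY_NAME["int8"]
INT16 = _BY_NAME["int16"]
INT32 = _BY_NAME["int32"]
UINT8 = _BY_NAME["uint8"]
UINT16 = _BY_NAME["uint16"]
FLOAT32 = _BY_NAME["float32"]
FLOAT64 = _BY_NAME["float64"]

SUPPORTED_DTYPES = tuple(_BY_NAME.values())

# Direct lossless-widening edges; closure below.  uint8 fits in int16,
# uint16 in int32, int32 and uint16 etc. in float64; float32 in float64.
_EDGES = {
    "int8": {"int16"},
    "int16": {"int32"},
    "int32": {"float64"},
    "uint8": {"int16"},
    "uint16": {"int32"},
    "float32": {"float64"},
    "float64": set(),
}


def _closure(edges: Mapping[str, set]) -> dict:
    out = {}
    for start in edges:
        seen = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nxt in edges[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        out[start] = frozenset(seen)
    return out


_WIDENS = _closure(_EDGES)


def dtype(spec: Union[str, DType, np.dtype, type]) -> DType:
    """Resolve a name, numpy dtype or DType to the canonical DType."""
    if isinstance(spec, DType):
        return spec
    name = np.dtype(spec).name if not isinstance(spec, str) else spec
    try:
        return _BY_NAME[name]
    except KeyError:
        raise EmkitError(f"unsupported element type: {name!r}") from None


class Dims4D(NamedTuple):
    """Image geometry: item count ``n`` and spatial extents ``z, y, x``.

    A 2-D stack has ``z == 1`` and ``n >= 1``; a volume has ``n == 1`` and
    ``z > 1``.
    """

    n: int
    z: int
    y: int
    x: int

    @property
    def total(self) -> int:
        return self.n * self.z * self.y * self.x

    @property
    def item_shape(self) -> tuple:
        return (self.z, self.y, self.x)

    def validate(self) -> "Dims4D":
        if any(int(v) < 1 for v in self):
            raise EmkitError(f"all extents must be >= 1, got {tuple(self)}")
        if self.n > 1 and self.z > 1:
            raise EmkitError(
                "a file item is either a 2-D stack (z == 1) or a single "
                f"volume (n == 1), got n={self.n}, z={self.z}"
            )
        return Dims4D(*(int(v) for v in self))


def dtype_cast(
    buffer: np.ndarray,
    src: DType,
    dst: DType,
    policy: str = "round-clamp",
) -> np.ndarray:
    """Convert a buffer between supported element types.

    Widening casts are value-exact.  Narrowing casts to integer types round
    half-to-even and then either clamp to the destination range
    (``policy="round-clamp"``) or raise :class:`CastError`
    (``policy="error-on-overflow"``).
    """
    if policy not in ("round-clamp", "error-on-overflow"):
        raise EmkitError(f"unknown cast policy {policy!r}")
    src, dst = dtype(src), dtype(dst)
    arr = np.asarray(buffer, dtype=src.numpy)
    if src == dst:
        return arr.copy()
    if src.widens_to(dst):
        return arr.astype(dst.numpy)

    vals = arr.astype(np.float64)
    if dst.is_float:
        info = np.finfo(dst.numpy)
        over = np.abs(vals[np.isfinite(vals)]) > info.max
        if over.any() and policy == "error-on-overflow":
            raise CastError(f"value overflows {dst.name}")
        out = np.clip(vals, -float(info.max), float(info.max))
        return out.astype(dst.numpy)

    info = np.iinfo(dst.numpy)
    rounded = np.rint(vals)  # round half to even
    if policy == "error-on-overflow":
        if (rounded < info.min).any() or (rounded > info.max).any():
            raise CastError(
                f"value out of {dst.name} range "
                f"[{info.min}, {info.max}] under error-on-overflow policy"
            )
    rounded = np.clip(rounded, info.min, info.max)
    return rounded.astype(dst.numpy)


class ImageStats(NamedTuple):
    min: float
    max: float
    mean: float
    std: float


class Image:
    """Dense 4-D pixel container with optional physical sampling.

    Parameters
    ----------
    data:
        Array reshaped to ``(n, z, y, x)``; 2-D input is treated as a single
        image, 3-D input as a single volume.  The buffer is copied.
    pixel_size:
        Physical sampling in Angstrom per pixel, or None when unknown.
    header_meta:
        Free-form mapping of source-file header fields, kept for provenance.
    """

    def __init__(
        self,
        data: np.ndarray,
        pixel_size: Optional[float] = None,
        header_meta: Optional[Mapping] = None,
    ) -> None:
        arr = np.asarray(data)
        if arr.ndim == 2:
            arr = arr[np.newaxis, np.newaxis]
        elif arr.ndim == 3:
            arr = arr[np.newaxis]
        elif arr.ndim != 4:
            raise EmkitError(f"image data must be 2-D..4-D, got {arr.ndim}-D")
        self._dtype = dtype(arr.dtype)
        self._data = np.ascontiguousarray(arr, dtype=self._dtype.numpy).copy()
        self._dims = Dims4D(*self._data.shape).validate()
        if pixel_size is not None and not pixel_size > 0:
            raise EmkitError(f"pixel_size must be > 0, got {pixel_size}")
        self.pixel_size = float(pixel_size) if pixel_size is not None else None
        self.header_meta = dict(header_meta) if header_meta else {}

    # -- construction -----------------------------------------------------
    @classmethod
    def full(cls, dims: Iterable[int], dt, fill=0, policy: str = "error-on-overflow") -> "Image":
        """Create a constant image; raises if fill is not representable."""
        dims = Dims4D(*dims).validate()
        dt = dtype(dt)
        cell = dtype_cast(np.asarray([fill], dtype=np.float64), FLOAT64, dt, policy)
        return cls(np.full(tuple(dims), cell[0], dtype=dt.numpy))

    # -- basic properties -------------------------------------------------
    @property
    def data(self) -> np.ndarray:
        return self._data

    @property
    def dims(self) -> Dims4D:
        return self._dims

    @property
    def dtype(self) -> DType:
        return self._dtype

    @property
    def n_items(self) -> int:
        return self._dims.n

    def stats(self) -> ImageStats:
        """Min/max/mean and population (divide-by-N) standard deviation."""
        vals = self._data.astype(np.float64)
        return ImageStats(
            float(vals.min()), float(vals.max()),
            float(vals.mean()), float(vals.std(ddof=0)),
        )

    # -- item access ------------------------------------------------------
    def item(self, i: int) -> "Image":
        """Copy of the i-th stack item as a single image (n == 1)."""
        if not 0 <= i < self._dims.n:
            raise EmkitError(
                f"item index {i} out of range for stack of {self._dims.n}"
            )
        out = Image(self._data[i].copy(), pixel_size=self.pixel_size,
                    header_meta=self.header_meta)
        return out

    def astype(self, dt, policy: str = "round-clamp") -> "Image":
        dt = dtype(dt)
        cast = dtype_cast(self._data, self._dtype, dt, policy)
        return Image(cast.reshape(self._data.shape),
                     pixel_size=self.pixel_size, header_meta=self.header_meta)

    def copy(self) -> "Image":
        return Image(self._data, pixel_size=self.pixel_size,
                     header_meta=self.header_meta)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ps = f", pixel_size={self.pixel_size}" if self.pixel_size else ""
        return f"Image(dims={tuple(self._dims)}, dtype={self._dtype.name}{ps})"


def stack_items(items: Iterable[Image]) -> Image:
    """Assemble single images of identical geometry into one stack."""
    items = list(items)
    if not items:
        raise EmkitError("cannot stack zero images")
    shapes = {im.dims.item_shape for im in items}
    dts = {im.dtype for im in items}
    if len(shapes) != 1 or len(dts) != 1:
        raise EmkitError("stacked items must share geometry and dtype")
    if any(im.n_items != 1 for im in items):
        raise EmkitError("stack_items expects single images (n == 1)")
    data = np.stack([im.data[0] for im in items])
    return Image(data, pixel_size=items[0].pixel_size)


# Spec-level operation aliases -------------------------------------------

def image_create(dims, dt, fill=0) -> Image:
    return Image.full(dims, dt, fill)


def image_stats(img: Image) -> ImageStats:
    return img.stats()


def image_index(img: Image, i: int) -> Image:
    return img.item(i)
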