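"""Format-dispatched image file I/O: MRC2014 and SPIDER handlers.

The :class:`ImageFile` session object selects a concrete handler from the
file extension (or an explicit ``format=``) and presents one interface for
single images, 2-D stacks and 3-D volumes.  Both handlers are implemented
directly against the published format descriptions:

* MRC2014 — 1024-byte binary header, ``MAP `` magic, machine stamp for byte
  order, mode codes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16).
  Stacks are written with ``ispg=0, mz=1, nz=n``; volumes with
  ``ispg=1, mz=nz``.  Pixel size is ``cella/m``.
* SPIDER — all-float header whose length ``labbyt`` is the smallest whole
  number of ``lenbyt = 4*nsam`` byte records reaching 1024 bytes; pixel data
  are float32.  Single-image files (iform 1/3) are read and written; stack
  files (istack > 0) are read-only.

Files are always written little-endian; reads honour the byte order a file
declares and swap when needed.
"""

from __future__ import annotations

import math
import os
import struct
import tempfile
from typing import NamedTuple, Optional

import numpy as np

from .dtypes import (
    FLOAT32, FLOAT64, INT8, INT16, INT32, UINT8, UINT16,
    Dims4D, DType, Image, dtype, dtype_cast,
)
from .errors import EmkitError, FormatError

_EXT_FORMAT = {
    ".mrc": "mrc", ".mrcs": "mrc", ".map": "mrc",
    ".spi": "spider", ".spider": "spider", ".stk": "spider",
}

_MRC_MODE_TO_DTYPE = {0: INT8, 1: INT16, 2: FLOAT32, 6: UINT16}
_DTYPE_TO_MRC_MODE = {INT8: 0, INT16: 1, FLOAT32: 2, UINT16: 6}
# Lossless or clamped fallbacks for dtypes without a native MRC mode.
_MRC_FALLBACK = {UINT8: UINT16, INT32: FLOAT32, FLOAT64: FLOAT32}

_MACHST_LE = bytes((0x44, 0x44, 0x00, 0x00))


def format_from_path(path: str, explicit: Optional[str] = None) -> str:
    if explicit is not None:
        if explicit not in ("mrc", "spider"):
            raise EmkitError(f"unknown image format {explicit!r}")
        return explicit
    ext = os.path.splitext(str(path))[1].lower()
    try:
        return _EXT_FORMAT[ext]
    except KeyError:
        raise EmkitError(
            f"cannot infer image format from extension {ext!r}; "
            "pass format='mrc' or 'spider'"
        ) from None


class ProbeResult(NamedTuple):
    format: str
    dims: Dims4D
    dtype: DType
    pixel_size: Optional[float]


# ---------------------------------------------------------------------------
# MRC2014 handler
# ---------------------------------------------------------------------------

class _MrcHeader(NamedTuple):
    nx: int
    ny: int
    nz: int
    mode: int
    mx: int
    my: int
    mz: int
    cella: tuple
    dmin: float
    dmax: float
    dmean: float
    ispg: int
    nsymbt: int
    rms: float
    byte_order: str  # "<" or ">"

    @property
    def dims(self) -> Dims4D:
        # ispg 0 with nz > 1 is a stack of 2-D images; ispg >= 1 a volume.
        if self.ispg == 0 and self.nz > 1:
            return Dims4D(self.nz, 1, self.ny, self.nx)
        return Dims4D(1, self.nz, self.ny, self.nx)

    @property
    def pixel_size(self) -> Optional[float]:
        if self.mx > 0 and self.cella[0] > 0:
            return self.cella[0] / self.mx
        return None


def _read_mrc_header(raw: bytes) -> _MrcHeader:
    if len(raw) < 1024:
        raise FormatError("malformed MRC header: file shorter than 1024 bytes")
    if raw[208:212] != b"MAP ":
        raise FormatError("malformed MRC header: missing 'MAP ' magic")
    machst = raw[212:216]
    bo = ">" if machst[0] == 0x11 else "<"
    ints = struct.unpack(bo + "10i", raw[0:40])
    nx, ny, nz, mode = ints[0], ints[1], ints[2], ints[3]
    mx, my, mz = ints[7], ints[8], ints[9]
    cella = struct.unpack(bo + "3f", raw[40:52])
    dmin, dmax, dmean = struct.unpack(bo + "3f", raw[76:88])
    ispg, nsymbt = struct.unpack(bo + "2i", raw[88:96])
    (rms,) = struct.unpack(bo + "f", raw[216:220])
    if mode not in _MRC_MODE_TO_DTYPE:
        raise FormatError(f"unsupported MRC mode {mode}")
    if min(nx, ny, nz) < 1 or nsymbt < 0:
        raise FormatError("malformed MRC header: non-positive extents")
    return _MrcHeader(nx, ny, nz, mode, mx, my, mz, cella,
                      dmin, dmax, dmean, ispg, nsymbt, rms, bo)


def _pack_mrc_header(img: Image, mode: int, is_stack: bool) -> bytes:
    dims = img.dims
    nz = dims.n if is_stack else dims.z
    mz = 1 if is_stack else dims.z
    ispg = 0 if is_stack else 1
    ps = img.pixel_size
    cella = (
        (ps * dims.x, ps * dims.y, ps * mz) if ps is not None else (0.0, 0.0, 0.0)
    )
    st = img.stats()
    h = bytearray(1024)
    struct.pack_into("<10i", h, 0, dims.x, dims.y, nz, mode,
                     0, 0, 0, dims.x, dims.y, mz)
    struct.pack_into("<6f", h, 40, *cella, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", h, 64, 1, 2, 3)  # mapc/mapr/maps
    struct.pack_into("<3f", h, 76, st.min, st.max, st.mean)
    struct.pack_into("<2i", h, 88, ispg, 0)  # ispg, nsymbt
    struct.pack_into("<i", h, 108, 20140)    # nversion
    h[208:212] = b"MAP "
    h[212:216] = _MACHST_LE
    struct.pack_into("<f", h, 216, st.std)
    return bytes(h)


class _MrcHandler:
    name = "mrc"

    @staticmethod
    def probe_bytes(raw: bytes):
        hdr = _read_mrc_header(raw)
        return hdr.dims, _MRC_MODE_TO_DTYPE[hdr.mode], hdr.pixel_size, hdr

    @staticmethod
    def read(path: str) -> Image:
        with open(path, "rb") as fh:
            raw = fh.read()
        hdr = _read_mrc_header(raw)
        dt = _MRC_MODE_TO_DTYPE[hdr.mode]
        dims = hdr.dims
        offset = 1024 + hdr.nsymbt
        nbytes = dims.total * dt.numpy.itemsize
        if len(raw) < offset + nbytes:
            raise FormatError("truncated MRC data section")
        buf = np.frombuffer(raw, dtype=dt.numpy.newbyteorder(hdr.byte_order),
                            count=dims.total, offset=offset)
        data = buf.astype(dt.numpy).reshape(tuple(dims))
        meta = {
            "mrc_mode": hdr.mode, "ispg": hdr.ispg, "nsymbt": hdr.nsymbt,
            "cella": tuple(hdr.cella), "mx": hdr.mx, "my": hdr.my, "mz": hdr.mz,
            "dmin": hdr.dmin, "dmax": hdr.dmax, "dmean": hdr.dmean,
            "rms": hdr.rms,
        }
        if hdr.nsymbt:
            meta["extended_header"] = raw[1024:1024 + hdr.nsymbt]
        return Image(data, pixel_size=hdr.pixel_size, header_meta=meta)

    @staticmethod
    def write(path: str, img: Image, dtype_policy: str = "round-clamp") -> None:
        dt = img.dtype
        if dt not in _DTYPE_TO_MRC_MODE:
            target = _MRC_FALLBACK[dt]
            if dtype_policy == "error-on-overflow" and dt in (INT32, FLOAT64):
                raise EmkitError(
                    f"{dt.name} has no exact MRC mode; refusing under "
                    "error-on-overflow policy"
                )
            img = img.astype(target, policy="round-clamp")
            dt = target
        mode = _DTYPE_TO_MRC_MODE[dt]
        is_stack = img.dims.z == 1 and img.dims.n >= 1
        header = _pack_mrc_header(img, mode, is_stack)
        data = np.ascontiguousarray(img.data, dtype=dt.numpy.newbyteorder("<"))
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# SPIDER handler
# ---------------------------------------------------------------------------

def _spider_geometry(nsam: int):
    lenbyt = nsam * 4
    labrec = max(1, math.ceil(1024 / lenbyt))
    return labrec, labrec * lenbyt, lenbyt


class _SpiderHeader(NamedTuple):
    nslice: int
    nrow: int
    nsam: int
    iform: int
    labrec: int
    labbyt: int
    lenbyt: int
    istack: int
    maxim: int
    scale: float
    byte_order: str


def _parse_spider_header(raw: bytes, offset: int = 0) -> _SpiderHeader:
    if len(raw) < offset + 1024:
        raise FormatError("malformed SPIDER header: fewer than 1024 bytes")
    for bo in ("<", ">"):
        vals = np.frombuffer(raw, dtype=bo + "f4", count=27, offset=offset)
        nslice, nrow, nsam = vals[0], vals[1], vals[11]
        iform, labrec, labbyt, lenbyt = vals[4], vals[12], vals[21], vals[22]
        istack, maxim = vals[23], vals[25]
        ok = (
            all(np.isfinite(vals[:27]))
            and nsam >= 1 and nrow >= 1 and nslice >= 1
            and float(nsam).is_integer() and float(nrow).is_integer()
            and float(nslice).is_integer()
            and lenbyt == nsam * 4
            and labbyt == labrec * lenbyt
            and labbyt >= 1024
            and iform in (1.0, 3.0)
        )
        if ok:
            return _SpiderHeader(
                int(nslice), int(nrow), int(nsam), int(iform), int(labrec),
                int(labbyt), int(lenbyt), int(istack), int(maxim),
                float(vals[20]), bo,
            )
    raise FormatError("malformed SPIDER header: geometry check failed")


def _spider_dims(hdr: _SpiderHeader) -> Dims4D:
    if hdr.istack > 0:
        return Dims4D(hdr.maxim, hdr.nslice, hdr.nrow, hdr.nsam)
    if hdr.iform == 3:
        return Dims4D(1, hdr.nslice, hdr.nrow, hdr.nsam)
    return Dims4D(1, 1, hdr.nrow, hdr.nsam)


def _pack_spider_header(img: Image) -> bytes:
    dims = img.dims
    if dims.n != 1:
        raise EmkitError("SPIDER writer only supports single-image files")
    labrec, labbyt, lenbyt = _spider_geometry(dims.x)
    st = img.stats()
    hdr = np.zeros(labbyt // 4, dtype="<f4")
    hdr[0] = dims.z                 # nslice
    hdr[1] = dims.y                 # nrow
    hdr[2] = dims.z * dims.y        # irec: total data records
    hdr[4] = 3.0 if dims.z > 1 else 1.0   # iform
    hdr[5] = 1.0                    # imami: statistics are valid
    hdr[6] = st.max
    hdr[7] = st.min
    hdr[8] = st.mean
    hdr[9] = st.std
    hdr[11] = dims.x                # nsam
    hdr[12] = labrec
    hdr[20] = img.pixel_size or 0.0  # scale field carries the sampling
    hdr[21] = labbyt
    hdr[22] = lenbyt
    return hdr.tobytes()


class _SpiderHandler:
    name = "spider"

    @staticmethod
    def probe_bytes(raw: bytes):
        hdr = _parse_spider_header(raw)
        ps = hdr.scale if hdr.scale > 0 else None
        return _spider_dims(hdr), FLOAT32, ps, hdr

    @staticmethod
    def read(path: str) -> Image:
        with open(path, "rb") as fh:
            raw = fh.read()
        hdr = _parse_spider_header(raw)
        dims = _spider_dims(hdr)
        dt = np.dtype(hdr.byte_order + "f4")
        item_count = hdr.nslice * hdr.nrow * hdr.nsam
        items = []
        if hdr.istack > 0:
            offset = hdr.labbyt  # overall stack header
            for _ in range(dims.n):
                offset += hdr.labbyt  # per-image header
                end = offset + item_count * 4
                if len(raw) < end:
                    raise FormatError("truncated SPIDER stack data")
                items.append(np.frombuffer(raw, dtype=dt, count=item_count,
                                           offset=offset))
                offset = end
        else:
            offset = hdr.labbyt
            if len(raw) < offset + item_count * 4:
                raise FormatError("truncated SPIDER data section")
            items.append(np.frombuffer(raw, dtype=dt, count=item_count,
                                       offset=offset))
        data = np.stack([it.astype(np.float32) for it in items]).reshape(tuple(dims))
        meta = {"iform": hdr.iform, "labrec": hdr.labrec, "labbyt": hdr.labbyt,
                "lenbyt": hdr.lenbyt, "istack": hdr.istack}
        ps = hdr.scale if hdr.scale > 0 else None
        return Image(data, pixel_size=ps, header_meta=meta)

    @staticmethod
    def write(path: str, img: Image, dtype_policy: str = "round-clamp") -> None:
        img32 = img.astype(FLOAT32, policy=dtype_policy)
        header = _pack_spider_header(img32)
        data = np.ascontiguousarray(img32.data, dtype="<f4")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(data.tobytes())


_HANDLERS = {"mrc": _MrcHandler, "spider": _SpiderHandler}


# ---------------------------------------------------------------------------
# Session object and module-level API
# ---------------------------------------------------------------------------

class ImageFile:
    """Open file session bound to one format handler.

    Modes: ``"r"`` (read), ``"w"`` (write a new file), ``"r+"``
    (read-modify-write).  In the write modes, items are collected in memory
    and the file — header statistics included — is written on :meth:`close`,
    so a handle that errors out leaves no partially-written file behind.
    """

    def __init__(self, path, mode: str = "r", format: Optional[str] = None,
                 dtype_policy: str = "round-clamp") -> None:
        if mode not in ("r", "w", "r+"):
            raise EmkitError(f"unknown mode {mode!r}")
        self.path = str(path)
        self.mode = mode
        self.format = format_from_path(self.path, format)
        self._handler = _HANDLERS[self.format]
        self._dtype_policy = dtype_policy
        self._closed = False
        self._items: list = []       # write-side buffer of Image items, n==1
        self._cached: Optional[Image] = None
        self.pixel_size: Optional[float] = None

        if mode in ("r", "r+"):
            if os.path.isdir(self.path):
                raise EmkitError(f"{self.path} is a directory")
            if not os.path.exists(self.path):
                raise EmkitError(f"no such file: {self.path}")
            whole = self._handler.read(self.path)
            self._cached = whole
            self.pixel_size = whole.pixel_size
            if mode == "r+":
                self._items = [whole.item(i) for i in range(whole.n_items)]

    # -- metadata ---------------------------------------------------------
    @property
    def dims(self) -> Optional[Dims4D]:
        if self._cached is not None and self.mode == "r":
            return self._cached.dims
        if self._items:
            z, y, x = self._items[0].dims.item_shape
            return Dims4D(len(self._items), z, y, x)
        return self._cached.dims if self._cached is not None else None

    @property
    def dtype(self) -> Optional[DType]:
        if self._cached is not None and self.mode == "r":
            return self._cached.dtype
        if self._items:
            return self._items[0].dtype
        return self._cached.dtype if self._cached is not None else None

    @property
    def n_images(self) -> int:
        d = self.dims
        return d.n if d is not None else 0

    # -- reading ----------------------------------------------------------
    def read(self, index: int = 0) -> Image:
        self._check_open()
        if self.mode == "w":
            raise EmkitError("handle opened write-only")
        src = self._cached
        if self.mode == "r+":
            if not 0 <= index < len(self._items):
                raise EmkitError(f"image index {index} out of range")
            return self._items[index].copy()
        return src.item(index)

    def read_all(self) -> Image:
        self._check_open()
        if self.mode == "w":
            raise EmkitError("handle opened write-only")
        return self._cached.copy()

    # -- writing ----------------------------------------------------------
    def write(self, img: Image, index: Optional[int] = None) -> None:
        self._check_open()
        if self.mode == "r":
            raise EmkitError("handle opened read-only")
        items = [img.item(i) for i in range(img.n_items)]
        if index is None:
            index = len(self._items)
        if index > len(self._items):
            raise EmkitError(
                f"sparse write: index {index} but file holds {len(self._items)}"
            )
        if self.format == "spider" and (index > 0 or len(items) > 1):
            raise EmkitError("SPIDER writer only supports single-image files")
        snapshot = list(self._items)
        for off, it in enumerate(items):
            pos = index + off
            if pos < len(self._items):
                self._items[pos] = it
            else:
                self._items.append(it)
        shapes = {it.dims.item_shape for it in self._items}
        dts = {it.dtype for it in self._items}
        if len(shapes) != 1 or len(dts) != 1:
            self._items = snapshot
            raise EmkitError("all items in a file must share geometry and dtype")
        if img.pixel_size is not None:
            self.pixel_size = img.pixel_size

    # -- lifecycle --------------------------------------------------------
    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        if self.mode == "r" or not self._items:
            return
        from .dtypes import stack_items

        whole = stack_items(self._items)
        if self.pixel_size is not None:
            whole.pixel_size = self.pixel_size
        # write to a sibling temp file, then atomically replace
        d = os.path.dirname(os.path.abspath(self.path)) or "."
        fd, tmp = tempfile.mkstemp(prefix=".emkit-", dir=d)
        os.close(fd)
        try:
            self._handler.write(tmp, whole, self._dtype_policy)
            os.replace(tmp, self.path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    def _check_open(self) -> None:
        if self._closed:
            raise EmkitError("operation on closed ImageFile")

    def __enter__(self) -> "ImageFile":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            self.close()
        else:
            self._closed = True  # drop buffered items, leave no output


def open_image_file(path, mode: str = "r", format: Optional[str] = None,
                    **kw) -> ImageFile:
    return ImageFile(path, mode=mode, format=format, **kw)


def probe(path, format: Optional[str] = None) -> ProbeResult:
    """Header-only inspection: format, dims, dtype and pixel size."""
    if os.path.isdir(str(path)):
        raise EmkitError(f"{path} is a directory")
    if not os.path.exists(str(path)):
        raise EmkitError(f"no such file: {path}")
    fmt = format_from_path(str(path), format)
    with open(path, "rb") as fh:
        raw = fh.read(4096)
    dims, dt, ps, _ = _HANDLERS[fmt].probe_bytes(raw)
    return ProbeResult(fmt, dims, dt, ps)


def load(path, index: Optional[int] = None, format: Optional[str] = None) -> Image:
    """Read a whole file, or a single 0-based stack item if index is given."""
    with ImageFile(path, "r", format=format) as fh:
        return fh.read(index) if index is not None else fh.read_all()


def save(img: Image, path, format: Optional[str] = None,
         dtype_policy: str = "round-clamp") -> None:
    """Write an image to a new file atomically (temp file + rename)."""
    with ImageFile(path, "w", format=format, dtype_policy=dtype_policy) as fh:
        fh.write(img)
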