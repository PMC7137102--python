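"""Deterministic test inputs and independent format/transform oracles.

Everything the test suite consumes is generated here at run time: phantom
images, byte-level MRC2014 and SPIDER reference files, a toy STAR document
and a direct O(N^2) DFT.  The reference writers and parsers are implemented
straight from the public format descriptions using ``struct``/raw numpy
buffers and deliberately share no code with :mod:`emkit.imgio`,
:mod:`emkit.tableio` or :mod:`emkit.fourier` — agreement between the two
independent implementations is what the cross-validation tests check.
"""

from __future__ import annotations

import argparse
import math
import os
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dtypes import Dims4D, DType, FLOAT32, Image, dtype
from .errors import EmkitError

PATTERNS = ("constant", "impulse", "checkerboard", "gaussian-blob",
            "uniform-noise")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a deterministic phantom image."""

    dims: Tuple[int, int, int, int]
    pattern: str = "gaussian-blob"
    seed: int = 0
    dtype: str = "float32"
    value: float = 1.0  # constant fill / impulse height

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise EmkitError(f"unknown phantom pattern {self.pattern!r}")
        Dims4D(*self.dims).validate()
        dtype(self.dtype)


def make_phantom(spec: PhantomSpec) -> Image:
    """Deterministic phantom: same spec and seed give identical buffers."""
    dims = Dims4D(*spec.dims)
    dt = dtype(spec.dtype).numpy
    n, z, y, x = dims
    if spec.pattern == "constant":
        data = np.full(tuple(dims), spec.value, dtype=dt)
    elif spec.pattern == "impulse":
        data = np.zeros(tuple(dims), dtype=dt)
        data[:, z // 2, y // 2, x // 2] = spec.value
    elif spec.pattern == "checkerboard":
        idx = np.indices((z, y, x)).sum(axis=0) % 2
        data = np.broadcast_to(idx.astype(dt), tuple(dims)).copy()
    elif spec.pattern == "gaussian-blob":
        sigma = min(y, x) / 6.0
        yy = np.arange(y) - y / 2.0
        xx = np.arange(x) - x / 2.0
        blob = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2 * sigma**2))
        data = np.broadcast_to(blob.astype(dt), tuple(dims)).copy()
    else:  # uniform-noise
        rng = np.random.default_rng(spec.seed)
        if dtype(spec.dtype).is_float:
            data = rng.random(tuple(dims)).astype(dt)
        else:
            # [0, 1) collapses to zero for integers; use a small safe range
            data = rng.integers(0, 100, size=tuple(dims)).astype(dt)
    return Image(data)


# ---------------------------------------------------------------------------
# MRC2014 reference writer / parser (independent of emkit.imgio)
# ---------------------------------------------------------------------------

_REF_MRC_MODE = {"int8": 0, "int16": 1, "float32": 2, "uint16": 6}
_REF_MODE_NP = {0: "i1", 1: "<i2", 2: "<f4", 6: "<u2"}


def write_reference_mrc(path, spec: PhantomSpec,
                        pixel_size: Optional[float] = None,
                        as_volume: Optional[bool] = None) -> np.ndarray:
    """Write an MRC file byte-by-byte from the format field table.

    Returns the retained source buffer (shape (n, z, y, x)) for bit-exact
    comparison.  Stacks get ispg=0/mz=1; volumes ispg=1/mz=nz.
    """
    img = make_phantom(spec)
    buf = img.data
    n, z, y, x = img.dims
    if spec.dtype not in _REF_MRC_MODE:
        raise EmkitError(f"no MRC mode for {spec.dtype}")
    mode = _REF_MRC_MODE[spec.dtype]
    volume = (z > 1) if as_volume is None else as_volume
    nz = z if volume else n
    mz = z if volume else 1
    ispg = 1 if volume else 0
    vals = buf.astype(np.float64)
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, x, y, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)          # nstart
    struct.pack_into("<3i", header, 28, x, y, mz)         # sampling grid
    if pixel_size:
        struct.pack_into("<3f", header, 40,
                         pixel_size * x, pixel_size * y, pixel_size * mz)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, vals.min(), vals.max(), vals.mean())
    struct.pack_into("<2i", header, 88, ispg, 0)
    struct.pack_into("<i", header, 108, 20140)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))
    struct.pack_into("<f", header, 216, vals.std())
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(
            buf, dtype=np.dtype(_REF_MODE_NP[mode])).tobytes())
    return buf


def parse_mrc_header(path) -> Dict[str, object]:
    """Minimal field-by-field MRC header parse for cross-validation."""
    with open(path, "rb") as fh:
        raw = fh.read(1024)
    if len(raw) < 1024:
        raise EmkitError("reference parser: short MRC header")
    bo = ">" if raw[212] == 0x11 else "<"
    nx, ny, nz, mode = struct.unpack(bo + "4i", raw[0:16])
    mx, my, mz = struct.unpack(bo + "3i", raw[28:40])
    cella = struct.unpack(bo + "3f", raw[40:52])
    dmin, dmax, dmean = struct.unpack(bo + "3f", raw[76:88])
    ispg, nsymbt = struct.unpack(bo + "2i", raw[88:96])
    (rms,) = struct.unpack(bo + "f", raw[216:220])
    return {
        "nx": nx, "ny": ny, "nz": nz, "mode": mode,
        "mx": mx, "my": my, "mz": mz, "cella": cella,
        "dmin": dmin, "dmax": dmax, "dmean": dmean,
        "ispg": ispg, "nsymbt": nsymbt, "rms": rms,
        "map_id": raw[208:212], "machst": raw[212:216],
    }


def read_reference_mrc_data(path) -> np.ndarray:
    """Parse header + data with the reference parser only."""
    hdr = parse_mrc_header(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    bo = ">" if hdr["machst"][0] == 0x11 else "<"
    np_dt = np.dtype(_REF_MODE_NP[hdr["mode"]]).newbyteorder(bo)
    count = hdr["nx"] * hdr["ny"] * hdr["nz"]
    data = np.frombuffer(raw, dtype=np_dt, count=count,
                         offset=1024 + hdr["nsymbt"])
    if hdr["ispg"] == 0 and hdr["nz"] > 1:
        shape = (hdr["nz"], 1, hdr["ny"], hdr["nx"])
    else:
        shape = (1, hdr["nz"], hdr["ny"], hdr["nx"])
    return data.reshape(shape)


# ---------------------------------------------------------------------------
# SPIDER reference writer / parser
# ---------------------------------------------------------------------------

def write_reference_spider(path, spec: PhantomSpec,
                           pixel_size: Optional[float] = None) -> np.ndarray:
    """Write a single-image SPIDER file from the header field table."""
    img = make_phantom(spec)
    n, z, y, x = img.dims
    if n != 1:
        raise EmkitError("SPIDER reference writer: single image only")
    buf = img.data.astype("<f4")
    lenbyt = x * 4
    labrec = max(1, math.ceil(1024 / lenbyt))
    labbyt = labrec * lenbyt
    vals = buf.astype(np.float64)
    hdr = np.zeros(labbyt // 4, dtype="<f4")
    hdr[0] = z                      # nslice
    hdr[1] = y                      # nrow
    hdr[2] = z * y                  # irec
    hdr[4] = 3.0 if z > 1 else 1.0  # iform
    hdr[5] = 1.0                    # imami
    hdr[6] = vals.max()
    hdr[7] = vals.min()
    hdr[8] = vals.mean()
    hdr[9] = vals.std()
    hdr[11] = x                     # nsam
    hdr[12] = labrec
    hdr[20] = pixel_size or 0.0     # scale
    hdr[21] = labbyt
    hdr[22] = lenbyt
    with open(path, "wb") as fh:
        fh.write(hdr.tobytes())
        fh.write(np.ascontiguousarray(buf).tobytes())
    return img.data


def parse_spider_header(path) -> Dict[str, float]:
    with open(path, "rb") as fh:
        raw = fh.read(108)
    vals = np.frombuffer(raw, dtype="<f4", count=27)
    return {
        "nslice": float(vals[0]), "nrow": float(vals[1]),
        "iform": float(vals[4]), "nsam": float(vals[11]),
        "labrec": float(vals[12]), "scale": float(vals[20]),
        "labbyt": float(vals[21]), "lenbyt": float(vals[22]),
        "istack": float(vals[23]), "maxim": float(vals[25]),
    }


def read_reference_spider_data(path) -> np.ndarray:
    hdr = parse_spider_header(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    z, y, x = int(hdr["nslice"]), int(hdr["nrow"]), int(hdr["nsam"])
    data = np.frombuffer(raw, dtype="<f4", count=z * y * x,
                         offset=int(hdr["labbyt"]))
    return data.reshape((1, z, y, x))


# ---------------------------------------------------------------------------
# Toy STAR document (written by a minimal serializer, parsed independently)
# ---------------------------------------------------------------------------

TOY_STAR_COLUMNS = ("id", "defocus", "name", "score")
TOY_STAR_ROWS = (
    (1, 1.2, "mic_a", 0.5),
    (2, 2.5, "mic_b", 1.5),
    (3, 1.8, "mic c", 2.5),
    (4, 3.0, "mic_d", None),  # None -> missing marker "."
)


def make_toy_star(path) -> None:
    """Write the toy micrograph table with a serializer of its own."""
    lines = ["data_micrographs", "", "loop_"]
    for j, name in enumerate(TOY_STAR_COLUMNS, start=1):
        lines.append(f"_{name} #{j}")
    for rid, defocus, name, score in TOY_STAR_ROWS:
        nm = f'"{name}"' if " " in name else name
        sc = "." if score is None else repr(score)
        lines.append(f"{rid} {repr(defocus)} {nm} {sc}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def parse_star_minimal(path) -> Dict[str, Tuple[List[str], List[List[str]]]]:
    """Tiny independent STAR reader: block -> (labels, raw string rows)."""
    blocks: Dict[str, Tuple[List[str], List[List[str]]]] = {}
    labels: List[str] = []
    values: List[str] = []
    block = None
    in_loop = False

    def close_loop():
        nonlocal labels, values, in_loop
        if block is not None and labels:
            ncol = len(labels)
            if len(values) % ncol:
                raise EmkitError("reference parser: ragged loop")
            rows = [values[k:k + ncol] for k in range(0, len(values), ncol)]
            blocks[block] = (list(labels), rows)
        labels, values, in_loop = [], [], False

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("data_"):
                close_loop()
                block = s[5:]
            elif s == "loop_":
                close_loop()
                in_loop = True
            elif s.startswith("_"):
                labels.append(s.split()[0][1:])
            else:
                toks = []
                i = 0
                while i < len(s):
                    if s[i].isspace():
                        i += 1
                    elif s[i] in "'\"":
                        j = s.index(s[i], i + 1)
                        toks.append(s[i + 1:j])
                        i = j + 1
                    else:
                        j = i
                        while j < len(s) and not s[j].isspace():
                            j += 1
                        toks.append(s[i:j])
                        i = j
                values.extend(toks)
    close_loop()
    return blocks


# ---------------------------------------------------------------------------
# Direct DFT oracle
# ---------------------------------------------------------------------------

MAX_DFT_ELEMENTS = 4096


def naive_dft(buffer: np.ndarray) -> np.ndarray:
    """Full complex spectrum by direct evaluation of the DFT sum.

    Accepts a 2-D or 3-D real array; evaluates sum_x f(x) e^{-2πi k·x/N}
    via explicitly constructed exponential matrices (no FFT algorithm).
    Capped at 4096 elements to keep the suite fast.
    """
    arr = np.asarray(buffer, dtype=np.float64)
    if arr.size > MAX_DFT_ELEMENTS:
        raise EmkitError(
            f"naive_dft capped at {MAX_DFT_ELEMENTS} elements, got {arr.size}"
        )
    out = arr.astype(np.complex128)
    for ax, n in enumerate(arr.shape):
        k = np.arange(n)
        w = np.exp(-2j * np.pi * np.outer(k, k) / n)
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, ax, 0), axes=1),
                          0, ax)
    return out


def naive_idft(spectrum: np.ndarray) -> np.ndarray:
    """Direct inverse DFT (applies 1/N); returns the complex result."""
    spec = np.asarray(spectrum, dtype=np.complex128)
    out = spec.copy()
    for ax, n in enumerate(spec.shape):
        k = np.arange(n)
        w = np.exp(2j * np.pi * np.outer(k, k) / n) / n
        out = np.moveaxis(np.tensordot(w, np.moveaxis(out, ax, 0), axes=1),
                          0, ax)
    return out


def naive_spectral_resize(buffer: np.ndarray,
                          new_shape: Tuple[int, ...]) -> np.ndarray:
    """Brute-force Fourier crop/pad: full DFT, centred frequency block,
    renormalize, Hermitian-symmetrize, inverse — all with the direct sums."""
    arr = np.asarray(buffer, dtype=np.float64)
    full = naive_dft(arr)
    out = np.zeros(new_shape, dtype=np.complex128)
    # map retained frequencies f in [-N2/2, N2/2) between grids, per axis
    def freqs(n_old, n_new):
        half = min(n_old, n_new) // 2
        fs = list(range(0, half)) + list(range(-half, 0))
        return [(f % n_old, f % n_new) for f in fs]

    axes_maps = [freqs(o, m) for o, m in zip(arr.shape, new_shape)]
    import itertools
    for combo in itertools.product(*axes_maps):
        src = tuple(c[0] for c in combo)
        dst = tuple(c[1] for c in combo)
        out[dst] = full[src]
    out *= np.prod(new_shape) / arr.size
    rev = out
    for ax in range(out.ndim):
        rev = np.roll(np.flip(rev, axis=ax), 1, axis=ax)
    out = 0.5 * (out + np.conj(rev))
    return naive_idft(out).real


# ---------------------------------------------------------------------------
# materialize the whole set for manual inspection
# ---------------------------------------------------------------------------

def write_fixture_set(outdir, seed: int = 0) -> List[str]:
    os.makedirs(outdir, exist_ok=True)
    written = []

    def p(name):
        written.append(os.path.join(outdir, name))
        return written[-1]

    write_reference_mrc(p("stack_16x16x10.mrcs"),
                        PhantomSpec((10, 1, 16, 16), "uniform-noise", seed),
                        pixel_size=1.0)
    write_reference_mrc(p("volume_16x16x8.mrc"),
                        PhantomSpec((1, 8, 16, 16), "uniform-noise", seed + 1),
                        pixel_size=1.5)
    write_reference_mrc(p("single_int8.mrc"),
                        PhantomSpec((1, 1, 16, 16), "uniform-noise", seed + 2,
                                    dtype="int8"))
    write_reference_spider(p("single_16x16.spi"),
                           PhantomSpec((1, 1, 16, 16), "uniform-noise",
                                       seed + 3))
    write_reference_spider(p("volume_16x16x8.spi"),
                           PhantomSpec((1, 8, 16, 16), "uniform-noise",
                                       seed + 4))
    make_toy_star(p("toy.star"))
    return written


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(
        prog="em-fixtures",
        description="materialize the deterministic fixture set",
    )
    ap.add_argument("outdir")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)
    for path in write_fixture_set(args.outdir, args.seed):
        print(path)
    return 0
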