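"""MRC2014/SPIDER round-trips and cross-validation against the independent
byte-level reference writers and parsers in the fixtures module."""

import numpy as np
import pytest

import emkit
from emkit import (
    EmkitError, FLOAT32, FLOAT64, FormatError, Image, ImageFile,
    SUPPORTED_DTYPES, load, probe, save,
)
from emkit import fixtures
from emkit.fixtures import PhantomSpec

GEOMETRIES = [  # (n, z, y, x) covering single 2-D, stacks, volumes
    (1, 1, 16, 16), (1, 1, 8, 12),
    (2, 1, 16, 16), (10, 1, 16, 16),
    (1, 2, 16, 16), (1, 8, 16, 16),
]


def phantom(dims, dt, seed=3):
    return fixtures.make_phantom(
        PhantomSpec(dims, "uniform-noise", seed=seed, dtype=dt.name))


class TestMrcRoundTrip:
    @pytest.mark.parametrize("dims", GEOMETRIES, ids=str)
    @pytest.mark.parametrize("dt", [d for d in SUPPORTED_DTYPES
                                    if d.name in ("int8", "int16", "float32",
                                                  "uint16")],
                             ids=lambda d: d.name)
    def test_write_read_bit_exact(self, tmp_path, dims, dt):
        img = phantom(dims, dt)
        path = tmp_path / "img.mrc"
        save(img, path)
        back = load(path)
        assert back.dtype == dt
        assert tuple(back.dims) == dims
        assert back.data.tobytes() == img.data.tobytes()
        meta = probe(path)
        assert meta.format == "mrc"
        assert tuple(meta.dims) == dims and meta.dtype == dt

    def test_pixel_size_round_trip_and_unset(self, tmp_path):
        img = phantom((1, 1, 16, 16), FLOAT32)
        img.pixel_size = 1.25
        save(img, tmp_path / "a.mrc")
        assert load(tmp_path / "a.mrc").pixel_size == pytest.approx(1.25)
        img.pixel_size = None
        save(img, tmp_path / "b.mrc")
        assert load(tmp_path / "b.mrc").pixel_size is None  # cella=0, not 0

    def test_header_statistics_match_image_stats(self, tmp_path):
        img = phantom((10, 1, 16, 16), FLOAT32)
        save(img, tmp_path / "s.mrcs")
        hdr = fixtures.parse_mrc_header(tmp_path / "s.mrcs")
        st = img.stats()
        assert hdr["dmin"] == pytest.approx(st.min, rel=1e-6)
        assert hdr["dmax"] == pytest.approx(st.max, rel=1e-6)
        assert hdr["dmean"] == pytest.approx(st.mean, rel=1e-6)
        assert hdr["rms"] == pytest.approx(st.std, rel=1e-6)

    def test_stack_volume_disambiguation(self, tmp_path):
        save(phantom((10, 1, 16, 16), FLOAT32), tmp_path / "stack.mrcs")
        hdr = fixtures.parse_mrc_header(tmp_path / "stack.mrcs")
        assert (hdr["ispg"], hdr["mz"], hdr["nz"]) == (0, 1, 10)
        save(phantom((1, 8, 16, 16), FLOAT32), tmp_path / "vol.mrc")
        hdr = fixtures.parse_mrc_header(tmp_path / "vol.mrc")
        assert (hdr["ispg"], hdr["mz"], hdr["nz"]) == (1, 8, 8)
        assert tuple(load(tmp_path / "vol.mrc").dims) == (1, 8, 16, 16)

    def test_big_endian_read_is_byte_swapped(self, tmp_path):
        """A byte-swapped file with the big-endian stamp reads identically."""
        img = phantom((1, 1, 8, 8), FLOAT32)
        save(img, tmp_path / "le.mrc")
        raw = bytearray((tmp_path / "le.mrc").read_bytes())
        head = np.frombuffer(bytes(raw[:1024]), dtype="<i4").byteswap()
        data = np.frombuffer(bytes(raw[1024:]), dtype="<f4").byteswap()
        swapped = bytearray(head.tobytes() + data.tobytes())
        swapped[208:212] = b"MAP "
        swapped[212:216] = bytes((0x11, 0x11, 0x00, 0x00))
        (tmp_path / "be.mrc").write_bytes(bytes(swapped))
        back = load(tmp_path / "be.mrc")
        assert np.array_equal(back.data, img.data)


class TestSpiderRoundTrip:
    @pytest.mark.parametrize("dims", [(1, 1, 16, 16), (1, 1, 8, 12),
                                      (1, 2, 16, 16), (1, 8, 16, 16)],
                             ids=str)
    def test_write_read_bit_exact(self, tmp_path, dims):
        img = phantom(dims, FLOAT32)
        path = tmp_path / "img.spi"
        save(img, path)
        back = load(path)
        assert back.data.tobytes() == img.data.tobytes()
        meta = probe(path)
        assert meta.format == "spider" and tuple(meta.dims) == dims

    def test_integer_input_is_widened_to_float32(self, tmp_path):
        img = phantom((1, 1, 16, 16), emkit.INT8)
        save(img, tmp_path / "a.spi")
        back = load(tmp_path / "a.spi")
        assert back.dtype == FLOAT32
        assert np.array_equal(back.data, img.data.astype(np.float32))

    def test_header_geometry_fields(self, tmp_path):
        save(phantom((1, 1, 16, 16), FLOAT32), tmp_path / "a.spi")
        hdr = fixtures.parse_spider_header(tmp_path / "a.spi")
        assert hdr["lenbyt"] == 16 * 4
        assert hdr["labbyt"] == hdr["labrec"] * hdr["lenbyt"]
        assert hdr["labbyt"] >= 1024
        assert hdr["iform"] == 1.0

    def test_stack_write_unsupported(self, tmp_path):
        img = phantom((3, 1, 8, 8), FLOAT32)
        with pytest.raises(EmkitError):
            save(img, tmp_path / "stack.stk")
        assert not (tmp_path / "stack.stk").exists()


class TestCrossValidation:
    """Agreement with the independent byte-level reference implementation."""

    def test_reference_mrc_stack_reads_bit_exact(self, tmp_path):
        spec = PhantomSpec((10, 1, 16, 16), "uniform-noise", seed=42)
        buf = fixtures.write_reference_mrc(tmp_path / "ref.mrcs", spec,
                                           pixel_size=1.0)
        meta = probe(tmp_path / "ref.mrcs")
        assert (meta.format, tuple(meta.dims)) == ("mrc", (10, 1, 16, 16))
        assert meta.dtype == FLOAT32 and meta.pixel_size == pytest.approx(1.0)
        img = load(tmp_path / "ref.mrcs", index=3)
        assert img.data[0].tobytes() == buf[3].tobytes()

    def test_reference_mrc_int8_single(self, tmp_path):
        spec = PhantomSpec((1, 1, 16, 16), "uniform-noise", 7, dtype="int8")
        buf = fixtures.write_reference_mrc(tmp_path / "ref.mrc", spec)
        img = load(tmp_path / "ref.mrc")
        assert img.dtype == emkit.INT8
        assert img.data.tobytes() == buf.tobytes()

    def test_reference_spider_single_and_volume(self, tmp_path):
        buf = fixtures.write_reference_spider(
            tmp_path / "a.spi", PhantomSpec((1, 1, 16, 16), "uniform-noise", 1))
        meta = probe(tmp_path / "a.spi")
        assert (meta.format, tuple(meta.dims)) == ("spider", (1, 1, 16, 16))
        assert meta.pixel_size is None
        assert load(tmp_path / "a.spi").data.tobytes() == \
            buf.astype(np.float32).tobytes()
        fixtures.write_reference_spider(
            tmp_path / "v.spi", PhantomSpec((1, 8, 16, 16), "uniform-noise", 2))
        assert tuple(probe(tmp_path / "v.spi").dims) == (1, 8, 16, 16)

    @pytest.mark.parametrize("dt", ["int8", "int16", "float32", "uint16"])
    def test_written_mrc_parses_identically_under_reference_parser(
            self, tmp_path, dt):
        img = phantom((2, 1, 16, 16), emkit.dtype(dt))
        img.pixel_size = 1.1
        save(img, tmp_path / "x.mrcs")
        hdr = fixtures.parse_mrc_header(tmp_path / "x.mrcs")
        assert (hdr["nx"], hdr["ny"], hdr["nz"]) == (16, 16, 2)
        assert hdr["map_id"] == b"MAP "
        assert hdr["machst"] == bytes((0x44, 0x44, 0x00, 0x00))
        assert hdr["cella"][0] == pytest.approx(16 * 1.1, rel=1e-6)
        data = fixtures.read_reference_mrc_data(tmp_path / "x.mrcs")
        assert data.tobytes() == img.data.tobytes()

    def test_written_spider_parses_identically_under_reference_parser(
            self, tmp_path):
        img = phantom((1, 1, 12, 20), FLOAT32)
        save(img, tmp_path / "x.spi")
        data = fixtures.read_reference_spider_data(tmp_path / "x.spi")
        assert data.tobytes() == img.data.tobytes()

    def test_cross_format_mrc_spider_mrc_is_lossless(self, tmp_path, rng):
        img = phantom((1, 1, 16, 16), FLOAT32)
        save(img, tmp_path / "a.mrc")
        save(load(tmp_path / "a.mrc"), tmp_path / "b.spi")
        save(load(tmp_path / "b.spi"), tmp_path / "c.mrc")
        assert load(tmp_path / "c.mrc").data.tobytes() == img.data.tobytes()


class TestErrors:
    def test_empty_file_is_malformed(self, tmp_path):
        (tmp_path / "zero.mrc").write_bytes(b"")
        with pytest.raises(FormatError):
            load(tmp_path / "zero.mrc")
        (tmp_path / "zero.spi").write_bytes(b"")
        with pytest.raises(FormatError):
            load(tmp_path / "zero.spi")

    def test_unknown_extension_needs_explicit_format(self, tmp_path):
        (tmp_path / "img.xyz").write_bytes(b"\0" * 2048)
        with pytest.raises(EmkitError):
            probe(tmp_path / "img.xyz")

    def test_missing_magic_rejected(self, tmp_path):
        img = phantom((1, 1, 8, 8), FLOAT32)
        save(img, tmp_path / "a.mrc")
        raw = bytearray((tmp_path / "a.mrc").read_bytes())
        raw[208:212] = b"XXXX"
        (tmp_path / "bad.mrc").write_bytes(bytes(raw))
        with pytest.raises(FormatError):
            load(tmp_path / "bad.mrc")

    def test_truncated_data_section(self, tmp_path):
        img = phantom((1, 1, 8, 8), FLOAT32)
        save(img, tmp_path / "a.mrc")
        raw = (tmp_path / "a.mrc").read_bytes()
        (tmp_path / "trunc.mrc").write_bytes(raw[:-16])
        with pytest.raises(FormatError):
            load(tmp_path / "trunc.mrc")

    def test_index_out_of_range(self, tmp_path):
        save(phantom((3, 1, 8, 8), FLOAT32), tmp_path / "s.mrcs")
        with pytest.raises(EmkitError):
            load(tmp_path / "s.mrcs", index=3)

    def test_sparse_write_index_rejected(self, tmp_path):
        with ImageFile(tmp_path / "s.mrcs", "w") as fh:
            fh.write(phantom((3, 1, 8, 8), FLOAT32))
            with pytest.raises(EmkitError):
                fh.write(phantom((1, 1, 8, 8), FLOAT32), index=5)
            fh.write(phantom((1, 1, 8, 8), FLOAT32), index=3)  # append ok
        assert load(tmp_path / "s.mrcs").n_items == 4

    def test_directory_path_rejected(self, tmp_path):
        with pytest.raises(EmkitError):
            probe(tmp_path)

    def test_failed_handle_leaves_no_file(self, tmp_path):
        target = tmp_path / "never.mrc"
        try:
            with ImageFile(target, "w") as fh:
                fh.write(phantom((1, 1, 8, 8), FLOAT32))
                raise RuntimeError("simulated failure mid-session")
        except RuntimeError:
            pass
        assert not target.exists()
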