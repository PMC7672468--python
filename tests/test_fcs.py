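"""FCS I/O and preprocessing: round-trips, slicing, transforms."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from cytosom import fcs


def _write(tmp_path, vals, columns, name="t.fcs"):
    path = tmp_path / name
    fcs.write_fcs(fcs.SampleMatrix(values=vals, columns=columns), path)
    return path


# ---------------------------------------------------------------------------
# header scans


def test_header_fields(tmp_path):
    vals = np.random.default_rng(0).standard_normal((1000, 10))
    path = _write(tmp_path, vals, [f"P{i}" for i in range(10)])
    hdr = fcs.read_fcs_header(path)
    assert hdr.n_events == 1000
    assert hdr.n_params == 10
    assert hdr.param_names == [f"P{i}" for i in range(10)]
    assert hdr.datatype == "F"
    assert hdr.byte_order == "<"
    assert hdr.data_length == 1000 * 10 * 4


def test_header_zero_events(tmp_path):
    path = _write(tmp_path, np.zeros((0, 3)), ["a", "b", "c"])
    hdr = fcs.read_fcs_header(path)
    assert hdr.n_events == 0
    mat = fcs.read_fcs(path)
    assert mat.values.shape == (0, 3)
    assert mat.columns == ["a", "b", "c"]


def test_header_scan_never_reads_data(tmp_path):
    """Truncate the DATA segment: the header scan must still succeed."""
    vals = np.random.default_rng(1).standard_normal((50, 4))
    path = _write(tmp_path, vals, list("abcd"))
    hdr = fcs.read_fcs_header(path)
    raw = path.read_bytes()
    truncated = tmp_path / "trunc.fcs"
    truncated.write_bytes(raw[: hdr.data_offset])  # drop all event bytes
    hdr2 = fcs.read_fcs_header(truncated)
    assert hdr2.n_events == 50
    with pytest.raises(IOError):
        fcs.read_fcs_events(truncated, 0, 50, header=hdr2)


def test_bad_magic(tmp_path):
    p = tmp_path / "bad.fcs"
    p.write_bytes(b"NOTFCS" + b" " * 100)
    with pytest.raises(fcs.FCSFormatError):
        fcs.read_fcs_header(p)


def test_short_file(tmp_path):
    p = tmp_path / "short.fcs"
    p.write_bytes(b"FCS3.1")
    with pytest.raises(fcs.FCSFormatError):
        fcs.read_fcs_header(p)


def test_integer_datatype_rejected(tmp_path):
    vals = np.zeros((2, 2))
    path = _write(tmp_path, vals, ["a", "b"])
    raw = bytearray(path.read_bytes())
    i = raw.find(b"$DATATYPE/F")
    raw[i : i + len(b"$DATATYPE/F")] = b"$DATATYPE/I"
    bad = tmp_path / "int.fcs"
    bad.write_bytes(bytes(raw))
    with pytest.raises(fcs.UnsupportedFormatError):
        fcs.read_fcs_header(bad)


# ---------------------------------------------------------------------------
# round-trips


@pytest.mark.parametrize("shape", [(0, 3), (1, 1), (100, 5), (2000, 12)])
def test_write_read_roundtrip_float32_exact(tmp_path, shape):
    vals = np.random.default_rng(2).standard_normal(shape) * 100
    path = _write(tmp_path, vals, [f"c{i}" for i in range(shape[1])])
    back = fcs.read_fcs(path)
    assert np.array_equal(back.values, vals.astype(np.float32))


def test_roundtrip_delimiter_in_channel_name(tmp_path):
    vals = np.ones((3, 2))
    names = ["CD4/FITC", "a//b"]
    path = _write(tmp_path, vals, names)
    back = fcs.read_fcs(path)
    assert back.columns == names


def test_datatype_d_roundtrip_bit_exact(tmp_path):
    """Hand-build a $DATATYPE=D file; doubles must round-trip bit-exactly."""
    vals = np.random.default_rng(3).standard_normal((20, 3))
    names = ["x", "y", "z"]
    pairs = [("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "D"), ("$MODE", "L"),
             ("$NEXTDATA", "0"), ("$PAR", "3"), ("$TOT", "20")]
    for i, n in enumerate(names, start=1):
        pairs += [(f"$P{i}N", n), (f"$P{i}B", "64")]

    def render(b, e):
        items = pairs + [("$BEGINDATA", f"{b:010d}"), ("$ENDDATA", f"{e:010d}")]
        return ("/" + "/".join(k + "/" + v for k, v in items) + "/").encode()

    probe = render(0, 0)
    text_begin = 58
    text_end = text_begin + len(probe) - 1
    data_begin = text_end + 1
    data_end = data_begin + 20 * 3 * 8 - 1
    header = (b"FCS3.1    " + f"{text_begin:>8d}".encode()
              + f"{text_end:>8d}".encode() + f"{data_begin:>8d}".encode()
              + f"{data_end:>8d}".encode() + b"       0" + b"       0")
    path = tmp_path / "doubles.fcs"
    path.write_bytes(header + render(data_begin, data_end)
                     + vals.astype("<f8").tobytes())
    back = fcs.read_fcs(path)
    assert back.values.dtype == np.float64
    assert np.array_equal(back.values, vals)


# ---------------------------------------------------------------------------
# partial event reads


@pytest.fixture()
def sliced_file(tmp_path):
    vals = np.random.default_rng(4).standard_normal((500, 6)).astype(np.float32)
    path = _write(tmp_path, vals, [f"m{i}" for i in range(6)])
    return path, vals


def test_full_range_equals_full_read(sliced_file):
    path, vals = sliced_file
    a = fcs.read_fcs_events(path, 0, 500)
    b = fcs.read_fcs(path)
    assert np.array_equal(a.values, b.values)
    assert np.array_equal(a.values, vals)


def test_slice_concatenation(sliced_file):
    path, vals = sliced_file
    parts = [fcs.read_fcs_events(path, a, b)
             for a, b in [(0, 120), (120, 121), (121, 500)]]
    cat = np.concatenate([p.values for p in parts])
    assert np.array_equal(cat, vals)


def test_empty_slice(sliced_file):
    path, _ = sliced_file
    mat = fcs.read_fcs_events(path, 42, 42)
    assert mat.values.shape == (0, 6)
    assert mat.columns == [f"m{i}" for i in range(6)]


def test_out_of_range(sliced_file):
    path, _ = sliced_file
    with pytest.raises(IndexError):
        fcs.read_fcs_events(path, 0, 501)
    with pytest.raises(IndexError):
        fcs.read_fcs_events(path, -1, 10)
    with pytest.raises(IndexError):
        fcs.read_fcs_events(path, 10, 5)


# ---------------------------------------------------------------------------
# compensation


def test_compensate_identity(small_matrix):
    spill = fcs.SpilloverMatrix(channels=small_matrix.columns[:3],
                                matrix=np.eye(3))
    out = fcs.compensate(small_matrix, spill)
    assert np.allclose(out.values, small_matrix.values)


def test_compensate_matches_dense_solve():
    S = np.array([[1.0, 0.1], [0.0, 1.0]])
    raw = np.array([[2.0, 3.0]])
    mat = fcs.SampleMatrix(values=raw, columns=["a", "b"])
    out = fcs.compensate(mat, fcs.SpilloverMatrix(["a", "b"], S))
    expected = np.linalg.solve(S.T, raw.T).T  # comp @ S = raw
    assert np.allclose(out.values, expected)
    assert np.allclose(out.values @ S, raw)


def test_compensate_inverse_recovers_raw(small_matrix):
    k = 4
    S = np.eye(k) + 0.05 * np.random.default_rng(5).random((k, k))
    spill = fcs.SpilloverMatrix(small_matrix.columns[:k], S)
    comp = fcs.compensate(small_matrix, spill)
    recovered = np.array(comp.values, copy=True)
    recovered[:, :k] = comp.values[:, :k] @ S
    assert np.allclose(recovered, small_matrix.values, rtol=1e-6)


def test_compensate_untouched_columns(small_matrix):
    S = np.array([[1.0, 0.2], [0.1, 1.0]])
    spill = fcs.SpilloverMatrix(small_matrix.columns[:2], S)
    out = fcs.compensate(small_matrix, spill)
    assert np.array_equal(out.values[:, 2:], small_matrix.values[:, 2:])


def test_compensate_transpose_flag(small_matrix):
    S = np.array([[1.0, 0.3], [0.0, 1.0]])
    spill_t = fcs.SpilloverMatrix(small_matrix.columns[:2], S.T)
    a = fcs.compensate(small_matrix, fcs.SpilloverMatrix(small_matrix.columns[:2], S))
    b = fcs.compensate(small_matrix, spill_t, transpose=True)
    assert np.allclose(a.values, b.values)


def test_singular_spillover_rejected(small_matrix):
    S = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError):
        fcs.SpilloverMatrix(small_matrix.columns[:2], S * [[1], [0]])
    near_sing = fcs.SpilloverMatrix(small_matrix.columns[:2],
                                    np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]]))
    with pytest.raises(np.linalg.LinAlgError):
        fcs.compensate(small_matrix, near_sing)


def test_parse_spillover_keyword():
    spill = fcs.parse_spillover_keyword("2,a,b,1,0.1,0.2,1")
    assert spill.channels == ["a", "b"]
    assert np.allclose(spill.matrix, [[1, 0.1], [0.2, 1]])
    with pytest.raises(fcs.FCSFormatError):
        fcs.parse_spillover_keyword("2,a,b,1,0.1")


def test_read_spillover_csv(tmp_path):
    p = tmp_path / "spill.csv"
    p.write_text("a,b\n1,0.1\n0.2,1\n")
    spill = fcs.read_spillover_csv(p)
    assert spill.channels == ["a", "b"]
    assert np.allclose(spill.matrix, [[1, 0.1], [0.2, 1]])


# ---------------------------------------------------------------------------
# asinh + scaling


def test_asinh_zero_fixed_point(small_matrix):
    mat = fcs.SampleMatrix(values=np.zeros((4, 2)), columns=["a", "b"])
    for cofactor in (5, 150, 500):
        assert np.all(fcs.transform_asinh(mat, cofactor).values == 0)


def test_asinh_closed_form():
    mat = fcs.SampleMatrix(values=np.array([[500.0]]), columns=["a"])
    out = fcs.transform_asinh(mat, cofactor=500)
    assert out.values[0, 0] == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)
    assert out.values[0, 0] == pytest.approx(0.8813735870, abs=1e-9)


def test_asinh_monotone():
    x = np.sort(np.random.default_rng(6).standard_normal(100))[:, None] * 1e4
    out = fcs.transform_asinh(fcs.SampleMatrix(values=x, columns=["a"]))
    assert np.all(np.diff(out.values[:, 0]) > 0)


def test_asinh_column_subset(small_matrix):
    out = fcs.transform_asinh(small_matrix, columns=["ch0"])
    assert np.array_equal(out.values[:, 1:], small_matrix.values[:, 1:])
    assert np.allclose(out.values[:, 0], np.arcsinh(small_matrix.values[:, 0] / 500))


def test_asinh_bad_cofactor(small_matrix):
    with pytest.raises(ValueError):
        fcs.transform_asinh(small_matrix, cofactor=0)
    with pytest.raises(ValueError):
        fcs.transform_asinh(small_matrix, cofactor=-1)


def test_asinh_commutes_with_row_permutation(small_matrix):
    perm = np.random.default_rng(8).permutation(small_matrix.n_events)
    a = fcs.transform_asinh(small_matrix).values[perm]
    permuted = fcs.SampleMatrix(values=small_matrix.values[perm],
                                columns=small_matrix.columns)
    b = fcs.transform_asinh(permuted).values
    assert np.array_equal(a, b)


def test_scale_columns_basic():
    mat = fcs.SampleMatrix(values=np.array([[1.0], [2.0], [3.0]]), columns=["a"])
    out, params = fcs.scale_columns(mat)
    assert out.values.mean() == pytest.approx(0, abs=1e-10)
    assert out.values.std(ddof=1) == pytest.approx(1, abs=1e-10)
    assert params.mean[0] == pytest.approx(2.0)
    assert params.std[0] == pytest.approx(1.0)  # sample std, n-1


def test_scale_columns_stats(small_matrix):
    out, _ = fcs.scale_columns(small_matrix)
    assert np.allclose(out.values.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(out.values.std(axis=0, ddof=1), 1, atol=1e-10)


def test_scale_constant_column_warns():
    mat = fcs.SampleMatrix(values=np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]),
                           columns=["const", "var"])
    with pytest.warns(RuntimeWarning, match="const"):
        out, params = fcs.scale_columns(mat)
    assert np.all(out.values[:, 0] == 0)  # centered only
    assert params.std[0] == 1.0


def test_apply_scaling_reproduces_affine_map(small_matrix):
    _, params = fcs.scale_columns(small_matrix)
    other = fcs.SampleMatrix(
        values=np.random.default_rng(9).standard_normal((50, 5)),
        columns=small_matrix.columns)
    out = fcs.apply_scaling(other, params)
    assert np.allclose(out.values, (other.values - params.mean) / params.std)


def test_apply_scaling_column_mismatch(small_matrix):
    _, params = fcs.scale_columns(small_matrix)
    other = fcs.SampleMatrix(values=np.zeros((2, 2)), columns=["x", "y"])
    with pytest.raises(ValueError):
        fcs.apply_scaling(other, params)


# ---------------------------------------------------------------------------
# SampleMatrix invariants


def test_sample_matrix_validation():
    with pytest.raises(ValueError):
        fcs.SampleMatrix(values=np.zeros((2, 2)), columns=["a"])
    with pytest.raises(ValueError):
        fcs.SampleMatrix(values=np.zeros((2, 2)), columns=["a", "a"])
    with pytest.raises(ValueError):
        fcs.SampleMatrix(values=np.zeros(3), columns=["a"])


def test_write_rejects_nonfinite(tmp_path):
    mat = fcs.SampleMatrix(values=np.array([[np.nan]]), columns=["a"])
    with pytest.raises(ValueError):
        fcs.write_fcs(mat, tmp_path / "nan.fcs")
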