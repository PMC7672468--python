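"""Flow Cytometry Standard (FCS) file I/O and cytometry preprocessing.

Reads FCS 3.0/3.1 files with float data ($DATATYPE F or D), supports
header-only scans and partial event-range reads (needed for balanced
dataset slicing), writes FCS 3.1, and implements the standard cytometry
preprocessing steps: spillover compensation, the asinh transform, and
per-channel z-scaling.

Event indices are 0-based and half-open ``[first, last)`` throughout;
the FCS ``$TOT`` keyword is a count, not an index.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FCSFormatError",
    "UnsupportedFormatError",
    "FCSHeader",
    "SampleMatrix",
    "SpilloverMatrix",
    "ColumnScaling",
    "read_fcs_header",
    "read_fcs_events",
    "read_fcs",
    "write_fcs",
    "compensate",
    "transform_asinh",
    "scale_columns",
    "apply_scaling",
    "parse_spillover_keyword",
    "read_spillover_csv",
]

#: TEXT-segment delimiter used by the writer. Delimiter characters inside
#: keys/values are escaped by doubling, per the FCS standard.
_DELIM = "/"

_HEADER_LEN = 58  # 10-byte version field + 6 right-justified 8-byte offsets


class FCSFormatError(ValueError):
    """Malformed FCS file (bad magic, offsets, or TEXT keywords)."""


class UnsupportedFormatError(FCSFormatError):
    """Structurally valid FCS file using a feature outside supported scope."""


@dataclass(frozen=True)
class FCSHeader:
    """Parsed FCS header + TEXT segment, without touching the DATA segment."""

    version: str
    text_segment: dict[str, str]
    n_events: int
    n_params: int
    param_names: list[str]
    datatype: str  # 'F' or 'D'
    byte_order: str  # '<' little-endian, '>' big-endian
    data_offset: int
    data_length: int

    @property
    def bytes_per_value(self) -> int:
        return 4 if self.datatype == "F" else 8

    @property
    def dtype(self) -> np.dtype:
        code = "f4" if self.datatype == "F" else "f8"
        return np.dtype(self.byte_order + code)


@dataclass
class SampleMatrix:
    """Events × parameters matrix with named channels.

    This is the in-memory container every other module consumes: rows are
    cytometry events (cells), columns are measurement channels/markers.
    """

    values: np.ndarray
    columns: list[str]
    source: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("SampleMatrix values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{self.values.shape[1]} data columns but "
                f"{len(self.columns)} column names"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("channel names must be unique")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.columns)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([pos[n] for n in names], dtype=np.intp)


@dataclass(frozen=True)
class SpilloverMatrix:
    """Square spillover (fluorescence cross-talk) matrix over named channels.

    Row i gives the fractions of channel i's true signal that leak into each
    measured channel; compensation right-divides measured values by this
    matrix.
    """

    channels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValueError("spillover matrix must be square over channels")
        if np.any(np.diag(m) == 0):
            raise ValueError("spillover matrix has a zero diagonal entry")
        if not np.all(np.isfinite(m)):
            raise ValueError("spillover matrix has non-finite entries")


@dataclass(frozen=True)
class ColumnScaling:
    """Fitted per-column affine standardization parameters (μ, σ)."""

    columns: list[str]
    mean: np.ndarray
    std: np.ndarray  # entries of 1.0 substituted where a column was constant


# ---------------------------------------------------------------------------
# reading


def _parse_offsets(raw: bytes) -> tuple[str, int, int]:
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS"):
        raise FCSFormatError(f"not an FCS file (magic {version!r})")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedFormatError(f"unsupported FCS version {version!r}")

    def off(i: int) -> int:
        s = raw[10 + 8 * i : 18 + 8 * i].decode("ascii").strip()
        if s == "":
            return 0
        try:
            return int(s)
        except ValueError as e:
            raise FCSFormatError(f"malformed header offset field {i}: {s!r}") from e

    return version, off(0), off(1)


def _split_text(blob: bytes) -> dict[str, str]:
    if not blob:
        raise FCSFormatError("empty TEXT segment")
    delim = blob[:1].decode("latin-1")
    body = blob[1:].decode("latin-1")
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    # Doubled delimiters inside values appear as empty strings between parts.
    tokens: list[str] = []
    buf = parts[0]
    i = 1
    while i < len(parts):
        if parts[i] == "" and i + 1 < len(parts):
            buf += delim + parts[i + 1]
            i += 2
        else:
            tokens.append(buf)
            buf = parts[i]
            i += 1
    tokens.append(buf)
    if len(tokens) % 2 != 0:
        raise FCSFormatError("TEXT segment has a key without a value")
    return {tokens[j].strip().upper() if tokens[j].startswith("$") else tokens[j]: tokens[j + 1]
            for j in range(0, len(tokens), 2)}


def _require(text: dict[str, str], key: str) -> str:
    try:
        return text[key]
    except KeyError:
        raise FCSFormatError(f"missing required keyword {key}") from None


def _header_from_text(version: str, text: dict[str, str]) -> FCSHeader:
    datatype = _require(text, "$DATATYPE").strip().upper()
    if datatype == "I":
        raise UnsupportedFormatError(
            "$DATATYPE=I (integer) data is not supported; only F and D"
        )
    if datatype not in ("F", "D"):
        raise UnsupportedFormatError(f"unsupported $DATATYPE={datatype!r}")

    byteord = _require(text, "$BYTEORD").strip()
    if byteord == "1,2,3,4":
        order = "<"
    elif byteord == "4,3,2,1":
        order = ">"
    else:
        raise UnsupportedFormatError(f"unsupported $BYTEORD={byteord!r}")

    n_events = int(_require(text, "$TOT"))
    n_params = int(_require(text, "$PAR"))
    if n_events < 0 or n_params < 0:
        raise FCSFormatError("$TOT/$PAR must be nonnegative")

    names = []
    bpv = 32 if datatype == "F" else 64
    for i in range(1, n_params + 1):
        names.append(_require(text, f"$P{i}N"))
        bits = text.get(f"$P{i}B")
        if bits is not None and int(bits) != bpv:
            raise UnsupportedFormatError(
                f"$P{i}B={bits} inconsistent with $DATATYPE={datatype}"
            )

    data_begin = int(text.get("$BEGINDATA", "0"))
    data_end = int(text.get("$ENDDATA", "0"))
    data_length = data_end - data_begin + 1 if data_end >= data_begin and data_begin > 0 else 0
    expected = n_events * n_params * (bpv // 8)
    if data_length and data_length != expected:
        raise FCSFormatError(
            f"DATA segment length {data_length} does not match "
            f"$TOT×$PAR×{bpv // 8} = {expected}"
        )
    return FCSHeader(
        version=version,
        text_segment=text,
        n_events=n_events,
        n_params=n_params,
        param_names=names,
        datatype=datatype,
        byte_order=order,
        data_offset=data_begin,
        data_length=expected,
    )


def read_fcs_header(path: str | Path) -> FCSHeader:
    """Parse the header and TEXT segment of an FCS file.

    Never touches the DATA segment, so scanning the headers of many large
    files (to plan balanced slices) is cheap.
    """
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER_LEN)
        if len(raw) < _HEADER_LEN:
            raise FCSFormatError(f"{path}: file shorter than FCS header")
        version, text_begin, text_end = _parse_offsets(raw)
        if text_begin <= 0 or text_end < text_begin:
            raise FCSFormatError(
                f"{path}: malformed TEXT offsets [{text_begin}, {text_end}]"
            )
        fh.seek(text_begin)
        blob = fh.read(text_end - text_begin + 1)
        text = _split_text(blob)
        hdr = _header_from_text(version, text)
        if hdr.data_offset == 0:
            # fall back to the binary header's DATA offsets (FCS 3.0 style)
            fh.seek(0)
            raw = fh.read(_HEADER_LEN)
            begin = int(raw[26:34].decode("ascii").strip() or "0")
            end = int(raw[34:42].decode("ascii").strip() or "0")
            if begin == 0 and hdr.n_events > 0:
                raise FCSFormatError(f"{path}: no DATA segment offsets")
            hdr = replace(hdr, data_offset=begin)
            if hdr.n_events and end - begin + 1 != hdr.data_length:
                raise FCSFormatError(f"{path}: DATA offsets inconsistent with $TOT")
        return hdr


def read_fcs_events(
    path: str | Path,
    first_event: int,
    last_event: int,
    header: FCSHeader | None = None,
) -> SampleMatrix:
    """Read events ``[first_event, last_event)`` without loading the rest.

    ``read_fcs_events(p, 0, n)`` equals a full read. Passing a previously
    scanned ``header`` skips re-parsing the TEXT segment.
    """
    hdr = header if header is not None else read_fcs_header(path)
    if not (0 <= first_event <= last_event <= hdr.n_events):
        raise IndexError(
            f"event range [{first_event}, {last_event}) out of bounds "
            f"for {hdr.n_events} events"
        )
    n = last_event - first_event
    row_bytes = hdr.n_params * hdr.bytes_per_value
    with open(path, "rb") as fh:
        fh.seek(hdr.data_offset + first_event * row_bytes)
        buf = fh.read(n * row_bytes)
    if len(buf) != n * row_bytes:
        raise IOError(f"{path}: truncated DATA segment")
    vals = np.frombuffer(buf, dtype=hdr.dtype).reshape(n, hdr.n_params)
    vals = np.ascontiguousarray(vals.astype(hdr.dtype.newbyteorder("=")))
    if not np.all(np.isfinite(vals)):
        raise FCSFormatError(f"{path}: non-finite values in DATA segment")
    return SampleMatrix(
        values=vals,
        columns=list(hdr.param_names),
        source={"file": str(path), "first_event": first_event, "last_event": last_event},
    )


def read_fcs(path: str | Path) -> SampleMatrix:
    """Read a whole FCS file."""
    hdr = read_fcs_header(path)
    return read_fcs_events(path, 0, hdr.n_events, header=hdr)


# ---------------------------------------------------------------------------
# writing


def _escape(s: str) -> str:
    return s.replace(_DELIM, _DELIM + _DELIM)


def write_fcs(matrix: SampleMatrix, path: str | Path, extra_text: dict[str, str] | None = None) -> None:
    """Write an FCS 3.1 file: $DATATYPE=F, little-endian, one DATA segment.

    Values are stored as float32, so a write/read round-trip is exact up to
    float32 quantization of each value. Channel names containing the TEXT
    delimiter are escaped and recovered verbatim.
    """
    vals = np.asarray(matrix.values, dtype="<f4")
    if not np.all(np.isfinite(vals)):
        raise ValueError("cannot write non-finite values to FCS")
    n, p = vals.shape

    pairs: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(p)),
        ("$TOT", str(n)),
    ]
    rng_kw = "262144"
    for i, name in enumerate(matrix.columns, start=1):
        pairs += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", rng_kw),
        ]
    if extra_text:
        pairs += list(extra_text.items())

    # DATA offsets are zero-padded to fixed width so the TEXT length does not
    # depend on the offset values (avoids the circular offset computation).
    data_len = n * p * 4

    def render(begin_data: int, end_data: int) -> bytes:
        items = pairs + [
            ("$BEGINDATA", f"{begin_data:010d}"),
            ("$ENDDATA", f"{end_data:010d}"),
        ]
        s = _DELIM + _DELIM.join(
            _escape(k) + _DELIM + _escape(v) for k, v in items
        ) + _DELIM
        return s.encode("latin-1")

    probe = render(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(probe) - 1
    data_begin = text_end + 1
    data_end = data_begin + data_len - 1  # begin−1 for an empty DATA segment
    text = render(data_begin, data_end)
    assert len(text) == len(probe)

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{data_begin:>8d}".encode() if data_end <= 99_999_999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(vals.tobytes())


# ---------------------------------------------------------------------------
# preprocessing transforms


def parse_spillover_keyword(value: str) -> SpilloverMatrix:
    """Parse the FCS ``$SPILLOVER`` keyword: ``k,name1..namek,v11,v12..vkk``."""
    parts = [p.strip() for p in value.split(",")]
    k = int(parts[0])
    if len(parts) != 1 + k + k * k:
        raise FCSFormatError(
            f"$SPILLOVER declares {k} channels but has {len(parts) - 1} fields"
        )
    channels = parts[1 : 1 + k]
    vals = np.array([float(x) for x in parts[1 + k :]], dtype=np.float64)
    return SpilloverMatrix(channels=channels, matrix=vals.reshape(k, k))


def read_spillover_csv(path: str | Path) -> SpilloverMatrix:
    """Read a spillover matrix from CSV whose header row names the channels."""
    import pandas as pd

    df = pd.read_csv(path)
    return SpilloverMatrix(channels=list(df.columns), matrix=df.to_numpy(dtype=np.float64))


def compensate(
    matrix: SampleMatrix, spill: SpilloverMatrix, transpose: bool = False
) -> SampleMatrix:
    """Undo fluorescence spillover by right-division with the spillover matrix.

    Solves ``compensated · S = raw`` for the channels named in ``spill``
    (the standard cytometry convention where spillover row i describes how
    channel i leaks into the others); all other columns pass through
    untouched. Set ``transpose=True`` if your matrix is stored in the
    opposite orientation.
    """
    S = spill.matrix.T if transpose else spill.matrix
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"spillover matrix over {spill.channels} is singular or "
            f"ill-conditioned (cond={cond:.3g})"
        )
    idx = matrix.column_index(spill.channels)
    out = np.array(matrix.values, dtype=np.float64, copy=True)
    # raw = comp @ S  =>  comp.T solves S.T x = raw.T
    out[:, idx] = np.linalg.solve(S.T, out[:, idx].T).T
    return SampleMatrix(values=out, columns=list(matrix.columns), source=matrix.source)


def transform_asinh(
    matrix: SampleMatrix,
    cofactor: float = 500.0,
    columns: Sequence[str] | None = None,
) -> SampleMatrix:
    """Variance-stabilize intensities: x ↦ asinh(x / cofactor).

    Cofactor 500 is the conventional choice for fluorescence flow cytometry
    (5 for mass cytometry). Applies to ``columns`` (default: all).
    """
    if not cofactor > 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    out = np.array(matrix.values, dtype=np.float64, copy=True)
    idx = (
        np.arange(out.shape[1])
        if columns is None
        else matrix.column_index(columns)
    )
    out[:, idx] = np.arcsinh(out[:, idx] / cofactor)
    return SampleMatrix(values=out, columns=list(matrix.columns), source=matrix.source)


def scale_columns(
    matrix: SampleMatrix,
) -> tuple[SampleMatrix, ColumnScaling]:
    """Standardize every column to mean 0 and (sample, n−1) std 1.

    Returns the fitted parameters so the identical affine map can be applied
    to other matrices (e.g. per-shard scaling with globally fitted μ, σ).
    Constant columns are centered but not divided; a warning is emitted.
    """
    vals = np.asarray(matrix.values, dtype=np.float64)
    mean = vals.mean(axis=0)
    std = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.zeros(vals.shape[1])
    degenerate = std == 0
    if np.any(degenerate):
        bad = [matrix.columns[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance columns centered but not scaled: {bad}",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_std = np.where(degenerate, 1.0, std)
    params = ColumnScaling(columns=list(matrix.columns), mean=mean, std=safe_std)
    return apply_scaling(matrix, params), params


def apply_scaling(matrix: SampleMatrix, params: ColumnScaling) -> SampleMatrix:
    """Apply previously fitted standardization parameters to a matrix."""
    if params.columns != matrix.columns:
        raise ValueError("scaling parameters were fitted on different columns")
    out = (np.asarray(matrix.values, dtype=np.float64) - params.mean) / params.std
    return SampleMatrix(values=out, columns=list(matrix.columns), source=matrix.source)
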