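"""Reading and writing FCS files (ISAC Flow Cytometry Standard).

Supports reading FCS 2.0 / 3.0 / 3.1 list-mode files with ``$DATATYPE`` F
(float32), D (float64) or I (unsigned integer), including multi-dataset files
chained through ``$NEXTDATA``, and writing single-dataset FCS 3.1 files with
float32 data.

Events are exposed as a float64 ``numpy`` matrix of shape
``(n_events, n_channels)`` holding the *stored* (unscaled) values; per-channel
``$PnE``/``$PnG`` scaling is a separate, explicit step (see
:mod:`cytolite.preprocess`). Channels are addressed everywhere by their
``$PnN`` short name.

Deliberate deviations from the letter of the standard, matching widespread
instrument practice:

* ``$PnE`` values of the form ``d,0`` with ``d > 0`` (log amplification with a
  zero offset, which the standard forbids) are repaired to ``d,1`` with a
  warning.
* Integer data whose ``$PnR`` is not the full range of ``$PnB`` bits are
  masked to ``ceil(log2($PnR))`` bits, mirroring acquisition-board behaviour
  and stripping stray high bits.
* When the HEADER data offsets are 0 (the FCS 3.x convention for files larger
  than the 8-digit header fields), ``$BEGINDATA``/``$ENDDATA`` from the TEXT
  segment are used instead.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    FormatError,
    IntegrityError,
    UnsupportedFeatureError,
    ChannelNotFoundError,
)

__all__ = [
    "ChannelInfo",
    "Sample",
    "read_fcs",
    "write_fcs",
    "parse_text_segment",
    "decode_data",
    "keyword_get",
]

_SUPPORTED_VERSIONS = (b"FCS2.0", b"FCS3.0", b"FCS3.1")

#: Spillover keyword spellings in precedence order ($SPILLOVER is FCS 3.1;
#: SPILL and $COMP are common in FCS 2.0/3.0 era files).
SPILLOVER_KEYWORDS = ("$SPILLOVER", "SPILL", "$COMP")


@dataclass(frozen=True)
class ChannelInfo:
    """Static description of one acquisition channel (one FCS parameter).

    Attributes
    ----------
    short_name:
        ``$PnN`` — the unique channel identifier, e.g. ``"FSC-A"``.
    stain_name:
        ``$PnS`` — optional human-readable stain/marker label.
    bits:
        ``$PnB`` — bit width of the stored values.
    range:
        ``$PnR`` — nominal maximal value.
    amplification:
        ``$PnE`` as a ``(decades, offset)`` pair; ``(0, 0)`` means linear.
    gain:
        ``$PnG`` — linear amplifier gain (divisor), default 1.
    """

    short_name: str
    stain_name: str | None = None
    bits: int = 32
    range: float = 262144.0
    amplification: tuple[float, float] = (0.0, 0.0)
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.bits not in (8, 16, 32, 64):
            raise FormatError(
                f"channel {self.short_name!r}: unsupported $PnB={self.bits}"
            )
        if self.range <= 0:
            raise FormatError(f"channel {self.short_name!r}: $PnR must be positive")
        d, f = self.amplification
        if (d, f) != (0.0, 0.0) and (d <= 0 or f <= 0):
            raise FormatError(
                f"channel {self.short_name!r}: invalid $PnE={d},{f} "
                "(both members must be positive for log amplification)"
            )
        if self.gain <= 0:
            raise FormatError(f"channel {self.short_name!r}: $PnG must be positive")


@dataclass
class Sample:
    """One FCS dataset: an event matrix plus keyword metadata.

    ``events`` always holds the current working values; when a processing step
    (scaling, compensation) replaces them, the previous matrix is retained in
    ``raw_events`` so exports can emit either.
    """

    events: np.ndarray
    channels: list[ChannelInfo]
    keywords: dict[str, str] = field(default_factory=dict)
    source_path: str | None = None
    display_name: str = ""
    scaled: bool = False
    compensated_channels: tuple[str, ...] = ()
    raw_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise IntegrityError("event matrix must be 2-dimensional")
        if self.events.shape[1] != len(self.channels):
            raise IntegrityError(
                f"event matrix has {self.events.shape[1]} columns but "
                f"{len(self.channels)} channels are declared"
            )
        names = [c.short_name for c in self.channels]
        if len(set(names)) != len(names):
            raise IntegrityError(f"duplicate channel short names: {names}")
        tot = keyword_get(self.keywords, "$TOT")
        if tot is not None and int(tot) != self.events.shape[0]:
            raise IntegrityError(
                f"$TOT={tot} disagrees with {self.events.shape[0]} events"
            )
        par = keyword_get(self.keywords, "$PAR")
        if par is not None and int(par) != len(self.channels):
            raise IntegrityError(
                f"$PAR={par} disagrees with {len(self.channels)} channels"
            )
        if not self.display_name:
            base = os.path.basename(self.source_path) if self.source_path else ""
            self.display_name = base or "sample"

    # -- convenience accessors -------------------------------------------------

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> list[str]:
        return [c.short_name for c in self.channels]

    def channel_index(self, name: str) -> int:
        for i, c in enumerate(self.channels):
            if c.short_name == name:
                return i
        raise ChannelNotFoundError(
            f"channel {name!r} not in sample {self.display_name!r} "
            f"(available: {self.channel_names})"
        )

    def data(self, name: str) -> np.ndarray:
        """Column of working values for channel ``name``."""
        return self.events[:, self.channel_index(name)]

    def spillover_keyword(self) -> str | None:
        """The stored spillover keyword value, if any.

        Recognizes ``$SPILLOVER``, ``SPILL`` and ``$COMP`` (in that precedence
        order) since pre-3.1 instruments used the unofficial spellings.
        """
        for kw in SPILLOVER_KEYWORDS:
            val = keyword_get(self.keywords, kw)
            if val is not None:
                return val
        return None


def keyword_get(keywords: dict[str, str], name: str, default=None):
    """Look up a keyword; matching is case-insensitive for ``$``-keywords."""
    if name in keywords:
        return keywords[name]
    if name.startswith("$"):
        upper = name.upper()
        for k, v in keywords.items():
            if k.upper() == upper:
                return v
    return default


# ---------------------------------------------------------------------------
# TEXT segment
# ---------------------------------------------------------------------------

def parse_text_segment(raw: bytes) -> dict[str, str]:
    """Decode a TEXT (or supplemental TEXT) segment into a keyword map.

    The first byte is the delimiter; keyword names and values alternate,
    each terminated by the delimiter, and the segment ends with a final
    delimiter. A doubled delimiter inside a token decodes to one literal
    delimiter character (values cannot be empty, so a doubled delimiter is
    unambiguous except at the very end of the segment).
    """
    if len(raw) < 2:
        raise FormatError("TEXT segment too short to contain a delimiter pair")
    delim = raw[0:1]
    if raw[-1:] != delim:
        raise FormatError("TEXT segment does not end with its delimiter")
    if len(raw) == 2:
        return {}

    tokens: list[str] = []
    cur = bytearray()
    i, n = 1, len(raw)
    d = raw[0]
    while i < n:
        if raw[i] == d:
            if i + 1 < n and raw[i + 1] == d:  # escaped delimiter
                cur.append(d)
                i += 2
                continue
            tokens.append(cur.decode("utf-8", errors="replace"))
            cur = bytearray()
            i += 1
        else:
            cur.append(raw[i])
            i += 1
    if cur:
        raise FormatError("TEXT segment has an unterminated token")

    if len(tokens) % 2 != 0:
        raise FormatError(
            f"TEXT segment holds an odd number of tokens ({len(tokens)})"
        )
    out: dict[str, str] = {}
    for k, v in zip(tokens[0::2], tokens[1::2]):
        if not k:
            raise FormatError("TEXT segment contains an empty keyword name")
        out[k] = v
    return out


def _serialize_text_segment(keywords: dict[str, str], delim: str = "/") -> bytes:
    parts = [delim]
    for k, v in keywords.items():
        if not k:
            raise FormatError("cannot serialize an empty keyword name")
        for token in (k, str(v)):
            if token.startswith(delim) or token.endswith(delim):
                # a leading/trailing delimiter cannot be distinguished from an
                # escape at the neighbouring token boundary — the one genuinely
                # ambiguous corner of the TEXT grammar
                raise FormatError(
                    f"token {token!r} may not start or end with the TEXT "
                    f"delimiter {delim!r}"
                )
            parts.append(token.replace(delim, delim * 2))
            parts.append(delim)
    return "".join(parts).encode("utf-8")


# ---------------------------------------------------------------------------
# DATA segment
# ---------------------------------------------------------------------------

def _byte_order(byteord: str) -> str:
    """Map a $BYTEORD permutation to a numpy byte-order character."""
    order = [tok.strip() for tok in byteord.split(",") if tok.strip()]
    if order == sorted(order):
        return "<"
    if order == sorted(order, reverse=True):
        return ">"
    raise UnsupportedFeatureError(
        f"mixed-endian $BYTEORD={byteord!r} is not supported"
    )


def decode_data(keywords: dict[str, str], raw: bytes) -> np.ndarray:
    """Decode a DATA segment into an ``(n_events, n_channels)`` float64 matrix.

    Only list mode (``$MODE=L``) is supported. Integer channels whose ``$PnR``
    does not fill their ``$PnB`` bit width are masked to ``ceil(log2($PnR))``
    bits before conversion.
    """
    mode = keyword_get(keywords, "$MODE", "L").upper()
    if mode != "L":
        raise UnsupportedFeatureError(
            f"$MODE={mode!r}: only list mode ('L') is supported"
        )
    datatype = keyword_get(keywords, "$DATATYPE", "").upper()
    if datatype == "A":
        raise UnsupportedFeatureError("$DATATYPE=A (ASCII) is not supported")
    if datatype not in ("F", "D", "I"):
        raise FormatError(f"unknown $DATATYPE={datatype!r}")

    n_par = int(keyword_get(keywords, "$PAR"))
    n_tot = int(keyword_get(keywords, "$TOT"))
    endian = _byte_order(keyword_get(keywords, "$BYTEORD", "1,2,3,4"))
    bits = [int(keyword_get(keywords, f"$P{i}B")) for i in range(1, n_par + 1)]

    if datatype in ("F", "D"):
        width = 32 if datatype == "F" else 64
        if any(b != width for b in bits):
            raise FormatError(
                f"$DATATYPE={datatype} requires $PnB={width} on every channel; "
                f"got {bits}"
            )
        expected = n_tot * n_par * width // 8
        if len(raw) < expected:
            raise IntegrityError(
                f"DATA segment holds {len(raw)} bytes but $TOT*$PAR*$PnB/8 "
                f"requires {expected}"
            )
        dtype = np.dtype(f"{endian}f{width // 8}")
        flat = np.frombuffer(raw[:expected], dtype=dtype)
        return flat.reshape(n_tot, n_par).astype(np.float64)

    # $DATATYPE=I — per-channel widths may differ.
    row_bytes = sum(b // 8 for b in bits)
    if any(b % 8 for b in bits):
        raise FormatError(f"integer $PnB values must be byte-aligned; got {bits}")
    expected = n_tot * row_bytes
    if len(raw) < expected:
        raise IntegrityError(
            f"DATA segment holds {len(raw)} bytes but $TOT rows of "
            f"{row_bytes} bytes require {expected}"
        )
    fields = {
        "names": [f"c{i}" for i in range(n_par)],
        "formats": [np.dtype(f"{endian}u{b // 8}") for b in bits],
    }
    rows = np.frombuffer(raw[:expected], dtype=np.dtype(fields))
    out = np.empty((n_tot, n_par), dtype=np.float64)
    for i in range(n_par):
        col = rows[f"c{i}"].astype(np.uint64)
        rng = float(keyword_get(keywords, f"$P{i + 1}R", 2 ** bits[i]))
        eff_bits = max(1, math.ceil(math.log2(rng))) if rng > 1 else bits[i]
        if eff_bits < bits[i]:
            col = col & np.uint64((1 << eff_bits) - 1)
        out[:, i] = col
    return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _parse_header_offsets(buf: bytes, base: int) -> dict[str, int]:
    header = buf[base : base + 58]
    if len(header) < 58:
        raise FormatError("HEADER segment truncated (needs 58 bytes)")
    names = ("text_begin", "text_end", "data_begin", "data_end",
             "analysis_begin", "analysis_end")
    offsets = {}
    for i, name in enumerate(names):
        fld = header[10 + 8 * i : 18 + 8 * i].strip()
        try:
            offsets[name] = int(fld) if fld else 0
        except ValueError as exc:
            raise FormatError(
                f"HEADER field {name!r} is not numeric: {fld!r}"
            ) from exc
    return offsets


def _parse_channels(keywords: dict[str, str]) -> list[ChannelInfo]:
    n_par = int(keyword_get(keywords, "$PAR"))
    channels = []
    for i in range(1, n_par + 1):
        name = keyword_get(keywords, f"$P{i}N", f"P{i}")
        amp_raw = keyword_get(keywords, f"$P{i}E", "0,0")
        try:
            d, f = (float(tok) for tok in amp_raw.split(","))
        except ValueError as exc:
            raise FormatError(f"$P{i}E={amp_raw!r} is not 'decades,offset'") from exc
        if d > 0 and f == 0:
            # common instrument bug: log amplification with zero offset
            warnings.warn(
                f"$P{i}E={amp_raw!r}: repairing zero offset to 1.0",
                stacklevel=3,
            )
            f = 1.0
        channels.append(
            ChannelInfo(
                short_name=name,
                stain_name=keyword_get(keywords, f"$P{i}S"),
                bits=int(keyword_get(keywords, f"$P{i}B", 32)),
                range=float(keyword_get(keywords, f"$P{i}R", 262144)),
                amplification=(d, f),
                gain=float(keyword_get(keywords, f"$P{i}G", 1.0)),
            )
        )
    return channels


def _read_dataset(buf: bytes, base: int, path: str | None) -> tuple[Sample, int]:
    version = buf[base : base + 6]
    if version not in _SUPPORTED_VERSIONS:
        raise FormatError(
            f"unrecognized FCS version marker {version!r} at offset {base} "
            f"(supported: {[v.decode() for v in _SUPPORTED_VERSIONS]})"
        )
    off = _parse_header_offsets(buf, base)
    if off["text_begin"] <= 0 or off["text_end"] <= off["text_begin"]:
        raise FormatError("HEADER declares an invalid TEXT segment range")
    text_raw = buf[base + off["text_begin"] : base + off["text_end"] + 1]
    keywords = parse_text_segment(text_raw)

    data_begin, data_end = off["data_begin"], off["data_end"]
    if data_begin == 0:  # FCS 3.x convention for large files: TEXT wins
        data_begin = int(keyword_get(keywords, "$BEGINDATA", 0))
        data_end = int(keyword_get(keywords, "$ENDDATA", 0))
    if data_begin <= 0 or data_end < data_begin:
        n_tot = int(keyword_get(keywords, "$TOT", 0))
        if n_tot == 0:
            events = np.empty((0, int(keyword_get(keywords, "$PAR", 0))))
            return (
                Sample(events, _parse_channels(keywords), keywords,
                       source_path=path),
                int(keyword_get(keywords, "$NEXTDATA", 0) or 0),
            )
        raise FormatError("no usable DATA segment offsets in HEADER or TEXT")
    raw = buf[base + data_begin : base + data_end + 1]
    events = decode_data(keywords, raw)
    sample = Sample(events, _parse_channels(keywords), keywords, source_path=path)
    nextdata = int(keyword_get(keywords, "$NEXTDATA", 0) or 0)
    return sample, nextdata


def read_fcs(path) -> list[Sample]:
    """Read an FCS 2.0/3.0/3.1 file, returning one :class:`Sample` per dataset.

    Datasets are chained through ``$NEXTDATA`` (offset relative to the start
    of the current dataset) until it is 0 or absent.
    """
    path = os.fspath(path)
    with open(path, "rb") as fh:
        buf = fh.read()
    if buf[:6] not in _SUPPORTED_VERSIONS:
        raise FormatError(
            f"{path}: not an FCS 2.0/3.0/3.1 file (header starts {buf[:6]!r})"
        )
    samples: list[Sample] = []
    base = 0
    seen: set[int] = set()
    while True:
        sample, nextdata = _read_dataset(buf, base, path)
        if len(samples) > 0:
            sample.display_name = f"{sample.display_name}#{len(samples) + 1}"
        samples.append(sample)
        if nextdata == 0:
            break
        base += nextdata
        if base in seen or base >= len(buf):
            raise IntegrityError(f"{path}: $NEXTDATA chain is circular or escapes the file")
        seen.add(base)
    return samples


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_HEADER_LEN = 58
_TEXT_START = 64  # small pad after the 58-byte header, for readability


def _build_dataset(sample: Sample, nextdata: int = 0) -> bytes:
    """Serialize one Sample as an FCS 3.1 dataset block ($DATATYPE=F)."""
    events = np.ascontiguousarray(sample.events, dtype="<f4")
    n_tot, n_par = events.shape
    data_bytes = events.tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width placeholders so the TEXT length is offset-independent
        "$BEGINDATA": "0" * 10,
        "$ENDDATA": "0" * 10,
        "$NEXTDATA": f"{nextdata:010d}",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, ch in enumerate(sample.channels, start=1):
        keywords[f"$P{i}N"] = ch.short_name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}R"] = _format_number(ch.range)
        d, f = ch.amplification
        keywords[f"$P{i}E"] = f"{_format_number(d)},{_format_number(f)}"
        if ch.stain_name:
            keywords[f"$P{i}S"] = ch.stain_name
        if ch.gain != 1.0:
            keywords[f"$P{i}G"] = _format_number(ch.gain)
    # carry through user keywords that do not collide with structural ones
    for k, v in sample.keywords.items():
        if k.upper() not in {kw.upper() for kw in keywords}:
            keywords[k] = v

    text = _serialize_text_segment(keywords)
    text_begin = _TEXT_START
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1
    keywords["$BEGINDATA"] = f"{data_begin:010d}"
    keywords["$ENDDATA"] = f"{data_end:010d}"
    text = _serialize_text_segment(keywords)
    assert text_end == text_begin + len(text) - 1  # placeholder width held

    def fmt(n: int) -> bytes:
        s = str(n)
        if len(s) > 8:
            s = "0"  # too large for the HEADER field; TEXT offsets take over
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        fmt(n) for n in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == _HEADER_LEN
    pad = b" " * (text_begin - _HEADER_LEN)
    return header + pad + text + data_bytes


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_fcs(sample: Sample, path=None) -> bytes:
    """Serialize ``sample`` as a single-dataset FCS 3.1 file.

    Data are written as little-endian float32 ($DATATYPE=F, $PnB=32), so
    ``read_fcs(write_fcs(s))`` reproduces the event matrix to float32
    precision. Returns the bytes; also writes them to ``path`` if given.
    """
    # Sample invariants are enforced by the constructor, but re-check the
    # keyword consistency here since keywords are a mutable dict.
    tot = keyword_get(sample.keywords, "$TOT")
    if tot is not None and int(tot) != sample.n_events:
        raise IntegrityError(f"$TOT={tot} disagrees with {sample.n_events} events")
    par = keyword_get(sample.keywords, "$PAR")
    if par is not None and int(par) != sample.n_channels:
        raise IntegrityError(
            f"$PAR={par} disagrees with {sample.n_channels} channels"
        )
    names = sample.channel_names
    if len(set(names)) != len(names):
        raise IntegrityError(f"duplicate channel short names: {names}")

    blob = _build_dataset(sample)
    if path is not None:
        with open(os.fspath(path), "wb") as fh:
            fh.write(blob)
    return blob
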