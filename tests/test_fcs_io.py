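"""FCS reading/writing: TEXT grammar, DATA decoding, round trips."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytolite import ChannelInfo, Sample, read_fcs, write_fcs
from cytolite.errors import FormatError, IntegrityError, UnsupportedFeatureError
from cytolite.fcs_io import decode_data, keyword_get, parse_text_segment


# ---------------------------------------------------------------------------
# TEXT segment grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        (b"/$PAR/3/$TOT/100/", {"$PAR": "3", "$TOT": "100"}),
        (b"/$CYT/A//B/", {"$CYT": "A/B"}),  # doubled delimiter escapes
        (b"//", {}),
        (b"|$PAR|2|", {"$PAR": "2"}),  # any delimiter byte
    ],
)
def test_parse_text_segment(raw, expected):
    assert parse_text_segment(raw) == expected


@pytest.mark.parametrize(
    "raw",
    [
        b"/$PAR/3/$TOT/",  # odd token count
        b"/$PAR/3",  # missing terminator
    ],
)
def test_parse_text_segment_grammar_errors(raw):
    with pytest.raises(FormatError):
        parse_text_segment(raw)


def test_keyword_lookup_case_insensitive_for_dollar_keywords():
    kw = {"$Par": "3", "custom": "x"}
    assert keyword_get(kw, "$PAR") == "3"
    assert keyword_get(kw, "CUSTOM") is None  # user keywords stay case-sensitive


@settings(derandomize=True, max_examples=50)
@given(
    st.dictionaries(
        st.text(
            alphabet=st.characters(
                min_codepoint=33, max_codepoint=126, exclude_characters="/"
            ),
            min_size=1,
            max_size=10,
        ),
        # values may contain 0, 1 or 2 consecutive *internal* delimiters;
        # leading/trailing delimiters are ambiguous by the grammar itself
        st.text(alphabet=list("ab/"), min_size=1, max_size=12).filter(
            lambda v: "///" not in v
            and not v.startswith("/")
            and not v.endswith("/")
        ),
        min_size=1,
        max_size=8,
    )
)
def test_text_segment_roundtrip(keywords):
    """Serialization and parsing are mutual inverses under escaping."""
    from cytolite.fcs_io import _serialize_text_segment

    raw = _serialize_text_segment(keywords)
    assert parse_text_segment(raw) == keywords


# ---------------------------------------------------------------------------
# DATA decoding
# ---------------------------------------------------------------------------

def _int_keywords(byteord, bits=(16, 16), tot=1, ranges=None):
    kw = {
        "$DATATYPE": "I",
        "$MODE": "L",
        "$BYTEORD": byteord,
        "$PAR": str(len(bits)),
        "$TOT": str(tot),
    }
    for i, b in enumerate(bits, start=1):
        kw[f"$P{i}B"] = str(b)
        kw[f"$P{i}R"] = str(ranges[i - 1]) if ranges else str(2 ** b)
    return kw


def test_decode_integer_big_endian():
    events = decode_data(_int_keywords("4,3,2,1"), bytes([0, 1, 0, 2]))
    assert events.tolist() == [[1.0, 2.0]]


def test_decode_endianness_is_byte_swap():
    raw = bytes([0x12, 0x34, 0xAB, 0xCD])
    le = decode_data(_int_keywords("1,2"), raw)
    be = decode_data(_int_keywords("2,1"), raw)
    swapped = [
        struct.unpack("<H", struct.pack(">H", int(v)))[0] for v in be.ravel()
    ]
    assert le.ravel().tolist() == swapped


def test_decode_integer_masks_to_pnr_bits():
    # $PnR=1024 on a 16-bit channel: stray high bits are stripped (10-bit mask)
    kw = _int_keywords("4,3,2,1", bits=(16,), ranges=(1024,))
    events = decode_data(kw, bytes([0xFF, 0xFF]))
    assert events[0, 0] == 1023


def test_decode_float_empty_data():
    kw = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": "3", "$TOT": "0", "$P1B": "32", "$P2B": "32", "$P3B": "32",
    }
    events = decode_data(kw, b"")
    assert events.shape == (0, 3)


def test_decode_rejects_histogram_mode_and_ascii():
    kw = _int_keywords("1,2")
    with pytest.raises(UnsupportedFeatureError):
        decode_data({**kw, "$MODE": "U"}, b"\x00\x00")
    with pytest.raises(UnsupportedFeatureError):
        decode_data({**kw, "$DATATYPE": "A"}, b"11")


def test_decode_rejects_mixed_widths_for_float():
    kw = {
        "$DATATYPE": "F", "$MODE": "L", "$BYTEORD": "1,2,3,4",
        "$PAR": "2", "$TOT": "1", "$P1B": "32", "$P2B": "16",
    }
    with pytest.raises(FormatError):
        decode_data(kw, b"\x00" * 6)


# ---------------------------------------------------------------------------
# Whole-file reading
# ---------------------------------------------------------------------------

def _minimal_fcs31(tmp_path, values=(1.0, 2.0, 3.0, 4.0)):
    """Hand-assemble a minimal FCS 3.1 file: 2 events x 2 float32 channels."""
    text = (
        "/$BEGINANALYSIS/0/$ENDANALYSIS/0/$BEGINSTEXT/0/$ENDSTEXT/0"
        "/$NEXTDATA/0/$DATATYPE/F/$MODE/L/$BYTEORD/1,2,3,4/$PAR/2/$TOT/2"
        "/$P1N/FL1/$P1B/32/$P1R/1024/$P1E/0,0"
        "/$P2N/FL2/$P2B/32/$P2R/1024/$P2E/0,0/"
    ).encode()
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data = struct.pack("<4f", *values)
    data_end = data_begin + len(data) - 1
    header = b"FCS3.1    " + b"".join(
        str(n).rjust(8).encode() for n in
        (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    path = tmp_path / "minimal.fcs"
    path.write_bytes(header + text + data)
    return path


def test_read_hand_assembled_minimal_file(tmp_path):
    """IEEE-754-encoded bytes decode to the exact float values."""
    samples = read_fcs(_minimal_fcs31(tmp_path))
    assert len(samples) == 1
    s = samples[0]
    assert s.events.tolist() == [[1.0, 2.0], [3.0, 4.0]]
    assert s.channel_names == ["FL1", "FL2"]
    assert s.keywords["$TOT"] == "2"


def test_read_truncated_data_is_integrity_error(tmp_path):
    path = _minimal_fcs31(tmp_path)
    blob = path.read_bytes()
    path.write_bytes(blob[:-4])  # DATA 4 bytes short of $TOT*$PAR*$PnB/8
    with pytest.raises(IntegrityError):
        read_fcs(path)


def test_read_rejects_unknown_version(tmp_path):
    path = tmp_path / "bad.fcs"
    path.write_bytes(b"FCS9.9" + b" " * 100)
    with pytest.raises(FormatError):
        read_fcs(path)


def test_nextdata_chaining_reads_all_datasets(tmp_path):
    """A two-dataset file chained via $NEXTDATA yields two Samples."""
    from cytolite.fcs_io import _build_dataset

    s1 = Sample(np.arange(6, dtype=float).reshape(2, 3),
                [ChannelInfo(f"A{i}") for i in range(3)])
    s2 = Sample(np.arange(12, dtype=float).reshape(4, 3),
                [ChannelInfo(f"A{i}") for i in range(3)])
    block2 = _build_dataset(s2)
    block1 = _build_dataset(s1, nextdata=0)
    # re-serialize block1 with the true offset of the second dataset
    block1 = _build_dataset(s1, nextdata=len(block1))
    path = tmp_path / "chained.fcs"
    path.write_bytes(block1 + block2)
    samples = read_fcs(path)
    assert [s.n_events for s in samples] == [2, 4]
    np.testing.assert_array_equal(samples[1].events,
                                  np.arange(12).reshape(4, 3))


# ---------------------------------------------------------------------------
# Writing + round trips
# ---------------------------------------------------------------------------

def test_write_read_roundtrip(tmp_path, rng, make_sample):
    events = rng.random((10, 3)) * 1e4
    sample = make_sample(events)
    path = tmp_path / "rt.fcs"
    write_fcs(sample, path)
    back = read_fcs(path)[0]
    np.testing.assert_array_equal(back.events, events.astype(np.float32))
    assert back.keywords["$PAR"] == "3"
    assert back.keywords["$TOT"] == "10"


def test_write_is_deterministic(rng, make_sample):
    sample = make_sample(rng.random((1000, 6)))
    assert write_fcs(sample) == write_fcs(sample)


def test_write_escapes_delimiter_in_channel_name(tmp_path):
    sample = Sample(np.ones((2, 1)), [ChannelInfo("FSC/A")])
    path = tmp_path / "slash.fcs"
    write_fcs(sample, path)
    assert read_fcs(path)[0].channel_names == ["FSC/A"]


def test_write_rejects_inconsistent_tot(make_sample, tmp_path):
    sample = make_sample(np.ones((3, 2)))
    sample.keywords["$TOT"] = "99"
    path = tmp_path / "never.fcs"
    with pytest.raises(IntegrityError):
        write_fcs(sample, path)
    assert not path.exists()  # nothing written before the failure


def test_single_value_roundtrip(tmp_path):
    sample = Sample(np.array([[7.0]]), [ChannelInfo("FL1")])
    path = tmp_path / "one.fcs"
    write_fcs(sample, path)
    assert read_fcs(path)[0].events.tolist() == [[7.0]]


def test_stain_names_and_amplification_survive_roundtrip(tmp_path):
    channels = [
        ChannelInfo("APC-A", stain_name="CD19", range=1024,
                    amplification=(4.0, 1.0)),
        ChannelInfo("FSC-A", gain=2.0),
    ]
    sample = Sample(np.ones((5, 2)), channels)
    path = tmp_path / "meta.fcs"
    write_fcs(sample, path)
    back = read_fcs(path)[0]
    assert back.channels[0].stain_name == "CD19"
    assert back.channels[0].amplification == (4.0, 1.0)
    assert back.channels[1].gain == 2.0


def test_pne_zero_offset_is_repaired(tmp_path, make_sample):
    """$PnE='4,0' (log amp, zero offset) is repaired to offset 1 with a warning."""
    sample = make_sample(np.ones((2, 1)), names=["FL1"])
    path = tmp_path / "pne.fcs"
    blob = write_fcs(sample, path)
    path.write_bytes(blob.replace(b"/$P1E/0,0/", b"/$P1E/4,0/"))
    with pytest.warns(UserWarning, match="repairing zero offset"):
        back = read_fcs(path)[0]
    assert back.channels[0].amplification == (4.0, 1.0)


def test_sample_invariants_rejected_at_construction():
    with pytest.raises(IntegrityError):
        Sample(np.ones((2, 2)), [ChannelInfo("A"), ChannelInfo("A")])
    with pytest.raises(IntegrityError):
        Sample(np.ones((2, 2)), [ChannelInfo("A")])
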