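"""Session persistence, batch renaming, and CSV export."""

import csv
import json

import numpy as np
import pytest

from cytolite import (
    IntervalGate,
    PolygonGate,
    Session,
    SpilloverMatrix,
    apply_gate,
    batch_rename,
    export_events_csv,
    export_stats_csv,
    gate_chain_stats,
    load_session,
    save_session,
)
from cytolite.errors import IntegrityError, SessionVersionError, StateError
from cytolite.preprocess import AxisScale, compensate


@pytest.fixture
def session():
    gates = [
        PolygonGate(
            "live", "FSC-A", "SSC-A",
            vertices=np.array([[0.1, 0.2], [3.7, 0.2], [2.0, 5.123456789012345]]),
            scale_y=AxisScale("arcsinh", cofactor=200),
        ),
        IntervalGate("CD19-", "APC-A", -1.5, 3.25,
                     scale=AxisScale("log10", floor=1), use_compensated=True),
    ]
    return Session(
        samples=[{"source_path": "/nonexistent/a.fcs", "display_name": "A"}],
        gates=gates,
        compensation=SpilloverMatrix(("APC-A", "PE-A"),
                                     np.array([[1, 0.123456789], [0.05, 1]])),
        compensation_mode="manual",
        applied={"A": ["live", "CD19-"]},
    )


def test_session_roundtrip_is_field_exact(session, tmp_path):
    path = tmp_path / "s.json"
    save_session(session, path)
    back = load_session(path)
    assert back.version == session.version
    assert back.samples == session.samples
    assert back.applied == session.applied
    assert back.compensation_mode == "manual"
    np.testing.assert_array_equal(
        back.compensation.coefficients, session.compensation.coefficients
    )
    for g1, g2 in zip(back.gates, session.gates):
        assert g1.to_dict() == g2.to_dict()  # bit-exact incl. vertex floats


def test_missing_source_file_is_flagged_not_fatal(session, tmp_path):
    path = tmp_path / "s.json"
    save_session(session, path)
    back = load_session(path)
    assert back.missing_files == ["/nonexistent/a.fcs"]


def test_minimal_session_roundtrip(tmp_path):
    session = Session(samples=[{"source_path": None, "display_name": "only"}])
    path = tmp_path / "min.json"
    save_session(session, path)
    back = load_session(path)
    assert back.gates == [] and back.compensation is None


def test_unresolved_gate_reference_fails_before_writing(tmp_path):
    session = Session(applied={"A": ["G9"]})
    path = tmp_path / "bad.json"
    with pytest.raises(IntegrityError):
        save_session(session, path)
    assert not path.exists()


def test_unknown_schema_version(session, tmp_path):
    path = tmp_path / "s.json"
    save_session(session, path)
    doc = json.loads(path.read_text())
    doc["schema_version"] = "99"
    path.write_text(json.dumps(doc))
    with pytest.raises(SessionVersionError, match="99"):
        load_session(path)


# ---------------------------------------------------------------------------
# batch renaming
# ---------------------------------------------------------------------------

def _named(make_sample, names):
    return [make_sample(np.ones((1, 1)), names=["FL1"], display_name=n)
            for n in names]


def test_batch_rename_prefix_strip(make_sample):
    samples = _named(make_sample, ["Specimen_001_A1", "Specimen_001_A2"])
    out = batch_rename(samples, [("Specimen_001_", "")])
    assert [s.display_name for s in out] == ["A1", "A2"]


def test_batch_rename_empty_mapping_is_identity(make_sample):
    samples = _named(make_sample, ["x", "y"])
    out = batch_rename(samples, [])
    assert [s.display_name for s in out] == ["x", "y"]


def test_batch_rename_first_matching_rule_wins(make_sample):
    samples = _named(make_sample, ["Tube_A"])
    out = batch_rename(samples, [("Tube_", "S_"), ("A", "Z")])
    assert out[0].display_name == "S_A"  # second rule never applied


def test_batch_rename_wildcards_and_duplicates(make_sample):
    samples = _named(make_sample, ["run1_well_A", "run2_well_A"])
    with pytest.warns(UserWarning, match="duplicate"):
        out = batch_rename(samples, [("run?_", "")])
    assert [s.display_name for s in out] == ["well_A", "well_A"]


def test_batch_rename_idempotent_when_no_rematch(make_sample):
    samples = _named(make_sample, ["Specimen_001_A1"])
    rules = [("Specimen_001_", "")]
    once = batch_rename(samples, rules)
    twice = batch_rename(once, rules)
    assert [s.display_name for s in twice] == [s.display_name for s in once]


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def test_export_events_header_and_row_count(make_sample, tmp_path, rng):
    sample = make_sample(rng.random((3, 3)) * 100, names=["FSC-A", "FL1", "FL2"])
    path = tmp_path / "events.csv"
    export_events_csv(sample, path, channels=["FSC-A", "FL1"])
    rows = list(csv.reader(path.open()))
    assert rows[0] == ["FSC-A", "FL1"]
    assert len(rows) == 4  # header + 3 events


def test_export_all_false_mask_is_header_only(make_sample, tmp_path):
    from cytolite.gating import GateMembership

    sample = make_sample(np.ones((5, 2)))
    path = tmp_path / "none.csv"
    export_events_csv(sample, path, mask=GateMembership("g", [False] * 5))
    assert len(list(csv.reader(path.open()))) == 1


def test_export_csv_reimports_exactly(make_sample, tmp_path, rng):
    """Full-precision serialization: the CSV reproduces the gated matrix."""
    sample = make_sample(rng.lognormal(5, 2, (50, 2)))
    gate = IntervalGate("g", "FL1", 0.0, float(np.median(sample.data("FL1"))))
    mask = apply_gate(sample, gate)
    path = tmp_path / "gated.csv"
    export_events_csv(sample, path, mask=mask)
    rows = list(csv.reader(path.open()))[1:]
    reimported = np.array([[float(v) for v in row] for row in rows])
    np.testing.assert_array_equal(reimported, sample.events[mask.mask])


def test_export_compensated_requires_compensation(make_sample, tmp_path, rng):
    sample = make_sample(rng.random((4, 2)))
    with pytest.raises(StateError):
        export_events_csv(sample, tmp_path / "x.csv", compensated=True)
    spill = SpilloverMatrix(("FL1", "FL2"), np.array([[1, 0.1], [0, 1]]))
    comp = compensate(sample, spill)
    path = tmp_path / "comp.csv"
    export_events_csv(comp, path, compensated=True)
    rows = list(csv.reader(path.open()))[1:]
    np.testing.assert_array_equal(
        np.array(rows, dtype=float), comp.events
    )
    # raw export from the compensated sample emits the original values
    export_events_csv(comp, path, compensated=False)
    rows = list(csv.reader(path.open()))[1:]
    np.testing.assert_array_equal(np.array(rows, dtype=float), sample.events)


def test_export_stain_names_in_header(tmp_path):
    from cytolite import ChannelInfo, Sample

    sample = Sample(np.ones((1, 1)), [ChannelInfo("APC-A", stain_name="CD19")])
    path = tmp_path / "stain.csv"
    export_events_csv(sample, path)
    assert path.read_text().splitlines()[0] == "APC-A (CD19)"


def test_export_stats_csv_rendering(make_sample, tmp_path):
    fl1 = np.where(np.arange(1000) < 800, 5.0, 50.0)
    fl2 = np.where(np.arange(1000) < 600, 5.0, 50.0)
    sample = make_sample(np.column_stack([fl1, fl2]))
    records = gate_chain_stats(
        sample,
        [IntervalGate("A", "FL1", 0, 10), IntervalGate("B", "FL2", 0, 10)],
    )
    path = tmp_path / "stats.csv"
    export_stats_csv(records, path)
    rows = list(csv.reader(path.open()))
    assert len(rows) == 4  # header + total + A + A>B
    by_chain = {r[1]: r for r in rows[1:]}
    assert by_chain["A"][3] == "80.00"
    assert by_chain["A > B"][3] == "75.00"
    assert by_chain["A > B"][4] == "60.00"


def test_export_stats_csv_empty_and_duplicates(make_sample, tmp_path):
    path = tmp_path / "empty.csv"
    export_stats_csv([], path)
    assert len(path.read_text().splitlines()) == 1
    sample = make_sample(np.ones((4, 1)), names=["FL1"])
    rec = gate_chain_stats(sample, [])[0]
    export_stats_csv([rec, rec], path)  # duplicates emitted verbatim
    assert len(path.read_text().splitlines()) == 3
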