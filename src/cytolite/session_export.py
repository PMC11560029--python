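"""Session persistence, batch renaming, and CSV export.

A session is a versioned JSON document — transparent and diffable — holding
the sample registry (source paths and display names), the gate definitions,
the compensation settings, and which gate chain is applied to which sample.
Numbers are serialized at full precision (Python's ``repr`` of a float
round-trips exactly), so ``load(save(session))`` is field-exact including
gate vertex coordinates.

CSV dialect: comma delimiter, ``.`` decimal point, LF line endings, UTF-8.
Event values are written with full-precision ``repr`` so a re-imported CSV
reproduces the in-memory gated matrix exactly.
"""

from __future__ import annotations

import csv
import json
import os
import re
import warnings
from dataclasses import dataclass, field

from .errors import (
    ChannelNotFoundError,
    IntegrityError,
    SessionVersionError,
    StateError,
)
from .fcs_io import Sample
from .gating import GateMembership, IntervalGate, PolygonGate, gate_from_dict
from .preprocess import SpilloverMatrix
from .stats import StatRecord

__all__ = [
    "Session",
    "SESSION_SCHEMA_VERSION",
    "save_session",
    "load_session",
    "batch_rename",
    "export_events_csv",
    "export_stats_csv",
]

SESSION_SCHEMA_VERSION = "1"
_SUPPORTED_VERSIONS = ("1",)

#: Summary statistics emitted per channel in the stats CSV, in column order.
_SUMMARY_FIELDS = ("mean", "median", "geometric_mean", "cv")


@dataclass
class Session:
    """Persistable analysis state."""

    version: str = SESSION_SCHEMA_VERSION
    samples: list[dict] = field(default_factory=list)  # {source_path, display_name}
    gates: list = field(default_factory=list)  # PolygonGate | IntervalGate
    compensation: SpilloverMatrix | None = None
    compensation_mode: str = "none"  # "auto" | "manual" | "none"
    applied: dict[str, list[str]] = field(default_factory=dict)
    missing_files: list[str] = field(default_factory=list)

    def validate(self) -> None:
        names = [g.name for g in self.gates]
        if len(set(names)) != len(names):
            raise IntegrityError(f"duplicate gate names: {names}")
        defined = set(names)
        for sample_name, chain in self.applied.items():
            for gate_name in chain:
                if gate_name not in defined:
                    raise IntegrityError(
                        f"sample {sample_name!r} references undefined gate "
                        f"{gate_name!r}"
                    )
        if self.compensation_mode not in ("auto", "manual", "none"):
            raise IntegrityError(
                f"unknown compensation mode {self.compensation_mode!r}"
            )

    def gate(self, name: str):
        for g in self.gates:
            if g.name == name:
                return g
        raise IntegrityError(f"gate {name!r} is not defined in this session")

    def chain_for(self, display_name: str) -> list:
        return [self.gate(n) for n in self.applied.get(display_name, [])]


def save_session(session: Session, path) -> None:
    """Write the session as a versioned JSON document (full precision)."""
    session.validate()
    doc = {
        "schema_version": session.version,
        "samples": [
            {"source_path": s.get("source_path"), "display_name": s.get("display_name")}
            for s in session.samples
        ],
        "gates": [g.to_dict() for g in session.gates],
        "compensation": {
            "mode": session.compensation_mode,
            "matrix": session.compensation.to_dict() if session.compensation else None,
        },
        "applied": {k: list(v) for k, v in session.applied.items()},
    }
    with open(os.fspath(path), "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_session(path) -> Session:
    """Read a session JSON document, re-validating all invariants.

    Sample source files missing on disk are tolerated: they are recorded in
    ``missing_files`` and only fail when data access is actually attempted.
    """
    with open(os.fspath(path), "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    version = str(doc.get("schema_version"))
    if version not in _SUPPORTED_VERSIONS:
        raise SessionVersionError(
            f"session schema version {version!r} is not supported "
            f"(supported: {_SUPPORTED_VERSIONS})"
        )
    comp_doc = doc.get("compensation") or {}
    matrix_doc = comp_doc.get("matrix")
    session = Session(
        version=version,
        samples=list(doc.get("samples", [])),
        gates=[gate_from_dict(d) for d in doc.get("gates", [])],
        compensation=SpilloverMatrix.from_dict(matrix_doc) if matrix_doc else None,
        compensation_mode=comp_doc.get("mode", "none"),
        applied={k: list(v) for k, v in doc.get("applied", {}).items()},
    )
    session.validate()
    for entry in session.samples:
        src = entry.get("source_path")
        if src and not os.path.exists(src):
            session.missing_files.append(src)
    return session


def _rule_to_regex(pattern: str) -> re.Pattern:
    """Rename-rule dialect: literal text with ``*`` (any run) and ``?`` (one char)."""
    return re.compile(
        "".join(
            ".*" if ch == "*" else "." if ch == "?" else re.escape(ch)
            for ch in pattern
        )
    )


def batch_rename(samples: list[Sample], mapping) -> list[Sample]:
    """Rename sample display names by an ordered rule list.

    Each rule is a ``(pattern, replacement)`` pair; the pattern is literal
    text, optionally with ``*`` / ``?`` wildcards, matched anywhere in the
    name. The first matching rule wins per sample (only its first occurrence
    is replaced); non-matching names pass through unchanged. Duplicate
    resulting names are allowed but flagged with a warning.
    """
    rules = [(_rule_to_regex(p), repl) for p, repl in mapping]
    renamed: list[Sample] = []
    for sample in samples:
        name = sample.display_name
        for regex, repl in rules:
            if regex.search(name):
                # lambda keeps the replacement literal (no backref expansion)
                name = regex.sub(lambda m, r=repl: r, name, count=1)
                break
        if name != sample.display_name:
            sample = Sample(
                events=sample.events,
                channels=sample.channels,
                keywords=dict(sample.keywords),
                source_path=sample.source_path,
                display_name=name,
                scaled=sample.scaled,
                compensated_channels=sample.compensated_channels,
                raw_events=sample.raw_events,
            )
        renamed.append(sample)
    names = [s.display_name for s in renamed]
    dups = {n for n in names if names.count(n) > 1}
    if dups:
        warnings.warn(f"batch_rename produced duplicate names: {sorted(dups)}")
    return renamed


def _header_label(sample: Sample, name: str) -> str:
    ch = sample.channels[sample.channel_index(name)]
    return f"{ch.short_name} ({ch.stain_name})" if ch.stain_name else ch.short_name


def export_events_csv(
    sample: Sample,
    path,
    mask: GateMembership | None = None,
    channels: list[str] | None = None,
    compensated: bool = False,
) -> None:
    """Write (gated) events as CSV, one row per event in original order.

    The header holds $PnN short names, with the stain name in parentheses
    when present. ``compensated`` selects the current (compensated) working
    values and requires the sample to actually be compensated; ``False``
    selects the uncompensated values (``raw_events`` when compensation has
    replaced the working matrix). Values are full-precision.
    """
    if channels is None:
        channels = sample.channel_names
    else:
        for name in channels:
            sample.channel_index(name)  # raises ChannelNotFoundError
    if compensated:
        if not sample.compensated_channels:
            raise StateError(
                f"sample {sample.display_name!r} has no compensated values"
            )
        matrix = sample.events
    else:
        matrix = sample.raw_events if sample.compensated_channels else sample.events
    idx = [sample.channel_index(n) for n in channels]
    rows = matrix[:, idx]
    if mask is not None:
        if len(mask) != sample.n_events:
            raise IntegrityError(
                f"mask length {len(mask)} does not match {sample.n_events} events"
            )
        rows = rows[mask.mask]
    with open(os.fspath(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_header_label(sample, n) for n in channels)
        for row in rows:
            writer.writerow(repr(float(v)) for v in row)


def export_stats_csv(records: list[StatRecord], path) -> None:
    """Write a hierarchical stats table as long-format CSV.

    Columns: sample, gate_chain (names joined with " > "), count,
    pct_of_parent, pct_of_total, then per-channel summaries in order of first
    appearance. Percentages are rendered to 0.01%; channel summaries at full
    precision. Duplicate (sample, chain) records are emitted verbatim.
    """
    channel_order: list[str] = []
    for rec in records:
        for name in rec.per_channel:
            if name not in channel_order:
                channel_order.append(name)
    header = ["sample", "gate_chain", "count", "pct_of_parent", "pct_of_total",
              "basis"]
    for name in channel_order:
        header.extend(f"{name}:{stat}" for stat in _SUMMARY_FIELDS)
    with open(os.fspath(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for rec in records:
            row = [
                rec.sample_name,
                " > ".join(rec.gate_chain) if rec.gate_chain else "(total)",
                str(rec.count),
                f"{rec.pct_of_parent:.2f}",
                f"{rec.pct_of_total:.2f}",
                rec.basis,
            ]
            for name in channel_order:
                summary = rec.per_channel.get(name, {})
                for stat in _SUMMARY_FIELDS:
                    val = summary.get(stat)
                    row.append("" if val is None or summary.get("empty") else repr(float(val)))
            writer.writerow(row)
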