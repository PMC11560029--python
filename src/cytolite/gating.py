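"""Global, order-independent gates.

Gates here are independent objects, not nodes of a hierarchy: a gate defined
once can be applied to any sample, alone or combined with others, and because
combination is plain set intersection the application order is fully
commutative — a chain A∘B selects exactly the same events as B∘A.

Two geometries are supported: a 2D polygon over a channel pair and a 1D
interval over one channel. Each gate stores the axis scales its coordinates
were drawn under, and membership is always evaluated in that transformed
space, so a gate drawn on a log axis means the same region for every sample
regardless of the current display scale.

Boundary convention (documented, since counts must be reproducible): points
exactly on a polygon edge or at an interval's ``low`` endpoint are inside;
``high`` is exclusive (half-open interval). Self-intersecting polygons are
accepted and interpreted by the even-odd rule, matching typical drawing
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GateDefinitionError, IntegrityError, ParameterError, StateError
from .fcs_io import Sample
from .preprocess import AxisScale, LINEAR, SpilloverMatrix, compensate

__all__ = [
    "PolygonGate",
    "IntervalGate",
    "GateMembership",
    "point_in_polygon",
    "points_in_polygon",
    "apply_gate",
    "combine_masks",
]


@dataclass(frozen=True, eq=False)  # eq=False: ndarray fields break field-wise ==
class PolygonGate:
    """Closed polygon over a channel pair, in gating-space coordinates."""

    name: str
    channel_x: str
    channel_y: str
    vertices: np.ndarray = field(repr=False)  # (n, 2), implicitly closed
    scale_x: AxisScale = LINEAR
    scale_y: AxisScale = LINEAR
    use_compensated: bool = False

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=np.float64)
        object.__setattr__(self, "vertices", verts)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise GateDefinitionError(
                f"gate {self.name!r}: a polygon needs >= 3 (x, y) vertices"
            )
        if self.channel_x == self.channel_y:
            raise GateDefinitionError(
                f"gate {self.name!r}: channel_x and channel_y must differ"
            )

    def to_dict(self) -> dict:
        return {
            "type": "polygon",
            "name": self.name,
            "channel_x": self.channel_x,
            "channel_y": self.channel_y,
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
            "scale_x": self.scale_x.to_dict(),
            "scale_y": self.scale_y.to_dict(),
            "use_compensated": self.use_compensated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolygonGate":
        return cls(
            name=d["name"],
            channel_x=d["channel_x"],
            channel_y=d["channel_y"],
            vertices=np.asarray(d["vertices"]),
            scale_x=AxisScale.from_dict(d["scale_x"]),
            scale_y=AxisScale.from_dict(d["scale_y"]),
            use_compensated=d.get("use_compensated", False),
        )


@dataclass(frozen=True)
class IntervalGate:
    """Half-open interval ``[low, high)`` on one channel, in gating space."""

    name: str
    channel: str
    low: float
    high: float
    scale: AxisScale = LINEAR
    use_compensated: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise GateDefinitionError(
                f"gate {self.name!r}: low ({self.low}) must be < high ({self.high})"
            )

    def to_dict(self) -> dict:
        return {
            "type": "interval",
            "name": self.name,
            "channel": self.channel,
            "low": float(self.low),
            "high": float(self.high),
            "scale": self.scale.to_dict(),
            "use_compensated": self.use_compensated,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalGate":
        return cls(
            name=d["name"],
            channel=d["channel"],
            low=d["low"],
            high=d["high"],
            scale=AxisScale.from_dict(d["scale"]),
            use_compensated=d.get("use_compensated", False),
        )


def gate_from_dict(d: dict):
    """Deserialize a gate from its session-JSON form."""
    kind = d.get("type")
    if kind == "polygon":
        return PolygonGate.from_dict(d)
    if kind == "interval":
        return IntervalGate.from_dict(d)
    raise GateDefinitionError(f"unknown gate type {kind!r}")


@dataclass
class GateMembership:
    """Per-event boolean membership of one gate (or gate combination)."""

    gate_name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 1:
            raise IntegrityError("membership mask must be 1-dimensional")

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def __len__(self) -> int:
        return len(self.mask)


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray casting) containment test.

    Points exactly on an edge count as inside. The polygon is implicitly
    closed; self-intersections follow the even-odd rule.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise GateDefinitionError("a polygon needs >= 3 (x, y) vertices")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    on_edge = np.zeros(len(points), dtype=bool)

    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        # horizontal ray toward +x: does edge (1→2) straddle py?
        straddles = (y1 > py) != (y2 > py)
        if y1 != y2:
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= straddles & (px < x_int)
        # exact on-segment test (boundary counts as inside)
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (px >= min(x1, x2)) & (px <= max(x1, x2))
            & (py >= min(y1, y2)) & (py <= max(y1, y2))
        )
        on_edge |= (cross == 0) & within
    return inside | on_edge


def point_in_polygon(point, vertices) -> bool:
    """Scalar convenience wrapper around :func:`points_in_polygon`."""
    return bool(points_in_polygon(np.asarray(point)[None, :], vertices)[0])


def _gate_values(sample: Sample, gate, comp: SpilloverMatrix | None) -> Sample:
    if getattr(gate, "use_compensated", False):
        if comp is not None:
            return compensate(sample, comp)
        if sample.compensated_channels:
            return sample
        raise StateError(
            f"gate {gate.name!r} requires compensated data but no spillover "
            "matrix was provided and the sample is not compensated"
        )
    return sample


def apply_gate(
    sample: Sample,
    gate: PolygonGate | IntervalGate,
    comp: SpilloverMatrix | None = None,
) -> GateMembership:
    """Evaluate one gate on a sample, returning per-event membership.

    Channel values are transformed by the gate's stored axis scales before
    the containment / interval test. A gate naming a channel absent from the
    sample raises :class:`ChannelNotFoundError` rather than silently
    returning an all-false mask.
    """
    src = _gate_values(sample, gate, comp)
    if isinstance(gate, PolygonGate):
        x = gate.scale_x.apply(src.data(gate.channel_x))
        y = gate.scale_y.apply(src.data(gate.channel_y))
        mask = points_in_polygon(np.column_stack([x, y]), gate.vertices)
    elif isinstance(gate, IntervalGate):
        v = gate.scale.apply(src.data(gate.channel))
        mask = (v >= gate.low) & (v < gate.high)
    else:
        raise GateDefinitionError(f"unknown gate object {type(gate).__name__}")
    return GateMembership(gate.name, mask)


def combine_masks(
    masks: list[GateMembership],
    n_events: int | None = None,
) -> GateMembership:
    """Intersect memberships (element-wise AND); order-independent.

    The empty combination is the identity element: all events pass
    (``n_events`` is then required to size the mask).
    """
    if not masks:
        if n_events is None:
            raise ParameterError(
                "combining an empty mask list requires n_events"
            )
        return GateMembership("", np.ones(n_events, dtype=bool))
    length = len(masks[0])
    out = np.ones(length, dtype=bool)
    for m in masks:
        if len(m) != length:
            raise IntegrityError(
                f"mask {m.gate_name!r} has length {len(m)}, expected {length}"
            )
        out &= m.mask
    name = " & ".join(sorted(m.gate_name for m in masks))
    return GateMembership(name, out)
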