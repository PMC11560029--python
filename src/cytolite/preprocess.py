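"""Channel scaling, axis transforms, and spillover compensation.

Spillover between fluorescence detectors is modelled linearly: with ``t`` the
row vector of true per-dye signals and ``S`` the spillover matrix in the
row-stain convention (``S[i, j]`` = fraction of dye *i*'s signal read by
detector *j*, ``S[i, i] = 1``), the observed vector is ``o = t · S``.
Compensation inverts this: ``t = o · S⁻¹``.

Compensation operates on linear (scaled) values and is applied before any
display/gating axis transform, since spillover is physically linear in light
intensity. The automatic estimator uses per-channel medians of single-stain
controls with background subtraction — robust against the heavy outlier tails
of cytometry data, where a least-squares fit on raw events would be dominated
by a few saturated events.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ChannelNotFoundError,
    DegenerateControlError,
    FormatError,
    ParameterError,
    SingularMatrixError,
    StateError,
)
from .fcs_io import Sample

__all__ = [
    "AxisScale",
    "SpilloverMatrix",
    "LINEAR",
    "apply_channel_scaling",
    "parse_spillover",
    "compensate",
    "estimate_spillover",
    "transform_axis",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class AxisScale:
    """A strictly monotone transform defining a display/gating coordinate.

    kind:
        ``"linear"`` (identity), ``"log10"`` (values below ``floor`` are
        clamped to ``floor`` first), or ``"arcsinh"``
        (``asinh(value / cofactor)``, linear near zero, logarithmic above
        ~``cofactor``; the default cofactor of 150 suits typical fluorescence
        intensities).
    """

    kind: str = "linear"
    cofactor: float = 150.0
    floor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "log10", "arcsinh"):
            raise ParameterError(f"unknown axis scale kind {self.kind!r}")
        if self.kind == "arcsinh" and self.cofactor <= 0:
            raise ParameterError("arcsinh cofactor must be positive")
        if self.kind == "log10" and self.floor <= 0:
            raise ParameterError("log10 floor must be positive")

    def apply(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=np.float64)
        if self.kind == "linear":
            return values
        if self.kind == "log10":
            return np.log10(np.maximum(values, self.floor))
        return np.arcsinh(values / self.cofactor)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "arcsinh":
            d["cofactor"] = self.cofactor
        if self.kind == "log10":
            d["floor"] = self.floor
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AxisScale":
        return cls(**d)


LINEAR = AxisScale("linear")


def transform_axis(values, scale: AxisScale) -> np.ndarray:
    """Element-wise monotone transform of ``values`` under ``scale``."""
    return scale.apply(values)


def apply_channel_scaling(sample: Sample) -> Sample:
    """Convert stored channel values to linear scale per $PnE/$PnG.

    A channel with log amplification ``(d, f)`` on range ``R`` maps a stored
    value ``c`` to ``f · 10^(d·c/R)``; a linear channel maps ``c`` to
    ``c / gain``. Returns a new Sample flagged ``scaled`` (applying twice is a
    :class:`StateError`); the stored values are kept in ``raw_events``.
    """
    if sample.scaled:
        raise StateError(f"sample {sample.display_name!r} is already scaled")
    events = sample.events.copy()
    for i, ch in enumerate(sample.channels):
        d, f = ch.amplification
        if (d, f) == (0.0, 0.0):
            if ch.gain != 1.0:
                events[:, i] = events[:, i] / ch.gain
        else:
            events[:, i] = f * np.power(10.0, d * events[:, i] / ch.range)
    return replace(
        sample,
        events=events,
        raw_events=sample.events,
        scaled=True,
        keywords=dict(sample.keywords),
    )


@dataclass(frozen=True, eq=False)  # eq=False: ndarray fields break field-wise ==
class SpilloverMatrix:
    """Square spillover matrix keyed to an ordered channel subset.

    Row-stain convention: ``coefficients[i, j]`` is the fraction of channel
    ``channel_names[i]``'s true signal observed on detector
    ``channel_names[j]``. The diagonal is 1 by definition.
    """

    channel_names: tuple[str, ...]
    coefficients: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coefficients, dtype=np.float64)
        object.__setattr__(self, "coefficients", coeff)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        k = len(self.channel_names)
        if coeff.shape != (k, k):
            raise FormatError(
                f"spillover matrix shape {coeff.shape} does not match "
                f"{k} channel names"
            )
        if k and not np.allclose(np.diag(coeff), 1.0, atol=1e-9):
            raise FormatError(
                f"spillover diagonal must be 1; got {np.diag(coeff)}"
            )
        if k and np.linalg.cond(coeff) > _COND_LIMIT:
            raise SingularMatrixError(
                "spillover matrix is singular or numerically non-invertible"
            )

    @property
    def k(self) -> int:
        return len(self.channel_names)

    def to_keyword_value(self) -> str:
        """$SPILLOVER keyword encoding: 'k,name_1..name_k,k² numbers'."""
        nums = ",".join(repr(float(x)) for x in self.coefficients.ravel())
        return f"{self.k},{','.join(self.channel_names)},{nums}"

    def to_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "coefficients": [[float(x) for x in row] for row in self.coefficients],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpilloverMatrix":
        return cls(tuple(d["channel_names"]), np.asarray(d["coefficients"]))

    @classmethod
    def identity(cls, channel_names) -> "SpilloverMatrix":
        names = tuple(channel_names)
        return cls(names, np.eye(len(names)))

    def to_csv(self) -> str:
        """CSV form: header row of channel names, then k rows of k numbers."""
        lines = [",".join(self.channel_names)]
        for row in self.coefficients:
            lines.append(",".join(repr(float(x)) for x in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str) -> "SpilloverMatrix":
        rows = [line.strip() for line in io.StringIO(text) if line.strip()]
        if not rows:
            raise FormatError("empty spillover CSV")
        names = tuple(tok.strip() for tok in rows[0].split(","))
        k = len(names)
        if len(rows) != k + 1:
            raise FormatError(
                f"spillover CSV declares {k} channels but has {len(rows) - 1} "
                "matrix rows"
            )
        coeff = np.array(
            [[float(tok) for tok in row.split(",")] for row in rows[1:]]
        )
        return cls(names, coeff)


def parse_spillover(value: str, all_channels: list[str]) -> SpilloverMatrix:
    """Parse the FCS spillover keyword grammar: ``k,name_1..name_k,k² numbers``."""
    tokens = [tok.strip() for tok in value.split(",")]
    try:
        k = int(tokens[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"spillover value does not start with a count: {value!r}") from exc
    if k < 1:
        raise FormatError(f"spillover channel count must be >= 1; got {k}")
    if len(tokens) != 1 + k + k * k:
        raise FormatError(
            f"spillover value for k={k} needs {1 + k + k * k} tokens; "
            f"got {len(tokens)}"
        )
    names = tuple(tokens[1 : 1 + k])
    for name in names:
        if name not in all_channels:
            raise ChannelNotFoundError(
                f"spillover names channel {name!r} not present in the sample"
            )
    try:
        coeff = np.array([float(tok) for tok in tokens[1 + k :]]).reshape(k, k)
    except ValueError as exc:
        raise FormatError(f"non-numeric spillover coefficient in {value!r}") from exc
    return SpilloverMatrix(names, coeff)


def compensate(sample: Sample, spill: SpilloverMatrix) -> Sample:
    """Remove spillover from the channels named in ``spill``.

    Solves ``true = observed · S⁻¹`` for the spill channels; all other
    channels are untouched. The uncompensated matrix is retained in
    ``raw_events`` so exports can emit either form.
    """
    idx = [sample.channel_index(name) for name in spill.channel_names]
    observed = sample.events[:, idx]
    try:
        # observed = true · S  ⇔  Sᵀ · trueᵀ = observedᵀ
        true = np.linalg.solve(spill.coefficients.T, observed.T).T
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError("spillover matrix is singular") from exc
    events = sample.events.copy()
    events[:, idx] = true
    return replace(
        sample,
        events=events,
        raw_events=sample.events,
        compensated_channels=spill.channel_names,
        keywords=dict(sample.keywords),
    )


def estimate_spillover(
    controls: dict[str, Sample],
    unstained: Sample | None = None,
) -> SpilloverMatrix:
    """Estimate a spillover matrix from single-stain controls.

    For the control stained for channel *i*, coefficient ``(i, j)`` is::

        (median_j(control_i) − background_j) / (median_i(control_i) − background_i)

    with backgrounds taken from the unstained sample's medians (0 if absent)
    and the diagonal forced to 1. Channel order follows the ``controls`` map.
    """
    names = tuple(controls)
    k = len(names)
    if unstained is not None:
        background = {n: float(np.median(unstained.data(n))) for n in names}
    else:
        background = {n: 0.0 for n in names}
    coeff = np.eye(k)
    for i, stain in enumerate(names):
        ctrl = controls[stain]
        denom = float(np.median(ctrl.data(stain))) - background[stain]
        if denom <= 0:
            raise DegenerateControlError(
                f"control for {stain!r} has no positive signal on its own "
                "channel after background subtraction"
            )
        for j, det in enumerate(names):
            if i == j:
                continue
            num = float(np.median(ctrl.data(det))) - background[det]
            coeff[i, j] = num / denom
    return SpilloverMatrix(names, coeff)
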