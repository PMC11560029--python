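"""Synthetic flow-cytometry data with known ground truth.

Emulates a T-cell activation experiment: Jurkat-style T cells co-cultured 1:1
with CD19⁺ B-line antigen-presenting cells under three peptide doses (none /
low / high), stained for CD19 (B-cell marker, APC-A), CD3 (TCR subunit,
Pacific Blue-A) and CD69 (activation marker, PE-A). The event mixture holds
debris/dead cells, cell doublets, B cells, and T cells split by CD3 and CD69
status, with linear spillover applied to the true fluorescence signals.

Every event carries a truth label, so gating, compensation and statistics can
be validated against designed population parameters. All numeric population
parameters (fractions, log-normal locations and widths, scatter means) are
package defaults chosen to make the populations separable the way a clean
real experiment is; they are not measurements of any particular dataset. The
CD69⁺ fractions per condition ({none: 0.05, low: 0.40, high: 0.80}) are
likewise configurable design defaults.

Scatter channels are drawn from normal distributions; fluorescence channels
from log-normals parameterized in log10 units. Doublets have FSC-A ≈ 2·FSC-H
(two cells' area at one cell's peak height); singlets have FSC-A ≈ FSC-H.
Each sample role (main sample, each compensation control, unstained) draws
from its own random stream seeded by ``(seed, role)``, so adding a control
never perturbs the main sample's events.

Instrument noise physics (photon statistics, baseline restoration, time
drift) is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import IntegrityError, ParameterError
from .fcs_io import ChannelInfo, Sample
from .gating import IntervalGate, PolygonGate
from .preprocess import AxisScale, SpilloverMatrix

__all__ = [
    "PopulationSpec",
    "ExperimentSpec",
    "SimulationTruth",
    "CONDITIONS",
    "default_tcell_spec",
    "default_tcell_gates",
    "simulate_experiment",
    "make_singlestain_controls",
    "write_truth_csv",
]

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")
FLUOR_CHANNELS = ("APC-A", "Pacific Blue-A", "PE-A")
MARKER_TO_CHANNEL = {"CD19": "APC-A", "CD3": "Pacific Blue-A", "CD69": "PE-A"}
STAIN_NAMES = {"APC-A": "CD19", "Pacific Blue-A": "CD3", "PE-A": "CD69"}

CONDITIONS = ("none", "low", "high")
#: Designed CD69+ fraction among live-singlet CD19− CD3+ T cells, per peptide
#: condition. Package defaults, configurable through ExperimentSpec.
DEFAULT_CD69_POSITIVE_FRACTION = {"none": 0.05, "low": 0.40, "high": 0.80}

CHANNEL_RANGE = 2 ** 24  # $PnR written to the FCS files

# log10-units locations/widths of the fluorescence clusters
_NEG = (2.0, 0.3)  # autofluorescence / unstained background
_CD19_POS = (4.5, 0.15)
_CD3_POS = (4.0, 0.15)
_CD69_POS = (3.8, 0.2)

#: Default spillover over (APC-A, Pacific Blue-A, PE-A); row = dye,
#: column = detector.
DEFAULT_SPILLOVER = SpilloverMatrix(
    FLUOR_CHANNELS,
    np.array(
        [
            [1.00, 0.03, 0.08],
            [0.02, 1.00, 0.12],
            [0.10, 0.05, 1.00],
        ]
    ),
)

# stable per-role stream indices for (seed, role) seeding
_ROLE_STREAM = {
    "main": 0,
    "control:APC-A": 1,
    "control:Pacific Blue-A": 2,
    "control:PE-A": 3,
    "unstained": 4,
}


@dataclass(frozen=True)
class PopulationSpec:
    """One mixture component of the simulated cell suspension.

    ``fsc_h`` is (mean, sd) of a normal in raw scatter units; ``fsc_a_ratio``
    relates FSC-A to FSC-H per event (≈1 for singlets, ≈2 for doublets) with
    additive noise ``fsc_a_noise``. ``ssc`` is (mean, sd). ``fluor`` maps
    each fluorescence channel to a (location, scale) pair of a log-normal in
    log10 units: the true signal is ``10^N(location, scale)``.
    """

    label: str
    fraction: float
    fsc_h: tuple[float, float]
    ssc: tuple[float, float]
    fluor: dict[str, tuple[float, float]]
    fsc_a_ratio: float = 1.0
    fsc_a_noise: float = 8000.0
    doublet: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ParameterError(
                f"population {self.label!r}: fraction must be in [0, 1]"
            )


@dataclass(frozen=True)
class ExperimentSpec:
    """Full description of one simulated acquisition."""

    n_events: int
    condition: str
    cd69_positive_fraction: float
    populations: tuple[PopulationSpec, ...]
    spillover: SpilloverMatrix = DEFAULT_SPILLOVER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ParameterError("n_events must be positive")
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition must be one of {CONDITIONS}; got {self.condition!r}"
            )
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"population fractions sum to {total}, not 1")
        if tuple(self.spillover.channel_names) != FLUOR_CHANNELS:
            raise IntegrityError(
                "spillover matrix must cover exactly the fluorescence channels "
                f"{FLUOR_CHANNELS} (got {self.spillover.channel_names})"
            )


@dataclass
class SimulationTruth:
    """Ground truth aligned to the simulated event rows."""

    labels: np.ndarray  # per-event population label (str)
    true_fluorescence: np.ndarray  # (n_events, 3) pre-spillover signals


def default_tcell_spec(
    condition: str,
    n_events: int = 20000,
    seed: int = 0,
    cd69_positive_fraction: float | None = None,
    spillover: SpilloverMatrix = DEFAULT_SPILLOVER,
) -> ExperimentSpec:
    """Default mixture for the T-cell activation experiment.

    Composition: 15% debris/dead, 10% doublets, and live singlets split 1:1
    between B cells (CD19⁺) and T cells (CD19⁻), matching the 1:1 co-culture.
    80% of T cells express CD3; among live-singlet CD3⁺ T cells the CD69⁺
    fraction is the per-condition default (or an explicit override).
    """
    if condition not in CONDITIONS:
        raise ParameterError(
            f"condition must be one of {CONDITIONS}; got {condition!r}"
        )
    p_act = (
        DEFAULT_CD69_POSITIVE_FRACTION[condition]
        if cd69_positive_fraction is None
        else cd69_positive_fraction
    )
    if not 0 <= p_act <= 1:
        raise ParameterError("cd69_positive_fraction must be in [0, 1]")

    live = 0.75
    b_frac = live * 0.5
    t_frac = live * 0.5
    t_cd3pos = t_frac * 0.8
    t_cd3neg = t_frac * 0.2

    neg = dict.fromkeys(FLUOR_CHANNELS, _NEG)

    def fluor(cd19=False, cd3=False, cd69=False):
        return {
            "APC-A": _CD19_POS if cd19 else _NEG,
            "Pacific Blue-A": _CD3_POS if cd3 else _NEG,
            "PE-A": _CD69_POS if cd69 else _NEG,
        }

    populations = (
        PopulationSpec(
            label="debris",
            fraction=0.15,
            fsc_h=(40000, 15000),
            ssc=(25000, 10000),
            fluor=neg,
            fsc_a_noise=5000.0,
        ),
        PopulationSpec(
            label="doublet",
            fraction=0.10,
            fsc_h=(210000, 25000),
            ssc=(140000, 30000),
            # B+T aggregates read positive for both lineage markers
            fluor=fluor(cd19=True, cd3=True),
            fsc_a_ratio=2.0,
            fsc_a_noise=15000.0,
            doublet=True,
        ),
        PopulationSpec(
            label="B",
            fraction=b_frac,
            fsc_h=(200000, 25000),
            ssc=(90000, 18000),
            fluor=fluor(cd19=True),
        ),
        PopulationSpec(
            label="T_CD3neg",
            fraction=t_cd3neg,
            fsc_h=(200000, 25000),
            ssc=(70000, 15000),
            fluor=fluor(),
        ),
        PopulationSpec(
            label="T_CD3pos_CD69neg",
            fraction=t_cd3pos * (1 - p_act),
            fsc_h=(200000, 25000),
            ssc=(70000, 15000),
            fluor=fluor(cd3=True),
        ),
        PopulationSpec(
            label="T_CD3pos_CD69pos",
            fraction=t_cd3pos * p_act,
            fsc_h=(200000, 25000),
            ssc=(70000, 15000),
            fluor=fluor(cd3=True, cd69=True),
        ),
    )
    return ExperimentSpec(
        n_events=n_events,
        condition=condition,
        cd69_positive_fraction=p_act,
        populations=populations,
        spillover=spillover,
        seed=seed,
    )


LOG10 = AxisScale("log10", floor=1.0)

#: log10-space thresholds separating negative from positive clusters, each
#: placed near the equal-z-score midpoint of the two clusters it separates
_CD19_THRESHOLD = 3.2
_CD3_THRESHOLD = 3.0
_CD69_THRESHOLD = 3.1


def default_tcell_gates() -> list:
    """The five-gate workflow matched to the default populations.

    Live polygon (FSC-A/SSC-A) → singlet polygon (FSC-A/FSC-H) →
    CD19⁻ interval → CD3⁺ interval → CD69⁺ interval. Fluorescence gates are
    drawn on log10 axes over compensated values.
    """
    live = PolygonGate(
        name="live",
        channel_x="FSC-A",
        channel_y="SSC-A",
        vertices=np.array(
            [
                [110000, 15000],
                [560000, 15000],
                [560000, 230000],
                [110000, 230000],
            ],
            dtype=float,
        ),
    )
    # band around FSC-H ≈ FSC-A: excludes doublets (FSC-H ≈ FSC-A / 2)
    singlet = PolygonGate(
        name="singlet",
        channel_x="FSC-A",
        channel_y="FSC-H",
        vertices=np.array(
            [
                [50000, 20000],
                [650000, 500000],
                [650000, 800000],
                [50000, 80000],
            ],
            dtype=float,
        ),
    )
    cd19_neg = IntervalGate(
        name="CD19-", channel="APC-A", low=-10.0, high=_CD19_THRESHOLD,
        scale=LOG10, use_compensated=True,
    )
    cd3_pos = IntervalGate(
        name="CD3+", channel="Pacific Blue-A", low=_CD3_THRESHOLD, high=10.0,
        scale=LOG10, use_compensated=True,
    )
    cd69_pos = IntervalGate(
        name="CD69+", channel="PE-A", low=_CD69_THRESHOLD, high=10.0,
        scale=LOG10, use_compensated=True,
    )
    return [live, singlet, cd19_neg, cd3_pos, cd69_pos]


def _role_rng(seed: int, role: str) -> np.random.Generator:
    stream = _ROLE_STREAM.get(role)
    if stream is None:
        raise ParameterError(f"unknown sample role {role!r}")
    return np.random.default_rng([int(seed), stream])


def _make_channels() -> list[ChannelInfo]:
    channels = [ChannelInfo(name, range=CHANNEL_RANGE) for name in SCATTER_CHANNELS]
    channels += [
        ChannelInfo(name, stain_name=STAIN_NAMES[name], range=CHANNEL_RANGE)
        for name in FLUOR_CHANNELS
    ]
    return channels


def _assemble_sample(
    scatter: np.ndarray,
    observed_fluor: np.ndarray,
    display_name: str,
) -> Sample:
    events = np.column_stack([scatter, observed_fluor])
    keywords = {
        "$TOT": str(events.shape[0]),
        "$PAR": str(events.shape[1]),
        "$CYT": "cytolite synthetic",
    }
    return Sample(
        events=events,
        channels=_make_channels(),
        keywords=keywords,
        display_name=display_name,
    )


def simulate_experiment(spec: ExperimentSpec) -> tuple[Sample, SimulationTruth]:
    """Draw one acquisition from the mixture, with spillover applied.

    Events are drawn population-by-population (multinomial counts), shuffled
    into a random order, and the observed fluorescence is ``true · S``.
    Identical specs (including the seed) give identical event matrices.
    """
    rng = _role_rng(spec.seed, "main")
    fractions = np.array([p.fraction for p in spec.populations])
    counts = rng.multinomial(spec.n_events, fractions / fractions.sum())

    scatter_parts, fluor_parts, label_parts = [], [], []
    for pop, m in zip(spec.populations, counts):
        if m == 0:
            continue
        fsc_h = rng.normal(pop.fsc_h[0], pop.fsc_h[1], m)
        fsc_a = pop.fsc_a_ratio * fsc_h + rng.normal(0, pop.fsc_a_noise, m)
        ssc = rng.normal(pop.ssc[0], pop.ssc[1], m)
        scatter = np.column_stack([fsc_a, fsc_h, ssc])
        scatter = np.clip(scatter, 0, CHANNEL_RANGE)
        true = np.column_stack(
            [
                np.power(10.0, rng.normal(*pop.fluor[name], size=m))
                for name in FLUOR_CHANNELS
            ]
        )
        scatter_parts.append(scatter)
        fluor_parts.append(true)
        label_parts.append(np.full(m, pop.label, dtype=object))

    scatter = np.concatenate(scatter_parts)
    true_fluor = np.concatenate(fluor_parts)
    labels = np.concatenate(label_parts)
    order = rng.permutation(spec.n_events)
    scatter, true_fluor, labels = scatter[order], true_fluor[order], labels[order]

    observed = true_fluor @ spec.spillover.coefficients
    sample = _assemble_sample(
        scatter, observed, display_name=f"tcell_{spec.condition}"
    )
    return sample, SimulationTruth(labels=labels, true_fluorescence=true_fluor)


def make_singlestain_controls(
    spec: ExperimentSpec,
    positive_fraction: float = 0.75,
) -> tuple[dict[str, Sample], Sample]:
    """Single-stain compensation controls plus an unstained sample.

    Each control holds a bright positive subpopulation on its own dye
    (75% of events by default, so whole-sample medians land inside the
    positive cluster) and an unstained-like negative subpopulation, with
    the spec's spillover applied. Returns ``(controls, unstained)``.
    """
    if not 0 < positive_fraction < 1:
        raise ParameterError("positive_fraction must be in (0, 1)")
    controls: dict[str, Sample] = {}
    n = spec.n_events
    for channel in FLUOR_CHANNELS:
        rng = _role_rng(spec.seed, f"control:{channel}")
        n_pos = int(round(n * positive_fraction))
        true = np.power(10.0, rng.normal(*_NEG, size=(n, 3)))
        true[:n_pos, FLUOR_CHANNELS.index(channel)] = np.power(
            10.0, rng.normal(*_CD19_POS, size=n_pos)
        )
        observed = true @ spec.spillover.coefficients
        scatter = np.column_stack(
            [
                rng.normal(200000, 25000, n),
                rng.normal(200000, 25000, n),
                rng.normal(80000, 16000, n),
            ]
        ).clip(0, CHANNEL_RANGE)
        controls[channel] = _assemble_sample(
            scatter, observed, display_name=f"control_{channel}"
        )

    rng = _role_rng(spec.seed, "unstained")
    true = np.power(10.0, rng.normal(*_NEG, size=(n, 3)))
    observed = true @ spec.spillover.coefficients
    scatter = np.column_stack(
        [
            rng.normal(200000, 25000, n),
            rng.normal(200000, 25000, n),
            rng.normal(80000, 16000, n),
        ]
    ).clip(0, CHANNEL_RANGE)
    unstained = _assemble_sample(scatter, observed, display_name="unstained")
    return controls, unstained


def write_truth_csv(truth: SimulationTruth, path) -> None:
    """Side file of per-event truth: label plus true (pre-spillover) signals."""
    import csv
    import os

    with open(os.fspath(path), "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["label", *(f"true_{c}" for c in FLUOR_CHANNELS)])
        for label, row in zip(truth.labels, truth.true_fluorescence):
            writer.writerow([label, *(repr(float(v)) for v in row)])
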