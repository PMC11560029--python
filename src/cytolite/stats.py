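"""Hierarchical population statistics.

Although gates are global and commutative, reporting follows the familiar
hierarchical reading: for an ordered chain of gates, each prefix of the chain
defines a population, and every population is summarized by its event count,
its percentage of the parent population (the previous prefix) and of the
ungated total, plus per-channel intensity summaries.

Percentages are kept at full precision internally; CSV rendering rounds to
0.01% (see :mod:`cytolite.session_export`) so exported tables do not depend on
display settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcs_io import Sample
from .gating import GateMembership, apply_gate, combine_masks
from .preprocess import SpilloverMatrix

__all__ = ["StatRecord", "gate_chain_stats", "channel_summary"]


def channel_summary(values) -> dict:
    """Summary statistics for one channel of one gated population.

    Returns ``mean``, ``median``, ``cv`` (sample standard deviation, n−1
    denominator, over the mean) and ``geometric_mean`` (``exp(mean(log v))``).
    The geometric mean is omitted — ``None``, with ``geometric_mean_omitted``
    set — when any value is non-positive; clamping instead would bias
    fluorescence summaries. An empty population yields ``{"empty": True}``
    with no summary fields.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return {"empty": True}
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    out = {
        "empty": False,
        "mean": mean,
        "median": float(np.median(values)),
        "cv": sd / mean if mean != 0 else float("nan"),
    }
    if np.all(values > 0):
        out["geometric_mean"] = float(np.exp(np.mean(np.log(values))))
        out["geometric_mean_omitted"] = False
    else:
        out["geometric_mean"] = None
        out["geometric_mean_omitted"] = True
    return out


@dataclass
class StatRecord:
    """Statistics of one chain prefix for one sample."""

    sample_name: str
    gate_chain: tuple[str, ...]
    count: int
    pct_of_parent: float
    pct_of_total: float
    per_channel: dict[str, dict] = field(default_factory=dict)
    zero_parent: bool = False  # parent population was empty; pct_of_parent := 0
    basis: str = "raw"  # "raw" or "compensated" — which values fed per_channel


def gate_chain_stats(
    sample: Sample,
    chain,
    comp: SpilloverMatrix | None = None,
    channels: list[str] | None = None,
) -> list[StatRecord]:
    """Hierarchical statistics along an ordered gate chain.

    One record per chain prefix, starting with the empty prefix (the ungated
    total, 100%/100%). Prefix *k*'s parent is prefix *k−1*. An empty parent
    population makes ``pct_of_parent`` 0 with the ``zero_parent`` flag rather
    than raising.

    Channel summaries are computed on compensated values when a spillover
    matrix is supplied (recorded via ``basis``), on the sample's working
    values otherwise.
    """
    chain = list(chain)
    n = sample.n_events
    if comp is not None and not sample.compensated_channels:
        from .preprocess import compensate

        value_sample = compensate(sample, comp)
        basis = "compensated"
    else:
        value_sample = sample
        basis = "compensated" if sample.compensated_channels else "raw"
    summary_channels = channels if channels is not None else sample.channel_names

    records: list[StatRecord] = []
    masks: list[GateMembership] = []
    parent_count = n
    cum = combine_masks([], n_events=n)
    for k in range(len(chain) + 1):
        if k > 0:
            masks.append(apply_gate(sample, chain[k - 1], comp))
            cum = combine_masks(masks, n_events=n)
        count = cum.count
        if k == 0:
            pct_parent = 100.0 if n else 0.0
            zero_parent = n == 0
        else:
            zero_parent = parent_count == 0
            pct_parent = 0.0 if zero_parent else 100.0 * count / parent_count
        pct_total = 100.0 * count / n if n else 0.0
        per_channel = {
            name: channel_summary(value_sample.data(name)[cum.mask])
            for name in summary_channels
        }
        records.append(
            StatRecord(
                sample_name=sample.display_name,
                gate_chain=tuple(g.name for g in chain[:k]),
                count=count,
                pct_of_parent=pct_parent,
                pct_of_total=pct_total,
                per_channel=per_channel,
                zero_parent=zero_parent,
                basis=basis,
            )
        )
        parent_count = count
    return records
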