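# cytolite

A headless compute layer for flow-cytometry analysis: everything a
plot-centric cytometry GUI does between the FCS file and the figure, as a
plain Python library with a small CLI.

Flow cytometry measures forward/side scatter and multi-channel fluorescence
for tens of thousands of single cells ("events") per sample. Routine analysis
is a pipeline of standard steps — parse the instrument's FCS file, undo
fluorescence spillover between detectors, select sub-populations with
geometric gates, and report population statistics. cytolite implements that
pipeline for people who want it scriptable and reproducible: batch analyses,
CI-tested gating strategies, and downstream work in pandas/matplotlib.

## What it does

- **FCS I/O** — reads FCS 2.0/3.0/3.1 list-mode files (`$DATATYPE` F/D/I,
  either byte order, multi-dataset `$NEXTDATA` chains) and writes FCS 3.1
  (float32). Channels are addressed by their `$PnN` short names.
- **Compensation** — spillover is modelled linearly: with true per-dye
  signals *t* (row vector) and spillover matrix *S* (rows = dyes, columns =
  detectors, diag *S* = 1), the detectors observe *o = t·S*; compensation
  computes *t = o·S⁻¹*. Matrices come from the file's `$SPILLOVER`/`SPILL`
  keyword, a CSV, or are estimated automatically from single-stain controls
  by background-subtracted median ratios.
- **Gating** — 2D polygon and 1D interval gates. Gates are *global,
  independent objects*: defined once, applicable to any sample, and combined
  by set intersection, so the application order is fully commutative. Each
  gate stores the axis scale (linear / log10 / arcsinh) it was drawn under
  and is always evaluated in that space.
- **Statistics** — hierarchical tables along a gate chain: event count, % of
  parent, % of total, and per-channel mean / median / geometric mean / CV.
- **Plot substrates** — histogram counts, 2D density grids with per-event
  density (the color of a "colored dot plot"), and contour levels; rendering
  is left to matplotlib or anything else.
- **Persistence** — versioned JSON sessions (samples, gates, compensation,
  applied chains), batch sample renaming, and full-precision CSV export of
  gated events and statistics.
- **Synthetic data** — a ground-truth simulator of a T-cell activation
  experiment (T/B co-culture with debris, doublets and spillover, three
  peptide doses), used throughout the test suite.

## Worked example

Simulate a high-peptide activation sample, apply the standard five-gate
strategy (live scatter gate → singlet gate → CD19⁻ → CD3⁺ → CD69⁺) and print
the gating hierarchy:

```python
from cytolite import gate_chain_stats
from cytolite.synthetic import (
    default_tcell_spec, default_tcell_gates, simulate_experiment,
)

spec = default_tcell_spec("high", n_events=20000, seed=1)
sample, truth = simulate_experiment(spec)
records = gate_chain_stats(sample, default_tcell_gates(), comp=spec.spillover)
for rec in records:
    chain = " > ".join(rec.gate_chain) or "(total)"
    print(f"{chain:45s} {rec.count:6d}  {rec.pct_of_parent:6.2f}% of parent"
          f"  {rec.pct_of_total:6.2f}% of total")
```

```
(total)                                        20000  100.00% of parent  100.00% of total
live                                           17011   85.06% of parent   85.06% of total
live > singlet                                 15086   88.68% of parent   75.43% of total
live > singlet > CD19-                          7542   49.99% of parent   37.71% of total
live > singlet > CD19- > CD3+                   6044   80.14% of parent   30.22% of total
live > singlet > CD19- > CD3+ > CD69+           4789   79.24% of parent   23.95% of total
```

Reading the table: 85% of events are intact live cells, 89% of those are
singlets, the CD19⁻ gate removes the B-cell half of the 1:1 co-culture, 80%
of the T cells express CD3, and 79.24% of those are CD69⁺ — close to the 80%
activation rate this simulation was designed with (the gap is binomial
sampling noise plus sub-percent gate leakage).

The same pipeline is available from the shell:

```bash
cytolite simulate --condition high --seed 1 --n-events 20000 --out high.fcs
cytolite info high.fcs
cytolite stats --session session.json --out stats.csv
cytolite export --session session.json --sample high --out gated.csv --compensated
```

## Layout

- `src/cytolite/fcs_io.py` — FCS reading/writing, TEXT-segment grammar
- `src/cytolite/preprocess.py` — $PnE/$PnG scaling, axis transforms, compensation
- `src/cytolite/gating.py` — polygon/interval gates, membership, combination
- `src/cytolite/stats.py` — hierarchical statistics, channel summaries
- `src/cytolite/plotdata.py` — histogram / density / contour substrates
- `src/cytolite/session_export.py` — JSON sessions, renaming, CSV export
- `src/cytolite/synthetic.py` — ground-truth experiment simulator
- `src/cytolite/cli.py` — `cytolite` command (info / gate / stats / export / simulate)

See `docs/methods.md` for the models, conventions and numerical choices.
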