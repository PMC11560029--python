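# Methods

This note documents the models, conventions and numerical choices behind
cytolite, and what the synthetic-data-based tests do and do not demonstrate
about real data.

## FCS file handling

An FCS dataset is a 58-byte HEADER (version marker plus six 8-digit segment
offsets), a delimited TEXT segment of keyword/value pairs, and a binary DATA
segment; files may chain several datasets through `$NEXTDATA`. cytolite reads
versions 2.0, 3.0 and 3.1 and writes 3.1.

Conventions and repairs, chosen to match instrument practice rather than the
letter of the standard:

- **Offsets.** When the HEADER data offsets are 0 (the 3.x convention for
  files whose offsets exceed the 8-digit fields), `$BEGINDATA`/`$ENDDATA`
  from TEXT are used. `$NEXTDATA` is interpreted relative to the start of the
  current dataset, the convention of widely used readers.
- **TEXT grammar.** A doubled delimiter inside a token decodes to one literal
  delimiter. The grammar is genuinely ambiguous for tokens that begin or end
  with the delimiter (the escape cannot be told from a token boundary), so
  the writer refuses to emit such tokens; tokens with internal delimiters
  round-trip exactly. `$`-keyword lookup is case-insensitive, as required;
  user keywords are case-sensitive.
- **Integer data.** Channels whose `$PnR` does not fill the `$PnB` bit width
  are masked to `ceil(log2($PnR))` bits, mirroring acquisition boards that
  leave stray high bits in the unused positions.
- **`$PnE` repair.** `d,0` with `d > 0` (log amplification with a zero
  offset) is invalid but common; it is repaired to `d,1` with a warning.
- **Spillover keyword.** `$SPILLOVER`, `SPILL` and `$COMP` are all
  recognized, in that precedence order, covering pre-3.1 instruments.
- Written files are `$DATATYPE=F`, `$PnB=32`, little-endian, single dataset;
  a write→read round trip therefore reproduces events to float32 precision
  (bit-exact when the inputs are float32-representable). ASCII data
  (`$DATATYPE=A`), histogram modes and FCS 4.x are not supported.

## Scaling and axis transforms

Stored values are converted to linear intensities explicitly, once: a channel
with `$PnE = d,f` on range `R` maps a stored value `c` to `f·10^(d·c/R)`; a
linear channel maps `c` to `c / gain`. The operation flags the sample so a
second application is an error rather than a silent double-scaling.

Display/gating transforms are `linear`, `log10` (values below a positive
`floor`, default 1, are clamped first — so the transform is monotone but not
strictly so below the floor), and `arcsinh(value / cofactor)`. The arcsinh
cofactor defaults to 150, a common choice for conventional cytometers:
roughly linear within ±cofactor (so negatives and zeros display sensibly) and
logarithmic above. A logicle/biexponential transform is not provided; arcsinh
covers the same display need with one parameter.

## Compensation

Spillover is linear in light intensity: with true per-dye signals `t` (row
vector over an ordered channel subset) and spillover matrix `S` (`S[i,j]` =
fraction of dye `i` read by detector `j`, `S[i,i] = 1`), the observed vector
is `o = t·S`, and compensation solves `t = o·S⁻¹` (LAPACK solve, not an
explicit inverse). Matrices with condition number above 1e12 are rejected as
singular. Compensation is defined on linear-scaled values and applied before
any axis transform, because the physics is linear in intensity; whether an
instrument's own software scales before or after is vendor-specific, so the
order here is a documented package convention.

The automatic estimator takes one single-stain control per channel plus an
optional unstained sample:

    S[i, j] = (median_j(control_i) − bg_j) / (median_i(control_i) − bg_i)

with `bg` the unstained medians (0 if absent) and the diagonal forced to 1.
Medians were chosen over least squares on raw events because cytometry data
carry heavy outlier tails (saturated events, aggregates) that dominate a
quadratic fit. The estimator assumes the whole-sample median lands inside the
positive cluster, i.e. controls that are majority-positive; the synthetic
controls use 75% positive events for this reason. Iterative refinement in the
style of AutoSpill is out of scope.

## Gating

Gates are independent global objects, not nodes of a tree: membership of a
gate in a sample is a boolean vector, chains are intersections, and
intersection is commutative and idempotent — the gated population is
identical under every application order, which the test suite checks
exhaustively over all 3! orders of random 3-gate sets.

Geometry and conventions:

- **Polygon gates** use the even-odd (ray casting) rule, so self-intersecting
  polygons behave as they do in drawing tools. Correctness is established
  against an independent signed-angle winding-number oracle on 10⁵ random
  simple polygons/points.
- **Boundary rule.** Points exactly on a polygon edge or vertex are inside;
  intervals are half-open `[low, high)`. Some convention is required for
  counts to be reproducible across implementations; this is the one chosen
  and tested.
- **Gating space.** A gate stores the axis scales its coordinates were drawn
  under and is always evaluated there. This matters: a straight polygon edge
  in log space is a curve in linear space, so "the same" vertices under a
  different scale select a different region. Only axis-parallel edges
  (rectangles, intervals) are invariant under per-axis monotone rescaling,
  and only that restricted invariance is asserted in tests.
- Quadrant and ellipse gates are not implemented; both are expressible as
  polygons to working precision.

## Hierarchical statistics

For an ordered gate chain, one record per prefix (the empty prefix is the
ungated total): count, % of parent (the previous prefix), % of total, and
per-channel mean, median, CV (sample SD, n−1, over the mean) and geometric
mean (`exp(mean(log v))`, omitted with a flag when any value ≤ 0 — clamping
would bias it). An empty parent yields 0% with a flag rather than an
exception. Percentages are exact internally; CSV rendering rounds to 0.01%.
Summaries are computed on compensated values when a spillover matrix is in
context, raw otherwise, and the table records which.

## Plot substrates

Histograms are equal-width in transformed space, right-open except the last
bin; optional smoothing is a window-3 moving average whose end-bin overflow
is folded back, so total mass is conserved exactly. The 2D density grid is a
histogram (default 256×256; 128 bins for 1D), optionally box-smoothed 3×3
with edge replication; each event's color value is its cell's density —
O(n), deterministic, no kernel bandwidth to pick. Normalized mode divides by
total mass × cell area so the grid integrates to 1. Contour levels for a
grid with maximum `m` are `k·m/(n+1)`, `k = 1..n`, strictly inside (0, m).

## Sessions, renaming, export

Sessions are versioned JSON (schema version "1"); floats are serialized with
`repr`, which round-trips IEEE doubles exactly, so save→load is field-exact
including gate vertices. Missing sample files are flagged at load and only
fail on data access. Rename rules are ordered `(pattern, replacement)` pairs
— literal text with `*`/`?` wildcards, matched anywhere in the name, first
matching rule wins, replacement is literal. Event CSVs use `repr` for the
same exact round trip; raw vs compensated is an explicit per-export choice.

## The synthetic experiment

The simulator emulates a T-cell activation readout: T cells co-cultured 1:1
with CD19⁺ antigen-presenting B cells, stained for CD19 (APC-A), CD3
(Pacific Blue-A) and CD69 (PE-A), measured with FSC-A/FSC-H/SSC-A scatter
channels, under three peptide doses. Default mixture: 15% debris/dead, 10%
doublets, live singlets split 1:1 B/T; 80% of T cells are CD3⁺; the CD69⁺
fraction among live CD3⁺ T cells is {none: 0.05, low: 0.40, high: 0.80}.
**All of these numbers, and the cluster locations below, are package design
defaults** chosen to produce clean, separable populations; they are not
measurements of any particular dataset.

- Scatter: per-population normals; FSC-A = ratio·FSC-H + noise with ratio 1
  for singlets and 2 for doublets (area doubles, peak height does not), which
  is what the FSC-A/FSC-H singlet gate exploits.
- Fluorescence: log-normals in log10 units — background (2.0, 0.3),
  CD19⁺ (4.5, 0.15), CD3⁺ (4.0, 0.15), CD69⁺ (3.8, 0.2) — mixed through a
  default spillover matrix with off-diagonals 0.02–0.12. Interval-gate
  thresholds sit near the equal-z-score midpoint between the clusters they
  separate (CD19: 3.2, CD3: 3.0, CD69: 3.1 in log10 space), making
  misclassification symmetric and sub-0.1%.
- Randomness: one `numpy` PCG64 stream per sample role, seeded from
  `(seed, role)`, so generating compensation controls never changes the main
  sample. Identical spec + seed gives bit-identical FCS bytes.

What passing tests show — and do not. The end-to-end tests demonstrate that
the pipeline (read → compensate → five gates → statistics) recovers designed
population fractions within binomial 3σ on well-separated Gaussian/log-normal
mixtures with exactly linear spillover. Real data add what the simulator
deliberately omits: photon-counting noise, baseline restoration artifacts,
time drift, non-lognormal autofluorescence, population overlap, and
imperfectly linear detectors. The tests validate the computations, not the
biology of any gating strategy.

## Problem sizes

The default validation scale is desk-sized by design: 20,000-event
simulations per condition, 10,000-event compensation controls, 10⁵ random
polygon/point instances, 100 randomized FCS round trips. All complete in
seconds; the same code paths scale linearly to multi-million-event files.
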