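# Methods

## Sequential strand-cleavage model

The cis-cleavage stage models the topology transitions of a negatively
supercoiled plasmid cut by a Cas12a–crRNA complex as first-order flows
among six compartments (all in percent of total DNA):

```
d/dt SC     = −(ka + kini)·SC
d/dt ucSC   = kini·SC
d/dt NICK   = ka·SC − (kb + kini2)·NICK + ka·NICK1
d/dt NICK1  = −(ka + kini)·NICK1
d/dt ucNICK = kini2·NICK + kini·NICK1
d/dt LIN    = kb·NICK
```

with observables `TotSC = SC + ucSC`, `TotNICK = NICK + NICK1 + ucNICK`,
and `LIN` matched to the gel-measured supercoiled/nicked/linear
percentages. `ka` (= k_NTS) is the NTS nicking rate, `kb` (= k_TS) the
linearization rate; `kini`, `kini2` drain material into "unconverted"
pools that never progress, capturing incomplete reactions; `NICK1` holds
plasmid that is already nicked at t = 0 (the measured t = 0 nicked
fraction is assigned entirely to it).

**Variant choice.** The traditional listing of this model couples NICK1
into `d/dt NICK` with a `−ka·NICK1` term. Summing the six equations shows
that version loses total mass at rate `2·ka·NICK1`, for an asymptotic
deficit of `2·ka·NICK1₀/(ka+kini)`, and it can drive NICK negative when
the pre-nicked fraction dominates. We therefore default to the
mass-conserving sign (`+ka·NICK1`: pre-nicked plasmid is nicked at `ka`,
then linearized at `kb`), which keeps the compartment sum at exactly 100
and every compartment non-negative for all non-negative rates. The
verbatim equations remain available as `variant="as_printed"`, and tests
assert both its analytic mass deficit and its negativity pathology. When
the initial nicked fraction is zero the two variants are identical, so
the choice only matters for pre-nicked substrate.

**Solution.** The system is linear with constant coefficients, so
trajectories are propagated by `expm(A·Δt)` between output points — exact
to machine precision, with no step-size tuning. An adaptive DOP853
integration (rtol = atol = 1e−13) is exposed separately
(`simulate_ivp`) as an independent cross-check; the two routes agree to
≤ 1e−8 on all compartments across the tested parameter grid.

**Fitting.** Per replicate, `(ka, kb, kini, kini2)` minimize the joint
equal-weight SSE of (TotSC, TotNICK, LIN) against the three observed
percentage curves — the behaviour of a standard multi-dataset curve fit.
Bounded trust-region least squares (`scipy.optimize.least_squares`, TRF,
rates ≥ 0) runs from 8 starts: the standard initial guesses
(0.50, 0.50, 0.01, 0.01 s⁻¹) plus log-spaced (ka, kb) restarts over
[1e−4, 10] s⁻¹, alternating equal and opposed pairs to cover both the
ka ≈ kb ridge and the fast-nick/slow-linearize corner of the multimodal
SSE surface. Ties (SSE within max(1e−12, 1e−6·SSE)) break to the lowest
ka. After optimization, any rate whose removal does not increase the SSE
beyond that same tolerance is snapped to zero: such a rate has no flux
through its step and is unidentifiable from the data (flat time courses
then report all rates as exactly 0). If the supercoiled fraction has
fallen below 5% by the second time point, `ka` is flagged as a lower
bound only. Condition-level results are the mean and sample s.d.
(n−1 denominator, reported only for ≥ 2 replicates) of ka and kb;
fold changes versus a reference condition follow the prose convention
"N.N× faster" (ratio > 1) / "N.N× slower" (reciprocal).

Time is in seconds throughout; rates in s⁻¹.

## Densitometry correction

Per-topology response slopes are fit by least squares **through the
origin** (zero DNA ⇒ zero signal; robust for 3–4 point dilution series),
with uncentered R² reported per topology. Correction factors use the
convention `f_i = mean(s)/s_i`. Only factor *ratios* affect downstream
percentages — scaling all factors by any c > 0 cancels in the
normalization — so the overall scale is a documented convention; this one
maps the GelRed-style response triple (1.2547, 1.1696, 0.5747) for
(nicked, linear, supercoiled) to factors ≈ (0.797, 0.855, 1.74).
Correction is multiplicative on raw intensities before summation;
percentages are corrected intensity over corrected lane total. Lanes with
zero corrected signal are dropped with a warning rather than propagating
NaNs.

## Trans-cleavage rates and melt curves

The pseudo-first-order trans rate is the OLS slope over points with
t ≤ 300 s (boundary inclusive; the window is configurable). Negative
slopes are reported as-is with a warning — a falling early signal is
diagnostic, not a zero rate. Background subtraction against a no-enzyme
control is available but off by default, since raw curves are the
conventional input; it requires identical time grids and annotates the
label. The slope is invariant to adding a constant to the signal and
scales linearly with signal gain.

Tm is the temperature of the global fluorescence maximum on the 25–99 °C
grid, accepted only if the maximum is interior and exceeds both endpoint
values by ≥ 5% of the curve's dynamic range — an affine-invariant
operationalization of "detectable peak"; curves failing it (e.g. strictly
monotonic traces) return an explicit no-peak value, not an error. Equal
maxima break to the lowest temperature (deterministic and conservative).

## Domain dynamics

Centre of mass is mass-weighted over **all** atoms of a selection
(standard atomic masses by element; hydrogens included when present),
with a geometric-centroid option for sensitivity checks. Contacts count
pairs of heavy atoms (element ≠ H), one from each selection, at distance
strictly < 3.5 Å; a KD-tree accelerates the search but is required by
tests to equal a brute-force all-pairs computation. A residue-pair
counting unit (distinct residue pairs with ≥ 1 qualifying atom pair) is
provided because the natural unit of "a contact" is ambiguous;
the unit in effect is carried in output metadata. Residue numbering is
taken verbatim from the input PDB (1-based, inclusive ranges); built-in
REC2/Nuc ranges: FnCas12a 340–591/1079–1254, LbCas12a 283–521/998–1179,
AsCas12a 321–526/1067–1262. All frames are weighted equally (no burn-in
discarded; inputs are assumed to be production frames).

KDE summaries use Gaussian kernels with Scott's-rule bandwidth h on a
512-point grid spanning [min − 3h, max + 3h]; the mode is the grid
argmax, and secondary local maxima above 50% of the main peak mark the
summary multimodal. A zero-variance series returns a degenerate
point-mass summary. The ±3h margin keeps ≥ 99.7% of each boundary
kernel's mass on-grid, so the quadrature integral of the density is 1
within 1e−3 for non-pathological samples.

## Synthetic data

Each generator is the exact forward model of its analysis stage, with all
randomness from a single integer seed (identical seed ⇒ bitwise-identical
output):

- **Time courses** solve the kinetic model on the requested grid;
  noise (default study conditions: 3 replicates, Gaussian
  s.d. 2 percentage points) is added per observable on the corrected
  scale — where real densitometry noise enters — then clipped at zero and
  renormalized to sum to 100, preserving the constraint the fitter
  assumes. Truncated-Gaussian rather than lognormal noise: simpler, and
  adequate at these noise levels. The true noise magnitude of real
  densitometry is unknown; `noise_sd` is a free knob, not a claim.
- **Gel lanes** apply a multiplicative dye bias (default
  (1.2547, 1.1696, 0.5747), the response triple behind the
  0.797/0.855/1.74 factors) so that the densitometry round trip is the
  identity on fractions in the noiseless case.
- **Fluorescence** follows `background + f_max·(1 − e^(−rate·t))`;
  **melt curves** plant a Gaussian unfolding peak at a known Tm (or a
  strictly rising no-peak trace).
- **Trajectories** place two rigid carbon clouds on a jitter-free 8 Å
  lattice. The lattice guarantees that a planted partner atom at 3.4 Å is
  ≥ 4.6 Å from every other atom of the opposite cloud, so planted contact
  counts are exact by construction. Per-frame COM separations are drawn
  from Normal(mean, sd) truncated above the cloud diameter plus a
  contact-clearance margin, so non-planted frames have exactly zero
  contacts. Moving planted atoms shifts the cloud COM slightly;
  COM-distance assertions therefore use trajectories without planted
  contacts. These toys emulate the geometry of domain motion, not
  physically realistic dynamics — force fields, solvent, and equilibration
  are out of scope — so passing tests demonstrate correctness of the
  *analysis*, not realism of the *ensemble*.

## Problem sizes

Defaults are chosen so the full synthetic pipeline (two conditions,
3 replicates, 16-point time courses) completes in seconds on one CPU:
fitting dominates at ~1 s per replicate. Distribution summaries use
400–4000 frames/draws, ample for mode locations at the reported
precision. Larger grids change nothing structurally.

## Known limitations

- The fitter assumes percentages summing to ~100 per lane; it does not
  model lane-to-lane loading variation beyond what normalization removes.
- `kini`/`kini2` are weakly identified when reactions run to completion;
  the parsimony snap reports them as 0 rather than returning an arbitrary
  value on a flat SSE ridge.
- Correction factors from a 3-point dilution series carry substantial
  uncertainty that is summarized only by R², not propagated into rate
  s.d.s.
- Binary trajectory formats (DCD/XTC) are not read; multi-model PDB only.
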