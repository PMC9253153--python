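# Methods

This note documents the statistical models, numerical choices, and known
limitations behind `kinenet`, in the order the pipeline runs.

## Kinematic feature extraction (`kinenet.kinematics`)

Anatomical neck angles (degrees, one waveform per movement plane, sampled at
100 Hz by default) are processed offline:

1. **Filtering.** 10th-order Butterworth low-pass at 10 Hz, applied
   forward–backward (`sosfiltfilt`) for zero phase. Zero-phase filtering is
   chosen because phase lag would bias peak timing and cycle segmentation;
   the stated order applies per pass. DC gain is exactly 1, so resting
   posture is unaffected.
2. **Neutral reference.** The neutral upright posture is the median angle
   over the first 0.5 s of the recording. Recordings are therefore expected
   to begin at rest; the synthetic generator writes a 1 s lead-in.
3. **Differentiation.** `np.gradient`: central differences in the interior
   (O(Δt²)), one-sided at the ends.
4. **Cycle detection.** Prominent angle extrema (at least 25% of the maximal
   excursion, cleaned to alternate in sign) delimit directional half-cycles;
   each segment runs from the previous extremum (movement onset for the
   first) to the current one, so it contains the full approach to that
   cycle's peak. A waveform with no prominent extrema yields an empty list
   and a warning rather than an error.
5. **Movement segmentation.** Within each half-cycle, the movement proper is
   the span where speed is at least 5% of the within-cycle peak speed
   (boundary samples included, so a linear ramp to 100 deg/s at 100 Hz
   starts exactly at sample 5).
6. **Features.** ROM = peak absolute excursion from neutral within the
   cycle (peak-from-neutral, not peak-to-peak — the convention is
   configurable in principle but fixed here); mean velocity = mean absolute
   speed over the trimmed segment; smoothness = SPARC per directional
   half-cycle (one value per direction, matching the six directional
   features aggregated downstream).

**SPARC.** With V(f) the magnitude spectrum of the segment's speed profile
(FFT zero-padded to 2^(⌈log₂ n⌉+4)), normalized as V̂ = V/V(0), and adaptive
cutoff f_c = min(20 Hz, highest f with V̂ ≥ 0.05),

  SPARC = −∫₀^{f_c} √((1/f_c)² + (dV̂/df)²) df ,

discretized on the FFT grid. The three parameters (20 Hz, 0.05, padding 4)
are the standard defaults of the measure. SPARC is strictly negative,
invariant to amplitude scaling and time reversal, and decreases as
oscillatory contamination grows (property-tested over increasing 10 Hz
contamination amplitudes).

**Tolerances.** On noise-free synthetic cycles the pipeline recovers the
requested ROM within 2% and mean velocity within 5%. The velocity bias is
structural and small: trimming the 5% tails of a sinusoidal speed bump
raises the segment mean by ≈3.2%. On noisy cohort recordings the smoothness
contamination also inflates mean speed, so the end-to-end round-trip test
uses a 10% velocity bound.

## Synthetic cohort (`kinenet.simulate`)

The generator emulates the reference cohort of 100 adults (15 without / 85
with a history of neck pain, pooled for analysis as in the reference study;
the two-group structure is available but off by default):

* **Feature table.** X = Z Lᵀ with Z iid standard normal and L the Cholesky
  factor of the target correlation matrix — population correlation exact by
  construction, which makes the factorization itself an oracle for tests.
  Defaults: the published pooled means/SDs (mixture formula across the two
  groups) and the published 6×6 Pearson matrix.
* **Marginal distortions** (after correlating, so rank structure is
  preserved): JPE through a strictly monotone shifted-exponential map with
  matched mean and SD (error magnitudes are right-skewed); TSK rounded to
  integers and clipped to the 17–68 scale (questionnaire totals are
  integers). Both exercise the nonparanormal step on realistic
  non-normality. Clipping is the only non-strictly-monotone step and
  affects <1% of draws.
* **Waveforms.** Cycles are raised-cosine transitions between +ROM and
  −ROM; transition durations are set so the mean angular speed equals the
  request exactly, with 5% cycle-to-cycle duration variability by default
  (the reference study reports no within-participant variances, so 5% CV is
  a design choice; amplitudes are kept fixed so the noise-free peak equals
  the requested ROM). Smoothness degradation is band-limited 8–15 Hz
  angular noise whose RMS amplitude is the `jerk_noise_amplitude` knob;
  it leaves ROM nearly intact while lowering SPARC monotonically. The
  noise-free profile is C³ at cycle junctions and exactly sinusoidal when
  durations are equal.
* **Relocation trials.** Six trials, alternating sides, with marked start
  and end samples whose angle difference equals the requested signed error
  exactly, so the joint reposition error is recoverable to machine
  precision.
* **Cohort recordings.** Per-participant waveforms reuse the table's ROM and
  velocity for all three planes; the SPARC→noise-amplitude map is a fixed
  monotone linear ramp anchored near the smoothest observed group mean, so
  requested and extracted smoothness agree in ordering but not numerically.

What passing tests on these data do *not* show: robustness to trunk
compensation, sensor drift, non-stationary cycle shapes, or missing data —
none of which the generator simulates.

## Nonparanormal transform and correlations (`kinenet.features`)

Each column is mapped through its truncated empirical CDF (average ranks
divided by n, winsorized to [δₙ, 1−δₙ] with δₙ = 1/(4 n^¼ √(π log n))), then
through the standard-normal quantile function, and rescaled to unit sample
SD. The transform is rank-based, hence invariant to strictly increasing
marginal distortions. One subtlety: when δₙ > 1/n (true for n ≲ 100) the
winsorization merges the most extreme rank(s), so Spearman correlations are
preserved *exactly* only for truncation levels below 1/n; at the default
level the change is far below sampling noise (<0.01). All six nodes,
including the integer-valued TSK, are transformed and then treated as
continuous.

Pearson matrices carry two-sided t-test p-values per pair with no
multiplicity correction, flagged `*` (p ≤ .05) and `**` (p < .01).

## Network estimation (`kinenet.glasso`, `kinenet.network`)

The graphical lasso maximizes log det Ω − tr(SΩ) − λΣ_{i≠j}|Ω_ij| (diagonal
unpenalized by default) by block coordinate descent — one soft-thresholded
lasso subproblem per row/column per sweep — converged when the largest
elementwise change of the working covariance between sweeps is < 1e−6. At
λ = 0 the solver reduces to blockwise matrix inversion (verified against
direct inversion to 1e−5 on random SPD inputs, and against scikit-learn's
independent implementation at positive penalties). The hot path is
numba-compiled so the bootstrap procedures can afford ~10⁴–10⁵ full path
fits.

Model selection fits a warm-started path of 100 log-spaced penalties from
λ_max = max off-diagonal |S| down to λ_max/100 and minimizes
EBIC = −2L + E log n + 4γE log p, L = (n/2)(log det Ω − tr(SΩ)), with E the
number of nonzero upper-triangle entries (|w| > 1e−8, separating exact
glasso zeros from numerical dust). Ties break toward the sparser (larger-λ)
model. γ defaults to 0.5, the conservative standard; γ = 0 reduces EBIC to
BIC and is the exploratory setting (`datasets.REFERENCE_GAMMA`) used for the
reference-cohort reproduction, whose analysis deliberately erred toward
discovery — at γ = 0.5 the printed matrix yields only a 2-edge network,
nothing like the published 12-edge structure, while γ = 0 reproduces the
published weights to within a few hundredths.

**Known limitation — dust edges.** Because one global λ serves all edges, at
large n the likelihood gain from un-shrinking strong true edges outweighs
the per-edge EBIC cost, and the selected model admits small spurious partial
correlations (|w| of order 1/√n) on truly absent edges. Support recovery is
therefore excellent for sensitivity and weight accuracy but not exact in
specificity; the sample-size simulation reports specificity explicitly for
this reason.

The printed-matrix input path accepts a correlation matrix plus n directly
and skips transformation — this is how published results are reproduced when
raw data are unavailable.

## Centrality (`kinenet.centrality`)

Strength = Σ_j |w_ij|. Closeness and betweenness use shortest paths with
edge length 1/|w|: closeness is the inverse total distance to all peers
(0 if any peer is unreachable); betweenness counts shortest paths through a
node with equal fractional credit among tied paths (Brandes accumulation via
networkx; distances via `scipy.sparse.csgraph.dijkstra`). Raw coefficients
are reported by default, z-scored optionally. All indices depend only on
|w| and are permutation-equivariant (property-tested against exhaustive
path-enumeration oracles).

## Stability (`kinenet.stability`)

All resampling is at the participant level with a seeded generator
(bit-reproducible).

* **Edge accuracy:** nonparametric bootstrap (default 1000 resamples with
  replacement), re-running transform + selection per resample; percentile
  2.5/97.5% intervals. Percentile CIs of a regularized estimator inherit
  its shrinkage bias, so coverage for strong edges sits near, but below,
  the nominal level at conservative γ; the machinery is validated at the
  reference-analysis settings.
* **Centrality stability:** case-dropping bootstrap over drop proportions
  0.05–0.75 in steps of 0.05 (fine enough to express CS values such as
  0.52); per proportion, subsample correlations of each centrality vector
  with the original. The CS coefficient is the largest proportion p such
  that ≥95% of subsample correlations reach 0.7 for every grid proportion
  ≤ p (0 if the smallest proportion already fails; correlations against a
  constant vector are undefined and counted as failures).
* **Sample-size planning:** Gaussian data simulated from a fitted model's
  implied covariance at a grid of n, re-estimated with the same settings;
  reports mean sensitivity, specificity, and true-vs-estimated weight
  correlation.

The published CS values themselves depend on the unavailable raw data, so
the machinery is validated on synthetic cohorts, not asserted against them.

## Pipeline and problem sizes

`run_pipeline` executes only the stages its input mode implies and persists
every stage output plus a `report.json` whose provenance block (config,
seed, version) re-runs the identical analysis; identical config + seed gives
byte-identical reports. The test suite exercises the heavy stochastic
validations at reduced sizes chosen to keep Monte-Carlo error well inside
the asserted margins: 20 replicates at n = 5000 for support recovery, 200
replicates × 200 bootstrap resamples at n = 500 for CI coverage, and
10–40-resample bootstraps for the stability unit tests.
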