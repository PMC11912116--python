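# Methods

## Spectrum model

A spectrum is a finite weighted point set X = {(v_i, x_i)} in
chemical-shift space: positions x_i in ppm over 1–3 axes, nonnegative
intensity weights v_i, total weight V_X = Σ v_i. Peak lists and gridded
intensity matrices are both mapped to this representation — a grid point
is a node like any picked peak, with its cell intensity as weight — so the
flow construction is identical for both. Grid cells with intensity at or
below a floor (default 0) are dropped at conversion; negative intensities
are baseline artifacts and must never become sink capacity. Grids can be
down-binned before conversion: output cells sum their constituent input
cells (total intensity is conserved exactly) and sit at the mean of their
coordinates; a non-divisible axis length sends the remainder cells into
the last bin.

## The flow program

Given a library {X_k} and a target Y with weights w_j, the network routes
the production V_Y from a source s through one hub per compound, the
hubs' peak nodes, and into target sinks of capacity w_j. A compound peak
i connects to exactly the target nodes within the assignment radius r
(closed ball) under the scaled Euclidean metric

    d(x, y) = sqrt( Σ_a (s_a (x_a − y_a))² ),

with default scales (1.0, 0.1) for (¹H, ¹³C), putting r on the ¹H ppm
scale where peak widths are 0.03–0.09 ppm. Arc costs equal d; absorption
costs c_ø (default 10⁶, required > r).

Because hub→peak flows are fixed fractions p_i = v_i / V_{X_k} of the hub
volume, the LP needs only one volume F_k per compound, one flow per
peak→target arc, and the absorbed volume:

    min  Σ c_{i→j} f_{i→j} + c_ø f_ø
    s.t. Σ_j f_{i→j} = p_i F_k          for every compound peak i
         Σ_i f_{i→j} ≤ w_j              for every target node j
         Σ_k F_k + f_ø = V_Y
         all variables ≥ 0

A compound peak with positive fraction and no target inside r forces
F_k = 0 (the method tolerates no missing peaks); such compounds remain in
the roster with zero flow so reports cover the full library. The LP is
solved with HiGHS via `scipy.optimize.linprog` over sparse constraint
matrices; infeasibility is impossible since absorption is uncapacitated,
and any non-optimal solver status raises rather than returning a partial
result. The test suite certifies the reduction by comparing objectives
against an independently coded dense LP of the full node-based program on
200 random instances (≤ 1e-9 relative).

### Numerical choices

- The closed neighborhood boundary is applied with a 1e-9 relative slack
  on r, so a target peak at exactly radius distance is kept despite float
  rounding of coordinate differences.
- Solver-tolerance negative flows are clipped to 0 on extraction;
  feasibility residuals (conservation, capacity, proportionality) are
  asserted ≤ 1e-8·V_Y in the tests.
- Equal-cost optima are genuinely degenerate; results pin the objective
  and the invariants, never a specific tie-broken flow. Variable ordering
  (library order, peak order, target index order) is fixed, so repeated
  solves of the same instance are deterministic.

## Setup variants

- **A (simultaneous, single pass)** — one LP over the whole library;
  compounds compete for target capacity. **D** is the same solve on a
  peak-list target instead of grid data.
- **B (independent)** — one single-compound LP per library entry against
  the full target (full capacities, full production). Useful as a
  robustness probe but structurally prone to over-detection: two compounds
  explaining the same peak both receive full flow. Source conservation
  holds per run only; the summed absorbed volume is bookkeeping, not a
  conserved quantity.
- **C (incremental)** — solve A-style LPs at increasing radii (default
  schedule 0.01, 0.02, … up to r_max), after each step reserving the
  assigned arc flows: residual capacities shrink and reserved flow is
  never displaced. Production at each step equals the residual capacity,
  so the absorption cost cannot distort step optima. Peak proportionality
  holds within each step; across steps only the aggregate consistency of
  cumulative arc and hub flows is guaranteed. Reservation trades a
  slightly higher assignment cost for robustness to large radii, where
  single-pass fits start displacing flow onto wrong compounds.

## Detection and quantification

Detection compares the flow fraction f_{s→k} / V_Y to a dimensionless
threshold ϑ with ≥ at the boundary. Concentration factors are
α_k = f_{s→k} / V_{X_k} — the unique linear reading under which an exact
superposition Y = Σ α_k* X_k with well-separated peaks returns
α_k = α_k* — and concentrations are c_k = α_k c_k°, with c_k° the
library acquisition concentration (default 30 mM). Evaluation uses
relative errors e_k = (c_k − c_k*) / c_k* over truly contained compounds
(truth ≤ 0 entries are excluded and flagged), their mean magnitude e̅, the
fraction inside the closed band [−0.5, 1.0], and precision/recall/F1
where every library compound absent from the truth set counts as a
negative. Parameter scans solve once per radius and reuse the flow for
all thresholds, since ϑ never enters the LP.

## Synthetic data

The generators emulate HSQC benchmark structure rather than any specific
instrument output:

- **Libraries** — uniform peak positions over ¹H 0–10 ppm × ¹³C 0–160
  ppm, 1–20 peaks per compound, lognormal raw weights normalized so
  V_{X_k} = c° × n_peaks (total signal proportional to concentration ×
  number of contributing CH groups), reference concentration 30 mM.
- **Mixtures** — scaled superpositions with α_k* = c_k*/c°, zero-mean
  Gaussian position jitter per axis, and unit-mean lognormal weight noise
  parameterized by its CV (multiplicative, so weights stay positive). The
  zero-noise case is an exact superposition.
- **Grid rendering** — each peak deposited as a separable Gaussian
  (per-axis SD from the 0.03–0.09 ppm width range; default 0.03 ppm ¹H,
  0.3 ppm ¹³C), integrated per cell via the CDF, truncated at 4 SD and
  renormalized so the discrete sum equals the peak weight exactly, plus
  optional additive Gaussian baseline noise.

All generators are bit-reproducible under their seed. They do not emulate
t1-noise streaks, solvent ridges, phase distortion, or matrix-dependent
systematic shifts, so passing benchmarks demonstrate correctness of the
optimization and its noise robustness in the modeled regime — not
performance on real biological samples.

### Benchmark problem sizes

The quantification benchmark uses 10 compounds with 3–8 peaks, position
jitter SD 0.01 ppm (¹H) / 0.1 ppm (¹³C) — isotropic in the scaled
metric — weight CV 10%, rendered on a 256×256 grid spanning the mixture
with a (0.2, 2.0) ppm margin, no baseline noise (baseline handling is
exercised separately by the blank-spectrum calibration, where detections
on a noise-only grid fall to zero as ϑ rises). The LP cross-check runs
200 instances of up to 5 compounds × 4 peaks against 20 target peaks.
These sizes keep a full run in seconds while exercising every code path;
the generators scale to hundreds of compounds (the library invariant
sweep runs at 501).

## Limitations

- No tolerance for missing peaks: one unmatched peak zeroes a compound.
  Grid targets soften this in practice because peak tails populate many
  nearby nodes.
- Peak shape is ignored in the cost; a grid target represents shape only
  implicitly through its many nodes.
- Setup B's reported totals are not globally conserved (by design).
- The default metric scales and incremental schedule are field-reasonable
  choices, configurable per run; optimal values depend on line widths and
  shift variability of the actual data.
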