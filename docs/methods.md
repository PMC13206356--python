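# Methods

## Model

A dynamic network is an ordered sequence of symmetric, nonnegative,
zero-diagonal weight matrices on a fixed node set. Each window is treated
as a closed accounting unit: edges carry interaction mass, nodes are the
sites it attaches to, and the normalized-Laplacian eigenmodes play the role
of micro-states.

**Internal energy.** `U = Σ_{i<j} w_ij`. For binary graphs this is the edge
count. No free-energy or external-work term is modeled; the discrete
relation `T = ΔU/ΔS` deliberately neglects work.

**Node energy.** `U_i = Σ_j [d_i/(d_i+d_j)] w_ij` with weighted degrees
`d_i = Σ_j w_ij`. Each unit of edge weight splits between its endpoints as
`d_i/(d_i+d_j) + d_j/(d_i+d_j) = 1`, so `Σ_i U_i = U` holds to machine
precision — this conservation is enforced by a property test over random
binary and weighted graphs. Isolated nodes get zero.

**Spectra and entropies.** The normalized Laplacian is
`L̃ = I − D^{−1/2} W D^{−1/2}` with zero rows/columns (including the
diagonal) for isolated nodes, so `tr L̃` equals the number of non-isolated
nodes. Micro-state probabilities are `p_i = λ̃_i/|V|`; we keep this
normalization verbatim even when isolates exist, in which case the retained
probabilities sum to less than one (the deficit is a property of the
definition, not a bug). The Spectral Core Entropy keeps the top-α terms of
`−Σ p_i ln p_i` (with `0·ln 0 = 0`); `α = |V|` recovers the full von
Neumann entropy. A renormalized variant (`p_i = λ̃_i/Σ_top-α λ̃`) measures
dispersion *within* the core; it is a control, not the default. Because
`−p ln p` is increasing for `p ≤ 1/e`, the plain SCE is non-decreasing
in α on all graphs whose eigenvalues satisfy `λ̃_max ≤ |V|/e` — effectively
all graphs with more than a handful of nodes.

**Temperature index.** `T_1 = 0`, `T_n = (U_n − U_{n−1})/(S_n − S_{n−1})`.
`T` is a dimensionless ratio: it is large when mass moves while the
spectral profile holds still, which is why it responds to strength-dominated
reconfiguration and is blind to mass-preserving rewiring. Transitions with
`|ΔS| < 1e−12` are set to NaN, counted, and excluded pairwise from all
downstream metrics — the definition itself is never regularized. On
synthetic weighted sequences degenerate transitions essentially never
occur; on real binarized sequences repeated graphs can produce them, and
the NaN policy keeps every run total.

**Solvers.** Dense `scipy.linalg.eigh` when `n ≤ 512` or `α > n/2`,
Lanczos (`eigsh`, largest-algebraic) otherwise, with a dense fallback on
non-convergence. Agreement is tested to 1e−8 on graphs up to 200 nodes.
Eigenvalues are clipped to the theoretical `[0, 2]` band to remove rounding
overshoot.

## Sliding-window construction

Windows `X[k·s : k·s+w]` for `k = 0 … ⌊(T−w)/s⌋`; Pearson correlation with
a zero diagonal; zero-variance columns (constant within a window) are
functionally disconnected there — all incident correlations set to 0 and
logged. Binarization keeps correlations **strictly greater** than the
threshold (default 0.5); negative correlations never become edges. Defaults
`w = 5`, `s = 1`, threshold 0.5 mirror the resting-state setting the
framework was designed for (≈2 s sampling, 176 time points per subject).

**SSIM.** The global single-window formula over all `N²` matrix entries
(both symmetric halves and the zero diagonal), with `C1 = (0.01 L)²`,
`C2 = (0.03 L)²`, `L = 1` for binary pairs and max−min of the pair for
weighted ones; population moments (ddof = 0). A local sliding-window
variant (scikit-image) sits behind `windowed=True` for sensitivity checks;
the global formula is the default because it is the printed definition of
the event score.

## Event labeling and evaluation

Events are transitions whose SSIM lies strictly below the subject's own
empirical q-quantile, `q ∈ {0.05, 0.07, 0.10}`; the labeling is independent
of the thermodynamic scores, avoiding circularity. A constant SSIM series
yields zero events and is flagged degenerate.

**Lag tolerance.** Two operationalizations of "detected within ±L windows"
are provided, because they answer different questions:

- `mode="dilate"` (default): labels are dilated by ±L and standard
  AUROC/AP computed against them. Under a structureless score the expected
  AUROC is 0.5, which makes this the right mode for comparing scores and
  aggregating benchmarks; it is what the DC-SBM benchmark and the cohort
  pipeline use (±1 tolerance for exact synthetic boundaries, ±2 for
  SSIM-derived labels on overlapping windows).
- `mode="event_max"`: each event becomes one positive scored by the
  maximum score in its neighborhood; negatives are transitions outside all
  neighborhoods. A lone spike within ±L of the only event scores AUROC 1.0,
  matching the event-centric phrasing of the criterion, but the null
  expectation is that of a max of 2L+1 draws (≈0.75 at L=1), so this mode
  is reserved for per-event detection statements such as the
  extreme-separation sanity checks.

**Spike MCC.** The top-q fraction of |score| values (floor count, ties
broken by stable order) is marked as spikes, with q equal to the event
rate, so both binary vectors have matched positive counts — MCC is
rate-sensitive and this removes the free threshold. Significance uses a
permutation test: uniform shuffles of the spike vector, add-one estimator
`p = (1 + #{MCC_perm ≥ MCC_obs})/(n_perm + 1)`, default 2000 permutations;
a circular-shift variant is exposed for autocorrelation robustness.
p-values are verified super-uniform under the null by Monte-Carlo.

**Group summaries.** Per-subject detection entries are summarized as the
median (and min–max) across quantile cutoffs, then as cohort medians per
group. Subject variability is the sample standard deviation (ddof = 1) of
the U and S series; groups are compared with the two-sample KS test, plus a
purely descriptive KL divergence from 20 shared-width histogram bins with
1e−9 additive smoothing and natural log. Node-level group differences are
per-node group-mean differences of subject-mean node energies, ranked by
magnitude, optionally joined against a plain region-label lookup table.

## Baselines and surrogate

The NetLSD-style score is the ℓ2 distance between heat-trace signatures
`h(t) = Σ_i e^{−t λ̃_i}` on a 250-point log-spaced grid in `[1e−2, 1e2]`
(limits: `h→N` as `t→0`, `h→`#components as `t→∞`). The k-means baseline
(k = 4, seeded, 10 restarts) clusters vectorized upper triangles of the
weighted correlation matrices and scores cluster switches as 0/1 events.
The surrogate null redraws each binary window as G(n, m) with m equal to
its edge count: the U series is preserved exactly by construction while all
block and degree structure is destroyed.

## Synthetic DC-SBM benchmark

80 nodes, 4 equal blocks, 45 windows in three 15-window segments; ground
truth change points at windows 15 and 30 (0-based, transition indexed by
the later window). Degree propensities θ ~ Uniform(0.5, 1.5), normalized to
unit mean within blocks; edge (i, j) appears with probability
`min(1, θ_i θ_j p_{b(i)b(j)})`; present edges carry LogNormal(0, 0.25)
weights times the segment gain. The θ and weight laws and the parameter
grids are design choices of this package (the generative recipe leaves
them open); they are config-exposed and fixed defaults are:

- **R1 (structure-only):** per-segment (p_in, p_out) drawn as ordered
  arrangements of {(0.25, 0.05), (0.30, 0.05), (0.35, 0.08), (0.40, 0.10)};
  a fresh pattern and weights every window; each window rescaled so its
  edge mass equals the previous window's **exactly** (the ΔU ≈ 0 contract
  tightened to ΔU = 0, which makes the R1 invariant assertable).
- **R2 (strength-only):** one wiring setting (0.30, 0.05); the edge
  pattern drawn once per series and frozen; weights redrawn i.i.d. per
  window (so ΔS never degenerates); per-segment gain from orderings of
  {1.2, 1.5, 2.0}. With weights also frozen (`redraw_weights=False`) the
  normalized Laplacian is exactly scale-invariant and SCE is constant —
  the "spectral silence" property test.
- **R3 (mixed):** arrangements of the three modest wiring pairs crossed
  with gain orderings; fresh pattern per window; no rescaling.

Five repeats per cell, cells cycled until the requested series count;
per-series seeds drawn from one master generator. Scoring computes the
full 80-eigenvalue spectrum once per window and shares it between SCE and
the heat trace. The acceptance script runs 500 series per regime (~90 s on
one CPU); the test suite uses 100 per regime (~20 s) — sizes chosen to
keep the Monte-Carlo error of regime medians near ±0.01–0.02.

Reproduced contracts: |T| at chance in R1 with |ΔSCE| clearly above it;
|T| strongest in R2 with spectra near chance; |ΔSCE| ≥ |T| in R3. The
absolute medians in the rewiring-driven cells run somewhat higher than the
reference setting they emulate, as expected when the exact parameter grids
of that setting are not available; the orderings are the robust surface.

## Fixture subjects

`make_fixture_subject` generates block-correlated Gaussian series with
planted covariance-regime switches, standing in for extracted regional
fMRI series. Regions load on a block factor and on a global factor whose
variance share toggles across regimes (0 vs 0.65 of the 0.8 total shared
variance); at each switch the block assignment is also permuted. The
global-synchronization toggle is essential: a pure block permutation
preserves edge mass, and a ratio index ΔU/ΔS cannot rank such switches
above its own heavy-tailed quiet-period noise — strength change is the
component |T| is built to see. Defaults: 60 regions, 6 blocks, 240 time
points, one switch at t = 120.

Fixture evaluation uses non-overlapping windows (w = s = 15). With stride
1 an abrupt switch diffuses across w transitions — each step exchanges a
single time point — so no single transition carries the change and the
lowest-SSIM transition cannot be pinned to ±2 windows; non-overlapping
windows concentrate the switch in exactly one transition. This is also why
real-data evaluation with overlapping windows needs the ±2 lag credit in
the first place.

What the fixture does **not** emulate: temporal autocorrelation
(hemodynamics), measurement noise structure, negative correlations between
networks, slow drifts, or subject-level heterogeneity beyond the
synchronization-level knob. Passing fixture tests shows the pipeline's
mechanics are correct and that its scores behave as designed under known
ground truth — not that real resting-state data meet these assumptions.

## Numerical choices and degenerate inputs

- `0·ln 0 = 0` throughout; entropies returned as +0.0.
- Eigenvalues clipped to [0, 2]; correlations clipped to [−1, 1] after
  symmetrization.
- Binarization strictly greater-than; a correlation of exactly 0.5 is not
  an edge.
- AUROC/AP undefined (NaN, never 0.5) when a class is empty after NaN
  masking; MCC defined as 0 when a confusion-matrix factor vanishes.
- All randomness flows through `numpy.random.Generator` objects seeded
  from explicit arguments; CLI runs serialize their full configuration
  into the output directory.

## Known limitations

- Binary thresholding at a fixed 0.5 is a design decision, not an optimum;
  weighted mode stores raw signed correlations and the energy accounting
  then requires nonnegative weights downstream (binary mode is the
  default real-data path).
- The plain SCE anti-aligns with full-spectrum entropy dynamics by
  construction (mass moving into the core raises SCE while lowering VNE);
  the renormalized control flips the sign. Both behaviors are tested.
- Group-level permutation-p summaries are descriptive; no multiplicity
  correction across subjects is applied.
- Real multi-subject fMRI cohorts are out of scope at desk scale; the
  pipeline emits the same table schemas on fixture cohorts instead.
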