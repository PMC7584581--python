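# Methods

`segint` implements a generative surrogate analysis of how the geometry,
topology, and local (resting-state-network-attached) edges of a structural
connectome shape the dynamic fluctuations between segregated and
integrated functional-connectivity patterns. The pipeline is: synthetic
connectome → constrained weight-permutation surrogates → delay-coupled
phase-oscillator simulation → hemodynamic BOLD conversion → tapered
sliding-window functional connectivity → signed network measures →
fluctuation-magnitude statistics.

## Synthetic connectome generator

The generator emulates the statistical structure of a group-level human
connectome so that every downstream stage is testable without imaging
data. Nodes are sampled on two mirrored ellipsoidal hemispheric shells
(semi-axes 30 × 65 × 50 mm, hemisphere centres ±32 mm lateral), giving a
broad, bimodal-ish distribution of inter-node Euclidean distances.
Streamline length is Euclidean distance times a tortuosity factor (1.2).

Candidate edge weights follow

    w = exp(-L / lambda) * m_comm * m_hub * m_homotopic * lognormal(0, sigma)

with decay scale `lambda` = 45 mm, within-community multiplier 3,
hub-incidence multiplier 3 per hub endpoint, homotopic (mirror-pair)
multiplier 6, and log-normal noise `sigma` = 1. Hub–hub pairs pay half
the distance cost (`2 lambda`), creating a long-range but strong core —
the wiring-cost/rich-club tradeoff. Communities are spatially coherent
(k-means on coordinates); hubs are the nodes nearest each community
centroid (15 % of nodes). Edge existence keeps the strongest candidate
weights up to the target density (0.19); a repair pass re-adds the
strongest bridging edges and drops the weakest removable edges so the
graph is connected at the exact target count.

Each node carries one of seven RSN labels. The VIS allotment (20 % of
nodes) is placed on the most posterior nodes, making it spatially compact;
under distance decay this yields the highest within-RSN edge density for
the visual network, the feature the local-contribution analysis probes.
Other labels are assigned at random in proportions CON .13 / DMN .17 /
LIM .10 / DAN .12 / VAN .12 / SMN .16.

What the generator does *not* emulate: subject-level variability and
consensus thresholding (the density target stands in for it),
tractography biases, hemispheric asymmetries, and empirical length
distributions beyond the qualitative shape. Passing tests therefore show
that the machinery behaves correctly under realistic structure, not that
the quantitative magnitudes transfer to empirical imaging data.

## Surrogate families

Surrogates permute non-zero weights on the fixed binary support within
disjoint *cells* of edges:

* **R** — one cell with every edge (no constraint);
* **G** — equal-width streamline-length bins;
* **T** — community blocks (each within-community block, plus the single
  between-communities block) intersected with rich-club degree
  categories (an edge's category is the smaller of its endpoint binary
  degrees, so permutation preserves the weighted rich-club curve
  exactly);
* **GT** — all three constraints intersected.

The number of length bins is selected by scanning candidate counts 100,
90, …, 10 and accepting the first whose percentage of bins with ≤ 3
edges is ≤ 10 % and whose bins all hold more than one edge; a config
override fixes the count directly (the reduced test profile uses 30).
The community partition is one max-Q* Louvain run-set (100 restarts) on
the parent, frozen and reused for all samples. "Permuted edges" are
edges lying in cells of size ≥ 2 (the permutation pool), which makes the
R family's permuted fraction exactly 1 by construction.

RSN main/control pairs restrict GT cells to edges incident
(main) / non-incident (control) to one RSN; the control pool is randomly
downselected, whole cells first and a partial cell to finish, so the
permutable counts match exactly (a parity fix shaves one edge from a
kept cell of size ≥ 3 when the remainder is 1). Across sample ensembles
the mean absolute fraction difference is < 1e-4.

### Strength-sequence adjustment

After permutation, weights are corrected so every node's strength
(weighted degree) matches the parent's. Each iteration rescales edge
(i, j) by sqrt((s*_i/s_i)(s*_j/s_j)); the composition of iterations is a
diagonal scaling W → F W F, which converges geometrically (max relative
strength error < 1e-3 within ~30 iterations on all tested instances;
non-convergence warns and reports the achieved error rather than
failing). A variant that re-imposes the post-permutation rank order
after every rescale was implemented and measured first: the projection
cancels the correction and the error stalls near its initial value, so
the rank constraint was dropped. Consequences, measured on the reduced
profile: the adjusted weights correlate with the post-permutation ranks
only moderately (Spearman ≈ 0.4–0.9 depending on family), and the
weight–length profile of G is preserved approximately rather than
exactly after adjustment (log-profile correlation with the parent ≈ 0.8
for G versus ≈ 0.25 for R; before adjustment G preserves per-bin means
exactly). The constraint hierarchy that the analysis depends on — G
retains geometry far better than R, GT retains everything best —
survives adjustment.

## Oscillator model

Node phases obey dθ_i/dt = 2πf + k Σ_j c_ij sin(θ_j(t − τ_ij) − θ_i(t))
with f = 60 Hz for all nodes, weights normalized so the mean non-zero
coupling is one, and delays τ_ij = L_ij / v with v = mean(L) / τ̄ and
mean delay τ̄ = 12 ms. Integration is deterministic Heun (explicit
trapezoidal) at dt = 0.2 ms; delays round to the nearest step (≤ 0.1 ms
error, far below the 16.7 ms oscillation period); the history buffer is
seeded by uncoupled backward rotation over the maximum delay (the length
of this uncoupled history phase is otherwise unspecified, so the
backward-rotation convention is this package's choice). Initial phases
are uniform on [0, 2π). The first 20 s are discarded as transient.

Numerics: the coupling term is evaluated from circular sin/cos history
buffers via the angle-difference identity, so the hot loop performs no
per-edge trigonometry; the kernel is numba-compiled. Convergence under
step halving is verified in the contracting (phase-locked) regime; in
the delay-frustrated chaotic regime trajectories decorrelate under any
step change and only distributional quantities are meaningful.

The order parameter r(t) = |(1/N) Σ e^{iθ_n}| tracks global synchrony;
its time mean summarizes a run. On the reduced 57-node profile the
synchrony transition spans ≈ 0.10 (k = 2.5) to ≈ 0.43 (k = 70) across
the canonical grid and continues to rise beyond it.

## Hemodynamics and BOLD

Neural amplitude sin(θ), stored at 1 kHz, drives the standard
four-state Balloon/Windkessel model per node (κ = 0.65 s⁻¹, γ = 0.41
s⁻¹, τ = 0.98 s, α = 0.32, ρ = 0.34, V₀ = 0.02, input gain 1 — the
standard published set, configurable and logged). The ODEs integrate
with the same Heun scheme at 1 ms. Raw BOLD is band-pass filtered with a
zero-phase 2nd-order Butterworth (0.021–0.1 Hz; the low cut equals
1/window-width and is re-derived when the window changes), sampled onto
the TR grid (0.72 s; the 0.1 Hz band edge leaves no energy near the TR
Nyquist), and the node-mean global signal is regressed out with an
intercept. Absolute BOLD amplitudes are not meaningful — only
correlation-based quantities, which are scale-invariant, feed the
analysis. Note the global-signal regression is homogeneous but not
additive (its regressor depends on the data), so "linearity" holds for
the filter/resampling stage only; the tests reflect that.

## Time-resolved functional connectivity

The taper is a rectangle of 66 TRs convolved with a Gaussian of σ = 9
TRs truncated at ±3σ (support 120 TRs), normalized to unit sum, and used
as *observation weights* in a weighted Pearson correlation (the
convention is this package's; pointwise signal multiplication is the
main alternative). Windows advance in steps of 3 TRs from the series
start; the last partial window is dropped. Correlations are Fisher
z-transformed with |r| clamped at 1 − 1e-15, kept signed, never
thresholded. Zero-variance nodes inside a window (detected with a
scale-relative tolerance) produce z = 0 with a warning. Robustness
settings (widths 44/88 TRs, steps 1/66 TRs) are reachable through the
config.

## Network measures

Signed modularity Q* splits w into positive/negative parts with
strength-product null terms e±_ij = s±_i s±_j / ν±, the negative term
weighted by 1/(ν⁺+ν⁻) and dropped when no negative weights exist; sums
run over ordered pairs including diagonal null terms, so the
single-community partition scores exactly zero. Louvain maximization
operates on the dense gain matrix whose block sums equal Q*; restart
randomization is the node visiting order (100 restarts, γ = 1, seeded),
ties break toward the first encountered community, and the max-Q*
partition is kept. Exhaustive enumeration of all set partitions on ≤ 8
nodes provides the oracle in tests.

The participation coefficient uses positive strengths only:
PC_i = 1 − Σ_c (κ⁺_ic/κ⁺_i)²; nodes with zero positive strength score 0
with a warning. The temporal participation coefficient averages the same
concentration sum over every window's partition. Per window the pipeline
records mean PC (with that window's partition), Q*, and afterwards the
mean TPC series; the magnitude of dynamic fluctuations is the sample SD
of each series across windows.

## Coupling selection and rejection

The reference synchrony is the mean time-mean order parameter over
seeded runs of the parent at the reference coupling. For each surrogate
sample, k is scanned over a grid and the value minimizing |mean r −
reference| is selected; if even the best value misses by more than the
rejection radius the sample is discarded and a fresh surrogate drawn.
The radius defaults to 0.085 — the printed tolerance of the original
protocol — because the synthetic parent's seed-to-seed synchrony spread
(< 0.01) is far narrower than its empirical counterpart and would
otherwise reject almost everything; setting it to null uses the measured
spread instead. Matching probes are short runs (20 s with a 5 s
transient in the reduced profile) compared against a reference built
with the same probe protocol, so estimator bias cancels; accepted
samples are then simulated at full length. The stage-1 empirical-fit
criteria (FC correlation at structurally connected edges > 0.33,
KS distance of windowed edge-weight pools < 0.33) are provided as
functions; the full two-stage empirical optimization requires imaging
data and is out of scope.

## Study conditions and problem sizes

Two profiles are frozen in the package. The full profile (`default_config`)
uses 114 nodes, density 0.19, 140 s runs, the canonical coupling grid
2.5–70 in steps of 2.5, and 50 samples per family. The reduced profile
(`desk_config`) — used by the test suite and the analysis drivers — uses
57 nodes, 8 accepted samples per family, 140 s runs, a 45–100 coupling
grid in steps of 2.5 (surrogate families synchronize at higher couplings
than the parent, so the grid extends beyond the canonical upper bound of
70), 30 length bins by override (the scan's hard all-bins-filled
criterion is unreliable at 303 edges), coupling probes integrated at a
coarsened 0.5 ms step (probe estimates at 0.5 ms and 0.2 ms agree to
< 0.01 in mean r; the coarse step is used on both sides of the match),
and reference coupling k = 67.5, the sweep's intermediate-synchrony
point (mean r ≈ 0.35, the analogue of the intermediate regime the
canonical parameters target). Fluctuation
comparisons on this profile are directional checks of the sign pattern
(G > R, T > R, actual > GT in median SD of mean PC), not magnitude
reproductions.

## Known limitations

* The directional comparison uses 8 samples per family, and each 140 s
  run yields only 16 heavily overlapping FC windows, so the per-sample
  SD estimate carries substantial noise: re-simulating the identical
  parent with different seeds spreads SD(mean PC) by roughly a factor of
  three. The G-vs-R and T-vs-R orderings reproduce at this scale; the
  parent-vs-GT contrast is smaller than that noise floor and does not
  reproduce reliably at 8 samples (larger ensembles recover it, with
  effect sizes well below those reported for full-size empirical
  connectomes).
* Coupling probes are shorter than scored runs; slow synchrony drift
  means probe-based matching is internally consistent but not identical
  to full-length matching.
* The strength adjustment preserves the permuted rank order only
  approximately (see above).
* Hemodynamic parameters are homogeneous across nodes; no physiological
  noise is injected.
* The generator's length distribution and multiplier values are
  plausible stand-ins, not fits to empirical tractography.
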