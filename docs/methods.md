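# Methods

This note documents the models and numerical choices behind `himnet`: what
is computed, with which defaults, and what the synthetic benchmark does and
does not establish.

## Graph model

All graphs are simple and undirected with weights in `[0, 1]`: symmetric
adjacency, zero diagonal. Node identity is by label and matrix order is the
declared label order; two graphs are comparable only when their label
sequences match exactly (`align_nodes` reorders explicitly — silent
reordering would hide data errors, as would silent symmetrization, so
adjacency files must be exactly symmetric and self-loops are rejected at
read time). Weights are 64-bit floats; "binary" means every entry is
exactly 0 or 1. Weighted graphs use the weighted Laplacian (degrees are
weight sums) and the same `N(N−1)` Hamming normalizer as binary ones.

## The Ipsen–Mikhailov distance

The spectral density of a graph at width γ is a sum of `N−1` Lorentzian
kernels centered at `ω_i = √λ_i`, normalized to unit mass on `[0, ∞)`:
`K = 1 / Σ_i (π/2 + arctan(ω_i/γ))`. Eigenvalues are sorted ascending and
exactly the first (always 0) is dropped, regardless of connectivity: a
disconnected graph contributes its additional zero modes as `ω = 0`
kernels. Eigenvalues in `(−1e−9, 0)` are treated as rounding noise and
clipped; anything more negative is an error.

**ε as an L2 norm.** The distance is implemented as the *square root* of
the squared-density integral. The two normalization facts — `ε_γ̄` on the
(empty, clique) pair equals 1, and HIM combining H and IM as a Euclidean
product — are only mutually consistent under the L2 reading; the literal
squared integral is available via `epsilon_gamma(..., take_root=False)`.

**Evaluation.** The integral of a product of two Lorentzians over
`[0, ∞)` has a closed form (partial fractions; the log term is evaluated
with `log1p` for stability at nearly equal centers, with the analytic
limit used below `|ω_a − ω_b| < 1e−9·γ`). The default path sums these
closed forms over all kernel pairs; an adaptive-quadrature path
(integration split at every kernel center, plus a semi-infinite tail
integral beyond `ω_max + 50γ`, relative tolerance 1e−10) is retained and
the two are cross-checked to 1e−8 in the tests. Squared distances that
come out at a small negative value through cancellation (isospectral
pairs) are clipped to 0.

**Calibration.** `γ̄(N)` solves `ε_γ(E_N, F_N) = 1`. The calibration
function is strictly decreasing in γ over the bracket (verified by a dense
γ-grid scan), so the root is unique; it is found by Brent's method on
`[1e−3, 10]` (geometrically expanded if needed) to tolerance 1e−12 and
cached per `N` process-wide. Reference value: `γ̄(6) = 0.434749181077`.
Projection graphs live on λ nodes, so D3 uses a separate `γ̄(λ)`
calibration from the layer-level `γ̄(ν)`; both are cached.

## The worked six-node example

The demonstration graphs (ring, star, 3-regular, 3×2 lattice) carry fixed
node labelings chosen so that the standard pairwise relations hold
(H(ring,star) = H(ring,lattice), H(star,C) = H(star,lattice), and C and
the lattice sharing six edges). Of the two 3-regular graphs on six nodes,
only the triangular prism admits labelings consistent with those
relations — an exhaustive permutation search shows the complete bipartite
K₃,₃ does not — so the prism is the package's canonical "network C", and
`worked_example_graphs()` includes K₃,₃ only for comparison.

## Distance series and changepoints

Series are materialized for `t = 1..τ` with `values[1] = 0` (the anchor
compared against itself); changepoint indices are reported on this 1-based
axis, a changepoint at `k` meaning segments `..k` and `k+1..`. The anchor
is always the first element of the series; sliding-window variants are out
of scope.

**Mean/variance cost.** Twice the negative Gaussian log-likelihood with
per-segment MLE mean and variance, `n(log 2π + log σ̂² + 1)`, with σ̂²
floored at 1e−12 so constant segments stay finite. Minimum segment length
2 (a variance needs two points). Note the small-segment behavior of this
cost family: at low penalties, short low-variance chunks of pure noise can
pay for themselves, which is precisely why a penalty *sweep* rather than a
single penalty is the recommended interface.

**PELT.** Exact dynamic programming with pruning. With a minimum segment
length L, the textbook pruning rule must be applied with a lag: a
candidate failing the inequality at step `s` may still be optimal at steps
`s+1 .. s+L−1` (where `s` itself is not yet an admissible boundary), so
candidates are scheduled for removal at `s + L`. Exactness is verified
against exhaustive enumeration on hundreds of short series.

**CROPS.** The sweep runs PELT at the range endpoints and recurses at the
crossing penalty `β* = (cost_lo − cost_hi)/(k_hi − k_lo)` whenever the
changepoint counts differ by more than one, yielding every optimal
segmentation in the range with at most `2 + #segmentations` PELT runs.
The default range is `[2·log τ, 10·log τ]` (natural log). The "stable"
segmentation reported by the model object is the one optimal over the
widest penalty sub-interval.

## Increment entropy

Increments `v_t = x_{t+1} − x_t` are scanned with a window of `m`
consecutive increments (default `m = 2`); each increment becomes a
two-letter symbol: its strict sign (−/0/+) and a magnitude bin
`q = min(⌊|v|·R/σ⌋, R)` (default `R = 2`). The entropy (base 2) of the
empirical word distribution, divided by `m − 1`, is returned.

The quantization scale σ is, by default, the standard deviation of the
increments *within the window*; a global-σ variant (std of the whole
increment series) sits behind `IncEntParams(scale="global")`. The windowed
default makes the statistic scale-invariant, at the cost of amplifying
rounding-level wiggles — a window whose spread is below 1e−9 of its
largest increment is therefore treated as constant. With `m = 2` the
`1/(m−1)` normalizer is inert; it matters for larger words.

## The scripted-spike synthetic benchmark

The generator emulates a multiplex system undergoing scheduled state
transitions: λ = 5 binary layers on ν = 10 nodes over τ = 30 steps, all
seeded from one shared Erdős–Rényi G(10, 0.3) draw (correlated
multiplexity), evolved by the perturbation `Π(N, (m, M))`: draw
`g ~ U[m, M]` and toggle `⌊g·n(n−1)/2⌋` distinct node pairs chosen without
replacement. Transition intensities: default (0.05, 0.2) at every ordinary
step, and a scripted mix of small (0.2, 0.3) / medium (0.25, 0.4) / large
(0.5, 0.7) per layer at the three spike times t = 10, 17, 24 (applied to
the previous state). A single seeded RNG drives everything in layer-major
order, so runs are bit-reproducible; one `g` is drawn per Π call (the rule
names a single `g`).

**What passing and failing tests show.** The generator implements the
stated rule verbatim, and the test suite verifies the rule-level contracts
exactly (toggle counts, schedule, determinism, degenerate controls). The
*indicator-level* expectations — recovery of the spike boundaries
{9, 16, 23} by the D3 changepoint analysis and a particular ranking of
increment entropies across the eight series — do **not** hold under this
rule, and the corresponding tests are left failing deliberately. The
reason is structural, not a tuning matter: the default transition toggles
≈5.6 of 45 pairs per step, so the normalized Hamming distance of every
layer (and every layer pair) contracts toward its stationary value 0.5
with factor ≈0.75 per step and the system fully mixes by t ≈ 6, *before
the first spike*; after that, spikes of any intensity barely move the
anchored distance series. Variant experiments (perturbation fractions
relative to the link count rather than all pairs; fluctuation around a
piecewise-constant state) do reproduce staircase-shaped D-series whose
changepoints sit at {9, 16, 23}, but none of these variants is compatible
with the stated rule, so they are not shipped as defaults. Users studying
transition detection should treat the spike intensities relative to the
mixing time of the default noise as the key design quantity.

The benchmark also does not emulate several features of real multiplex
data: weighted layers, heterogeneous layer densities, persistent node-level
heterogeneity (all pairs are exchangeable), and missing observations.

## Event-data pipeline

WEIS-coded dyadic event files are parsed into (date, source, target,
3-digit code) records; the 66 monitored categories each define one layer
of a monthly multiplex network with a binary undirected link per dyad per
category per month. The node set is the union of all actors over the whole
range, fixed across time — early months carry many isolated nodes, which
is required for HIM comparability across months. Direction is discarded
and within-month duplicates collapse. Actor codes are used verbatim (no
alias merging; any upstream merging is unrecoverable — a reproducibility
caveat). The First-Gulf-War analysis window is Aug 1990 – Mar 1991 and the
full range Apr 1979 – Mar 1999 (240 months); both are configurable. The
deposited full dataset must be downloaded separately; the test suite
exercises the pipeline on a small synthetic fixture only.

## MDS and communities

Classical (Torgerson) MDS: double-center `−D²/2`, top-k nonnegative
eigenpairs, eigenvectors scaled by `√eigenvalue`, each eigenvector's first
nonzero coordinate made positive for reproducible output. Community
detection on projection graphs delegates to igraph's multilevel (Louvain)
implementation; it is a thin wrapper that records modularity and seed, not
a re-implementation.

## Known limitations

* IM (hence HIM at small H) cannot separate isospectral graphs; HIM is
  still nonzero for non-identical isomorphic graphs through its Hamming
  component.
* The closed-form ε path assumes well-separated or exactly coincident
  kernel centers; the `1e−9·γ` switchover is tested but extremely tight
  near-degenerate spectra fall back on the analytic limit.
* Directed graphs, multigraphs, weights outside `[0, 1]`, and inter-layer
  coupling links are out of scope.
* The meanvar cost over-segments low-variance noise at small penalties;
  interpret single-penalty results with care and prefer the CROPS sweep.
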