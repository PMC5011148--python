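# himnet

Graph distances and dynamics analysis for time series of multiplex
networks: the Hamming–Ipsen–Mikhailov (HIM) metric, network-of-networks
projections, and changepoint/entropy indicators for detecting state
transitions.

## Who this is for

Anyone comparing networks on a shared node set over time — political event
networks, biological pathways, power grids, social interaction layers —
who needs a single real-valued indicator that answers: *when did the
system's structure change?*

## The method

**The HIM distance.** For two simple undirected graphs `G1`, `G2` on the
same `N` nodes (binary or `[0,1]`-weighted), three distances are defined:

* the normalized **Hamming** distance (local, edit-based)

  `H(G1,G2) = Σ_{i≠j} |A¹_ij − A²_ij| / (N(N−1))`,

  which is 0 only for identical graphs and 1 only for complementary ones;

* the **Ipsen–Mikhailov** distance (global, spectral): each graph gets a
  Lorentzian spectral density built on the vibrational frequencies
  `ω_i = √λ_i` of its Laplacian `L = D − A`,

  `ρ(ω, γ) = K Σ_{i=1}^{N−1} γ / ((ω − ω_i)² + γ²)`,  `∫₀^∞ ρ dω = 1`,

  and `IM(G1,G2) = ε_γ̄ = ( ∫₀^∞ [ρ₁(ω,γ̄) − ρ₂(ω,γ̄)]² dω )^{1/2}`, with the
  width `γ̄` calibrated per `N` so that `ε_γ̄(E_N, F_N) = 1` for the empty
  graph / clique pair;

* their **glocal** combination

  `HIM_ξ(G1,G2) = √(H² + ξ·IM²) / √(1+ξ)`,  ξ = 1 by default,

  bounded in `[0,1]`, zero only for identical graphs, one only on
  `(E_N, F_N)`.

**Multiplex dynamics.** A multiplex series has λ layers on ν shared nodes
observed at τ time steps. Each snapshot is projected to one graph — the
*metric projection* (complete weighted graph on the λ layers, edge weights
`1 − HIM(L_i, L_j)`) or the *collapsed projection* (boolean OR / mean of
the layers) — and three anchored distance series are extracted:
per-layer `D1(t) = HIM(L_i(t), L_i(1))`, collapsed `D2`, and metric `D3`.
The series are then scored with increment entropy (unpredictability) and
mean/variance changepoint detection (exact PELT, with a CROPS penalty
sweep over `[2·log τ, 10·log τ]`).

## Worked example

The classic six-node demonstration: ring (A), star (B), 3-regular
triangular prism (C), 3×2 lattice (D):

```python
from himnet import hamming_distance, im_distance, him_distance
from himnet.him import worked_example_graphs

gs = worked_example_graphs()
for a, b in [("ring", "lattice"), ("prism", "lattice"), ("star", "prism")]:
    print(f"{a:7s} vs {b:8s}  H={hamming_distance(gs[a], gs[b]):.4f}  "
          f"IM={im_distance(gs[a], gs[b]):.4f}  HIM={him_distance(gs[a], gs[b]):.4f}")
```

prints

```
ring    vs lattice   H=0.4667  IM=0.0827  HIM=0.3351
prism   vs lattice   H=0.2667  IM=0.1510  HIM=0.2167
star    vs prism     H=0.5333  IM=0.4534  HIM=0.4950
```

Reading the numbers: the ring and the lattice share few edges (large H)
but are spectrally almost alike (small IM) — locally different, globally
similar. The prism and the lattice are the closest pair overall
(HIM ≈ 0.217); the star and the prism are the farthest (HIM ≈ 0.495),
disagreeing both edge-wise and spectrally.

A full multiplex analysis runs through the model object:

```python
from himnet import MultiplexDynamics
from himnet.synthetic import SyntheticScenario, generate_scenario

series = generate_scenario(SyntheticScenario(seed=1))   # τ=30, λ=5, ν=10
results = MultiplexDynamics(series).fit()
print(results.summary())
```

which reports the increment entropy of all eight series (five D1 curves,
their mean, D2, D3) and the CROPS changepoint sweep of D2 and D3.

## Command line

```bash
him dist --metric him g1.graphml g2.graphml
him matrix --out dist.csv g1.edges g2.edges g3.edges
him synth --tau 30 --seed 42 --out scenario/
him series --kind d3 --out d3.csv scenario/manifest.yaml
him incent d3.csv --m 2 --r 2
him changepoint d3.csv --crops --out cps.json
him mds dist.csv --k 2 --out coords.csv
him gulf build --src events.txt --out series/
```

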