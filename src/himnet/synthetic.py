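"""Synthetic multiplex time series with scripted state transitions.

The generator emulates a small dynamic multiplex benchmark: λ binary layers
on ν shared nodes evolve over τ time steps by random link toggling.  A
perturbation Π(N, (m, M)) of a binary graph N draws g ~ Uniform[m, M] and
swaps the present/absent status of ⌊g·n(n-1)/2⌋ distinct node pairs chosen
uniformly without replacement.

Four named transition intensities are used: default σd = (0.05, 0.2),
small σs = (0.2, 0.3), medium σm = (0.25, 0.4) and large σl = (0.5, 0.7).
All layers start from perturbations of a single shared Erdős–Rényi G(ν, p)
draw (correlated multiplexity); at three scripted spike times a per-layer
mix of small/medium/large transitions is applied, and every other step
applies the default transition to the previous state.  The spikes are the
ground-truth state transitions a changepoint analysis should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph, MultiplexSeries, MultiplexSnapshot

__all__ = [
    "PerturbationSpec",
    "TRANSITIONS",
    "SyntheticScenario",
    "perturb",
    "erdos_renyi",
    "generate_scenario",
    "run_synthetic_experiment",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Fraction bounds 0 <= low <= high <= 1 of node pairs to toggle."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError(f"need 0 <= low <= high <= 1, got ({self.low}, {self.high})")


#: The four named transition intensities.
TRANSITIONS: dict[str, PerturbationSpec] = {
    "default": PerturbationSpec(0.05, 0.2),
    "small": PerturbationSpec(0.2, 0.3),
    "medium": PerturbationSpec(0.25, 0.4),
    "large": PerturbationSpec(0.5, 0.7),
}


def perturb(g: Graph, spec: PerturbationSpec, rng: np.random.Generator) -> Graph:
    """Toggle ⌊g·n(n-1)/2⌋ uniformly chosen node pairs, g ~ U[low, high].

    One g is drawn per call; the toggled pairs are sampled without
    replacement, so the result differs from the input in exactly that many
    pairs.
    """
    if not g.is_binary:
        raise ValueError("perturbation is defined for binary graphs only")
    n = g.n
    n_pairs = n * (n - 1) // 2
    frac = rng.uniform(spec.low, spec.high)
    k = int(np.floor(frac * n_pairs))
    a = np.array(g.adjacency)
    if k > 0:
        iu, ju = np.triu_indices(n, k=1)
        chosen = rng.choice(n_pairs, size=k, replace=False)
        for idx in chosen:
            i, j = iu[idx], ju[idx]
            a[i, j] = a[j, i] = 1.0 - a[i, j]
    return Graph(a, g.node_labels)


def erdos_renyi(
    n: int, p: float, rng: np.random.Generator, labels=None
) -> Graph:
    """Erdős–Rényi G(n, p): each unordered pair present independently."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    a = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < p
    a[iu[present], ju[present]] = 1.0
    a = a + a.T
    return Graph(a, tuple(labels) if labels else ())


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the scripted-spike benchmark.

    Defaults: τ=30 steps, λ=5 layers, ν=10 nodes, base density p=0.3 and
    spikes at (τ1, τ2, τ3) = (10, 17, 24); the initial step is τ0 = 1.
    """

    tau: int = 30
    lam: int = 5
    nu: int = 10
    er_p: float = 0.3
    spikes: tuple[int, int, int] = (10, 17, 24)
    seed: int = 0
    transitions: dict = field(default_factory=lambda: dict(TRANSITIONS))

    def __post_init__(self) -> None:
        t1, t2, t3 = self.spikes
        if not 1 < t1 < t2 < t3 <= self.tau:
            raise ValueError(f"need 1 < τ1 < τ2 < τ3 <= τ, got {self.spikes}")
        if not 0.0 < self.er_p < 1.0:
            raise ValueError(f"base density must be in (0, 1), got {self.er_p}")
        if self.lam < 1 or self.nu < 2:
            raise ValueError("need at least 1 layer and 2 nodes")


# Per-spike transition assignment, keyed by layer index 1..5: which layers
# receive the small / medium / large transition at each scripted spike.
_SPIKE_PLAN = {
    0: {"small": (1, 2), "medium": (3, 4), "large": (5,)},        # t = τ0
    1: {"small": (1, 3, 5), "medium": (), "large": (2, 4)},       # t = τ1
    2: {"small": (3, 5), "medium": (1, 2), "large": (4,)},        # t = τ2
    3: {"small": (5,), "medium": (3,), "large": (1, 2, 4)},       # t = τ3
}


def _transition_for(sc: SyntheticScenario, t: int, layer_1based: int) -> str:
    events = {1: 0, sc.spikes[0]: 1, sc.spikes[1]: 2, sc.spikes[2]: 3}
    if t in events:
        plan = _SPIKE_PLAN[events[t]]
        for name, layers in plan.items():
            if layer_1based in layers and layer_1based <= 5:
                return name
        if layer_1based <= 5:
            return "default"
    return "default"


def generate_scenario(sc: SyntheticScenario) -> MultiplexSeries:
    """Generate the scripted multiplex series, deterministically in the seed.

    All λ layers at t = 1 are perturbations of one shared Erdős–Rényi draw.
    The generator is driven by a single seeded RNG in layer-major order
    within each time step, so runs are exactly reproducible.  Layers beyond
    the fifth (if λ > 5) follow the default transition throughout.
    """
    rng = np.random.default_rng(sc.seed)
    base = erdos_renyi(sc.nu, sc.er_p, rng)
    layers_prev: list[Graph] = []
    snapshots = []
    for t in range(1, sc.tau + 1):
        layers_t = []
        for i in range(1, sc.lam + 1):
            spec = sc.transitions[_transition_for(sc, t, i)]
            source = base if t == 1 else layers_prev[i - 1]
            layers_t.append(perturb(source, spec, rng))
        layers_prev = layers_t
        snapshots.append(MultiplexSnapshot(tuple(layers_t)))
    return MultiplexSeries(tuple(snapshots))


def run_synthetic_experiment(
    scenario: SyntheticScenario | None = None,
    him_params=None,
    incent_params=None,
    cp_config=None,
):
    """Full benchmark run: generate, project, and score one scenario.

    Computes the λ per-layer D1 series, their mean, D2 and D3; the
    increment entropy of each (m=2, R=2 by default); and PELT/CROPS
    mean-variance changepoints of D2 and D3 over the penalty range
    [2·log τ, 10·log τ].  Returns a :class:`MultiplexDynamicsResults`.
    """
    from .model import MultiplexDynamics

    sc = scenario or SyntheticScenario()
    series = generate_scenario(sc)
    model = MultiplexDynamics(series, him_params=him_params)
    return model.fit(incent_params=incent_params, cp_config=cp_config)
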