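"""Synthetic data generation from the model's own generative process.

The generator produces a reaction catalog, a sample dataset and the ground
truth used to produce them, so that inference can be validated by parameter
recovery. The defaults reproduce the published simulation-study design:
samples draw their metabosystem mixture θ_n from a sparse symmetric
Dirichlet; each of ~Poisson(1000) reaction tokens draws a metabosystem
Z ~ Cat(θ_n), a subnetwork Y ~ Cat(φ_Z), a pair count J ~ Poisson(2)+1,
then J substrate compounds from δ_Y and J product compounds from γ_Y.

A reaction's identity is the (sorted substrate multiset, sorted product
multiset) of a token's draws; identical draws within a sample accumulate
abundance multiplicity, which makes the output shaped like real
reaction-abundance input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Reaction, ReactionCatalog, SampleDataset

__all__ = ["SimulationParams", "GroundTruth", "simulate", "simulation_grid"]


@dataclass
class SimulationParams:
    """Parameters of the generative simulation.

    Defaults correspond to one cell of the published simulation grid:
    40 samples over 100 compounds, 3 metabosystems of 10 subnetworks,
    ~1000 reaction tokens per sample, Poisson(2)+1 substrate-product pairs
    per token, generating concentration 0.10 at the θ and φ levels.
    """

    N: int = 40
    C: int = 100
    K: int = 3
    L: int = 10
    mean_reactions: float = 1000.0
    mean_extra_pairs: float = 2.0
    alpha_theta_gen: float = 0.10
    alpha_phi_gen: float = 0.10
    alpha_delta_gen: float = 0.05
    alpha_gamma_gen: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("N", "C", "K", "L"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.mean_reactions <= 0 or self.mean_extra_pairs < 0:
            raise ValueError("mean_reactions must be > 0 and mean_extra_pairs >= 0")
        for name in (
            "alpha_theta_gen",
            "alpha_phi_gen",
            "alpha_delta_gen",
            "alpha_gamma_gen",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GroundTruth:
    """The latent quantities a simulation was generated from.

    ``z_true[n]`` / ``y_true[n]`` hold per-token labels of sample ``n`` in
    draw order (which is also the dataset's token expansion order, since
    occurrences are registered in first-appearance order with accumulating
    multiplicity — identical tokens are exchangeable).
    """

    theta_true: np.ndarray  # (N, K)
    phi_true: np.ndarray  # (K, L)
    delta_true: np.ndarray  # (L, C)
    gamma_true: np.ndarray  # (L, C)
    z_true: list[np.ndarray] = field(default_factory=list)
    y_true: list[np.ndarray] = field(default_factory=list)


def simulate(params: SimulationParams) -> tuple[ReactionCatalog, SampleDataset, GroundTruth]:
    """Generate (catalog, dataset, truth) from the model, deterministically.

    One root generator drives the whole simulation; the stream order is
    fixed (θ rows, φ rows, δ rows, γ rows, then per-sample tokens in
    sample order) so a given seed always yields byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    N, C, K, L = params.N, params.C, params.K, params.L

    theta = np.vstack([rng.dirichlet(np.full(K, params.alpha_theta_gen)) for _ in range(N)])
    phi = np.vstack([rng.dirichlet(np.full(L, params.alpha_phi_gen)) for _ in range(K)])
    delta = np.vstack([rng.dirichlet(np.full(C, params.alpha_delta_gen)) for _ in range(L)])
    gamma = np.vstack([rng.dirichlet(np.full(C, params.alpha_gamma_gen)) for _ in range(L)])

    compounds_used: set[int] = set()
    reaction_key_to_idx: dict[tuple[tuple[int, ...], tuple[int, ...]], int] = {}
    reaction_keys: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    occurrences: list[list[tuple[int, int]]] = []
    z_true: list[np.ndarray] = []
    y_true: list[np.ndarray] = []

    for n in range(N):
        i_n = 0
        while i_n == 0:  # a sample must contain at least one token
            i_n = int(rng.poisson(params.mean_reactions))
        z_n = np.empty(i_n, dtype=np.int64)
        y_n = np.empty(i_n, dtype=np.int64)
        occ: list[tuple[int, int]] = []
        occ_pos: dict[int, int] = {}
        for i in range(i_n):
            z = int(rng.choice(K, p=theta[n]))
            y = int(rng.choice(L, p=phi[z]))
            z_n[i] = z
            y_n[i] = y
            j = int(rng.poisson(params.mean_extra_pairs)) + 1
            subs = tuple(sorted(int(c) for c in rng.choice(C, size=j, p=delta[y])))
            prods = tuple(sorted(int(c) for c in rng.choice(C, size=j, p=gamma[y])))
            key = (subs, prods)
            r = reaction_key_to_idx.get(key)
            if r is None:
                r = len(reaction_keys)
                reaction_key_to_idx[key] = r
                reaction_keys.append(key)
                compounds_used.update(subs)
                compounds_used.update(prods)
            if r in occ_pos:
                pos = occ_pos[r]
                occ[pos] = (r, occ[pos][1] + 1)
            else:
                occ_pos[r] = len(occ)
                occ.append((r, 1))
        occurrences.append(occ)
        z_true.append(z_n)
        y_true.append(y_n)

    # Dense compound indexing covers the full simulated universe [0, C) so
    # that truth matrices and catalog indices line up column-for-column.
    from .core import Compound

    compounds = [Compound(f"C{c:05d}", c) for c in range(C)]
    reactions = []
    for r, (subs, prods) in enumerate(reaction_keys):
        pairs = tuple(zip(subs, prods))
        reactions.append(Reaction.from_pairs(f"SR{r:06d}", pairs))
    catalog = ReactionCatalog(compounds, reactions)
    dataset = SampleDataset([f"sample{n:03d}" for n in range(N)], occurrences, catalog)
    truth = GroundTruth(theta, phi, delta, gamma, z_true, y_true)
    return catalog, dataset, truth


def simulation_grid(base_seed: int = 100000) -> list[SimulationParams]:
    """The full factorial simulation-study grid, with deterministic seeds.

    Levels: N ∈ {40,60,80,100} × C ∈ {100,500,1000} × K ∈ {3,5} ×
    L ∈ {10,20,50} × generating α ∈ {0.05,0.10,0.20} (the same α applied to
    the θ and φ levels). 216 cells, each with mean_reactions=1000 and
    mean_extra_pairs=2.
    """
    grid: list[SimulationParams] = []
    i = 0
    for n in (40, 60, 80, 100):
        for c in (100, 500, 1000):
            for k in (3, 5):
                for l in (10, 20, 50):
                    for a in (0.05, 0.10, 0.20):
                        grid.append(
                            SimulationParams(
                                N=n,
                                C=c,
                                K=k,
                                L=l,
                                mean_reactions=1000.0,
                                mean_extra_pairs=2.0,
                                alpha_theta_gen=a,
                                alpha_phi_gen=a,
                                seed=base_seed + i,
                            )
                        )
                        i += 1
    return grid
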