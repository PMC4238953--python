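"""Shared test helpers: tiny-problem builders and an independent
brute-force oracle for the collapsed model.

The oracle evaluates the collapsed joint probability P(Z, Y, data | α) of a
full label configuration directly from Dirichlet-multinomial normalizing
constants (products of gamma functions), using plain Python loops and
``math.lgamma`` — fully independent of the package's sampler path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from biomenet.core import Compound, Reaction, ReactionCatalog, SampleDataset


class TinyProblem:
    """Explicit token-level description of a small inference problem.

    ``tokens[n]`` is a list of (substrate slot compounds, product slot
    compounds) per token of sample ``n`` — equal-length lists, one entry
    per substrate-product pair.
    """

    def __init__(self, tokens, C, K, L, a_th=0.01, a_ph=0.01, a_de=0.01, a_ga=0.01):
        self.tokens = tokens
        self.C, self.K, self.L = C, K, L
        self.a_th, self.a_ph, self.a_de, self.a_ga = a_th, a_ph, a_de, a_ga
        # flat views in sample-then-token order (the sampler's expansion order)
        self.token_sample = []
        self.sub = []
        self.prod = []
        for n, toks in enumerate(tokens):
            for subs, prods in toks:
                assert len(subs) == len(prods) >= 1
                self.token_sample.append(n)
                self.sub.append(list(subs))
                self.prod.append(list(prods))
        self.T = len(self.token_sample)
        self.N = len(tokens)

    def build(self):
        """Materialise as (catalog, dataset) with one reaction per distinct
        (substrate slots, product slots) combination."""
        compounds = [Compound(f"C{c}", c) for c in range(self.C)]
        key_to_idx: dict = {}
        reactions: list[Reaction] = []
        occurrences = []
        for toks in self.tokens:
            occ: list[tuple[int, int]] = []
            pos: dict[int, int] = {}
            for subs, prods in toks:
                key = (tuple(subs), tuple(prods))
                if key not in key_to_idx:
                    key_to_idx[key] = len(reactions)
                    reactions.append(
                        Reaction.from_pairs(f"R{len(reactions)}", tuple(zip(subs, prods)))
                    )
                r = key_to_idx[key]
                if r in pos:
                    occ[pos[r]] = (r, occ[pos[r]][1] + 1)
                else:
                    pos[r] = len(occ)
                    occ.append((r, 1))
            occurrences.append(occ)
        catalog = ReactionCatalog(compounds, reactions)
        dataset = SampleDataset([f"s{n}" for n in range(self.N)], occurrences, catalog)
        return catalog, dataset

    # -- oracle ------------------------------------------------------------

    def log_joint_config(self, z, y) -> float:
        """Collapsed log P(Z=z, Y=y, data | α) via gamma-function products."""
        lg = math.lgamma
        N, K, L, C = self.N, self.K, self.L, self.C
        c_nk = [[0] * K for _ in range(N)]
        c_kl = [[0] * L for _ in range(K)]
        d_lc = [[0] * C for _ in range(L)]
        g_lc = [[0] * C for _ in range(L)]
        for t in range(self.T):
            n, k, l = self.token_sample[t], z[t], y[t]
            c_nk[n][k] += 1
            c_kl[k][l] += 1
            for c in self.sub[t]:
                d_lc[l][c] += 1
            for c in self.prod[t]:
                g_lc[l][c] += 1
        lp = 0.0
        for n in range(N):
            i_n = sum(c_nk[n])
            lp += lg(K * self.a_th) - lg(i_n + K * self.a_th)
            for k in range(K):
                lp += lg(c_nk[n][k] + self.a_th) - lg(self.a_th)
        for k in range(K):
            c_k = sum(c_kl[k])
            lp += lg(L * self.a_ph) - lg(c_k + L * self.a_ph)
            for l in range(L):
                lp += lg(c_kl[k][l] + self.a_ph) - lg(self.a_ph)
        for counts, alpha in ((d_lc, self.a_de), (g_lc, self.a_ga)):
            for l in range(L):
                tot = sum(counts[l])
                lp += lg(C * alpha) - lg(tot + C * alpha)
                for c in range(C):
                    lp += lg(counts[l][c] + alpha) - lg(alpha)
        return lp

    def enumerate_posterior(self) -> dict[tuple[int, ...], float]:
        """Exact posterior over full label configurations by enumeration.

        A configuration is encoded as a tuple of per-token flat labels
        ``k * L + l``.
        """
        states = list(itertools.product(range(self.K * self.L), repeat=self.T))
        lps = np.empty(len(states))
        for i, flat in enumerate(states):
            z = [f // self.L for f in flat]
            y = [f % self.L for f in flat]
            lps[i] = self.log_joint_config(z, y)
        lps -= lps.max()
        w = np.exp(lps)
        w /= w.sum()
        return {flat: float(p) for flat, p in zip(states, w)}

    def brute_conditional(self, t: int, z, y) -> np.ndarray:
        """Exact K×L conditional for token ``t`` given all other labels,
        as a ratio of enumerated collapsed joints."""
        z = list(z)
        y = list(y)
        table = np.empty((self.K, self.L))
        for k in range(self.K):
            for l in range(self.L):
                z[t], y[t] = k, l
                table[k, l] = self.log_joint_config(z, y)
        table -= table.max()
        table = np.exp(table)
        return table / table.sum()


def encode_config(z, y, L: int) -> tuple[int, ...]:
    return tuple(int(zz) * L + int(yy) for zz, yy in zip(z, y))


def random_tiny_problem(rng: np.random.Generator, peaked: bool = False) -> TinyProblem:
    """A random small instance (N=2, K=L=2, C=4, ≤6 tokens, J≤2)."""
    alphas = (
        [0.01, 0.01, 0.01, 0.01]
        if peaked
        else list(rng.uniform(0.05, 1.0, size=4))
    )
    tokens = []
    for n in range(2):
        n_tok = int(rng.integers(1, 4))  # 1..3 tokens per sample
        toks = []
        for _ in range(n_tok):
            j = int(rng.integers(1, 3))  # 1..2 pairs
            subs = rng.integers(0, 4, size=j).tolist()
            prods = rng.integers(0, 4, size=j).tolist()
            toks.append((subs, prods))
        tokens.append(toks)
    return TinyProblem(tokens, C=4, K=2, L=2, a_th=alphas[0], a_ph=alphas[1],
                       a_de=alphas[2], a_ga=alphas[3])


def set_labels(state, z, y) -> None:
    """Force a state's labels (and count tables) to a given configuration."""
    for t in range(len(state.z)):
        state.remove_token(t)
        state.add_token(t, int(z[t]), int(y[t]))
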