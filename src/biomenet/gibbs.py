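"""Collapsed Gibbs sampler over per-token (metabosystem, subnetwork) labels.

The mixture weights θ (sample → metabosystem), φ (metabosystem →
subnetwork) and the subnetwork compound distributions δ, γ are integrated
out analytically; the sampler walks over the discrete joint labels (Z, Y)
of every token, drawing each token's pair of labels from its full
conditional given all other tokens.

A *token* is one occurrence of one reaction in one sample. It contributes
one count at the sample→metabosystem and metabosystem→subnetwork levels,
and — through its J substrate-product pairs — J substrate slots to δ and J
product slots to γ. The conditional for a token with labels (k, l) is
proportional to::

    (count_nk[n,k] + α_θ)
    · (count_kl[k,l] + α_φ) / (count_k[k] + L·α_φ)
    · Π_j (dcount_lc[l,c_j] + α_δ + a_j) / (dcount_l[l] + C·α_δ + j)     (substrate slots)
    · Π_j (gcount_lc[l,c'_j] + α_γ + a'_j) / (gcount_l[l] + C·α_γ + j)   (product slots)

where counts exclude the token itself and ``a_j`` counts earlier slots of
the same token holding the same compound (the ascending-factorial form of
the Dirichlet-multinomial joint predictive for J conditionally-iid draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from . import _kernels
from .core import ModelSpec, ReactionCatalog, SampleDataset, logger

__all__ = [
    "SamplerSchedule",
    "TokenData",
    "AssignmentState",
    "LabelDraw",
    "SamplerRun",
    "init_state",
    "conditional_table",
    "gibbs_sweep",
    "log_joint",
    "run_sampler",
]


@dataclass
class SamplerSchedule:
    """MCMC schedule: discard ``burn_in`` sweeps, then retain one draw every
    ``lag`` sweeps until ``n_retained`` draws are collected.

    The defaults (100 burn-in, 500 retained, lag 20) match the published
    analyses; total sweeps = burn_in + n_retained·lag.
    """

    burn_in: int = 100
    n_retained: int = 500
    lag: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 1 or self.n_retained < 1 or self.lag < 1:
            raise ValueError("burn_in, n_retained and lag must all be >= 1")

    @property
    def total_sweeps(self) -> int:
        return self.burn_in + self.n_retained * self.lag


class TokenData:
    """Flattened token arrays: one entry per reaction instance.

    Slot arrays are CSR-style: token ``t`` owns substrate slots
    ``sub_comp[sub_indptr[t]:sub_indptr[t+1]]`` (and the product analogue).
    ``sub_rep[j]`` counts earlier slots of the same token holding the same
    compound, precomputed for the ascending-factorial predictive.
    """

    def __init__(self, dataset: SampleDataset, catalog: ReactionCatalog):
        token_sample: list[int] = []
        token_reaction: list[int] = []
        for n, occ in enumerate(dataset.occurrences):
            for r, m in occ:
                token_sample.extend([n] * m)
                token_reaction.extend([r] * m)
        self.token_sample = np.array(token_sample, dtype=np.int32)
        self.token_reaction = np.array(token_reaction, dtype=np.int32)
        self.n_tokens = len(token_sample)
        self.n_samples = dataset.n_samples

        sub_slots = [catalog.reactions[r].substrate_slots for r in self.token_reaction]
        prod_slots = [catalog.reactions[r].product_slots for r in self.token_reaction]
        self.sub_indptr = np.zeros(self.n_tokens + 1, dtype=np.int64)
        self.prod_indptr = np.zeros(self.n_tokens + 1, dtype=np.int64)
        np.cumsum([len(s) for s in sub_slots], out=self.sub_indptr[1:])
        np.cumsum([len(s) for s in prod_slots], out=self.prod_indptr[1:])
        self.sub_comp = np.fromiter(
            (c for s in sub_slots for c in s), dtype=np.int32, count=self.sub_indptr[-1]
        )
        self.prod_comp = np.fromiter(
            (c for s in prod_slots for c in s), dtype=np.int32, count=self.prod_indptr[-1]
        )
        self.sub_rep = _within_token_repeats(self.sub_comp, self.sub_indptr)
        self.prod_rep = _within_token_repeats(self.prod_comp, self.prod_indptr)
        # slot → owning token, used when rebuilding δ/γ counts from labels
        self.sub_slot_token = np.repeat(
            np.arange(self.n_tokens, dtype=np.int64), np.diff(self.sub_indptr)
        )
        self.prod_slot_token = np.repeat(
            np.arange(self.n_tokens, dtype=np.int64), np.diff(self.prod_indptr)
        )


def _within_token_repeats(comp: np.ndarray, indptr: np.ndarray) -> np.ndarray:
    rep = np.zeros(len(comp), dtype=np.int32)
    for t in range(len(indptr) - 1):
        lo, hi = indptr[t], indptr[t + 1]
        seen: dict[int, int] = {}
        for j in range(lo, hi):
            c = int(comp[j])
            rep[j] = seen.get(c, 0)
            seen[c] = rep[j] + 1
    return rep


@dataclass
class AssignmentState:
    """Per-token labels plus the sufficient-statistic count tables."""

    z: np.ndarray  # (T,) metabosystem labels
    y: np.ndarray  # (T,) subnetwork labels
    count_nk: np.ndarray  # (N, K)
    count_kl: np.ndarray  # (K, L)
    count_k: np.ndarray  # (K,)
    dcount_lc: np.ndarray  # (L, C) substrate-slot counts
    dcount_l: np.ndarray  # (L,)
    gcount_lc: np.ndarray  # (L, C) product-slot counts
    gcount_l: np.ndarray  # (L,)
    tokens: TokenData
    rng: np.random.Generator

    def remove_token(self, t: int) -> None:
        """Remove token ``t``'s entire contribution from all count tables."""
        tk = self.tokens
        n, k, l = tk.token_sample[t], self.z[t], self.y[t]
        self.count_nk[n, k] -= 1
        self.count_kl[k, l] -= 1
        self.count_k[k] -= 1
        s = tk.sub_comp[tk.sub_indptr[t] : tk.sub_indptr[t + 1]]
        p = tk.prod_comp[tk.prod_indptr[t] : tk.prod_indptr[t + 1]]
        np.subtract.at(self.dcount_lc[l], s, 1)
        self.dcount_l[l] -= len(s)
        np.subtract.at(self.gcount_lc[l], p, 1)
        self.gcount_l[l] -= len(p)

    def add_token(self, t: int, k: int, l: int) -> None:
        """Assign token ``t`` to (k, l) and restore its counts."""
        tk = self.tokens
        n = tk.token_sample[t]
        self.z[t] = k
        self.y[t] = l
        self.count_nk[n, k] += 1
        self.count_kl[k, l] += 1
        self.count_k[k] += 1
        s = tk.sub_comp[tk.sub_indptr[t] : tk.sub_indptr[t + 1]]
        p = tk.prod_comp[tk.prod_indptr[t] : tk.prod_indptr[t + 1]]
        np.add.at(self.dcount_lc[l], s, 1)
        self.dcount_l[l] += len(s)
        np.add.at(self.gcount_lc[l], p, 1)
        self.gcount_l[l] += len(p)

    def check_invariants(self, dataset: SampleDataset) -> None:
        """Raise if any count-table conservation invariant is violated."""
        if not np.array_equal(self.count_nk.sum(axis=1), dataset.totals):
            raise AssertionError("count_nk rows do not sum to I_n")
        if not np.array_equal(self.count_kl.sum(axis=1), self.count_k):
            raise AssertionError("count_kl rows do not match count_k")
        if int(self.count_k.sum()) != self.tokens.n_tokens:
            raise AssertionError("total token count not conserved")
        if not np.array_equal(self.dcount_lc.sum(axis=1), self.dcount_l):
            raise AssertionError("dcount_lc rows do not match dcount_l")
        if not np.array_equal(self.gcount_lc.sum(axis=1), self.gcount_l):
            raise AssertionError("gcount_lc rows do not match gcount_l")
        if int(self.dcount_l.sum()) != len(self.tokens.sub_comp):
            raise AssertionError("substrate slot total not conserved")
        if int(self.gcount_l.sum()) != len(self.tokens.prod_comp):
            raise AssertionError("product slot total not conserved")
        if (
            self.count_nk.min() < 0
            or self.count_kl.min() < 0
            or self.dcount_lc.min() < 0
            or self.gcount_lc.min() < 0
        ):
            raise AssertionError("negative count in state")


def init_state(
    dataset: SampleDataset,
    catalog: ReactionCatalog,
    spec: ModelSpec,
    seed: int,
) -> AssignmentState:
    """Initialise with independent uniform-random labels for every token."""
    if dataset.n_samples == 0:
        raise ValueError("dataset has no samples")
    tokens = TokenData(dataset, catalog)
    rng = np.random.default_rng(seed)
    T = tokens.n_tokens
    K, L, C = spec.K, spec.L, catalog.n_compounds
    z = rng.integers(0, K, size=T).astype(np.int32)
    y = rng.integers(0, L, size=T).astype(np.int32)

    count_nk = np.zeros((dataset.n_samples, K), dtype=np.int64)
    np.add.at(count_nk, (tokens.token_sample, z), 1)
    count_kl = np.zeros((K, L), dtype=np.int64)
    np.add.at(count_kl, (z, y), 1)
    count_k = count_kl.sum(axis=1)
    dcount_lc = np.zeros((L, C), dtype=np.int64)
    np.add.at(dcount_lc, (y[tokens.sub_slot_token], tokens.sub_comp), 1)
    gcount_lc = np.zeros((L, C), dtype=np.int64)
    np.add.at(gcount_lc, (y[tokens.prod_slot_token], tokens.prod_comp), 1)
    return AssignmentState(
        z=z,
        y=y,
        count_nk=count_nk,
        count_kl=count_kl,
        count_k=count_k,
        dcount_lc=dcount_lc,
        dcount_l=dcount_lc.sum(axis=1),
        gcount_lc=gcount_lc,
        gcount_l=gcount_lc.sum(axis=1),
        tokens=tokens,
        rng=rng,
    )


def conditional_table(
    t: int,
    state: AssignmentState,
    spec: ModelSpec,
    force_log: bool | None = None,
) -> np.ndarray:
    """Full-conditional K×L probability table for token ``t``.

    Precondition: the token's contribution has already been removed from
    all count tables (``state.remove_token(t)``). This reference
    implementation mirrors the compiled kernel; ``force_log`` overrides the
    automatic choice between the direct-product and log-space paths.
    """
    tk = state.tokens
    n = tk.token_sample[t]
    K, L = spec.K, spec.L
    C = state.dcount_lc.shape[1]
    s = tk.sub_comp[tk.sub_indptr[t] : tk.sub_indptr[t + 1]]
    s_rep = tk.sub_rep[tk.sub_indptr[t] : tk.sub_indptr[t + 1]]
    p = tk.prod_comp[tk.prod_indptr[t] : tk.prod_indptr[t + 1]]
    p_rep = tk.prod_rep[tk.prod_indptr[t] : tk.prod_indptr[t + 1]]
    if np.min(state.count_nk) < 0 or np.min(state.dcount_lc) < 0 or np.min(state.gcount_lc) < 0:
        raise ValueError("negative count encountered: state is corrupt")
    use_log = len(s) > _kernels.LOG_SLOT_THRESHOLD if force_log is None else force_log

    j_s = np.arange(len(s))
    j_p = np.arange(len(p))
    # (L, J) predictive factors for each slot under each subnetwork
    d_num = state.dcount_lc[:, s] + spec.alpha_delta + s_rep
    d_den = state.dcount_l[:, None] + C * spec.alpha_delta + j_s
    g_num = state.gcount_lc[:, p] + spec.alpha_gamma + p_rep
    g_den = state.gcount_l[:, None] + C * spec.alpha_gamma + j_p
    theta_f = state.count_nk[n] + spec.alpha_theta  # (K,)
    phi_f = (state.count_kl + spec.alpha_phi) / (
        state.count_k[:, None] + L * spec.alpha_phi
    )  # (K, L)
    if use_log:
        log_f = np.sum(np.log(d_num) - np.log(d_den), axis=1) + np.sum(
            np.log(g_num) - np.log(g_den), axis=1
        )
        log_w = np.log(theta_f)[:, None] + np.log(phi_f) + log_f[None, :]
        log_w -= log_w.max()
        w = np.exp(log_w)
    else:
        f = np.prod(d_num / d_den, axis=1) * np.prod(g_num / g_den, axis=1)
        w = theta_f[:, None] * phi_f * f[None, :]
    return w / w.sum()


def gibbs_sweep(
    state: AssignmentState,
    dataset: SampleDataset,
    catalog: ReactionCatalog,
    spec: ModelSpec,
    order: np.ndarray | None = None,
) -> AssignmentState:
    """One full sweep: every token is re-sampled exactly once.

    The default visit order is sample index then token index (the order
    tokens were expanded in). Each token consumes one uniform variate from
    the state's generator.
    """
    tk = state.tokens
    if order is None:
        order = np.arange(tk.n_tokens, dtype=np.int64)
    else:
        order = np.asarray(order, dtype=np.int64)
    uniforms = state.rng.random(len(order))
    _kernels.sweep_kernel(
        order,
        uniforms,
        state.z,
        state.y,
        tk.token_sample,
        tk.sub_indptr,
        tk.sub_comp,
        tk.sub_rep,
        tk.prod_indptr,
        tk.prod_comp,
        tk.prod_rep,
        state.count_nk,
        state.count_kl,
        state.count_k,
        state.dcount_lc,
        state.dcount_l,
        state.gcount_lc,
        state.gcount_l,
        spec.alpha_theta,
        spec.alpha_phi,
        spec.alpha_delta,
        spec.alpha_gamma,
    )
    return state


def log_joint(state: AssignmentState, spec: ModelSpec) -> float:
    """Log of the collapsed joint probability P(Z, Y, data | α), up to the
    data-dependent constants that do not involve the labels."""
    a_th, a_ph = spec.alpha_theta, spec.alpha_phi
    a_de, a_ga = spec.alpha_delta, spec.alpha_gamma
    N, K = state.count_nk.shape
    L, C = state.dcount_lc.shape
    i_n = state.count_nk.sum(axis=1)
    lp = float(
        N * gammaln(K * a_th)
        - gammaln(i_n + K * a_th).sum()
        + gammaln(state.count_nk + a_th).sum()
        - N * K * gammaln(a_th)
    )
    lp += float(
        K * gammaln(L * a_ph)
        - gammaln(state.count_k + L * a_ph).sum()
        + gammaln(state.count_kl + a_ph).sum()
        - K * L * gammaln(a_ph)
    )
    lp += float(
        L * gammaln(C * a_de)
        - gammaln(state.dcount_l + C * a_de).sum()
        + gammaln(state.dcount_lc + a_de).sum()
        - L * C * gammaln(a_de)
    )
    lp += float(
        L * gammaln(C * a_ga)
        - gammaln(state.gcount_l + C * a_ga).sum()
        + gammaln(state.gcount_lc + a_ga).sum()
        - L * C * gammaln(a_ga)
    )
    return lp


@dataclass
class LabelDraw:
    """Labels of one retained draw."""

    z: np.ndarray
    y: np.ndarray


@dataclass
class SamplerRun:
    """Retained draws plus per-draw mixture-weight estimates."""

    draws: list[LabelDraw]
    theta_draws: np.ndarray  # (D, N, K)
    phi_draws: np.ndarray  # (D, K, L)
    log_joint: np.ndarray  # (D,)
    spec: ModelSpec
    schedule: SamplerSchedule
    tokens: TokenData
    final_state: AssignmentState


def _theta_phi_from_counts(state: AssignmentState, dataset: SampleDataset):
    theta = state.count_nk / dataset.totals[:, None]
    count_k = state.count_k.astype(float)
    L = state.count_kl.shape[1]
    phi = np.empty_like(state.count_kl, dtype=float)
    for k in range(state.count_kl.shape[0]):
        if count_k[k] == 0:
            phi[k] = 1.0 / L
        else:
            phi[k] = state.count_kl[k] / count_k[k]
    return theta, phi


def run_sampler(
    dataset: SampleDataset,
    catalog: ReactionCatalog,
    spec: ModelSpec,
    schedule: SamplerSchedule,
    log_every: int = 0,
) -> SamplerRun:
    """Burn in, then retain ``n_retained`` label draws at the given lag.

    Per-draw θ and φ estimates (assignment relative frequencies) are
    recorded alongside the labels, as is the collapsed log joint.
    """
    state = init_state(dataset, catalog, spec, schedule.seed)
    sweep_no = 0

    def _log(msg_state):
        if log_every and sweep_no % log_every == 0:
            logger.info(
                "sweep %d / %d, log joint %.3f",
                sweep_no,
                schedule.total_sweeps,
                log_joint(msg_state, spec),
            )

    for _ in range(schedule.burn_in):
        gibbs_sweep(state, dataset, catalog, spec)
        sweep_no += 1
        _log(state)

    draws: list[LabelDraw] = []
    D = schedule.n_retained
    N, K, L = dataset.n_samples, spec.K, spec.L
    theta_draws = np.empty((D, N, K))
    phi_draws = np.empty((D, K, L))
    lp = np.empty(D)
    for d in range(D):
        for _ in range(schedule.lag):
            gibbs_sweep(state, dataset, catalog, spec)
            sweep_no += 1
            _log(state)
        draws.append(LabelDraw(state.z.copy(), state.y.copy()))
        theta_draws[d], phi_draws[d] = _theta_phi_from_counts(state, dataset)
        lp[d] = log_joint(state, spec)

    return SamplerRun(
        draws=draws,
        theta_draws=theta_draws,
        phi_draws=phi_draws,
        log_joint=lp,
        spec=spec,
        schedule=schedule,
        tokens=state.tokens,
        final_state=state,
    )
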