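"""Posterior estimates of mixture weights and subnetwork profiles.

θ and φ are estimated per retained draw as plain assignment relative
frequencies and averaged across draws. The compound distributions δ, γ and
the per-subnetwork reaction profile are estimated as prior-smoothed
frequencies, so that unseen compounds/reactions keep a small positive mass
and downstream divergence computations are defined on full support.

Averaging across draws assumes labels do not switch within the chain;
sparse symmetric priors keep modes well separated in practice, and a
diagnostic counts the consecutive-draw φ permutation mismatches so that
switching, if it happens, is at least visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ModelSpec, ReactionCatalog, SampleDataset, logger
from .gibbs import LabelDraw, SamplerRun, TokenData

__all__ = [
    "PosteriorSummary",
    "theta_from_draw",
    "phi_from_draw",
    "summarize",
    "label_switch_events",
]


@dataclass
class PosteriorSummary:
    """Posterior-mean mixture weights and subnetwork profiles."""

    theta_mean: np.ndarray  # (N, K)
    phi_mean: np.ndarray  # (K, L)
    delta_mean: np.ndarray  # (L, C)
    gamma_mean: np.ndarray  # (L, C)
    subnetwork_reaction_profile: np.ndarray  # (L, R)
    theta_draws: np.ndarray  # (D, N, K)
    phi_draws: np.ndarray  # (D, K, L)
    sample_ids: list[str]
    reaction_ids: list[str]
    compound_ids: list[str]
    n_draws: int


def theta_from_draw(draw: LabelDraw, dataset: SampleDataset, K: int) -> np.ndarray:
    """Per-sample metabosystem frequencies: row n = count_nk[n,·] / I_n."""
    count_nk = np.zeros((dataset.n_samples, K), dtype=np.int64)
    pos = 0
    for n, occ in enumerate(dataset.occurrences):
        i_n = int(dataset.totals[n])
        np.add.at(count_nk[n], draw.z[pos : pos + i_n], 1)
        pos += i_n
    return count_nk / dataset.totals[:, None]


def phi_from_draw(draw: LabelDraw, K: int, L: int) -> np.ndarray:
    """Per-metabosystem subnetwork frequencies, pooled across samples.

    An empty metabosystem (no tokens assigned) yields a uniform row and a
    logged warning.
    """
    count_kl = np.zeros((K, L), dtype=np.int64)
    np.add.at(count_kl, (draw.z, draw.y), 1)
    count_k = count_kl.sum(axis=1)
    phi = np.empty((K, L), dtype=float)
    for k in range(K):
        if count_k[k] == 0:
            logger.warning("metabosystem %d has no assigned tokens; uniform phi row", k)
            phi[k] = 1.0 / L
        else:
            phi[k] = count_kl[k] / count_k[k]
    return phi


def _compound_counts(draw: LabelDraw, tokens: TokenData, L: int, C: int):
    dcount = np.zeros((L, C), dtype=np.int64)
    np.add.at(dcount, (draw.y[tokens.sub_slot_token], tokens.sub_comp), 1)
    gcount = np.zeros((L, C), dtype=np.int64)
    np.add.at(gcount, (draw.y[tokens.prod_slot_token], tokens.prod_comp), 1)
    return dcount, gcount


def summarize(
    run: SamplerRun,
    dataset: SampleDataset,
    catalog: ReactionCatalog,
    spec: ModelSpec,
    alpha_reaction: float | None = None,
) -> PosteriorSummary:
    """Average per-draw estimates into a :class:`PosteriorSummary`.

    ``alpha_reaction`` is the smoothing concentration for the reaction
    profile (defaults to ``spec.alpha_delta``).
    """
    if not run.draws:
        raise ValueError("need at least one retained draw")
    a_r = spec.alpha_delta if alpha_reaction is None else alpha_reaction
    K, L = spec.K, spec.L
    C = catalog.n_compounds
    R = catalog.n_reactions
    tokens = run.tokens

    theta_mean = run.theta_draws.mean(axis=0)
    phi_mean = run.phi_draws.mean(axis=0)

    delta_mean = np.zeros((L, C))
    gamma_mean = np.zeros((L, C))
    profile = np.zeros((L, R))
    for draw in run.draws:
        dcount, gcount = _compound_counts(draw, tokens, L, C)
        delta_mean += (dcount + spec.alpha_delta) / (
            dcount.sum(axis=1, keepdims=True) + C * spec.alpha_delta
        )
        gamma_mean += (gcount + spec.alpha_gamma) / (
            gcount.sum(axis=1, keepdims=True) + C * spec.alpha_gamma
        )
        count_lr = np.zeros((L, R), dtype=np.int64)
        np.add.at(count_lr, (draw.y, tokens.token_reaction), 1)
        profile += (count_lr + a_r) / (count_lr.sum(axis=1, keepdims=True) + R * a_r)
    D = len(run.draws)
    delta_mean /= D
    gamma_mean /= D
    profile /= D

    switches = label_switch_events(run.phi_draws)
    if switches:
        logger.warning(
            "phi label-switching diagnostic: %d of %d consecutive draw pairs "
            "best-match with a non-identity metabosystem permutation",
            switches,
            D - 1,
        )

    return PosteriorSummary(
        theta_mean=theta_mean,
        phi_mean=phi_mean,
        delta_mean=delta_mean,
        gamma_mean=gamma_mean,
        subnetwork_reaction_profile=profile,
        theta_draws=run.theta_draws,
        phi_draws=run.phi_draws,
        sample_ids=list(dataset.sample_ids),
        reaction_ids=catalog.reaction_ids,
        compound_ids=catalog.compound_ids,
        n_draws=D,
    )


def label_switch_events(phi_draws: np.ndarray) -> int:
    """Count consecutive draw pairs whose best φ-row matching is not the
    identity permutation (a within-chain label-switching indicator)."""
    D = phi_draws.shape[0]
    events = 0
    for d in range(1, D):
        cost = np.abs(phi_draws[d - 1][:, None, :] - phi_draws[d][None, :, :]).sum(axis=2)
        _, cols = linear_sum_assignment(cost)
        if not np.array_equal(cols, np.arange(cost.shape[0])):
            events += 1
    return events
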