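"""Downstream summaries: reaction compositions, divergence matrices,
component matching, and principal / discriminatory / core subnetworks.

A metabosystem's *reaction composition* is its φ-weighted mixture of
subnetwork reaction profiles; compositions are compared with the
Jensen-Shannon divergence (base-2 by default, so 1 is the maximum),
assembled into block divergence matrices across runs, and coordinated
across runs or L values by optimal assignment on composition divergence.

Subnetwork categories (defaults are this package's reconstruction and are
configurable):

* *principal* for metabosystem k: φ_kl strictly greater than 2/L;
* *discriminatory* for k: principal for some metabosystem, and the
  membership score |log(φ_kl / max_{k'≠k} φ_k'l)| is at least a threshold
  (default ln 2, i.e. ≥ 2-fold enrichment);
* *core*: membership > 2/L in every metabosystem and discriminatory for
  none.

*Principal reactions* of a subnetwork are those with profile mass at least
2/R, R the number of distinct reactions in the dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import rel_entr

from .core import ReactionCatalog
from .summaries import PosteriorSummary

__all__ = [
    "MetabosystemProfile",
    "SubnetworkReport",
    "reaction_composition",
    "jsd",
    "divergence_matrix",
    "match_components",
    "principal_subnetworks",
    "membership_score",
    "discriminatory_subnetworks",
    "core_subnetworks",
    "principal_reactions",
    "subnetwork_report",
    "subnetwork_graph",
]

DEFAULT_SCORE_THRESHOLD = math.log(2.0)


@dataclass
class MetabosystemProfile:
    """Distribution over catalog reactions for each metabosystem."""

    composition: np.ndarray  # (K, R)
    reaction_ids: list[str]
    tag: str = ""


def reaction_composition(summary: PosteriorSummary, tag: str = "") -> MetabosystemProfile:
    """Row k = Σ_l φ_mean[k,l] · profile[l,·] — the metabosystem's mixture
    of its subnetworks' reaction distributions."""
    comp = summary.phi_mean @ summary.subnetwork_reaction_profile
    return MetabosystemProfile(comp, list(summary.reaction_ids), tag=tag)


def jsd(p, q, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two distributions.

    ½KL(p‖m) + ½KL(q‖m) with m = ½(p+q), using the 0·log(0/x) = 0
    convention; base-2 by default so disjoint supports give 1.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-D of equal length")
    for v, name in ((p, "p"), (q, "q")):
        if v.min() < -1e-12 or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a probability vector")
    m = 0.5 * (p + q)
    div = 0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum()
    return float(div / math.log(base))


def divergence_matrix(
    profiles: list[MetabosystemProfile], base: float = 2.0
) -> pd.DataFrame:
    """Pairwise JSD over all (run tag, metabosystem) composition rows.

    Rows/columns are labelled ``tag:mK`` so within- vs between-metabosystem
    blocks can be assembled into the usual heat-map layout.
    """
    ref_ids = profiles[0].reaction_ids
    for prof in profiles:
        if prof.reaction_ids != ref_ids:
            raise ValueError("all profiles must share one reaction catalog")
    rows = []
    labels = []
    for prof in profiles:
        for k in range(prof.composition.shape[0]):
            rows.append(prof.composition[k])
            labels.append(f"{prof.tag or 'run'}:m{k}")
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jsd(rows[i], rows[j], base=base)
    return pd.DataFrame(mat, index=labels, columns=labels)


def match_components(reference: np.ndarray, other: np.ndarray, metric: str = "jsd") -> np.ndarray:
    """Optimal component relabelling of ``other`` against ``reference``.

    Both are (K, d) row-stochastic arrays (mixture rows or compositions).
    Returns ``perm`` with ``other[perm[i]]`` matched to ``reference[i]``,
    minimising total pairwise JSD (or L1) over all permutations via the
    assignment problem.
    """
    reference = np.asarray(reference, dtype=float)
    other = np.asarray(other, dtype=float)
    if reference.shape != other.shape:
        raise ValueError("component counts (and dimensions) must match")
    k = reference.shape[0]
    cost = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if metric == "jsd":
                cost[i, j] = jsd(reference[i], other[j])
            elif metric == "l1":
                cost[i, j] = np.abs(reference[i] - other[j]).sum()
            else:
                raise ValueError(f"unknown metric {metric!r}")
    _, cols = linear_sum_assignment(cost)
    return cols


def principal_subnetworks(phi_mean: np.ndarray) -> tuple[list[list[int]], list[int]]:
    """Subnetworks with membership strictly above 2/L per metabosystem.

    Returns (per-metabosystem lists, sorted union).
    """
    phi_mean = np.asarray(phi_mean, dtype=float)
    K, L = phi_mean.shape
    threshold = 2.0 / L
    per_k = [sorted(np.nonzero(phi_mean[k] > threshold)[0].tolist()) for k in range(K)]
    union = sorted(set(itertools.chain.from_iterable(per_k)))
    return per_k, union


def membership_score(
    phi_mean: np.ndarray, k: int, l: int, eps: float = 1e-12
) -> float:
    """|log(φ_kl / max_{k'≠k} φ_k'l)| — enrichment of subnetwork l in
    metabosystem k relative to its strongest other metabosystem.

    Natural log; entries floored at ``eps`` before the ratio.
    """
    phi_mean = np.asarray(phi_mean, dtype=float)
    K = phi_mean.shape[0]
    if K < 2:
        raise ValueError("membership score needs at least 2 metabosystems")
    own = max(phi_mean[k, l], eps)
    others = np.delete(phi_mean[:, l], k)
    best_other = max(others.max(), eps)
    return abs(math.log(own / best_other))


def discriminatory_subnetworks(
    phi_mean: np.ndarray, score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> np.ndarray:
    """Boolean (K, L) flags: principal somewhere AND enriched in k at the
    score threshold. A subnetwork flagged for k distinguishes k from all
    other metabosystems."""
    phi_mean = np.asarray(phi_mean, dtype=float)
    K, L = phi_mean.shape
    _, union = principal_subnetworks(phi_mean)
    principal_any = np.zeros(L, dtype=bool)
    principal_any[union] = True
    flags = np.zeros((K, L), dtype=bool)
    for k in range(K):
        for l in range(L):
            if not principal_any[l]:
                continue
            # enrichment must be in k's favour, not merely large in magnitude
            others = np.delete(phi_mean[:, l], k)
            if phi_mean[k, l] <= others.max():
                continue
            if membership_score(phi_mean, k, l) >= score_threshold:
                flags[k, l] = True
    return flags


def core_subnetworks(
    phi_mean: np.ndarray, score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> list[int]:
    """Subnetworks abundant (> 2/L) in *every* metabosystem and
    discriminatory for none."""
    phi_mean = np.asarray(phi_mean, dtype=float)
    K, L = phi_mean.shape
    threshold = 2.0 / L
    disc = discriminatory_subnetworks(phi_mean, score_threshold)
    return [
        l
        for l in range(L)
        if bool((phi_mean[:, l] > threshold).all()) and not disc[:, l].any()
    ]


def principal_reactions(
    profile: np.ndarray, r_unique: int
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Per-subnetwork reactions with profile mass ≥ 2/R_unique.

    Returns, for each subnetwork, (reaction indices sorted by descending
    probability, their probabilities, cumulative retained probability).
    """
    profile = np.asarray(profile, dtype=float)
    if r_unique < 1:
        raise ValueError("r_unique must be >= 1")
    threshold = 2.0 / r_unique
    out = []
    for row in profile:
        keep = np.nonzero(row >= threshold)[0]
        order = keep[np.argsort(-row[keep], kind="stable")]
        out.append((order, row[order], float(row[order].sum())))
    return out


@dataclass
class SubnetworkReport:
    """Per-subnetwork membership, category flags and principal reactions."""

    table: pd.DataFrame  # one row per (metabosystem, subnetwork)
    core: list[int]
    principal_union: list[int]
    principal_reaction_lists: list[tuple[np.ndarray, np.ndarray, float]]


def subnetwork_report(
    summary: PosteriorSummary,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> SubnetworkReport:
    """Assemble the per-(metabosystem, subnetwork) category table."""
    phi = summary.phi_mean
    K, L = phi.shape
    per_k, union = principal_subnetworks(phi)
    disc = discriminatory_subnetworks(phi, score_threshold)
    core = core_subnetworks(phi, score_threshold)
    rows = []
    for k in range(K):
        for l in range(L):
            rows.append(
                {
                    "metabosystem": k,
                    "subnetwork": l,
                    "membership": phi[k, l],
                    "principal": l in per_k[k],
                    "score": membership_score(phi, k, l) if K > 1 else 0.0,
                    "discriminatory": bool(disc[k, l]),
                    "core": l in core,
                }
            )
    pr = principal_reactions(
        summary.subnetwork_reaction_profile, len(summary.reaction_ids)
    )
    return SubnetworkReport(
        table=pd.DataFrame(rows),
        core=core,
        principal_union=union,
        principal_reaction_lists=pr,
    )


def subnetwork_graph(
    catalog: ReactionCatalog,
    reaction_indices,
    currency_compounds: set[str] | None = None,
):
    """Bipartite reaction-compound graph of one subnetwork's reactions.

    Reaction nodes carry ``kind='reaction'`` (drawn as squares), compound
    nodes ``kind='compound'`` (circles); edges touching a currency compound
    are flagged ``currency=True`` (dashed in the published figures).
    Requires networkx (imported lazily).
    """
    import networkx as nx

    currency = currency_compounds or set()
    g = nx.DiGraph()
    for r_idx in reaction_indices:
        r = catalog.reactions[int(r_idx)]
        g.add_node(r.reaction_id, kind="reaction")
        for s in r.substrates:
            cid = catalog.compounds[s].compound_id
            g.add_node(cid, kind="compound")
            g.add_edge(cid, r.reaction_id, currency=cid in currency)
        for p in r.products:
            cid = catalog.compounds[p].compound_id
            g.add_node(cid, kind="compound")
            g.add_edge(r.reaction_id, cid, currency=cid in currency)
    return g
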