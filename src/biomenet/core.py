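"""Domain types and file I/O for reaction catalogs and sample abundance tables.

The central objects are:

* :class:`ReactionCatalog` — the universe of compounds and reactions. Each
  reaction is a hyper-edge connecting a substrate compound set to a product
  compound set; for modelling it is decomposed into directed
  substrate→product *pairs*.
* :class:`SampleDataset` — per-sample reaction occurrences with integer
  multiplicities (abundances). One occurrence of one reaction in one sample
  is a *token*, the unit that receives latent labels during inference.
* :class:`ModelSpec` — the model dimensions (K metabosystems, L subnetworks)
  and the four symmetric-Dirichlet concentration parameters.

All file formats are plain TSV with opaque string identifiers; dense
0-based integer indexing is an internal convention that never leaks into
files.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("biomenet")

__all__ = [
    "BiomenetError",
    "FormatError",
    "ReferenceError_",
    "Compound",
    "Reaction",
    "ReactionCatalog",
    "SampleDataset",
    "ModelSpec",
    "read_catalog",
    "write_catalog",
    "read_abundances",
    "write_abundances",
    "write_matrix",
    "read_matrix",
]


class BiomenetError(Exception):
    """Base class for package errors."""


class FormatError(BiomenetError):
    """Malformed input file (bad column count, bad value, duplicate ID)."""


class ReferenceError_(BiomenetError):
    """An identifier refers to an entity that does not exist."""


@dataclass(frozen=True)
class Compound:
    """A chemical compound with an opaque ID and a dense integer index."""

    compound_id: str
    index: int


@dataclass(frozen=True)
class Reaction:
    """A reaction hyper-edge decomposed into substrate→product pairs.

    ``substrates`` and ``products`` are sorted tuples of unique compound
    indices. ``pairs`` is the list of directed (substrate, product) pairs a
    token of this reaction contributes to the model; for catalog-file
    reactions it is the full Cartesian product ``substrates × products``
    (reversed pairs appended when the reaction is reversible), while the
    synthetic generator may register reactions with an explicit pair list
    preserving the multiplicity of its compound draws.
    """

    reaction_id: str
    substrates: tuple[int, ...]
    products: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]

    @classmethod
    def from_sets(
        cls,
        reaction_id: str,
        substrates: set[int] | tuple[int, ...],
        products: set[int] | tuple[int, ...],
        reversible: bool = False,
    ) -> "Reaction":
        subs = tuple(sorted(set(substrates)))
        prods = tuple(sorted(set(products)))
        if not subs or not prods:
            raise FormatError(
                f"reaction {reaction_id!r}: substrate and product sets must be non-empty"
            )
        pairs = tuple(itertools.product(subs, prods))
        if reversible:
            pairs = pairs + tuple((p, s) for s, p in pairs)
        return cls(reaction_id, subs, prods, pairs)

    @classmethod
    def from_pairs(
        cls, reaction_id: str, pairs: tuple[tuple[int, int], ...]
    ) -> "Reaction":
        if not pairs:
            raise FormatError(f"reaction {reaction_id!r}: empty pair list")
        subs = tuple(sorted({s for s, _ in pairs}))
        prods = tuple(sorted({p for _, p in pairs}))
        return cls(reaction_id, subs, prods, tuple(pairs))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def substrate_slots(self) -> tuple[int, ...]:
        """Compound index of each substrate slot (one per pair, in order)."""
        return tuple(s for s, _ in self.pairs)

    @property
    def product_slots(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.pairs)


class ReactionCatalog:
    """Indexed collection of compounds and reactions."""

    def __init__(self, compounds: list[Compound], reactions: list[Reaction]):
        self.compounds = compounds
        self.reactions = reactions
        self.compound_index: dict[str, int] = {
            c.compound_id: c.index for c in compounds
        }
        self.reaction_index: dict[str, int] = {
            r.reaction_id: i for i, r in enumerate(reactions)
        }
        if len(self.reaction_index) != len(reactions):
            raise FormatError("duplicate reaction IDs in catalog")
        for i, c in enumerate(compounds):
            if c.index != i:
                raise FormatError("compound indices must be dense and ordered")
        n = len(compounds)
        for r in reactions:
            for idx in itertools.chain(r.substrates, r.products):
                if not (0 <= idx < n):
                    raise ReferenceError_(
                        f"reaction {r.reaction_id!r} references compound index {idx} "
                        f"outside [0, {n})"
                    )

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def compound_ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]


class SampleDataset:
    """Per-sample reaction tokens with abundance multiplicities.

    ``occurrences[n]`` is a list of ``(reaction_index, multiplicity)`` in
    first-appearance order; ``totals[n]`` (the model's I_n) is the token
    count of sample ``n``.
    """

    def __init__(
        self,
        sample_ids: list[str],
        occurrences: list[list[tuple[int, int]]],
        catalog: ReactionCatalog,
    ):
        if len(sample_ids) != len(occurrences):
            raise ValueError("sample_ids and occurrences length mismatch")
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample IDs")
        self.sample_ids = sample_ids
        self.occurrences = occurrences
        r_max = catalog.n_reactions
        for n, occ in enumerate(occurrences):
            if not occ:
                raise FormatError(f"sample {sample_ids[n]!r} has no tokens (I_n >= 1 required)")
            for r, m in occ:
                if m < 1:
                    raise FormatError(
                        f"sample {sample_ids[n]!r}: multiplicity {m} < 1"
                    )
                if not (0 <= r < r_max):
                    raise ReferenceError_(
                        f"sample {sample_ids[n]!r}: reaction index {r} not in catalog"
                    )
        self.totals = np.array([sum(m for _, m in occ) for occ in occurrences], dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_tokens(self) -> int:
        return int(self.totals.sum())


@dataclass
class ModelSpec:
    """Model dimensions and symmetric-Dirichlet concentrations.

    The default concentration 0.01 for all four levels encourages each
    sample to use few metabosystems, each metabosystem to use few
    subnetworks, and each subnetwork to involve few compounds.
    """

    K: int
    L: int
    alpha_theta: float = 0.01
    alpha_phi: float = 0.01
    alpha_delta: float = 0.01
    alpha_gamma: float = 0.01

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        for name in ("alpha_theta", "alpha_phi", "alpha_delta", "alpha_gamma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _data_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_catalog(path, exclude_compounds: set[str] | None = None) -> ReactionCatalog:
    """Read a reaction catalog from a TSV file.

    Columns: ``reaction_id``, comma-joined substrate compound IDs,
    comma-joined product compound IDs, and an optional ``reversible`` flag
    (0/1). Compound indices are assigned in first-appearance order
    (substrates before products, within each line).

    ``exclude_compounds`` removes currency-like compounds before pair
    decomposition; reactions left without substrates or products are
    dropped with a warning.
    """
    exclude = exclude_compounds or set()
    compounds: list[Compound] = []
    comp_idx: dict[str, int] = {}
    reactions: list[Reaction] = []
    seen_rids: set[str] = set()

    def intern(cid: str) -> int:
        if cid not in comp_idx:
            comp_idx[cid] = len(compounds)
            compounds.append(Compound(cid, len(compounds)))
        return comp_idx[cid]

    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) not in (3, 4):
            raise FormatError(f"{path}:{lineno}: expected 3 or 4 tab-separated columns")
        rid = parts[0].strip()
        if not rid:
            raise FormatError(f"{path}:{lineno}: empty reaction_id")
        if rid in seen_rids:
            raise FormatError(f"{path}:{lineno}: duplicate reaction_id {rid!r}")
        seen_rids.add(rid)
        sub_ids = [c.strip() for c in parts[1].split(",") if c.strip()]
        prod_ids = [c.strip() for c in parts[2].split(",") if c.strip()]
        if not sub_ids or not prod_ids:
            raise FormatError(f"{path}:{lineno}: empty substrate or product list")
        reversible = False
        if len(parts) == 4:
            flag = parts[3].strip()
            if flag not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: reversible flag must be 0 or 1")
            reversible = flag == "1"
        sub_ids = [c for c in sub_ids if c not in exclude]
        prod_ids = [c for c in prod_ids if c not in exclude]
        if not sub_ids or not prod_ids:
            logger.warning(
                "reaction %s dropped: empty substrate or product set after "
                "currency-compound exclusion",
                rid,
            )
            continue
        subs = {intern(c) for c in sub_ids}
        prods = {intern(c) for c in prod_ids}
        reactions.append(Reaction.from_sets(rid, subs, prods, reversible=reversible))

    return ReactionCatalog(compounds, reactions)


def write_catalog(catalog: ReactionCatalog, path) -> None:
    ids = catalog.compound_ids
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# reaction_id\tsubstrates\tproducts\n")
        for r in catalog.reactions:
            subs = ",".join(ids[i] for i in r.substrates)
            prods = ",".join(ids[i] for i in r.products)
            fh.write(f"{r.reaction_id}\t{subs}\t{prods}\n")


def read_abundances(path, catalog: ReactionCatalog) -> SampleDataset:
    """Read a per-sample reaction-abundance TSV (sample_id, reaction_id, count).

    Duplicate (sample, reaction) rows are summed. Counts must be positive
    integers. Sample order follows first appearance.
    """
    sample_ids: list[str] = []
    sample_pos: dict[str, int] = {}
    acc: list[dict[int, int]] = []

    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
        sid, rid, count_s = (p.strip() for p in parts)
        if rid not in catalog.reaction_index:
            raise ReferenceError_(
                f"{path}:{lineno}: reaction {rid!r} not present in catalog"
            )
        try:
            count = int(count_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: count {count_s!r} is not an integer") from None
        if count <= 0:
            raise FormatError(f"{path}:{lineno}: count must be positive, got {count}")
        if sid not in sample_pos:
            sample_pos[sid] = len(sample_ids)
            sample_ids.append(sid)
            acc.append({})
        r = catalog.reaction_index[rid]
        bucket = acc[sample_pos[sid]]
        bucket[r] = bucket.get(r, 0) + count

    occurrences = [list(bucket.items()) for bucket in acc]
    return SampleDataset(sample_ids, occurrences, catalog)


def write_abundances(dataset: SampleDataset, catalog: ReactionCatalog, path) -> None:
    rids = catalog.reaction_ids
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# sample_id\treaction_id\tcount\n")
        for sid, occ in zip(dataset.sample_ids, dataset.occurrences):
            for r, m in occ:
                fh.write(f"{sid}\t{rids[r]}\t{m}\n")


def write_matrix(matrix, row_labels, col_labels, path) -> None:
    """Write a labelled 2-D matrix as TSV with repr-roundtrip float precision."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    row_labels = list(row_labels)
    col_labels = list(col_labels)
    if matrix.shape != (len(row_labels), len(col_labels)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match labels "
            f"({len(row_labels)} rows, {len(col_labels)} cols)"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id"] + [str(c) for c in col_labels]) + "\n")
        for label, row in zip(row_labels, matrix):
            fh.write(str(label) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`.

    Returns ``(matrix, row_labels, col_labels)``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_labels = header[1:]
        row_labels = []
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(col_labels) + 1:
                raise FormatError(f"{path}: ragged row for label {parts[0]!r}")
            row_labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows, dtype=float), row_labels, col_labels
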