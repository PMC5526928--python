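"""Phylogenies and trait-evolution covariance structures.

This module owns the tree-shaped plumbing of the pipeline: reading a rooted
Newick phylogeny, reconciling it with a species-keyed trait table, and
building the expected between-species covariance (or correlation) matrices
implied by three trait-evolution models:

* **Brownian motion (BM)** — covariance between two species equals the shared
  path length from the root to their most recent common ancestor.
* **Pagel's lambda** — the BM covariance with every off-diagonal entry damped
  by a factor ``lambda`` in [0, 1]; ``lambda = 1`` recovers BM and
  ``lambda = 0`` removes all phylogenetic structure.
* **Ornstein–Uhlenbeck (OU)** — a stationary-OU *correlation* structure,
  ``corr(i, j) = exp(-alpha * d_ij)`` with ``d_ij`` the patristic (tip-to-tip
  path) distance; the overall variance is absorbed into the GLS scale
  ``sigma^2`` estimated downstream.

All matrices carry their tip order explicitly so downstream stages can align
trait vectors without positional guessing.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NewickError",
    "TreeTraitMismatchError",
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "bm_covariance",
    "lambda_transform",
    "patristic_distances",
    "ou_correlation",
    "align_tree_and_table",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be interpreted as a valid rooted tree."""


class TreeTraitMismatchError(ValueError):
    """Raised when a tree and a trait table cannot be reconciled."""


class Phylogeny:
    """A rooted phylogeny with branch lengths, wrapping a :class:`dendropy.Tree`.

    Invariants enforced at construction:

    * all branch lengths are finite and non-negative, and every non-root edge
      carries an explicit length;
    * tip labels are unique and non-empty;
    * every root-to-tip path has positive total length.

    Polytomies are permitted.  Internal node labels and bootstrap annotations
    are tolerated and ignored.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._depths = self._compute_depths()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def _validate(self) -> None:
        seen: set[str] = set()
        for leaf in self._tree.leaf_node_iter():
            label = None if leaf.taxon is None else leaf.taxon.label
            if not label:
                raise NewickError("tip with empty label")
            if label in seen:
                raise NewickError(f"duplicate tip label {label!r}")
            seen.add(label)
        if len(seen) < 2:
            raise NewickError("tree must have at least two tips")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            bl = node.edge.length
            if bl is None:
                raise NewickError(
                    f"missing branch length on edge above "
                    f"{_node_name(node)!r}"
                )
            if not math.isfinite(bl) or bl < 0:
                raise NewickError(
                    f"invalid branch length {bl!r} on edge above "
                    f"{_node_name(node)!r}"
                )

    def _compute_depths(self) -> dict:
        depths: dict = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                depths[node] = node.edge.length or 0.0
            else:
                depths[node] = depths[parent] + node.edge.length
        for leaf in self._tree.leaf_node_iter():
            if depths[leaf] <= 0:
                raise NewickError(
                    f"zero-length root-to-tip path to {leaf.taxon.label!r}"
                )
        return depths

    # -- basic queries ---------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in the left-to-right order of the Newick string."""
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in ``tip_labels`` order."""
        return np.array(
            [self._depths[leaf] for leaf in self._tree.leaf_node_iter()]
        )

    @property
    def max_depth(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, rel_tol: float = 0.01) -> bool:
        """True when the tip-depth range is within ``rel_tol`` of the max depth."""
        d = self.tip_depths()
        return bool((d.max() - d.min()) <= rel_tol * d.max())

    # -- IO ---------------------------------------------------------------

    def to_newick(self) -> str:
        out = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=True,
        )
        return out.strip() + "\n"

    # -- manipulation -----------------------------------------------------

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a copy of the tree restricted to ``labels`` (order-preserving).

        Unifurcations produced by pruning are collapsed, merging branch
        lengths, so path lengths between retained tips are unchanged.
        """
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeTraitMismatchError(
                f"labels not in tree: {sorted(missing)}"
            )
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        # retain_taxa suppresses unifurcations internally (default).
        return Phylogeny(clone)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Phylogeny(n_tips={self.n_tips}, max_depth={self.max_depth:.4g})"


def _node_name(node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label or "<internal>"


@dataclass
class PhyloCovariance:
    """A between-species covariance (or correlation) matrix with its tip order.

    ``model_tag`` is one of ``"BM"``, ``"LAMBDA"``, ``"OU"``; ``params`` holds
    the model parameter (``lambda`` or ``alpha``) where applicable.  Under BM
    the units are trait variance per unit ``sigma^2``; under OU the matrix is
    a correlation matrix (unit diagonal) and ``sigma^2`` carries all scale.
    """

    tip_order: list[str]
    matrix: np.ndarray
    model_tag: str = "BM"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.tip_order)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match tip order")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(self.matrix) <= 0):
            raise ValueError("covariance diagonal must be positive")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.tip_order, columns=self.tip_order
        )

    def restrict_to(self, labels: Sequence[str]) -> "PhyloCovariance":
        idx = [self.tip_order.index(lab) for lab in labels]
        sub = self.matrix[np.ix_(idx, idx)]
        return PhyloCovariance(list(labels), sub, self.model_tag, dict(self.params))


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string with branch lengths into a :class:`Phylogeny`.

    Raises :class:`NewickError` for malformed syntax, duplicate or empty tip
    labels, or missing/negative branch lengths.  Quoted labels, internal node
    labels and bootstrap values are handled per the Newick standard.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse error classes
        raise NewickError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


def bm_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance matrix of a tree.

    Entry ``(i, j)`` is the root-to-MRCA path length of tips *i* and *j*;
    the diagonal holds root-to-tip depths.  For an ultrametric tree the
    diagonal is constant.
    """
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    depths = tree._depths
    tipsets: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [index[node.taxon.label]]
        else:
            groups = [tipsets.pop(ch) for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            tipsets[node] = [i for g in groups for i in g]
    np.fill_diagonal(C, tree.tip_depths())
    return PhyloCovariance(labels, C, model_tag="BM")


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Apply Pagel's lambda: scale off-diagonal entries of a BM covariance by ``lam``.

    ``lam`` must lie in [0, 1]; the diagonal is left unchanged.
    """
    if C.model_tag != "BM":
        raise ValueError(f"lambda transform requires a BM covariance, got {C.model_tag}")
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = lam * C.matrix
    np.fill_diagonal(V, np.diag(C.matrix))
    return PhyloCovariance(
        list(C.tip_order), V, model_tag="LAMBDA", params={"lambda": float(lam)}
    )


def patristic_distances(tree: Phylogeny) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix as a labelled DataFrame.

    ``d(i, j) = depth_i + depth_j - 2 * bm_cov(i, j)``.
    """
    C = bm_covariance(tree)
    d = np.diag(C.matrix)
    D = d[:, None] + d[None, :] - 2.0 * C.matrix
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=C.tip_order, columns=C.tip_order)


def ou_correlation(distances: pd.DataFrame, alpha: float) -> PhyloCovariance:
    """Stationary Ornstein–Uhlenbeck correlation matrix, ``exp(-alpha * d_ij)``.

    ``alpha`` (> 0) is the strength of attraction toward the optimum; larger
    values decorrelate species faster with patristic distance.  The diagonal
    is 1 by construction; the stationary variance ``sigma^2 / (2 alpha)`` is
    absorbed into the GLS scale downstream.
    """
    if not (alpha > 0 and math.isfinite(alpha)):
        raise ValueError(f"alpha must be positive and finite, got {alpha}")
    D = np.asarray(distances.to_numpy(), dtype=float)
    R = np.exp(-alpha * D)
    np.fill_diagonal(R, 1.0)
    return PhyloCovariance(
        list(distances.index), R, model_tag="OU", params={"alpha": float(alpha)}
    )


def align_tree_and_table(
    tree: Phylogeny,
    table: pd.DataFrame,
    trait_names: Sequence[str],
    species_col: str | None = None,
) -> tuple[Phylogeny, pd.DataFrame]:
    """Reconcile a tree with a species-keyed trait table.

    The tree is pruned to species present in the table with every requested
    trait non-missing; the table is reordered to the pruned tree's tip order.
    Dropped species are reported through the module logger.

    ``table`` is keyed by its index unless ``species_col`` names a column.
    """
    if species_col is not None:
        table = table.set_index(species_col)
    if table.index.duplicated().any():
        dups = sorted(table.index[table.index.duplicated()].unique())
        raise TreeTraitMismatchError(f"duplicated species rows: {dups}")
    missing_cols = [t for t in trait_names if t not in table.columns]
    if missing_cols:
        raise TreeTraitMismatchError(f"traits absent from table: {missing_cols}")

    tips = set(tree.tip_labels)
    in_both = [sp for sp in table.index if sp in tips]
    if not in_both:
        raise TreeTraitMismatchError("tree tips and table species do not overlap")

    complete = [
        sp for sp in in_both if table.loc[sp, list(trait_names)].notna().all()
    ]
    if not complete:
        raise TreeTraitMismatchError(
            "no species has all requested traits non-missing"
        )

    dropped_tree = sorted(tips - set(complete))
    dropped_table = sorted(set(table.index) - set(complete))
    for sp in dropped_tree:
        logger.info("align: dropping tree tip %s (missing from table or traits)", sp)
    for sp in dropped_table:
        if sp not in dropped_tree:
            logger.info("align: dropping table row %s (not a tree tip)", sp)

    pruned = tree.prune_to(complete)
    conformed = table.loc[pruned.tip_labels]
    return pruned, conformed
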