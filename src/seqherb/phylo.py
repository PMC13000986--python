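"""Newick trees to unit-diagonal correlation matrices for taxon random effects.

Under a Brownian-motion model of trait evolution on a tree, the covariance
between two tips equals the shared root-to-MRCA path length; scaling by the
tip depths yields a correlation matrix with unit diagonal that can serve as
the level-covariance of a taxon random effect.  Trees are handled with
dendropy; taxon-name matching is case-insensitive and treats underscores and
spaces as equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np


class PhyloError(ValueError):
    """Raised for unusable trees or taxon mismatches."""


def normalize_name(name: str) -> str:
    return " ".join(str(name).strip().lower().replace("_", " ").split())


@dataclass
class PhyloCorrelation:
    """Unit-diagonal correlation matrix keyed by taxon names."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (len(self.taxa), len(self.taxa)):
            raise PhyloError("matrix shape does not match the taxon list")
        if not np.allclose(M, M.T, atol=1e-12):
            raise PhyloError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(M), 1.0, atol=1e-12):
            raise PhyloError("correlation matrix diagonal is not 1")
        if np.linalg.eigvalsh(M).min() < -1e-10:
            raise PhyloError("correlation matrix is not positive semidefinite")
        self.matrix = M

    def submatrix(self, taxa: Sequence[str]) -> "PhyloCorrelation":
        index = {normalize_name(t): i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if normalize_name(t) not in index]
        if missing:
            raise PhyloError(f"taxa absent from correlation matrix: {missing}")
        idx = [index[normalize_name(t)] for t in taxa]
        return PhyloCorrelation(list(taxa), self.matrix[np.ix_(idx, idx)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a file path or a Newick string."""
    text = None
    p = Path(str(source))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    labels = [normalize_name(t.label) for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise PhyloError("tip labels are not unique after normalization")
    return tree


def prune_to_taxa(
    tree: dendropy.Tree, taxa: Iterable[str]
) -> tuple[dendropy.Tree, list[str]]:
    """Induced subtree on the requested tips, plus the list of missing taxa.

    Internal unary nodes are collapsed with branch lengths summed.  Taxa not
    found in the tree (after name normalization) are reported in the second
    return value rather than raising, mirroring the practice of excluding
    unplaced species from phylogenetic sensitivity analyses.
    """
    wanted = list(taxa)
    by_norm = {normalize_name(t.label): t.label for t in tree.taxon_namespace}
    matched = [by_norm[normalize_name(t)] for t in wanted if normalize_name(t) in by_norm]
    missing = [t for t in wanted if normalize_name(t) not in by_norm]
    if len(matched) < 2:
        raise PhyloError(
            f"fewer than 2 requested taxa found in the tree (matched {matched})"
        )
    pruned = tree.extract_tree_with_taxa_labels(
        labels=matched, suppress_unifurcations=True
    )
    return pruned, missing


def correlation_from_tree(
    tree: dendropy.Tree, covariance: bool = False
) -> PhyloCorrelation:
    """Brownian-motion (co)variance of the tips, scaled to unit diagonal.

    VCV[i, j] is the root-to-MRCA shared path length; the correlation scales
    by sqrt(depth_i * depth_j), which on an ultrametric tree is the common
    tip depth.  With ``covariance=True`` the raw VCV is returned instead
    (diagonal = tip depths).
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: normalize_name(nd.taxon.label))
    labels = [lf.taxon.label for lf in leaves]
    depths = np.array([lf.root_distance for lf in leaves], dtype=float)
    for lab, dep in zip(labels, depths):
        if dep <= 0:
            raise PhyloError(f"zero-depth tip {lab!r}: correlation undefined")
    n = len(leaves)
    pdm = tree.phylogenetic_distance_matrix()
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depths[i]
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            shared = 0.5 * (depths[i] + depths[j] - dist)
            V[i, j] = V[j, i] = max(shared, 0.0)
    if covariance:
        out = PhyloCorrelation.__new__(PhyloCorrelation)
        out.taxa = labels
        out.matrix = V
        return out
    scale = np.sqrt(np.outer(depths, depths))
    C = V / scale
    np.fill_diagonal(C, 1.0)
    return PhyloCorrelation(labels, C)
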