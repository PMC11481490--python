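"""Genome-wide conflict summaries: gene concordance factors, the pairwise
Robinson-Foulds distance matrix, and classical (Torgerson) multidimensional
scaling of that matrix.

The gene concordance factor (gCF) of a species-tree internal branch is the
percentage of *decisive* gene trees containing the branch: a gene tree is
decisive for a branch if, after restricting the branch's bipartition to the
gene tree's taxa, both sides still hold at least two taxa; it is concordant
if that restricted bipartition occurs in the gene tree.  With complete gene
trees every tree is decisive for every branch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeio import Bipartition, PhyloTree, bipartitions, rf_distance

__all__ = [
    "BranchConcordance",
    "MDSResult",
    "gene_concordance_factors",
    "rf_matrix",
    "classical_mds",
    "annotate_species_tree_gcf",
]


@dataclass
class BranchConcordance:
    """gCF bookkeeping for one internal species-tree branch."""

    branch: Bipartition
    n_decisive: int
    n_concordant: int
    gcf: float  # in [0, 100]; NaN when no gene tree is decisive
    highlight: bool


@dataclass
class MDSResult:
    """Classical-MDS embedding: centered coordinates, eigenvalues, row labels."""

    coords: np.ndarray  # (n_points, k), columns MDS1, MDS2, ...
    eigenvalues: np.ndarray  # all eigenvalues, descending
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"MDS{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, columns=cols, index=self.labels)


def gene_concordance_factors(
    species_tree: PhyloTree,
    gene_trees: list[PhyloTree],
    highlight_threshold: float = 60.0,
) -> list[BranchConcordance]:
    """gCF for every internal branch of the species tree.

    Gene trees may cover a taxon subset; a tree whose restriction of a branch
    leaves fewer than two taxa on either side is not decisive for it and does
    not enter that branch's denominator.  ``highlight`` is strict
    ``gcf > highlight_threshold``.
    """
    sp_taxa = species_tree.leaf_names()
    for gt in gene_trees:
        extra = gt.leaf_names() - sp_taxa
        if extra:
            raise ValueError(f"gene-tree taxa not in species tree: {sorted(extra)}")
    # per gene tree: taxon set and both sides of every split, for O(1) lookup
    gene_sets = []
    for gt in gene_trees:
        taxa = gt.leaf_names()
        sides: set[frozenset[str]] = set()
        for bp in bipartitions(gt):
            sides.add(bp.side)
            sides.add(taxa - bp.side)
        gene_sets.append((taxa, sides))

    out = []
    for bp in sorted(bipartitions(species_tree), key=lambda b: sorted(b.side)):
        decisive = concordant = 0
        for taxa, sides in gene_sets:
            left = bp.side & taxa
            right = taxa - left
            if len(left) < 2 or len(right) < 2:
                continue
            decisive += 1
            if left in sides:
                concordant += 1
        gcf = 100.0 * concordant / decisive if decisive else math.nan
        out.append(
            BranchConcordance(
                branch=bp,
                n_decisive=decisive,
                n_concordant=concordant,
                gcf=gcf,
                highlight=bool(decisive and gcf > highlight_threshold),
            )
        )
    return out


def annotate_species_tree_gcf(
    species_tree: PhyloTree, concordances: list[BranchConcordance]
) -> PhyloTree:
    """Copy of the species tree with gCF written as internal-node supports."""
    tree = species_tree.copy()
    taxa = tree.leaf_names()
    ref = min(taxa)
    by_side = {c.branch.side: c.gcf for c in concordances}
    sets = tree.leaf_sets()
    for nd in tree.internal_nodes(exclude_root=True):
        side = sets[id(nd)]
        if ref in side:
            side = taxa - side
        gcf = by_side.get(side)
        if gcf is not None and not math.isnan(gcf):
            nd.support = round(gcf, 4)
    return tree


def rf_matrix(trees: list[PhyloTree]) -> np.ndarray:
    """Symmetric matrix of pairwise RF distances; all trees share one leaf set."""
    n = len(trees)
    splits = [bipartitions(t) for t in trees]
    leaf_sets = [t.leaf_names() for t in trees]
    for ls in leaf_sets[1:]:
        if ls != leaf_sets[0]:
            rf_distance(trees[0], trees[leaf_sets.index(ls)])  # raises with names
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = len(splits[i] ^ splits[j])
            mat[i, j] = mat[j, i] = d
    return mat


def classical_mds(dist: np.ndarray, k: int = 2) -> MDSResult:
    """Torgerson's classical MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and scales
    eigenvectors by the square roots of their (positive) eigenvalues.  RF
    distances are generally non-Euclidean, so negative eigenvalues can occur;
    those dimensions are dropped and, if fewer than ``k`` positive dimensions
    remain, the result is truncated with a warning.  Each axis's sign is fixed
    by making its largest-magnitude loading positive.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("distances must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = dist.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dist * dist) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-9 * abs(vals[0])) if n else 0.0
    pos = vals > tol
    n_pos = int(pos.sum())
    kept = min(k, n_pos)
    if kept < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalue dimension(s); returning {kept}",
            RuntimeWarning,
            stacklevel=2,
        )
    coords = vecs[:, :kept] * np.sqrt(vals[:kept])
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    labels = [f"point{i}" for i in range(n)]
    if kept == 0:
        coords = np.zeros((n, min(k, 1)))
    return MDSResult(coords=coords, eigenvalues=vals, labels=labels)
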