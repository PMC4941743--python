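"""Trees: newick I/O, stratigraphic time-calibration, phylogenetic covariance.

Fossil supertrees typically arrive with no (or zero) branch lengths; the
calibration here dates every internal node at the oldest first-appearance
datum (FAD) among its descendant tips, resolves the zero-length branches
that this creates by pushing the subtending node older by a fixed
``vartime`` increment (cascading rootward), and optionally extends each
terminal branch so the tip ends at its last-appearance datum (LAD).  The
result is a non-ultrametric tree with strictly positive branch lengths in
units of Ma, from which the standard Brownian-motion covariance matrix
(shared root-to-tip path lengths) is built for the comparative models.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .trace_io import normalize_taxon

logger = logging.getLogger(__name__)


@dataclass
class TaxonRange:
    """Stratigraphic range of a taxon: first and last appearance, Ma."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if not (self.fad >= self.lad >= 0):
            raise ValueError(
                f"{self.taxon}: require FAD >= LAD >= 0, got "
                f"FAD={self.fad}, LAD={self.lad}"
            )


@dataclass
class PhyloCovariance:
    """Shared root-to-tip path lengths between tips, in Ma.

    ``V[i, j]`` is the branch length shared by the root-to-tip paths of
    taxa i and j (the depth of their MRCA below the root); the diagonal
    holds each tip's total root-to-tip distance.
    """

    taxa: list[str]
    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        n = len(self.taxa)
        if self.V.shape != (n, n):
            raise ValueError("V shape does not match number of taxa")
        if not np.allclose(self.V, self.V.T):
            raise ValueError("V must be symmetric")

    def subset(self, taxa: Iterable[str]) -> "PhyloCovariance":
        taxa = list(taxa)
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(taxa, self.V[np.ix_(idx, idx)])


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Tip labels are taken as taxon names; branch lengths are optional.
    Malformed input raises with the parser's position diagnostics.
    """
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick (branch lengths included when present)."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree file."""
    return parse_newick(Path(path).read_text())


def load_ranges(path: str | Path) -> list[TaxonRange]:
    """Read a FAD/LAD table (CSV columns: taxon, FAD_Ma, LAD_Ma)."""
    df = pd.read_csv(path)
    required = {"taxon", "FAD_Ma", "LAD_Ma"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ranges table missing columns: {sorted(missing)}")
    return [
        TaxonRange(normalize_taxon(r.taxon), float(r.FAD_Ma), float(r.LAD_Ma))
        for r in df.itertuples(index=False)
    ]


def _range_map(ranges: Iterable[TaxonRange]) -> dict[str, TaxonRange]:
    out: dict[str, TaxonRange] = {}
    for r in ranges:
        key = normalize_taxon(r.taxon)
        if key in out:
            raise ValueError(f"duplicate range entry for taxon {key!r}")
        out[key] = r
    return out


def time_calibrate(
    tree: dendropy.Tree,
    ranges: Iterable[TaxonRange],
    vartime: float = 1.0,
    add_term: bool = True,
) -> dendropy.Tree:
    """Date a tree from taxon FAD/LADs; all output branch lengths > 0.

    Procedure (deterministic; permutation of the ranges table is
    irrelevant):

    1. Basic dating: each internal node's age is the oldest FAD among its
       descendant tips.  Tips terminate at their LAD when ``add_term`` is
       on, else at their FAD.
    2. Zero-length-branch adjustment: whenever a node's age equals the
       age/termination of one of its children (a zero branch), the node
       is shifted older by ``vartime``; the shift cascades rootward so no
       branch goes negative.  Ties among FADs are handled by the same
       rule (a single ``vartime`` shift per node).

    The input tree is not modified; a dated clone is returned.
    """
    if vartime <= 0:
        raise ValueError("vartime must be > 0")
    rmap = _range_map(ranges)
    dated = tree.clone(depth=1)

    missing = [
        lf.taxon.label
        for lf in dated.leaf_node_iter()
        if normalize_taxon(lf.taxon.label) not in rmap
    ]
    if missing:
        raise ValueError(f"tips missing from ranges table: {sorted(missing)}")

    # Post-order: age of a leaf's dating point is its FAD; its branch ends
    # at term (LAD if add_term).  Internal age = max child requirement,
    # +vartime if any child branch would otherwise have zero length.
    age: dict[dendropy.Node, float] = {}
    term: dict[dendropy.Node, float] = {}
    for node in dated.postorder_node_iter():
        if node.is_leaf():
            rng = rmap[normalize_taxon(node.taxon.label)]
            age[node] = rng.fad
            term[node] = rng.lad if add_term else rng.fad
        else:
            kids = node.child_nodes()
            a = max(age[c] for c in kids)
            if any(np.isclose(a, term[c]) or term[c] > a for c in kids):
                a = max(a, max(term[c] for c in kids)) + vartime
            age[node] = a
            term[node] = a

    for node in dated.postorder_node_iter():
        parent = node.parent_node
        if parent is None:
            node.edge.length = None
            continue
        length = age[parent] - term[node]
        if length <= 0:  # pragma: no cover - guarded by construction
            raise AssertionError(f"non-positive branch length {length}")
        node.edge.length = float(length)

    dated.seed_node.annotations.add_new("age_Ma", age[dated.seed_node])
    dated._root_age = age[dated.seed_node]  # convenience for callers
    return dated


def root_age(tree: dendropy.Tree) -> float:
    """Age of the root node in Ma for a calibrated tree."""
    if hasattr(tree, "_root_age"):
        return float(tree._root_age)
    # fall back to max root-to-tip distance (exact for trees with an
    # extant tip at 0 Ma)
    return float(max(lf.distance_from_root() for lf in tree.leaf_node_iter()))


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Build the Brownian-motion covariance matrix of a calibrated tree.

    ``V[i, j]`` is the depth (sum of branch lengths from the root) of the
    MRCA of tips i and j; ``V[i, i]`` is tip i's root-to-tip distance.
    The tree need not be ultrametric: fossil tips simply end earlier.
    """
    tips = list(tree.leaf_node_iter())
    taxa = [lf.taxon.label for lf in tips]
    n = len(tips)

    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)

    # tip-set bitmask per internal node -> MRCA depth via preorder refinement
    V = np.zeros((n, n))
    index = {tip: i for i, tip in enumerate(tips)}

    def fill(node: dendropy.Node) -> list[int]:
        if node.is_leaf():
            i = index[node]
            V[i, i] = depth[node]
            return [i]
        groups = [fill(c) for c in node.child_nodes()]
        d = depth[node]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        V[i, j] = V[j, i] = d
        merged = [i for g in groups for i in g]
        return merged

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 100))
    try:
        fill(tree.seed_node)
    finally:
        sys.setrecursionlimit(old)
    return PhyloCovariance(taxa, V)
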