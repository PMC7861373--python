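"""Neighbour-joining trees on Bruvo distances with locus bootstrap.

The tree is the Saitou-Nei neighbour-joining reconstruction, which is
exact on additive distance matrices.  Branch support resamples the locus
set with replacement (not individuals), recomputing distances and the
tree per replicate; the support of an internal bipartition is the
fraction of replicates containing it.  Supports below 0.5 are suppressed
when rendering, so only well-supported branches are labelled.
"""

from __future__ import annotations

import io
import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .bruvo import DistanceMatrix, distance_matrix
from .genotype_io import GenotypeTable

logger = logging.getLogger(__name__)


class PhylogenyError(ValueError):
    pass


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Unrooted NJ tree; negative branch lengths are clamped to zero and
    the total clamped deficit recorded on ``tree.negative_length_deficit``.

    Tie-breaking in the Q-matrix minimization is deterministic in the
    input label order.
    """
    if len(dm) < 3:
        raise PhylogenyError("neighbour joining needs at least 3 taxa")
    sk = SkbioDM(dm.values, ids=dm.labels)
    tree = nj(sk, neg_as_zero=False)
    deficit = 0.0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            deficit += -node.length
            node.length = 0.0
    tree.negative_length_deficit = deficit
    if deficit > 0:
        logger.info("clamped negative branch lengths (total deficit %.6g)",
                    deficit)
    return tree


def _bipartitions(tree: TreeNode, all_leaves: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the alphabetically first leaf (unrooted comparison)."""
    anchor = min(all_leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if anchor in side:
            side = all_leaves - side
        out.add(side)
    return out


def bootstrap_support(table: GenotypeTable, n_boot: int = 1000,
                      seed: int | None = None,
                      loci: list[str] | None = None) -> TreeNode:
    """NJ tree with locus-bootstrap support on internal nodes.

    Each replicate resamples the loci with replacement, recomputes the
    Bruvo distance matrix and the NJ tree; ``node.support`` is the
    fraction of replicates containing the node's bipartition.  With
    ``n_boot=0`` the plain tree is returned without supports.
    """
    loci = list(loci) if loci is not None else list(table.loci)
    if len(loci) < 2:
        raise PhylogenyError("locus bootstrap needs at least 2 loci")
    base = neighbor_joining(distance_matrix(table, loci))
    if n_boot == 0:
        return base
    all_leaves = frozenset(t.name for t in base.tips())
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        sampled = [loci[k] for k in rng.integers(0, len(loci), size=len(loci))]
        rep = neighbor_joining(distance_matrix(table, sampled))
        for bp in _bipartitions(rep, all_leaves):
            counts[bp] = counts.get(bp, 0) + 1
    anchor = min(all_leaves)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if anchor in side:
            side = all_leaves - side
        node.support = counts.get(side, 0) / n_boot
    return base


def annotate_ancestry(tree: TreeNode, dominant_labels: dict,
                      colour_map: dict) -> TreeNode:
    """Colour leaves by dominant inferred ancestor.

    ``dominant_labels`` maps leaf name -> cluster id or None; leaves with
    no dominant ancestor are left uncoloured.  Unknown leaf names or a
    used ancestor missing from ``colour_map`` are errors.
    """
    leaf_names = {t.name for t in tree.tips()}
    unknown = set(dominant_labels) - leaf_names
    if unknown:
        raise PhylogenyError(f"unknown leaf name(s) in map: {sorted(unknown)}")
    used = {v for v in dominant_labels.values() if v is not None}
    missing = used - set(colour_map)
    if missing:
        raise PhylogenyError(
            f"colour map lacks ancestor id(s): {sorted(missing)}"
        )
    for tip in tree.tips():
        anc = dominant_labels.get(tip.name)
        tip.ancestor_cluster = anc
        tip.colour = colour_map[anc] if anc is not None else None
    return tree


def to_newick(tree: TreeNode, min_support: float = 0.5) -> str:
    """Newick string with bootstrap supports as internal node labels;
    supports below ``min_support`` are suppressed."""
    clone = tree.copy()
    base_nodes = list(tree.non_tips(include_self=True))
    for node, orig in zip(clone.non_tips(include_self=True), base_nodes):
        sup = getattr(orig, "support", None)
        node.name = (f"{sup:.3f}" if sup is not None and sup >= min_support
                     else None)
        node.support = None  # the writer would otherwise emit it unformatted
    buf = io.StringIO()
    clone.write(buf, format="newick")
    return buf.getvalue().strip()


def colour_table(tree: TreeNode) -> pd.DataFrame:
    """Companion leaf-annotation table for an ancestry-annotated tree."""
    rows = [{"leaf": t.name,
             "ancestor": getattr(t, "ancestor_cluster", None),
             "colour": getattr(t, "colour", None)} for t in tree.tips()]
    return pd.DataFrame(rows)
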