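"""Root-to-tip molecular-clock outlier test on a rooted phylogeny.

Under a strict molecular clock every tip of a rooted tree lies at the same
distance (substitutions/site) from the root.  Given a non-ultrametric tree
-- here, a distance tree of promoter sequences artificially rooted on the
edge separating marsupials from eutherians -- each tip's root-to-tip
distance is compared to the mean distance plus/minus a Bonferroni-adjusted
Student t interval on the empirical SD; tips beyond the upper bound are
classified "faster", below the lower bound "slower", otherwise "typical".
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["load_tree", "root_between", "root_to_tip", "clock_outliers",
           "ClockReport"]


class NonMonophylyError(ValueError):
    """No single edge separates the two requested tip sets."""


@dataclass
class ClockReport:
    table: pd.DataFrame  # tip, distance, class
    mean: float
    half_width: float
    alpha: float
    m: int

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["class"] != "typical"]


def load_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def root_between(tree: dendropy.Tree, clade_a, clade_b,
                 fraction: float = 0.5) -> dendropy.Tree:
    """Root the tree on the edge separating ``clade_a`` from ``clade_b``.

    Both tip sets must be monophyletic on opposite sides of a single edge
    of the unrooted tree.  The root is placed at ``fraction`` of the edge
    length from the clade_a side, preserving all path lengths.  Returns a
    new tree; the input is not modified.
    """
    set_a, set_b = frozenset(clade_a), frozenset(clade_b)
    tree = tree.clone(depth=1)
    tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not (set_a <= tips and set_b <= tips):
        missing = (set_a | set_b) - tips
        raise NonMonophylyError(f"tips not in tree: {sorted(missing)}")
    if set_a | set_b != tips or set_a & set_b:
        raise NonMonophylyError("clades must bipartition the tip set")
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = _leafset(node)
        if below == set_a or below == set_b:
            target = node
            below_is_a = below == set_a
            break
    if target is None:
        raise NonMonophylyError("no single edge separates the two clades")
    root = tree.seed_node
    children = root.child_nodes()
    if target.parent_node is root and len(children) == 2:
        # already rooted on the separating edge: the unrooted edge is the
        # two root branches combined; reposition the root along it
        sibling = children[0] if children[1] is target else children[1]
        length = (target.edge.length or 0.0) + (sibling.edge.length or 0.0)
        d_target = (fraction if below_is_a else 1.0 - fraction) * length
        target.edge.length = d_target
        sibling.edge.length = length - d_target
        return tree
    edge = target.edge
    length = edge.length or 0.0
    d_head = (fraction if below_is_a else 1.0 - fraction) * length
    tree.reroot_at_edge(edge, length1=length - d_head, length2=d_head,
                        update_bipartitions=False)
    return tree


def root_to_tip(tree: dendropy.Tree) -> pd.Series:
    """Sum of branch lengths from the root to each tip."""
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    dist = {lf.taxon.label: float(lf.root_distance)
            for lf in tree.leaf_node_iter()}
    return pd.Series(dist, name="distance")


def clock_outliers(distances: pd.Series, alpha: float = 0.05,
                   m: int | None = None) -> ClockReport:
    """Classify tips whose root-to-tip distance departs from the mean.

    The acceptance band is mean +/- t_{1-alpha/(2m), N-1} * SD of the tip
    distances, Bonferroni-adjusted for ``m`` comparisons (default: the
    number of tips).  Tips above the band are "faster", below "slower".
    """
    distances = pd.Series(distances, dtype=float)
    n = len(distances)
    if n < 3:
        raise ValueError("outlier test requires >= 3 tips")
    m = n if m is None else m
    mean = float(distances.mean())
    sd = float(distances.std(ddof=1))
    half = float(stats.t.ppf(1 - alpha / (2 * m), n - 1) * sd)
    cls = np.where(distances > mean + half, "faster",
                   np.where(distances < mean - half, "slower", "typical"))
    table = pd.DataFrame({"tip": distances.index,
                          "distance": distances.to_numpy(),
                          "class": cls})
    return ClockReport(table=table, mean=mean, half_width=half,
                       alpha=alpha, m=m)
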