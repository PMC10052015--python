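"""16S rRNA distances and neighbor-joining trees.

Distances from an alignment use either the raw proportion of differing
sites (p-distance) or the Jukes–Cantor correction
``d = -(3/4) ln(1 - 4p/3)``, with columns gapped in either sequence of a
pair excluded (pairwise deletion).  Tree construction is the Saitou–Nei
neighbor-joining algorithm with the standard Q-criterion, implemented here
directly because it is the one exactly testable method for this analysis:
on additive distance matrices NJ provably recovers the generating tree.
Negative branch-length estimates are clamped to zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "seq_distance",
    "distance_matrix",
    "neighbor_joining",
    "cluster_check",
    "tree_to_newick",
]

_GAPS = {"-", ".", "?"}


def seq_distance(a: str, b: str, model: str = "p") -> float:
    """Pairwise distance between two aligned sequences.

    ``model``: ``"p"`` (proportion of mismatches) or ``"jc"``
    (Jukes–Cantor).  Sites with a gap in either sequence are excluded.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    compared = mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in _GAPS or y in _GAPS:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped) sites")
    p = mismatches / compared
    if model == "p":
        return p
    if model == "jc":
        if p >= 0.75:
            raise ValueError(f"saturated distance (p = {p:.3f} >= 0.75) under Jukes-Cantor")
        return -0.75 * np.log1p(-4.0 * p / 3.0)
    raise ValueError(f"unknown model {model!r}")


def distance_matrix(seqs: Mapping[str, str], model: str = "p") -> pd.DataFrame:
    """Symmetric distance matrix over a named set of aligned sequences."""
    labels = list(seqs)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = seq_distance(seqs[labels[i]], seqs[labels[j]], model)
    return pd.DataFrame(mat, index=labels, columns=labels)


def neighbor_joining(dm: pd.DataFrame) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; returns an unrooted dendropy tree.

    Deterministic: among equal Q values the lowest (i, j) index pair in the
    current working order is joined.
    """
    labels = list(dm.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    d = dm.to_numpy(float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")

    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
    active = list(range(len(labels)))

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative NJ branch length {x:.4g} clamped to 0")
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest index pair among minima
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if best is None or q[i, j] < q[best] - 1e-12:
                    best = (i, j)
        i, j = best
        dij = sub[i, j]
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        ni, nj = nodes[active[i]], nodes[active[j]]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = clamp(li)
        nj.edge.length = clamp(lj)
        # distances from the new node to the remaining clusters
        new_d = {}
        for k_pos, k in enumerate(active):
            if k_pos in (i, j):
                continue
            new_d[k] = (sub[i, k_pos] + sub[j, k_pos] - dij) / 2.0
        new_index = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k, val in new_d.items():
            d[new_index, k] = d[k, new_index] = val
        nodes.append(parent)
        active = [a for p, a in enumerate(active) if p not in (i, j)] + [new_index]

    # final three-way join (closed form)
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    root = dendropy.Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = clamp(ln)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def cluster_check(tree: dendropy.Tree, groups: Mapping[str, str], outgroup: str) -> dict[str, bool]:
    """Monophyly of each leaf group on the tree rooted at ``outgroup``.

    ``groups`` maps leaf label -> group name; the outgroup leaf itself need
    not be assigned.  Returns group name -> is-monophyletic.
    """
    work = tree.clone(depth=1)
    out_node = work.find_node_with_taxon_label(outgroup)
    if out_node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    work.to_outgroup_position(out_node, update_bipartitions=True)
    work.is_rooted = True  # rooted at the outgroup for clade queries

    leaf_labels = {leaf.taxon.label for leaf in work.leaf_node_iter()}
    unknown = set(groups) - leaf_labels
    if unknown:
        raise ValueError(f"group assignments for absent leaves: {sorted(unknown)}")

    by_group: dict[str, set[str]] = {}
    for label, g in groups.items():
        if label == outgroup:
            continue
        by_group.setdefault(g, set()).add(label)

    report = {}
    for g, members in sorted(by_group.items()):
        if len(members) == 1:
            report[g] = True
            continue
        mrca = work.mrca(taxon_labels=sorted(members))
        clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        report[g] = clade == members
    return report
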