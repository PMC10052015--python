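"""Distances, neighbor joining and monophyly checks."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.calculate import treecompare

from phrscan.phylo import cluster_check, distance_matrix, neighbor_joining, seq_distance, tree_to_newick
from phrscan.simulate import CLADE_TREE_NEWICK, gen_tree_sequences


def test_identical_sequences_distance_zero():
    assert seq_distance("ACGTACGT", "ACGTACGT", "p") == 0.0
    assert seq_distance("ACGTACGT", "ACGTACGT", "jc") == 0.0


def test_jukes_cantor_closed_form():
    a = "A" * 100
    b = "C" * 10 + "A" * 90
    assert seq_distance(a, b, "p") == pytest.approx(0.10)
    assert seq_distance(a, b, "jc") == pytest.approx(-0.75 * np.log(1 - 0.4 / 3), abs=1e-12)
    assert round(seq_distance(a, b, "jc"), 5) == 0.10733


def test_gap_columns_excluded_pairwise():
    assert seq_distance("AC-T", "ACG-", "p") == 0.0  # only 2 comparable sites, both equal
    with pytest.raises(ValueError, match="no comparable"):
        seq_distance("--", "AA", "p")


def test_jc_saturation_is_an_error_and_jc_dominates_p():
    with pytest.raises(ValueError, match="saturated"):
        seq_distance("AAAA", "CCCC", "jc")
    d_p = seq_distance("AAAAAAAAAA", "CCCAAAAAAA", "p")
    d_jc = seq_distance("AAAAAAAAAA", "CCCAAAAAAA", "jc")
    assert d_jc >= d_p


def test_distance_matrix_symmetric_zero_diagonal():
    seqs = {"a": "ACGTACGT", "b": "ACGTACGA", "c": "TCGTACGA"}
    dm = distance_matrix(seqs, "p")
    m = dm.to_numpy()
    assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)


def _random_tree(rng, n_taxa):
    taxa = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa, taxon_namespace=tns, rng=rng
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = rng.uniform(0.05, 1.0)
    return tree


def _additive_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return pd.DataFrame(m, index=labels, columns=labels)


def _rf_unrooted(newick1: str, newick2: str, labels) -> int:
    tns = dendropy.TaxonNamespace(list(labels))
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    for t in (t1, t2):
        t.is_rooted = False
        t.collapse_basal_bifurcation()
        t.encode_bipartitions()
    return treecompare.symmetric_difference(t1, t2)


@pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
def test_nj_recovers_random_additive_trees_exactly(n_taxa, seed):
    import random

    rng = random.Random(seed)
    true_tree = _random_tree(rng, n_taxa)
    dm = _additive_matrix(true_tree)
    est = neighbor_joining(dm)

    # same unrooted topology
    assert _rf_unrooted(tree_to_newick(est), true_tree.as_string(schema="newick"), dm.index) == 0
    # and identical path distances (branch lengths recovered)
    est_m = _additive_matrix(est)
    assert np.allclose(est_m.loc[dm.index, dm.columns].to_numpy(), dm.to_numpy(), atol=1e-9)


def test_three_taxon_closed_form():
    dm = pd.DataFrame(
        [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]], index=list("abc"), columns=list("abc")
    )
    tree = neighbor_joining(dm)
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_matches_scikit_bio():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    import random

    true_tree = _random_tree(random.Random(7), 6)
    dm = _additive_matrix(true_tree)
    ours = neighbor_joining(dm)
    theirs = skbio_nj(SkbioDM(dm.to_numpy(), ids=list(dm.index)))
    tns = dendropy.TaxonNamespace(list(dm.index))
    t1 = dendropy.Tree.get(data=tree_to_newick(ours), schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=str(theirs).replace("root", ""), schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2) == 0


def test_degenerate_equal_distances_deterministic():
    labels = list("abcd")
    dm = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
    n1 = tree_to_newick(neighbor_joining(dm))
    n2 = tree_to_newick(neighbor_joining(dm))
    assert n1 == n2


def test_taxon_order_invariance_up_to_relabeling():
    import random

    true_tree = _random_tree(random.Random(11), 6)
    dm = _additive_matrix(true_tree)
    perm = list(dm.index)[::-1]
    dm2 = dm.loc[perm, perm]
    tns = dendropy.TaxonNamespace(list(dm.index))
    t1 = dendropy.Tree.get(data=tree_to_newick(neighbor_joining(dm)), schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=tree_to_newick(neighbor_joining(dm2)), schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert treecompare.symmetric_difference(t1, t2) == 0


def test_newick_round_trip_preserves_lengths():
    dm = pd.DataFrame(
        [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]], index=list("abc"), columns=list("abc")
    )
    tree = neighbor_joining(dm)
    newick = tree_to_newick(tree)
    back = dendropy.Tree.get(data=newick, schema="newick")
    lengths = sorted(l.edge.length for l in back.leaf_node_iter())
    orig = sorted(l.edge.length for l in tree.leaf_node_iter())
    assert np.allclose(lengths, orig, atol=1e-9)


def test_too_few_taxa_rejected():
    dm = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=list("ab"), columns=list("ab"))
    with pytest.raises(ValueError):
        neighbor_joining(dm)


def test_monophyly_on_simple_tree():
    tree = dendropy.Tree.get(data="((A1:1,A2:1):1,(B1:1,B2:1):1,OUT:3);", schema="newick")
    groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
    report = cluster_check(tree, groups, outgroup="OUT")
    assert report == {"A": True, "B": True}


def test_planted_paraphyly_detected():
    tree = dendropy.Tree.get(data="(((A1:1,B1:1):1,A2:2):1,B2:3,OUT:4);", schema="newick")
    report = cluster_check(tree, {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}, outgroup="OUT")
    assert report["A"] is False


def test_missing_outgroup_is_an_error():
    tree = dendropy.Tree.get(data="((A1:1,A2:1):1,B1:2);", schema="newick")
    with pytest.raises(ValueError, match="outgroup"):
        cluster_check(tree, {"A1": "A", "A2": "A"}, outgroup="ZZZ")


def test_evolved_clades_recovered_monophyletic():
    """Sequences evolved on a 3-clade tree yield an NJ tree with all clades monophyletic."""
    seqs, _, truth = gen_tree_sequences(seed=13, seq_length=800)
    dm = distance_matrix(seqs, "jc")
    tree = neighbor_joining(dm)
    groups = {t: t[0] for t in truth["taxa"] if t != "OUT"}
    report = cluster_check(tree, groups, outgroup="OUT")
    assert report == {"A": True, "B": True, "C": True}

    # every clade of the (polytomous) generating tree appears in the NJ tree
    tns = dendropy.TaxonNamespace(sorted(seqs))
    t1 = dendropy.Tree.get(data=tree_to_newick(tree), schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=CLADE_TREE_NEWICK, schema="newick", taxon_namespace=tns)
    for t in (t1, t2):
        t.is_rooted = False
        t.encode_bipartitions()
    _, false_negatives = treecompare.false_positives_and_negatives(t2, t1)
    assert false_negatives == 0


def test_zero_length_branches_give_zero_distances():
    newick = "((A1:0,A2:0):0,(B1:0,B2:0):0,OUT:0);"
    seqs, _, _ = gen_tree_sequences(seed=0, newick=newick, seq_length=200)
    assert len(set(seqs.values())) == 1
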