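"""Independent test oracles shared across test modules."""

import itertools

import networkx as nx
import numpy as np

from divlimit.phylo import read_tree


def oracle_max_edge_disjoint(tree, window):
    """Maximum number of edge-disjoint leaf pairs with pair time inside
    ``window``, computed independently of the production algorithm:
    candidate pairs are nodes of a compatibility graph (edge = paths
    share no tree edge) and the answer is its maximum clique size."""
    tree = read_tree(tree)
    edge_ids = {e: i for i, e in enumerate(tree.preorder_edge_iter())}
    paths, depths = {}, {}
    for leaf in tree.leaf_node_iter():
        ids, node, depth = [], leaf, 0.0
        while node.parent_node is not None:
            ids.append(edge_ids[node.edge])
            depth += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = frozenset(ids)
        depths[leaf.taxon.label] = depth
    lo, hi = window
    hi = np.inf if hi is None else hi
    cands = []
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a, b in itertools.combinations(sorted(paths), 2):
        t = pdm.patristic_distance(taxa[a], taxa[b]) / 2.0
        if lo <= t <= hi:
            cands.append(((a, b), paths[a] ^ paths[b]))
    if not cands:
        return 0
    g = nx.Graph()
    g.add_nodes_from(range(len(cands)))
    for i, j in itertools.combinations(range(len(cands)), 2):
        if not (cands[i][1] & cands[j][1]):
            g.add_edge(i, j)
    best = 1
    for clique in nx.find_cliques(g):
        best = max(best, len(clique))
    return best
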