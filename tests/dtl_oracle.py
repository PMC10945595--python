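"""Brute-force DTL reconciliation oracle: exhaustive enumeration over all
mappings of internal gene nodes to species nodes.

Independent of the package's dynamic program — events and losses are
scored directly from a full mapping by the standard rules:

* an edge (g -> child) is vertical if the child's image is a descendant-
  or-equal of g's image, a transfer edge if the images are incomparable,
  and invalid if the child maps to a strict ancestor;
* at most one child edge of a node may be a transfer;
* a non-transfer node is a codivergence iff its two children map into
  distinct child subtrees of its (internal) image, else a duplication;
* losses: codivergence charges dist(child-subtree root, child image) per
  side, duplication charges dist(own image, child image) per child, the
  vertical side of a transfer charges dist(own image, child image), the
  transferred side charges nothing.
"""

from __future__ import annotations

import itertools


def _index_species(species_tree):
    nodes = list(species_tree.postorder_node_iter())
    idx = {n: i for i, n in enumerate(nodes)}
    parent = [idx[n.parent_node] if n.parent_node is not None else -1 for n in nodes]
    children = [[idx[c] for c in n.child_nodes()] for n in nodes]
    n = len(nodes)
    anc = [[False] * n for _ in range(n)]
    depth = [0] * n
    for i in range(n):
        j, d = i, 0
        while j != -1:
            anc[j][i] = True
            j = parent[j]
            d += 1
        depth[i] = d - 1
    leaf_of = {nd.taxon.label: idx[nd] for nd in nodes if nd.is_leaf()}
    return nodes, children, anc, depth, leaf_of


def oracle_min_cost(gene_tree, species_tree, costs, allow_transfer=True):
    """Minimum reconciliation cost by exhaustive mapping enumeration."""
    nodes, children, anc, depth, leaf_of = _index_species(species_tree)
    n = len(nodes)

    def dist(a, d):
        return depth[d] - depth[a]

    gnodes = list(gene_tree.postorder_node_iter())
    internals = [g for g in gnodes if not g.is_leaf()]
    fixed = {}
    for g in gnodes:
        if g.is_leaf():
            label = g.taxon.label
            sp = label if label in leaf_of else label.rsplit("_", 1)[0]
            fixed[g] = leaf_of[sp]

    best = float("inf")
    for assign in itertools.product(range(n), repeat=len(internals)):
        M = dict(fixed)
        M.update(zip(internals, assign))
        cost = 0.0
        valid = True
        for g in internals:
            s = M[g]
            kids = g.child_nodes()
            vertical, transfer = [], []
            for c in kids:
                m = M[c]
                if anc[s][m]:
                    vertical.append(m)
                elif anc[m][s]:
                    valid = False
                    break
                else:
                    transfer.append(m)
            if not valid or len(transfer) > 1:
                valid = False
                break
            if transfer:
                if not allow_transfer:
                    valid = False
                    break
                cost += costs.transfer + costs.loss * dist(s, vertical[0])
            else:
                m1, m2 = vertical
                codiv_options = []
                for a, b in itertools.permutations(children[s], 2):
                    if anc[a][m1] and anc[b][m2]:
                        codiv_options.append(
                            costs.codivergence
                            + costs.loss * (dist(a, m1) + dist(b, m2))
                        )
                dup_cost = (costs.duplication
                            + costs.loss * (dist(s, m1) + dist(s, m2)))
                cost += min(codiv_options + [dup_cost])
            if cost >= best:
                break
        if valid and cost < best:
            best = cost
    return best
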