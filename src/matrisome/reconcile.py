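"""Gene-tree / species-tree reconciliation under duplication-transfer-loss
costs.

Two reconciliation routines are provided. ``reconcile_dl`` is the classic
LCA (last-common-ancestor) reconciliation: each gene node maps to the LCA
of its children's images, a node is a duplication iff it maps to the same
species node as one of its children, and losses are counted by the
path-depth rule. ``reconcile_dtl`` is a dynamic program over gene nodes x
species nodes that additionally allows transfers between
non-ancestrally-related species lineages (undated convention), with
deterministic tie-breaking (codivergence > duplication > transfer, then
smallest species-node index).

Default event costs are duplication 1.5, transfer 1, codivergence 0; the
loss cost defaults to 1 (a zero loss cost degenerates the model, since
losses become free) and is configurable.

Support-driven rearrangement collapses weakly supported gene-tree edges
into polytomies and re-resolves each polytomy to minimize reconciliation
cost (exhaustively up to degree 6, stepwise best-join above).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

from .io import node_support, read_newick, write_newick

INF = float("inf")


@dataclass(frozen=True)
class ReconciliationCosts:
    duplication: float = 1.5
    transfer: float = 1.0
    codivergence: float = 0.0
    loss: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.duplication, self.transfer, self.codivergence, self.loss):
            if v < 0:
                raise ValueError("costs must be nonnegative")


@dataclass
class Reconciliation:
    """Event-annotated embedding of a gene tree into a species tree."""

    events: dict          # gene node -> event name ("codivergence"|"duplication"|"transfer"|"leaf")
    mapping: dict         # gene node -> species node
    duplications: int
    transfers: int
    codivergences: int
    losses: int
    total_cost: float

    def counts(self) -> dict[str, int]:
        return {
            "duplications": self.duplications,
            "transfers": self.transfers,
            "codivergences": self.codivergences,
            "losses": self.losses,
        }


DEFAULT_RANKS = ("species", "genus", "family", "order", "class", "phylum", "kingdom")


def collapse_to_ranks(
    species_tree: dendropy.Tree,
    rank_map: dict[str, str],
    retained: tuple[str, ...] = DEFAULT_RANKS,
) -> dendropy.Tree:
    """Contract internal nodes whose rank is not in the retained set.

    ``rank_map`` maps internal-node labels to ranks; unlabeled/unranked
    internal nodes are contracted. The leaf set is unchanged; a root left
    with a single child is suppressed.
    """
    tree = read_newick(write_newick(species_tree))  # work on a clone
    retained_set = set(retained)
    for node in list(tree.postorder_internal_node_iter()):
        if node is tree.seed_node:
            continue
        rank = rank_map.get(node.label) if node.label is not None else None
        if rank not in retained_set:
            node.edge.collapse()
    root = tree.seed_node
    while len(root.child_nodes()) == 1 and not root.child_nodes()[0].is_leaf():
        only = root.child_nodes()[0]
        root.remove_child(only)
        for gc in list(only.child_nodes()):
            only.remove_child(gc)
            root.add_child(gc)
        if only.label is not None and root.label is None:
            root.label = only.label
    return tree


# ---------------------------------------------------------------------------
# species-tree indexing helpers
# ---------------------------------------------------------------------------


class _SpeciesIndex:
    """Postorder-indexed species tree with ancestry/distance tables."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.postorder_node_iter())
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.leaf_index = {
            n.taxon.label: self.index[n] for n in self.nodes if n.is_leaf()
        }
        self.children = [
            [self.index[c] for c in n.child_nodes()] for n in self.nodes
        ]
        self.parent = [
            self.index[n.parent_node] if n.parent_node is not None else -1
            for n in self.nodes
        ]
        self.root = self.index[tree.seed_node]
        # ancestor_or_equal[a][d]: a is on the path from root to d
        self.anc = [[False] * self.n for _ in range(self.n)]
        self.depth = [0] * self.n
        for i, node in enumerate(self.nodes):
            j = i
            d = 0
            while j != -1:
                self.anc[j][i] = True
                j = self.parent[j]
                d += 1
            self.depth[i] = d - 1
        self.comparable = [
            [self.anc[a][b] or self.anc[b][a] for b in range(self.n)]
            for a in range(self.n)
        ]
        self.incomparable = [
            [b for b in range(self.n) if not self.comparable[a][b]]
            for a in range(self.n)
        ]

    def dist(self, anc: int, desc: int) -> int:
        """Edge count from ancestor to descendant (0 if equal)."""
        if not self.anc[anc][desc]:
            raise ValueError("dist() needs an ancestor/descendant pair")
        return self.depth[desc] - self.depth[anc]

    def lca(self, a: int, b: int) -> int:
        while not (self.anc[a][b]):
            a = self.parent[a]
        return a

    def label(self, i: int) -> str:
        n = self.nodes[i]
        return n.taxon.label if n.is_leaf() else (n.label or f"node{i}")


def resolve_gene_leaf(label: str, species_labels: set[str],
                      leaf_map: dict[str, str] | None = None) -> str:
    """Species for a gene leaf: explicit map, exact label, else the prefix
    before the last underscore."""
    if leaf_map and label in leaf_map:
        return leaf_map[label]
    if label in species_labels:
        return label
    prefix = label.rsplit("_", 1)[0]
    if prefix in species_labels:
        return prefix
    raise ValueError(f"cannot resolve gene leaf {label!r} to a species")


def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: dict[str, str] | None = None,
) -> dict[dendropy.Node, dendropy.Node]:
    """Map each gene node to the species LCA of its leaf descendants."""
    sidx = _SpeciesIndex(species_tree)
    species_labels = set(sidx.leaf_index)
    out_idx: dict[dendropy.Node, int] = {}
    for g in gene_tree.postorder_node_iter():
        if g.is_leaf():
            sp = resolve_gene_leaf(g.taxon.label, species_labels, leaf_map)
            out_idx[g] = sidx.leaf_index[sp]
        else:
            acc = None
            for c in g.child_nodes():
                acc = out_idx[c] if acc is None else sidx.lca(acc, out_idx[c])
            out_idx[g] = acc
    return {g: sidx.nodes[i] for g, i in out_idx.items()}


def reconcile_dl(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    costs: ReconciliationCosts = ReconciliationCosts(),
    leaf_map: dict[str, str] | None = None,
) -> Reconciliation:
    """LCA duplication-loss reconciliation (no transfers).

    A gene node is a duplication iff its species image equals the image of
    at least one child; losses follow the standard path-depth rule.
    """
    sidx = _SpeciesIndex(species_tree)
    mapping = lca_map(gene_tree, species_tree, leaf_map)
    midx = {g: sidx.index[s] for g, s in mapping.items()}
    events: dict = {}
    dups = codivs = losses = 0
    for g in gene_tree.postorder_node_iter():
        if g.is_leaf():
            events[g] = "leaf"
            continue
        children = g.child_nodes()
        is_dup = any(midx[c] == midx[g] for c in children)
        events[g] = "duplication" if is_dup else "codivergence"
        if is_dup:
            dups += 1
        else:
            codivs += 1
        for c in children:
            d = sidx.dist(midx[g], midx[c])
            losses += d if is_dup else max(0, d - 1)
    total = (dups * costs.duplication + codivs * costs.codivergence
             + losses * costs.loss)
    return Reconciliation(events, mapping, dups, 0, codivs, losses, total)


# ---------------------------------------------------------------------------
# DTL dynamic program
# ---------------------------------------------------------------------------


def reconcile_dtl(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    costs: ReconciliationCosts = ReconciliationCosts(),
    leaf_map: dict[str, str] | None = None,
) -> Reconciliation:
    """Minimum-cost DTL reconciliation (undated species tree).

    Dynamic program over gene nodes x species nodes minimizing the sum of
    event costs plus loss cost times loss count; transfers are allowed
    only between non-ancestrally-related species lineages. The gene tree
    must be binary. Tie-breaking is total and deterministic, so event
    counts are reproducible run to run.
    """
    for g in gene_tree.preorder_internal_node_iter():
        if len(g.child_nodes()) != 2:
            raise ValueError("DTL reconciliation requires a binary gene tree")
    sidx = _SpeciesIndex(species_tree)
    species_labels = set(sidx.leaf_index)
    ns = sidx.n
    gene_nodes = list(gene_tree.postorder_node_iter())

    C: dict[dendropy.Node, list[float]] = {}      # cost with g mapped exactly at s
    IN: dict[dendropy.Node, list[float]] = {}     # cost with g mapped at or below s
    cptr: dict[dendropy.Node, list] = {}          # backpointer for C
    inptr: dict[dendropy.Node, list] = {}         # backpointer for IN

    # event preference for ties: codivergence < duplication < transfer
    _PREF = {"codivergence": 0, "duplication": 1, "transfer": 2, "leaf": 0}

    for g in gene_nodes:
        c_row = [INF] * ns
        c_bp = [None] * ns
        if g.is_leaf():
            sp = resolve_gene_leaf(g.taxon.label, species_labels, leaf_map)
            si = sidx.leaf_index[sp]
            c_row[si] = 0.0
            c_bp[si] = ("leaf",)
        else:
            g1, g2 = g.child_nodes()
            in1, in2 = IN[g1], IN[g2]
            # cheapest IN over species incomparable with s, per child
            best_inc1 = [
                min(((in1[t], t) for t in sidx.incomparable[s]), default=(INF, -1))
                for s in range(ns)
            ]
            best_inc2 = [
                min(((in2[t], t) for t in sidx.incomparable[s]), default=(INF, -1))
                for s in range(ns)
            ]
            for s in range(ns):
                options = []  # (cost, pref, tiebreak, bp)
                kids = sidx.children[s]
                if kids:
                    for a, b in itertools.permutations(kids, 2):
                        cost = costs.codivergence + in1[a] + in2[b]
                        options.append((cost, 0, (a, b),
                                        ("codivergence", (g1, a), (g2, b))))
                cost = costs.duplication + in1[s] + in2[s]
                options.append((cost, 1, (s, s), ("duplication", (g1, s), (g2, s))))
                t1_cost, t1 = best_inc2[s]
                if t1 >= 0:
                    cost = costs.transfer + in1[s] + t1_cost
                    options.append((cost, 2, (s, t1),
                                    ("transfer", (g1, s), (g2, t1))))
                t2_cost, t2 = best_inc1[s]
                if t2 >= 0:
                    cost = costs.transfer + in2[s] + t2_cost
                    options.append((cost, 2, (t2, s),
                                    ("transfer", (g1, t2), (g2, s))))
                best = min(options, key=lambda o: (o[0], o[1], o[2]))
                if best[0] < INF:
                    c_row[s] = best[0]
                    c_bp[s] = best[3]
        C[g] = c_row
        cptr[g] = c_bp
        in_row = [INF] * ns
        in_bp = [None] * ns
        for s in range(ns):  # postorder: children before parents
            best_cost, best_bp = c_row[s], ("here",)
            for child in sidx.children[s]:
                cand = costs.loss + in_row[child]
                if cand < best_cost:  # ties prefer mapping here (fewer losses)
                    best_cost, best_bp = cand, ("descend", child)
            in_row[s] = best_cost
            in_bp[s] = best_bp
        IN[g] = in_row
        inptr[g] = in_bp

    root = gene_tree.seed_node
    best_s = min(range(ns), key=lambda s: (C[root][s], s))
    total = C[root][best_s]
    if total == INF:
        raise ValueError("no feasible reconciliation")

    events: dict = {}
    mapping: dict = {}
    counts = {"duplication": 0, "transfer": 0, "codivergence": 0, "loss": 0}

    def trace_in(g: dendropy.Node, s: int) -> None:
        """Follow the IN chain from s down to g's exact mapping."""
        while True:
            bp = inptr[g][s]
            if bp[0] == "here":
                trace_c(g, s)
                return
            counts["loss"] += 1
            s = bp[1]

    def trace_c(g: dendropy.Node, s: int) -> None:
        bp = cptr[g][s]
        mapping[g] = sidx.nodes[s]
        if bp[0] == "leaf":
            events[g] = "leaf"
            return
        events[g] = bp[0]
        counts[bp[0]] += 1
        for child, target in bp[1:]:
            trace_in(child, target)

    trace_c(root, best_s)
    return Reconciliation(
        events, mapping,
        counts["duplication"], counts["transfer"], counts["codivergence"],
        counts["loss"], total,
    )


def reconciliation_newick(gene_tree: dendropy.Tree, recon: Reconciliation) -> str:
    """Gene tree serialized with event tags (D/T/S) as internal labels."""
    tag = {"duplication": "D", "transfer": "T", "codivergence": "S"}
    clone = read_newick(write_newick(gene_tree))
    # align clones by leaf-set-identical traversal order
    for orig, copy in zip(gene_tree.postorder_node_iter(), clone.postorder_node_iter()):
        ev = recon.events.get(orig)
        if ev in tag:
            copy.label = tag[ev]
    return write_newick(clone)


# ---------------------------------------------------------------------------
# support-driven rearrangement
# ---------------------------------------------------------------------------


def _to_structure(node: dendropy.Node):
    if node.is_leaf():
        return node.taxon.label
    return tuple(_to_structure(c) for c in node.child_nodes())


def _structure_newick(struct) -> str:
    if isinstance(struct, str):
        return struct
    return "(" + ",".join(_structure_newick(c) for c in struct) + ")"


def _caterpillar(items: tuple):
    out = items[0]
    for nxt in items[1:]:
        out = (out, nxt)
    return out


def _resolve_all_canonical(struct):
    if isinstance(struct, str):
        return struct
    kids = tuple(_resolve_all_canonical(c) for c in struct)
    if len(kids) <= 2:
        return kids
    return _caterpillar(kids)


def _binary_shapes(items: tuple):
    """All rooted binary topologies over the given subtree list."""
    if len(items) == 1:
        yield items[0]
        return
    if len(items) == 2:
        yield (items[0], items[1])
        return
    first, rest = items[0], items[1:]
    for shape in _binary_shapes(rest):
        for edited in _insert_everywhere(shape, first):
            yield edited


def _insert_everywhere(shape, item):
    yield (item, shape)
    if not isinstance(shape, str):
        a, b = shape
        for ea in _insert_everywhere(a, item):
            yield (ea, b)
        for eb in _insert_everywhere(b, item):
            yield (a, eb)


def _find_polytomy(struct, path=()):
    """Path (child-index tuple) of the deepest-first polytomy, or None."""
    if isinstance(struct, str):
        return None
    for i, child in enumerate(struct):
        found = _find_polytomy(child, path + (i,))
        if found is not None:
            return found
    if len(struct) > 2:
        return path
    return None


def _get_at(struct, path):
    for i in path:
        struct = struct[i]
    return struct


def _set_at(struct, path, value):
    if not path:
        return value
    return tuple(
        _set_at(c, path[1:], value) if i == path[0] else c
        for i, c in enumerate(struct)
    )


def rearrange_weak_edges(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    costs: ReconciliationCosts = ReconciliationCosts(),
    support_threshold: float = 98.0,
    leaf_map: dict[str, str] | None = None,
    exhaustive_max_degree: int = 6,
) -> dendropy.Tree:
    """Collapse weakly supported edges and re-resolve to minimize DTL cost.

    Internal edges with support below ``support_threshold`` are collapsed
    into polytomies; each polytomy is then re-resolved — exhaustively over
    all rooted binary shapes for degree <= ``exhaustive_max_degree``, by
    stepwise best join above — scoring every candidate by the DTL cost of
    the full tree (any not-yet-resolved polytomies caterpillar-resolved
    for scoring). The returned tree is binary, carries topology only
    (supports are meaningless after rearrangement), and never costs more
    than the input tree.
    """
    orig_cost = reconcile_dtl(gene_tree, species_tree, costs, leaf_map).total_cost
    work = read_newick(write_newick(gene_tree))
    for node in list(work.postorder_internal_node_iter()):
        if node is work.seed_node:
            continue
        sup = node_support(node)
        if sup is not None and sup < support_threshold:
            node.edge.collapse()
    struct = _to_structure(work.seed_node)

    def full_cost(s) -> float:
        tree = read_newick(_structure_newick(_resolve_all_canonical(s)) + ";")
        return reconcile_dtl(tree, species_tree, costs, leaf_map).total_cost

    while True:
        path = _find_polytomy(struct)
        if path is None:
            break
        kids = _get_at(struct, path)
        if len(kids) <= exhaustive_max_degree:
            best = None
            for shape in _binary_shapes(kids):
                c = full_cost(_set_at(struct, path, shape))
                if best is None or c < best[0]:
                    best = (c, shape)
            struct = _set_at(struct, path, best[1])
        else:
            items = list(kids)
            while len(items) > 2:
                best = None
                for i in range(len(items)):
                    for j in range(i + 1, len(items)):
                        trial = [it for k, it in enumerate(items) if k not in (i, j)]
                        trial.append((items[i], items[j]))
                        c = full_cost(_set_at(struct, path, _caterpillar(tuple(trial))))
                        if best is None or c < best[0]:
                            best = (c, i, j)
                _, i, j = best
                joined = (items[i], items[j])
                items = [it for k, it in enumerate(items) if k not in (i, j)]
                items.append(joined)
            struct = _set_at(struct, path, (items[0], items[1]))

    final_tree = read_newick(_structure_newick(struct) + ";")
    final_cost = reconcile_dtl(final_tree, species_tree, costs, leaf_map).total_cost
    if final_cost > orig_cost:
        return read_newick(write_newick(gene_tree))
    return final_tree
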