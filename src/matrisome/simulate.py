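"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters plus a single integer
seed, and returns its dataset together with a :class:`PlantedTruth` record
sufficient to score the downstream estimator without re-reading simulator
internals.

The codon simulator is an acceptance-rejection scheme, not a named ML
model: single-nucleotide changes are proposed with transition:transversion
weight kappa:1, changes creating stop codons are rejected, nonsynonymous
changes are accepted with probability min(1, omega) and synonymous changes
with probability min(1, 1/omega), so the accepted nonsynonymous:synonymous
rate ratio equals omega over the whole range omega >= 0. Branch lengths
are expected accepted substitutions per codon site.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .genetic_code import NUCLEOTIDES, SENSE_CODONS, is_stop, translate_codon
from .io import CodonAlignment, SequenceRecord, read_newick, validate_codon_alignment

AA20 = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"


@dataclass(frozen=True)
class PlantedTruth:
    """True parameters / event counts planted by a simulator run."""

    kind: str
    params: dict

    def as_dict(self) -> dict:
        return {"kind": self.kind, **self.params}


@dataclass(frozen=True)
class CodonSimSpec:
    """Specification for codon-alignment simulation along a tree.

    ``tree`` carries branch lengths in expected accepted substitutions per
    codon site; ``omega`` is the target dN/dS; ``kappa`` the
    transition/transversion proposal bias.
    """

    tree: dendropy.Tree
    omega: float
    kappa: float
    n_codons: int
    seed: int

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _evolve_branch(codons: list[str], t: float, omega: float, kappa: float,
                   rng: np.random.Generator) -> list[str]:
    """Apply Poisson(t * n_codons) accepted substitutions via rejection
    sampling of kappa-weighted single-nucleotide proposals."""
    codons = list(codons)
    n = len(codons)
    k_events = rng.poisson(t * n)
    p_nonsyn = min(1.0, omega)
    p_syn = 1.0 if omega == 0 else min(1.0, 1.0 / omega)
    for _ in range(k_events):
        for _attempt in range(100000):
            site = rng.integers(n)
            pos = rng.integers(3)
            cur = codons[site]
            old = cur[pos]
            # transition gets weight kappa, each transversion weight 1
            u = rng.random() * (kappa + 2.0)
            if u < kappa:
                new = _TRANSITION_OF[old]
            else:
                tvs = [x for x in NUCLEOTIDES if x != old and x != _TRANSITION_OF[old]]
                new = tvs[0] if u < kappa + 1.0 else tvs[1]
            cand = cur[:pos] + new + cur[pos + 1:]
            if is_stop(cand):
                continue
            syn = translate_codon(cand) == translate_codon(cur)
            accept_p = p_syn if syn else p_nonsyn
            if accept_p >= 1.0 or rng.random() < accept_p:
                codons[site] = cand
                break
        else:
            raise RuntimeError("no acceptable substitution found")
    return codons


def simulate_codon_alignment(spec: CodonSimSpec) -> tuple[CodonAlignment, PlantedTruth]:
    """Markov-simulate a gap-free codon alignment along ``spec.tree``.

    The root sequence is drawn uniformly from sense codons; the same spec
    and seed reproduce the alignment byte for byte.
    """
    leaves = spec.tree.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = np.random.default_rng(spec.seed)
    root_codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=spec.n_codons)]
    seqs: dict[str, str] = {}
    state: dict[dendropy.Node, list[str]] = {spec.tree.seed_node: root_codons}
    branch_lengths: dict[str, float] = {}
    for node in spec.tree.preorder_node_iter():
        if node is spec.tree.seed_node:
            continue
        t = node.edge.length if node.edge.length is not None else 0.0
        state[node] = _evolve_branch(state[node.parent_node], t, spec.omega, spec.kappa, rng)
        if node.is_leaf():
            seqs[node.taxon.label] = "".join(state[node])
            branch_lengths[node.taxon.label] = t
    records = [SequenceRecord(lbl, "", seqs[lbl]) for lbl in sorted(seqs)]
    aln = validate_codon_alignment(records)
    truth = PlantedTruth("codon_alignment", {
        "omega": spec.omega, "kappa": spec.kappa, "n_codons": spec.n_codons,
        "seed": spec.seed, "terminal_branch_lengths": branch_lengths,
    })
    return aln, truth


def simulate_family_counts(
    n_families: int,
    proteomes: list[str],
    focal_id: str,
    expanded: dict[str, int],
    background_mean: float,
    seed: int,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Family x proteome count matrix with planted focal expansions.

    Non-focal counts (and unplanted focal counts) are Poisson draws with
    the stated mean; planted families receive their planted count in the
    focal column exactly. Family ids are ``fam0001`` .. and planted family
    names may be given directly as such ids or as integer indices.
    """
    if focal_id not in proteomes:
        raise ValueError(f"focal proteome {focal_id!r} not in proteome list")
    if background_mean <= 0:
        raise ValueError("background_mean must be positive")
    if any(v < 0 for v in expanded.values()):
        raise ValueError("planted counts must be nonnegative")
    rng = np.random.default_rng(seed)
    families = [f"fam{i + 1:04d}" for i in range(n_families)]
    counts = rng.poisson(background_mean, size=(n_families, len(proteomes)))
    df = pd.DataFrame(counts, index=families, columns=proteomes)
    planted = {}
    for fam, cnt in expanded.items():
        fam_id = families[fam] if isinstance(fam, int) else fam
        if fam_id not in df.index:
            raise ValueError(f"unknown family {fam!r}")
        df.loc[fam_id, focal_id] = cnt
        planted[fam_id] = cnt
    truth = PlantedTruth("family_counts", {
        "focal_id": focal_id, "background_mean": background_mean,
        "expanded": planted, "seed": seed,
    })
    return df, truth


# ---------------------------------------------------------------------------
# Gene-tree simulation with duplication, transfer, loss
# ---------------------------------------------------------------------------


class _GeneNode:
    __slots__ = ("kind", "children", "species", "alive")

    def __init__(self, kind: str, species=None):
        self.kind = kind          # speciation | duplication | transfer | leaf | loss
        self.children: list[_GeneNode] = []
        self.species = species
        self.alive = False


def _species_edges(tree: dendropy.Tree):
    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    ancestors: dict[dendropy.Node, set[dendropy.Node]] = {}
    for n in nodes:
        anc = set()
        p = n.parent_node
        while p is not None:
            anc.add(p)
            p = p.parent_node
        ancestors[n] = anc
    incomparable = {
        n: [m for m in nodes if m is not n and m not in ancestors[n] and n not in ancestors[m]]
        for n in nodes
    }
    return nodes, incomparable


def simulate_gene_tree(
    species_tree: dendropy.Tree,
    dup_rate: float,
    transfer_rate: float,
    loss_rate: float,
    seed: int,
    max_retries: int = 50,
) -> tuple[dendropy.Tree, PlantedTruth]:
    """Forward birth-death-with-transfer simulation down a species tree.

    Surviving gene lineages become leaves labeled ``<species>_<copy#>``.
    The truth records event counts on the *surviving* history: a
    duplication or transfer counts only when both resulting lineages leave
    surviving descendants; a loss counts when it is visible against a
    surviving sibling context. Transfer recipients are drawn uniformly
    among species branches incomparable to the donor branch (undated
    convention), the transferred copy restarting at the recipient's top.
    """
    for rate in (dup_rate, transfer_rate, loss_rate):
        if rate < 0:
            raise ValueError("rates must be nonnegative")
    _, incomparable = _species_edges(species_tree)

    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        root = _GeneNode("speciation", species_tree.seed_node)
        total = dup_rate + transfer_rate + loss_rate

        def run_branch(gnode: _GeneNode, snode: dendropy.Node, t_left: float) -> _GeneNode:
            """Evolve one lineage along the species branch ending at snode."""
            while total > 0:
                wait = rng.exponential(1.0 / total)
                if wait >= t_left:
                    break
                t_left -= wait
                u = rng.random() * total
                if u < loss_rate:
                    return _GeneNode("loss", snode)
                if u < loss_rate + dup_rate:
                    dup = _GeneNode("duplication", snode)
                    dup.children.append(run_branch(dup, snode, t_left))
                    dup.children.append(run_branch(dup, snode, t_left))
                    return dup
                # transfer
                options = incomparable[snode]
                if not options:
                    continue  # nowhere to go; event has no effect
                recipient = options[rng.integers(len(options))]
                tr = _GeneNode("transfer", snode)
                tr.children.append(run_branch(tr, snode, t_left))
                r_len = recipient.edge.length if recipient.edge.length is not None else 1.0
                tr.children.append(run_branch(tr, recipient, r_len))
                return tr
            # reached the bottom of the species branch
            if snode.is_leaf():
                return _GeneNode("leaf", snode)
            spec_node = _GeneNode("speciation", snode)
            for child in snode.child_nodes():
                c_len = child.edge.length if child.edge.length is not None else 1.0
                spec_node.children.append(run_branch(spec_node, child, c_len))
            return spec_node

        for child in species_tree.seed_node.child_nodes():
            c_len = child.edge.length if child.edge.length is not None else 1.0
            root.children.append(run_branch(root, child, c_len))

        def mark(node: _GeneNode) -> bool:
            if node.kind == "leaf":
                node.alive = True
                return True
            if node.kind == "loss":
                node.alive = False
                return False
            results = [mark(c) for c in node.children]
            node.alive = any(results)
            return node.alive

        mark(root)
        if not root.alive:
            continue

        counts = {"duplication": 0, "transfer": 0, "loss": 0}

        def count_events(node: _GeneNode) -> None:
            if node.kind == "duplication":
                # visible only when both copies leave descendants
                if all(c.alive for c in node.children):
                    counts["duplication"] += 1
            elif node.kind == "transfer":
                # the species jump is part of the surviving history
                # whenever the transferred copy survives
                if node.children[1].alive:
                    counts["transfer"] += 1
            if node.kind in ("duplication", "transfer", "speciation"):
                dead = [c for c in node.children if not c.alive]
                live = [c for c in node.children if c.alive]
                if live:
                    counts["loss"] += len(dead)
            for c in node.children:
                count_events(c)

        count_events(root)

        # prune dead lineages, contract single-child nodes, label leaves
        copy_counter: dict[str, int] = {}

        def prune(node: _GeneNode):
            if node.kind == "leaf":
                sp = node.species.taxon.label
                copy_counter[sp] = copy_counter.get(sp, 0) + 1
                return f"{sp}_{copy_counter[sp]}"
            live = [c for c in node.children if c.alive]
            subs = [prune(c) for c in live]
            if len(subs) == 1:
                return subs[0]
            return "(" + ",".join(subs) + ")"

        newick = prune(root)
        if "(" not in newick:
            continue  # single surviving lineage: not a usable gene tree
        gene_tree = read_newick(newick + ";")
        truth = PlantedTruth("gene_tree", {
            "dup_rate": dup_rate, "transfer_rate": transfer_rate,
            "loss_rate": loss_rate, "seed": seed,
            "duplications": counts["duplication"],
            "transfers": counts["transfer"],
            "losses": counts["loss"],
        })
        return gene_tree, truth
    raise RuntimeError(
        f"gene family went extinct in all {max_retries} attempts"
    )


def simulate_peptides(
    motif: dict[int, str],
    n_fore: int,
    n_back: int,
    background_freqs: dict[str, float] | None = None,
    width: int = 13,
    central_residue: str = "S",
    fraction: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], list[str], PlantedTruth]:
    """Foreground/background peptide windows with a planted motif.

    Windows are strings of odd ``width`` centered on ``central_residue``
    (one of S/T/Y); flanks are i.i.d. draws from ``background_freqs``
    (uniform over the 20 amino acids by default). The motif maps offsets in
    [-halfwidth, +halfwidth] to residues and is written into a ``fraction``
    of foreground windows; offset 0, if present, must be an S/T/Y and
    overrides ``central_residue``.
    """
    if width % 2 == 0 or width < 3:
        raise ValueError("width must be odd and >= 3")
    half = width // 2
    if 0 in motif:
        if motif[0] not in "STY":
            raise ValueError("central motif residue must be one of S, T, Y")
        central_residue = motif[0]
    if central_residue not in "STY":
        raise ValueError("central residue must be one of S, T, Y")
    if any(abs(pos) > half for pos in motif):
        raise ValueError(f"motif positions must lie within +/-{half}")
    if background_freqs is None:
        background_freqs = {aa: 1.0 / len(AA20) for aa in AA20}
    aas = sorted(background_freqs)
    probs = np.array([background_freqs[a] for a in aas], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)

    def draw(n: int) -> list[str]:
        mat = rng.choice(len(aas), size=(n, width), p=probs)
        out = []
        for row in mat:
            chars = [aas[i] for i in row]
            chars[half] = central_residue
            out.append("".join(chars))
        return out

    back = draw(n_back)
    fore = draw(n_fore)
    n_planted = int(round(fraction * n_fore))
    planted_idx = rng.choice(n_fore, size=n_planted, replace=False) if n_planted else []
    for i in planted_idx:
        chars = list(fore[i])
        for pos, res in motif.items():
            chars[half + pos] = res
        fore[i] = "".join(chars)
    truth = PlantedTruth("peptides", {
        "motif": dict(motif), "fraction": fraction, "seed": seed,
        "central_residue": central_residue, "n_fore": n_fore, "n_back": n_back,
    })
    return fore, back, truth
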