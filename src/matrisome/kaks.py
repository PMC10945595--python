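"""Pairwise and per-branch synonymous/nonsynonymous divergence (NG86 style).

The estimator counts potential synonymous (S) and nonsynonymous (N) sites
per codon from its single-nucleotide mutational neighborhood, counts
observed synonymous (Sd) and nonsynonymous (Sn) differences by averaging
over all equally weighted stop-free substitution pathways between codon
pairs, converts the proportions ps = Sd/S and pn = Sn/N to distances with
the Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p), and
reports the selection-pressure ratio omega = dN/dS.

Quality filters mirror standard practice for desk-scale comparative
datasets: pairs with omega > 10, dS < 0.01, or dS or dN > 3 are discarded
(inaccurate or saturated estimates), and alignment rows with more than 30%
gaps or ambiguous sites are dropped before estimation.

Per-branch estimates reconstruct ancestral sequences column-wise by Fitch
parsimony and score each terminal branch as a tip-vs-parent pairwise
comparison (a Miyamoto-Fitch-style ancestral-inference approach).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import dendropy

from .genetic_code import NUCLEOTIDES, is_stop, is_transition, translate_codon
from .io import CodonAlignment, SequenceRecord


class SaturationError(ValueError):
    """Observed proportion at or beyond the Jukes-Cantor domain (p >= 0.75)."""


@dataclass(frozen=True)
class KaKsEstimate:
    """All NG86 quantities for one sequence pair (or tip-vs-ancestor pair).

    Sd/Sn are observed synonymous/nonsynonymous substitutions; S/N are
    potential sites averaged over the two sequences; ps = Sd/S, pn = Sn/N;
    dS/dN are their Jukes-Cantor corrections; omega = dN/dS. dS, dN, or
    omega are NaN when saturated or undefined, with the matching flag set.
    """

    id_a: str
    id_b: str
    Sd: float
    Sn: float
    S: float
    N: float
    ps: float
    pn: float
    dS: float
    dN: float
    omega: float
    codons_compared: int
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class DivergenceRate:
    """Silent-site divergence rate mu = dS / (2 T) per site per year."""

    group_id: str
    dS_mean: float
    T_years: float
    mu: float


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Transition/transversion and silent/nonsilent counts vs a master."""

    master_id: str
    query_id: str
    transitions: int
    transversions: int
    silent: int
    nonsilent: int
    indels: int


def count_sites(codon: str, include_stop_neighbors: bool = False) -> tuple[float, float]:
    """Potential synonymous (s) and nonsynonymous (n) sites of a sense codon.

    At each position the synonymous fraction is counted among the three
    single-nucleotide neighbors; by default neighbors that are stop codons
    are excluded from the denominator at that position (mutational-
    opportunity convention). Always returns s + n = 3.
    """
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if any(c not in NUCLEOTIDES for c in codon):
        raise ValueError(f"ambiguous codon {codon!r}")
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        denom = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1:]
            if is_stop(nb) and not include_stop_neighbors:
                continue
            denom += 1
            if not is_stop(nb) and translate_codon(nb) == aa:
                syn += 1
        if denom:
            s += syn / denom
    return s, 3.0 - s


def _pathway_counts(a: str, b: str) -> tuple[float, float]:
    """Observed synonymous/nonsynonymous counts between two sense codons,
    averaged over equally weighted substitution pathways.

    Pathways passing through stop codons are excluded; in the degenerate
    case where every pathway hits a stop, all pathways are averaged
    (with a warning) so the codon pair still contributes its differences.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    stopfree: list[tuple[int, int]] = []
    allpaths: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = a
        syn = nsyn = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if is_stop(nxt):
                hit_stop = True
            if not is_stop(cur) and not is_stop(nxt) and translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        allpaths.append((syn, nsyn))
        if not hit_stop:
            stopfree.append((syn, nsyn))
    paths = stopfree
    if not paths:
        warnings.warn(
            f"all substitution pathways between {a} and {b} pass through "
            "stop codons; averaging over all pathways",
            stacklevel=2,
        )
        paths = allpaths
    sd = sum(p[0] for p in paths) / len(paths)
    sn = sum(p[1] for p in paths) / len(paths)
    return sd, sn


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Raises :class:`SaturationError` for p >= 0.75 (outside the domain);
    estimates built on such proportions carry a ``saturated`` flag instead
    of a silently capped value.
    """
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 0.75: distance saturated")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _comparable_codons(res_a: str, res_b: str):
    """Yield (codon_a, codon_b) for in-frame positions where both codons are
    unambiguous sense codons (gapped/ambiguous/stop codons are skipped)."""
    n = min(len(res_a), len(res_b)) // 3
    for i in range(n):
        ca = res_a[3 * i: 3 * i + 3]
        cb = res_b[3 * i: 3 * i + 3]
        if any(c not in NUCLEOTIDES for c in ca + cb):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        yield ca, cb


def pairwise_ng86(seq_a: SequenceRecord, seq_b: SequenceRecord,
                  include_stop_neighbors: bool = False) -> KaKsEstimate:
    """NG86 pairwise estimate for two equal-length in-frame sequences.

    Codons containing gaps or ambiguity in either sequence are skipped.
    S and N are averaged over the two sequences; multi-position codon
    differences average over all stop-free substitution pathways.
    """
    if len(seq_a.residues) != len(seq_b.residues):
        raise ValueError(
            f"sequences {seq_a.id!r}/{seq_b.id!r} differ in length"
        )
    Sd = Sn = 0.0
    s_a = n_a = s_b = n_b = 0.0
    codons = 0
    for ca, cb in _comparable_codons(seq_a.residues, seq_b.residues):
        codons += 1
        sa, na = count_sites(ca, include_stop_neighbors)
        sb, nb = count_sites(cb, include_stop_neighbors)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sd, sn = _pathway_counts(ca, cb)
        Sd += sd
        Sn += sn
    if codons == 0:
        raise ValueError(
            f"no comparable codons between {seq_a.id!r} and {seq_b.id!r}"
        )
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    ps = Sd / S if S > 0 else 0.0
    pn = Sn / N if N > 0 else 0.0
    flags: set[str] = set()
    nan = float("nan")
    try:
        dS = jc_correct(ps)
    except SaturationError:
        dS = nan
        flags.add("saturated")
    try:
        dN = jc_correct(pn)
    except SaturationError:
        dN = nan
        flags.add("saturated")
    if dS == 0.0 or math.isnan(dS):
        omega = nan
        if dS == 0.0:
            flags.add("omega_undefined")
    else:
        omega = dN / dS
    return KaKsEstimate(
        id_a=seq_a.id, id_b=seq_b.id, Sd=Sd, Sn=Sn, S=S, N=N, ps=ps, pn=pn,
        dS=dS, dN=dN, omega=omega, codons_compared=codons,
        flags=frozenset(flags),
    )


def all_pairwise(alignment: CodonAlignment) -> list[KaKsEstimate]:
    """NG86 estimates for every unordered member pair of an alignment."""
    out = []
    members = alignment.members
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            out.append(pairwise_ng86(members[i], members[j]))
    return out


# Discard rules, checked in this order; first match is the recorded reason.
_FILTER_RULES = ("omega>10", "dS<0.01", "dS>3", "dN>3", "omega_undefined")


def filter_estimates(
    estimates,
    omega_max: float = 10.0,
    ds_min: float = 0.01,
    ds_max: float = 3.0,
    dn_max: float = 3.0,
):
    """Split estimates into (kept, discarded-with-reason).

    Discards pairs with omega > 10, dS < 0.01, dS > 3, or dN > 3, plus
    undefined-omega pairs; saturated distances count against the ds/dn
    ceilings they exceeded by construction.
    """
    kept: list[KaKsEstimate] = []
    discarded: list[tuple[KaKsEstimate, str]] = []
    for est in estimates:
        reason = None
        ds_bad_high = (not math.isnan(est.dS) and est.dS > ds_max) or (
            "saturated" in est.flags and est.ps >= 0.75)
        dn_bad_high = (not math.isnan(est.dN) and est.dN > dn_max) or (
            "saturated" in est.flags and est.pn >= 0.75)
        if not math.isnan(est.omega) and est.omega > omega_max:
            reason = "omega>10"
        elif not math.isnan(est.dS) and est.dS < ds_min:
            reason = "dS<0.01"
        elif ds_bad_high:
            reason = "dS>3"
        elif dn_bad_high:
            reason = "dN>3"
        elif "omega_undefined" in est.flags or math.isnan(est.omega):
            reason = "omega_undefined"
        if reason is None:
            kept.append(est)
        else:
            discarded.append((est, reason))
    return kept, discarded


def filter_alignment_members(
    alignment: CodonAlignment, max_gap_frac: float = 0.30
) -> tuple[CodonAlignment, list[str]]:
    """Drop rows whose gap+ambiguity fraction strictly exceeds the cutoff.

    Returns the filtered alignment and the removed member ids.
    """
    kept = []
    removed = []
    for m in alignment.members:
        frac = sum(1 for c in m.residues if c in "-N") / len(m.residues)
        if frac > max_gap_frac:
            removed.append(m.id)
        else:
            kept.append(m)
    if not kept:
        raise ValueError("gap filter removed every alignment member")
    return CodonAlignment(tuple(kept), alignment.length,
                          alignment.flagged & frozenset(k.id for k in kept)), removed


def silent_rate(dS_mean: float, T_years: float, group_id: str = "") -> DivergenceRate:
    """Absolute silent-site divergence rate mu = dS / (2 T) per site/year."""
    if T_years <= 0:
        raise ValueError("divergence time T must be positive")
    if dS_mean < 0:
        raise ValueError("mean dS must be nonnegative")
    return DivergenceRate(group_id, dS_mean, T_years, dS_mean / (2.0 * T_years))


# ---------------------------------------------------------------------------
# Per-branch estimates via Fitch parsimony ancestral reconstruction
# ---------------------------------------------------------------------------

_FULL = frozenset(NUCLEOTIDES)


def _fitch_up(tree: dendropy.Tree, sequences: dict[str, str], length: int):
    """Fitch up-pass state sets per node per column; gaps/ambiguity act as
    wildcards."""
    sets: dict[dendropy.Node, list[frozenset[str]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            seq = sequences[node.taxon.label]
            sets[node] = [
                frozenset(seq[i]) if seq[i] in NUCLEOTIDES else _FULL
                for i in range(length)
            ]
        else:
            children = node.child_nodes()
            cols = []
            for i in range(length):
                inter = frozenset.intersection(*(sets[c][i] for c in children))
                if inter:
                    cols.append(inter)
                else:
                    cols.append(frozenset.union(*(sets[c][i] for c in children)))
            sets[node] = cols
    return sets


def branch_estimates(alignment: CodonAlignment, tree: dendropy.Tree) -> list[KaKsEstimate]:
    """NG86 estimate per terminal branch, against the Fitch-reconstructed
    parent sequence.

    Ambiguous ancestral states are resolved by preferring the tip's own
    state on the branch being scored, then alphabetically; estimates are
    returned in leaf-label order with ``id_b`` set to
    ``"<tip>.ancestor"``.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_nodes()]
    if len(leaves) < 3:
        raise ValueError("branch estimates need at least 3 leaves")
    seqs = {m.id: m.residues for m in alignment.members}
    missing = [l for l in leaves if l not in seqs]
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {missing}")
    length = alignment.length
    up = _fitch_up(tree, seqs, length)

    # top-down assignment: inherit the parent's state where the up-set
    # allows it (the most-parsimonious choice), else alphabetical minimum
    assigned: dict[dendropy.Node, list[str]] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.parent_node is None:
            assigned[node] = [min(s) for s in up[node]]
        else:
            par = assigned[node.parent_node]
            assigned[node] = [
                par[i] if par[i] in up[node][i] else min(up[node][i])
                for i in range(length)
            ]
    out = []
    for leaf in sorted(tree.leaf_nodes(), key=lambda n: n.taxon.label):
        parent = leaf.parent_node
        grand = parent.parent_node
        tip_seq = seqs[leaf.taxon.label]
        anc = []
        for i in range(length):
            cand = up[parent][i]
            if grand is not None and assigned[grand][i] in cand:
                anc.append(assigned[grand][i])     # forced by parsimony
            elif tip_seq[i] in cand:
                anc.append(tip_seq[i])             # ambiguous: prefer tip
            else:
                anc.append(min(cand))              # ambiguous: alphabetical
        anc_rec = SequenceRecord(
            f"{leaf.taxon.label}.ancestor", "", "".join(anc)
        )
        tip_rec = SequenceRecord(leaf.taxon.label, "", tip_seq)
        est = pairwise_ng86(tip_rec, anc_rec)
        out.append(est)
    return out


# ---------------------------------------------------------------------------
# Transition/transversion spectra against a maximum-similarity master
# ---------------------------------------------------------------------------


def _pairwise_identity(a: str, b: str) -> float:
    both = [(x, y) for x, y in zip(a, b) if x in NUCLEOTIDES and y in NUCLEOTIDES]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def choose_master(records) -> str:
    """Id of the sequence with maximum mean pairwise identity to all others
    (ties broken by lexicographically smallest id)."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences to choose a master")
    length = len(records[0].residues)
    if any(len(r.residues) != length for r in records):
        raise ValueError("sequences must be aligned (equal length)")
    best_id = None
    best_score = -1.0
    for r in sorted(records, key=lambda x: x.id):
        score = sum(
            _pairwise_identity(r.residues, o.residues)
            for o in records if o.id != r.id
        ) / (len(records) - 1)
        if score > best_score + 1e-12:
            best_id, best_score = r.id, score
    return best_id


def titv_spectrum(master: SequenceRecord, query: SequenceRecord) -> SubstitutionSpectrum:
    """Classify each differing aligned column as transition/transversion and
    silent/nonsilent (by mutating the master codon in place); gap columns
    count as indels, and columns in codons containing gaps or ambiguity are
    excluded from the silent/nonsilent split."""
    a, b = master.residues, query.residues
    if len(a) != len(b):
        raise ValueError("master and query must be aligned (equal length)")
    ti = tv = silent = nonsilent = indels = 0
    for i in range(len(a)):
        x, y = a[i], b[i]
        if x == y:
            continue
        if x == "-" or y == "-":
            indels += 1
            continue
        if x not in NUCLEOTIDES or y not in NUCLEOTIDES:
            continue  # ambiguity: neither substitution nor indel
        if is_transition(x, y):
            ti += 1
        else:
            tv += 1
        ci = i // 3
        codon = a[3 * ci: 3 * ci + 3]
        if len(codon) == 3 and all(c in NUCLEOTIDES for c in codon) and not is_stop(codon):
            mutated = codon[: i % 3] + y + codon[i % 3 + 1:]
            if not is_stop(mutated) and translate_codon(mutated) == translate_codon(codon):
                silent += 1
            else:
                nonsilent += 1
    return SubstitutionSpectrum(
        master_id=master.id, query_id=query.id, transitions=ti,
        transversions=tv, silent=silent, nonsilent=nonsilent, indels=indels,
    )
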