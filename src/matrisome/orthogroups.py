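"""Orthologous-group clustering and cross-family sharing statistics.

All-vs-all protein similarity is computed as the Jaccard index of k-mer
sets (a fast, dependency-free stand-in for alignment-based all-vs-all
search; precomputed score tables from an external aligner can be supplied
instead). Proteins are clustered by single-linkage connected components of
the thresholded similarity graph, and each cluster is attributed to the
exact combination of taxonomic families it spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def kmer_similarity(seq_a: str, seq_b: str, k: int = 5) -> float:
    """Jaccard index of the two sequences' k-mer sets (symmetric, in [0,1],
    1.0 for identical sequences)."""
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"sequences must be at least {k} residues long")
    ka = {seq_a[i: i + k] for i in range(len(seq_a) - k + 1)}
    kb = {seq_b[i: i + k] for i in range(len(seq_b) - k + 1)}
    return len(ka & kb) / len(ka | kb)


def similarity_matrix(sequences: dict[str, str], k: int = 5) -> pd.DataFrame:
    """Symmetric pairwise k-mer similarity over protein ids (diagonal 1)."""
    ids = sorted(sequences)
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kmer_similarity(sequences[ids[i]], sequences[ids[j]], k)
    return pd.DataFrame(mat, index=ids, columns=ids)


def read_similarity_table(source, sep: str = "\t") -> pd.DataFrame:
    """Build a similarity matrix from long-format (idA, idB, score) rows,
    symmetrized with diagonal 1."""
    df = pd.read_csv(source, sep=sep, comment="#")
    ids = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b, s in df.itertuples(index=False):
        mat.loc[a, b] = mat.loc[b, a] = float(s)
    return mat


@dataclass(frozen=True)
class ClusterSet:
    """Disjoint clusters covering all input ids, with per-cluster species
    presence. Cluster ids are assigned in order of smallest member id."""

    clusters: tuple[tuple[str, ...], ...]
    species_of: dict[str, str]

    def cluster_species(self, idx: int) -> set[str]:
        return {self.species_of[p] for p in self.clusters[idx]}


def cluster(sim: pd.DataFrame, threshold: float, species_of: dict[str, str] | None = None) -> ClusterSet:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever similarity >= threshold.

    Output is invariant to input ordering (ids are canonically sorted) and
    monotone: raising the threshold only refines clusters.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ids = sorted(sim.index)
    mat = sim.loc[ids, ids].to_numpy()
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    adj = csr_matrix(mat >= threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for pid, lab in zip(ids, labels):
        groups.setdefault(lab, []).append(pid)
    ordered = sorted((tuple(sorted(g)) for g in groups.values()), key=lambda g: g[0])
    if species_of is None:
        species_of = {pid: pid.rsplit("_", 1)[0] for pid in ids}
    return ClusterSet(tuple(ordered), species_of)


def sharing_table(clusters: ClusterSet, family_of_species: dict[str, str]) -> pd.DataFrame:
    """Cluster/protein counts per exact taxonomic-family combination.

    Each cluster contributes to exactly one row: the sorted set of families
    present in it (single-family rows are the in-paralog clusters). Rows
    are sorted by descending cluster count, then by combination label;
    cluster and protein counts are conserved across rows.
    """
    rows: dict[str, dict[str, int]] = {}
    for members in clusters.clusters:
        fams = set()
        for pid in members:
            sp = clusters.species_of[pid]
            if sp not in family_of_species:
                raise ValueError(f"species {sp!r} has no taxonomic family mapping")
            fams.add(family_of_species[sp])
        key = "+".join(sorted(fams))
        entry = rows.setdefault(key, {"clusters": 0, "proteins": 0})
        entry["clusters"] += 1
        entry["proteins"] += len(members)
    df = pd.DataFrame(
        [{"families": k, "n_families": k.count("+") + 1,
          "cluster_count": v["clusters"], "protein_count": v["proteins"]}
         for k, v in rows.items()]
    )
    return df.sort_values(
        ["cluster_count", "families"], ascending=[False, True]
    ).reset_index(drop=True)
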