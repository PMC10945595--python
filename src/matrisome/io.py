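"""Domain types and readers/writers for the formats the pipeline touches.

Sequences travel as :class:`SequenceRecord` (FASTA), trees as rooted
:class:`dendropy.Tree` objects (Newick, with optional branch lengths and
0-100 support values on internal edges), and tabular data (annotations,
family counts, divergence times) as pandas DataFrames read from
tab-separated text with a mandatory header row.

Conventions: sequence and alignment columns are 0-based half-open
internally and 1-based inclusive in reports; codon ``i`` spans columns
``[3i, 3i+3)``. The gap symbol is ``-`` and the ambiguity symbols are
``N`` (nucleotide) and ``X`` (protein); the ``.`` gap dialect is rejected.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE = "nucleotide"
AMINOACID = "aminoacid"

_NUC_RESIDUES = set("ACGTUN-")
_AA_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "-", "*"}


class FastaError(ValueError):
    """Malformed FASTA input (duplicate ids, empty bodies, bad residues)."""


class NewickParseError(ValueError):
    """Malformed Newick input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence with a declared alphabet.

    Residues are stored uppercase; the alphabet admits its ambiguity
    symbol (N for nucleotide, X for amino acid) and the gap symbol ``-``.
    """

    id: str
    description: str
    residues: str
    alphabet: str = NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if self.alphabet not in (NUCLEOTIDE, AMINOACID):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = _NUC_RESIDUES if self.alphabet == NUCLEOTIDE else _AA_RESIDUES
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodonAlignment:
    """A gapped in-frame nucleotide alignment (column count divisible by 3).

    ``flagged`` lists member ids whose ungapped frame contains an internal
    stop codon; such rows are kept but marked for downstream caution.
    """

    members: tuple[SequenceRecord, ...]
    length: int
    flagged: frozenset[str] = field(default_factory=frozenset)

    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def get(self, seq_id: str) -> SequenceRecord:
        for m in self.members:
            if m.id == seq_id:
                return m
        raise KeyError(seq_id)


def read_fasta(source, alphabet: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Parse FASTA text (stream, path, or string) into SequenceRecords.

    Residues are uppercased; input order is preserved. Duplicate ids and
    header-only entries raise :class:`FastaError` naming the offender.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        source = _stdio.StringIO(source)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("U", "T") if alphabet == NUCLEOTIDE else str(rec.seq).upper()
        if not residues:
            raise FastaError(f"record {rec.id!r} has an empty sequence body")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        try:
            records.append(SequenceRecord(rec.id, desc, residues, alphabet))
        except ValueError as exc:
            raise FastaError(str(exc)) from exc
    return records


def write_fasta(records: Iterable[SequenceRecord]) -> str:
    """Serialize records to FASTA text; exact inverse of :func:`read_fasta`."""
    handle = _stdio.StringIO()
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, handle, "fasta")
    return handle.getvalue()


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick tree, preserving polytomies and underscores.

    Internal-node labels are interpreted as support values on the 0-100
    scale (the label-after-parenthesis convention).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    if tree.seed_node is None or not tree.leaf_nodes():
        raise NewickParseError("tree has no leaves")
    labels = [lf.taxon.label for lf in tree.leaf_nodes()]
    if len(labels) != len(set(labels)):
        raise NewickParseError("duplicate leaf labels")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to one-line Newick; inverse of :func:`read_newick`."""
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    ).strip()
    return text + ("\n" if not text.endswith("\n") else "")


def node_support(node: dendropy.Node) -> float | None:
    """Support value (0-100) stored on an internal node's label, if any."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_nodes()]


_STOPS = {"TAA", "TAG", "TGA"}


def validate_codon_alignment(members: Sequence[SequenceRecord]) -> CodonAlignment:
    """Validate equal lengths, frame (length % 3 == 0), and flag stop rows.

    A member whose ungapped in-frame codons include an internal stop is
    flagged (not removed). All-gap members are rejected.
    """
    if not members:
        raise ValueError("codon alignment needs at least one member")
    length = len(members[0].residues)
    for m in members:
        if m.alphabet != NUCLEOTIDE:
            raise ValueError(f"member {m.id!r} is not a nucleotide sequence")
        if len(m.residues) != length:
            raise ValueError(
                f"member {m.id!r} has length {len(m.residues)}, expected {length}"
            )
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} not divisible by 3")
    flagged = set()
    for m in members:
        if set(m.residues) == {"-"}:
            raise ValueError(f"member {m.id!r} consists entirely of gaps")
        n_codons = length // 3
        for i in range(n_codons - 1):  # terminal stop is legitimate
            codon = m.residues[3 * i: 3 * i + 3]
            if codon in _STOPS:
                flagged.add(m.id)
                break
    return CodonAlignment(tuple(members), length, frozenset(flagged))


# ---------------------------------------------------------------------------
# Delimited tables (tab-separated, mandatory header; comma via sep=",")
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "protein_id", "organism", "taxonomic_family", "organ",
    "annotation_keywords", "pI", "MW_kDa", "extraction_category",
]


def read_annotation_table(source, sep: str = "\t") -> pd.DataFrame:
    """Read a protein-annotation table; keywords are ';'-separated in-cell.

    Validates: unique protein_id, pI in (0, 14), MW_kDa > 0.
    """
    df = pd.read_csv(source, sep=sep, dtype={"protein_id": str}, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if "extraction_category" not in df.columns:
        df["extraction_category"] = None
    if df["protein_id"].duplicated().any():
        dups = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"duplicate protein ids: {dups}")
    pI = df["pI"].dropna()
    if ((pI <= 0) | (pI >= 14)).any():
        raise ValueError("pI values must lie in (0, 14)")
    mw = df["MW_kDa"].dropna()
    if (mw <= 0).any():
        raise ValueError("MW_kDa values must be positive")
    df["annotation_keywords"] = (
        df["annotation_keywords"].fillna("").map(
            lambda s: [k.strip() for k in str(s).split(";") if k.strip()]
        )
    )
    return df


def write_annotation_table(df: pd.DataFrame, sep: str = "\t") -> str:
    out = df.copy()
    if "annotation_keywords" in out.columns:
        out["annotation_keywords"] = out["annotation_keywords"].map(
            lambda ks: ";".join(ks) if isinstance(ks, (list, tuple)) else ks
        )
    return out.to_csv(sep=sep, index=False)


def read_divergence_times(source, sep: str = "\t") -> pd.DataFrame:
    """Read {group_id, T_years} rows; T_years must be positive."""
    df = pd.read_csv(source, sep=sep, comment="#")
    if not {"group_id", "T_years"} <= set(df.columns):
        raise ValueError("divergence-time table needs columns group_id, T_years")
    if (df["T_years"] <= 0).any():
        raise ValueError("T_years must be positive")
    return df


def read_count_matrix(source, sep: str = "\t") -> pd.DataFrame:
    """Read a wide family x proteome count matrix (first column = family)."""
    df = pd.read_csv(source, sep=sep, index_col=0, comment="#")
    if (df.values < 0).any():
        raise ValueError("family counts must be nonnegative")
    return df.astype(int)


def neighbor_joining(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix (plumbing).

    Thin wrapper over scikit-bio's NJ so reconciliation workflows can build
    a working topology without an external tool.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(distances.values, ids=list(distances.index))
    sk_tree = nj(dm)
    return read_newick(str(sk_tree))
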