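"""Matrisome assembly: deduplication, functional classification, binding
categories, and the molecular-weight band.

Curated wall proteins are assigned one of nine functional classes
(structural, signaling, interacting domains, lipid metabolism, acting on
wall polysaccharides, protease, oxidoreductase, miscellaneous, unknown) by
keyword lookup against a packaged, user-extensible table; unknown proteins
are subclassified as CW-known unknown (annotated, but not with a wall
class), DUF (carrying a domain-of-unknown-function id), or POF (no
recognized annotation at all). Each protein also receives one of three
binding categories (acidic labile / weakly bound salt-extracted / strongly
bound), from extraction metadata when available or a flagged pI heuristic
otherwise, and an in/out flag for the 20-156 kDa molecular-weight band.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources

import pandas as pd

from .io import SequenceRecord


class FunctionalClass(str, Enum):
    STRUCTURAL = "structural"
    SIGNALING = "signaling"
    INTERACTING_DOMAINS = "interacting_domains"
    LIPID_METABOLISM = "lipid_metabolism"
    ACTING_ON_POLYSACCHARIDES = "acting_on_polysaccharides"
    PROTEASE = "protease"
    OXIDOREDUCTASE = "oxidoreductase"
    MISCELLANEOUS = "miscellaneous"
    UNKNOWN = "unknown"


class UnknownSubclass(str, Enum):
    CW_KNOWN_UNKNOWN = "cw_known_unknown"
    DUF = "duf"
    POF = "pof"


class BindingCategory(str, Enum):
    LABILE = "labile"
    WEAKLY_BOUND = "weakly_bound"
    STRONGLY_BOUND = "strongly_bound"


# Priority when keywords match several classes: enzyme evidence beats
# domain-presence evidence; first match wins.
CLASS_PRIORITY = (
    FunctionalClass.ACTING_ON_POLYSACCHARIDES,
    FunctionalClass.PROTEASE,
    FunctionalClass.OXIDOREDUCTASE,
    FunctionalClass.LIPID_METABOLISM,
    FunctionalClass.INTERACTING_DOMAINS,
    FunctionalClass.SIGNALING,
    FunctionalClass.STRUCTURAL,
    FunctionalClass.MISCELLANEOUS,
)

_DUF_RE = re.compile(r"^DUF\d+$", re.IGNORECASE)


@dataclass(frozen=True)
class ProteinRecord:
    """One curated wall-protein entry: sequence, metadata, assignments."""

    seq: SequenceRecord
    organism: str
    taxonomic_family: str = ""
    organ: str = ""
    keywords: tuple[str, ...] = ()
    pI: float | None = None
    MW_kDa: float | None = None
    extraction_category: BindingCategory | None = None
    functional_class: FunctionalClass | None = None
    unknown_subclass: UnknownSubclass | None = None
    binding_category: BindingCategory | None = None
    binding_heuristic: bool = False
    in_mw_band: bool | None = None

    @property
    def id(self) -> str:
        return self.seq.id


def load_keyword_map(source=None) -> dict[str, FunctionalClass]:
    """Load the keyword -> functional class table (packaged default)."""
    if source is None:
        source = resources.files("matrisome.data").joinpath("keyword_classes.tsv")
        text = source.read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    mapping: dict[str, FunctionalClass] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        mapping[row["keyword"].strip().lower()] = FunctionalClass(row["functional_class"])
    if not mapping:
        raise ValueError("keyword map is empty")
    return mapping


def deduplicate(records: list[ProteinRecord]) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Collapse exact-duplicate sequences within the same organism.

    The representative is the lexicographically smallest id; the returned
    mapping lists collapsed id -> representative id. Identical sequences
    from different organisms are all kept. Idempotent.
    """
    groups: dict[tuple[str, str], list[ProteinRecord]] = {}
    for rec in records:
        groups.setdefault((rec.organism, rec.seq.residues), []).append(rec)
    survivors: list[ProteinRecord] = []
    mapping: dict[str, str] = {}
    chosen: set[str] = set()
    for group in groups.values():
        rep = min(group, key=lambda r: r.id)
        chosen.add(rep.id)
        for rec in group:
            if rec.id != rep.id:
                mapping[rec.id] = rep.id
    for rec in records:  # preserve input order among survivors
        if rec.id in chosen:
            survivors.append(rec)
    return survivors, mapping


def classify_functional(
    record: ProteinRecord, keyword_map: dict[str, FunctionalClass]
) -> tuple[FunctionalClass, UnknownSubclass | None]:
    """Assign the functional class by first-match over the priority order.

    No matching keyword yields ``unknown`` with a subclass: DUF if any
    keyword is a DUF domain id, CW-known unknown if other (non-wall)
    annotation exists, POF if the record carries no annotation at all.
    """
    if not keyword_map:
        raise ValueError("keyword map must not be empty")
    kws = [k.strip().lower() for k in record.keywords if k.strip()]
    matched: set[FunctionalClass] = set()
    for kw in kws:
        if kw in keyword_map:
            matched.add(keyword_map[kw])
    for cls in CLASS_PRIORITY:
        if cls in matched:
            return cls, None
    if any(_DUF_RE.match(k) for k in record.keywords):
        return FunctionalClass.UNKNOWN, UnknownSubclass.DUF
    if kws:
        return FunctionalClass.UNKNOWN, UnknownSubclass.CW_KNOWN_UNKNOWN
    return FunctionalClass.UNKNOWN, UnknownSubclass.POF


def assign_binding_category(record: ProteinRecord) -> tuple[BindingCategory, bool]:
    """Binding category from extraction metadata, else a flagged pI
    heuristic (pI < 6 labile, pI >= 7 weakly bound, else strongly bound).

    Returns (category, heuristic_flag).
    """
    if record.extraction_category is not None:
        return BindingCategory(record.extraction_category), False
    if record.pI is None:
        raise ValueError(
            f"record {record.id!r}: no extraction category and no pI"
        )
    if record.pI < 6.0:
        return BindingCategory.LABILE, True
    if record.pI >= 7.0:
        return BindingCategory.WEAKLY_BOUND, True
    return BindingCategory.STRONGLY_BOUND, True


def apply_mw_band(records: list[ProteinRecord], lo: float = 20.0, hi: float = 156.0) -> list[ProteinRecord]:
    """Flag each record as inside/outside the [lo, hi] kDa band (inclusive
    on both ends); nothing is deleted."""
    out = []
    for rec in records:
        if rec.MW_kDa is None:
            raise ValueError(f"record {rec.id!r} has no MW_kDa")
        out.append(replace(rec, in_mw_band=(lo <= rec.MW_kDa <= hi)))
    return out


def class_distribution(records: list[ProteinRecord]) -> pd.DataFrame:
    """Counts and percentages per functional class (percents sum to 100)."""
    if not records:
        raise ValueError("no records to summarize")
    counts: dict[str, int] = {}
    for rec in records:
        if rec.functional_class is None:
            raise ValueError(f"record {rec.id!r} is not classified")
        key = rec.functional_class.value
        if rec.functional_class is FunctionalClass.UNKNOWN and rec.unknown_subclass:
            key = f"unknown/{rec.unknown_subclass.value}"
        counts[key] = counts.get(key, 0) + 1
    total = len(records)
    df = pd.DataFrame(
        [{"class": k, "count": v, "percent": 100.0 * v / total}
         for k, v in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    )
    return df


def curate(
    records: list[ProteinRecord],
    keyword_map: dict[str, FunctionalClass] | None = None,
    mw_lo: float = 20.0,
    mw_hi: float = 156.0,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Full curation pass: deduplicate, classify, assign binding category,
    apply the MW band. Returns (curated records, dedup mapping)."""
    if keyword_map is None:
        keyword_map = load_keyword_map()
    survivors, mapping = deduplicate(records)
    out = []
    for rec in survivors:
        cls, sub = classify_functional(rec, keyword_map)
        cat, heur = assign_binding_category(rec)
        out.append(replace(
            rec, functional_class=cls, unknown_subclass=sub,
            binding_category=cat, binding_heuristic=heur,
        ))
    out = apply_mw_band(out, mw_lo, mw_hi)
    return out, mapping


def records_to_table(records: list[ProteinRecord]) -> pd.DataFrame:
    """Tidy one-row-per-protein table of all curated fields."""
    rows = []
    for r in records:
        rows.append({
            "protein_id": r.id,
            "organism": r.organism,
            "taxonomic_family": r.taxonomic_family,
            "organ": r.organ,
            "functional_class": r.functional_class.value if r.functional_class else "",
            "unknown_subclass": r.unknown_subclass.value if r.unknown_subclass else "",
            "binding_category": r.binding_category.value if r.binding_category else "",
            "binding_heuristic": bool(r.binding_heuristic),
            "pI": r.pI,
            "MW_kDa": r.MW_kDa,
            "in_mw_band": r.in_mw_band,
        })
    return pd.DataFrame(rows)
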