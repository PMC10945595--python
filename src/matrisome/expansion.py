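"""Gene-family expansion testing from family x proteome count matrices.

For each family, the focal proteome's count is compared against the
cross-proteome distribution via Z = (focal - mean) / SD. A family is
called expanded when Z exceeds 2 (strictly) and the focal proteome has at
least 3 members. The mean and SD include the focal proteome by default
(the formula's "all proteomes" reading) and use the sample (n-1)
denominator; both choices are configurable. A leave-clade-out variant
recomputes mean/SD after dropping proteomes of a named clade (keeping the
focal one), mirroring a focal-vs-all-except-relatives comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class FamilyCountMatrix:
    """Integer counts of family members per proteome plus the focal id."""

    counts: pd.DataFrame           # families x proteomes
    focal_id: str
    clade_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.focal_id not in self.counts.columns:
            raise ValueError(f"focal proteome {self.focal_id!r} absent from matrix")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class ExpansionScore:
    """Z-score record for one family; ``z`` is NaN when SD is zero."""

    family_id: str
    focal_count: int
    mean: float
    sd: float
    z: float
    expanded: bool


def zscore_family(
    counts_row: pd.Series,
    focal_id: str,
    exclude_focal: bool = False,
    population_sd: bool = False,
    z_min: float = 2.0,
    members_min: int = 3,
) -> ExpansionScore:
    """Z-score of the focal proteome's count against the row's proteomes.

    Degenerate rows (SD = 0) yield z = NaN and are never called expanded.
    """
    if focal_id not in counts_row.index:
        raise ValueError(f"focal proteome {focal_id!r} not in row")
    if len(counts_row) < 3:
        raise ValueError("need at least 3 proteomes")
    focal = int(counts_row[focal_id])
    pool = counts_row.drop(focal_id) if exclude_focal else counts_row
    values = pool.to_numpy(dtype=float)
    mean = float(values.mean())
    ddof = 0 if population_sd else 1
    sd = float(values.std(ddof=ddof))
    if sd == 0.0:
        z = float("nan")
    else:
        z = (focal - mean) / sd
    name = counts_row.name if counts_row.name is not None else ""
    score = ExpansionScore(str(name), focal, mean, sd, z, False)
    return ExpansionScore(
        score.family_id, focal, mean, sd, z,
        call_expanded(score, z_min=z_min, members_min=members_min),
    )


def call_expanded(score: ExpansionScore, z_min: float = 2.0, members_min: int = 3) -> bool:
    """Expansion call: z strictly above ``z_min`` with at least
    ``members_min`` focal members; undefined z never qualifies."""
    if math.isnan(score.z):
        return False
    return score.z > z_min and score.focal_count >= members_min


def zscore_excluding(
    counts_row: pd.Series,
    focal_id: str,
    excluded_clade: str,
    clade_map: dict[str, str],
    **kwargs,
) -> ExpansionScore:
    """Leave-clade-out Z-score: proteomes of ``excluded_clade`` are removed
    from the comparison pool (the focal proteome is always retained)."""
    drop = [
        p for p in counts_row.index
        if p != focal_id and clade_map.get(p) == excluded_clade
    ]
    reduced = counts_row.drop(drop)
    if len(reduced) < 3:
        raise ValueError(
            f"excluding clade {excluded_clade!r} leaves {len(reduced)} proteomes (<3)"
        )
    return zscore_family(reduced, focal_id, **kwargs)


def score_matrix(
    matrix: FamilyCountMatrix,
    excluded_clade: str | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Score every family of a matrix; returns a tidy DataFrame sorted by
    descending z (NaN last)."""
    rows = []
    for fam in matrix.counts.index:
        row = matrix.counts.loc[fam]
        if excluded_clade is not None:
            if matrix.clade_map is None:
                raise ValueError("clade exclusion requires a clade map")
            s = zscore_excluding(row, matrix.focal_id, excluded_clade,
                                 matrix.clade_map, **kwargs)
        else:
            s = zscore_family(row, matrix.focal_id, **kwargs)
        rows.append({
            "family": s.family_id, "focal_count": s.focal_count,
            "mean": s.mean, "sd": s.sd, "z": s.z, "expanded": s.expanded,
        })
    df = pd.DataFrame(rows)
    return df.sort_values("z", ascending=False, na_position="last").reset_index(drop=True)
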