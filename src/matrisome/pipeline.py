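"""End-to-end orchestration with a single config and deterministic outputs.

A :class:`RunConfig` carries the stage selection, all stage parameters
(every threshold defaulting to the analysis defaults: omega > 10,
dS < 0.01, dS/dN > 3, 30% gap rule, Z > 2 with >= 3 members, DTL costs
1.5/1/0 with loss 1, support threshold 98, motif occurrence 4 at p < 1e-6,
MW band 20-156 kDa) and the master seed. Outputs are tab-separated tables
whose header comment records the tool version, the config hash and the
seed; rerunning an identical config reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expansion import FamilyCountMatrix, score_matrix
from .io import read_newick, write_fasta
from .kaks import all_pairwise, filter_estimates, silent_rate
from .motifs import motifx, site_composition
from .reconcile import ReconciliationCosts, reconcile_dtl
from .simulate import (
    CodonSimSpec,
    simulate_codon_alignment,
    simulate_family_counts,
    simulate_gene_tree,
    simulate_peptides,
)

ALL_STAGES = ("kaks", "expand", "reconcile", "motifs")


@dataclass
class RunConfig:
    """Stage selection plus every stage parameter, with analysis defaults."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # codon simulation + dN/dS
    pair_tree: str = "((A:0.15,B:0.15):0.05,(C:0.10,D:0.10):0.05);"
    omega: float = 0.5
    kappa: float = 2.0
    n_codons: int = 300
    omega_max: float = 10.0
    ds_min: float = 0.01
    ds_max: float = 3.0
    dn_max: float = 3.0
    max_gap_frac: float = 0.30
    T_years: float = 2.0e6
    # expansion
    n_families: int = 200
    n_proteomes: int = 20
    focal_id: str = "P01"
    n_planted: int = 5
    planted_count: int = 12
    background_mean: float = 1.0
    z_min: float = 2.0
    members_min: int = 3
    # reconciliation
    species_tree: str = "((A:1,B:1):1,(C:1,D:1):1);"
    dup_rate: float = 0.1
    transfer_rate: float = 0.05
    loss_rate: float = 0.05
    dup_cost: float = 1.5
    transfer_cost: float = 1.0
    codiv_cost: float = 0.0
    loss_cost: float = 1.0
    support_threshold: float = 98.0
    # motifs
    motif: dict = field(default_factory=lambda: {-3: "R", 1: "P"})
    n_fore: int = 60
    n_back: int = 2000
    min_occurrence: int = 4
    p_threshold: float = 1.0e-6
    mw_lo: float = 20.0
    mw_hi: float = 156.0

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.md5(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        data = yaml.safe_load(Path(source).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "motif" in data:
            data["motif"] = {int(k): v for k, v in data["motif"].items()}
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the selected stages on synthetic inputs; returns the run dir.

    Every output table carries a provenance header; identical configs
    produce byte-identical runs.
    """
    bad = [s for s in config.stages if s not in ALL_STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# matrisome {__version__} config_hash={config.config_hash()} "
              f"seed={config.seed}\n")
    (out / "manifest.yaml").write_text(
        header + yaml.safe_dump(_jsonable(asdict(config)), sort_keys=True)
    )

    if "kaks" in config.stages:
        aln, truth = simulate_codon_alignment(CodonSimSpec(
            tree=read_newick(config.pair_tree), omega=config.omega,
            kappa=config.kappa, n_codons=config.n_codons, seed=config.seed,
        ))
        (out / "alignment.fasta").write_text(write_fasta(aln.members))
        ests = all_pairwise(aln)
        kept, discarded = filter_estimates(
            ests, config.omega_max, config.ds_min, config.ds_max, config.dn_max
        )
        rows = [{
            "id_a": e.id_a, "id_b": e.id_b, "Sd": e.Sd, "Sn": e.Sn,
            "S": e.S, "N": e.N, "ps": e.ps, "pn": e.pn, "ds": e.dS,
            "dn": e.dN, "omega": e.omega, "codons": e.codons_compared,
            "kept": e in kept,
            "discard_reason": dict((id(x), r) for x, r in discarded).get(id(e), ""),
        } for e in ests]
        _write_tsv(pd.DataFrame(rows), out / "kaks_estimates.tsv", header)
        ds_vals = [e.dS for e in kept]
        if ds_vals:
            rate = silent_rate(sum(ds_vals) / len(ds_vals), config.T_years, "demo")
            _write_tsv(pd.DataFrame([{
                "group_id": rate.group_id, "dS_mean": rate.dS_mean,
                "T_years": rate.T_years, "mu": rate.mu,
            }]), out / "divergence_rates.tsv", header)

    if "expand" in config.stages:
        proteomes = [f"P{i + 1:02d}" for i in range(config.n_proteomes)]
        planted = {i: config.planted_count for i in range(config.n_planted)}
        counts, truth = simulate_family_counts(
            config.n_families, proteomes, config.focal_id, planted,
            config.background_mean, config.seed,
        )
        matrix = FamilyCountMatrix(counts, config.focal_id)
        scores = score_matrix(matrix, z_min=config.z_min,
                              members_min=config.members_min)
        _write_tsv(scores, out / "expansion_scores.tsv", header)

    if "reconcile" in config.stages:
        sp_tree = read_newick(config.species_tree)
        gtree, truth = simulate_gene_tree(
            sp_tree, config.dup_rate, config.transfer_rate, config.loss_rate,
            config.seed,
        )
        costs = ReconciliationCosts(config.dup_cost, config.transfer_cost,
                                    config.codiv_cost, config.loss_cost)
        recon = reconcile_dtl(gtree, read_newick(config.species_tree), costs)
        df = pd.DataFrame([{
            "duplications": recon.duplications,
            "transfers": recon.transfers,
            "codivergences": recon.codivergences,
            "losses": recon.losses,
            "total_cost": recon.total_cost,
            "true_duplications": truth.params["duplications"],
            "true_transfers": truth.params["transfers"],
        }])
        _write_tsv(df, out / "reconciliation_events.tsv", header)

    if "motifs" in config.stages:
        fore, back, truth = simulate_peptides(
            config.motif, config.n_fore, config.n_back, seed=config.seed,
        )
        found = motifx(fore, back, truth.params["central_residue"],
                       config.min_occurrence, config.p_threshold)
        df = pd.DataFrame([{
            "pattern": m.pattern(),
            "motif": ";".join(f"{p}:{r}" for p, r in m.motif.items()),
            "fold_enrichment": m.fold_enrichment, "p_value": m.p_value,
            "foreground_matches": m.foreground_matches,
        } for m in found])
        if df.empty:
            df = pd.DataFrame(columns=[
                "pattern", "motif", "fold_enrichment", "p_value",
                "foreground_matches",
            ])
        _write_tsv(df, out / "motifs.tsv", header)
        comp = site_composition(fore)
        _write_tsv(pd.DataFrame([comp]), out / "site_composition.tsv", header)

    return out


def report(run_dir) -> dict[str, pd.DataFrame]:
    """Summary tables of a completed run (medians, calls, event counts)."""
    run_dir = Path(run_dir)
    tables = {}
    for name in ("kaks_estimates", "divergence_rates", "expansion_scores",
                 "reconciliation_events", "motifs", "site_composition"):
        path = run_dir / f"{name}.tsv"
        if path.exists():
            tables[name] = pd.read_csv(path, sep="\t", comment="#")
    if not tables:
        raise ValueError(f"no pipeline outputs found in {run_dir}")
    summary: dict[str, pd.DataFrame] = {}
    if "kaks_estimates" in tables:
        est = tables["kaks_estimates"]
        kept = est[est["kept"]]
        summary["kaks_summary"] = pd.DataFrame([{
            "n_pairs": len(est), "n_kept": len(kept),
            "median_ds": kept["ds"].median(),
            "median_dn": kept["dn"].median(),
            "median_omega": kept["omega"].median(),
        }])
    if "expansion_scores" in tables:
        sc = tables["expansion_scores"]
        summary["expansion_calls"] = sc[sc["expanded"]].reset_index(drop=True)
    if "reconciliation_events" in tables:
        summary["reconciliation_events"] = tables["reconciliation_events"]
    if "motifs" in tables:
        summary["motifs"] = tables["motifs"]
    return summary
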