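"""Run configuration and the simulate -> DE -> DM -> integrate -> co-express chain.

All thresholds default to the published values: significance alpha 0.05,
fold change 2, minimum CpG coverage 5 reads, TSS window 5 kb, region merge
gap 200 bp, region retention fraction 20%, correlation cutoff 0.8, Z-score
band +-1.  Every source of randomness flows from the single seed; two runs
with an identical configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexpr, diffmeth, integration, io, simulate
from .simulate import STAGES, SimulationParams

logger = logging.getLogger("methtx")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s:%(stage)s] %(message)s"))


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "methtx_run"
    # input paths; None means simulate with sim params below
    counts_path: str | None = None
    methylation_dir: str | None = None
    annotation_path: str | None = None
    blacklist_path: str | None = None
    design_path: str | None = None
    # thresholds (published defaults)
    alpha: float = 0.05
    fc: float = 2.0
    min_cov: int = 5
    window: int = 5000
    max_gap: int = 200
    min_frac: float = 0.20
    corr_cutoff: float = 0.8
    z: float = 1.0
    stages: tuple[str, ...] = STAGES
    sim: SimulationParams = field(default_factory=SimulationParams)

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("fc", "min_cov", "window", "max_gap", "corr_cutoff", "z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_frac must be in [0, 1]")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["library_size_factors"] = (
            None
            if self.sim.library_size_factors is None
            else list(map(float, self.sim.library_size_factors))
        )
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # hash is path-independent
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationParams(**raw.pop("sim", {}))
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__},
                  sim=sim)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg


def _tsv_header(config: RunConfig) -> str:
    return f"config_hash={config.config_hash()} seed={config.seed}"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_tsv_header(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def _load_or_simulate(config: RunConfig):
    if config.counts_path is not None:
        design = io.read_design(config.design_path)
        counts = io.read_counts(config.counts_path, design)
        genes = io.read_gene_bed(config.annotation_path)
        meth_dir = Path(config.methylation_dir)
        paths = {p.name.removesuffix(".cov.tsv"): p for p in sorted(meth_dir.glob("*.cov.tsv"))}
        meth = io.read_methylation(paths)
        cpgs = meth[["chrom", "pos"]].drop_duplicates().sort_values(["chrom", "pos"])
        chroms = [(c, int(g["pos"].max()) + 10_000) for c, g in cpgs.groupby("chrom")]
        genome = simulate.GenomeModel(chromosomes=chroms, genes=genes,
                                      cpg_sites=cpgs.reset_index(drop=True))
        truth = None
    else:
        params = dataclasses.replace(config.sim, seed=config.seed)
        design, counts, genome, meth, truth = simulate.simulate_dataset(params)
    return design, counts, genome, meth, truth


def run_all(config: RunConfig) -> dict:
    """Execute the five stages in order; write outputs and a JSON run summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    lfc_threshold = float(np.log2(config.fc))
    stage_name = "setup"
    try:
        design, counts, genome, meth, truth = _load_or_simulate(config)
        io.write_design(design, outdir / "design.tsv")
        _write_tsv(counts.reset_index(), outdir / "counts.tsv", config)
        io.write_gene_bed(genome.genes, outdir / "genes.bed")
        blacklist = (
            io.read_bed_positions(config.blacklist_path)
            if config.blacklist_path
            else None
        )
        if truth is not None:
            _write_tsv(truth.de_genes, outdir / "truth_de_genes.tsv", config)
            _write_tsv(truth.dm_sites, outdir / "truth_dm_sites.tsv", config)
            _write_tsv(truth.coupled, outdir / "truth_coupled.tsv", config)

        de_results: dict[str, pd.DataFrame] = {}
        dmp_results: dict[str, pd.DataFrame] = {}
        coupled: dict[str, list] = {}
        size_factors = None

        for stage in config.stages:
            stage_name = f"de:{stage}"
            est = diffexpr.NegativeBinomialDE(
                stage=stage, alpha=config.alpha, lfc_threshold=lfc_threshold
            ).fit(counts, design)
            size_factors = est.size_factors_
            de_results[stage] = est.results_
            _write_tsv(est.results_, outdir / f"de_{stage}.tsv", config)
            _write_tsv(diffexpr.ma_table(est.results_, cap=2.0, alpha=config.alpha),
                       outdir / f"ma_{stage}.tsv", config)

            stage_name = f"dm:{stage}"
            filtered = diffmeth.filter_sites(
                meth, design, stage, blacklist=blacklist, min_cov=config.min_cov
            )
            dm = diffmeth.test_dmp(filtered, design, stage, alpha=config.alpha)
            dm = diffmeth.annotate_sites(dm, genome)
            dmp_results[stage] = dm
            _write_tsv(dm, outdir / f"dmp_{stage}.tsv", config)
            dmps = dm.loc[dm["is_dmp"]]
            if not dmps.empty:
                io.write_bed(
                    dmps.assign(start=dmps["pos"], end=dmps["pos"],
                                name=dmps["direction"], score=0),
                    outdir / f"dmp_{stage}.bed",
                )

            stage_name = f"integrate:{stage}"
            loci, regions = integration.integrate_stage(
                de_results[stage], dm, genome.genes, stage,
                window=config.window, max_gap=config.max_gap,
                min_frac=config.min_frac, alpha=config.alpha,
            )
            coupled[stage] = loci
            loci_df = pd.DataFrame(
                [
                    {
                        "gene_id": l.gene_id, "stage": l.stage, "M": l.M,
                        "chrom": l.region.chrom, "start": l.region.start,
                        "end": l.region.end, "n_cpg": len(l.region.cpg_positions),
                        "frac_sig": l.region.frac_sig, "mean_delta": l.mean_delta,
                        "coupling": l.coupling,
                    }
                    for l in loci
                ],
                columns=["gene_id", "stage", "M", "chrom", "start", "end",
                         "n_cpg", "frac_sig", "mean_delta", "coupling"],
            )
            _write_tsv(loci_df, outdir / f"coupled_{stage}.tsv", config)
            if regions:
                io.write_bed(
                    pd.DataFrame(
                        {
                            "chrom": [r.chrom for r in regions],
                            "start": [r.start for r in regions],
                            "end": [r.end for r in regions],
                            "name": [
                                f"{r.gene_id}|{'retained' if r.retained else 'excluded'}"
                                for r in regions
                            ],
                            "score": [round(100 * r.frac_sig) for r in regions],
                        }
                    ),
                    outdir / f"regions_{stage}.bed",
                )

            summary["stages"][stage] = {
                "de_genes": int(de_results[stage]["regulated"].sum()),
                "dmps": int(dm["is_dmp"].sum()),
                "regions": len(regions),
                "retained_regions": sum(r.retained for r in regions),
                "coupled_loci": len(loci),
            }
            logger.info("stage complete", extra={"stage": stage_name})

        stage_name = "coexpress"
        union = coexpression.union_de_genes(
            de_results, alpha=config.alpha, lfc_threshold=lfc_threshold
        )
        _, normalized = diffexpr.normalize_counts(counts)
        if union:
            expr = normalized.loc[sorted(union)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = coexpression.correlation_network(expr, cutoff=config.corr_cutoff)
            zsc = coexpression.condition_zscores(expr, design)
            groups = coexpression.assign_groups(zsc)
            _write_tsv(net.edges_, outdir / "network_edges.tsv", config)
            _write_tsv(zsc.reset_index(names="gene_id"), outdir / "zscores.tsv", config)
            _write_tsv(groups, outdir / "groups.tsv", config)
            group_sizes = groups["group"].value_counts().to_dict()
            nodes, edges = len(net.nodes_), len(net.edges_)
        else:
            group_sizes, nodes, edges = {}, 0, 0

        per_stage_genes = {s: {l.gene_id for l in coupled[s]} for s in config.stages}
        coupling_all = [l.coupling for s in config.stages for l in coupled[s]]
        summary["union_de_genes"] = len(union)
        summary["network"] = {"nodes": nodes, "edges": edges}
        summary["groups"] = {str(k): int(v) for k, v in sorted(group_sizes.items())}
        summary["coupled"] = {
            "total_loci": len(coupling_all),
            "canonical": coupling_all.count("canonical"),
            "non_canonical": coupling_all.count("non_canonical"),
            **integration.stage_specificity(per_stage_genes),
        }
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
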