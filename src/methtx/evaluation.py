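"""Planted-truth benchmark routines: null calibration and effect recovery.

These drive both the test suite and the reproduction script.  Each function
simulates data under stated conditions with the package's own generator,
runs the corresponding test, and scores the outcome against the planted
truth.  Seeds are explicit; all results are recomputed at call time.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import diffexpr, diffmeth, pipeline, simulate
from .simulate import STAGES, SimulationParams, _beta_binomial


def _stage_table(design: pd.DataFrame, stage: str, p_conv: float, p_gf: float,
                 n_sites: int, coverage: float, phi: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    sub = design.loc[design["stage"] == stage].reset_index(drop=True)
    n_samp = len(sub)
    cov = 5 + rng.poisson(max(coverage - 5, 0), size=(n_sites, n_samp))
    p = np.where((sub["condition"] == "CONV_R").to_numpy(), p_conv, p_gf)
    x = _beta_binomial(rng, cov, np.broadcast_to(p, (n_sites, n_samp)), phi)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.repeat(np.arange(1, n_sites + 1) * 1000, n_samp),
            "sample_id": np.tile(sub["sample_id"].to_numpy(), n_sites),
            "X": x.ravel(),
            "N": cov.ravel(),
        }
    )


def dm_null_calibration(n_sites: int = 2000, n_replicates: int = 20,
                        coverage: float = 30.0, phi: float = 0.05,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of null CpGs called significant, averaged over replicates."""
    design = simulate.generate_design(5, seed)
    fractions = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, 101, rep])
        level = float(np.clip(rng.beta(0.8, 0.8), 0.05, 0.95))
        table = _stage_table(design, "W4", level, level, n_sites, coverage, phi, rng)
        res = diffmeth.test_dmp(table, design, "W4", alpha=alpha)
        fractions.append(float((res["padj"] < alpha).mean()))
    return {"mean_fraction": float(np.mean(fractions)),
            "max_fraction": float(np.max(fractions)), "n": n_sites * n_replicates}


def dm_effect_recovery(n_sites: int = 500, delta: float = 0.3,
                       baseline: float = 0.2, coverage: float = 30.0,
                       phi: float = 0.05, alpha: float = 0.05,
                       seed: int = 0) -> dict:
    """Power and delta-estimate accuracy at a planted methylation shift."""
    design = simulate.generate_design(5, seed)
    rng = np.random.default_rng([seed, 211])
    table = _stage_table(design, "W4", baseline + delta, baseline,
                         n_sites, coverage, phi, rng)
    res = diffmeth.test_dmp(table, design, "W4", alpha=alpha)
    err = res["delta"] - delta
    return {
        "sensitivity": float((res["padj"] < alpha).mean()),
        "delta_bias": float(err.mean()),
        "delta_mae": float(err.abs().mean()),
        "n": n_sites,
    }


def de_recovery(n_genes: int = 2000, frac_de: float = 0.05, log2fc: float = 2.0,
                dispersion: float = 0.1, stage: str = "W4",
                seed: int = 7) -> dict:
    """Sensitivity and false-discovery proportion for planted DE genes."""
    design = simulate.generate_design(5, seed)
    genome = simulate.generate_genome(n_genes, 100, seed=seed)
    params = SimulationParams(
        n_genes=n_genes, n_cpgs=100, frac_de_genes=frac_de,
        planted_log2fc=log2fc, nb_dispersion=dispersion, seed=seed,
    )
    counts, truth = simulate.simulate_expression(genome, design, params)
    res = diffexpr.test_de(counts, design, stage)
    called = set(res.loc[res["regulated"], "gene_id"])
    planted = set(truth.de_genes.loc[truth.de_genes["stage"] == stage, "gene_id"])
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdp": (len(called) - tp) / len(called) if called else 0.0,
        "n_planted": len(planted),
        "n_called": len(called),
    }


def end_to_end_recovery(seed: int = 0, outdir: str | None = None) -> dict:
    """Full pipeline on the default synthetic dataset, scored against truth.

    Returns the fraction of planted coupled (gene, stage) pairs recovered,
    the coupled-locus count of a matched null rerun, and pipeline summaries.
    """
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        base = outdir or tmp
        cfg = pipeline.RunConfig(
            seed=seed, outdir=f"{base}/effects",
            sim=SimulationParams(seed=seed),
        )
        summary = pipeline.run_all(cfg)

        truth = pd.read_csv(f"{base}/effects/truth_coupled.tsv", sep="\t", comment="#")
        planted = set(zip(truth["gene_id"], truth["stage"]))
        found: set[tuple[str, str]] = set()
        couplings = []
        for stage in STAGES:
            loci = pd.read_csv(f"{base}/effects/coupled_{stage}.tsv",
                               sep="\t", comment="#")
            found |= set(zip(loci["gene_id"], loci["stage"]))
            couplings.extend(loci["coupling"].tolist())

        null_cfg = pipeline.RunConfig(
            seed=seed, outdir=f"{base}/null",
            sim=simulate.null_params(SimulationParams(seed=seed)),
        )
        null_summary = pipeline.run_all(null_cfg)

        recovered = len(planted & found)
        return {
            "n_planted": len(planted),
            "n_recovered": recovered,
            "recovery_fraction": recovered / len(planted) if planted else float("nan"),
            "canonical_fraction": (
                couplings.count("canonical") / len(couplings) if couplings else float("nan")
            ),
            "total_loci": len(couplings),
            "null_coupled_loci": null_summary["coupled"]["total_loci"],
            "summary": summary,
            "null_summary": null_summary,
        }
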