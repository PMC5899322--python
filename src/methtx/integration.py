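"""Hierarchical coupling of differential expression to nearby differential methylation.

For each microbially regulated gene the CpG sites within +-5 kb of its TSS
(symmetric, strand-independent, inclusive at the bound) are merged into
methylation regions wherever consecutive sites are at most 200 bp apart.
Regions in which fewer than 20% of CpGs reach stage-level adjusted
significance are excluded (exactly 20% is retained); a second-level BH
correction is then applied to the pooled raw p-values of all CpGs in the
retained regions, and a coupled locus is emitted per (gene, region) pair
containing at least one CpG significant after this hierarchical correction.
Coupling is canonical when expression and methylation move in opposite
directions (e.g. hypomethylation with increased expression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class MethylRegion:
    """A run of CpGs with consecutive gaps <= max_gap, linked to a gene."""

    chrom: str
    cpg_positions: list[int]
    gene_id: str | None = None
    n_sig: int = 0
    frac_sig: float = 0.0
    retained: bool = False

    @property
    def start(self) -> int:
        return self.cpg_positions[0]

    @property
    def end(self) -> int:
        return self.cpg_positions[-1]


@dataclass
class CoupledLocus:
    """A microbially regulated gene paired with a proximal differentially
    methylated region; canonical iff expression and methylation shift in
    opposite directions."""

    gene_id: str
    stage: str
    M: float
    region: MethylRegion
    mean_delta: float
    coupling: str
    sig_positions: list[int] = field(default_factory=list)


def window_sites(tss: int, positions: np.ndarray, window: int = 5000) -> np.ndarray:
    """Positions with |pos - tss| <= window (inclusive); strand-independent."""
    positions = np.asarray(positions)
    return positions[np.abs(positions.astype(np.int64) - int(tss)) <= window]


def merge_regions(
    positions, max_gap: int = 200, chrom: str = "chr?", gene_id: str | None = None
) -> list[MethylRegion]:
    """Partition sorted unique positions into maximal runs with gaps <= max_gap."""
    positions = list(positions)
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be sorted and unique")
    regions: list[MethylRegion] = []
    current: list[int] = []
    for p in positions:
        p = int(p)
        if current and p - current[-1] > max_gap:
            regions.append(MethylRegion(chrom=chrom, cpg_positions=current, gene_id=gene_id))
            current = []
        current.append(p)
    if current:
        regions.append(MethylRegion(chrom=chrom, cpg_positions=current, gene_id=gene_id))
    return regions


def filter_regions(
    regions: list[MethylRegion],
    site_padj: dict[int, float],
    min_frac: float = 0.20,
    alpha: float = 0.05,
) -> list[MethylRegion]:
    """Flag regions retained when >= min_frac of their CpGs have padj < alpha.

    Exactly min_frac is retained (the exclusion rule is strictly-less-than).
    A region CpG without an adjusted p is an error naming the position.
    """
    for region in regions:
        for p in region.cpg_positions:
            if p not in site_padj:
                raise KeyError(f"no adjusted p-value for region CpG at position {p}")
        region.n_sig = sum(1 for p in region.cpg_positions if site_padj[p] < alpha)
        region.frac_sig = region.n_sig / len(region.cpg_positions)
        region.retained = region.frac_sig >= min_frac
    return regions


def hierarchical_fdr(
    retained_regions: list[MethylRegion], site_raw_p: dict[int, float]
) -> dict[int, float]:
    """Second-level BH over the pooled raw p-values of retained-region CpGs.

    CpGs of excluded regions get no final p.  Positions shared by several
    regions enter the pool once.
    """
    retained = [r for r in retained_regions if r.retained]
    if not retained:
        warnings.warn("no retained regions; hierarchical FDR pool is empty", stacklevel=2)
        return {}
    pool = sorted({p for r in retained for p in r.cpg_positions})
    missing = [p for p in pool if p not in site_raw_p]
    if missing:
        raise KeyError(f"no raw p-value for retained-region CpG at position {missing[0]}")
    raw = np.array([site_raw_p[p] for p in pool])
    padj = multipletests(raw, method="fdr_bh")[1]
    return dict(zip(pool, padj.astype(float)))


def couple_genes(
    de_results: pd.DataFrame,
    regions: list[MethylRegion],
    site_delta: dict[int, float],
    final_padj: dict[int, float],
    stage: str,
    alpha: float = 0.05,
) -> list[CoupledLocus]:
    """Emit a CoupledLocus per (gene, retained region) with a final-significant CpG.

    mean_delta is the mean methylation difference over all region CpGs;
    canonical iff sign(M) * sign(mean_delta) < 0.
    """
    m_by_gene = dict(zip(de_results["gene_id"], de_results["log2FoldChange"]))
    loci: list[CoupledLocus] = []
    for region in regions:
        if not region.retained:
            continue
        if region.gene_id is None or region.gene_id not in m_by_gene:
            raise KeyError(f"region {region.chrom}:{region.start}-{region.end} "
                           f"linked to unknown gene {region.gene_id!r}")
        sig = [p for p in region.cpg_positions
               if p in final_padj and final_padj[p] < alpha]
        if not sig:
            continue
        mean_delta = float(np.mean([site_delta[p] for p in region.cpg_positions]))
        m = float(m_by_gene[region.gene_id])
        if mean_delta == 0.0:
            warnings.warn(
                f"region {region.chrom}:{region.start}-{region.end} has zero mean "
                "methylation difference; coupling reported as non_canonical",
                stacklevel=2,
            )
            coupling = "non_canonical"
        else:
            coupling = "canonical" if np.sign(m) * np.sign(mean_delta) < 0 else "non_canonical"
        loci.append(
            CoupledLocus(
                gene_id=region.gene_id, stage=stage, M=m, region=region,
                mean_delta=mean_delta, coupling=coupling, sig_positions=sig,
            )
        )
    return loci


def integrate_stage(
    de_results: pd.DataFrame,
    dmp_results: pd.DataFrame,
    genes: pd.DataFrame,
    stage: str,
    window: int = 5000,
    max_gap: int = 200,
    min_frac: float = 0.20,
    alpha: float = 0.05,
) -> tuple[list[CoupledLocus], list[MethylRegion]]:
    """Run the hierarchical procedure end to end for one stage.

    de_results: per-gene table with gene_id, log2FoldChange, padj, regulated.
    dmp_results: per-CpG table with chrom, pos, delta, pvalue, padj.
    genes: annotation with gene_id, chrom, tss.
    """
    regulated = de_results.loc[de_results["regulated"]]
    gene_info = genes.set_index("gene_id")
    dm_by_chrom = {c: g.sort_values("pos") for c, g in dmp_results.groupby("chrom", sort=False)}

    all_regions: list[MethylRegion] = []
    for gene_id in regulated["gene_id"]:
        if gene_id not in gene_info.index:
            raise KeyError(f"regulated gene {gene_id!r} missing from annotation")
        chrom = str(gene_info.loc[gene_id, "chrom"])
        tss = int(gene_info.loc[gene_id, "tss"])
        dm = dm_by_chrom.get(chrom)
        if dm is None:
            continue
        hits = window_sites(tss, dm["pos"].to_numpy(), window=window)
        if len(hits) == 0:
            continue
        all_regions.extend(merge_regions(hits, max_gap=max_gap, chrom=chrom, gene_id=gene_id))

    if not all_regions:
        return [], []

    padj_map: dict[str, dict[int, float]] = {}
    rawp_map: dict[str, dict[int, float]] = {}
    delta_map: dict[str, dict[int, float]] = {}
    for chrom, g in dmp_results.groupby("chrom", sort=False):
        padj_map[chrom] = dict(zip(g["pos"].astype(int), g["padj"]))
        rawp_map[chrom] = dict(zip(g["pos"].astype(int), g["pvalue"]))
        delta_map[chrom] = dict(zip(g["pos"].astype(int), g["delta"]))

    loci: list[CoupledLocus] = []
    # regions are chromosome-scoped; filter and pool per chromosome, then one
    # shared hierarchical BH pool across chromosomes (positions are unique per
    # chromosome, so key the pool by (chrom, pos))
    by_chrom: dict[str, list[MethylRegion]] = {}
    for r in all_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    pooled_raw: dict[tuple[str, int], float] = {}
    for chrom, regs in by_chrom.items():
        filter_regions(regs, padj_map[chrom], min_frac=min_frac, alpha=alpha)
        for r in regs:
            if r.retained:
                for p in r.cpg_positions:
                    pooled_raw[(chrom, p)] = rawp_map[chrom][p]
    if pooled_raw:
        keys = sorted(pooled_raw)
        padj = multipletests(np.array([pooled_raw[k] for k in keys]), method="fdr_bh")[1]
        final = dict(zip(keys, padj.astype(float)))
        for chrom, regs in by_chrom.items():
            final_chrom = {p: q for (c, p), q in final.items() if c == chrom}
            loci.extend(
                couple_genes(de_results, regs, delta_map[chrom], final_chrom,
                             stage, alpha=alpha)
            )
    return loci, all_regions


def stage_specificity(per_stage_genes: dict[str, set[str]]) -> dict[str, int]:
    """Bookkeeping: union, multi-stage and stage-specific coupled-gene counts."""
    union = set().union(*per_stage_genes.values()) if per_stage_genes else set()
    counts = {g: sum(g in s for s in per_stage_genes.values()) for g in union}
    multi = {g for g, c in counts.items() if c > 1}
    return {
        "union": len(union),
        "multi_stage": len(multi),
        "stage_specific": len(union) - len(multi),
    }
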