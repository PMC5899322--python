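"""Synthetic paired RNA-seq / RRBS data with planted microbiota effects.

Emulates the study layout the analysis assumes: two colonisation conditions
(conventionally raised, CONV-R, vs germ-free, GF) sampled at three postnatal
stages (week 1, week 4, week 12-16) with five biological replicates per cell.
Expression is negative-binomial read counts; methylation is beta-binomial
methylated/total read counts per CpG, with RRBS-style low-coverage dropout.
Condition effects are planted per stage, and a fraction of differentially
expressed genes receive a coupled differentially methylated region (a run of
>= 3 CpGs with pairwise gaps <= 200 bp) within 5 kb of their TSS, so the
downstream integration step has recoverable ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("CONV_R", "GF")
STAGES = ("W1", "W4", "W12_16")

# fixed per-module RNG offsets so adding draws in one generator never shifts another
_RNG_OFFSETS = {"design": 11, "genome": 23, "expression": 37, "methylation": 53}


def _rng(seed: int, module: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _RNG_OFFSETS[module]])


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def generate_design(n_per_group: int = 5, seed: int = 0) -> pd.DataFrame:
    """Full-factorial design: 2 conditions x 3 stages x ``n_per_group`` replicates.

    Returns a DataFrame with columns ``sample_id, condition, stage, replicate``.
    Fewer than 2 replicates per cell makes downstream variance estimation
    impossible and raises ``ValueError``.
    """
    if n_per_group < 2:
        raise ValueError(
            f"n_per_group must be >= 2 (got {n_per_group}): at least two "
            "replicates per (condition, stage) cell are required to estimate variance"
        )
    rows = []
    for stage in STAGES:
        for condition in CONDITIONS:
            for rep in range(1, n_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{stage}_{condition}_{rep}",
                        "condition": condition,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "condition", "stage", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in design: {dupes}")
    bad_cond = set(design["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}; expected {CONDITIONS}")
    bad_stage = set(design["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages {sorted(bad_stage)}; expected {STAGES}")


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Minimal gene/CpG coordinate model (stand-in for a real mouse annotation).

    ``genes`` columns: gene_id, chrom, strand, start, end, tss (1-based,
    inclusive; tss = start on '+', end on '-').  ``cpg_sites`` columns:
    chrom, pos (1-based, sorted, unique per chromosome).
    """

    chromosomes: list[tuple[str, int]]
    genes: pd.DataFrame
    cpg_sites: pd.DataFrame

    def tss_of(self, gene_id: str) -> tuple[str, int]:
        row = self.genes.loc[self.genes["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(f"unknown gene {gene_id}")
        return str(row["chrom"].iloc[0]), int(row["tss"].iloc[0])


def generate_genome(
    n_genes: int,
    n_cpgs: int,
    seed: int = 0,
    n_chromosomes: int = 3,
    frac_tss_proximal: float = 0.6,
) -> GenomeModel:
    """Lay out non-overlapping genes on a few chromosomes and scatter CpGs.

    A majority (``frac_tss_proximal``) of CpGs are placed in short runs
    (gaps 20-180 bp) within +-4.5 kb of gene TSSs so region merging and the
    5-kb integration window have substrate; the remainder are uniform.
    Deterministic given the seed.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1 (got {n_genes})")
    if n_cpgs < 1:
        raise ValueError(f"n_cpgs must be >= 1 (got {n_cpgs})")
    rng = _rng(seed, "genome")
    n_chromosomes = max(1, min(n_chromosomes, n_genes))

    # distribute genes round-robin, then lay each chromosome out left to right
    genes_per_chrom = [len(r) for r in np.array_split(np.arange(n_genes), n_chromosomes)]
    gene_rows = []
    chromosomes: list[tuple[str, int]] = []
    gid = 0
    for ci, ng in enumerate(genes_per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = int(rng.integers(5_000, 15_000))
        for _ in range(ng):
            length = int(rng.integers(2_000, 8_001))
            start = cursor
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            gene_rows.append(
                {
                    "gene_id": f"gene{gid:05d}",
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "tss": tss,
                }
            )
            gid += 1
            cursor = end + 1 + int(rng.integers(12_000, 25_000))
        chromosomes.append((chrom, cursor + 10_000))

    genes = pd.DataFrame(gene_rows)
    chrom_len = dict(chromosomes)

    capacity = sum(length // 4 for _, length in chromosomes)
    if n_cpgs > capacity:
        raise ValueError(
            f"cannot place {n_cpgs} CpGs on {capacity} available positions; "
            "increase gene count or reduce n_cpgs"
        )

    # TSS-proximal clustered CpGs: cycle genes, drop runs near each TSS
    positions: dict[str, set[int]] = {c: set() for c, _ in chromosomes}
    target_proximal = int(round(frac_tss_proximal * n_cpgs))
    placed = 0
    order = rng.permutation(len(genes))
    gi = 0
    while placed < target_proximal:
        row = genes.iloc[order[gi % len(genes)]]
        gi += 1
        run_len = int(rng.integers(3, 9))
        offset = int(rng.integers(-4_500, 4_001))
        pos = int(row["tss"]) + offset
        for _ in range(run_len):
            if placed >= target_proximal:
                break
            if 1 <= pos <= chrom_len[row["chrom"]] and pos not in positions[row["chrom"]]:
                positions[row["chrom"]].add(pos)
                placed += 1
            pos += int(rng.integers(20, 181))

    # uniform background CpGs, topped up until the exact requested count
    guard = 0
    while placed < n_cpgs:
        ci = int(rng.integers(n_chromosomes))
        chrom, length = chromosomes[ci]
        pos = int(rng.integers(1, length + 1))
        if pos not in positions[chrom]:
            positions[chrom].add(pos)
            placed += 1
        guard += 1
        if guard > 100 * n_cpgs:
            raise ValueError("failed to place requested CpG count; genome too small")

    cpg_rows = [
        {"chrom": chrom, "pos": pos}
        for chrom, _ in chromosomes
        for pos in sorted(positions[chrom])
    ]
    cpg_sites = pd.DataFrame(cpg_rows)
    return GenomeModel(chromosomes=chromosomes, genes=genes, cpg_sites=cpg_sites)


# ---------------------------------------------------------------------------
# simulation parameters and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Effect structure and noise levels for the paired simulation.

    Defaults encode the study layout the analysis targets: five replicates per
    condition/stage cell, NB expression around a mean of 100 with dispersion
    0.1, 5% of genes differentially expressed per stage at |log2FC| = 2,
    beta-binomial CpG counts at coverage ~30 with dispersion phi = 0.05,
    planted methylation shifts of 0.3 on a 0.2 baseline, and a coupled
    promoter-proximal DMR for 2/15 of the DE genes (40 coupled loci at the
    default 2000-gene scale).
    """

    n_genes: int = 2000
    n_cpgs: int = 20000
    mean_expression: float = 100.0
    nb_dispersion: float = 0.1
    library_size_factors: np.ndarray | None = None  # per sample; drawn if None
    frac_de_genes: float = 0.05  # per stage, disjoint gene sets
    planted_log2fc: float = 2.0
    baseline_methylation: float = 0.2
    bb_dispersion: float = 0.05  # phi in [0, 1)
    planted_meth_diff: float = 0.3  # delta added to CONV-R at planted stages
    coverage_mean: float = 30.0
    low_coverage_rate: float = 0.10  # per (site, sample) sub-5-coverage dropout
    frac_dm_sites: float = 0.01  # standalone DM CpGs, split across stages
    frac_coupled: float = 2.0 / 15.0  # fraction of DE genes given a proximal DMR
    frac_canonical: float = 0.57  # coupled loci with methylation opposing expression
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_de_genes", "frac_dm_sites", "frac_coupled",
                     "frac_canonical", "low_coverage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.mean_expression <= 0 or self.nb_dispersion <= 0:
            raise ValueError("mean_expression and nb_dispersion must be positive")
        if not 0.0 < self.baseline_methylation < 1.0:
            raise ValueError("baseline_methylation must be in (0, 1)")
        if not 0.0 <= self.bb_dispersion < 1.0:
            raise ValueError("bb_dispersion must be in [0, 1)")
        if not -1.0 < self.planted_meth_diff < 1.0:
            raise ValueError("planted_meth_diff must be in (-1, 1)")
        shifted = self.baseline_methylation + abs(self.planted_meth_diff)
        if not 0.0 < shifted < 1.0:
            raise ValueError(
                "baseline_methylation + |planted_meth_diff| must stay inside (0, 1)"
            )
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")


@dataclass
class TruthTable:
    """Planted ground truth: DE genes, DM CpGs, and coupled loci."""

    de_genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "stage", "log2fc"])
    )
    dm_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "stage", "delta"])
    )
    coupled: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "stage", "chrom", "start", "end", "n_cpg", "coupling"]
        )
    )

    def copy(self) -> "TruthTable":
        return TruthTable(
            de_genes=self.de_genes.copy(),
            dm_sites=self.dm_sites.copy(),
            coupled=self.coupled.copy(),
        )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_expression(
    genome: GenomeModel, design: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, TruthTable]:
    """Draw a genes x samples NB count matrix with stage-specific planted effects.

    Planted genes get their CONV-R mean multiplied by 2**log2fc at their stage
    (sign drawn at random per gene); disjoint gene sets are planted per stage.
    Returns the count matrix (index gene_id, columns sample_id) and the truth.
    """
    params.validate()
    validate_design(design)
    rng = _rng(params.seed, "expression")
    gene_ids = genome.genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    n_samples = len(design)

    base_mean = rng.lognormal(
        mean=np.log(params.mean_expression) - 0.5, sigma=1.0, size=n_genes
    )
    if params.library_size_factors is not None:
        sf = np.asarray(params.library_size_factors, dtype=float)
        if sf.shape != (n_samples,) or np.any(sf <= 0):
            raise ValueError("library_size_factors must be positive, one per sample")
    else:
        sf = rng.lognormal(mean=0.0, sigma=0.15, size=n_samples)
    sf = sf / np.exp(np.mean(np.log(sf)))

    n_de = int(round(params.frac_de_genes * n_genes))
    perm = rng.permutation(n_genes)
    truth_rows = []
    effect = np.zeros((n_genes, n_samples))  # log2 shift applied to CONV-R cells
    conv_mask = (design["condition"] == "CONV_R").to_numpy()
    for si, stage in enumerate(STAGES):
        planted = perm[si * n_de : (si + 1) * n_de]
        signs = rng.choice([-1.0, 1.0], size=len(planted))
        cols = conv_mask & (design["stage"] == stage).to_numpy()
        for g, s in zip(planted, signs):
            lfc = s * params.planted_log2fc
            if lfc != 0.0:
                effect[g, cols] = lfc
                truth_rows.append(
                    {"gene_id": gene_ids[g], "stage": stage, "log2fc": lfc}
                )

    mu = base_mean[:, None] * sf[None, :] * np.exp2(effect)
    counts = _nb_draw(rng, mu, params.nb_dispersion)
    matrix = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                          columns=design["sample_id"].to_numpy())
    truth = TruthTable(
        de_genes=pd.DataFrame(truth_rows, columns=["gene_id", "stage", "log2fc"])
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, phi: float
) -> np.ndarray:
    """Beta-binomial draws with Var(X/N) = p(1-p)(1 + (N-1)phi)/N."""
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if phi <= 0:
        return rng.binomial(n, p)
    conc = (1.0 - phi) / phi
    a = np.clip(p * conc, 1e-8, None)
    b = np.clip((1.0 - p) * conc, 1e-8, None)
    pi = rng.beta(a, b)
    return rng.binomial(n, pi)


def _find_cpg_run(
    positions: np.ndarray, tss: int, window: int, max_gap: int, min_run: int
) -> np.ndarray | None:
    """First run of >= min_run CpGs with gaps <= max_gap inside |pos - tss| <= window."""
    near = positions[np.abs(positions - tss) <= window]
    if len(near) < min_run:
        return None
    gaps = np.diff(near)
    run_start = 0
    for i, g in enumerate(gaps):
        if g > max_gap:
            if i + 1 - run_start >= min_run:
                return near[run_start : i + 1]
            run_start = i + 1
    if len(near) - run_start >= min_run:
        return near[run_start:]
    return None


def simulate_methylation(
    genome: GenomeModel,
    design: pd.DataFrame,
    params: SimulationParams,
    truth: TruthTable | None = None,
    window: int = 5000,
    max_gap: int = 200,
) -> tuple[pd.DataFrame, TruthTable]:
    """Draw per-CpG per-sample beta-binomial methylation counts.

    Coverage is 5 + Poisson(coverage_mean - 5), with an independent dropout
    mask replacing a ``low_coverage_rate`` fraction of entries with coverage
    drawn uniformly from {0..4} (0 = the site is simply absent in that sample,
    the RRBS missing-site structure).  Standalone DM CpGs and coupled DMRs
    (runs of >= 3 CpGs, gaps <= 200 bp, within 5 kb of a planted DE gene's
    TSS) shift CONV-R methylation by +-planted_meth_diff at their stage.

    Returns a long table (chrom, pos, sample_id, X, N) and the completed truth.
    """
    params.validate()
    validate_design(design)
    if truth is None:
        truth = TruthTable()
    else:
        truth = truth.copy()
    if params.frac_coupled > 0 and truth.de_genes.empty and params.frac_de_genes > 0:
        raise ValueError(
            "coupling requested but no DE truth supplied; run simulate_expression first"
        )
    rng = _rng(params.seed, "methylation")

    sites = genome.cpg_sites.reset_index(drop=True)
    n_sites = len(sites)
    n_samples = len(design)
    site_key = pd.Index(zip(sites["chrom"], sites["pos"]))

    # baseline per-site methylation: bimodal, planted sites pinned to baseline
    p0 = np.clip(rng.beta(0.8, 0.8, size=n_sites), 0.02, 0.98)

    conv_mask = (design["condition"] == "CONV_R").to_numpy()
    stage_arr = design["stage"].to_numpy()

    delta = np.zeros((n_sites, n_samples))
    planted_mask = np.zeros(n_sites, dtype=bool)
    dm_rows = []
    coupled_rows = []

    # ---- coupled DMRs near planted DE genes -------------------------------
    if params.frac_coupled > 0 and not truth.de_genes.empty:
        de = truth.de_genes
        counts_per_stage = {s: int((de["stage"] == s).sum()) for s in STAGES}
        total = params.frac_coupled * sum(counts_per_stage.values())
        n_total = int(round(total))
        # largest-remainder allocation across stages
        raw = {s: params.frac_coupled * counts_per_stage[s] for s in STAGES}
        alloc = {s: int(np.floor(raw[s])) for s in STAGES}
        remainder = sorted(STAGES, key=lambda s: raw[s] - alloc[s], reverse=True)
        i = 0
        while sum(alloc.values()) < n_total:
            alloc[remainder[i % len(remainder)]] += 1
            i += 1
        genes_idx = genome.genes.set_index("gene_id")
        pos_by_chrom = {
            c: g["pos"].to_numpy() for c, g in sites.groupby("chrom", sort=False)
        }
        any_placed = False
        for stage in STAGES:
            want = min(alloc[stage], counts_per_stage[stage])
            stage_de = de.loc[de["stage"] == stage]
            order = rng.permutation(len(stage_de))
            placed = 0
            for oi in order:
                if placed >= want:
                    break
                row = stage_de.iloc[oi]
                grow = genes_idx.loc[row["gene_id"]]
                chrom, tss = str(grow["chrom"]), int(grow["tss"])
                run = _find_cpg_run(pos_by_chrom[chrom], tss, window, max_gap, 3)
                if run is None:
                    continue
                run = run[: min(len(run), 6)]
                canonical = rng.random() < params.frac_canonical
                meth_sign = -np.sign(row["log2fc"]) if canonical else np.sign(row["log2fc"])
                d = float(meth_sign) * abs(params.planted_meth_diff)
                cols = conv_mask & (stage_arr == stage)
                idx = site_key.get_indexer([(chrom, int(p)) for p in run])
                fresh = idx[(idx >= 0) & ~planted_mask[idx]]
                if len(fresh) < 3:
                    continue
                delta[np.ix_(fresh, np.where(cols)[0])] = d
                planted_mask[fresh] = True
                p0[fresh] = params.baseline_methylation
                for j in fresh:
                    dm_rows.append(
                        {"chrom": chrom, "pos": int(sites["pos"].iloc[j]),
                         "stage": stage, "delta": d}
                    )
                coupled_rows.append(
                    {
                        "gene_id": row["gene_id"],
                        "stage": stage,
                        "chrom": chrom,
                        "start": int(sites["pos"].iloc[fresh].min()),
                        "end": int(sites["pos"].iloc[fresh].max()),
                        "n_cpg": int(len(fresh)),
                        "coupling": "canonical" if canonical else "non_canonical",
                    }
                )
                placed += 1
                any_placed = True
            if want > 0 and placed == 0 and counts_per_stage[stage] > 0:
                if not any_placed:
                    raise ValueError(
                        "coupling requested but no CpG runs found within any "
                        "DE gene's TSS window"
                    )

    # ---- standalone DM CpGs ------------------------------------------------
    n_dm = int(round(params.frac_dm_sites * n_sites))
    if n_dm > 0 and params.planted_meth_diff != 0.0:
        free = np.where(~planted_mask)[0]
        chosen = rng.permutation(free)[:n_dm]
        per_stage = np.array_split(chosen, len(STAGES))
        for stage, group in zip(STAGES, per_stage):
            cols = np.where(conv_mask & (stage_arr == stage))[0]
            signs = rng.choice([-1.0, 1.0], size=len(group))
            for j, s in zip(group, signs):
                d = float(s) * abs(params.planted_meth_diff)
                delta[j, cols] = d
                planted_mask[j] = True
                p0[j] = params.baseline_methylation
                dm_rows.append(
                    {"chrom": sites["chrom"].iloc[j], "pos": int(sites["pos"].iloc[j]),
                     "stage": stage, "delta": d}
                )

    # ---- coverage and methylated counts -----------------------------------
    lam = max(params.coverage_mean - 5.0, 0.0)
    cov = 5 + rng.poisson(lam, size=(n_sites, n_samples))
    drop = rng.random((n_sites, n_samples)) < params.low_coverage_rate
    cov[drop] = rng.integers(0, 5, size=int(drop.sum()))

    p_eff = np.clip(p0[:, None] + delta, 0.005, 0.995)
    x = _beta_binomial(rng, cov, p_eff, params.bb_dispersion)

    keep = cov > 0
    si, sj = np.where(keep)
    table = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[si],
            "pos": sites["pos"].to_numpy()[si],
            "sample_id": design["sample_id"].to_numpy()[sj],
            "X": x[keep],
            "N": cov[keep],
        }
    )
    truth.dm_sites = pd.DataFrame(dm_rows, columns=["chrom", "pos", "stage", "delta"])
    truth.coupled = pd.DataFrame(
        coupled_rows,
        columns=["gene_id", "stage", "chrom", "start", "end", "n_cpg", "coupling"],
    )
    return table, truth


def simulate_dataset(
    params: SimulationParams, n_per_group: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, GenomeModel, pd.DataFrame, TruthTable]:
    """Convenience wrapper: design, genome, expression, methylation, truth."""
    design = generate_design(n_per_group=n_per_group, seed=params.seed)
    genome = generate_genome(params.n_genes, params.n_cpgs, seed=params.seed)
    counts, truth = simulate_expression(genome, design, params)
    meth, truth = simulate_methylation(genome, design, params, truth)
    return design, counts, genome, meth, truth


def null_params(params: SimulationParams) -> SimulationParams:
    """Copy of ``params`` with every planted effect switched off."""
    return dataclasses.replace(
        params, planted_log2fc=0.0, planted_meth_diff=0.0,
        frac_de_genes=0.0, frac_dm_sites=0.0, frac_coupled=0.0,
    )
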