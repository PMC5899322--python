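"""Per-CpG differential methylation between CONV-R and GF within a stage.

The test works on arcsine-transformed methylation proportions,
t = arcsin(2 (X + 0.5)/(N + 1) - 1), a variance-stabilising link under which
a beta-binomial observation has approximate variance (1 + (N - 1) phi) / N
(delta method), with phi the extra-binomial dispersion.  phi is estimated per
site by method of moments from residual variance around group means — a
closed-form generalized-least-squares scheme, no iterative fitting — and the
group difference is then a GLS-weighted contrast with weights
N / (1 + (N - 1) phi), referred to N(0, 1).  BH adjustment is per stage.

RRBS pre-filtering: entries with coverage below 5 reads are dropped, blacklist
positions (e.g. strain-specific SNPs) are removed entirely, and a site must
keep at least 2 covered samples in each condition at the tested stage.
Missingness is handled per site, never by discarding samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .simulate import GenomeModel, validate_design

logger = logging.getLogger(__name__)

_PHI_MAX = 0.99


def arcsine_transform(X, N):
    """Continuity-corrected arcsine link: arcsin(2 (X + 0.5)/(N + 1) - 1).

    Strictly increasing in X with range inside (-pi/2, pi/2); N = 0 is an
    error because no proportion is observable.
    """
    X = np.asarray(X, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N < 1):
        raise ValueError("arcsine_transform requires N >= 1")
    if np.any((X < 0) | (X > N)):
        raise ValueError("require 0 <= X <= N")
    return np.arcsin(2.0 * (X + 0.5) / (N + 1.0) - 1.0)


def filter_sites(
    table: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    blacklist: set[tuple[str, int]] | None = None,
    min_cov: int = 5,
    min_samples_per_group: int = 2,
) -> pd.DataFrame:
    """Coverage, blacklist and per-group support filter for one stage.

    Drops (site, sample) entries with N < min_cov, removes blacklisted
    (chrom, pos) everywhere, restricts to samples of the stage, and keeps only
    sites with >= min_samples_per_group retained samples in each condition.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    validate_design(design)
    if blacklist:
        for entry in blacklist:
            if (not isinstance(entry, tuple) or len(entry) != 2
                    or not isinstance(entry[1], (int, np.integer)) or entry[1] < 1):
                raise ValueError(f"malformed blacklist entry {entry!r}")
    stage_samples = design.loc[design["stage"] == stage, "sample_id"]
    sub = table.loc[table["sample_id"].isin(stage_samples)].copy()
    sub = sub.loc[sub["N"] >= min_cov]
    if blacklist:
        key = pd.MultiIndex.from_frame(sub[["chrom", "pos"]])
        sub = sub.loc[~key.isin(blacklist)]
    cond = design.set_index("sample_id")["condition"]
    sub["_cond"] = sub["sample_id"].map(cond)
    support = sub.groupby(["chrom", "pos", "_cond"], sort=False).size().unstack(
        "_cond", fill_value=0
    )
    for c in ("CONV_R", "GF"):
        if c not in support.columns:
            support[c] = 0
    ok = support.index[
        (support["CONV_R"] >= min_samples_per_group)
        & (support["GF"] >= min_samples_per_group)
    ]
    key = pd.MultiIndex.from_frame(sub[["chrom", "pos"]])
    out = sub.loc[key.isin(ok)].drop(columns="_cond").reset_index(drop=True)
    return out


class ArcsineGLSDM(BaseEstimator):
    """Beta-binomial arcsine-GLS differential methylation test for one stage.

    Parameters
    ----------
    stage : str
        Developmental stage to contrast ("W1", "W4", "W12_16").
    alpha : float
        Adjusted-p threshold for the DMP call.
    phi : float or None
        If given, fixes the dispersion instead of estimating it per site
        (used for oracle checks; default None = method-of-moments estimate).

    Fitted attributes
    -----------------
    results_ : pd.DataFrame with columns chrom, pos, delta, phi, stat,
        pvalue, padj, direction, is_dmp.  ``delta`` is the weighted mean
        methylation proportion difference CONV-R minus GF.
    excluded_ : list of (chrom, pos, reason) for sites that could not be
        tested (zero residual degrees of freedom).
    """

    def __init__(self, stage: str = "W4", alpha: float = 0.05, phi: float | None = None):
        self.stage = stage
        self.alpha = alpha
        self.phi = phi

    def fit(self, X: pd.DataFrame, design: pd.DataFrame) -> "ArcsineGLSDM":
        table = X
        validate_design(design)
        stage_design = design.loc[design["stage"] == self.stage]
        samples = stage_design["sample_id"].to_numpy()
        is_conv = (stage_design["condition"] == "CONV_R").to_numpy()

        sub = table.loc[table["sample_id"].isin(samples)]
        if sub.empty:
            raise ValueError(f"no methylation records for stage {self.stage!r}")
        xw = sub.pivot_table(index=["chrom", "pos"], columns="sample_id",
                             values="X", aggfunc="first")
        nw = sub.pivot_table(index=["chrom", "pos"], columns="sample_id",
                             values="N", aggfunc="first")
        xw = xw.reindex(columns=samples)
        nw = nw.reindex(columns=samples)
        xa = xw.to_numpy(dtype=float)
        na = nw.to_numpy(dtype=float)
        obs = np.isfinite(na) & (na >= 1)

        n1 = (obs & is_conv[None, :]).sum(axis=1)
        n2 = (obs & ~is_conv[None, :]).sum(axis=1)
        testable = (n1 >= 2) & (n2 >= 2)
        excluded = []
        for chrom, pos in xw.index[~testable]:
            excluded.append((chrom, int(pos), "fewer than 2 covered samples in a group"))
            logger.info("site %s:%d excluded: insufficient residual df", chrom, pos)
        if not testable.any():
            raise ValueError("no testable sites after support filtering")
        xa, na, obs = xa[testable], na[testable], obs[testable]
        n1, n2 = n1[testable], n2[testable]
        index = xw.index[testable]

        with np.errstate(invalid="ignore"):
            t = np.where(obs, np.arcsin(2.0 * (xa + 0.5) / (na + 1.0) - 1.0), 0.0)

        g1 = obs & is_conv[None, :]
        g2 = obs & ~is_conv[None, :]

        # --- method-of-moments phi from residuals around unweighted group means
        tbar1 = np.where(g1, t, 0.0).sum(axis=1) / n1
        tbar2 = np.where(g2, t, 0.0).sum(axis=1) / n2
        resid = np.where(g1, t - tbar1[:, None], 0.0) + np.where(g2, t - tbar2[:, None], 0.0)
        S = (resid**2).sum(axis=1)
        inv_n = np.where(obs, 1.0 / np.where(obs, na, 1.0), 0.0)
        frac = np.where(obs, (na - 1.0) / np.where(obs, na, 1.0), 0.0)
        A = (1.0 - 1.0 / n1) * np.where(g1, inv_n, 0.0).sum(axis=1) \
            + (1.0 - 1.0 / n2) * np.where(g2, inv_n, 0.0).sum(axis=1)
        B = (1.0 - 1.0 / n1) * np.where(g1, frac, 0.0).sum(axis=1) \
            + (1.0 - 1.0 / n2) * np.where(g2, frac, 0.0).sum(axis=1)
        if self.phi is not None:
            phi = np.full(len(S), float(self.phi))
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                phi = (S - A) / B
            phi = np.where(np.isfinite(phi), phi, 0.0)
            phi = np.clip(phi, 0.0, _PHI_MAX)

        # --- GLS contrast with weights N / (1 + (N - 1) phi)
        w = np.where(obs, na / (1.0 + (na - 1.0) * phi[:, None]), 0.0)
        w1 = np.where(g1, w, 0.0)
        w2 = np.where(g2, w, 0.0)
        W1 = w1.sum(axis=1)
        W2 = w2.sum(axis=1)
        m1 = (w1 * t).sum(axis=1) / W1
        m2 = (w2 * t).sum(axis=1) / W2
        diff = m1 - m2
        se = np.sqrt(1.0 / W1 + 1.0 / W2)
        stat = diff / se
        pvalue = np.clip(2.0 * stats.norm.sf(np.abs(stat)), 0.0, 1.0)
        padj = multipletests(pvalue, method="fdr_bh")[1]

        # delta on the proportion scale: weighted group mean proportions
        prop = np.where(obs, xa / np.where(obs, na, 1.0), 0.0)
        p1 = (w1 * prop).sum(axis=1) / W1
        p2 = (w2 * prop).sum(axis=1) / W2
        delta = p1 - p2

        results = pd.DataFrame(
            {
                "chrom": index.get_level_values(0),
                "pos": index.get_level_values(1).astype(int),
                "delta": delta,
                "phi": phi,
                "stat": stat,
                "pvalue": pvalue,
                "padj": padj,
            }
        )
        results = classify_direction(results)
        results["is_dmp"] = results["padj"] < self.alpha
        results = results.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self.results_ = results
        self.excluded_ = excluded
        return self


def test_dmp(table: pd.DataFrame, design: pd.DataFrame, stage: str,
             alpha: float = 0.05) -> pd.DataFrame:
    """Arcsine-GLS differential methylation for one stage; see ArcsineGLSDM."""
    return ArcsineGLSDM(stage=stage, alpha=alpha).fit(table, design).results_


def classify_direction(results: pd.DataFrame) -> pd.DataFrame:
    """hyper iff delta > 0, hypo iff delta < 0, undirected at exactly 0."""
    out = results.copy()
    out["direction"] = np.select(
        [out["delta"] > 0, out["delta"] < 0], ["hyper", "hypo"], default="undirected"
    )
    return out


def annotate_sites(
    results: pd.DataFrame,
    genome: GenomeModel,
    promoter_halfwidth: int = 1000,
    exons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign genomic location with precedence promoter > exon > intron > intergenic.

    Promoter is the symmetric window [tss - hw, tss + hw].  Without an exon
    table, each gene body counts as a single exon (so intron never fires).
    Sites hitting several genes resolve by precedence, then nearest TSS.
    Unknown chromosomes map to intergenic with a warning.
    """
    genes = genome.genes
    known = set(genes["chrom"])
    locs = []
    by_chrom = {c: g for c, g in genes.groupby("chrom", sort=False)}
    exons_by_chrom = (
        {c: g for c, g in exons.groupby("chrom", sort=False)} if exons is not None else None
    )
    for chrom, pos in zip(results["chrom"], results["pos"]):
        if chrom not in known:
            warnings.warn(f"site on unknown chromosome {chrom!r}; intergenic", stacklevel=2)
            locs.append("intergenic")
            continue
        g = by_chrom[chrom]
        tss = g["tss"].to_numpy()
        in_prom = np.abs(pos - tss) <= promoter_halfwidth
        if in_prom.any():
            locs.append("promoter")
            continue
        in_body = (g["start"].to_numpy() <= pos) & (pos <= g["end"].to_numpy())
        if in_body.any():
            if exons_by_chrom is None:
                locs.append("exon")  # genes without exon detail = single exon
                continue
            ex = exons_by_chrom.get(chrom)
            in_exon = (
                ex is not None
                and bool(((ex["start"].to_numpy() <= pos) & (pos <= ex["end"].to_numpy())).any())
            )
            locs.append("exon" if in_exon else "intron")
            continue
        locs.append("intergenic")
    out = results.copy()
    out["location"] = locs
    return out


def top_k_by_padj(results: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """The k most significant sites; ties broken by (chrom, pos) for stability."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = results.sort_values(["padj", "chrom", "pos"], kind="stable")
    if len(ordered) < k:
        warnings.warn(
            f"requested top {k} but only {len(ordered)} sites available", stacklevel=2
        )
    return ordered.head(k).reset_index(drop=True)
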