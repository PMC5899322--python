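"""Negative-binomial differential expression between CONV-R and GF within a stage.

Library-size normalisation uses median-of-ratios against a geometric-mean
reference.  Per gene, an NB Wald test: gene-wise dispersion by method of
moments on normalised counts, shrunk 50/50 toward a fitted mean-dispersion
trend; the Wald statistic log2FC / SE is referred to N(0, 1) and p-values are
Benjamini-Hochberg adjusted across all tested genes.  A gene is called
microbially regulated when adjusted p < 0.05 and |log2FC| > 1 (fold change
> 2), both strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .simulate import validate_design

_MIN_DISP = 1e-8
_PSEUDO_MEAN = 1e-8
_LFC_CLAMP = 30.0


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors (geometric mean 1) and normalised counts.

    Falls back to total-count ratios when fewer than 10 genes are positive in
    every sample.  An all-zero sample is an error naming the sample.
    """
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene_ids in count matrix")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    totals = arr.sum(axis=0)
    for j, t in enumerate(totals):
        if t <= 0:
            raise ValueError(f"sample {counts.columns[j]!r} has zero total count")

    all_pos = (arr > 0).all(axis=1)
    if all_pos.sum() < 10:
        sf = totals.astype(float)
    else:
        ref = np.exp(np.mean(np.log(arr[all_pos]), axis=1))
        sf = np.median(arr[all_pos] / ref[:, None], axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return size_factors, normalized


def _fit_dispersion_trend(mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of disp ~ a0 + a1/mean, coefficients clamped >= 0."""
    ok = (mean > 0) & np.isfinite(disp) & (disp > _MIN_DISP)
    if ok.sum() < 10:
        med = float(np.median(disp[np.isfinite(disp)])) if np.isfinite(disp).any() else 0.1
        return max(med, _MIN_DISP), 0.0
    x = 1.0 / mean[ok]
    y = disp[ok]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0 = max(float(coef[0]), _MIN_DISP)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


class NegativeBinomialDE(BaseEstimator):
    """Per-gene NB Wald test of CONV-R vs GF at one developmental stage.

    Parameters
    ----------
    stage : str
        Stage to test ("W1", "W4" or "W12_16").
    alpha : float
        Adjusted-p threshold for the regulated call (strict <).
    lfc_threshold : float
        |log2FC| threshold for the regulated call (strict >); 1 means
        fold change > 2.
    shrinkage : float
        Weight of the trend in the dispersion shrinkage (0.5 = 50/50).

    Fitted attributes
    -----------------
    size_factors_ : pd.Series
    dispersions_ : pd.Series  (shrunk, per gene)
    results_ : pd.DataFrame with columns gene_id, baseMean, log2FoldChange,
        lfcSE, stat, pvalue, padj, regulated.  Fold change is oriented
        CONV-R over GF.
    """

    def __init__(self, stage: str = "W4", alpha: float = 0.05,
                 lfc_threshold: float = 1.0, shrinkage: float = 0.5):
        self.stage = stage
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.shrinkage = shrinkage

    def fit(self, X: pd.DataFrame, design: pd.DataFrame) -> "NegativeBinomialDE":
        counts, design = X, design
        validate_design(design)
        if not set(counts.columns) == set(design["sample_id"]):
            raise ValueError("count matrix columns must match design sample_ids")
        sub = design.loc[design["stage"] == self.stage]
        n1 = int((sub["condition"] == "CONV_R").sum())
        n2 = int((sub["condition"] == "GF").sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(
                f"stage {self.stage!r} needs >= 2 replicates per condition "
                f"(got CONV_R={n1}, GF={n2})"
            )
        size_factors, normalized = normalize_counts(counts)
        cols1 = sub.loc[sub["condition"] == "CONV_R", "sample_id"].to_numpy()
        cols2 = sub.loc[sub["condition"] == "GF", "sample_id"].to_numpy()
        y1 = normalized[cols1].to_numpy()
        y2 = normalized[cols2].to_numpy()
        s1 = size_factors[cols1].to_numpy()
        s2 = size_factors[cols2].to_numpy()

        mu1 = y1.mean(axis=1)
        mu2 = y2.mean(axis=1)
        mu = (n1 * mu1 + n2 * mu2) / (n1 + n2)

        # method-of-moments dispersion on normalised counts:
        # Var(K/s) = mu/s + alpha*mu^2, pooled within groups
        ss = ((y1 - mu1[:, None]) ** 2).sum(axis=1) + ((y2 - mu2[:, None]) ** 2).sum(axis=1)
        pooled_var = ss / (n1 + n2 - 2)
        mean_inv_s = np.mean(np.concatenate([1.0 / s1, 1.0 / s2]))
        with np.errstate(divide="ignore", invalid="ignore"):
            disp_gw = (pooled_var - mu * mean_inv_s) / np.square(mu)
        disp_gw = np.where(np.isfinite(disp_gw), disp_gw, _MIN_DISP)
        disp_gw = np.clip(disp_gw, _MIN_DISP, None)
        a0, a1 = _fit_dispersion_trend(mu, disp_gw)
        with np.errstate(divide="ignore"):
            disp_tr = a0 + a1 / np.where(mu > 0, mu, np.inf)
        disp = (1.0 - self.shrinkage) * disp_gw + self.shrinkage * disp_tr
        disp = np.clip(disp, _MIN_DISP, None)

        m = np.log2((mu1 + _PSEUDO_MEAN) / (mu2 + _PSEUDO_MEAN))
        m = np.clip(m, -_LFC_CLAMP, _LFC_CLAMP)

        # delta-method variance of each group mean of normalised counts;
        # zero group means get a half-count floor so SE stays finite
        floor1 = 0.5 / (n1 * np.mean(s1))
        floor2 = 0.5 / (n2 * np.mean(s2))
        mu1v = np.maximum(mu1, floor1)
        mu2v = np.maximum(mu2, floor2)
        v1 = (mu1v[:, None] / s1[None, :] + disp[:, None] * mu1v[:, None] ** 2).sum(axis=1) / n1**2
        v2 = (mu2v[:, None] / s2[None, :] + disp[:, None] * mu2v[:, None] ** 2).sum(axis=1) / n2**2
        se = np.sqrt(v1 / mu1v**2 + v2 / mu2v**2) / np.log(2.0)
        se = np.where(se > 0, se, np.inf)

        stat = m / se
        pvalue = 2.0 * stats.norm.sf(np.abs(stat))

        all_zero = (mu1 == 0) & (mu2 == 0)
        m[all_zero] = 0.0
        stat[all_zero] = 0.0
        pvalue[all_zero] = 1.0
        pvalue = np.clip(pvalue, 0.0, 1.0)

        padj = multipletests(pvalue, method="fdr_bh")[1]
        regulated = (padj < self.alpha) & (np.abs(m) > self.lfc_threshold)

        base_mean = np.concatenate([y1, y2], axis=1).mean(axis=1)
        self.size_factors_ = size_factors
        self.dispersions_ = pd.Series(disp, index=counts.index, name="dispersion")
        self.results_ = pd.DataFrame(
            {
                "gene_id": counts.index.to_numpy(),
                "baseMean": base_mean,
                "log2FoldChange": m,
                "lfcSE": se,
                "stat": stat,
                "pvalue": pvalue,
                "padj": padj,
                "regulated": regulated,
            }
        ).reset_index(drop=True)
        return self


def test_de(counts: pd.DataFrame, design: pd.DataFrame, stage: str,
            alpha: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """NB Wald differential expression for one stage; see NegativeBinomialDE."""
    est = NegativeBinomialDE(stage=stage, alpha=alpha, lfc_threshold=lfc_threshold)
    return est.fit(counts, design).results_


def classify_regulated(results: pd.DataFrame, alpha: float = 0.05,
                       lfc_threshold: float = 1.0) -> set[str]:
    """Genes with padj < alpha and |log2FC| > lfc_threshold (both strict)."""
    mask = (results["padj"] < alpha) & (results["log2FoldChange"].abs() > lfc_threshold)
    return set(results.loc[mask, "gene_id"])


def ma_table(results: pd.DataFrame, cap: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """MA summary: mean expression A, log2FC clamped to +-cap, significance flag."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    out = pd.DataFrame(
        {
            "gene_id": results["gene_id"],
            "A": results["baseMean"],
            "M": results["log2FoldChange"].clip(-cap, cap),
            "significant": results["padj"] < alpha,
        }
    )
    if results.empty:
        warnings.warn("empty DE result table", stacklevel=2)
    return out
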