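"""Co-expression network over microbially regulated genes, condition Z-score
profiles, temporal/microbiota expression groups, and hypergeometric enrichment.

The network takes the union of genes called regulated at any stage, computes
pairwise Spearman correlations over all samples, and keeps positive edges at
rho >= 0.8 by default (co-expression semantics; ``signed=True`` uses |rho|).
Per gene, the six condition means (2 conditions x 3 stages) are standardised
to Z-scores (mean 0, sample SD with denominator n - 1 = 5) and matched
against the six published group criteria, evaluated in ascending order with
first-match-wins.  Groups 3 and 4 share identical printed criteria, so the
rule emits group 3 and group 4 is reserved.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .simulate import CONDITIONS, STAGES, validate_design


def union_de_genes(per_stage_results: dict[str, pd.DataFrame],
                   alpha: float = 0.05, lfc_threshold: float = 1.0) -> set[str]:
    """Union of regulated genes over the per-stage DE tables."""
    out: set[str] = set()
    for results in per_stage_results.values():
        mask = (results["padj"] < alpha) & (results["log2FoldChange"].abs() > lfc_threshold)
        out |= set(results.loc[mask, "gene_id"])
    if not out:
        warnings.warn("no regulated genes in any stage; empty union", stacklevel=2)
    return out


class SpearmanNetwork(BaseEstimator):
    """Spearman co-expression network builder.

    Parameters
    ----------
    cutoff : float
        Minimum correlation for an edge (rho >= cutoff).
    signed : bool
        If True, edges use |rho| >= cutoff; default keeps positive
        co-expression only.

    Fitted attributes
    -----------------
    edges_ : pd.DataFrame (gene_a, gene_b, rho) with gene_a < gene_b.
    nodes_ : list of genes with at least one edge.
    dropped_ : list of zero-variance genes excluded before correlation.
    """

    def __init__(self, cutoff: float = 0.8, signed: bool = False):
        self.cutoff = cutoff
        self.signed = signed

    def fit(self, X: pd.DataFrame, y=None) -> "SpearmanNetwork":
        expr = X
        if expr.shape[1] < 3:
            raise ValueError("at least 3 samples are required for correlation")
        variances = expr.var(axis=1)
        dropped = list(expr.index[variances == 0])
        if dropped:
            warnings.warn(f"excluding {len(dropped)} zero-variance genes", stacklevel=2)
        expr = expr.loc[variances > 0]
        genes = expr.index.to_numpy()
        rows = []
        if len(genes) >= 2:
            rho = stats.spearmanr(expr.to_numpy(), axis=1).statistic
            if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
                rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
            score = np.abs(rho) if self.signed else rho
            ii, jj = np.where(np.triu(score >= self.cutoff, k=1))
            for i, j in zip(ii, jj):
                a, b = sorted((genes[i], genes[j]))
                rows.append({"gene_a": a, "gene_b": b, "rho": float(rho[i, j])})
        self.edges_ = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"])
        self.nodes_ = sorted(set(self.edges_["gene_a"]) | set(self.edges_["gene_b"]))
        self.dropped_ = dropped
        return self


def correlation_network(expr: pd.DataFrame, cutoff: float = 0.8,
                        signed: bool = False) -> SpearmanNetwork:
    """Build the co-expression network; see SpearmanNetwork."""
    return SpearmanNetwork(cutoff=cutoff, signed=signed).fit(expr)


def condition_zscores(normalized: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per gene, Z-scores of the six condition means across themselves.

    Columns are "{stage}:{condition}"; standardisation uses the sample SD
    (denominator 5 for six cells); all-equal means give all-zero Z.
    """
    validate_design(design)
    cells = []
    means = {}
    for stage, condition in product(STAGES, CONDITIONS):
        cols = design.loc[
            (design["stage"] == stage) & (design["condition"] == condition), "sample_id"
        ]
        if len(cols) == 0:
            raise ValueError(f"design cell ({condition}, {stage}) is empty")
        key = f"{stage}:{condition}"
        cells.append(key)
        means[key] = normalized[cols].mean(axis=1)
    m = pd.DataFrame(means)[cells]
    center = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    z = m.sub(center, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    z.index = normalized.index
    return z


def _hi(z: float) -> bool:
    return z > 1.0


def _lo(z: float) -> bool:
    return z < -1.0


def _normal(z: float) -> bool:
    return -1.0 <= z <= 1.0


def assign_group(z: dict[str, float]) -> int | None:
    """Assign one gene's six-cell Z profile to an expression group (1-6).

    high = Z > +1, low = Z < -1, normal = -1 <= Z <= +1.  Criteria, evaluated
    in order with first-match-wins:

    1: high in W1 (both conditions), low in W4 and W12/16 (both conditions).
    2: high in W12 CONV-R, low in W12 GF, normal in W1 (both) and W4 CONV-R,
       low in W4 GF.
    3: high in W12 CONV-R, low in W12 GF, low in W1 and W4 (both conditions).
       (Group 4's printed criteria coincide with group 3's; group 4 is
       reserved and never emitted.)
    5: high in W12 GF and W4 GF; low in W12 CONV-R, W1 GF, W1 CONV-R and
       W4 CONV-R.
    6: high in W12 GF and W4 GF; low in W12 CONV-R and W4 CONV-R; normal in
       W1 (both conditions).

    Returns the group number or None (unassigned).
    """
    w1c, w1g = z["W1:CONV_R"], z["W1:GF"]
    w4c, w4g = z["W4:CONV_R"], z["W4:GF"]
    w12c, w12g = z["W12_16:CONV_R"], z["W12_16:GF"]

    if _hi(w1c) and _hi(w1g) and _lo(w4c) and _lo(w4g) and _lo(w12c) and _lo(w12g):
        return 1
    if (_hi(w12c) and _lo(w12g) and _normal(w1c) and _normal(w1g)
            and _normal(w4c) and _lo(w4g)):
        return 2
    if (_hi(w12c) and _lo(w12g) and _lo(w1c) and _lo(w1g) and _lo(w4c) and _lo(w4g)):
        return 3
    if (_hi(w12g) and _lo(w12c) and _hi(w4g) and _lo(w1g) and _lo(w1c) and _lo(w4c)):
        return 5
    if (_hi(w12g) and _lo(w12c) and _hi(w4g) and _lo(w4c)
            and _normal(w1g) and _normal(w1c)):
        return 6
    return None


def assign_groups(zscores: pd.DataFrame) -> pd.DataFrame:
    """Apply assign_group row-wise; returns gene_id and group (0 = unassigned)."""
    groups = [assign_group(row.to_dict()) or 0 for _, row in zscores.iterrows()]
    return pd.DataFrame({"gene_id": zscores.index.to_numpy(), "group": groups})


def hypergeom_enrich(
    selected: set[str],
    annotation_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``selected`` in each annotation set.

    p = P(overlap >= observed) drawing |selected| from |universe| with
    |annotation ∩ universe| successes; BH-adjusted across labels.
    """
    extra = selected - universe
    if extra:
        raise ValueError(f"selected genes outside universe: {sorted(extra)[:5]}")
    rows = []
    for label, genes in annotation_sets.items():
        ann = genes & universe
        overlap = len(selected & ann)
        if len(selected) == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(ann), len(selected)))
        rows.append({"label": label, "overlap": overlap,
                     "annotation_size": len(ann), "pvalue": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["label", "overlap", "annotation_size", "pvalue"])
    if not table.empty:
        table["padj"] = multipletests(table["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        table["padj"] = []
    return table
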