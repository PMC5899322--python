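"""Co-expression: union rule, Spearman edge calling and its monotone-transform
invariance, condition Z-scores, the group truth table, and hypergeometric
enrichment against exhaustive enumeration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import methtx
from methtx.simulate import CONDITIONS, STAGES


def _de(genes, regulated):
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2FoldChange": [2.0 if r else 0.1 for r in regulated],
            "padj": [0.01 if r else 0.9 for r in regulated],
        }
    )


class TestUnion:
    def test_set_union(self):
        per_stage = {
            "W1": _de(["a", "b"], [True, True]),
            "W4": _de(["b", "c"], [True, True]),
            "W12_16": _de(["d"], [False]),
        }
        assert methtx.union_de_genes(per_stage) == {"a", "b", "c"}

    def test_empty_union_warns(self):
        with pytest.warns(UserWarning, match="empty union"):
            assert methtx.union_de_genes({"W1": _de(["a"], [False])}) == set()

    def test_disjoint_sizes_add(self):
        # disjoint per-stage sets of sizes 56, 614 and 1084 give a union of 1754
        g = [f"g{i}" for i in range(1754)]
        per_stage = {
            "W1": _de(g[:56], [True] * 56),
            "W4": _de(g[56:670], [True] * 614),
            "W12_16": _de(g[670:], [True] * 1084),
        }
        assert len(methtx.union_de_genes(per_stage)) == 1754


class TestNetwork:
    def _expr(self, rows, genes):
        return pd.DataFrame(rows, index=genes)

    def test_duplicated_gene_perfect_edge(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        net = methtx.correlation_network(self._expr([x, x, rng.normal(size=30)],
                                                    ["a", "b", "c"]))
        edges = set(zip(net.edges_["gene_a"], net.edges_["gene_b"]))
        assert ("a", "b") in edges
        assert net.edges_.set_index(["gene_a", "gene_b"]).loc[("a", "b"), "rho"] == 1.0

    def test_latent_profile_pairs_detected(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            latent = rng.normal(size=30)
            a = latent + 0.25 * rng.normal(size=30)
            b = latent + 0.25 * rng.normal(size=30)
            net = methtx.correlation_network(self._expr([a, b], ["a", "b"]))
            detected += len(net.edges_) > 0
        assert detected >= 95

    def test_independent_noise_rarely_connected(self):
        edges = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            net = methtx.correlation_network(
                self._expr(rng.normal(size=(2, 30)), ["a", "b"])
            )
            edges += len(net.edges_)
        assert edges / 100 <= 0.01

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 30)) + 5
        net1 = methtx.correlation_network(self._expr(x, list("abcd")), cutoff=0.0)
        net2 = methtx.correlation_network(
            self._expr(np.exp(x), list("abcd")), cutoff=0.0
        )
        pd.testing.assert_frame_equal(net1.edges_, net2.edges_)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            methtx.correlation_network(pd.DataFrame(np.ones((2, 2)), index=["a", "b"]))

    def test_zero_variance_excluded_with_warning(self):
        rng = np.random.default_rng(4)
        expr = self._expr([np.ones(30), rng.normal(size=30)], ["flat", "ok"])
        with pytest.warns(UserWarning, match="zero-variance"):
            net = methtx.correlation_network(expr)
        assert "flat" not in net.nodes_ and net.dropped_ == ["flat"]

    def test_signed_mode_keeps_anticorrelation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        expr = self._expr([x, -x], ["up", "down"])
        assert len(methtx.correlation_network(expr).edges_) == 0
        signed = methtx.correlation_network(expr, signed=True)
        assert len(signed.edges_) == 1 and signed.edges_["rho"].iloc[0] == -1.0


class TestConditionZscores:
    def test_equal_means_all_zero(self, design):
        expr = pd.DataFrame(
            np.ones((3, len(design))), columns=design["sample_id"], index=list("abc")
        )
        z = methtx.condition_zscores(expr, design)
        assert (z.to_numpy() == 0).all()

    def test_outlier_condition_positive(self, design):
        # means (10,10,10,10,10,16): only the outlier cell exceeds +1
        vals = {}
        for stage in STAGES:
            for cond in CONDITIONS:
                cols = design.loc[
                    (design.stage == stage) & (design.condition == cond), "sample_id"
                ]
                level = 16.0 if (stage == "W12_16" and cond == "GF") else 10.0
                for c in cols:
                    vals[c] = level
        expr = pd.DataFrame([vals], index=["g"])[design["sample_id"]]
        z = methtx.condition_zscores(expr, design)
        assert z.loc["g", "W12_16:GF"] > 1
        assert (z.drop(columns="W12_16:GF").loc["g"] < 0).all()
        # standardisation: mean 0, sample SD 1
        assert z.loc["g"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.loc["g"].std(ddof=1) == pytest.approx(1.0)

    def test_permutation_equivariance(self, design):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.normal(10, 2, size=(2, len(design))),
            columns=design["sample_id"], index=["a", "b"],
        )
        z1 = methtx.condition_zscores(expr, design)
        # relabel stages cyclically: z values follow the relabelling
        mapping = {"W1": "W4", "W4": "W12_16", "W12_16": "W1"}
        shuffled = design.copy()
        shuffled["stage"] = shuffled["stage"].map(mapping)
        z2 = methtx.condition_zscores(expr, shuffled)
        for stage in STAGES:
            for cond in CONDITIONS:
                assert z2.loc["a", f"{mapping[stage]}:{cond}"] == pytest.approx(
                    z1.loc["a", f"{stage}:{cond}"]
                )

    def test_empty_cell_rejected(self, design):
        sub = design.loc[~((design.stage == "W4") & (design.condition == "GF"))]
        expr = pd.DataFrame(
            np.ones((1, len(sub))), columns=sub["sample_id"], index=["g"]
        )
        with pytest.raises(ValueError, match="GF.*W4|W4.*GF"):
            methtx.condition_zscores(expr, sub.reset_index(drop=True))


class TestGroupAssignment:
    H, L, N = 1.5, -1.5, 0.0

    def _z(self, w1c, w1g, w4c, w4g, w12c, w12g):
        return {
            "W1:CONV_R": w1c, "W1:GF": w1g,
            "W4:CONV_R": w4c, "W4:GF": w4g,
            "W12_16:CONV_R": w12c, "W12_16:GF": w12g,
        }

    def truth_table(self):
        H, L, N = self.H, self.L, self.N
        return [
            # (profile, expected group)
            (self._z(H, H, L, L, L, L), 1),    # high W1, low later, cond-independent
            (self._z(1.4, 1.3, L, L, L, L), 1),
            (self._z(N, N, N, L, H, L), 2),    # adult CONV-R induction, W4 GF low
            (self._z(L, L, L, L, H, L), 3),    # adult CONV-R induction, low before
            (self._z(L, L, L, H, L, H), 5),    # GF high W4+W12, low elsewhere
            (self._z(N, N, L, H, L, H), 6),    # GF high W4+W12, normal W1
            (self._z(0, 0, 0, 0, 0, 0), None),
            (self._z(H, L, L, L, L, L), None),  # W1 high in one condition only
            (self._z(N, N, N, N, H, L), None),  # no W4 GF repression -> not group 2
            (self._z(L, L, L, H, H, L), None),  # mixed adult pattern
            (self._z(H, H, H, H, L, L), None),
            (self._z(N, N, L, H, L, N), None),  # W12 GF not high
        ]

    def test_truth_table(self):
        for z, expected in self.truth_table():
            assert methtx.assign_group(z) == expected, z

    def test_group4_reserved(self):
        # the printed criteria for groups 3 and 4 coincide; the rule emits 3
        z = self._z(self.L, self.L, self.L, self.L, self.H, self.L)
        assert methtx.assign_group(z) == 3

    def test_assign_groups_frame(self):
        profiles = pd.DataFrame(
            [self._z(self.H, self.H, self.L, self.L, self.L, self.L),
             self._z(0, 0, 0, 0, 0, 0)],
            index=["g1", "g2"],
        )
        out = methtx.assign_groups(profiles)
        assert out.set_index("gene_id")["group"].to_dict() == {"g1": 1, "g2": 0}


def exhaustive_hypergeom_p(n_universe, annotation, selected_size, observed):
    """P(overlap >= observed) by enumerating all equally likely draws."""
    total = comb(n_universe, selected_size, exact=True)
    hits = 0
    universe = list(range(n_universe))
    for draw in combinations(universe, selected_size):
        if len(set(draw) & annotation) >= observed:
            hits += 1
    return hits / total


class TestHypergeomEnrichment:
    def test_worked_example(self):
        # universe 10, annotation 5, selected 4, overlap 4 -> C(5,4)/C(10,4)
        universe = {f"g{i}" for i in range(10)}
        ann = {f"g{i}" for i in range(5)}
        sel = {f"g{i}" for i in range(4)}
        out = methtx.hypergeom_enrich(sel, {"set": ann}, universe)
        assert out["pvalue"].iloc[0] == pytest.approx(1 / 42)

    def test_empty_selection_p_one(self):
        out = methtx.hypergeom_enrich(
            set(), {"set": {"a"}}, {"a", "b"}
        )
        assert out["pvalue"].iloc[0] == 1.0

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            methtx.hypergeom_enrich({"x"}, {}, {"a"})

    def test_matches_exhaustive_enumeration(self):
        # every configuration with |universe| <= 12 (sampled grid over sizes)
        rng = np.random.default_rng(0)
        for n_universe in (3, 5, 8, 12):
            universe = {f"g{i}" for i in range(n_universe)}
            for ann_size in range(0, n_universe + 1, max(1, n_universe // 3)):
                ann_idx = set(rng.choice(n_universe, size=ann_size, replace=False).tolist())
                ann = {f"g{i}" for i in ann_idx}
                for sel_size in range(0, n_universe + 1, max(1, n_universe // 3)):
                    sel_idx = rng.choice(n_universe, size=sel_size, replace=False)
                    sel = {f"g{i}" for i in sel_idx}
                    observed = len(sel & ann)
                    got = methtx.hypergeom_enrich(sel, {"s": ann}, universe)
                    expected = (
                        1.0 if sel_size == 0
                        else exhaustive_hypergeom_p(n_universe, ann_idx, sel_size, observed)
                    )
                    assert got["pvalue"].iloc[0] == pytest.approx(expected, abs=1e-12)
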