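"""Integration procedure: window and merge semantics against a brute-force
oracle, boundary rules at 200 bp / 20% / 5 kb, hierarchical BH, coupling
classification, and end-to-end exactness on a constructed fixture."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methtx
from methtx.integration import MethylRegion


def brute_force_merge(positions, max_gap=200):
    """Connected components of the pairwise <= max_gap graph (independent oracle)."""
    g = nx.Graph()
    g.add_nodes_from(positions)
    for a in positions:
        for b in positions:
            if a < b and b - a <= max_gap:
                g.add_edge(a, b)
    return sorted(sorted(c) for c in nx.connected_components(g))


class TestWindowSites:
    def test_symmetric_inclusive_window(self):
        pos = np.array([4_999, 5_000, 10_000, 15_000, 15_001])
        hits = methtx.window_sites(10_000, pos, window=5000)
        assert hits.tolist() == [5_000, 10_000, 15_000]

    def test_boundary_exactly_5000_included(self):
        assert methtx.window_sites(10_000, np.array([15_000]), 5000).tolist() == [15_000]
        assert methtx.window_sites(10_000, np.array([15_001]), 5000).tolist() == []

    def test_strand_independent(self):
        # the window depends only on the TSS coordinate
        pos = np.arange(0, 30_000, 700)
        assert (
            methtx.window_sites(12_000, pos).tolist()
            == methtx.window_sites(12_000, pos[::-1][::-1]).tolist()
        )


class TestMergeRegions:
    @pytest.mark.parametrize(
        "positions,expected",
        [
            ([100, 250, 900], [[100, 250], [900]]),
            ([100, 300], [[100, 300]]),          # gap exactly 200 merges
            ([100, 301], [[100], [301]]),        # 201 splits
            ([42], [[42]]),
            ([], []),
        ],
    )
    def test_examples(self, positions, expected):
        regions = methtx.merge_regions(positions, max_gap=200)
        assert [r.cpg_positions for r in regions] == expected
        if regions:
            assert regions[0].start == expected[0][0]
            assert regions[-1].end == expected[-1][-1]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            methtx.merge_regions([5, 3, 10])
        with pytest.raises(ValueError, match="sorted"):
            methtx.merge_regions([3, 3, 10])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 40)
            positions = sorted(
                set(rng.integers(0, 5000, size=n).tolist())
            )
            got = [r.cpg_positions for r in methtx.merge_regions(positions)]
            assert got == brute_force_merge(positions)

    @given(
        st.sets(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=60),
        st.integers(min_value=1, max_value=500),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_properties(self, posset, max_gap):
        positions = sorted(posset)
        regions = methtx.merge_regions(positions, max_gap=max_gap)
        flat = [p for r in regions for p in r.cpg_positions]
        assert flat == positions  # union preserved, order kept
        for r in regions:
            assert (np.diff(r.cpg_positions) <= max_gap).all()
        for a, b in zip(regions, regions[1:]):
            assert b.start - a.end > max_gap  # maximality


class TestFilterRegions:
    def _region(self, n, chrom="chr1"):
        return MethylRegion(chrom=chrom, cpg_positions=list(range(100, 100 + n * 10, 10)),
                            gene_id="g")

    @pytest.mark.parametrize(
        "n,n_sig,retained",
        [
            (10, 1, False),  # 10% < 20% -> excluded
            (10, 2, True),   # exactly 20% retained
            (1, 1, True),    # singleton significant
            (1, 0, False),
            (5, 1, True),    # 20% boundary again
        ],
    )
    def test_fraction_rule(self, n, n_sig, retained):
        region = self._region(n)
        padj = {p: (0.01 if i < n_sig else 0.5)
                for i, p in enumerate(region.cpg_positions)}
        out = methtx.filter_regions([region], padj)[0]
        assert out.retained is retained
        assert out.frac_sig == pytest.approx(n_sig / n)

    def test_missing_padj_names_position(self):
        region = self._region(3)
        with pytest.raises(KeyError, match="110"):
            methtx.filter_regions([region], {100: 0.01, 120: 0.5})


class TestHierarchicalFDR:
    def test_single_cpg_identity(self):
        region = MethylRegion("chr1", [100], retained=True)
        assert methtx.hierarchical_fdr([region], {100: 0.01}) == {100: 0.01}

    def test_hand_bh(self):
        region = MethylRegion("chr1", [10, 20, 30, 40], retained=True)
        out = methtx.hierarchical_fdr(
            [region], {10: 0.01, 20: 0.02, 30: 0.03, 40: 0.04}
        )
        # BH: min over j >= i of m p_j / j = 0.04 for every rank
        assert all(v == pytest.approx(0.04) for v in out.values())

    def test_excluded_region_cpgs_absent(self):
        kept = MethylRegion("chr1", [10], retained=True)
        dropped = MethylRegion("chr1", [500], retained=False)
        out = methtx.hierarchical_fdr([kept, dropped], {10: 0.02, 500: 0.001})
        assert 500 not in out

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert methtx.hierarchical_fdr([], {}) == {}


class TestCoupleGenes:
    def _de(self, m):
        return pd.DataFrame(
            {"gene_id": ["g1"], "log2FoldChange": [m], "padj": [0.001],
             "regulated": [True]}
        )

    def _region(self, retained=True):
        r = MethylRegion("chr1", [100, 200], gene_id="g1", retained=retained)
        r.frac_sig = 1.0
        return r

    @pytest.mark.parametrize(
        "m,delta,expected",
        [
            (2.0, -0.3, "canonical"),       # up with hypomethylation
            (2.0, 0.3, "non_canonical"),
            (-2.0, 0.3, "canonical"),
            (-2.0, -0.3, "non_canonical"),
        ],
    )
    def test_coupling_sign_rule(self, m, delta, expected):
        loci = methtx.couple_genes(
            self._de(m), [self._region()], {100: delta, 200: delta},
            {100: 0.01, 200: 0.01}, "W4",
        )
        assert len(loci) == 1 and loci[0].coupling == expected

    def test_zero_mean_delta_warns_non_canonical(self):
        with pytest.warns(UserWarning, match="zero mean"):
            loci = methtx.couple_genes(
                self._de(1.5), [self._region()], {100: 0.2, 200: -0.2},
                {100: 0.01, 200: 0.01}, "W4",
            )
        assert loci[0].coupling == "non_canonical"

    def test_no_final_significant_cpg_emits_nothing(self):
        loci = methtx.couple_genes(
            self._de(1.5), [self._region()], {100: 0.2, 200: 0.2},
            {100: 0.2, 200: 0.9}, "W4",
        )
        assert loci == []

    def test_unknown_gene_rejected(self):
        region = self._region()
        region.gene_id = "mystery"
        with pytest.raises(KeyError, match="mystery"):
            methtx.couple_genes(self._de(1.0), [region], {}, {}, "W4")


class TestEndToEndFixture:
    """Hand-built dataset with fully predictable coupling output."""

    def _fixture(self):
        genes = pd.DataFrame(
            [
                # geneA: regulated, has a proximal significant region -> coupled
                {"gene_id": "geneA", "chrom": "chr1", "strand": "+",
                 "start": 10_000, "end": 12_000, "tss": 10_000},
                # geneB: regulated, region present but nothing significant
                {"gene_id": "geneB", "chrom": "chr1", "strand": "-",
                 "start": 50_000, "end": 52_000, "tss": 52_000},
                # geneC: not regulated, would otherwise couple
                {"gene_id": "geneC", "chrom": "chr1", "strand": "+",
                 "start": 90_000, "end": 92_000, "tss": 90_000},
            ]
        )
        de = pd.DataFrame(
            {
                "gene_id": ["geneA", "geneB", "geneC"],
                "log2FoldChange": [2.0, -1.5, 3.0],
                "padj": [0.001, 0.02, 0.001],
                "regulated": [True, True, False],
            }
        )
        dmp = pd.DataFrame(
            {
                "chrom": "chr1",
                # three CpGs near geneA TSS (gaps 100), two near geneB, two near geneC
                "pos": [9_900, 10_000, 10_100, 51_900, 52_050, 89_950, 90_050],
                "delta": [-0.3, -0.35, -0.25, 0.2, 0.2, 0.4, 0.4],
                "pvalue": [1e-5, 1e-4, 0.3, 0.4, 0.5, 1e-6, 1e-6],
                "padj": [1e-4, 1e-3, 0.5, 0.6, 0.7, 1e-5, 1e-5],
            }
        )
        return genes, de, dmp

    def test_exact_coupled_set(self):
        genes, de, dmp = self._fixture()
        loci, regions = methtx.integrate_stage(de, dmp, genes, "W4")
        assert [(l.gene_id, l.coupling) for l in loci] == [("geneA", "canonical")]
        locus = loci[0]
        assert locus.region.cpg_positions == [9_900, 10_000, 10_100]
        # mean delta over ALL region CpGs
        assert locus.mean_delta == pytest.approx((-0.3 - 0.35 - 0.25) / 3)
        by_gene = {r.gene_id: r for r in regions}
        assert by_gene["geneA"].retained  # 2/3 significant
        assert not by_gene["geneB"].retained  # 0/2 significant
        assert "geneC" not in by_gene  # never screened: not regulated

    def test_window_monotonicity(self):
        genes, de, dmp = self._fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small, _ = methtx.integrate_stage(de, dmp, genes, "W4", window=500)
            large, _ = methtx.integrate_stage(de, dmp, genes, "W4", window=8000)
        small_keys = {(l.gene_id, l.region.start) for l in small}
        large_keys = {(l.gene_id, l.region.start) for l in large}
        assert small_keys <= large_keys

    def test_min_frac_monotonicity(self):
        genes, de, dmp = self._fixture()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strict, _ = methtx.integrate_stage(de, dmp, genes, "W4", min_frac=0.9)
            lax, _ = methtx.integrate_stage(de, dmp, genes, "W4", min_frac=0.1)
        assert {(l.gene_id, l.region.start) for l in strict} <= {
            (l.gene_id, l.region.start) for l in lax
        }


def test_stage_specificity_bookkeeping():
    per_stage = {
        "W1": {"a", "b"},
        "W4": {"b", "c", "d"},
        "W12_16": {"e"},
    }
    out = methtx.integration.stage_specificity(per_stage)
    assert out == {"union": 5, "multi_stage": 1, "stage_specific": 4}
    assert out["union"] - out["multi_stage"] == out["stage_specific"]
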