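"""CPM filtering, the NB Wald surrogate test, BH adjustment, DEG counting,
ortholog mapping and signature selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizmap import synthetic as ssyn
from seizmap import transcriptomics as T


def bh_oracle(p):
    """Literal step-up enumeration: the adjusted p of a hypothesis is the
    smallest level q at which the BH rejection set includes it."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    eps = 1e-12  # guards the <= comparisons against float round-off
    candidate_levels = sorted({n * p[order[j]] / (j + 1) for j in range(n)} | {1.0})
    adj = [None] * n
    for i in range(n):
        best = 1.0
        for q in candidate_levels:
            # largest j with p_(j) <= j q / n; reject all with p <= p_(j)
            cut = -1
            for j in range(n):
                if p[order[j]] <= (j + 1) * q / n + eps:
                    cut = j
            if cut >= 0 and p[i] <= p[order[cut]]:
                best = min(best, q)
        adj[i] = min(best, 1.0)
    return adj


def two_group_counts(values_a, values_b):
    """Tiny matrix from explicit per-sample counts of one gene plus stable
    helper genes so size factors are well defined."""
    n = len(values_a)
    data = {f"a_{i + 1}": [values_a[i], 100, 200] for i in range(n)}
    data.update({f"b_{i + 1}": [values_b[i], 100, 200] for i in range(n)})
    counts = pd.DataFrame(data, index=["g_test", "g_h1", "g_h2"])
    design = {c: c.split("_")[0] for c in counts.columns}
    return counts, design


class TestCPM:
    def test_definition(self):
        counts = pd.DataFrame({"s1": [100, 999_900]}, index=["g1", "g2"])
        assert T.cpm(counts).loc["g1", "s1"] == pytest.approx(100.0)

    def test_all_zero_gene(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [0, 20]}, index=["g1", "g2"])
        assert (T.cpm(counts).loc["g1"] == 0).all()

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, (30, 4)))
        np.testing.assert_allclose(T.cpm(counts).sum(axis=0), 1e6)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError):
            T.cpm(counts)


class TestFilterExpressed:
    def test_zero_gene_dropped_and_one_condition_suffices(self):
        counts = pd.DataFrame(
            {
                "wt_1": [0, 50_000, 0], "wt_2": [0, 50_000, 0],
                "mut_1": [0, 0, 50_000], "mut_2": [0, 0, 50_000],
            },
            index=["dead", "wt_only", "mut_only"],
        )
        design = {c: c.rsplit("_", 1)[0] for c in counts.columns}
        kept = T.filter_expressed(counts, design)
        assert list(kept.index) == ["wt_only", "mut_only"]

    def test_idempotent_and_subset(self):
        counts, _ = ssyn.simulate_counts(ssyn.CountSimConfig(n_genes=300, seed=2))
        design = ssyn.design_of(counts)
        once = T.filter_expressed(counts, design)
        twice = T.filter_expressed(once, design)
        assert set(once.index) <= set(counts.index)
        pd.testing.assert_frame_equal(once, twice)


class TestNBWald:
    def test_identical_groups_give_null_result(self):
        counts, design = two_group_counts([50, 60, 55, 52], [50, 60, 55, 52])
        res = T.nb_wald_test(counts, design, ("b", "a")).set_index("gene_id")
        row = res.loc["g_test"]
        assert row["log2fc"] == pytest.approx(0.0, abs=1e-9)
        assert abs(row["wald"]) < 1e-6
        assert row["pvalue"] > 0.99

    def test_sign_consistency(self):
        counts, truth = ssyn.simulate_counts(
            ssyn.CountSimConfig(n_genes=500, frac_de=0.2, seed=13)
        )
        design = ssyn.design_of(counts)
        res = T.nb_wald_test(T.filter_expressed(counts, design), design, ("hom", "wt"))
        nz = res[res["log2fc"] != 0]
        assert (np.sign(nz["wald"]) == np.sign(nz["log2fc"])).all()

    def test_null_type_one_error_calibrated(self):
        counts, _ = ssyn.simulate_counts(ssyn.CountSimConfig(n_genes=2000, frac_de=0.0, seed=7))
        design = ssyn.design_of(counts)
        res = T.nb_wald_test(T.filter_expressed(counts, design), design, ("hom", "wt"))
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_genes_recovered(self):
        counts, truth = ssyn.simulate_counts(
            ssyn.CountSimConfig(n_genes=2000, frac_de=0.1, seed=8)
        )
        design = ssyn.design_of(counts)
        res = T.nb_wald_test(T.filter_expressed(counts, design), design, ("hom", "wt"))
        merged = res.merge(truth, on="gene_id")
        planted = merged[merged["is_de"]]
        hit = (planted["padj"] < 0.05) & (
            np.sign(planted["wald"]) == np.sign(planted["true_log2fc"])
        )
        assert hit.mean() >= 0.9

    def test_all_zero_gene_excluded(self):
        counts, design = two_group_counts([50, 60, 55, 52], [10, 12, 9, 14])
        counts.loc["g_dead"] = 0
        res = T.nb_wald_test(counts, design, ("b", "a"))
        assert "g_dead" not in set(res["gene_id"])

    def test_too_few_replicates_rejected(self):
        counts = pd.DataFrame({"a_1": [5], "b_1": [9], "b_2": [7]}, index=["g"])
        with pytest.raises(ValueError):
            T.nb_wald_test(counts, {"a_1": "a", "b_1": "b", "b_2": "b"}, ("b", "a"))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert T.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(
            T.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(T.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_step_up_enumeration(self, p):
        np.testing.assert_allclose(T.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            T.bh_adjust([0.0, 0.5])


class TestCountDEG:
    def test_empty(self):
        assert T.count_deg(pd.DataFrame()) == (0, 0, 0)

    def test_table_fixture_counts(self, top_genes):
        assert T.count_deg(top_genes, alpha=0.05) == (20, 10, 10)

    def test_table_fixture_with_fold_change_cut(self, top_genes):
        # one up gene (fold change 1.93) falls below the 2-fold rule
        assert T.count_deg(top_genes, alpha=0.05, min_abs_fc=2.0) == (19, 9, 10)

    def test_conservation_property(self):
        rng = np.random.default_rng(3)
        res = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(200)],
                "fold_change": rng.lognormal(0, 1, 200),
                "padj": rng.uniform(0, 1, 200),
            }
        )
        for fc in (None, 1.5, 2.0):
            n, up, down = T.count_deg(res, min_abs_fc=fc)
            assert n == up + down


class TestMapOrthologs:
    def de_rows(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "wald", "pvalue"])
        df["log2fc"] = df["wald"] / 5
        df["fold_change"] = 2.0 ** df["log2fc"]
        df["padj"] = df["pvalue"]
        return df

    def test_bijective_table_renames_only(self):
        de = self.de_rows([("z1", 3.0, 0.01), ("z2", -2.0, 0.02)])
        table = pd.DataFrame({"source_id": ["z1", "z2"], "target_symbol": ["H1", "H2"]})
        out = T.map_orthologs(de, table).set_index("gene_id")
        assert out.loc["H1", "wald"] == 3.0 and out.loc["H2", "wald"] == -2.0

    def test_one_to_many_duplicates_statistics(self):
        de = self.de_rows([("z1", 3.0, 0.01)])
        table = pd.DataFrame({"source_id": ["z1", "z1"], "target_symbol": ["H1", "H2"]})
        out = T.map_orthologs(de, table)
        assert sorted(out["gene_id"]) == ["H1", "H2"]
        assert (out["wald"] == 3.0).all()

    def test_many_to_one_keeps_largest_abs_wald(self):
        de = self.de_rows([("z1", 3.0, 0.01), ("z2", -5.0, 0.001)])
        table = pd.DataFrame({"source_id": ["z1", "z2"], "target_symbol": ["H1", "H1"]})
        out = T.map_orthologs(de, table)
        assert len(out) == 1 and out.loc[0, "wald"] == -5.0

    def test_unmapped_dropped_and_empty_table_rejected(self):
        de = self.de_rows([("z1", 3.0, 0.01), ("z2", 1.0, 0.3)])
        table = pd.DataFrame({"source_id": ["z1"], "target_symbol": ["H1"]})
        assert list(T.map_orthologs(de, table)["gene_id"]) == ["H1"]
        with pytest.raises(ValueError):
            T.map_orthologs(de, table.iloc[:0])


class TestSelectSignature:
    def test_exact_split_takes_everything(self):
        rng = np.random.default_rng(4)
        de = pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in range(100)],
                "wald": np.concatenate([rng.uniform(1, 9, 50), rng.uniform(-9, -1, 50)]),
            }
        )
        de["pvalue"] = 1e-3
        sig = T.select_signature(de, k=50)
        assert len(sig.up) == 50 and len(sig.down) == 50
        assert set(sig.up).isdisjoint(sig.down)

    def test_table_fixture_ordering(self, top_genes):
        sig = T.select_signature(top_genes, k=10)
        assert sig.up[0] == "prl2"
        assert sig.down[0] == "sv2a"
        assert len(sig.up) == len(sig.down) == 10

    def test_row_order_invariance_and_tie_break(self):
        de = pd.DataFrame(
            {
                "gene_id": ["b", "a", "c", "d"],
                "wald": [2.0, 2.0, -1.0, -3.0],
                "pvalue": [0.01, 0.01, 0.02, 0.001],
            }
        )
        sig1 = T.select_signature(de, k=2)
        sig2 = T.select_signature(de.iloc[::-1].reset_index(drop=True), k=2)
        assert sig1 == sig2
        assert sig1.up == ("a", "b")  # equal wald and p: lexicographic

    def test_short_side_takes_all_available(self):
        de = pd.DataFrame(
            {"gene_id": ["u1", "d1", "d2"], "wald": [4.0, -1.0, -2.0], "pvalue": [0.01] * 3}
        )
        sig = T.select_signature(de, k=5)
        assert sig.up == ("u1",) and len(sig.down) == 2
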