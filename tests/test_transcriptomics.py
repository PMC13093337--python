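import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from owh_screen import synthetic_data as sd
from owh_screen import transcriptomics as tx


@pytest.fixture
def counts():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.integers(1, 1000, size=(30, 8)).astype(float),
                       index=[f"T{i}" for i in range(30)],
                       columns=[f"s{j}" for j in range(8)])
    return raw


class TestNormalize:
    def test_scaling_invariance(self, counts):
        hk = ["T0", "T1", "T2"]
        base = tx.normalize_expression(counts, housekeeping=hk)
        scaled = counts.copy()
        scaled["s3"] = scaled["s3"] * 2.0
        again = tx.normalize_expression(scaled, housekeeping=hk)
        pd.testing.assert_frame_equal(base, again)

    def test_identity_case(self, counts):
        # pre-scale every sample to geometric mean 1
        geo = np.exp(np.log(counts).mean(axis=0))
        pre = counts.div(geo, axis=1)
        out = tx.normalize_expression(pre)
        assert np.allclose(out, np.log2(pre + 1.0))

    def test_zero_maps_to_zero(self):
        raw = pd.DataFrame({"s0": [0.0, 1.0, 1.0], "s1": [0.0, 1.0, 1.0]},
                           index=["a", "b", "c"])
        out = tx.normalize_expression(raw)
        assert out.loc["a"].eq(0.0).all()

    def test_all_zero_sample_raises(self):
        raw = pd.DataFrame({"s0": [0.0, 0.0], "s1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-zero"):
            tx.normalize_expression(raw)


class TestDifferentialExpression:
    def test_planted_shift_recovered(self):
        cfg = sd.SimulationConfig(seed=17, n_deg=20, n_emergent=0,
                                  noise_sd=0.05)
        values, meta, truth = sd.gen_expression_panel(cfg)
        deg = tx.differential_expression(values, meta, "OGD", "control",
                                         region="cortex")
        planted = truth.loc[truth["effect"] == "deg", "transcript"]
        lfc = deg.loc[planted, "log2fc"]
        assert np.all((lfc >= 0.9) & (lfc <= 1.1))
        assert deg.loc[planted, "significant"].all()

    def test_antisymmetry(self, expression_panel):
        _, values, meta, _ = expression_panel
        ab = tx.differential_expression(values, meta, "OGD", "control")
        ba = tx.differential_expression(values, meta, "control", "OGD")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p"], ba["p"])

    def test_type_i_calibration(self):
        rng = np.random.default_rng(1)
        rates = []
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(12)],
                             "group": ["A"] * 6 + ["B"] * 6,
                             "region": ["cortex"] * 12})
        for _ in range(100):
            values = pd.DataFrame(rng.normal(size=(200, 12)),
                                  columns=meta["sample_id"])
            deg = tx.differential_expression(values, meta, "A", "B")
            rates.append(deg["significant"].mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_lfc_cut(self, expression_panel):
        _, values, meta, _ = expression_panel
        deg = tx.differential_expression(values, meta, "OGD", "control",
                                         lfc_cut=5.0)
        assert not deg["significant"].any()

    def test_missing_group_raises(self, expression_panel):
        _, values, meta, _ = expression_panel
        with pytest.raises(ValueError):
            tx.differential_expression(values, meta, "OGD", "nonexistent")


class TestPCA:
    def test_k1_for_dominant_variance(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=100)
        # two transcripts, variance split ~99:1 across samples
        values = pd.DataFrame({f"s{i}": [10 * t[i], 0.1 * rng.normal()]
                               for i in range(100)},
                              index=["T0", "T1"])
        model = tx.pca_select(values)
        assert model.k_selected == 1

    def test_ratios_sum_to_one(self, expression_panel):
        _, values, _, _ = expression_panel
        model = tx.pca_select(values)
        assert np.sum(model.explained_variance_ratio) == pytest.approx(1.0)

    def test_isotropic_needs_most_components(self):
        rng = np.random.default_rng(3)
        d = 20
        values = pd.DataFrame(rng.normal(size=(d, 500)))
        model = tx.pca_select(values)
        assert abs(model.k_selected - int(np.ceil(0.95 * d))) <= 1

    def test_contributions_sum_100(self, expression_panel):
        _, values, _, _ = expression_panel
        model = tx.pca_select(values)
        sums = model.contributions.sum(axis=0)
        assert np.allclose(sums, 100.0)

    def test_reconstruction_lossless(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(size=(10, 25)))
        model = tx.pca_select(values)
        X = values.T.to_numpy()
        centered = X - X.mean(axis=0)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-9)


class TestTopContributors:
    def test_dominant_variable(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(5, 50)) * 0.01,
                              index=[f"T{i}" for i in range(5)])
        values.loc["T3"] += rng.normal(size=50) * 10
        model = tx.pca_select(values)
        top = tx.top_contributors(model, 1, k=1)
        assert top.loc[0, "transcript"] == "T3"
        assert top.loc[0, "contribution"] > 95.0

    def test_clamped_k(self, expression_panel):
        _, values, _, _ = expression_panel
        model = tx.pca_select(values)
        top = tx.top_contributors(model, 2, k=10_000)
        assert len(top) == len(values)

    def test_descending_order(self, expression_panel):
        _, values, _, _ = expression_panel
        model = tx.pca_select(values)
        top = tx.top_contributors(model, 1, k=25)
        assert len(top) == 25
        assert top["contribution"].is_monotonic_decreasing


class TestVennPartition:
    def test_basic_partition(self):
        out = tx.venn_partition({"S1": {"A", "B"}, "S2": {"B", "C"}})
        region = out.set_index("element")["region"]
        assert region["A"] == "S1"
        assert region["C"] == "S2"
        assert region["B"] == "S1&S2"

    def test_disjoint(self):
        out = tx.venn_partition({"S1": {"A"}, "S2": {"B"}})
        assert set(out["region"]) == {"S1", "S2"}

    def test_region_count_bound(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(50)]
        sets = {f"S{k}": set(rng.choice(universe, 20)) for k in range(4)}
        out = tx.venn_partition(sets)
        assert out["region"].nunique() <= 2**4 - 1
        # every element in exactly one region
        assert out["element"].is_unique


def brute_force_combo_filter(tables):
    ogd, az, epo, azepo = tables
    result = []
    for t in ogd.index:
        if (ogd.loc[t, "significant"] and not azepo.loc[t, "significant"]
                and az.loc[t, "significant"] and epo.loc[t, "significant"]):
            result.append(t)
    return result


class TestComboNormalized:
    def random_deg_tables(self, rng, n=40):
        idx = [f"T{i}" for i in range(n)]
        tables = []
        for _ in range(4):
            tables.append(pd.DataFrame(
                {"log2fc": rng.normal(size=n), "p": rng.random(n),
                 "significant": rng.random(n) < 0.4,
                 "direction": "up"}, index=idx))
        return tables

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tables = self.random_deg_tables(rng)
            got = tx.combo_normalized_transcripts(*tables)
            assert got == brute_force_combo_filter(tables)

    def test_planted_combo_restoration(self, expression_panel):
        cfg, values, meta, truth = expression_panel
        degs = {g: tx.differential_expression(values, meta, g, "control")
                for g in ("OGD", "Az", "Epo", "AzEpo")}
        got = set(tx.combo_normalized_transcripts(
            degs["OGD"], degs["Az"], degs["Epo"], degs["AzEpo"]))
        planted = set(truth.loc[truth["restored_by"] == "AzEpo", "transcript"])
        az_restored = set(truth.loc[truth["restored_by"] == "Az", "transcript"])
        assert planted <= got
        assert not (az_restored & got)

    def test_no_ogd_degs_empty(self):
        rng = np.random.default_rng(8)
        tables = self.random_deg_tables(rng)
        tables[0]["significant"] = False
        assert tx.combo_normalized_transcripts(*tables) == []

    def test_mismatched_panel_raises(self):
        rng = np.random.default_rng(9)
        tables = self.random_deg_tables(rng)
        tables[1] = tables[1].iloc[:-1]
        with pytest.raises(ValueError, match="mismatched"):
            tx.combo_normalized_transcripts(*tables)


class TestEnrichment:
    def test_exact_full_overlap_p(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = set(universe[:10])
        query = list(gene_set)
        out = tx.geneset_enrichment(query, {"S": gene_set}, universe)
        expected = 1.0 / comb(100, 10)
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = set(universe[:10])
        query = universe[50:60]
        out = tx.geneset_enrichment(query, {"S": gene_set}, universe)
        expected = float(stats.hypergeom.sf(-1, 100, 10, 10))
        assert out.loc[0, "p"] == pytest.approx(expected)
        assert out.loc[0, "p"] == 1.0

    def test_bh_arithmetic(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_fold_enrichment(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = set(universe[:20])
        query = universe[:10]
        out = tx.geneset_enrichment(query, {"S": gene_set}, universe)
        assert out.loc[0, "fold_enrichment"] == pytest.approx(
            (10 / 10) / (20 / 100))

    def test_empty_query_raises(self):
        with pytest.raises(ValueError):
            tx.geneset_enrichment([], {"S": {"a"}}, ["a"])

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\n")
        sets = tx.read_gmt(path)
        assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g2"}}
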