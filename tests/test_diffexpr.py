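"""Moderated t, BH adjustment, DE calling, phenotypes, clustering, ddCt."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ltrfunc.diffexpr import (DeConfig, aggregate_loci, bh_adjust, call_de,
                              classify_phenotype, ddct, linkage_to_newick,
                              moderated_t, top_variance_cluster, trigamma_inverse)
from ltrfunc.synthetic_chip import SimParams, generate_design, simulate


def _sheet(n_per_group, conditions=("NS", "LPS")):
    rows = []
    i = 0
    for cond in conditions:
        for j in range(n_per_group):
            rows.append({"sample_id": f"S{i}", "donor": f"D{i}",
                         "condition": cond, "replicate": 1})
            i += 1
    return pd.DataFrame(rows)


def _frame(x, sheet):
    return pd.DataFrame(x, index=[f"p{i}" for i in range(len(x))],
                        columns=sheet["sample_id"])


class TestModeratedT:
    def test_identical_groups_null_result(self):
        sheet = _sheet(3)
        x = np.tile(np.arange(5, dtype=float)[:, None], (1, 6))
        res = moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))
        assert (res["log2fc"] == 0).all()
        assert (res["t_mod"] == 0).all()
        assert (res["p"] == 1).all()

    def test_single_sample_group_rejected(self):
        sheet = _sheet(3).iloc[[0, 1, 2, 3]]
        x = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError, match="LPS"):
            moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))

    def test_d0_zero_limit_matches_plain_t(self, monkeypatch):
        """At d0 = 0 the squeeze vanishes and the moderated t must equal the
        ordinary two-sample t (scipy is the independent oracle)."""
        import ltrfunc.diffexpr as dx
        monkeypatch.setattr(dx, "fit_variance_prior", lambda s2, df: (0.0, 1.0))
        rng = np.random.default_rng(1)
        x = rng.normal(0, np.exp(rng.normal(0, 1, 500))[:, None], (500, 10))
        sheet = _sheet(5)
        res = moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))
        plain = stats.ttest_ind(x[:, 5:], x[:, :5], axis=1)
        assert np.allclose(res["t_mod"], plain.statistic)
        assert np.allclose(res["p"], plain.pvalue)

    def test_d0_infinite_limit_matches_z_test(self, monkeypatch):
        """At d0 = inf every probeset uses the prior variance s0^2: the
        statistic is the z-like test with pooled variance, normal p-values."""
        import ltrfunc.diffexpr as dx
        s0 = 0.25
        monkeypatch.setattr(dx, "fit_variance_prior",
                            lambda s2, df: (np.inf, s0))
        rng = np.random.default_rng(2)
        x = rng.normal(0, 0.5, (500, 10))
        sheet = _sheet(5)
        res = moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))
        assert np.isinf(res["df_total"].iloc[0])
        z = res["log2fc"] / np.sqrt(s0 * (1 / 5 + 1 / 5))
        assert np.allclose(res["t_mod"], z)
        assert np.allclose(res["p"], 2 * stats.norm.sf(np.abs(z)))

    def test_prior_df_tracks_variance_heterogeneity(self):
        """The fitted d0 is small when true variances are wildly spread and
        large when they are homogeneous."""
        from ltrfunc.diffexpr import fit_variance_prior
        rng = np.random.default_rng(12)
        d = 8
        spread = rng.normal(0, np.exp(rng.normal(0, 3, 4000))[:, None], (4000, d + 1))
        homo = rng.normal(0, 0.5, (4000, d + 1))
        d0_spread, _ = fit_variance_prior(spread.var(axis=1, ddof=1), d)
        d0_homo, _ = fit_variance_prior(homo.var(axis=1, ddof=1), d)
        assert d0_spread < 1.0
        assert d0_homo > 50.0

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(3)
        n = 10_000
        s = 0.1 * np.sqrt(4 / rng.chisquare(4, n))
        x = rng.normal(0, s[:, None], (n, 30))
        sheet = _sheet(15)
        res = moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))
        assert abs((res["p"] < 0.05).mean() - 0.05) < 0.01
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01

    def test_matches_limma_on_fixture(self, tmp_path):
        """Bioconductor limma is the independent oracle for the full
        empirical-Bayes computation (hyperparameters, t, p)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; limma oracle cannot run")
        rng = np.random.default_rng(4)
        n = 300
        s = 0.2 * np.sqrt(6 / rng.chisquare(6, n))
        x = rng.normal(0, s[:, None], (n, 6))
        x[:30, 3:] += 1.5
        mat_path = tmp_path / "mat.csv"
        out_path = tmp_path / "limma.csv"
        pd.DataFrame(x).to_csv(mat_path, index=False)
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv("{mat_path}"))
        design <- cbind(Intercept=1, Grp=c(0,0,0,1,1,1))
        fit <- eBayes(lmFit(x, design))
        write.csv(data.frame(lfc=fit$coefficients[,2], t=fit$t[,2],
                             p=fit$p.value[,2]), "{out_path}", row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        lim = pd.read_csv(out_path)
        sheet = _sheet(3)
        res = moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))
        assert np.allclose(res["log2fc"], lim["lfc"], atol=1e-10)
        assert np.allclose(res["t_mod"], lim["t"], atol=1e-8)
        assert np.allclose(res["p"], lim["p"], atol=1e-10)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in [1e-4, 0.01, 0.5, 2.0, 50.0]:
            x = trigamma_inverse(y)
            assert polygamma(1, x) == pytest.approx(y, rel=1e-6)


class TestBhAdjust:
    def test_hand_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_all_ones(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        for n in (1, 2, 10, 137, 1000):
            p = rng.uniform(size=n)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCallDe:
    def _results(self, adj_p, lfc):
        return pd.DataFrame({"adj_p": adj_p, "log2fc": lfc,
                             "p": adj_p, "significant": False,
                             "direction": "ns"},
                            index=[f"p{i}" for i in range(len(adj_p))])

    def test_strict_boundaries(self):
        res = self._results([0.05, 0.049, 0.049], [2.0, 1.0, 1.01])
        sig, counts = call_de(res)
        # adj_p == 0.05 exactly and |lfc| == 1.0 exactly are both excluded
        assert list(sig.index) == ["p2"]
        assert counts == {"n_up": 1, "n_down": 0}

    def test_planted_up_probesets_recovered(self):
        params = SimParams(seed=41,
                           program_mix={"tolerisable": 1.0, "non_tolerisable": 0.0,
                                        "down_modulated": 0.0, "constitutive": 0.0},
                           fraction_active=0.2, attributable_fraction=0.0,
                           n_loci={"HERV_prototypes": 0, "HERV_Dfam": 500,
                                   "MaLR_Dfam": 0, "gene": 0})
        records, truth, sheet, matrix = simulate(params)
        res = moderated_t(matrix, sheet, ("LPS", "NS"))
        sig, counts = call_de(res)
        planted = truth.probesets.loc[
            truth.probesets["locus_id"].isin(
                truth.loci.loc[truth.loci["base_active"], "locus_id"]),
            "probeset_id"]
        assert counts["n_up"] >= 0.9 * len(planted)

    def test_empirical_fdr_bounded(self):
        rng = np.random.default_rng(7)
        n, k = 10_000, 1000
        s = 0.15 * np.sqrt(4 / rng.chisquare(4, n))
        x = rng.normal(0, s[:, None], (n, 30))
        x[:k, 15:] += 2.0
        sheet = _sheet(15)
        res = moderated_t(_frame(x, sheet), sheet, ("LPS", "NS"))
        sig, _ = call_de(res)
        false = np.array([int(i[1:]) >= k for i in sig.index])
        assert len(sig) > 0
        assert false.mean() <= 0.07


class TestAggregateLoci:
    def test_multiple_probesets_one_locus(self, small_sim):
        records = small_sim["records"]
        res = pd.DataFrame({
            "log2fc": [2.0, 2.0, 2.0], "adj_p": [0.01] * 3,
            "significant": [True] * 3, "direction": ["up"] * 3,
        }, index=[records[0].probeset_id, records[1].probeset_id,
                  records[2].probeset_id])
        # first three probesets of the first locus
        assert len({records[i].locus_id for i in range(3)}) == 1
        agg = aggregate_loci(res, records)
        assert agg["n_del"] + agg["n_deg"] == 1

    def test_per_repertoire_counts_sum_to_total(self, small_sim):
        matrix, sheet, records = (small_sim["matrix"], small_sim["sheet"],
                                  small_sim["records"])
        res = moderated_t(matrix, sheet, ("LPS", "NS"))
        agg = aggregate_loci(res, records)
        assert sum(agg["per_repertoire"].values()) == agg["n_del"]

    def test_unannotated_probeset_errors(self, small_sim):
        res = pd.DataFrame({"log2fc": [2.0], "adj_p": [0.01],
                            "significant": [True], "direction": ["up"]},
                           index=["not_a_probeset"])
        with pytest.raises(ValueError):
            aggregate_loci(res, small_sim["records"])


class TestPhenotype:
    def _res(self, directions):
        return pd.DataFrame({"direction": directions,
                             "log2fc": [2 if d == "up" else -2 if d == "down" else 0
                                        for d in directions],
                             "adj_p": [0.01 if d != "ns" else 0.5
                                       for d in directions]},
                            index=[f"p{i}" for i in range(len(directions))])

    def test_truth_table_disjoint_and_exhaustive(self):
        labels = ["up", "down", "ns"]
        rows_a, rows_b, expected = [], [], []
        for d1 in labels:
            for d2 in labels:
                rows_a.append(d1)
                rows_b.append(d2)
                if d1 == "up" and d2 == "down":
                    expected.append("tolerisable")
                elif d1 == "up":
                    expected.append("non_tolerisable")
                elif d1 == "down":
                    expected.append("down_modulated")
                else:
                    expected.append("unclassified")
        out = classify_phenotype(self._res(rows_a), self._res(rows_b))
        assert list(out["phenotype"]) == expected

    def test_mismatched_probesets_error(self):
        a = self._res(["up"])
        b = self._res(["up", "down"])
        with pytest.raises(ValueError):
            classify_phenotype(a, b)

    def test_planted_program_recovery(self, small_sim):
        matrix, sheet, records, truth = (small_sim["matrix"], small_sim["sheet"],
                                         small_sim["records"], small_sim["truth"])
        de1 = moderated_t(matrix, sheet, ("LPS", "NS"))
        de2 = moderated_t(matrix, sheet, ("ET", "LPS"))
        _, locus_pheno = classify_phenotype(de1, de2, records)
        merged = locus_pheno.set_index("locus_id").join(
            truth.loci.set_index("locus_id"))
        act = merged[merged["base_active"]]
        for prog in ("tolerisable", "non_tolerisable", "down_modulated"):
            sub = act[act["program"] == prog]
            assert len(sub) > 5
            assert (sub["phenotype"] == prog).mean() >= 0.90


class TestClustering:
    def test_condition_blocks_recovered(self):
        """Three condition blocks with strong distinct programs separate
        exactly at a k=3 cut (construction)."""
        from scipy.cluster.hierarchy import fcluster
        rng = np.random.default_rng(10)
        sheet = generate_design(5, ("NS", "LPS", "ET"), 3)
        n = 600
        base = rng.normal(8, 1, n)[:, None]
        shift = {"NS": 0.0, "LPS": 2.0, "ET": -2.0}
        cond_sign = rng.choice([-1.0, 1.0], n)[:, None]
        cols = []
        for _, row in sheet.iterrows():
            cols.append(base[:, 0] + cond_sign[:, 0] * shift[row["condition"]]
                        + rng.normal(0, 0.2, n))
        m = pd.DataFrame(np.column_stack(cols),
                         index=[f"p{i}" for i in range(n)],
                         columns=sheet["sample_id"])
        clust = top_variance_cluster(m, DeConfig(top_variance_fraction=0.2))
        labels = fcluster(clust["linkage"], 3, criterion="maxclust")
        conds = sheet.set_index("sample_id").loc[clust["samples"],
                                                 "condition"].to_numpy()
        df = pd.DataFrame({"cluster": labels, "condition": conds})
        assert df.groupby("cluster")["condition"].nunique().eq(1).all()
        assert df.groupby("condition")["cluster"].nunique().eq(1).all()

    def test_duplicated_sample_merges_first(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (50, 4))
        x[:, 3] = x[:, 2]  # S3 duplicates S2
        m = pd.DataFrame(x, index=[f"p{i}" for i in range(50)],
                         columns=["S0", "S1", "S2", "S3"])
        clust = top_variance_cluster(m, DeConfig(top_variance_fraction=1.0))
        first_merge = clust["linkage"][0]
        assert {int(first_merge[0]), int(first_merge[1])} == {2, 3}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_probeset_order_invariant(self, small_sim):
        m = small_sim["matrix"]
        c1 = top_variance_cluster(m)
        c2 = top_variance_cluster(m.sample(frac=1.0, random_state=9))
        assert np.allclose(c1["linkage"], c2["linkage"])

    def test_newick_export_contains_all_samples(self, small_sim):
        clust = top_variance_cluster(small_sim["matrix"])
        nwk = linkage_to_newick(clust["linkage"], clust["samples"])
        assert nwk.endswith(";")
        for s in clust["samples"]:
            assert s in nwk


class TestDdct:
    def test_zero_ddct_gives_unit_fc(self):
        ct = pd.Series([20.0, 20.0], index=["a", "b"])
        refs = pd.DataFrame({"r1": [15.0, 15.0]}, index=["a", "b"])
        cond = pd.Series(["NS", "LPS"], index=["a", "b"])
        fc = ddct(ct, refs, cond, "NS")
        assert fc["a"] == pytest.approx(1.0)
        assert fc["b"] == pytest.approx(1.0)

    def test_minus_one_ddct_doubles(self):
        ct = pd.Series([20.0, 19.0], index=["a", "b"])
        refs = pd.DataFrame({"r1": [15.0, 15.0]}, index=["a", "b"])
        cond = pd.Series(["NS", "LPS"], index=["a", "b"])
        fc = ddct(ct, refs, cond, "NS")
        assert fc["b"] == pytest.approx(2.0)

    def test_hand_computed_example(self):
        # target 24 with ref 20 -> dCt 4; calibrator dCt 5 -> FC 2^(5-4) = 2
        ct = pd.Series([25.0, 24.0], index=["cal", "x"])
        refs = pd.DataFrame({"r1": [20.0, 20.0]}, index=["cal", "x"])
        cond = pd.Series(["NS", "LPS"], index=["cal", "x"])
        fc = ddct(ct, refs, cond, "NS")
        assert fc["x"] == pytest.approx(2.0)

    def test_missing_calibrator_errors(self):
        ct = pd.Series([20.0], index=["a"])
        refs = pd.DataFrame({"r1": [15.0]}, index=["a"])
        with pytest.raises(ValueError):
            ddct(ct, refs, pd.Series(["LPS"], index=["a"]), "NS")
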