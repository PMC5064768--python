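"""Background model, escapee calling, enrichment and trajectory clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from germreprog import methylation_quant as mq
from germreprog import reprog_dynamics as rd
from germreprog.core_io import FeatureSet
from germreprog.methylation_quant import MethMatrix, ProbeSet

from conftest import make_features


def matrix_from_arrays(start, end, prefix="p"):
    ids = [f"{prefix}{i:06d}" for i in range(len(start))]
    probes = pd.DataFrame(
        {
            "probe_id": ids,
            "chrom": "chr1",
            "start": np.arange(len(start)) * 1000,
            "end": np.arange(len(start)) * 1000 + 1000,
        }
    )
    fr = pd.DataFrame({"a": start, "b": end}, index=pd.Index(ids, name="probe_id"))
    return MethMatrix(
        probes=probes,
        samples=["a", "b"],
        fractions=fr,
        total_calls=fr * 0,
        covered_cpgs=fr * 0 + 100,
    )


class TestBackgroundModel:
    def test_constant_offset_with_discrete_starts_calls_nothing(self):
        # ten distinct start levels, each bin single-valued: a rigid -0.3
        # shift leaves zero spread per bin and no significant calls
        start = np.repeat(np.linspace(0.4, 0.9, 10), 60)
        end = start - 0.3
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=10, min_bin_n=50)
        assert np.allclose(model.bin_mad, 0.0)
        calls = rd.call_outliers(model, alpha=0.05)
        assert (calls.table["class"] == "ns").all()

    def test_identical_starts_collapse_to_single_bin(self, caplog):
        start = np.full(300, 0.6)
        end = np.random.default_rng(0).uniform(0.1, 0.4, size=300)
        mm = matrix_from_arrays(start, end)
        with caplog.at_level("WARNING"):
            model = rd.fit_background(mm, "a", "b", n_bins=10, min_bin_n=20)
        assert model.n_bins == 1
        assert any("single bin" in r.message for r in caplog.records)

    def test_too_few_probes_for_two_bins_errors(self):
        rng = np.random.default_rng(1)
        mm = matrix_from_arrays(rng.uniform(size=60), rng.uniform(size=60))
        with pytest.raises(ValueError, match="bins"):
            rd.fit_background(mm, "a", "b", n_bins=20, min_bin_n=50)

    def test_bin_medians_match_sort_oracle(self):
        rng = np.random.default_rng(12)
        start = rng.uniform(0.2, 0.9, size=10_000)
        end = np.clip(start - 0.3 + rng.normal(0, 0.05, size=10_000), 0, 1)
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=20, min_bin_n=50)
        # oracle: sort probes by start, split into 20 equal chunks, median end
        order = np.argsort(start, kind="stable")
        for b in range(model.n_bins):
            members = model.bin_id == b
            assert np.isclose(model.bin_median[b], np.median(end[members]))
        # equal occupancy within rounding
        occ = np.bincount(model.bin_id)
        assert occ.max() - occ.min() <= 2

    def test_missing_probes_excluded(self):
        start = np.array([0.5, np.nan, 0.7, 0.8] * 50)
        end = np.array([0.2, 0.3, np.nan, 0.5] * 50)
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=2, min_bin_n=10)
        assert len(model.start) == 100  # only rows complete in both samples


class TestOutlierCalls:
    def test_probe_at_bin_median_is_ns(self):
        start = np.repeat([0.5, 0.8], 101)
        end = np.concatenate([np.linspace(0.1, 0.3, 101), np.linspace(0.4, 0.6, 101)])
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=2, min_bin_n=50)
        calls = rd.call_outliers(model).table
        med_rows = calls[np.isclose(calls["end"], 0.2) | np.isclose(calls["end"], 0.5)]
        assert (med_rows["class"] == "ns").all() and (med_rows["p"] == 1.0).all()

    def test_extreme_member_has_smallest_attainable_p(self):
        start = np.full(0, np.nan)
        n = 200
        rng = np.random.default_rng(5)
        start = rng.uniform(0.4, 0.6, size=n)
        end = rng.normal(0.3, 0.02, size=n)
        end[0] = 0.99
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=1, min_bin_n=50)
        calls = rd.call_outliers(model).table
        top = calls.loc[calls["end"].idxmax()]
        assert top["p"] == pytest.approx(2 / (n + 1))
        assert top["class"] == "higher"

    def test_null_calibration_close_to_alpha(self):
        rng = np.random.default_rng(77)
        n = 10_000
        start = rng.uniform(0, 1, size=n)
        end = rng.normal(0.5, 0.1, size=n)  # independent of start: exchangeable per bin
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=20, min_bin_n=50)
        for alpha in (0.01, 0.05):
            frac = (rd.call_outliers(model, alpha=alpha).table["p"] < alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert abs(frac - alpha) < 4 * se + 2 / 500  # MC error + rank discreteness

    def test_raising_end_fraction_never_lowers_high_side_significance(self):
        rng = np.random.default_rng(9)
        n = 400
        start = rng.uniform(0.4, 0.6, size=n)
        end = rng.normal(0.3, 0.05, size=n)
        mm = matrix_from_arrays(start, end)
        model = rd.fit_background(mm, "a", "b", n_bins=4, min_bin_n=50)
        base = rd.call_outliers(model).table.set_index("probe_id")
        # push one mid-pack probe upward and refit: its class may move
        # ns->higher but never higher->lower, and p on the high side shrinks
        target = base.index[10]
        for bump in (0.05, 0.15, 0.4):
            end2 = end.copy()
            end2[10] = end[10] + bump
            model2 = rd.fit_background(matrix_from_arrays(start, end2), "a", "b",
                                       n_bins=4, min_bin_n=50)
            tab2 = rd.call_outliers(model2).table.set_index("probe_id")
            assert tab2.loc[target, "class"] != "lower"
            if tab2.loc[target, "end"] > model2.bin_median[int(tab2.loc[target, "bin"])]:
                assert tab2.loc[target, "p"] <= base.loc[target, "p"] + 1e-12

    def test_mad_z_separates_planted_escapees(self):
        rng = np.random.default_rng(31)
        n = 4000
        start = rng.uniform(0.4, 0.9, size=n)
        end = start - 0.3 + rng.normal(0, 0.05, size=n)
        planted = rng.random(n) < 0.05
        end[planted] += 0.35
        mm = matrix_from_arrays(start, np.clip(end, 0, 1))
        model = rd.fit_background(mm, "a", "b", n_bins=20, min_bin_n=50)
        calls = rd.call_outliers(model, alpha=0.05, correction="bh", method="mad_z")
        ids = np.array([f"p{i:06d}" for i in range(n)])
        called = np.isin(ids, list(calls.higher_ids))
        sens = called[planted].mean()
        fdp = (~planted)[called].mean() if called.any() else 0.0
        assert sens >= 0.9 and fdp <= 0.1


def hypergeom_sf_oracle(k, M, n, N):
    """Exhaustive upper tail P(X >= k) via exact binomial coefficients."""
    total = 0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x)
    return total / math.comb(M, N)


class TestEnrichment:
    def universe(self, n=200):
        df = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 1000,
            }
        )
        return ProbeSet(mode="tiling", params={}, df=df)

    def test_group_equals_universe_gives_zero_ratio_and_large_p(self):
        uni = self.universe()
        feats = {"f": make_features([("chr1", 0, 50_500)])}
        tab = rd.enrich_features(set(uni.df["probe_id"]), uni, feats)
        assert tab.iloc[0]["log2_ratio"] == 0.0
        assert tab.iloc[0]["p"] >= 0.5

    def test_feature_covering_nothing_reports_missing_ratio(self):
        uni = self.universe()
        feats = {"f": make_features([("chr2", 0, 100)])}
        tab = rd.enrich_features({"p0"}, uni, feats)
        assert tab.iloc[0]["pct_universe"] == 0.0
        assert np.isnan(tab.iloc[0]["log2_ratio"])

    def test_planted_enrichment_matches_exact_hypergeometric(self):
        # feature covers 10% of a 200-probe universe; group of 40 with 50% overlap
        uni = self.universe(200)
        feat_rows = [("chr1", i * 1000, i * 1000 + 999) for i in range(20)]
        feats = {"f": make_features(feat_rows)}
        group = {f"p{i}" for i in range(10)} | {f"p{i}" for i in range(100, 130)}
        tab = rd.enrich_features(group, uni, feats)
        row = tab.iloc[0]
        assert row["pct_group"] == pytest.approx(25.0)
        assert row["pct_universe"] == pytest.approx(10.0)
        assert row["log2_ratio"] == pytest.approx(math.log2(2.5))
        assert row["p"] == pytest.approx(hypergeom_sf_oracle(10, 200, 20, 40), rel=1e-9)

    def test_half_in_group_vs_ten_pct_background_ratio(self):
        uni = self.universe(500)
        feat_rows = [("chr1", i * 1000, i * 1000 + 999) for i in range(50)]
        group = {f"p{i}" for i in range(25)} | {f"p{i}" for i in range(450, 475)}
        tab = rd.enrich_features(group, uni, {"f": make_features(feat_rows)})
        row = tab.iloc[0]
        assert row["log2_ratio"] == pytest.approx(math.log2(50.0 / 10.0), abs=1e-9)
        assert row["p"] == pytest.approx(hypergeom_sf_oracle(25, 500, 50, 50), rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rd.enrich_features(set(), self.universe(), {})


class TestKMeans:
    def trajectories(self, n=350, seed=2):
        rng = np.random.default_rng(seed)
        archetypes = np.array(
            [
                [0.05, 0.05, 0.05, 0.05],
                [0.30, 0.70, 0.65, 0.60],
                [0.30, 0.65, 0.35, 0.15],
                [0.50, 0.50, 0.50, 0.50],
                [0.90, 0.90, 0.90, 0.90],
                [0.05, 0.60, 0.05, 0.05],
                [0.80, 0.20, 0.80, 0.20],
            ]
        )
        truth = rng.integers(0, 7, size=n)
        X = archetypes[truth] + rng.normal(0, 0.05, size=(n, 4))
        return np.clip(X, 0, 1), truth

    def matrix(self, X):
        ids = [f"p{i:05d}" for i in range(len(X))]
        probes = pd.DataFrame(
            {"probe_id": ids, "chrom": "chr1", "start": 0, "end": 2000}
        )
        fr = pd.DataFrame(X, index=pd.Index(ids, name="probe_id"),
                          columns=["t0", "t1", "t2", "t3"])
        return MethMatrix(probes=probes, samples=["t0", "t1", "t2", "t3"],
                          fractions=fr, total_calls=fr * 0, covered_cpgs=fr * 0)

    def test_k1_centroid_is_the_mean_vector(self):
        X, _ = self.trajectories()
        tc = rd.kmeans_trajectories(self.matrix(X), k=1, seed=0, n_restarts=3)
        np.testing.assert_allclose(tc.centroids.iloc[0].to_numpy(), X.mean(axis=0), atol=1e-9)

    def test_k_equals_n_distinct_gives_zero_inertia(self):
        X = np.array([[0.1, 0.1, 0.1, 0.1], [0.5, 0.5, 0.5, 0.5], [0.9, 0.9, 0.9, 0.9]])
        tc = rd.kmeans_trajectories(self.matrix(X), k=3, seed=0, n_restarts=5)
        assert tc.inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed_and_best_of_restarts(self):
        X, _ = self.trajectories()
        mm = self.matrix(X)
        a = rd.kmeans_trajectories(mm, k=7, seed=123, n_restarts=25)
        b = rd.kmeans_trajectories(mm, k=7, seed=123, n_restarts=25)
        pd.testing.assert_series_equal(a.labels, b.labels)
        single = rd.kmeans_trajectories(mm, k=7, seed=123, n_restarts=1)
        assert a.inertia <= single.inertia + 1e-12

    def test_clusters_ordered_by_descending_size(self):
        X, _ = self.trajectories(n=500, seed=8)
        tc = rd.kmeans_trajectories(self.matrix(X), k=7, seed=1, n_restarts=10)
        sizes = tc.labels.value_counts().sort_index().to_numpy()
        assert all(sizes[i] >= sizes[i + 1] for i in range(len(sizes) - 1))

    def test_missing_timepoint_probes_excluded(self):
        X, _ = self.trajectories(n=60)
        X[5, 2] = np.nan
        tc = rd.kmeans_trajectories(self.matrix(X), k=3, seed=0, n_restarts=3)
        assert "p00005" not in tc.labels.index

    def test_fewer_probes_than_k_rejected(self):
        X = np.full((3, 4), 0.5)
        with pytest.raises(ValueError):
            rd.kmeans_trajectories(self.matrix(X), k=7, seed=0)


class TestChipOverlay:
    def universe(self, n=50):
        df = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 1000,
            }
        )
        return ProbeSet(mode="tiling", params={}, df=df)

    def test_uniform_coverage_scores_equal_and_all_tied_enriched(self):
        reads = make_features([("chr1", i * 1000 + 400, i * 1000 + 500) for i in range(50)])
        out = rd.overlay_chip(self.universe(), reads)
        assert out["score"].nunique() == 1
        assert out["enriched"].all()  # ties at the threshold are all included

    def test_probe_without_reads_scores_zero(self):
        reads = make_features([("chr1", 400, 500)])
        out = rd.overlay_chip(self.universe(), reads)
        assert out.loc[out["probe_id"] == "p10", "score"].iloc[0] == 0.0

    def test_read_spanning_probe_boundary_counts_for_both(self):
        reads = make_features([("chr1", 950, 1050)])
        out = rd.overlay_chip(self.universe(), reads)
        assert out.loc[out["probe_id"].isin(["p0", "p1"]), "reads"].tolist() == [1, 1]

    def test_zero_signal_rejected(self):
        empty = FeatureSet(pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": "int64", "end": "int64"}))
        with pytest.raises(ValueError, match="zero"):
            rd.overlay_chip(self.universe(), empty)


class TestCorrelation:
    def test_identity_gives_r_one(self):
        x = pd.Series([0.1, 0.4, 0.9], index=["a", "b", "c"])
        r, n = rd.correlate_meth_expr(x, x, log_transform=False)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_anticorrelated_gives_negative_r(self):
        rng = np.random.default_rng(0)
        meth = pd.Series(rng.uniform(size=100), index=[f"g{i}" for i in range(100)])
        expr = pd.Series(2 ** (5 * (1 - meth.to_numpy())), index=meth.index)
        r, _ = rd.correlate_meth_expr(meth, expr)
        assert r < -0.9

    def test_independent_inputs_stay_inside_permutation_null_band(self):
        rng = np.random.default_rng(13)
        n = 300
        meth = pd.Series(rng.uniform(size=n), index=[f"g{i}" for i in range(n)])
        expr = pd.Series(rng.lognormal(2, 1, size=n), index=meth.index)
        r, _ = rd.correlate_meth_expr(meth, expr)
        null = []
        e = np.log2(expr.to_numpy() + 1)
        m = meth.to_numpy()
        for _ in range(500):
            null.append(np.corrcoef(m, rng.permutation(e))[0, 1])
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo < r < hi

    def test_too_few_genes_rejected(self):
        x = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError):
            rd.correlate_meth_expr(x, x)
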