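"""Beta regression vs an independent numeric ML oracle, statistic
propagation, joint classification, correlation, DMR overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from methcap.crossplatform import (
    CpGBetaRegression,
    beta_regression_per_cpg,
    classify_cpgs,
    correlate_methods,
    overlap_dmrs,
    propagate_region_stats,
)


def _sites(n):
    return pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) * 100 + 50})


def oracle_beta_fit(y, x):
    """Independent numeric ML: direct minimization of the beta negative
    log-likelihood over (b0, b1, log phi) with scipy."""

    def nll(theta):
        b0, b1, ltau = theta
        mu = expit(b0 + b1 * x)
        phi = np.exp(ltau)
        a, b = phi * mu, phi * (1 - mu)
        return -np.sum(
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
        )

    best = None
    for start in ([0.0, 0.0, 2.0], [-1.0, 1.0, 3.0], [1.0, -1.0, 1.0]):
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


class TestBetaRegression:
    def test_separated_groups_match_oracle(self):
        # 5 + 5 samples, totals 30: group A ~0.2, group B ~0.8
        meth = np.array([[6, 7, 5, 6, 6, 24, 23, 25, 24, 24]], dtype=float)
        total = np.full((1, 10), 30.0)
        groups = ["normal"] * 5 + ["primary"] * 5
        model = CpGBetaRegression(contrast=("primary", "normal"))
        model.fit((_sites(1), meth, total), groups)
        res = model.results_.iloc[0]
        assert res["diff"] == pytest.approx(0.6, abs=0.05)
        assert res["pvalue"] < 1e-3
        # oracle on the same squeezed proportions
        y = (meth[0] / total[0] * 9 + 0.5) / 10
        x = np.array([0.0] * 5 + [1.0] * 5)
        b0, b1, _ = oracle_beta_fit(y, x)
        # fitted means are reported on the original scale (squeeze inverted)
        assert res["prop_ref"] == pytest.approx((expit(b0) * 10 - 0.5) / 9, abs=1e-3)
        assert res["prop_tumor"] == pytest.approx(
            (expit(b0 + b1) * 10 - 0.5) / 9, abs=1e-3
        )

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(5)
        total = np.full((20, 8), 30.0)
        meth = rng.binomial(30, 0.5, size=(20, 8)).astype(float)
        groups = ["normal"] * 4 + ["primary"] * 4
        res = beta_regression_per_cpg(
            (_sites(20), meth, total), groups, contrast=("primary", "normal")
        )
        assert np.abs(res["diff"]).mean() < 0.1
        assert (res["pvalue"] > 0.1).mean() > 0.7

    def test_uncovered_group_skipped_and_reported(self):
        meth = np.array([[5, 5, 5, 5], [5, 5, 0, 0]], dtype=float)
        total = np.array([[10, 10, 10, 10], [10, 10, 0, 0]], dtype=float)
        groups = ["normal", "normal", "primary", "primary"]
        model = CpGBetaRegression(contrast=("primary", "normal"))
        model.fit((_sites(2), meth, total), groups)
        assert len(model.results_) == 1
        assert len(model.skipped_) == 1
        assert model.skipped_["pos"].iloc[0] == 150

    def test_wald_p_in_unit_interval(self):
        rng = np.random.default_rng(6)
        total = rng.integers(5, 60, size=(50, 6)).astype(float)
        meth = rng.binomial(total.astype(int), rng.uniform(0.1, 0.9, (50, 1)))
        groups = ["normal"] * 3 + ["primary"] * 3
        res = beta_regression_per_cpg(
            (_sites(50), meth.astype(float), total), groups
        )
        assert ((res["pvalue"] >= 0) & (res["pvalue"] <= 1)).all()


def _regions(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "logFC", "simes_p"])
    df["direction"] = np.where(df["logFC"] >= 0, "hyper", "hypo")
    return df


class TestPropagation:
    def test_cpgs_inherit_region_stats(self):
        regions = _regions([("chr1", 1000, 2000, 1.5, 0.01)])
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": [1100, 1500, 1900]})
        out = propagate_region_stats(regions, cpgs)
        assert out["mbde_covered"].all()
        assert (out["mbde_logfc"] == 1.5).all()
        assert (out["mbde_p"] == 0.01).all()

    def test_half_open_boundary(self):
        regions = _regions([("chr1", 1000, 2000, 1.5, 0.01)])
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": [999, 1000, 1999, 2000]})
        out = propagate_region_stats(regions, cpgs)
        assert out["mbde_covered"].tolist() == [False, True, True, False]

    def test_region_without_cpgs_contributes_nothing(self):
        regions = _regions([("chr1", 5000, 6000, 1.0, 0.5)])
        cpgs = pd.DataFrame({"chrom": "chr1", "pos": [100, 9000]})
        out = propagate_region_stats(regions, cpgs)
        assert not out["mbde_covered"].any()

    def test_overlapping_regions_rejected(self):
        regions = _regions(
            [("chr1", 1000, 2000, 1.0, 0.5), ("chr1", 1500, 2500, 1.0, 0.5)]
        )
        with pytest.raises(ValueError, match="overlapping"):
            propagate_region_stats(regions, pd.DataFrame({"chrom": ["chr1"], "pos": [1]}))

    def test_round_trip_reproduces_region_stats(self):
        rng = np.random.default_rng(2)
        starts = np.arange(10) * 3000
        regions = _regions(
            [
                ("chr1", int(s), int(s) + 1000, float(rng.normal()), float(rng.random()))
                for s in starts
            ]
        )
        cpgs = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 30_000, 300)}
        ).drop_duplicates().reset_index(drop=True)
        out = propagate_region_stats(regions, cpgs)
        covered = out[out["mbde_covered"]]
        grouped = covered.groupby("region_id").agg(
            lfc=("mbde_logfc", "first"), p=("mbde_p", "first"),
            lfc_n=("mbde_logfc", "nunique"), p_n=("mbde_p", "nunique"),
        )
        for rid, row in grouped.iterrows():
            assert row["lfc_n"] == 1 and row["p_n"] == 1
            assert row["lfc"] == regions.loc[rid, "logFC"]
            assert row["p"] == regions.loc[rid, "simes_p"]


class TestClassification:
    def _frame(self, te_diff, lfc, p):
        return pd.DataFrame(
            {"te_diff": [te_diff], "te_p": [0.5], "mbde_logfc": [lfc], "mbde_p": [p]}
        )

    @pytest.mark.parametrize(
        "te_diff,lfc,p,joint,sub",
        [
            (0.2, 1.0, 0.01, "hyper-concordant", "none"),
            (-0.2, -1.0, 0.01, "hypo-concordant", "none"),
            (-0.1, -0.5, 0.2, "other", "TE-only-hypo"),
            (0.1, 0.5, 0.2, "other", "TE-only-hyper"),
            (0.0, 0.0, 0.6, "iso", "none"),
            (0.0, 1.0, 0.01, "other", "MBDE-only-hyper"),
            (0.2, -1.0, 0.01, "other", "discordant"),
        ],
    )
    def test_rule_table(self, te_diff, lfc, p, joint, sub):
        out = classify_cpgs(self._frame(te_diff, lfc, p))
        assert out["joint_class"].iloc[0] == joint
        assert out["joint_subclass"].iloc[0] == sub

    def test_classes_partition_exactly(self):
        rng = np.random.default_rng(3)
        n = 500
        records = pd.DataFrame(
            {
                "te_diff": np.round(rng.normal(0, 0.1, n), 2),
                "te_p": rng.random(n),
                "mbde_logfc": np.round(rng.normal(0, 1, n), 2),
                "mbde_p": rng.random(n),
            }
        )
        out = classify_cpgs(records)
        counts = out["joint_class"].value_counts()
        assert counts.sum() == n

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_cpgs(pd.DataFrame({"te_diff": [0.1]}))


class TestCorrelation:
    def _records(self, x, y, density=None):
        df = pd.DataFrame({"mbde_logfc": x, "te_diff": y})
        if density is not None:
            df["density_class"] = density
        return df

    def test_proportional_gives_r_one(self):
        x = np.linspace(-2, 2, 50)
        summ = correlate_methods(self._records(x, 0.1 * x), stratify_by_density=False)
        assert summ.overall_r == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        x = np.linspace(-2, 2, 50)
        summ = correlate_methods(self._records(x, -0.1 * x), stratify_by_density=False)
        assert summ.overall_r == pytest.approx(-1.0)

    def test_zero_variance_stratum_undefined_not_zero(self):
        rec = self._records(
            [1.0, 1.0, 1.0, 0.5, 1.0, 2.0],
            [0.1, 0.2, 0.3, 0.0, 0.1, 0.2],
            density=["low"] * 3 + ["high"] * 3,
        )
        summ = correlate_methods(rec)
        low = summ.per_stratum.set_index("density_class").loc["low"]
        assert np.isnan(low["pearson_r"])

    def test_small_stratum_undefined(self):
        rec = self._records([1.0, 2.0], [0.1, 0.2], density=["low", "low"])
        summ = correlate_methods(rec, min_n=3)
        assert np.isnan(summ.per_stratum["pearson_r"].iloc[0])


def _dmrs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction"])


class TestOverlap:
    def test_one_bp_overlap_counts(self):
        a = _dmrs([("chr1", 100, 200, "hyper")])
        b = _dmrs([("chr1", 199, 300, "hyper")])
        part = overlap_dmrs(a, b)
        assert len(part.both_a) == 1 and len(part.both_b) == 1

    def test_half_open_touching_does_not_overlap(self):
        a = _dmrs([("chr1", 100, 200, "hyper")])
        b = _dmrs([("chr1", 200, 300, "hyper")])
        part = overlap_dmrs(a, b)
        assert len(part.both_a) == 0 and len(part.a_only) == 1

    def test_direction_must_match(self):
        a = _dmrs([("chr1", 100, 200, "hyper")])
        b = _dmrs([("chr1", 150, 250, "hypo")])
        part = overlap_dmrs(a, b)
        assert len(part.both_a) == 0

    def test_region_counted_once_despite_two_partners(self):
        a = _dmrs([("chr1", 100, 500, "hyper")])
        b = _dmrs([("chr1", 120, 180, "hyper"), ("chr1", 300, 400, "hyper")])
        part = overlap_dmrs(a, b)
        assert len(part.both_a) == 1
        assert part.counts["both_a"]["hyper"] == 1
        assert part.counts["both_b"]["hyper"] == 2

    def test_matches_brute_force_pairwise_scan(self):
        rng = np.random.default_rng(9)
        def rand_set(n):
            starts = np.sort(rng.choice(np.arange(0, 40_000, 400), n, replace=False))
            return _dmrs(
                [
                    ("chr1", int(s), int(s + rng.integers(50, 390)),
                     rng.choice(["hyper", "hypo"]))
                    for s in starts
                ]
            )
        a, b = rand_set(30), rand_set(25)
        part = overlap_dmrs(a, b)
        for i, ra in a.iterrows():
            expect = any(
                ra["chrom"] == rb["chrom"]
                and ra["direction"] == rb["direction"]
                and ra["start"] < rb["end"]
                and rb["start"] < ra["end"]
                for _, rb in b.iterrows()
            )
            got = ((part.both_a["start"] == ra["start"]) &
                   (part.both_a["end"] == ra["end"])).any()
            assert got == expect
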