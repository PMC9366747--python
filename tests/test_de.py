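import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmod.de import (
    bh_adjust,
    cpm,
    cpm_filter,
    ddct,
    fit_f_dist,
    log_cpm,
    moderated_t_test,
    select_enriched,
    tmm_factors,
)
from oracles import oracle_bh, oracle_ddct, oracle_tmm_factor


def _random_counts(rng, n_feat=40, n_samp=6):
    return pd.DataFrame(
        rng.negative_binomial(20, 0.05, size=(n_feat, n_samp)),
        index=[f"g{i}" for i in range(n_feat)],
        columns=[f"s{j}" for j in range(n_samp)],
    )


class TestCpmFilter:
    def test_cpm_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = _random_counts(rng)
        assert np.allclose(cpm(counts).sum(axis=0), 1e6)

    def test_threshold_in_exactly_min_samples(self):
        counts = pd.DataFrame(
            np.ones((1, 15), dtype=int) * 1000,
            index=["bulk"], columns=[f"s{j}" for j in range(15)],
        )
        # feature at CPM >= 1 in exactly 3 of 15 samples
        extra = pd.DataFrame(
            [[2, 2, 2] + [0] * 12], index=["rare"], columns=counts.columns
        )
        mat = pd.concat([counts * 500, extra])
        kept = cpm_filter(mat, min_cpm=1, min_samples=3)
        assert "rare" in kept.index

    def test_all_zero_feature_removed(self):
        rng = np.random.default_rng(1)
        counts = _random_counts(rng)
        counts.loc["g0"] = 0
        assert "g0" not in cpm_filter(counts).index

    def test_zero_library_sample_fails_named(self):
        rng = np.random.default_rng(2)
        counts = _random_counts(rng)
        counts["s3"] = 0
        with pytest.raises(ValueError, match="s3"):
            cpm_filter(counts)

    def test_retained_set_equals_direct_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            counts = _random_counts(rng, n_feat=30, n_samp=8)
            counts.iloc[rng.integers(0, 30, 10), :] = rng.integers(
                0, 3, size=(10, 8)
            )
            kept = set(cpm_filter(counts, 1.0, 3).index)
            lib = counts.sum(axis=0)
            expected = {
                g for g in counts.index
                if sum(
                    counts.loc[g, s] * 1e6 / lib[s] >= 1.0
                    for s in counts.columns
                ) >= 3
            }
            assert kept == expected


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(4)
        col = rng.negative_binomial(20, 0.05, size=40)
        counts = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed(self):
        rng = np.random.default_rng(5)
        col = rng.negative_binomial(20, 0.05, size=40) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_factor_matches_stepwise_oracle(self):
        """Inflated-feature toy matrix equals an independently coded
        trimmed, precision-weighted mean of M-values."""
        rng = np.random.default_rng(6)
        counts = _random_counts(rng, n_feat=20, n_samp=2) + 1
        counts.iloc[0, 0] *= 25
        fac = tmm_factors(counts)
        lib = counts.sum(axis=0)
        # reference is s1 or s0 by the upper-quartile rule; compute both ways
        f_raw = oracle_tmm_factor(
            counts["s0"], counts["s1"], lib["s0"], lib["s1"]
        )
        # the oracle gives the unnormalised factor of s0 vs reference s1
        expected = pd.Series({"s0": f_raw, "s1": 1.0})
        expected /= np.exp(np.log(expected).mean())
        assert np.allclose(fac, expected[fac.index], rtol=1e-10) or \
            np.allclose(fac, (1 / expected)[fac.index], rtol=1e-10)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent cross-check against edgeR's reference implementation."""
        rng = np.random.default_rng(7)
        counts = _random_counts(rng, n_feat=50, n_samp=6)
        counts.iloc[0, 0] *= 30
        mat_path = tmp_path / "m.tsv"
        counts.to_csv(mat_path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'm <- as.matrix(read.delim("{mat_path}", row.names=1))\n'
            'f <- calcNormFactors(DGEList(counts=m), method="TMM")'
            '$samples$norm.factors\n'
            'cat(sprintf("%.10f\\n", f))\n'
        )
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        edger = np.array([float(x) for x in res.stdout.split()])
        mine = tmm_factors(counts).to_numpy()
        assert np.allclose(mine, edger, rtol=1e-6)

    def test_degenerate_trim_warns_and_returns_one(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10], "c": [5, 5]})
        with pytest.warns(UserWarning):
            fac = tmm_factors(counts)
        assert (fac > 0).all()


class TestModeratedT:
    def _matrix(self, rng, n_feat=200, n=3):
        y = rng.normal(5, 1, size=(n_feat, 2 * n))
        return pd.DataFrame(
            y, index=[f"g{i}" for i in range(n_feat)],
            columns=[f"s{j}" for j in range(2 * n)],
        ), ["A"] * n + ["B"] * n

    def test_equal_variances_drive_d0_to_infinity(self):
        """If every feature has the same sample variance the prior df is
        infinite and every posterior variance equals that common variance."""
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 6)
        mu = rng.normal(5, 2, 50)
        y = pd.DataFrame(np.add.outer(mu, base))
        res = moderated_t_test(y, ["A"] * 3 + ["B"] * 3)
        assert not np.isfinite(res.attrs["d0"])
        s2_post = res.attrs["s2_post"]
        assert np.allclose(s2_post, s2_post[0])

    def test_d0_zero_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(9)
        y, groups = self._matrix(rng, n_feat=50)
        res = moderated_t_test(y, groups, d0_override=0.0)
        t_ref, p_ref = stats.ttest_ind(
            y.iloc[:, 3:], y.iloc[:, :3], axis=1, equal_var=True
        )
        assert np.allclose(res["t"], t_ref)
        assert np.allclose(res["p"], p_ref)

    def test_prior_recovery_from_simulated_variances(self):
        """Moment estimator recovers (d0, s0^2) from 2000 simulated
        variances drawn as s0^2 d0/chi2(d0) scaled chi2(df)/df."""
        rng = np.random.default_rng(1)
        d0_true, s0_true, df = 4.0, 1.0, 8
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 2000)
        s2 = sigma2 * rng.chisquare(df, 2000) / df
        d0_hat, s0_hat = fit_f_dist(s2, df)
        assert abs(d0_hat - d0_true) <= 0.25 * d0_true
        assert abs(s0_hat - s0_true) <= 0.10 * s0_true

    def test_matches_limma_ebayes(self, tmp_path):
        """Moderated t, p, prior df and prior variance agree with limma on
        the same expression matrix."""
        rng = np.random.default_rng(10)
        counts = _random_counts(rng, n_feat=80, n_samp=6)
        lc = log_cpm(counts, tmm_factors(counts))
        lc_path = tmp_path / "lc.tsv"
        lc.to_csv(lc_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'lc <- as.matrix(read.delim("{lc_path}", row.names=1))\n'
            'design <- model.matrix(~factor(c("A","A","A","B","B","B")))\n'
            'fit <- eBayes(lmFit(lc, design))\n'
            'tt <- topTable(fit, coef=2, number=Inf, sort.by="none")\n'
            'tt$df.prior <- fit$df.prior; tt$s2.prior <- fit$s2.prior\n'
            f'write.table(tt, "{out_path}", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        lim = pd.read_csv(out_path, sep="\t")
        res = moderated_t_test(lc, ["A"] * 3 + ["B"] * 3)
        assert res.attrs["d0"] == pytest.approx(lim["df.prior"].iloc[0], rel=1e-4)
        assert res.attrs["s0_sq"] == pytest.approx(lim["s2.prior"].iloc[0], rel=1e-4)
        assert np.allclose(res["log2fc"], lim["logFC"], atol=1e-8)
        assert np.allclose(res["t"], lim["t"], atol=1e-6)
        assert np.allclose(res["p"], lim["P.Value"], atol=1e-8)

    def test_input_validation(self):
        rng = np.random.default_rng(11)
        y, groups = self._matrix(rng, n_feat=20)
        with pytest.raises(ValueError, match="two group levels"):
            moderated_t_test(y, ["A"] * 6)
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t_test(y, ["A", "B", "B", "B", "B", "B"])
        with pytest.raises(ValueError, match="10 features"):
            moderated_t_test(y.iloc[:5], groups)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_nan_propagates_and_excluded_from_m(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        # m = 2 for the valid entries
        assert out[0] == pytest.approx(0.02)
        assert out[2] == pytest.approx(0.04)

    def test_matches_literal_oracle_and_is_monotone(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(1, 40))
            mine = bh_adjust(p)
            assert np.allclose(mine, oracle_bh(p.tolist()))
            order = np.argsort(p)
            assert (np.diff(mine[order]) >= -1e-12).all()
            assert (mine >= p - 1e-12).all()
            assert (mine <= 1.0).all()


class TestSelectEnriched:
    def test_threshold_rules(self):
        de = pd.DataFrame(
            {"log2fc": [2.5, 2.5, -3.0, 1.0],
             "padj": [0.01, 0.06, 0.001, 0.01]},
            index=["up_b", "ns", "up_a", "small_fc"],
        )
        up_b, up_a = select_enriched(de, alpha=0.05, lfc=2.0)
        assert up_b == {"up_b"}
        assert up_a == {"up_a"}
        assert up_b.isdisjoint(up_a)


class TestDdct:
    def _table(self, ct_treated, ct_control):
        rows = []
        labels = []
        for i, (t, r1, r2) in enumerate(ct_treated):
            rows.append({"target": t, "ref1": r1, "ref2": r2})
            labels.append("treated")
        for i, (t, r1, r2) in enumerate(ct_control):
            rows.append({"target": t, "ref1": r1, "ref2": r2})
            labels.append("control")
        ct = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])
        return ct, labels

    def test_closed_form_example(self):
        ct, labels = self._table([(25, 20, 20)], [(28, 20, 20)])
        res = ddct(ct, "target", ["ref1", "ref2"], labels, "treated", "control")
        assert res["ddct"] == pytest.approx(-3.0)
        assert res["rq"] == pytest.approx(8.0)

    def test_identity_when_groups_equal(self):
        ct, labels = self._table([(24, 20, 21)], [(24, 20, 21)])
        res = ddct(ct, "target", ["ref1", "ref2"], labels, "treated", "control")
        assert res["rq"] == pytest.approx(1.0)

    def test_matches_independent_formula_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            tr = [(rng.uniform(18, 30),) + tuple(rng.uniform(18, 25, 2))
                  for _ in range(4)]
            co = [(rng.uniform(18, 30),) + tuple(rng.uniform(18, 25, 2))
                  for _ in range(4)]
            ct, labels = self._table(tr, co)
            res = ddct(ct, "target", ["ref1", "ref2"], labels,
                       "treated", "control")
            expected = oracle_ddct(
                [x[0] for x in tr], [list(x[1:]) for x in tr],
                [x[0] for x in co], [list(x[1:]) for x in co],
            )
            assert res["rq"] == pytest.approx(expected)

    def test_missing_reference_gene_fails(self):
        ct, labels = self._table([(25, 20, 20)], [(28, 20, 20)])
        with pytest.raises(ValueError, match="RNU"):
            ddct(ct, "target", ["RNU5G"], labels, "treated", "control")
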