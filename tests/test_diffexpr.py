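"""Two-group fits, empirical-Bayes shrinkage, moderated t, ranking, enrichment."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from follitime.diffexpr import (
    ebayes_moderate,
    fit_two_group,
    hypergeometric_enrichment,
    moderated_t,
    rank_by_logfc,
    read_gmt,
    run_de,
    write_gmt,
)
from follitime.matrix import ExpressionMatrix


def _matrix(values, cols=None):
    values = np.asarray(values, dtype=float)
    cols = cols or [f"s{j}" for j in range(values.shape[1])]
    meta = pd.DataFrame({"condition": ["x"] * len(cols), "day": range(len(cols))},
                        index=pd.Index(cols, name="sample_id"))
    idx = pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id")
    return ExpressionMatrix(pd.DataFrame(values, index=idx, columns=cols), meta)


class TestFitTwoGroup:
    def test_zero_variance_arithmetic(self):
        m = _matrix([[2, 2, 4, 4]])
        fit = fit_two_group(m, ["s0", "s1"], ["s2", "s3"])
        assert fit.logfc[0] == pytest.approx(2.0)
        assert fit.s2[0] == pytest.approx(0.0)
        assert fit.df == 2

    def test_antisymmetry_exact(self, random_matrix):
        ids = random_matrix.sample_ids.tolist()
        a, b = ids[:7], ids[7:]
        f1 = fit_two_group(random_matrix, a, b)
        f2 = fit_two_group(random_matrix, b, a)
        assert np.array_equal(f1.logfc, -f2.logfc)
        assert np.array_equal(f1.s2, f2.s2)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(50, 9)))
        a, b = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 9)]
        fit = fit_two_group(m, a, b)
        for i in range(50):
            va = m.values.iloc[i][a].to_numpy()
            vb = m.values.iloc[i][b].to_numpy()
            assert fit.logfc[i] == pytest.approx(vb.mean() - va.mean(), abs=1e-12)
            pooled = (np.sum((va - va.mean()) ** 2) + np.sum((vb - vb.mean()) ** 2)) / 7
            assert fit.s2[i] == pytest.approx(pooled, abs=1e-12)

    def test_single_sample_group_allowed(self):
        m = _matrix(np.random.default_rng(0).normal(size=(10, 5)))
        fit = fit_two_group(m, ["s0"], ["s1", "s2", "s3", "s4"])
        assert fit.df == 3
        assert np.isfinite(fit.logfc).all()

    def test_overlap_and_unknown_ids_rejected(self, random_matrix):
        ids = random_matrix.sample_ids.tolist()
        with pytest.raises(ValueError, match="overlap"):
            fit_two_group(random_matrix, ids[:3], ids[2:5])
        with pytest.raises(ValueError, match="unknown"):
            fit_two_group(random_matrix, ids[:3], ["nope", "nah"])


class TestEbayes:
    def test_identical_variances_give_no_heterogeneity(self):
        s2 = np.full(100, 0.7)
        model = ebayes_moderate(s2, df=6)
        assert np.isinf(model.d0)
        assert np.allclose(model.posterior_var, model.s0_sq)
        assert model.s0_sq == pytest.approx(0.7, rel=1e-6)

    def test_forced_infinite_prior_df(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(6, 500) / 6
        model = ebayes_moderate(s2, df=6, d0_override=np.inf)
        assert np.allclose(model.posterior_var, model.s0_sq)

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(4)
        d0, s0_sq, df, n = 4.0, 0.05, 12, 5000
        sigma2 = s0_sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        model = ebayes_moderate(s2, df=df)
        assert abs(model.d0 - d0) / d0 < 0.15
        assert abs(model.s0_sq - s0_sq) / s0_sq < 0.15

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ebayes_moderate(np.zeros(20), df=6)

    def test_shrinkage_stays_between_s2_and_prior(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(4, 300) / 4 * rng.lognormal(0, 1, 300)
        model = ebayes_moderate(s2, df=4)
        lo = np.minimum(s2, model.s0_sq) - 1e-12
        hi = np.maximum(s2, model.s0_sq) + 1e-12
        assert np.all(model.posterior_var >= lo) and np.all(model.posterior_var <= hi)


class TestModeratedT:
    def _fit_model(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        m = _matrix(rng.normal(size=(n, 10)))
        ids = m.sample_ids.tolist()
        fit = fit_two_group(m, ids[:5], ids[5:])
        return m, fit

    def test_null_logfc_gives_t_zero_p_one(self):
        # two genes with exactly equal group means
        m = _matrix([[1.0, 2.0, 1.0, 2.0], [3.0, 5.0, 5.0, 3.0]])
        fit = fit_two_group(m, ["s0", "s1"], ["s2", "s3"])
        assert np.allclose(fit.logfc, 0.0)
        model = ebayes_moderate(fit.s2, fit.df)
        tab = moderated_t(fit, model)
        assert np.allclose(tab["t_moderated"], 0.0)
        assert np.allclose(tab["p_value"], 1.0)

    def test_linearity_in_logfc(self):
        _, fit = self._fit_model()
        model = ebayes_moderate(fit.s2, fit.df)
        t1 = moderated_t(fit, model)["t_moderated"]
        fit.logfc = 2.0 * fit.logfc
        t2 = moderated_t(fit, model)["t_moderated"]
        assert np.allclose(t2, 2.0 * t1)

    def test_no_shrinkage_matches_classical_pooled_t(self):
        m, fit = self._fit_model(seed=3)
        model = ebayes_moderate(fit.s2, fit.df, d0_override=0.0)
        tab = moderated_t(fit, model)
        ids = m.sample_ids.tolist()
        ref = stats.ttest_ind(
            m.values[ids[5:]].to_numpy(), m.values[ids[:5]].to_numpy(), axis=1, equal_var=True
        )
        assert np.allclose(tab["t_moderated"], ref.statistic, atol=1e-10)
        assert np.allclose(tab["p_value"], ref.pvalue, atol=1e-10)

    def test_swapping_groups_negates_t(self, random_matrix):
        ids = random_matrix.sample_ids.tolist()
        d1 = run_de(random_matrix, ids[:7], ids[7:])
        d2 = run_de(random_matrix, ids[7:], ids[:7])
        assert np.allclose(d1["t_moderated"], -d2["t_moderated"])
        assert np.allclose(d1["logFC"], -d2["logFC"])

    def test_null_type_one_error_calibrated(self):
        # fraction of p < 0.05 on pure-noise data, averaged over replicates
        from follitime.synthetic_data import ArchetypeSpec, generate_timecourse

        fracs = []
        for rep in range(20):
            m, _ = generate_timecourse([ArchetypeSpec("flat", 500, noise_sd=0.3)], seed=100 + rep)
            ids = m.sample_ids.tolist()
            de = run_de(m, ids[:7], ids[7:])
            fracs.append(float((de["p_value"] < 0.05).mean()))
        assert abs(np.mean(fracs) - 0.05) < 0.01

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma_reference(self, tmp_path):
        rng = np.random.default_rng(12)
        n = 200
        m = _matrix(rng.normal(0, rng.lognormal(0, 0.5, (n, 1)), size=(n, 8)))
        ids = m.sample_ids.tolist()
        a, b = ids[:4], ids[4:]
        de = run_de(m, a, b)
        m.values.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("expr.tsv", row.names=1))
            design <- cbind(Intercept=1, B=c(0,0,0,0,1,1,1,1))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2])
            write.table(out, "limma.tsv", sep="\t", quote=FALSE)
            cat(fit$df.prior, fit$s2.prior, sep="\n")
            """
        )
        (tmp_path / "run.R").write_text(script)
        res = subprocess.run(
            ["Rscript", "run.R"], cwd=tmp_path, capture_output=True, text=True, check=True
        )
        d0_ref, s0_ref = (float(v) for v in res.stdout.split())
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        assert np.allclose(de["t_moderated"], ref["t"], rtol=1e-6)
        assert np.allclose(de["p_value"], ref["p"], rtol=1e-5)
        assert de.attrs["d0"] == pytest.approx(d0_ref, rel=1e-4)
        assert de.attrs["s0_sq"] == pytest.approx(s0_ref, rel=1e-4)


class TestRanking:
    def _table(self, logfc, t=None, ids=None):
        ids = ids or [f"g{i + 1}" for i in range(len(logfc))]
        t = t if t is not None else np.ones(len(logfc))
        return pd.DataFrame(
            {"logFC": logfc, "t_moderated": t}, index=pd.Index(ids, name="gene_id")
        )

    def test_descending_logfc(self):
        order = rank_by_logfc(self._table([3.0, 1.0, 2.0]))
        assert order.tolist() == ["g1", "g3", "g2"]

    def test_ties_broken_by_abs_t_then_id(self):
        tab = self._table([1.0, 1.0, 1.0], t=[-5.0, 2.0, 2.0], ids=["b", "c", "a"])
        assert rank_by_logfc(tab).tolist() == ["b", "a", "c"]

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(7)
        tab = self._table(rng.integers(0, 3, 30).astype(float), t=rng.normal(size=30))
        order = rank_by_logfc(tab)
        oracle = sorted(
            tab.index, key=lambda g: (-tab.loc[g, "logFC"], -abs(tab.loc[g, "t_moderated"]), g)
        )
        assert order.tolist() == oracle


class TestEnrichment:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        res = hypergeometric_enrichment(hits, universe, {"S": set(hits)})
        assert res["p_value"].iloc[0] == pytest.approx(1 / math.comb(20, 5))

    def test_p_bounded_by_one(self):
        universe = {f"g{i}" for i in range(30)}
        hits = {"g0", "g1"}
        res = hypergeometric_enrichment(hits, universe, {"S": {"g25", "g26"}})
        assert 0 < res["p_value"].iloc[0] <= 1.0

    def test_matches_enumeration_oracle(self):
        universe = {f"g{i}" for i in range(12)}
        hits = {f"g{i}" for i in range(5)}
        members = {"g0", "g1", "g7", "g8"}
        res = hypergeometric_enrichment(hits, universe, {"S": members})
        obs = res["overlap"].iloc[0]
        # exhaustive: P(overlap >= obs) for 5 draws from 12 with 4 marked
        M, n, N = 12, 4, 5
        p = sum(
            math.comb(n, k) * math.comb(M - n, N - k) / math.comb(M, N)
            for k in range(obs, min(n, N) + 1)
        )
        assert res["p_value"].iloc[0] == pytest.approx(p, rel=1e-12)

    def test_large_sets_excluded_and_bh_applied(self):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(10)}
        collection = {
            "big": set(universe),
            "small": {f"g{i}" for i in range(8)},
        }
        res = hypergeometric_enrichment(hits, universe, collection, max_set_size=50)
        assert res["set"].tolist() == ["small"]
        assert "adj_p" in res

    def test_empty_universe_and_bad_hits_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeometric_enrichment(set(), set(), {})
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"x"}, {"y"}, {})

    def test_gmt_roundtrip(self, tmp_path):
        sets = {"alpha": {"g1", "g2"}, "beta": {"g3"}}
        write_gmt(sets, tmp_path / "c.gmt")
        assert read_gmt(tmp_path / "c.gmt") == sets
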