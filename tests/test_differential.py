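"""Differential screens: normalization, moderated t, hubs, DMR test, PLS-DA."""

import subprocess
import textwrap

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq
from scipy.special import digamma, polygamma

from triomr import differential as diff
from triomr.datatypes import FeatureMatrix, GeneAnnotation, SampleSheet, ValidationError


def _counts(rng, n_genes, n_samples, mean=200):
    return pd.DataFrame(rng.poisson(mean, size=(n_genes, n_samples)),
                        index=[f"g{i:03d}" for i in range(n_genes)],
                        columns=[f"S{i:03d}" for i in range(n_samples)])


class TestNormalize:
    def test_all_zero_gene_filtered(self, sheet40):
        rng = np.random.default_rng(0)
        counts = _counts(rng, 10, 40)
        counts.iloc[0] = 0
        out = diff.normalize_and_filter_counts(counts, min_cpm=1.0)
        assert "g000" not in out.index

    def test_formula_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        counts = _counts(rng, 50, 12)
        out = diff.normalize_and_filter_counts(counts, min_cpm=0.0, min_samples=0)
        lib = counts.sum(axis=0).to_numpy()
        expected = np.log2((counts.to_numpy() + 0.5) / (lib + 1.0) * 1e6)
        assert np.allclose(out.to_numpy(), expected, atol=1e-12)

    def test_zero_library_sample_rejected(self):
        counts = pd.DataFrame([[1, 0], [2, 0]], columns=["A", "B"])
        with pytest.raises(ValidationError, match="B"):
            diff.normalize_and_filter_counts(counts)

    def test_equal_counts_equal_libraries_symmetric(self):
        counts = pd.DataFrame({"A": [100, 50], "B": [100, 50]}, index=["g1", "g2"])
        out = diff.normalize_and_filter_counts(counts, min_cpm=0.0, min_samples=0)
        assert np.allclose(out["A"], out["B"])


def _oracle_moments(s_sq, d):
    """Independent method-of-moments fit: brentq inversion of trigamma."""
    e = np.log(s_sq) - digamma(d / 2) + np.log(d / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - polygamma(1, d / 2)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0_half = brentq(lambda y: polygamma(1, y) - evar, 1e-6, 1e8)
    d0 = 2 * d0_half
    s0 = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0


class TestModeratedT:
    def _fit(self, sheet40, seed=0, n_genes=20):
        rng = np.random.default_rng(seed)
        n = len(sheet40.samples)
        X = sheet40.design_matrix()
        beta = rng.normal(0, 1, size=(n_genes, X.shape[1]))
        sd = np.sqrt(0.5 / rng.chisquare(8, n_genes) * 8)
        Y = beta @ X.T + rng.normal(0, sd[:, None], size=(n_genes, n))
        logexpr = pd.DataFrame(Y, index=[f"g{i:03d}" for i in range(n_genes)],
                               columns=sheet40.samples)
        return logexpr

    def test_zero_prior_df_recovers_ordinary_t(self, sheet40):
        logexpr = self._fit(sheet40)
        rec, params = diff.moderated_de_test(logexpr, sheet40, prior_df=0.0)
        assert np.allclose(rec["t"], rec["t_ordinary"], atol=1e-10)

    def test_equal_residual_variances_no_shrinkage(self, sheet40):
        """When every gene has the same residual variance the prior collapses
        onto it and moderation changes nothing."""
        rng = np.random.default_rng(3)
        n = len(sheet40.samples)
        base = rng.normal(0, 1, n)
        logexpr = pd.DataFrame(
            np.stack([base + mu for mu in range(6)]),
            index=[f"g{i}" for i in range(6)], columns=sheet40.samples)
        rec, params = diff.moderated_de_test(logexpr, sheet40)
        assert np.isinf(params.d0)
        ok = np.isfinite(rec["t_ordinary"])
        assert np.allclose(rec.loc[ok, "t"], rec.loc[ok, "t_ordinary"], atol=1e-8)

    def test_matches_independent_moments_oracle(self, sheet40):
        logexpr = self._fit(sheet40, seed=4)
        rec, params = diff.moderated_de_test(logexpr, sheet40)
        d0, s0 = _oracle_moments(params.s_sq, params.df_residual)
        assert params.d0 == pytest.approx(d0, abs=1e-6)
        assert params.s0_sq == pytest.approx(s0, rel=1e-8)
        stilde = (d0 * s0 + params.df_residual * params.s_sq) / (d0 + params.df_residual)
        assert np.allclose(params.s_tilde_sq, stilde, atol=1e-8)
        # moderated t and p recomputed from the oracle parameters
        X = sheet40.design_matrix()
        unscaled = np.sqrt(np.linalg.inv(X.T @ X)[1, 1])
        t = rec["logFC"].to_numpy() / (np.sqrt(stilde) * unscaled)
        assert np.allclose(rec["t"], t, atol=1e-8)
        p = 2 * stats.t.sf(np.abs(t), d0 + params.df_residual)
        assert np.allclose(rec["p"], p, atol=1e-8)

    def test_matches_limma_ebayes(self, sheet40, tmp_path):
        """Cross-check the empirical-Bayes fit against Bioconductor limma."""
        logexpr = self._fit(sheet40, seed=6, n_genes=25)
        logexpr.to_csv(tmp_path / "y.tsv", sep="\t")
        sheet40.table.to_csv(tmp_path / "design.tsv", sep="\t")
        rscript = textwrap.dedent("""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("y.tsv", row.names=1))
            d <- read.delim("design.tsv", row.names=1)
            X <- model.matrix(~ group + exercise, data=d)
            fit <- eBayes(lmFit(y, X))
            out <- data.frame(d0=fit$df.prior, s0=fit$s2.prior,
                              t=fit$t[, "group"], p=fit$p.value[, "group"])
            write.csv(out, "limma.csv")
        """)
        (tmp_path / "run.R").write_text(rscript)
        subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        limma = pd.read_csv(tmp_path / "limma.csv", index_col=0)
        rec, params = diff.moderated_de_test(logexpr, sheet40)
        assert params.d0 == pytest.approx(limma["d0"].iloc[0], rel=1e-4)
        assert params.s0_sq == pytest.approx(limma["s0"].iloc[0], rel=1e-4)
        assert np.allclose(rec["t"], limma["t"], rtol=1e-6)
        assert np.allclose(rec["p"], limma["p"], rtol=1e-6)

    def test_large_prior_df_pools_variance(self, sheet40):
        """As d0 grows the moderated statistic becomes a z-score with the
        pooled prior variance."""
        logexpr = self._fit(sheet40, seed=7)
        rec, params = diff.moderated_de_test(logexpr, sheet40, prior_df=1e8)
        X = sheet40.design_matrix()
        unscaled = np.sqrt(np.linalg.inv(X.T @ X)[1, 1])
        z = rec["logFC"].to_numpy() / (np.sqrt(params.s0_sq) * unscaled)
        assert np.allclose(rec["t"], z, rtol=1e-6)
        rec0, _ = diff.moderated_de_test(logexpr, sheet40, prior_df=1e-8)
        assert np.allclose(rec0["t"], rec0["t_ordinary"], rtol=1e-6)

    def test_bh_adjustment_is_monotone(self, sheet40):
        logexpr = self._fit(sheet40, seed=8, n_genes=40)
        rec, _ = diff.moderated_de_test(logexpr, sheet40)
        ordered = rec.sort_values("p")
        assert (np.diff(ordered["adj_p"]) >= -1e-15).all()
        assert (rec["adj_p"] >= rec["p"] - 1e-15).all()

    def test_too_few_samples_rejected(self):
        table = pd.DataFrame({"group": [0, 1, 0], "exercise": [1, 0, 1]},
                             index=["a", "b", "c"])
        sheet = SampleSheet(table=table)
        logexpr = pd.DataFrame(np.ones((2, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValidationError, match="samples"):
            diff.moderated_de_test(logexpr, sheet)


class TestSelectDegs:
    @pytest.mark.parametrize("adjp,logfc,kept", [
        (0.005, -5.2, True),
        (0.005, 4.9, False),
        (0.01, 5.0, True),    # inclusive thresholds
        (0.011, 8.0, False),
    ])
    def test_threshold_rule(self, adjp, logfc, kept):
        rec = pd.DataFrame({"gene_id": ["g"], "logFC": [logfc], "adj_p": [adjp]})
        out = diff.select_degs(rec)
        assert (len(out) == 1) is kept

    def test_empty_input(self):
        assert diff.select_degs(pd.DataFrame()).empty


def _greedy_planar_oracle(corr: pd.DataFrame):
    """Exhaustive greedy replay of the planar-filter rule."""
    genes = list(corr.index)
    pairs = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = sorted((genes[i], genes[j]))
            pairs.append((-abs(corr.iloc[i, j]), a, b))
    pairs.sort()
    g = nx.Graph()
    g.add_nodes_from(genes)
    edges = []
    for _, a, b in pairs:
        g.add_edge(a, b)
        if nx.check_planarity(g)[0]:
            edges.append((a, b))
        else:
            g.remove_edge(a, b)
    return set(edges)


class TestPlanarHubs:
    def test_k4_fully_retained(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(size=(4, 30)), index=list("abcd"))
        _, edges = diff.planar_hub_genes(mat)
        assert len(edges) == 6  # K4 is planar

    def test_triangle_retained(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(3, 20)), index=list("abc"))
        hubs, edges = diff.planar_hub_genes(mat)
        assert len(edges) == 3

    def test_matches_exhaustive_greedy_replay(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(5, 60))
        load = rng.normal(size=(30, 5))
        mat = pd.DataFrame(load @ base + 0.6 * rng.normal(size=(30, 60)),
                           index=[f"g{i:02d}" for i in range(30)])
        _, edges = diff.planar_hub_genes(mat)
        corr = pd.DataFrame(np.corrcoef(mat), index=mat.index, columns=mat.index)
        assert {(a, b) for a, b, _ in edges} == _greedy_planar_oracle(corr)

    def test_constant_gene_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(4, 20)), index=list("abcd"))
        mat.loc["a"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            hubs, edges = diff.planar_hub_genes(mat)
        assert all("a" not in e[:2] for e in edges)

    def test_too_few_genes_rejected(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)))
        with pytest.raises(ValidationError):
            diff.planar_hub_genes(mat)


def _meth_matrix(rng, props, coverage, samples):
    n_sites = props.shape[0]
    ids = [f"1.{1000 + i}" for i in range(n_sites)]
    cov = pd.DataFrame(coverage, index=ids, columns=samples)
    mc = pd.DataFrame(rng.binomial(coverage, props), index=ids, columns=samples)
    meta = pd.DataFrame({"site_id": ids, "chrom": "1",
                         "pos": 1000 + np.arange(n_sites), "strand": "+"}, index=ids)
    return FeatureMatrix(layer="methylation", samples=samples, coverage=cov,
                         methylated=mc, feature_meta=meta)


class TestMethylationTest:
    def test_exact_null_site(self, sheet40):
        """Identical per-sample proportions in both groups: PMD 0, coef 0, p 1."""
        n = len(sheet40.samples)
        cov = np.full((1, n), 40)
        ids = ["1.1000"]
        mc = pd.DataFrame(np.full((1, n), 20), index=ids, columns=sheet40.samples)
        fm = FeatureMatrix(
            layer="methylation", samples=sheet40.samples,
            coverage=pd.DataFrame(cov, index=ids, columns=sheet40.samples),
            methylated=mc,
            feature_meta=pd.DataFrame({"site_id": ids, "chrom": "1",
                                       "pos": [1000], "strand": "+"}, index=ids))
        rec = diff.methylation_site_test(fm, sheet40)
        assert rec["pmd"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert rec["coef_group"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert rec["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_pmd_sign_convention(self, sheet40):
        """Case mean 0.70 vs control 0.50 gives PMD = +20, direction hyper."""
        rng = np.random.default_rng(0)
        group = sheet40.group.astype(bool)
        n = len(group)
        props = np.where(group, 0.70, 0.50)[None, :]
        cov = np.full((1, n), 500)
        ids = ["1.1000"]
        mc = pd.DataFrame((props * cov).round().astype(int), index=ids,
                          columns=sheet40.samples)
        fm = FeatureMatrix(layer="methylation", samples=sheet40.samples,
                           coverage=pd.DataFrame(cov, index=ids, columns=sheet40.samples),
                           methylated=mc,
                           feature_meta=pd.DataFrame({"site_id": ids, "chrom": "1",
                                                      "pos": [1000], "strand": "+"},
                                                     index=ids))
        rec = diff.methylation_site_test(fm, sheet40)
        assert rec["pmd"].iloc[0] == pytest.approx(20.0, abs=0.5)
        assert rec["direction"].iloc[0] == "hyper"

    def test_matches_statsmodels_glm_oracle(self, sheet40):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = len(sheet40.samples)
        n_sites = 50
        X = sheet40.design_matrix()
        eta = rng.normal(0, 0.8, size=(n_sites, 1)) + \
            rng.normal(0, 0.7, size=(n_sites, 1)) * sheet40.group[None, :]
        props = 1 / (1 + np.exp(-eta))
        coverage = rng.poisson(30, size=(n_sites, n)) + 1
        fm = _meth_matrix(rng, props, coverage, sheet40.samples)
        rec = diff.methylation_site_test(fm, sheet40)
        X_red = np.delete(X, 1, axis=1)
        for i in range(0, n_sites, 7):
            endog = np.column_stack([fm.methylated.iloc[i],
                                     fm.coverage.iloc[i] - fm.methylated.iloc[i]])
            full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
            red = sm.GLM(endog, X_red, family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - red.llf)
            assert rec["coef_group"].iloc[i] == pytest.approx(full.params[1], abs=1e-6)
            assert rec["lrt"].iloc[i] == pytest.approx(lrt, abs=1e-6)

    def test_pmd_bounded(self, small_bundle):
        rec = diff.methylation_site_test(small_bundle.methylation, small_bundle.sheet)
        assert rec["pmd"].between(-100, 100).all()


class TestSelectDmrs:
    def _rec(self, q, pmd):
        return pd.DataFrame({"site_id": ["s"], "q": [q], "pmd": [pmd],
                             "direction": ["hyper" if pmd > 0 else "hypo"]})

    def test_q_boundary_strict(self):
        sel, _, _ = diff.select_dmrs(self._rec(0.01, 50.0))
        assert sel.empty

    def test_printed_pmd_value_survives_stringent_cut(self):
        """|PMD| = 15.10461 with q << 0.01 is retained at the 15% threshold."""
        sel, _, _ = diff.select_dmrs(self._rec(3.46e-52, 15.10461), pmd_min=15.0)
        assert len(sel) == 1

    def test_negative_pmd_passes_absolute_filter(self):
        sel, hyper, hypo = diff.select_dmrs(self._rec(1e-5, -21.88445), pmd_min=15.0)
        assert len(sel) == 1 and len(hypo) == 1 and hyper.empty

    def test_partition_into_hyper_hypo(self, small_bundle):
        rec = diff.methylation_site_test(small_bundle.methylation, small_bundle.sheet)
        sel, hyper, hypo = diff.select_dmrs(rec)
        assert len(sel) == len(hyper) + len(hypo)


class TestAnnotateNearestTss:
    def _ann(self, rows):
        return GeneAnnotation(pd.DataFrame(rows))

    def test_single_gene_on_chromosome(self):
        ann = self._ann([{"gene_id": "A", "chrom": "1", "tss": 100, "strand": "+"}])
        dmrs = pd.DataFrame({"site_id": ["1.5000"], "chrom": ["1"], "pos": [5000]})
        out = diff.annotate_nearest_tss(dmrs, ann)
        assert out["gene_id"].tolist() == ["A"]

    def test_equidistant_tie_smaller_tss_wins(self):
        ann = self._ann([{"gene_id": "B", "chrom": "1", "tss": 200, "strand": "+"},
                         {"gene_id": "A", "chrom": "1", "tss": 100, "strand": "+"}])
        dmrs = pd.DataFrame({"site_id": ["1.150"], "chrom": ["1"], "pos": [150]})
        out = diff.annotate_nearest_tss(dmrs, ann)
        assert out["gene_id"].tolist() == ["A"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        ann_rows = [{"gene_id": f"G{i:03d}", "chrom": str(rng.integers(1, 4)),
                     "tss": int(rng.integers(1, 10**6)), "strand": "+"}
                    for i in range(40)]
        ann = self._ann(ann_rows)
        sites = pd.DataFrame({
            "site_id": [f"x{i}" for i in range(100)],
            "chrom": [str(rng.integers(1, 4)) for _ in range(100)],
            "pos": rng.integers(1, 10**6, 100),
        })
        out = diff.annotate_nearest_tss(sites, ann).set_index("site_id")
        tab = ann.table
        for _, s in sites.iterrows():
            sub = tab[tab["chrom"] == s["chrom"]].copy()
            sub["d"] = (sub["tss"] - s["pos"]).abs()
            best = sub.sort_values(["d", "tss", "gene_id"]).iloc[0]
            assert out.loc[s["site_id"], "gene_id"] == best["gene_id"]

    def test_unmapped_chromosome_warns(self):
        ann = self._ann([{"gene_id": "A", "chrom": "1", "tss": 100, "strand": "+"}])
        dmrs = pd.DataFrame({"site_id": ["9.1"], "chrom": ["9"], "pos": [1]})
        with pytest.warns(UserWarning, match="absent"):
            out = diff.annotate_nearest_tss(dmrs, ann)
        assert out.empty


def _metab_matrix(rng, n_metab, sheet, effects=None):
    n = len(sheet.samples)
    logv = rng.normal(0, 0.5, size=(n_metab, n))
    if effects is not None:
        logv += np.asarray(effects)[:, None] * sheet.group[None, :]
    df = pd.DataFrame(np.exp(logv), index=[f"m{i:02d}" for i in range(n_metab)],
                      columns=sheet.samples)
    return FeatureMatrix(layer="metabolite", samples=sheet.samples, values=df,
                         feature_meta=pd.DataFrame(index=df.index))


class TestPlsdaVip:
    def test_mean_squared_vip_is_one(self, sheet40):
        rng = np.random.default_rng(0)
        fm = _metab_matrix(rng, 12, sheet40)
        vip = diff.plsda_vip(fm, sheet40, n_components=2)
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_separating_metabolite_dominates(self, sheet40):
        rng = np.random.default_rng(1)
        effects = np.zeros(10)
        effects[3] = 3.0
        fm = _metab_matrix(rng, 10, sheet40, effects)
        vip = diff.plsda_vip(fm, sheet40, n_components=2)
        assert vip.iloc[3] > 1.0
        assert vip.iloc[3] == vip.max()

    def test_matches_sklearn_reference(self, sheet40):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(2)
        fm = _metab_matrix(rng, 10, sheet40, rng.normal(0, 0.5, 10))
        vip = diff.plsda_vip(fm, sheet40, n_components=2)
        # independent VIP from the sklearn fit on the same autoscaled matrix
        logv = np.log(fm.values.to_numpy())
        X = ((logv - logv.mean(axis=1, keepdims=True))
             / logv.std(axis=1, ddof=1, keepdims=True)).T
        y = sheet40.group - sheet40.group.mean()
        pls = PLSRegression(n_components=2, scale=False).fit(X, y)
        T, W, Q = pls.x_scores_, pls.x_weights_, pls.y_loadings_
        ss = (Q.ravel() ** 2) * (T ** 2).sum(axis=0)
        wn = W / np.linalg.norm(W, axis=0, keepdims=True)
        ref = np.sqrt(X.shape[1] * (wn ** 2 @ ss) / ss.sum())
        assert np.allclose(vip.to_numpy(), ref, atol=1e-6)

    def test_zero_variance_metabolite_rejected(self, sheet40):
        rng = np.random.default_rng(3)
        fm = _metab_matrix(rng, 5, sheet40)
        fm.values.iloc[2] = 1.0
        with pytest.raises(ValidationError, match="m02"):
            diff.plsda_vip(fm, sheet40)

    def test_component_bounds(self, sheet40):
        rng = np.random.default_rng(4)
        fm = _metab_matrix(rng, 6, sheet40)
        with pytest.raises(ValidationError, match="n_components"):
            diff.plsda_vip(fm, sheet40, n_components=0)


class TestMetaboliteLogistic:
    def test_matches_independent_irls_oracle(self, sheet40):
        rng = np.random.default_rng(5)
        fm = _metab_matrix(rng, 20, sheet40, rng.normal(0, 0.4, 20))
        out = diff.metabolite_logistic(fm, sheet40)
        y = sheet40.group
        covs = sheet40.covariate_matrix()
        logv = np.log(fm.values.to_numpy())
        scaled = ((logv - logv.mean(axis=1, keepdims=True))
                  / logv.std(axis=1, ddof=1, keepdims=True))
        for i in range(0, 20, 3):
            X = np.column_stack([np.ones(len(y)), scaled[i], covs])
            beta = np.zeros(X.shape[1])
            for _ in range(60):  # straight Newton-Raphson
                mu = 1 / (1 + np.exp(-X @ beta))
                W = mu * (1 - mu)
                step = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - mu))
                beta += step
                if np.abs(step).max() < 1e-12:
                    break
            assert out["estimate"].iloc[i] == pytest.approx(beta[1], abs=1e-6)

    def test_wald_p_printed_convention(self):
        """The reported estimate/se pair (0.53, 0.21) prints p = 0.01."""
        p = 2 * stats.norm.sf(0.53 / 0.21)
        assert round(p, 2) == 0.01


class TestSelectDams:
    def _inputs(self, vip, p):
        vips = pd.Series([vip], index=["m"], name="vip")
        logi = pd.DataFrame({"metabolite": ["m"], "estimate": [0.5], "se": [0.2],
                             "p": [p]}).set_index("metabolite", drop=False)
        return vips, logi

    @pytest.mark.parametrize("vip,p,kept", [
        (1.07, 0.03, True),   # printed Isobutyrylcarnitine row survives
        (1.0, 0.03, False),   # VIP threshold strict
        (2.0, 0.05, False),   # p threshold strict
        (1.5, 0.01, True),
    ])
    def test_strict_thresholds(self, vip, p, kept):
        vips, logi = self._inputs(vip, p)
        out = diff.select_dams(vips, logi)
        assert (len(out) == 1) is kept

    def test_mismatched_universe_rejected(self):
        vips, logi = self._inputs(1.5, 0.01)
        with pytest.raises(ValidationError):
            diff.select_dams(vips.rename(index={"m": "other"}), logi)
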