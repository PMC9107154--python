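"""Differential screening of the three omic layers.

Three screens mirror the study design:

* expression — library-size normalization to log2 counts-per-million, then a
  per-gene linear model (group + covariates) with empirical-Bayes variance
  moderation; significant genes filtered on BH-adjusted p and |log2 fold
  change|, then reduced to co-expression hub genes on a greedily built planar
  correlation network (a light-weight stand-in for full multiscale embedded
  network analysis).
* methylation — per-site binomial logistic regression of (methylated,
  unmethylated) counts on group + covariates, likelihood-ratio p for the group
  term, FDR q-values, and the percent methylation difference (PMD) between
  group mean proportions.
* metabolites — PLS-DA variable importance in projection (VIP) combined with
  a per-metabolite logistic regression of group on scaled log abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, expit, polygamma

from ._stats import bh_adjust, qvalues, trigamma_inverse
from .datatypes import FeatureMatrix, GeneAnnotation, SampleSheet, ValidationError

COEF_CLAMP = 15.0  # logistic separation guard on the linear predictor scale


# ---------------------------------------------------------------------------
# Expression


def normalize_and_filter_counts(
    counts: FeatureMatrix | pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Log2 counts-per-million with pseudocount 0.5 and a low-count filter.

    A gene is kept iff its plain CPM exceeds ``min_cpm`` in at least
    ``min_samples`` samples (default: 25% of samples).  The returned matrix is
    log2((count + 0.5) / (libsize + 1) * 1e6) with the sample axis unchanged.
    """
    df = counts.values if isinstance(counts, FeatureMatrix) else counts
    mat = df.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValidationError("counts must be non-negative")
    lib = mat.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(f"sample {df.columns[zero[0]]!r} has zero total counts")
    if min_samples is None:
        min_samples = int(np.ceil(0.25 * df.shape[1]))
    cpm = mat / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    logcpm = np.log2((mat + 0.5) / (lib + 1.0) * 1e6)
    return pd.DataFrame(logcpm[keep], index=df.index[keep], columns=df.columns)


@dataclass
class ModeratedFitParams:
    """Empirical-Bayes variance moderation parameters.

    ``d0`` (prior df) and ``s0_sq`` (prior variance) come from a
    method-of-moments fit to the log residual variances (digamma/trigamma
    inversion); posterior variances interpolate between each gene's ``s_sq``
    and the prior.
    """

    d0: float
    s0_sq: float
    df_residual: float
    s_sq: np.ndarray
    s_tilde_sq: np.ndarray


def _fit_prior_moments(s_sq: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene residual variances."""
    z = np.log(np.maximum(s_sq, 1e-300))
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    n = e.size
    evar = float(((e - emean) ** 2).sum() / max(n - 1, 1)) - float(polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # zero spread in the log variances: the prior collapses onto the
        # common (geometric mean) variance with infinite prior df
        d0 = np.inf
        s0_sq = float(np.exp(np.log(np.maximum(s_sq, 1e-300)).mean()))
    return d0, s0_sq


def moderated_de_test(
    logexpr: pd.DataFrame,
    design: SampleSheet,
    prior_df: float | None = None,
) -> tuple[pd.DataFrame, ModeratedFitParams]:
    """Per-gene linear model with empirical-Bayes moderated t for the group term.

    ``prior_df`` overrides the estimated prior degrees of freedom (0 recovers
    the ordinary t-test; ``inf`` pools all genes to the prior variance).
    Returns one record per gene (logFC, moderated/ordinary t, raw and
    BH-adjusted p) plus the moderation parameters.
    """
    X = design.design_matrix()
    n, p = X.shape
    if logexpr.shape[1] != n:
        raise ValidationError("expression sample axis differs from design")
    if n < p + 1:
        raise ValidationError(f"need at least {p + 1} samples for {p} model parameters, got {n}")
    Y = logexpr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    d = float(n - p)
    s_sq = (resid ** 2).sum(axis=0) / d
    xtx_inv = np.linalg.inv(X.T @ X)
    unscaled = float(np.sqrt(xtx_inv[1, 1]))
    coef = beta[1]  # group column

    if prior_df is None:
        d0, s0_sq = _fit_prior_moments(s_sq, d)
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_prior_moments(s_sq, d)
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef / (np.sqrt(s_tilde_sq) * unscaled)
        t_ord = coef / (np.sqrt(s_sq) * unscaled)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    records = pd.DataFrame({
        "gene_id": logexpr.index,
        "logFC": coef,
        "t": t_mod,
        "p": p_raw,
        "adj_p": bh_adjust(p_raw),
        "t_ordinary": t_ord,
    }).set_index("gene_id", drop=False)
    params = ModeratedFitParams(d0=d0, s0_sq=s0_sq, df_residual=d,
                                s_sq=s_sq, s_tilde_sq=s_tilde_sq)
    return records, params


def select_degs(records: pd.DataFrame, adjp_max: float = 0.01,
                min_abs_logfc: float = 5.0) -> pd.DataFrame:
    """Significant genes: adjusted p <= ``adjp_max`` and |logFC| >= ``min_abs_logfc``
    (both thresholds inclusive)."""
    if records.empty:
        return records
    keep = (records["adj_p"] <= adjp_max) & (records["logFC"].abs() >= min_abs_logfc)
    return records[keep]


def planar_hub_genes(
    deg_logexpr: pd.DataFrame, hub_quantile: float = 0.9
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy planar-filtered co-expression network and its hub genes.

    Gene pairs are ranked by |Pearson r| (ties broken lexicographically) and
    inserted greedily while the graph stays planar; hubs are nodes whose
    degree exceeds the ``hub_quantile`` quantile of the degree distribution.
    """
    if deg_logexpr.shape[0] < 3:
        raise ValidationError("planar network needs at least 3 genes")
    mat = deg_logexpr.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    if (sd == 0).any():
        for g in deg_logexpr.index[sd == 0]:
            warnings.warn(f"excluding constant gene {g!r} from network")
        deg_logexpr = deg_logexpr.loc[sd > 0]
        mat = deg_logexpr.to_numpy(dtype=float)
        if mat.shape[0] < 3:
            raise ValidationError("fewer than 3 non-constant genes")
    genes = list(deg_logexpr.index)
    corr = np.corrcoef(mat)
    pairs = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = sorted((genes[i], genes[j]))
            pairs.append((-abs(corr[i, j]), a, b, corr[i, j]))
    pairs.sort()
    g = nx.Graph()
    g.add_nodes_from(genes)
    edges: list[tuple[str, str, float]] = []
    max_edges = 3 * len(genes) - 6
    for _, a, b, r in pairs:
        g.add_edge(a, b)
        if nx.check_planarity(g, counterexample=False)[0]:
            edges.append((a, b, float(r)))
            if len(edges) >= max_edges:
                break
        else:
            g.remove_edge(a, b)
    degrees = np.array([g.degree(x) for x in genes], dtype=float)
    cut = float(np.quantile(degrees, hub_quantile))
    hubs = [genes[i] for i in range(len(genes)) if degrees[i] > cut]
    if not hubs:
        # near-regular small networks: the strict quantile cut can exclude
        # everything, so fall back to the maximal-degree nodes
        hubs = [genes[i] for i in range(len(genes)) if degrees[i] == degrees.max()]
    return hubs, edges


# ---------------------------------------------------------------------------
# Methylation


def _batched_binomial_irls(
    meth: np.ndarray, cov: np.ndarray, X: np.ndarray,
    max_iter: int = 50, tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit a binomial logistic GLM per site (rows) by IRLS, vectorized.

    Cells with zero coverage carry zero weight.  Returns (coefficients,
    deviance, converged flag, clamped flag); coefficients hitting the
    separation clamp are frozen at +/-COEF_CLAMP.
    """
    n_sites, n = meth.shape
    p = X.shape[1]
    B = np.zeros((n_sites, p))
    covf = cov.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(covf > 0, meth / np.maximum(covf, 1.0), 0.0)
    # initialize intercept at the empirical logit of the pooled proportion
    pooled = (meth.sum(axis=1) + 0.5) / (covf.sum(axis=1) + 1.0)
    B[:, 0] = np.log(pooled / (1.0 - pooled))
    converged = np.zeros(n_sites, dtype=bool)
    clamped = np.zeros(n_sites, dtype=bool)
    dev_old = np.full(n_sites, np.inf)
    dev = dev_old
    for _ in range(max_iter):
        eta = np.clip(B @ X.T, -COEF_CLAMP * 2, COEF_CLAMP * 2)
        mu = expit(eta)
        w = covf * mu * (1.0 - mu)
        w = np.maximum(w, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = eta + np.where(w > 0, (y - mu) / np.maximum(mu * (1.0 - mu), 1e-12), 0.0)
        XtWX = np.einsum("ni,sn,nj->sij", X, w, X)
        XtWz = np.einsum("ni,sn,sn->si", X, w, z)
        # ridge jitter keeps near-separated fits solvable
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        B_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        over = np.abs(B_new) > COEF_CLAMP
        if over.any():
            clamped |= over.any(axis=1)
            B_new = np.clip(B_new, -COEF_CLAMP, COEF_CLAMP)
        B = np.where(converged[:, None], B, B_new)
        dev = _binomial_deviance(meth, covf, expit(np.clip(B @ X.T, -50, 50)))
        done = np.abs(dev - dev_old) < tol * (np.abs(dev) + 0.1)
        converged |= done
        if converged.all():
            break
        dev_old = dev
    return B, dev, converged, clamped


def _binomial_deviance(meth: np.ndarray, cov: np.ndarray, mu: np.ndarray) -> np.ndarray:
    y = meth.astype(float)
    miss = cov - y
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (cov * mu)), 0.0)
        t2 = np.where(miss > 0, miss * np.log(miss / (cov * (1.0 - mu))), 0.0)
    t1 = np.where(cov > 0, t1, 0.0)
    t2 = np.where(cov > 0, t2, 0.0)
    return 2.0 * (t1 + t2).sum(axis=1)


def methylation_site_test(
    meth: FeatureMatrix, design: SampleSheet,
    min_covered_per_group: int = 3, q_method: str = "bh",
) -> pd.DataFrame:
    """Per-site binomial logistic regression with a likelihood-ratio group test.

    PMD is 100 x (mean case proportion - mean control proportion) over covered
    samples.  Sites with fewer than ``min_covered_per_group`` covered samples
    in either group are skipped.  Non-converged fits keep p = NaN.
    """
    cov = meth.coverage.to_numpy(dtype=float)
    mc = meth.methylated.to_numpy(dtype=float)
    X = design.design_matrix()
    group = design.group.astype(bool)

    covered = cov >= 1
    enough = (covered[:, group].sum(axis=1) >= min_covered_per_group) & (
        covered[:, ~group].sum(axis=1) >= min_covered_per_group)
    idx = np.flatnonzero(enough)
    if idx.size == 0:
        raise ValidationError("no site has enough covered samples in both groups")

    B_full, dev_full, conv_full, clamp_full = _batched_binomial_irls(mc[idx], cov[idx], X)
    X_red = np.delete(X, 1, axis=1)
    _, dev_red, conv_red, _ = _batched_binomial_irls(mc[idx], cov[idx], X_red)
    lrt = np.maximum(dev_red - dev_full, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    ok = conv_full & conv_red
    p = np.where(ok, p, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(covered, mc / np.maximum(cov, 1.0), np.nan)
    case_mean = np.nanmean(prop[np.ix_(idx, group)], axis=1)
    ctrl_mean = np.nanmean(prop[np.ix_(idx, ~group)], axis=1)
    pmd = 100.0 * (case_mean - ctrl_mean)

    meta = meth.feature_meta.iloc[idx]
    records = pd.DataFrame({
        "site_id": meth.coverage.index[idx],
        "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(),
        "strand": meta["strand"].to_numpy(),
        "coef_group": B_full[:, 1],
        "p": p,
        "q": qvalues(p, q_method),
        "pmd": pmd,
        "direction": np.where(pmd > 0, "hyper", np.where(pmd < 0, "hypo", "none")),
        "converged": ok,
        "clamped": clamp_full,
        "lrt": lrt,
    }).set_index("site_id", drop=False)
    return records


def select_dmrs(records: pd.DataFrame, q_max: float = 0.01,
                pmd_min: float = 10.0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Significant sites: q < ``q_max`` and |PMD| > ``pmd_min`` (both strict).

    Returns (selected, hyper-methylated, hypo-methylated)."""
    if records.empty:
        return records, records, records
    keep = (records["q"] < q_max) & (records["pmd"].abs() > pmd_min)
    keep &= records["q"].notna()
    sel = records[keep]
    return sel, sel[sel["pmd"] > 0], sel[sel["pmd"] < 0]


def annotate_nearest_tss(dmrs: pd.DataFrame, annotation: GeneAnnotation) -> pd.DataFrame:
    """Map each site to the gene with minimal |position - TSS| on its chromosome.

    Ties break to the smaller TSS coordinate, then lexicographic gene id.
    Sites on chromosomes absent from the annotation are left unmapped with a
    warning.
    """
    if annotation.table.empty:
        raise ValidationError("empty gene annotation")
    ann = annotation.table
    by_chrom = {str(c): sub for c, sub in ann.groupby(ann["chrom"].astype(str))}
    rows = []
    for _, site in dmrs.iterrows():
        chrom = str(site["chrom"])
        sub = by_chrom.get(chrom)
        if sub is None:
            warnings.warn(f"site {site['site_id']} on chromosome {chrom} absent from annotation")
            continue
        dist = (sub["tss"] - int(site["pos"])).abs()
        cand = sub.assign(distance=dist).sort_values(
            ["distance", "tss", "gene_id"], kind="mergesort")
        best = cand.iloc[0]
        rows.append({"site_id": site["site_id"], "gene_id": best["gene_id"],
                     "distance": int(best["distance"])})
    return pd.DataFrame(rows, columns=["site_id", "gene_id", "distance"])


# ---------------------------------------------------------------------------
# Metabolites


def _autoscale_log(metab: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    df = metab.values if isinstance(metab, FeatureMatrix) else metab
    logged = np.log(df.to_numpy(dtype=float))
    sd = logged.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = df.index[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance metabolite {bad!r}")
    scaled = (logged - logged.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(scaled, index=df.index, columns=df.columns)


def plsda_vip(metab: FeatureMatrix | pd.DataFrame, groups: SampleSheet,
              n_components: int = 2) -> pd.Series:
    """Variable importance in projection from a NIPALS PLS-DA fit.

    Metabolite abundances are log-transformed and autoscaled; the response is
    the binary group.  VIP_j = sqrt(p * sum_a SS_a (w_ja / ||w_a||)^2 /
    sum_a SS_a) with SS_a the y-variance explained by component a, so the mean
    squared VIP is exactly 1.
    """
    scaled = _autoscale_log(metab)
    X = scaled.to_numpy(dtype=float).T.copy()  # samples x metabolites
    y = groups.group - groups.group.mean()
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if not (1 <= n_components < rank):
        raise ValidationError(f"n_components must be in [1, rank={rank}), got {n_components}")
    W = np.zeros((p, n_components))
    ss = np.zeros(n_components)
    yres = y.astype(float).copy()
    for a in range(n_components):
        w = X.T @ yres
        w /= np.linalg.norm(w)
        t = X @ w
        tt = t @ t
        p_load = X.T @ t / tt
        q = yres @ t / tt
        X = X - np.outer(t, p_load)
        yres = yres - q * t
        W[:, a] = w
        ss[a] = (q ** 2) * tt
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn ** 2 @ ss) / ss.sum())
    return pd.Series(vip, index=scaled.index, name="vip")


def metabolite_logistic(metab: FeatureMatrix | pd.DataFrame,
                        design: SampleSheet) -> pd.DataFrame:
    """Per-metabolite logistic regression of group on scaled log abundance.

    Covariates enter additively; the reported (estimate, se, Wald p) belong to
    the abundance term.  Perfect separation is flagged and leaves p = NaN.
    """
    import statsmodels.api as sm

    scaled = _autoscale_log(metab)
    y = design.group
    covs = design.covariate_matrix()
    rows = []
    for mid in scaled.index:
        x = scaled.loc[mid].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(x), x, covs])
        flagged = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            est, se = float(fit.params[1]), float(fit.bse[1])
            if not fit.converged or abs(est) > COEF_CLAMP:
                flagged = True
        except Exception:
            flagged = True
            est, se = np.nan, np.nan
        if flagged or se == 0 or not np.isfinite(se):
            p = np.nan
        else:
            p = 2.0 * stats.norm.sf(abs(est / se))
        rows.append({"metabolite": mid, "estimate": est, "se": se, "p": p,
                     "separated": flagged})
    return pd.DataFrame(rows).set_index("metabolite", drop=False)


def select_dams(vips: pd.Series, logistic_results: pd.DataFrame,
                vip_min: float = 1.0, p_max: float = 0.05) -> pd.DataFrame:
    """Significant metabolites: VIP > ``vip_min`` and Wald p < ``p_max`` (strict)."""
    if set(vips.index) != set(logistic_results.index):
        raise ValidationError("VIP and logistic results cover different metabolites")
    merged = logistic_results.copy()
    merged["vip"] = vips.reindex(merged.index)
    keep = (merged["vip"] > vip_min) & (merged["p"] < p_max) & merged["p"].notna()
    return merged[keep]
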