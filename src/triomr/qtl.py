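"""QTL mapping: additive linear regression of every feature on every variant.

The scan residualizes both the transformed feature and the dosage on the
covariates plus an intercept, then regresses feature residuals on dosage
residuals; by the Frisch-Waugh theorem this is mathematically identical to a
per-pair ordinary least squares fit with the covariates included directly,
but runs as matrix products over all (variant, feature) pairs at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit

from .datatypes import FeatureMatrix, GenotypeMatrix, SampleSheet, ValidationError

P_FLOOR = 1e-300  # avoid zero p-values propagating into downstream log-scales


def transform_features(fm: FeatureMatrix) -> pd.DataFrame:
    """Feature matrix on the unbounded scale used by QTL scans and MR.

    expression -> log2 counts-per-million (pseudocount 0.5); methylation ->
    logit proportion with 0.5-count smoothing; metabolite -> natural log
    abundance.
    """
    if fm.layer == "expression":
        mat = fm.values.to_numpy(dtype=float)
        lib = mat.sum(axis=0)
        return pd.DataFrame(np.log2((mat + 0.5) / (lib + 1.0) * 1e6),
                            index=fm.values.index, columns=fm.values.columns)
    if fm.layer == "methylation":
        cov = fm.coverage.to_numpy(dtype=float)
        mc = fm.methylated.to_numpy(dtype=float)
        prop = (mc + 0.5) / (cov + 1.0)
        return pd.DataFrame(logit(prop), index=fm.coverage.index,
                            columns=fm.coverage.columns)
    if fm.layer == "metabolite":
        return pd.DataFrame(np.log(fm.values.to_numpy(dtype=float)),
                            index=fm.values.index, columns=fm.values.columns)
    raise ValidationError(f"unknown layer {fm.layer!r}")


def _residualize(mat: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``mat`` on [intercept, covariates]."""
    n = mat.shape[0]
    Q = np.column_stack([np.ones(n), covs])
    coef, *_ = np.linalg.lstsq(Q, mat, rcond=None)
    return mat - Q @ coef


def qtl_scan(
    genotypes: GenotypeMatrix,
    features: pd.DataFrame,
    covariates: SampleSheet | np.ndarray | None = None,
    layer: str = "",
    covariate_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Associate every variant with every feature under an additive model.

    ``features`` is a transformed feature matrix (features x samples) aligned
    to the genotype sample axis.  ``covariates`` may be a SampleSheet (columns
    chosen by ``covariate_cols``, default its covariate list) or a raw array.
    Monomorphic variants yield records with p = NaN and a flag.

    Returns one record per (variant, feature): beta (per alt allele), se,
    t, p (two-sided, df = n - 2 - n_covariates), n, flag.
    """
    if list(features.columns) != genotypes.samples:
        raise ValidationError("feature sample axis differs from genotypes")
    if isinstance(covariates, SampleSheet):
        cols = covariate_cols if covariate_cols is not None else covariates.covariates
        covs = covariates.table[list(cols)].to_numpy(dtype=float)
    elif covariates is None:
        covs = np.empty((len(genotypes.samples), 0))
    else:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
    n = len(genotypes.samples)
    n_cov = covs.shape[1]
    df = n - 2 - n_cov
    if df <= 0:
        raise ValidationError("not enough samples for the covariate model")

    G = _residualize(genotypes.dosages.astype(float), covs)       # n x m
    F = _residualize(features.to_numpy(dtype=float).T, covs)      # n x k
    gss = (G ** 2).sum(axis=0)                                    # m
    mono = gss <= 1e-12
    gss_safe = np.where(mono, 1.0, gss)
    xty = G.T @ F                                                 # m x k
    beta = xty / gss_safe[:, None]
    fss = (F ** 2).sum(axis=0)                                    # k
    rss = np.maximum(fss[None, :] - beta * xty, 0.0)
    sigma_sq = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma_sq / gss_safe[:, None])
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = sigma_sq <= 1e-28
    p = np.maximum(p, P_FLOOR)

    m, k = beta.shape
    variant_ids = np.repeat(genotypes.variants["id"].to_numpy(), k)
    feature_ids = np.tile(features.index.to_numpy(), m)
    flag = np.where(np.repeat(mono, k), "monomorphic",
                    np.where(degenerate.ravel(), "degenerate fit", ""))
    records = pd.DataFrame({
        "variant": variant_ids,
        "feature": feature_ids,
        "layer": layer,
        "beta": beta.ravel(),
        "se": se.ravel(),
        "t": t.ravel(),
        "p": np.where(np.repeat(mono, k), np.nan, p.ravel()),
        "n": n,
        "flag": flag,
    })
    records.loc[records["flag"] == "monomorphic", ["beta", "se", "t"]] = np.nan
    return records


def select_qtls(records: pd.DataFrame, p_max: float = 1e-5) -> pd.DataFrame:
    """Significant QTLs: strict p < ``p_max`` (NaN p never selected)."""
    if records.empty:
        return records
    return records[records["p"].notna() & (records["p"] < p_max)]
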