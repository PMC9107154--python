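"""Parameter-recovery and calibration experiments on synthetic data.

These functions drive the generator through the analysis chain and compare
results against the planted truth; the test suite and the acceptance script
both call them.  Every experiment derives per-replicate seeds from one base
seed, so results are reproducible and instrument order plays no role.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import qtl as qtlmod
from .datatypes import QtlEffect, SyntheticTruth
from .mr import IVSet, mr_ivw, mr_presso, mr_weighted_median
from .network import MRConfig, QtlStore, bidirectional_mr, mediation_test
from .simulate import VariantSpec, chain_truth, gen_genotypes, gen_omics_from_truth

QTL_COVARIATES = ("group", "exercise")


def _scan_all_layers(genotypes, expr, meth, metab, sheet) -> QtlStore:
    covs = sheet.table[list(QTL_COVARIATES)].to_numpy(dtype=float)
    recs = {}
    for layer, fm in (("expression", expr), ("methylation", meth), ("metabolite", metab)):
        feats = qtlmod.transform_features(fm)
        recs[layer] = qtlmod.qtl_scan(genotypes, feats, covs, layer=layer)
    return QtlStore(recs)


def chain_recovery(n_reps: int = 100, base_seed: int = 0,
                   n_boot: int = 400, n_sim: int = 400) -> pd.DataFrame:
    """Run the full MR chain on the planted X -> M -> Y fixture.

    Per replicate: simulate, scan QTLs on all layers, call the X-Y direction
    by bi-directional MR, and run the mediation decomposition.  Returns one
    row per replicate with the direction call, the mediation declaration and
    the indirect-effect estimate; the planted indirect effect is b1*b2.
    """
    rows = []
    for i in range(n_reps):
        seed = base_seed + i
        genotypes, truth = chain_truth(seed)
        expr, meth, metab, sheet, _ = gen_omics_from_truth(genotypes, truth)
        store = _scan_all_layers(genotypes, expr, meth, metab, sheet)
        x = ("metabolite", "met001")
        m = ("expression", "g001")
        y = ("methylation", truth.meth_sites["site_id"].iloc[0])
        cfg = MRConfig(seed=seed, n_boot=n_boot, n_sim=n_sim)
        dec = bidirectional_mr((x, y), store, genotypes, cfg)
        res = mediation_test(x, m, y, store, genotypes, cfg)
        rows.append({
            "seed": seed, "direction": dec.direction,
            "tier_forward": dec.tier_forward, "tier_reverse": dec.tier_reverse,
            "mediated": bool(res.mediated),
            "indirect": res.indirect if res.testable else np.nan,
            "total": res.total if res.testable else np.nan,
        })
    return pd.DataFrame(rows)


def qtl_coverage(n_reps: int = 200, base_seed: int = 0, beta: float = 0.5,
                 n_samples: int = 104) -> float:
    """Empirical 95%-CI coverage of a planted metabolite QTL effect.

    One variant, one log-normal metabolite; the scan's t-based confidence
    interval should cover the planted per-allele effect in about 95% of
    replicates.
    """
    hits = 0
    for i in range(n_reps):
        seed = base_seed + i
        spec = VariantSpec(chrom_variants={"1": 3}, af_range=(0.3, 0.5))
        genotypes = gen_genotypes(n_samples, spec, seed)
        sites = pd.DataFrame({"site_id": ["1.1000"], "chrom": "1", "pos": [1000],
                              "strand": "+"})
        truth = SyntheticTruth(expr_features=["g001"], meth_sites=sites,
                               metab_features=["met001"], seed=seed + 1)
        truth.qtl_effects.append(QtlEffect("rs00001", "metabolite", "met001", beta))
        expr, meth, metab, sheet, _ = gen_omics_from_truth(genotypes, truth)
        covs = sheet.table[list(QTL_COVARIATES)].to_numpy(dtype=float)
        rec = qtlmod.qtl_scan(genotypes, qtlmod.transform_features(metab), covs,
                              layer="metabolite")
        row = rec[(rec["variant"] == "rs00001") & (rec["feature"] == "met001")].iloc[0]
        df = row["n"] - 2 - len(QTL_COVARIATES)
        half = stats.t.ppf(0.975, df) * row["se"]
        hits += row["beta"] - half <= beta <= row["beta"] + half
    return hits / n_reps


def _null_ivset(rng: np.random.Generator, k: int = 10,
                causal_beta: float = 0.0) -> IVSet:
    """Summary-statistic instrument set with valid instruments and a known
    causal effect (0 under the null)."""
    beta_exp = rng.uniform(0.3, 0.8, k) * rng.choice((-1.0, 1.0), k)
    se_exp = rng.uniform(0.03, 0.08, k)
    se_out = rng.uniform(0.05, 0.15, k)
    beta_out = causal_beta * beta_exp + rng.normal(0.0, se_out)
    table = pd.DataFrame({
        "variant": [f"v{j:03d}" for j in range(k)],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "proxy": False, "proxy_r2": np.nan,
        "theta": beta_out / beta_exp, "se_theta": se_out / np.abs(beta_exp),
        "weight": (np.abs(beta_exp) / se_out) ** 2,
    })
    return IVSet(exposure="x", outcome="y", table=table)


def ivw_null_rejection(n_reps: int = 1000, base_seed: int = 0,
                       alpha: float = 0.05) -> float:
    """Two-sided IVW rejection rate under the no-effect null (valid IVs)."""
    rng = np.random.default_rng(base_seed)
    rejections = 0
    for _ in range(n_reps):
        fit = mr_ivw(_null_ivset(rng))
        rejections += fit.p < alpha
    return rejections / n_reps


def weighted_median_robustness(n_reps: int = 100, base_seed: int = 0,
                               causal_beta: float = 0.5,
                               invalid_frac: float = 0.4,
                               pleiotropy: float = 0.4) -> tuple[float, float]:
    """2-se coverage of the true effect for the weighted median and for IVW
    when a minority of instruments carries balanced pleiotropy.

    Returns (weighted-median rate, IVW rate).  The weighted median remains
    nearly unbiased (its breakdown point is 50% of weight); IVW averages over
    the contaminated ratios and its coverage collapses.
    """
    rng = np.random.default_rng(base_seed)
    ok_wm = ok_ivw = 0
    for _ in range(n_reps):
        ivs = _null_ivset(rng, k=10, causal_beta=causal_beta)
        t = ivs.table
        k_bad = int(round(invalid_frac * len(t)))
        bad = rng.choice(len(t), size=k_bad, replace=False)
        offsets = pleiotropy * np.where(np.arange(k_bad) % 2 == 0, 1.0, -1.0)
        t.loc[t.index[bad], "beta_out"] += offsets
        t["theta"] = t["beta_out"] / t["beta_exp"]
        seed = int(rng.integers(2**31))
        wm = mr_weighted_median(IVSet("x", "y", t), n_boot=400, seed=seed)
        ivw = mr_ivw(IVSet("x", "y", t))
        ok_wm += abs(wm.estimate - causal_beta) <= 2.0 * wm.se
        ok_ivw += abs(ivw.estimate - causal_beta) <= 2.0 * ivw.se
    return ok_wm / n_reps, ok_ivw / n_reps


def presso_outlier_detection(n_reps: int = 100, base_seed: int = 0,
                             displacement_se: float = 10.0) -> float:
    """Fraction of replicates where the residual-sum outlier test flags one
    instrument displaced by ``displacement_se`` ratio-se units among nine
    consistent ones."""
    rng = np.random.default_rng(base_seed)
    flagged = 0
    for _ in range(n_reps):
        ivs = _null_ivset(rng, k=10, causal_beta=0.5)
        t = ivs.table
        j = int(rng.integers(len(t)))
        t.loc[t.index[j], "beta_out"] += displacement_se * t["se_out"].iloc[j]
        t["theta"] = t["beta_out"] / t["beta_exp"]
        outlier_variant = t["variant"].iloc[j]
        fit = mr_presso(IVSet("x", "y", t), n_sim=500,
                        seed=int(rng.integers(2**31)))
        flagged += outlier_variant in fit.extras.get("outliers", [])
    return flagged / n_reps


def null_scan_pvalues(n_variants: int = 200, n_features: int = 50,
                      n_samples: int = 104, seed: int = 0) -> np.ndarray:
    """P-values of a QTL scan with zero planted effects (should be uniform)."""
    spec = VariantSpec(chrom_variants={"1": n_variants}, af_range=(0.1, 0.5))
    genotypes = gen_genotypes(n_samples, spec, seed)
    sites = pd.DataFrame({"site_id": ["1.1000"], "chrom": "1", "pos": [1000],
                          "strand": "+"})
    truth = SyntheticTruth(
        expr_features=["g001"], meth_sites=sites,
        metab_features=[f"met{i + 1:04d}" for i in range(n_features)],
        seed=seed + 1)
    _, _, metab, sheet, _ = gen_omics_from_truth(genotypes, truth)
    covs = sheet.table[list(QTL_COVARIATES)].to_numpy(dtype=float)
    rec = qtlmod.qtl_scan(genotypes, qtlmod.transform_features(metab), covs,
                          layer="metabolite")
    return rec["p"].dropna().to_numpy()
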