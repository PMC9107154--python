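"""Summary-statistic Mendelian randomization estimators and instrument handling.

Implements instrument-set construction (selection at a QTL p threshold, LD
proxy substitution at r^2 > 0.8, optional LD pruning, Wald-ratio and weight
computation) and five estimators: fixed-effect inverse-variance weighting,
simple and weighted median with parametric-bootstrap standard errors,
MR-Egger regression with its directional-pleiotropy intercept test, and an
MR-PRESSO-style residual-sum-of-squares global/outlier test with outlier-
corrected re-estimation.

All estimators operate on per-instrument summary statistics (beta, se) for
the exposure and the outcome; seeds are applied after sorting instruments by
variant id, so every result is invariant to instrument row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ValidationError

Z95 = 1.959964  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Instrument sets


@dataclass
class IVSet:
    """Harmonized instrument table for one exposure -> outcome MR test.

    ``table`` columns: variant, beta_exp, se_exp, beta_out, se_out, proxy,
    proxy_r2, theta (per-instrument Wald ratio), se_theta (first-order),
    weight (se_theta^-2).  An empty table marks the pair untestable.
    """

    exposure: str
    outcome: str
    table: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.table):
            if self.table["variant"].duplicated().any():
                raise ValidationError("duplicate instrument variants")
            if (self.table["beta_exp"].abs() <= 0).any():
                raise ValidationError("zero exposure effect among instruments")
            self.table = self.table.sort_values("variant").reset_index(drop=True)

    @property
    def n_instruments(self) -> int:
        return len(self.table)

    @property
    def testable(self) -> bool:
        return self.n_instruments > 0


@dataclass
class MRFit:
    """One causal estimate: method tag, estimate, se, 95% CI, p, extras."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    extras: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @classmethod
    def untestable(cls, method: str, reason: str) -> "MRFit":
        return cls(method, np.nan, np.nan, np.nan, np.nan, np.nan,
                   flags=["untestable: " + reason])

    @property
    def testable(self) -> bool:
        return np.isfinite(self.p)


def ci_and_p(estimate: float, se: float) -> tuple[tuple[float, float], float]:
    """Normal-theory 95% CI (estimate +/- 1.959964 se) and two-sided p."""
    if not se > 0:
        raise ValidationError(f"standard error must be positive, got {se}")
    ci = (estimate - Z95 * se, estimate + Z95 * se)
    p = 2.0 * stats.norm.sf(abs(estimate) / se)
    return ci, max(p, np.finfo(float).tiny)


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               second_order: bool = False) -> tuple[float, float]:
    """Per-instrument causal ratio theta = beta_out/beta_exp and its se.

    First-order se is se_out/|beta_exp| (default); the second-order option
    adds the exposure-uncertainty delta-method term.
    """
    if abs(beta_exp) <= 0:
        raise ValidationError("beta_exposure must be non-zero")
    theta = beta_out / beta_exp
    if second_order:
        se = np.sqrt(se_out ** 2 / beta_exp ** 2
                     + beta_out ** 2 * se_exp ** 2 / beta_exp ** 4)
    else:
        se = se_out / abs(beta_exp)
    return float(theta), float(se)


def ld_r2(genotypes: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation between two dosage columns."""
    a, b = genotypes.column(v1), genotypes.column(v2)
    if a.std() == 0 or b.std() == 0:
        raise ValidationError(f"monomorphic variant among ({v1}, {v2}): r^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def build_iv_set(
    exposure_qtls: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    proxy_r2_min: float = 0.8,
    prune_r2_max: float | None = 0.1,
    beta_floor: float = 1e-8,
    second_order: bool = False,
    exposure: str = "",
    outcome: str = "",
) -> IVSet:
    """Assemble a harmonized instrument set for one exposure -> outcome test.

    ``exposure_qtls`` are pre-selected instruments (variant, beta, se, p);
    ``outcome_stats`` are summary statistics for the outcome feature keyed by
    variant.  Instruments missing from the outcome statistics are replaced by
    the highest-r^2 proxy with r^2 strictly above ``proxy_r2_min`` (effect
    sign aligned by the dosage-correlation sign).  Greedy LD pruning keeps
    the smallest-p instrument of each correlated clump (r^2 >
    ``prune_r2_max``); pass None to disable.
    """
    notes: list[str] = []
    out_by_variant = outcome_stats.set_index("variant") if "variant" in outcome_stats else outcome_stats
    qtls = exposure_qtls.sort_values("p", kind="mergesort")

    if prune_r2_max is not None and genotypes is not None and len(qtls) > 1:
        kept: list[str] = []
        for v in qtls["variant"]:
            clumped = False
            for k in kept:
                try:
                    if ld_r2(genotypes, v, k) > prune_r2_max:
                        clumped = True
                        break
                except ValidationError:
                    continue
            if not clumped:
                kept.append(v)
        dropped = len(qtls) - len(kept)
        if dropped:
            notes.append(f"pruned {dropped} instruments at r^2 > {prune_r2_max}")
        qtls = qtls[qtls["variant"].isin(kept)]

    rows = []
    available = set(out_by_variant.index)
    for _, q in qtls.iterrows():
        variant = q["variant"]
        proxy_used, proxy_r2, sign = False, np.nan, 1.0
        if variant in available:
            o = out_by_variant.loc[variant]
        else:
            if genotypes is None:
                notes.append(f"{variant}: absent from outcome stats, no genotypes for proxy search")
                continue
            best, best_r2, best_sign = None, 0.0, 1.0
            target = genotypes.column(variant)
            if target.std() == 0:
                notes.append(f"{variant}: monomorphic, skipped")
                continue
            for cand in available:
                try:
                    col = genotypes.column(cand)
                except KeyError:
                    continue
                if col.std() == 0:
                    continue
                r = float(np.corrcoef(target, col)[0, 1])
                if r * r > best_r2:
                    best, best_r2, best_sign = cand, r * r, np.sign(r) or 1.0
            if best is None or not best_r2 > proxy_r2_min:
                notes.append(f"{variant}: no proxy above r^2 {proxy_r2_min}")
                continue
            o = out_by_variant.loc[best]
            proxy_used, proxy_r2, sign = True, best_r2, best_sign
        beta_exp = float(q["beta"])
        if abs(beta_exp) < beta_floor:
            notes.append(f"{variant}: |beta_exposure| below positivity floor, dropped")
            continue
        beta_out = sign * float(o["beta"])
        se_out = float(o["se"])
        if not np.isfinite(beta_out) or not np.isfinite(se_out) or se_out <= 0:
            notes.append(f"{variant}: unusable outcome statistics, dropped")
            continue
        theta, se_theta = wald_ratio(beta_exp, float(q["se"]), beta_out, se_out,
                                     second_order=second_order)
        rows.append({
            "variant": variant, "beta_exp": beta_exp, "se_exp": float(q["se"]),
            "beta_out": beta_out, "se_out": se_out,
            "proxy": proxy_used, "proxy_r2": proxy_r2,
            "theta": theta, "se_theta": se_theta, "weight": se_theta ** -2,
        })
    cols = ["variant", "beta_exp", "se_exp", "beta_out", "se_out", "proxy",
            "proxy_r2", "theta", "se_theta", "weight"]
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        notes.append("untestable pair: zero usable instruments")
    return IVSet(exposure=exposure, outcome=outcome, table=table, notes=notes)


# ---------------------------------------------------------------------------
# Estimators


def mr_ivw(ivs: IVSet, random_effects: bool = False) -> MRFit:
    """Fixed-effect inverse-variance weighted estimate.

    Equivalent to weighted least squares of beta_out on beta_exp through the
    origin with weights se_out^-2.  The multiplicative random-effects option
    scales the se by max(1, sqrt(Q / (k - 1))).
    """
    if not ivs.testable:
        return MRFit.untestable("IVW", "no instruments")
    t = ivs.table
    w = t["weight"].to_numpy()
    theta = t["theta"].to_numpy()
    est = float((w * theta).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    flags = []
    if random_effects and len(t) > 1:
        q = float((w * (theta - est) ** 2).sum())
        phi = max(1.0, np.sqrt(q / (len(t) - 1)))
        se *= phi
        flags.append(f"random-effects scale {phi:.3f}")
    (lo, hi), p = ci_and_p(est, se)
    return MRFit("IVW", est, se, lo, hi, p, flags=flags)


def _sorted_theta_weights(ivs: IVSet) -> tuple[np.ndarray, np.ndarray]:
    t = ivs.table
    order = np.argsort(t["theta"].to_numpy(), kind="stable")
    return t["theta"].to_numpy()[order], t["weight"].to_numpy()[order]


def weighted_median_estimate(theta: np.ndarray, weight: np.ndarray) -> float:
    """Weighted 50th percentile of ratios via cumulative-midpoint interpolation.

    With normalized weights w'_j and running sums S_j, the midpoints are
    p_j = S_j - w'_j/2; the estimate linearly interpolates theta at p = 1/2.
    Equal weights reduce this to the interpolated simple median.
    """
    order = np.argsort(theta, kind="stable")
    th, w = theta[order], weight[order]
    wn = w / w.sum()
    mid = np.cumsum(wn) - 0.5 * wn
    return float(np.interp(0.5, mid, th))


def _bootstrap_median_se(ivs: IVSet, estimator, n_boot: int, seed: int) -> float:
    t = ivs.table  # already sorted by variant id
    theta = t["theta"].to_numpy()
    se = t["se_theta"].to_numpy()
    w = t["weight"].to_numpy()
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta[None, :], se[None, :], size=(n_boot, theta.size))
    ests = np.array([estimator(d, w) for d in draws])
    return float(ests.std(ddof=1))


def mr_simple_median(ivs: IVSet, n_boot: int = 1000, seed: int = 0) -> MRFit:
    """Unweighted (interpolated) median of Wald ratios; bootstrap se."""
    if ivs.n_instruments < 3:
        return MRFit.untestable("simple-median", "needs >= 3 instruments")
    est = float(np.median(ivs.table["theta"].to_numpy()))
    se = _bootstrap_median_se(ivs, lambda d, w: float(np.median(d)), n_boot, seed)
    (lo, hi), p = ci_and_p(est, se)
    return MRFit("simple-median", est, se, lo, hi, p)


def mr_weighted_median(ivs: IVSet, n_boot: int = 1000, seed: int = 0) -> MRFit:
    """Weighted median of Wald ratios (consistent when >= 50% of weight is on
    valid instruments); bootstrap se."""
    if ivs.n_instruments < 3:
        return MRFit.untestable("weighted-median", "needs >= 3 instruments")
    t = ivs.table
    est = weighted_median_estimate(t["theta"].to_numpy(), t["weight"].to_numpy())
    se = _bootstrap_median_se(ivs, weighted_median_estimate, n_boot, seed)
    (lo, hi), p = ci_and_p(est, se)
    return MRFit("weighted-median", est, se, lo, hi, p)


def mr_egger(ivs: IVSet) -> MRFit:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Rows are oriented so every beta_exp is positive; weights are se_out^-2.
    The slope is the causal estimate; the intercept with its se and p is the
    directional-pleiotropy test.
    """
    if ivs.n_instruments < 3:
        if ivs.n_instruments == 2:
            fit = _egger_wls(ivs)
            fit.flags.append("saturated: exact 2-instrument fit")
            return fit
        return MRFit.untestable("Egger", "needs >= 2 instruments")
    return _egger_wls(ivs)


def _egger_wls(ivs: IVSet) -> MRFit:
    t = ivs.table
    sign = np.sign(t["beta_exp"].to_numpy())
    x = sign * t["beta_exp"].to_numpy()
    y = sign * t["beta_out"].to_numpy()
    w = t["se_out"].to_numpy() ** -2.0
    if np.ptp(x) <= 0:
        return MRFit.untestable("Egger", "zero spread in exposure effects")
    X = np.column_stack([np.ones_like(x), x])
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * y))
    cov = np.linalg.inv(XtWX)
    alpha, beta = float(coef[0]), float(coef[1])
    se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    (lo, hi), p = ci_and_p(beta, se_b)
    _, p_int = ci_and_p(alpha, se_a) if se_a > 0 else ((np.nan, np.nan), np.nan)
    return MRFit("Egger", beta, se_b, lo, hi, p,
                 extras={"intercept": alpha, "intercept_se": se_a,
                         "intercept_p": p_int})


def _loo_ivw_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out origin-constrained WLS slopes, vectorized."""
    sxy = (w * x * y).sum()
    sxx = (w * x * x).sum()
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(ivs: IVSet, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> MRFit:
    """Pleiotropy residual-sum-and-outlier test with corrected re-estimate.

    The observed global statistic is RSS = sum_j (beta_out_j - bhat_(-j) *
    beta_exp_j)^2 with bhat_(-j) the leave-one-out IVW slope; its null
    distribution comes from parametric simulations drawing beta*_exp_j ~
    N(beta_exp_j, se_exp_j) and beta*_out_j ~ N(bhat_(-j) beta_exp_j,
    se_out_j).  Per-instrument terms are compared against their simulated
    distributions with Bonferroni correction; the corrected estimate is IVW
    after removing flagged outliers.
    """
    if ivs.n_instruments < 4:
        return MRFit.untestable("PRESSO-corrected", "needs >= 4 instruments")
    t = ivs.table  # sorted by variant id: draws are order-invariant
    x = t["beta_exp"].to_numpy()
    y = t["beta_out"].to_numpy()
    se_x = t["se_exp"].to_numpy()
    se_y = t["se_out"].to_numpy()
    w = se_y ** -2.0
    k = x.size

    loo = _loo_ivw_slopes(x, y, w)
    obs_terms = (y - loo * x) ** 2
    obs_rss = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    xs = rng.normal(x[None, :], se_x[None, :], size=(n_sim, k))
    ys = rng.normal(loo[None, :] * x[None, :], se_y[None, :], size=(n_sim, k))
    sxy = (w * xs * ys).sum(axis=1, keepdims=True)
    sxx = (w * xs * xs).sum(axis=1, keepdims=True)
    loo_sim = (sxy - w * xs * ys) / (sxx - w * xs * xs)
    sim_terms = (ys - loo_sim * xs) ** 2
    sim_rss = sim_terms.sum(axis=1)
    global_p = float((sim_rss >= obs_rss).mean())
    global_p = max(global_p, 1.0 / (n_sim + 1))

    outlier_p = (sim_terms >= obs_terms[None, :]).mean(axis=0)
    outliers = np.flatnonzero(outlier_p < outlier_alpha / k)
    outlier_ids = [t["variant"].iloc[i] for i in outliers]

    keep = np.setdiff1d(np.arange(k), outliers)
    extras = {"global_p": global_p, "outliers": outlier_ids,
              "n_outliers": len(outlier_ids)}
    if keep.size == 0:
        fit = MRFit.untestable("PRESSO-corrected", "all instruments flagged as outliers")
        fit.extras = extras
        return fit
    sub = IVSet(ivs.exposure, ivs.outcome, t.iloc[keep].reset_index(drop=True))
    base = mr_ivw(sub)
    return MRFit("PRESSO-corrected", base.estimate, base.se, base.ci_low,
                 base.ci_high, base.p, extras=extras)


def run_all_estimators(ivs: IVSet, n_boot: int = 1000, n_sim: int = 1000,
                       seed: int = 0) -> dict[str, MRFit]:
    """All five estimators on one instrument set (untestable fits included)."""
    if not ivs.testable:
        return {m: MRFit.untestable(m, "no instruments")
                for m in ("IVW", "simple-median", "weighted-median", "Egger",
                          "PRESSO-corrected")}
    return {
        "IVW": mr_ivw(ivs),
        "simple-median": mr_simple_median(ivs, n_boot=n_boot, seed=seed),
        "weighted-median": mr_weighted_median(ivs, n_boot=n_boot, seed=seed),
        "Egger": mr_egger(ivs),
        "PRESSO-corrected": mr_presso(ivs, n_sim=n_sim, seed=seed),
    }


def fits_to_frame(exposure: str, outcome: str, fits: dict[str, MRFit],
                  n_ivs: int, n_proxies: int) -> pd.DataFrame:
    """Serialize per-method fits to one tidy row per (exposure, outcome, method)."""
    rows = []
    for method, fit in fits.items():
        rows.append({
            "exposure": exposure, "outcome": outcome, "method": method,
            "estimate": fit.estimate, "se": fit.se,
            "ci_low": fit.ci_low, "ci_high": fit.ci_high, "p": fit.p,
            "egger_intercept_p": fit.extras.get("intercept_p", np.nan),
            "presso_global_p": fit.extras.get("global_p", np.nan),
            "n_ivs": n_ivs, "n_proxies": n_proxies,
            "flags": ";".join(fit.flags),
        })
    return pd.DataFrame(rows)
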