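"""Bi-directional MR over cross-omics biomarker pairs and network-MR mediation.

The pair grid is every cross-layer biomarker pair, each tested in both
directions.  A direction is *significant* when at least two counted MR
methods reach p < 0.01 and *suggestive* when at least two reach p < 0.05;
direction calls combine the two directional tiers.  Mediation of an
X -> M -> Y triple decomposes the total IVW effect of X on Y into the
indirect path-product effect beta1 * beta2 (delta-method se) and the direct
remainder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ValidationError
from .mr import IVSet, MRFit, build_iv_set, mr_ivw, run_all_estimators

COUNTED_METHODS = ("IVW", "simple-median", "weighted-median", "Egger")


@dataclass
class MRConfig:
    """Thresholds and options threaded through pair-level MR."""

    qtl_p_max: float = 1e-5
    proxy_r2_min: float = 0.8
    prune_r2_max: float | None = 0.1
    n_boot: int = 1000
    n_sim: int = 1000
    seed: int = 0
    counted_methods: tuple[str, ...] = COUNTED_METHODS
    sig_p: float = 0.01
    sug_p: float = 0.05
    mediation_test: str = "indirect_onesided"  # | sobel | difference


class QtlStore:
    """Per-layer QTL summary statistics with instrument/outcome lookups."""

    def __init__(self, records_by_layer: dict[str, pd.DataFrame]):
        self._records = records_by_layer

    def instruments(self, layer: str, feature: str, p_max: float) -> pd.DataFrame:
        rec = self._records[layer]
        sub = rec[(rec["feature"] == feature) & rec["p"].notna() & (rec["p"] < p_max)]
        return sub

    def outcome_stats(self, layer: str, feature: str) -> pd.DataFrame:
        rec = self._records[layer]
        return rec[(rec["feature"] == feature) & rec["beta"].notna()]


@dataclass
class PairDecision:
    """Outcome of bi-directional MR on one cross-layer pair."""

    exposure: str            # forward-direction exposure (layer:feature)
    outcome: str
    p_forward: dict[str, float]
    p_reverse: dict[str, float]
    tier_forward: str        # significant | suggestive | null | untestable
    tier_reverse: str
    direction: str           # forward | reverse | bidirectional | none
    fits_forward: dict[str, MRFit] = field(default_factory=dict)
    fits_reverse: dict[str, MRFit] = field(default_factory=dict)
    n_ivs_forward: int = 0
    n_ivs_reverse: int = 0
    n_proxies_forward: int = 0
    n_proxies_reverse: int = 0


def enumerate_pairs(set_a: list, set_b: list) -> list[tuple]:
    """All |A| x |B| cross-layer pairs (each later tested in both directions)."""
    if not set_a or not set_b:
        warnings.warn("empty biomarker set: no pairs to test")
        return []
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise ValidationError(f"biomarker id spaces overlap across layers: {sorted(overlap)}")
    return [(a, b) for a in set_a for b in set_b]


def assign_tier(pvalues: dict[str, float], counted: tuple[str, ...] = COUNTED_METHODS,
                sig_p: float = 0.01, sug_p: float = 0.05) -> str:
    """Tier by the counting rule: >=2 counted methods p < 0.01 -> significant;
    else >=2 with p < 0.05 -> suggestive; no finite p -> untestable."""
    ps = [pvalues[m] for m in counted if m in pvalues and np.isfinite(pvalues[m])]
    if not ps:
        return "untestable"
    if sum(p < sig_p for p in ps) >= 2:
        return "significant"
    if sum(p < sug_p for p in ps) >= 2:
        return "suggestive"
    return "null"


def classify_direction(tier_forward: str, tier_reverse: str) -> str:
    """forward / reverse if only that direction reaches at least suggestive;
    bidirectional if both do; none otherwise (untestable counts as null)."""
    fwd = tier_forward in ("significant", "suggestive")
    rev = tier_reverse in ("significant", "suggestive")
    if fwd and rev:
        return "bidirectional"
    if fwd:
        return "forward"
    if rev:
        return "reverse"
    return "none"


def _one_direction(exposure: tuple[str, str], outcome: tuple[str, str],
                   store: QtlStore, genotypes: GenotypeMatrix,
                   config: MRConfig) -> tuple[dict[str, MRFit], IVSet]:
    exp_layer, exp_feat = exposure
    out_layer, out_feat = outcome
    inst = store.instruments(exp_layer, exp_feat, config.qtl_p_max)
    outs = store.outcome_stats(out_layer, out_feat)
    ivs = build_iv_set(
        inst, outs, genotypes,
        proxy_r2_min=config.proxy_r2_min, prune_r2_max=config.prune_r2_max,
        exposure=f"{exp_layer}:{exp_feat}", outcome=f"{out_layer}:{out_feat}",
    )
    fits = run_all_estimators(ivs, n_boot=config.n_boot, n_sim=config.n_sim,
                              seed=config.seed)
    return fits, ivs


def bidirectional_mr(pair: tuple[tuple[str, str], tuple[str, str]],
                     qtl_store: QtlStore, genotypes: GenotypeMatrix,
                     config: MRConfig | None = None) -> PairDecision:
    """Run all applicable estimators in both directions and call the direction."""
    config = config or MRConfig()
    a, b = pair
    fits_fwd, ivs_fwd = _one_direction(a, b, qtl_store, genotypes, config)
    fits_rev, ivs_rev = _one_direction(b, a, qtl_store, genotypes, config)

    def _countable(fits):
        # a saturated (2-instrument) Egger fit has zero residual df; its p
        # carries no evidence and must not enter the method-counting rule
        return {m: (np.nan if any("saturated" in fl for fl in f.flags) else f.p)
                for m, f in fits.items()}

    p_fwd = _countable(fits_fwd)
    p_rev = _countable(fits_rev)
    tier_f = assign_tier(p_fwd, config.counted_methods, config.sig_p, config.sug_p)
    tier_r = assign_tier(p_rev, config.counted_methods, config.sig_p, config.sug_p)
    return PairDecision(
        exposure=f"{a[0]}:{a[1]}", outcome=f"{b[0]}:{b[1]}",
        p_forward=p_fwd, p_reverse=p_rev,
        tier_forward=tier_f, tier_reverse=tier_r,
        direction=classify_direction(tier_f, tier_r),
        fits_forward=fits_fwd, fits_reverse=fits_rev,
        n_ivs_forward=ivs_fwd.n_instruments, n_ivs_reverse=ivs_rev.n_instruments,
        n_proxies_forward=int(ivs_fwd.table["proxy"].sum()) if ivs_fwd.testable else 0,
        n_proxies_reverse=int(ivs_rev.table["proxy"].sum()) if ivs_rev.testable else 0,
    )


@dataclass
class MediationResult:
    """Total/indirect/direct decomposition of an X -> M -> Y triple.

    indirect = beta1 * beta2 with delta-method se
    sqrt(beta1^2 se2^2 + beta2^2 se1^2); direct = total - indirect exactly.
    """

    x: str
    m: str
    y: str
    total: float
    total_se: float
    beta1: float
    beta1_se: float
    beta2: float
    beta2_se: float
    indirect: float
    indirect_se: float
    direct: float
    p: float
    test: str
    testable: bool = True
    reason: str = ""

    @property
    def mediated(self) -> bool:
        return self.testable and self.p < 0.05


def mediation_p(indirect: float, indirect_se: float, total: float,
                total_se: float, test: str) -> float:
    """Mediation p-value under the selected test variant."""
    if test == "indirect_onesided":
        return float(stats.norm.sf(abs(indirect) / indirect_se))
    if test == "sobel":
        return float(2.0 * stats.norm.sf(abs(indirect) / indirect_se))
    if test == "difference":
        z = (total - indirect) / np.sqrt(total_se ** 2 + indirect_se ** 2)
        return float(2.0 * stats.norm.sf(abs(z)))
    raise ValidationError(f"unknown mediation test {test!r}")


def mediation_test(x: tuple[str, str], m: tuple[str, str], y: tuple[str, str],
                   qtl_store: QtlStore, genotypes: GenotypeMatrix,
                   config: MRConfig | None = None) -> MediationResult:
    """Network-MR mediation decomposition using IVW path estimates.

    Fits X -> Y (total), X -> M (beta1) and M -> Y (beta2); mediation is
    declared when the configured test (default: one-sided normal on
    indirect/se) gives p < 0.05.
    """
    config = config or MRConfig()
    labels = tuple(f"{l}:{f}" for l, f in (x, m, y))

    def _ivw(exposure, outcome):
        inst = qtl_store.instruments(exposure[0], exposure[1], config.qtl_p_max)
        outs = qtl_store.outcome_stats(outcome[0], outcome[1])
        ivs = build_iv_set(inst, outs, genotypes,
                           proxy_r2_min=config.proxy_r2_min,
                           prune_r2_max=config.prune_r2_max,
                           exposure=f"{exposure[0]}:{exposure[1]}",
                           outcome=f"{outcome[0]}:{outcome[1]}")
        return mr_ivw(ivs)

    tot, f1, f2 = _ivw(x, y), _ivw(x, m), _ivw(m, y)
    if not (tot.testable and f1.testable and f2.testable):
        bad = [lbl for lbl, f in zip(("X->Y", "X->M", "M->Y"), (tot, f1, f2))
               if not f.testable]
        return MediationResult(*labels, *(np.nan,) * 9, np.nan,
                               test=config.mediation_test, testable=False,
                               reason=f"untestable path(s): {', '.join(bad)}")
    indirect = f1.estimate * f2.estimate
    indirect_se = float(np.sqrt(f1.estimate ** 2 * f2.se ** 2
                                + f2.estimate ** 2 * f1.se ** 2))
    direct = tot.estimate - indirect
    p = mediation_p(indirect, indirect_se, tot.estimate, tot.se,
                    config.mediation_test)
    return MediationResult(
        *labels,
        total=tot.estimate, total_se=tot.se,
        beta1=f1.estimate, beta1_se=f1.se,
        beta2=f2.estimate, beta2_se=f2.se,
        indirect=indirect, indirect_se=indirect_se, direct=direct,
        p=p, test=config.mediation_test,
    )


def spearman_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho over biomarkers (columns); samples in rows.

    Symmetric with unit diagonal; constant columns give NaN off-diagonals.
    """
    if values.shape[0] < 3:
        raise ValidationError("Spearman matrix needs at least 3 samples")
    mat = values.to_numpy(dtype=float)
    const = mat.std(axis=0) == 0
    ranks = pd.DataFrame(mat).rank().to_numpy()  # midranks on ties
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks.T)
    rho = np.atleast_2d(rho)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=values.columns, columns=values.columns)


def correlation_heatmap(rho: pd.DataFrame, path: str) -> None:
    """Render the Spearman matrix as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.3 * len(rho) + 2,) * 2)
    im = ax.imshow(rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho)), rho.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rho)), rho.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
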