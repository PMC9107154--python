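"""Synthetic genotype + tri-omics generator with a known planted truth.

The generator emulates the statistical structure a trans-omics causal study
assumes: biallelic SNPs in Hardy-Weinberg equilibrium (optionally in LD
blocks), cis/trans QTL effects on features of each omic layer, directed
causal edges between features (e.g. a metabolite -> gene -> methylation
chain), a binary group contrast and a binary covariate.  Every planted
parameter is recorded in a :class:`~triomr.datatypes.SyntheticTruth` so that
downstream stages can be tested by parameter recovery.

Observation models per layer:

* expression: counts ~ Poisson(exp(latent)) per gene and sample;
* methylation: proportion = expit(latent), methylated ~ Binomial(coverage,
  proportion) with coverage ~ 1 + Poisson(coverage_mean - 1);
* metabolites: abundance = exp(latent).

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .datatypes import (
    CausalEdge,
    FeatureMatrix,
    GeneAnnotation,
    GenotypeMatrix,
    QtlEffect,
    SampleSheet,
    StudyBundle,
    SyntheticTruth,
    ValidationError,
    site_id,
)


@dataclass
class VariantSpec:
    """Per-chromosome variant counts plus allele-frequency and LD-block config.

    ``ld_block_size`` consecutive variants share an AR(1) latent Gaussian with
    lag correlation ``ld_rho``; blocks never span chromosomes and are mutually
    independent.  ``ld_block_size = 1`` gives fully independent variants.
    """

    chrom_variants: dict[str, int] = field(default_factory=lambda: {"1": 100})
    af_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0

    def total(self) -> int:
        return sum(self.chrom_variants.values())


def _haplotypes_for_block(rng: np.random.Generator, n: int, step_rho: np.ndarray,
                          thresholds: np.ndarray) -> np.ndarray:
    """Draw one haplotype per sample for a block via a shared AR(1) latent
    Gaussian thresholded at each variant's allele frequency; ``step_rho[j]``
    is the latent correlation between variants j-1 and j."""
    m = thresholds.size
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    for j in range(1, m):
        r = step_rho[j]
        z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return (z < thresholds[None, :]).astype(np.int8)


def _latent_rho_for_allele_corr(t1: float, t2: float, p1: float, p2: float,
                                target: float) -> float:
    """Latent Gaussian correlation giving thresholded-indicator (allele)
    correlation ``target``; thresholding attenuates correlation, so the
    latent value must exceed the target."""
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal

    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def phi(r: float) -> float:
        p11 = multivariate_normal(mean=[0.0, 0.0],
                                  cov=[[1.0, r], [r, 1.0]]).cdf([t1, t2])
        return (p11 - p1 * p2) / denom

    hi = 0.9999
    if phi(hi) <= target:
        return hi
    return float(brentq(lambda r: phi(r) - target, 0.0, hi, xtol=1e-6))


def gen_genotypes(n_samples: int, variant_spec: VariantSpec, seed: int) -> GenotypeMatrix:
    """Generate an additive dosage matrix under HWE with optional LD blocks.

    Dosages are sums of two independent haplotypes; within a block each
    haplotype is a thresholded AR(1) Gaussian, so adjacent-variant dosage
    correlation tracks ``ld_rho``.
    """
    if n_samples < 2:
        raise ValidationError(f"need at least 2 samples, got {n_samples}")
    lo, hi = variant_spec.af_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValidationError(f"allele-frequency range must lie in (0, 0.5], got {variant_spec.af_range}")
    rng = np.random.default_rng(seed)
    block = max(1, int(variant_spec.ld_block_size))
    rho = float(variant_spec.ld_rho) if block > 1 else 0.0

    cols: list[np.ndarray] = []
    rows: list[dict] = []
    counter = 0
    for chrom, m in variant_spec.chrom_variants.items():
        pos = np.cumsum(rng.integers(500, 5000, size=m))
        if block > 1:
            # tightly linked variants share an allele frequency: the
            # correlation of two binary alleles is bounded by how closely
            # their frequencies match, so high-LD blocks require equal afs
            n_blocks = int(np.ceil(m / block))
            afs = np.repeat(rng.uniform(lo, hi, size=n_blocks), block)[:m]
        else:
            afs = rng.uniform(lo, hi, size=m)
        for v in range(m):
            counter += 1
            rows.append({
                "id": f"rs{counter:05d}", "chrom": str(chrom), "pos": int(pos[v]),
                "ref": "A", "alt": "G", "af": float(afs[v]),
            })
        thresholds = ndtri(afs)
        start = 0
        dos = np.zeros((n_samples, m), dtype=np.int8)
        while start < m:
            stop = min(start + block, m)
            th = thresholds[start:stop]
            step = np.zeros(stop - start)
            for j in range(1, stop - start):
                step[j] = _latent_rho_for_allele_corr(
                    th[j - 1], th[j], afs[start + j - 1], afs[start + j], rho
                ) if rho > 0 else 0.0
            h1 = _haplotypes_for_block(rng, n_samples, step, th)
            h2 = _haplotypes_for_block(rng, n_samples, step, th)
            dos[:, start:stop] = h1 + h2
            start = stop
        cols.append(dos)
    variants = pd.DataFrame(rows)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    gm = GenotypeMatrix(samples=samples, dosages=np.concatenate(cols, axis=1), variants=variants)
    gm.validate()
    return gm


def _toposort_features(truth: SyntheticTruth) -> list[tuple[str, str]]:
    """All (layer, feature) nodes in a topological order of the causal edges."""
    g = nx.DiGraph()
    for layer in ("expression", "methylation", "metabolite"):
        for f in truth.features(layer):
            g.add_node((layer, f))
    for e in truth.causal_edges:
        for node in (e.source, e.target):
            if node not in g:
                raise ValidationError(f"causal edge references unknown feature {node}")
        g.add_edge(e.source, e.target)
    try:
        return list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible as exc:
        raise ValidationError("causal-edge graph contains a cycle") from exc


def gen_omics_from_truth(
    genotypes: GenotypeMatrix, truth: SyntheticTruth
) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix, SampleSheet, GeneAnnotation]:
    """Simulate the three omic layers plus sample sheet and TSS annotation.

    Each feature's latent value is the sum of its planted QTL dosage effects,
    upstream causal-edge contributions (evaluated in topological order on the
    latent scale), group and covariate effects, and Gaussian layer noise;
    the latent is then pushed through the layer's observation model.
    """
    rng = np.random.default_rng(truth.seed)
    n = len(genotypes.samples)
    order = _toposort_features(truth)

    known = set(genotypes.variant_ids)
    for q in truth.qtl_effects:
        if q.variant not in known:
            raise ValidationError(f"planted QTL references unknown variant {q.variant!r}")
        if q.feature not in truth.features(q.layer):
            raise ValidationError(f"planted QTL references unknown feature {q.layer}:{q.feature}")
    for key in truth.group_effects:
        if key[1] not in truth.features(key[0]):
            raise ValidationError(f"group effect on unknown feature {key}")

    # sample sheet: balanced groups, binary covariate with group-dependent prevalence
    group = np.zeros(n, dtype=int)
    group[n // 2:] = 1
    exercise = np.where(group == 0, rng.random(n) < 0.85, rng.random(n) < 0.67).astype(int)
    sheet = SampleSheet(
        table=pd.DataFrame({"group": group, "exercise": exercise},
                           index=pd.Index(genotypes.samples, name="sample")),
        covariates=("exercise",),
    )

    qtl_by_feat: dict[tuple[str, str], list[QtlEffect]] = {}
    for q in truth.qtl_effects:
        qtl_by_feat.setdefault((q.layer, q.feature), []).append(q)
    edges_by_target: dict[tuple[str, str], list[CausalEdge]] = {}
    for e in truth.causal_edges:
        edges_by_target.setdefault(e.target, []).append(e)

    base = {"expression": truth.expr_base, "methylation": truth.meth_base,
            "metabolite": truth.metab_base}
    grp = group.astype(float)
    cov = exercise.astype(float)

    # signals are base-free so causal edges propagate deviations, not baselines
    signal: dict[tuple[str, str], np.ndarray] = {}
    latent: dict[tuple[str, str], np.ndarray] = {}
    for node in order:
        layer, feat = node
        val = np.full(n, truth.base_offsets.get(node, 0.0))
        for q in qtl_by_feat.get(node, []):
            val = val + q.beta * genotypes.column(q.variant)
        for e in edges_by_target.get(node, []):
            val = val + e.beta * signal[e.source]
        val = val + truth.group_effects.get(node, 0.0) * grp
        for (cname, target), beta in truth.covariate_effects.items():
            if target == node and cname == "exercise":
                val = val + beta * cov
        val = val + rng.normal(0.0, truth.noise_sd[layer], size=n)
        signal[node] = val
        latent[node] = base[layer] + val

    expr_ids = truth.features("expression")
    expr_latent = np.array([latent[("expression", f)] for f in expr_ids])
    counts = rng.poisson(np.exp(expr_latent))
    expression = FeatureMatrix(
        layer="expression", samples=genotypes.samples,
        values=pd.DataFrame(counts, index=pd.Index(expr_ids, name="gene_id"),
                            columns=genotypes.samples),
        feature_meta=pd.DataFrame({"gene_id": expr_ids}, index=expr_ids),
    )

    sites = truth.meth_sites.reset_index(drop=True)
    meth_ids = list(sites["site_id"])
    meth_latent = np.array([latent[("methylation", s)] for s in meth_ids])
    prop = expit(meth_latent)
    coverage = 1 + rng.poisson(truth.coverage_mean - 1.0, size=(len(meth_ids), n))
    methylated = rng.binomial(coverage, prop)
    methylation = FeatureMatrix(
        layer="methylation", samples=genotypes.samples,
        coverage=pd.DataFrame(coverage, index=pd.Index(meth_ids, name="site_id"),
                              columns=genotypes.samples),
        methylated=pd.DataFrame(methylated, index=pd.Index(meth_ids, name="site_id"),
                                columns=genotypes.samples),
        feature_meta=sites.set_index(sites["site_id"]),
    )

    metab_ids = truth.features("metabolite")
    metab_latent = np.array([latent[("metabolite", f)] for f in metab_ids])
    metabolite = FeatureMatrix(
        layer="metabolite", samples=genotypes.samples,
        values=pd.DataFrame(np.exp(metab_latent),
                            index=pd.Index(metab_ids, name="metabolite"),
                            columns=genotypes.samples),
        feature_meta=pd.DataFrame({"metabolite": metab_ids}, index=metab_ids),
    )

    annotation = _tss_annotation(genotypes, expr_ids, rng)
    for fm in (expression, methylation, metabolite):
        fm.validate(sheet)
    return expression, methylation, metabolite, sheet, annotation


def _tss_annotation(genotypes: GenotypeMatrix, expr_ids: list[str],
                    rng: np.random.Generator) -> GeneAnnotation:
    """One TSS per expression feature, spread over the genotyped chromosomes."""
    chroms = list(dict.fromkeys(genotypes.variants["chrom"]))
    rows = []
    for i, gene in enumerate(expr_ids):
        chrom = chroms[i % len(chroms)]
        rows.append({
            "gene_id": gene, "chrom": chrom,
            "tss": int(1000 + i * 50_000 + rng.integers(0, 10_000)),
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    ann = GeneAnnotation(pd.DataFrame(rows))
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# Default study-scale scenario


@dataclass
class ScenarioConfig:
    """Knobs for the default study-scale scenario (two groups of 52, one
    binary covariate), including the planted metabolite -> gene -> methylation
    causal chain used by recovery tests.

    QTL betas are per alt allele at a reference dosage variance of 0.42 and
    are calibrated to each instrument's realized dosage variance, so every
    instrument carries a comparable partial R^2.
    """

    n_samples: int = 104
    n_genes: int = 60
    n_sites: int = 40
    n_metabolites: int = 30
    variants_per_chrom: int = 60
    n_chrom: int = 2
    ld_block_size: int = 4
    ld_rho: float = 0.8
    n_instruments: int = 3          # instruments planted per biomarker
    qtl_beta: float = 1.0           # per-alt-allele effect, latent scale
    meth_qtl_beta: float = 0.9      # meQTLs need more signal over binomial noise
    chain_gene_qtl_scale: float = 1.5   # mediator inherits upstream variance,
                                        # so its instruments must be stronger
    chain_site_qtl_beta: float = 0.3    # chain outcome site: weak meQTLs only
    chain_metab_qtl_scale: float = 1.4  # chain source metabolite: extra-strong IVs
    group_logfc: float = 4.0        # natural-log group shift on affected genes
    group_meth: float = 1.2         # logit-scale shift on affected sites
    group_metab: float = 1.2        # log-scale shift on affected metabolites
    chain_b1: float = 0.6           # metabolite -> gene
    chain_b2: float = 0.6           # gene -> methylation
    module_beta: float = 1.0        # chain gene -> co-expression module genes
    n_deg: int = 10
    n_dmr: int = 6
    n_dam: int = 8


V_REF = 0.42  # dosage variance of an allele frequency 0.3 variant under HWE


def _plant_instruments(truth: SyntheticTruth, genotypes: GenotypeMatrix,
                       plan: list[tuple[str, str, int, float]],
                       slots: np.ndarray, rng: np.random.Generator) -> None:
    """Plant per-biomarker QTL effects calibrated to realized dosage variance.

    ``plan`` rows are (layer, feature, n_instruments, per-allele beta at the
    reference variance).  Baseline offsets absorb the realized mean dosage
    contribution so latents stay centred.
    """
    pos = 0
    for layer, feat, n_inst, base_beta in plan:
        planted = 0.0
        for _ in range(n_inst):
            variant = genotypes.variants["id"].iloc[int(slots[pos])]
            col = genotypes.column(variant)
            v = max(float(col.var()), 0.05)
            beta = base_beta * np.sqrt(V_REF / v)
            beta *= (0.99 + 0.02 * rng.random()) * rng.choice((-1.0, 1.0))
            truth.qtl_effects.append(QtlEffect(variant, layer, feat, beta))
            planted += beta * float(col.mean())
            pos += 1
        node = (layer, feat)
        truth.base_offsets[node] = truth.base_offsets.get(node, 0.0) - planted


def study_truth(config: ScenarioConfig, seed: int) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate genotypes and build the default planted-truth scenario.

    The chain runs ``met001 -> g001 -> <first site>``: the source metabolite
    and mediator gene both carry group effects and instruments, and ``g001``
    is additionally wired to seven other group-affected genes so it surfaces
    as a co-expression hub.  The chain's outcome site carries only weak
    (sub-threshold) meQTLs, as is typical of single CpGs at this sample size.
    """
    c = config
    rng = np.random.default_rng(seed)
    spec = VariantSpec(
        chrom_variants={str(i + 1): c.variants_per_chrom for i in range(c.n_chrom)},
        af_range=(0.3, 0.5), ld_block_size=c.ld_block_size, ld_rho=c.ld_rho,
    )
    genotypes = gen_genotypes(c.n_samples, spec, seed)
    genes = [f"g{i + 1:03d}" for i in range(c.n_genes)]
    metabs = [f"met{i + 1:03d}" for i in range(c.n_metabolites)]
    site_pos = np.cumsum(rng.integers(10_000, 100_000, size=c.n_sites)) + 10_000
    sites = pd.DataFrame({
        "site_id": [site_id("1", int(p)) for p in site_pos],
        "chrom": "1", "pos": site_pos.astype(int),
        "strand": np.where(rng.random(c.n_sites) < 0.5, "+", "-"),
    })
    site_ids = list(sites["site_id"])

    truth = SyntheticTruth(expr_features=genes, meth_sites=sites,
                           metab_features=metabs, seed=seed + 1)

    # desired net group contrasts: first n_deg genes, n_dmr sites, n_dam metabolites
    sign = lambda i: 1.0 if i % 2 == 0 else -1.0
    net_group: dict[tuple[str, str], float] = {}
    for i in range(c.n_deg):
        net_group[("expression", genes[i])] = sign(i) * c.group_logfc
    for i in range(c.n_dmr):
        net_group[("methylation", site_ids[i])] = sign(i) * c.group_meth
    for i in range(c.n_dam):
        net_group[("metabolite", metabs[i])] = sign(i) * c.group_metab
    # mild exercise effect on a few features of each layer
    truth.covariate_effects[("exercise", ("expression", genes[0]))] = 0.3
    truth.covariate_effects[("exercise", ("methylation", site_ids[0]))] = 0.2
    truth.covariate_effects[("exercise", ("metabolite", metabs[0]))] = 0.3

    # instruments: disjoint variant sets per biomarker involved in MR
    n_var = spec.total()
    plan: list[tuple[str, str, int, float]] = []
    for g in genes[: c.n_deg]:
        if g == genes[0]:
            plan.append(("expression", g, min(3, c.n_instruments),
                         c.qtl_beta * c.chain_gene_qtl_scale))
        else:
            plan.append(("expression", g, c.n_instruments, c.qtl_beta))
    for s_ in site_ids[: c.n_dmr]:
        if s_ == site_ids[0]:
            plan.append(("methylation", s_, min(3, c.n_instruments), c.chain_site_qtl_beta))
        else:
            plan.append(("methylation", s_, c.n_instruments, c.meth_qtl_beta))
    for m in metabs[: c.n_dam]:
        scale = c.chain_metab_qtl_scale if m == metabs[0] else 1.0
        plan.append(("metabolite", m, c.n_instruments, c.qtl_beta * scale))
    need = sum(p[2] for p in plan)
    if need > n_var:
        raise ValidationError(f"scenario needs {need} instrument variants, only {n_var} generated")
    # spread instruments so block-mates of an instrument stay free as proxies
    slots = rng.permutation(n_var)[:need]
    _plant_instruments(truth, genotypes, plan, slots, rng)

    # the planted causal chain metabolite -> gene -> methylation, plus a
    # co-expression module around the chain gene so it surfaces as a hub
    truth.causal_edges.append(CausalEdge(("metabolite", metabs[0]), ("expression", genes[0]), c.chain_b1))
    truth.causal_edges.append(CausalEdge(("expression", genes[0]), ("methylation", site_ids[0]), c.chain_b2))
    for j in range(1, 8):
        truth.causal_edges.append(CausalEdge(("expression", genes[0]), ("expression", genes[j]),
                                             c.module_beta))

    # convert desired net group contrasts into direct effects: subtract what a
    # node inherits through its causal edges, so the observed case-control
    # contrast equals the planted value; offset baselines for symmetry
    for node in _toposort_features(truth):
        inh = sum(e.beta * net_group.get(e.source, 0.0)
                  for e in truth.causal_edges if e.target == node)
        if node in net_group or inh:
            direct = net_group.get(node, 0.0) - inh
            truth.group_effects[node] = direct
            truth.base_offsets[node] = truth.base_offsets.get(node, 0.0) - 0.5 * direct
    return genotypes, truth


def chain_truth(seed: int, *, n_samples: int = 104, n_instruments: int = 3,
                qtl_beta: float = 1.0, b1: float = 0.6, b2: float = 0.6,
                n_null_genes: int = 15, n_null_sites: int = 5,
                n_null_metabs: int = 5,
                n_variants: int = 40) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Minimal scenario with one planted metabolite -> gene -> methylation
    chain (X -> M -> Y), disjoint calibrated instrument sets per node, and a
    handful of null features so per-million expression normalization is well
    defined.  The outcome site carries only weak sub-threshold meQTLs."""
    rng = np.random.default_rng(seed)
    spec = VariantSpec(chrom_variants={"1": n_variants}, af_range=(0.3, 0.5))
    genotypes = gen_genotypes(n_samples, spec, seed)
    genes = [f"g{i + 1:03d}" for i in range(1 + n_null_genes)]
    metabs = [f"met{i + 1:03d}" for i in range(1 + n_null_metabs)]
    n_sites = 1 + n_null_sites
    pos = np.cumsum(rng.integers(10_000, 100_000, size=n_sites)) + 10_000
    sites = pd.DataFrame({
        "site_id": [site_id("1", int(p)) for p in pos],
        "chrom": "1", "pos": pos.astype(int), "strand": "+",
    })
    truth = SyntheticTruth(expr_features=genes, meth_sites=sites,
                           metab_features=metabs, seed=seed + 1)
    plan = [
        ("metabolite", metabs[0], n_instruments, qtl_beta * 1.4),
        ("expression", genes[0], n_instruments, qtl_beta * 1.5),
        ("methylation", sites["site_id"].iloc[0], n_instruments, 0.3),
    ]
    slots = rng.permutation(n_variants)[: sum(p[2] for p in plan)]
    _plant_instruments(truth, genotypes, plan, slots, rng)
    truth.causal_edges.append(CausalEdge(("metabolite", metabs[0]), ("expression", genes[0]), b1))
    truth.causal_edges.append(
        CausalEdge(("expression", genes[0]), ("methylation", sites["site_id"].iloc[0]), b2))
    return genotypes, truth


def simulate_study(config: ScenarioConfig | None = None, seed: int = 0) -> StudyBundle:
    """Generate a full study bundle under the default planted scenario."""
    config = config or ScenarioConfig()
    genotypes, truth = study_truth(config, seed)
    expression, methylation, metabolite, sheet, annotation = gen_omics_from_truth(genotypes, truth)
    bundle = StudyBundle(
        genotypes=genotypes, expression=expression, methylation=methylation,
        metabolite=metabolite, sheet=sheet, annotation=annotation, truth=truth,
        provenance={"seed": seed, "scenario": vars(config).copy()},
    )
    bundle.validate()
    return bundle
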