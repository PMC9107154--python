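"""End-to-end orchestration: differential screens -> QTL scans -> pair MR ->
mediation, with every threshold configurable and study defaults built in.

Stage outputs are serialized as TSV tables; the report records stage counts
and file paths and is itself written as deterministic JSON (same config and
seed give byte-identical output).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential as diff
from . import io as tio
from . import network as net
from . import qtl as qtlmod
from .datatypes import StudyBundle
from .simulate import ScenarioConfig, simulate_study

log = logging.getLogger("triomr")

PATHWAY_CLASSES = (
    ("metabolite", "expression", "methylation"),   # Metabolomic -> Transcriptomic -> Epigenomic
    ("metabolite", "methylation", "expression"),   # Metabolomic -> Epigenomic -> Transcriptomic
    ("expression", "metabolite", "methylation"),   # Transcriptomic -> Metabolomic -> Epigenomic
)

_CLASS_LABEL = {"expression": "Transcriptomic", "methylation": "Epigenomic",
                "metabolite": "Metabolomic"}


@dataclass
class PipelineConfig:
    """All thresholds of the analysis chain; defaults mirror the study design
    (adjP <= 0.01 & |logFC| >= 5; Q < 0.01 & PMD > 10/15; VIP > 1 & p < 0.05;
    QTL P < 1e-5; proxy r^2 > 0.8; >= 2 methods P < 0.01; mediation P < 0.05).
    """

    seed: int = 0
    outdir: str = "triomr_out"
    input_dir: str | None = None             # load a bundle instead of simulating
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    write_bundle: bool = False
    heatmap: bool = False

    deg_adjp_max: float = 0.01
    deg_min_abs_logfc: float = 5.0
    min_cpm: float = 1.0
    hub_quantile: float = 0.9
    dmr_q_max: float = 0.01
    dmr_pmd_min: float = 10.0
    dmr_pmd_min_mr: float = 15.0
    q_method: str = "bh"
    dam_vip_min: float = 1.0
    dam_p_max: float = 0.05
    pls_components: int = 2
    qtl_p_max: float = 1e-5
    qtl_covariates: tuple[str, ...] = ("group", "exercise")
    full_qtl_scan: bool = False
    mr: net.MRConfig = field(default_factory=net.MRConfig)
    # mediate every triple of the three pathway classes (default); when False,
    # only triples whose X->M and M->Y pair decisions point forward
    mediate_all: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "scenario" in raw and isinstance(raw["scenario"], dict):
            raw["scenario"] = ScenarioConfig(**raw["scenario"])
        if "mr" in raw and isinstance(raw["mr"], dict):
            raw["mr"] = net.MRConfig(**raw["mr"])
        if "qtl_covariates" in raw:
            raw["qtl_covariates"] = tuple(raw["qtl_covariates"])
        return cls(**raw)


@dataclass
class PipelineReport:
    """Stage counts and output paths; every count equals the row count of the
    referenced TSV."""

    counts: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"counts": self.counts, "paths": self.paths,
                       "notes": self.notes, "config": self.config},
                      fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _save(df: pd.DataFrame, outdir: Path, name: str, report: PipelineReport,
          count_key: str | None = None) -> None:
    path = outdir / name
    df.to_csv(path, sep="\t", index=False)
    report.paths[name.removesuffix(".tsv")] = str(path)
    if count_key is not None:
        report.counts[count_key] = int(len(df))


def run_pipeline(config: PipelineConfig, bundle: StudyBundle | None = None) -> PipelineReport:
    """Execute the full chain on a loaded or freshly simulated study bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=_config_dict(config))

    if bundle is None:
        if config.input_dir:
            bundle = tio.load_study_bundle(config.input_dir)
            log.info("loaded study bundle from %s", config.input_dir)
        else:
            bundle = simulate_study(config.scenario, seed=config.seed)
            log.info("simulated study bundle (seed=%d)", config.seed)
    if config.write_bundle:
        report.paths.update(tio.write_bundle(bundle, outdir / "bundle"))

    # ---- differential expression + hubs -----------------------------------
    logexpr = diff.normalize_and_filter_counts(bundle.expression, min_cpm=config.min_cpm)
    de_records, de_params = diff.moderated_de_test(logexpr, bundle.sheet)
    degs = diff.select_degs(de_records, config.deg_adjp_max, config.deg_min_abs_logfc)
    log.info("DEG screen: adjP<=%g & |logFC|>=%g kept %d of %d genes",
             config.deg_adjp_max, config.deg_min_abs_logfc, len(degs), len(de_records))
    _save(de_records, outdir, "deg_records.tsv", report, "genes_tested")
    _save(degs, outdir, "degs.tsv", report, "degs")
    if len(degs) >= 3:
        # co-expression on covariate-adjusted expression: the group contrast
        # would otherwise dominate every pairwise correlation among DEGs
        deg_expr = logexpr.loc[degs.index]
        resid = qtlmod._residualize(deg_expr.to_numpy().T, bundle.sheet.design_matrix()[:, 1:]).T
        hubs, edges = diff.planar_hub_genes(
            pd.DataFrame(resid, index=deg_expr.index, columns=deg_expr.columns),
            config.hub_quantile)
        _save(pd.DataFrame(edges, columns=["gene_a", "gene_b", "r"]),
              outdir, "coexpression_edges.tsv", report)
    else:
        hubs = list(degs.index)
        report.notes.append("fewer than 3 DEGs: planar network skipped, all DEGs kept as hubs")
    _save(pd.DataFrame({"gene_id": hubs}), outdir, "hub_genes.tsv", report, "hub_genes")

    # ---- differential methylation -----------------------------------------
    dmr_records = diff.methylation_site_test(bundle.methylation, bundle.sheet,
                                             q_method=config.q_method)
    dmrs10, hyper, hypo = diff.select_dmrs(dmr_records, config.dmr_q_max, config.dmr_pmd_min)
    dmrs15, _, _ = diff.select_dmrs(dmr_records, config.dmr_q_max, config.dmr_pmd_min_mr)
    tss_map = diff.annotate_nearest_tss(dmrs10, bundle.annotation)
    log.info("DMR screen: Q<%g & |PMD|>%g kept %d (hyper %d / hypo %d); PMD>%g kept %d",
             config.dmr_q_max, config.dmr_pmd_min, len(dmrs10), len(hyper),
             len(hypo), config.dmr_pmd_min_mr, len(dmrs15))
    _save(dmr_records, outdir, "dmr_records.tsv", report, "sites_tested")
    _save(dmrs10, outdir, "dmrs_pmd10.tsv", report, "dmrs_pmd10")
    _save(dmrs15, outdir, "dmrs_pmd15.tsv", report, "dmrs_pmd15")
    _save(tss_map, outdir, "dmr_nearest_tss.tsv", report, "dmr_annotated_genes")
    report.counts["dmrs_hyper"] = int(len(hyper))
    report.counts["dmrs_hypo"] = int(len(hypo))
    report.counts["dmr_annotated_genes"] = int(tss_map["gene_id"].nunique()) if len(tss_map) else 0

    # ---- differential metabolites -----------------------------------------
    vips = diff.plsda_vip(bundle.metabolite, bundle.sheet, config.pls_components)
    logi = diff.metabolite_logistic(bundle.metabolite, bundle.sheet)
    dams = diff.select_dams(vips, logi, config.dam_vip_min, config.dam_p_max)
    log.info("DAM screen: VIP>%g & p<%g kept %d of %d metabolites",
             config.dam_vip_min, config.dam_p_max, len(dams), len(vips))
    dam_table = logi.assign(vip=vips)
    _save(dam_table, outdir, "dam_records.tsv", report, "metabolites_tested")
    _save(dams, outdir, "dams.tsv", report, "dams")

    # ---- QTL scans on selected biomarkers ---------------------------------
    selected = {
        "expression": list(hubs),
        "methylation": list(dmrs15.index),
        "metabolite": list(dams.index),
    }
    covs = bundle.sheet.table[list(config.qtl_covariates)].to_numpy(dtype=float)
    qtl_records: dict[str, pd.DataFrame] = {}
    qtl_selected: dict[str, pd.DataFrame] = {}
    layer_qtl_name = {"expression": "eqtl", "methylation": "meqtl", "metabolite": "metaqtl"}
    for layer in ("expression", "methylation", "metabolite"):
        feats = qtlmod.transform_features(bundle.layer(layer))
        if not config.full_qtl_scan:
            feats = feats.loc[[f for f in selected[layer] if f in feats.index]]
        if feats.empty:
            report.notes.append(f"no selected {layer} biomarkers: QTL scan skipped")
            qtl_records[layer] = pd.DataFrame(
                columns=["variant", "feature", "layer", "beta", "se", "t", "p", "n", "flag"])
            qtl_selected[layer] = qtl_records[layer]
        else:
            rec = qtlmod.qtl_scan(bundle.genotypes, feats, covs, layer=layer)
            qtl_records[layer] = rec
            qtl_selected[layer] = qtlmod.select_qtls(rec, config.qtl_p_max)
        _save(qtl_selected[layer], outdir, f"{layer_qtl_name[layer]}.tsv", report,
              f"{layer_qtl_name[layer]}s")
        log.info("%s scan: %d significant at P<%g", layer_qtl_name[layer],
                 len(qtl_selected[layer]), config.qtl_p_max)
    store = net.QtlStore(qtl_records)

    # ---- Spearman correlation across selected biomarkers ------------------
    biom_values = {}
    for layer, feats in selected.items():
        tf = qtlmod.transform_features(bundle.layer(layer))
        for f in feats:
            if f in tf.index:
                biom_values[f] = tf.loc[f].to_numpy()
    if len(biom_values) >= 2:
        vals = pd.DataFrame(biom_values, index=bundle.sheet.samples)
        rho = net.spearman_matrix(vals)
        rho.to_csv(outdir / "spearman_biomarkers.tsv", sep="\t")
        report.paths["spearman_biomarkers"] = str(outdir / "spearman_biomarkers.tsv")
        if config.heatmap:
            net.correlation_heatmap(rho, str(outdir / "spearman_heatmap.png"))
            report.paths["spearman_heatmap"] = str(outdir / "spearman_heatmap.png")

    # ---- bi-directional MR over the pair grid -----------------------------
    mr_cfg = dataclasses.replace(config.mr, seed=config.seed)
    pair_classes = [("expression", "methylation"), ("methylation", "metabolite"),
                    ("expression", "metabolite")]
    decisions: list[net.PairDecision] = []
    decision_lookup: dict[tuple[str, str], str] = {}
    pair_rows = []
    fit_frames = []
    for la, lb in pair_classes:
        pairs = []
        if selected[la] and selected[lb]:
            pairs = net.enumerate_pairs(selected[la], selected[lb])
        else:
            report.notes.append(f"pair class {la}-{lb} skipped: empty biomarker set")
        for a, b in pairs:
            dec = net.bidirectional_mr(((la, a), (lb, b)), store, bundle.genotypes, mr_cfg)
            decisions.append(dec)
            decision_lookup[(f"{la}:{a}", f"{lb}:{b}")] = dec.direction
            row = {"pair_class": f"{_CLASS_LABEL[la]}-{_CLASS_LABEL[lb]}",
                   "exposure": dec.exposure, "outcome": dec.outcome,
                   "tier_forward": dec.tier_forward, "tier_reverse": dec.tier_reverse,
                   "direction": dec.direction}
            for m, p in dec.p_forward.items():
                row[f"p_fwd_{m}"] = p
            for m, p in dec.p_reverse.items():
                row[f"p_rev_{m}"] = p
            pair_rows.append(row)
            from .mr import fits_to_frame
            fit_frames.append(fits_to_frame(dec.exposure, dec.outcome, dec.fits_forward,
                                            dec.n_ivs_forward, dec.n_proxies_forward))
            fit_frames.append(fits_to_frame(dec.outcome, dec.exposure, dec.fits_reverse,
                                            dec.n_ivs_reverse, dec.n_proxies_reverse))
    pair_df = pd.DataFrame(pair_rows)
    _save(pair_df, outdir, "pair_decisions.tsv", report, "pairs_tested")
    mr_df = (pd.concat(fit_frames, ignore_index=True)
             if fit_frames else pd.DataFrame())
    _save(mr_df, outdir, "mr_results.tsv", report)
    for tier in ("significant", "suggestive"):
        report.counts[f"pairs_{tier}"] = (
            int(((pair_df.get("tier_forward") == tier) | (pair_df.get("tier_reverse") == tier)).sum())
            if len(pair_df) else 0)
    report.counts["pairs_with_direction"] = (
        int((pair_df["direction"] != "none").sum()) if len(pair_df) else 0)

    # ---- mediation over the three pathway classes -------------------------
    def _forward_ok(exp_node: tuple[str, str], out_node: tuple[str, str]) -> bool:
        a, b = f"{exp_node[0]}:{exp_node[1]}", f"{out_node[0]}:{out_node[1]}"
        if (a, b) in decision_lookup:
            return decision_lookup[(a, b)] in ("forward", "bidirectional")
        if (b, a) in decision_lookup:
            return decision_lookup[(b, a)] in ("reverse", "bidirectional")
        return False

    med_rows = []
    n_mediated = 0
    for lx, lm, ly in PATHWAY_CLASSES:
        label = " -> ".join(_CLASS_LABEL[l] for l in (lx, lm, ly))
        for fx in selected[lx]:
            for fm_ in selected[lm]:
                for fy in selected[ly]:
                    x, m, y = (lx, fx), (lm, fm_), (ly, fy)
                    if not config.mediate_all and not (
                            _forward_ok(x, m) and _forward_ok(m, y)):
                        continue
                    res = net.mediation_test(x, m, y, store, bundle.genotypes, mr_cfg)
                    med_rows.append({
                        "pathway_class": label, "X": fx, "M": fm_, "Y": fy,
                        "beta": res.indirect, "se": res.indirect_se, "p": res.p,
                        "total": res.total, "direct": res.direct,
                        "mediated": res.mediated, "testable": res.testable,
                    })
                    n_mediated += bool(res.mediated)
    med_df = pd.DataFrame(med_rows, columns=["pathway_class", "X", "M", "Y", "beta",
                                             "se", "p", "total", "direct",
                                             "mediated", "testable"])
    _save(med_df, outdir, "mediation.tsv", report, "mediation_triples_tested")
    report.counts["mediation_triples"] = int(n_mediated)
    log.info("mediation: %d of %d eligible triples declared at P<0.05",
             n_mediated, len(med_df))

    report.to_json(outdir / "report.json")
    report.paths["report"] = str(outdir / "report.json")
    return report


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
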