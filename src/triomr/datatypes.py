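"""Shared in-memory containers for the tri-omics pipeline.

Sample axes are kept as explicit ordered lists of sample ids; every container
that carries per-sample data validates against the :class:`SampleSheet` it is
used with.  Feature matrices follow the omics convention of features in rows
and samples in columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

LAYERS = ("expression", "methylation", "metabolite")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (samples x variants) with variant metadata.

    ``dosages`` holds hard calls in {0, 1, 2}.  ``variants`` is a DataFrame
    with columns ``id, chrom, pos, ref, alt, af`` (1-based positions, alt
    allele frequency used at generation time).
    """

    samples: list[str]
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["id"])

    def column(self, variant_id: str) -> np.ndarray:
        idx = self._index().get(variant_id)
        if idx is None:
            raise KeyError(f"unknown variant {variant_id!r}")
        return self.dosages[:, idx].astype(float)

    def _index(self) -> dict[str, int]:
        if not hasattr(self, "_vidx"):
            self._vidx = {v: i for i, v in enumerate(self.variants["id"])}
        return self._vidx

    def validate(self) -> None:
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValidationError("dosages must all be in {0, 1, 2}")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r}")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValidationError(f"positions not strictly increasing on {chrom}")


@dataclass
class SampleSheet:
    """Per-sample design information: binary group plus named covariates."""

    table: pd.DataFrame
    group_col: str = "group"
    covariates: tuple[str, ...] = ("exercise",)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def group(self) -> np.ndarray:
        """Group as 0/1 (1 = case / overweight-obese)."""
        g = self.table[self.group_col]
        levels = sorted(pd.unique(g))
        if len(levels) != 2:
            raise ValidationError(
                f"group column {self.group_col!r} must have exactly two levels, got {levels}"
            )
        return (g == levels[1]).to_numpy().astype(float)

    def covariate_matrix(self) -> np.ndarray:
        """Covariate columns as a float array (n_samples x n_covariates)."""
        if not self.covariates:
            return np.empty((len(self.table), 0))
        return self.table[list(self.covariates)].to_numpy(dtype=float)

    def design_matrix(self) -> np.ndarray:
        """[intercept, group, covariates...] design, n_samples x (2 + n_cov)."""
        n = len(self.table)
        return np.column_stack([np.ones(n), self.group, self.covariate_matrix()])

    def validate(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in sample sheet")
        _ = self.group  # raises if not two non-empty levels


@dataclass
class FeatureMatrix:
    """One omic layer, samples aligned to a SampleSheet.

    * ``expression``: ``values`` holds non-negative counts (genes x samples);
      ``feature_meta`` carries at least ``gene_id``.
    * ``methylation``: ``coverage`` and ``methylated`` hold per-site per-sample
      counts; ``feature_meta`` carries ``chrom, pos, strand``.  Site ids use
      the ``<chrom>.<position>`` convention.
    * ``metabolite``: ``values`` holds positive abundances.
    """

    layer: str
    samples: list[str]
    values: pd.DataFrame | None = None
    coverage: pd.DataFrame | None = None
    methylated: pd.DataFrame | None = None
    feature_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def feature_ids(self) -> list[str]:
        if self.layer == "methylation":
            return list(self.coverage.index)
        return list(self.values.index)

    def validate(self, sheet: SampleSheet | None = None) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if self.layer == "methylation":
            if self.coverage is None or self.methylated is None:
                raise ValidationError("methylation layer needs coverage and methylated")
            if (self.methylated.to_numpy() > self.coverage.to_numpy()).any():
                raise ValidationError("methylated count exceeds coverage")
            if (self.methylated.to_numpy() < 0).any():
                raise ValidationError("negative methylated count")
            cols = list(self.coverage.columns)
        else:
            if self.values is None:
                raise ValidationError(f"{self.layer} layer needs a values matrix")
            if (self.values.to_numpy() < 0).any():
                raise ValidationError(f"negative values in {self.layer} matrix")
            cols = list(self.values.columns)
        if cols != self.samples:
            raise ValidationError(f"{self.layer} column order differs from sample axis")
        if sheet is not None and self.samples != sheet.samples:
            raise ValidationError(f"{self.layer} sample axis differs from sample sheet")


@dataclass
class GeneAnnotation:
    """Gene TSS annotation: columns ``gene_id, chrom, tss, strand`` (1-based)."""

    table: pd.DataFrame

    def validate(self) -> None:
        if self.table["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")


@dataclass
class QtlEffect:
    variant: str
    layer: str
    feature: str
    beta: float


@dataclass
class CausalEdge:
    source: tuple[str, str]  # (layer, feature)
    target: tuple[str, str]
    beta: float


@dataclass
class SyntheticTruth:
    """Planted structure of a simulated study; the oracle for recovery tests.

    Feature effects act on each layer's latent natural scale: log mean counts
    for expression, logit methylation proportion, log abundance for
    metabolites.
    """

    expr_features: list[str]
    meth_sites: pd.DataFrame  # site_id, chrom, pos, strand
    metab_features: list[str]
    qtl_effects: list[QtlEffect] = field(default_factory=list)
    causal_edges: list[CausalEdge] = field(default_factory=list)
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    base_offsets: dict[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"expression": 0.3, "methylation": 0.3, "metabolite": 0.35}
    )
    expr_base: float = 6.0        # log mean counts, exp(6) ~ 400 reads
    meth_base: float = 0.0        # logit scale, 50% methylation
    metab_base: float = 0.0       # log abundance
    coverage_mean: float = 30.0   # RRBS coverage, shifted Poisson
    seed: int = 0

    def features(self, layer: str) -> list[str]:
        if layer == "expression":
            return list(self.expr_features)
        if layer == "methylation":
            return list(self.meth_sites["site_id"])
        if layer == "metabolite":
            return list(self.metab_features)
        raise ValidationError(f"unknown layer {layer!r}")


@dataclass
class StudyBundle:
    """Everything one simulated or loaded study comprises."""

    genotypes: GenotypeMatrix
    expression: FeatureMatrix
    methylation: FeatureMatrix
    metabolite: FeatureMatrix
    sheet: SampleSheet
    annotation: GeneAnnotation
    truth: SyntheticTruth | None = None
    provenance: dict = field(default_factory=dict)

    def layer(self, name: str) -> FeatureMatrix:
        return {
            "expression": self.expression,
            "methylation": self.methylation,
            "metabolite": self.metabolite,
        }[name]

    def validate(self) -> None:
        self.sheet.validate()
        self.genotypes.validate()
        if self.genotypes.samples != self.sheet.samples:
            raise ValidationError("genotype sample axis differs from sample sheet")
        for name in LAYERS:
            self.layer(name).validate(self.sheet)
        self.annotation.validate()


def site_id(chrom: str | int, pos: int) -> str:
    """Methylation site id in ``<chrom>.<position>`` notation (e.g. 6.110721178)."""
    return f"{chrom}.{pos}"


def check_aligned(samples: Sequence[str], other: Sequence[str], what: str) -> None:
    if list(samples) != list(other):
        missing = sorted(set(samples) ^ set(other))
        raise ValidationError(f"sample mismatch in {what}: offending samples {missing}")
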