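"""Domain types shared by every pipeline stage.

The pipeline passes a small set of value objects between stages: paired
expression matrices (log2 scale, features x samples), per-sample subtype
classification records from an external nearest-template classifier,
UP/DOWN subtype gene signatures, a microRNA -> predicted-target map, and
the per-stage result records (differential expression, target enrichment,
regulons, stepwise-regression attributions, final candidates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClassificationRecord",
    "SubtypeSignature",
    "TargetMap",
    "DiffExpResult",
    "EnrichmentResult",
    "Regulon",
    "SlrAttribution",
    "MicroRnaAttribution",
    "CandidateRecord",
    "NullModelSpec",
    "CoreSampleSets",
    "FdrGridResult",
    "EnrichmentThresholds",
    "MraResult",
    "RankedEnrichment",
]

UP = "UP"
DOWN = "DOWN"


class ExpressionMatrix:
    """A features x samples expression matrix on the log2 scale.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces unique
    feature/sample identifiers and finite values, and records whether the
    matrix has been linearized (``2**x``) so downstream code never guesses
    the scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features (genes or microRNAs), columns are samples.
    linear : bool
        True if the values are on the linear scale rather than log2.
    """

    def __init__(self, values: pd.DataFrame, linear: bool = False):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(
                "expression matrix contains non-finite values; apply a NaN "
                "policy at load time (see mmra.io.read_expression_matrix)"
            )
        self.values = values
        self.linear = bool(linear)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.linear)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def to_linear(self) -> "ExpressionMatrix":
        if self.linear:
            return self
        return ExpressionMatrix(np.power(2.0, self.values), linear=True)

    def __repr__(self) -> str:  # pragma: no cover
        scale = "linear" if self.linear else "log2"
        return f"ExpressionMatrix({self.shape[0]} features x {self.shape[1]} samples, {scale})"


@dataclass(frozen=True)
class ClassificationRecord:
    """One sample's assignment by one subtype classifier.

    ``ntp_fdr`` is the nearest-template-prediction confidence FDR and
    ``delta`` the distance of the sample from the nearest subtype template;
    both drive subtype-core selection.
    """

    sample_id: str
    classifier: str
    subtype: str
    ntp_fdr: float
    delta: float

    def __post_init__(self):
        if not (0.0 <= self.ntp_fdr <= 1.0):
            raise ValueError(f"ntp_fdr must be in [0,1], got {self.ntp_fdr}")
        if not np.isfinite(self.delta) or self.delta < 0:
            raise ValueError(f"delta must be finite and >= 0, got {self.delta}")


@dataclass(frozen=True)
class SubtypeSignature:
    """A directional gene signature of one subtype of one classifier."""

    classifier: str
    subtype: str
    direction: str  # UP or DOWN
    genes: frozenset

    def __post_init__(self):
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be UP or DOWN, got {self.direction}")
        object.__setattr__(self, "genes", frozenset(self.genes))

    @property
    def name(self) -> str:
        return f"{self.classifier}.{self.subtype}.{self.direction}"


@dataclass
class TargetMap:
    """microRNA -> predicted target genes, with per-pair provenance.

    A pair is retained only when at least two prediction databases agree,
    or when it is experimentally validated.
    """

    targets: dict  # microrna -> set of gene ids
    provenance: dict = field(default_factory=dict)  # (mirna, gene) -> (n_db, validated)

    def __post_init__(self):
        self.targets = {m: set(g) for m, g in self.targets.items()}
        for (m, g), (n_db, validated) in self.provenance.items():
            if n_db < 2 and not validated:
                raise ValueError(
                    f"pair ({m}, {g}) retained with {n_db} agreeing databases "
                    "and no validation"
                )

    def genes(self, microrna: str) -> set:
        return self.targets.get(microrna, set())

    @property
    def micrornas(self) -> list[str]:
        return sorted(self.targets)

    @property
    def gene_space(self) -> set:
        out: set = set()
        for g in self.targets.values():
            out |= g
        return out


@dataclass(frozen=True)
class DiffExpResult:
    """A subtype-specific differential microRNA (stage-1 survivor)."""

    microrna: str
    classifier: str
    subtype: str
    ks_p: float
    fold_change: float  # linear scale, > 0
    direction: str

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive (linear scale)")
        expected = UP if self.fold_change > 1 else DOWN
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction} inconsistent with FC {self.fold_change}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric target-enrichment outcome of one microRNA vs one signature."""

    microrna: str
    classifier: str
    subtype: str
    direction: str
    p_raw: float
    p_adj: float
    oe_ratio: float
    k_observed: int = 0
    n_targets: int = 0


@dataclass
class Regulon:
    """Single-hub consensus network around one microRNA.

    ``edges`` maps target gene -> (mean MI across supporting bootstraps,
    support count, binomial support p).
    """

    hub: str
    edges: dict  # gene -> (mi, support_count, support_p)
    n_boot: int = 0

    @property
    def genes(self) -> set:
        return set(self.edges)

    def mi(self, gene: str) -> float:
        return self.edges[gene][0]

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SlrAttribution:
    """Stepwise-regression outcome for one response gene."""

    gene: str
    selected: list  # list of (microrna, coefficient)
    aic: float


@dataclass
class MicroRnaAttribution:
    """Per-microRNA aggregation of stepwise selections over one signature."""

    microrna: str
    classifier: str
    subtype: str
    direction: str
    fraction: float
    fraction_negative: float
    fraction_positive: float
    n_genes_fit: int

    def __post_init__(self):
        for f in (self.fraction, self.fraction_negative, self.fraction_positive):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fractions must lie in [0,1], got {f}")


@dataclass
class CandidateRecord:
    """A final candidate master-regulator microRNA for one subtype."""

    microrna: str
    classifier: str
    subtype: str
    expression_direction: str
    signature_direction: str
    slr_fraction: float
    opposite_direction: bool
    ks_p: float = float("nan")
    fold_change: float = float("nan")
    enrichment_p_adj: float = float("nan")
    oe_ratio: float = float("nan")
    mra_p: float = float("nan")
    other_signatures: list = field(default_factory=list)


@dataclass
class NullModelSpec:
    """Selection rules for non-differential microRNAs used as the MRA null.

    ``min_expressed_fraction`` — a microRNA must be detected in more than
    this fraction of samples (0.10 reproduces "more than 45 of 450").
    ``snr_bound`` — bound on the absolute signal-to-noise ratio
    (group mean log2 difference over the sum of group s.d.) in every
    subtype contrast; ``snr_literal_negative`` switches to the literal
    one-sided reading SNR < -snr_bound.
    ``max_regulon_overlap`` — a null regulon may share at most this
    fraction (of the smaller set) with any candidate regulon.
    """

    min_expressed_fraction: float = 0.10
    detection_threshold: float = 0.0
    snr_bound: float = 0.05
    snr_literal_negative: bool = False
    max_regulon_overlap: float = 0.70
    fallback_mra_threshold: float = 1e-4


@dataclass
class CoreSampleSets:
    """Subtype-core sample ids for one classifier plus the delta cutoff used."""

    classifier: str
    cores: dict  # subtype -> list of sample ids (high-confidence members)
    members: dict  # subtype -> list of all assigned sample ids
    delta_threshold: float


@dataclass
class FdrGridResult:
    """Permutation-FDR estimates over a (p threshold, FC threshold) grid."""

    table: pd.DataFrame  # columns p_threshold, fc_threshold, n_observed, mean_n_permuted, fdr
    recommended: tuple  # (p_threshold, fc_threshold)


@dataclass
class EnrichmentThresholds:
    """Per-classifier enrichment thresholds with the random-set FDR grid."""

    per_classifier: dict  # classifier -> (p_threshold, oe_threshold)
    fdr_table: pd.DataFrame


@dataclass
class MraResult:
    """Fisher-exact overlap test between a regulon and one subtype signature."""

    microrna: str
    classifier: str
    subtype: str
    direction: str
    overlap: int
    fisher_p: float
    passed: bool = False


@dataclass
class RankedEnrichment:
    """MI-weighted preranked enrichment of a signature within a regulon."""

    es: float
    nes: float
    perm_p: float
    leading_edge: list
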