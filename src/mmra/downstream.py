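"""Post-pipeline validation procedures.

Consolidation of microRNA-subtype associations in an independent cell-line
panel (null-model fold-change thresholds plus subtype-level correlation
fractions), differential expression after microRNA silencing with a
wild-type-versus-scramble specificity filter, enrichment of silencing
responses in joint stem-subtype signatures, and identification of "core
targets" — genes upregulated in vitro upon silencing AND anti-associated
with the same microRNA in tumor data by stepwise regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .slr import fit_stepwise

logger = logging.getLogger("mmra")

__all__ = [
    "ConsolidationResult",
    "CoreTarget",
    "nullmodel_fc_threshold",
    "correlation_fraction",
    "consolidate_associations",
    "silencing_de",
    "signature_shift_test",
    "identify_core_targets",
    "core_target_network",
]


@dataclass
class ConsolidationResult:
    microrna: str
    fold_change: float
    fc_threshold: float
    fc_pass: bool
    correlation_fraction: float
    correlation_threshold: float
    corr_pass: bool

    @property
    def validated(self) -> bool:
        return self.fc_pass and self.corr_pass


@dataclass
class CoreTarget:
    gene: str
    micrornas: list  # microRNAs with a negative SLR coefficient for this gene
    in_vitro_upregulated_by: list = field(default_factory=list)

    @property
    def degree(self) -> int:
        return len(self.micrornas)


def _abs_fc(x_log2: np.ndarray, y_log2: np.ndarray) -> float:
    """Absolute linear fold change max(FC, 1/FC) between log2 groups."""
    fc = 2.0 ** (x_log2.mean() - y_log2.mean())
    return max(fc, 1.0 / fc)


def nullmodel_fc_threshold(mirna, labels: dict, target_subtype: str,
                           set_size: int, n_random: int = 1000,
                           percentile: float = 90.0, seed=None) -> float:
    """Fold-change significance threshold from random microRNA sets.

    ``labels`` maps sample id -> subtype. For each of ``n_random`` draws a
    random set of ``set_size`` microRNAs is taken and its absolute linear
    fold changes between the target-subtype samples and the rest are pooled;
    the threshold is the requested percentile of that null distribution.
    """
    rng = np.random.default_rng(seed)
    values = mirna.values.to_numpy(dtype=float)
    in_s = np.array([labels.get(s) == target_subtype for s in mirna.sample_ids])
    if in_s.sum() == 0 or in_s.sum() == in_s.size:
        raise ValueError(f"target subtype {target_subtype!r} splits no samples")
    n_mirnas = values.shape[0]
    set_size = min(set_size, n_mirnas)
    fcs = np.abs(values[:, in_s].mean(axis=1) - values[:, ~in_s].mean(axis=1))
    all_abs_fc = 2.0 ** fcs  # per-microRNA absolute FC, reused across draws
    pooled = np.empty(n_random * set_size)
    for b in range(n_random):
        pick = rng.choice(n_mirnas, size=set_size, replace=False)
        pooled[b * set_size:(b + 1) * set_size] = all_abs_fc[pick]
    return float(np.percentile(pooled, percentile))


def correlation_fraction(signature_expr: pd.DataFrame, mirna_expr: np.ndarray,
                         labels: dict, r_threshold: float) -> float:
    """Fraction of signature genes whose subtype-mean profile correlates with
    the microRNA's beyond |Spearman r| > r_threshold.

    Means are taken per subtype (genes x subtypes against a subtype-mean
    microRNA vector); constant gene profiles are excluded and logged.
    Requires at least four subtypes — rank correlations over three points
    are unreliable.
    """
    sample_ids = list(signature_expr.columns)
    subtypes = sorted({labels[s] for s in sample_ids if s in labels})
    if len(subtypes) < 4:
        raise ValueError("subtype-level correlation needs >= 4 subtypes")
    groups = [[i for i, s in enumerate(sample_ids) if labels.get(s) == st]
              for st in subtypes]
    gene_means = np.column_stack([
        signature_expr.to_numpy(dtype=float)[:, idx].mean(axis=1) for idx in groups
    ])
    mir_means = np.array([np.asarray(mirna_expr, dtype=float)[idx].mean()
                          for idx in groups])
    n_counted = n_valid = 0
    for row, gene in zip(gene_means, signature_expr.index):
        if np.ptp(row) == 0:
            logger.info("gene %s constant across subtype means; excluded", gene)
            continue
        r, _ = stats.spearmanr(row, mir_means)
        n_valid += 1
        if abs(r) > r_threshold:
            n_counted += 1
    if n_valid == 0:
        raise ValueError("no signature gene has a non-constant subtype profile")
    return n_counted / n_valid


def consolidate_associations(mirna, labels: dict, candidates,
                             signature_expr_by_key: dict,
                             r_threshold: float, corr_fraction_cut: float,
                             n_random: int = 1000, percentile: float = 90.0,
                             seed=None) -> list[ConsolidationResult]:
    """Cell-line consolidation: null-model FC threshold + correlation fraction.

    ``candidates`` is a list of (microrna, subtype); ``signature_expr_by_key``
    maps (microrna, subtype) -> signature-gene expression DataFrame over the
    same cell lines.
    """
    rng = np.random.default_rng(seed)
    results = []
    for mid, subtype in candidates:
        fc_thr = nullmodel_fc_threshold(mirna, labels, subtype,
                                        set_size=len(candidates),
                                        n_random=n_random, percentile=percentile,
                                        seed=rng)
        in_s = np.array([labels.get(s) == subtype for s in mirna.sample_ids])
        fc = _abs_fc(mirna.row(mid)[in_s], mirna.row(mid)[~in_s])
        frac = correlation_fraction(signature_expr_by_key[(mid, subtype)],
                                    mirna.row(mid), labels, r_threshold)
        results.append(ConsolidationResult(
            microrna=mid, fold_change=fc, fc_threshold=fc_thr,
            fc_pass=fc > fc_thr, correlation_fraction=frac,
            correlation_threshold=corr_fraction_cut,
            corr_pass=frac > corr_fraction_cut,
        ))
    return results


def silencing_de(transduced: pd.DataFrame, scramble: pd.DataFrame,
                 wildtype: pd.DataFrame, fc_thr: float = 1.5,
                 p_thr: float = 0.05) -> tuple[list, list]:
    """Genes responding to microRNA silencing, cleaned of vector effects.

    Each frame is genes x replicates (log2). A gene responds when its
    absolute linear FC between transduced and scramble exceeds ``fc_thr``
    and the two-sided Welch t-test p-value is below ``p_thr``; genes meeting
    the same criteria between wild-type and scramble are filtered out as
    transduction artifacts. Returns (upregulated, downregulated) gene lists.
    """
    for name, df in (("transduced", transduced), ("scramble", scramble),
                     ("wildtype", wildtype)):
        if df.shape[1] < 2:
            raise ValueError(f"{name} needs >= 2 replicates for the t-test")
    genes = transduced.index
    if not (genes.equals(scramble.index) and genes.equals(wildtype.index)):
        raise ValueError("the three matrices must share the same gene index")

    def hits(a: pd.DataFrame, b: pd.DataFrame):
        av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
        diff = av.mean(axis=1) - bv.mean(axis=1)
        _, p = stats.ttest_ind(av, bv, axis=1, equal_var=False)
        sig = (np.maximum(2.0 ** diff, 2.0 ** -diff) > fc_thr) & (p < p_thr)
        return sig & (diff > 0), sig & (diff < 0)

    up_t, down_t = hits(transduced, scramble)
    up_w, down_w = hits(wildtype, scramble)
    artifact = up_w | down_w
    up = [g for g, u, a in zip(genes, up_t, artifact) if u and not a]
    down = [g for g, d, a in zip(genes, down_t, artifact) if d and not a]
    return up, down


def signature_shift_test(up_genes, down_genes, ssm_up, ssm_down, universe,
                         p_thr: float = 0.05) -> dict:
    """Hypergeometric enrichment of silencing responses in the joint
    stem-subtype signatures (upregulated vs SSM-UP, downregulated vs SSM-DOWN)."""
    universe = set(universe)

    def one(genes, sig):
        genes = set(genes) & universe
        sig = set(sig) & universe
        k = len(genes & sig)
        if not genes or not sig:
            return {"k": k, "p": 1.0, "fold": 0.0, "significant": False}
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(sig), len(genes)))
        expected = len(genes) * len(sig) / len(universe)
        return {"k": k, "p": p, "fold": k / expected if expected else 0.0,
                "significant": p < p_thr}

    return {"up_in_ssm_up": one(up_genes, ssm_up),
            "down_in_ssm_down": one(down_genes, ssm_down)}


def identify_core_targets(up_genes_by_mirna: dict, mrna, mirna,
                          validated_micrornas) -> list[CoreTarget]:
    """Core targets of functionally validated microRNAs.

    For every gene upregulated in vitro upon silencing of any validated
    microRNA, a stepwise model is fitted on the tumor expression matrix with
    the validated microRNAs as candidates. A gene is a core target of
    microRNA M when M is selected with a negative coefficient; the in-vitro
    evidence (which silencings upregulated it) is kept per gene so edges can
    be labelled in-vitro+in-vivo versus in-vivo-only.
    """
    validated = [m for m in validated_micrornas if m in set(mirna.feature_ids)]
    if not validated:
        raise ValueError("no validated microRNA present in the expression matrix")
    candidates_matrix = np.vstack([mirna.row(m) for m in validated])
    all_up = sorted({g for genes in up_genes_by_mirna.values() for g in genes})
    expressed = set(mrna.feature_ids)
    out = []
    for g in all_up:
        if g not in expressed:
            continue
        fit = fit_stepwise(mrna.row(g), candidates_matrix, validated, gene_id=g)
        negatives = [m for m, coef in fit.selected if coef < 0]
        if not negatives:
            continue
        upregulated_by = sorted(m for m, genes in up_genes_by_mirna.items()
                                if g in genes)
        out.append(CoreTarget(gene=g, micrornas=negatives,
                              in_vitro_upregulated_by=upregulated_by))
    return out


def core_target_network(core_targets) -> nx.Graph:
    """Bipartite microRNA-gene graph; edge style 'solid' when the in-vitro
    and in-vivo evidence concern the same microRNA, 'dashed' otherwise."""
    g = nx.Graph()
    for ct in core_targets:
        g.add_node(ct.gene, kind="gene")
        for m in ct.micrornas:
            g.add_node(m, kind="microrna")
            style = "solid" if m in ct.in_vitro_upregulated_by else "dashed"
            g.add_edge(m, ct.gene, style=style)
    return g
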