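"""Stage 4 — stepwise linear regression attribution and the final candidates.

Each subtype-signature gene that appears in at least one regulon is modelled
as a linear function of the log2 expression of the microRNAs whose regulons
contain it (pooled over all classifiers). A bidirectional stepwise search
starting from the full model and minimizing the Akaike information criterion
selects the minimal explanatory set. Selections are then aggregated per
microRNA into the fraction of each signature's genes it explains, the 90th
percentile of the pooled fraction distribution becomes the significance
threshold, and a final candidate record is emitted for every
microRNA-subtype association that survived stages 1-3 and exceeds the
fraction threshold.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    DOWN,
    UP,
    CandidateRecord,
    MicroRnaAttribution,
    SlrAttribution,
)

logger = logging.getLogger("mmra")

__all__ = [
    "fit_stepwise",
    "fit_signature_genes",
    "aggregate_fractions",
    "fraction_threshold",
    "final_candidates",
]

_AIC_TOL = 1e-8
_RSS_FLOOR = 1e-12


def _aic(y: np.ndarray, X: np.ndarray, subset: tuple) -> tuple[float, np.ndarray]:
    """Gaussian AIC of the OLS fit of y on X[:, subset] plus an intercept.

    AIC = n*log(RSS/n) + 2*(k+1); a perfect fit is floored at RSS = 1e-12
    so degenerate (collinear) inputs stay comparable instead of -inf.
    """
    n = y.size
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = max(float(resid @ resid), _RSS_FLOOR)
    return n * np.log(rss / n) + 2 * (len(subset) + 1), coef


def fit_stepwise(gene_log2, microrna_log2_matrix, candidate_ids,
                 gene_id: str = "") -> SlrAttribution:
    """Bidirectional AIC-stepwise selection starting from the full model.

    ``microrna_log2_matrix`` is (n_candidates x n_samples). At each step
    every single-variable drop and re-addition is scored; the best move is
    taken while it lowers the AIC, with exact ties (within 1e-8) broken
    toward the smaller model. Returns the selected microRNAs with their
    signed coefficients and the final model's AIC; the selection is empty
    when the intercept-only model minimizes AIC.
    """
    y = np.asarray(gene_log2, dtype=float)
    X = np.asarray(microrna_log2_matrix, dtype=float).T  # samples x candidates
    p = X.shape[1]
    if p != len(candidate_ids) or p < 1:
        raise ValueError("candidate_ids must match the matrix rows and be nonempty")
    if y.size <= p + 1:
        raise ValueError(
            f"n_samples={y.size} too small for {p} candidates (need n > p + 1)"
        )
    current = tuple(range(p))
    aic_cur, coef = _aic(y, X, current)
    while True:
        moves = []  # (aic, is_drop, subset)
        for j in current:
            sub = tuple(k for k in current if k != j)
            moves.append((_aic(y, X, sub)[0], True, sub))
        for j in range(p):
            if j not in current:
                sub = tuple(sorted(current + (j,)))
                moves.append((_aic(y, X, sub)[0], False, sub))
        if not moves:
            break
        # prefer drops on ties (smaller model), then lower AIC
        moves.sort(key=lambda m: (round(m[0] / _AIC_TOL), not m[1], m[2]))
        best_aic, best_is_drop, best_sub = moves[0]
        improves = best_aic < aic_cur - _AIC_TOL
        tie_drop = best_is_drop and best_aic <= aic_cur + _AIC_TOL
        if improves or tie_drop:
            current, (aic_cur, coef) = best_sub, (best_aic, _aic(y, X, best_sub)[1])
        else:
            break
    selected = [(candidate_ids[j], float(coef[i + 1]))
                for i, j in enumerate(current)]
    return SlrAttribution(gene=gene_id, selected=selected, aic=float(aic_cur))


def fit_signature_genes(mrna, mirna, regulons, signatures) -> dict:
    """Fit the stepwise model for every signature gene found in a regulon.

    Candidates for a gene are the microRNAs (pooled across classifiers)
    whose regulon contains it. Genes in several signatures are fitted once.
    Returns gene -> SlrAttribution.
    """
    gene_candidates: dict = {}
    for reg in regulons:
        for g in reg.genes:
            gene_candidates.setdefault(g, set()).add(reg.hub)
    sig_genes: set = set()
    for s in signatures:
        sig_genes |= s.genes
    fits = {}
    expressed = set(mrna.feature_ids)
    for g in sorted(sig_genes & set(gene_candidates) & expressed):
        cand = sorted(gene_candidates[g])
        mat = np.vstack([mirna.row(m) for m in cand])
        fits[g] = fit_stepwise(mrna.row(g), mat, cand, gene_id=g)
    return fits


def aggregate_fractions(fits: dict, signatures,
                        eligible_genes=None) -> list[MicroRnaAttribution]:
    """Aggregate per-gene selections to per-(microRNA, signature) fractions.

    fraction = (# signature genes whose selected set contains the microRNA)
    / (# signature genes eligible for modelling), split by coefficient
    sign. ``eligible_genes`` is the gene space of the expression matrix;
    signature genes outside every regulon have no model and count as
    unselected, so the fraction is on the scale of the whole signature.
    When ``eligible_genes`` is None only fitted genes enter the denominator.
    """
    mirnas = sorted({m for fit in fits.values() for m, _ in fit.selected})
    out = []
    for sig in signatures:
        if eligible_genes is None:
            denom_genes = [g for g in sig.genes if g in fits]
        else:
            denom_genes = [g for g in sig.genes if g in eligible_genes]
        if not denom_genes:
            continue
        denom = len(denom_genes)
        for m in mirnas:
            n_sel = n_neg = n_pos = 0
            for g in denom_genes:
                if g not in fits:
                    continue
                for mid, coef in fits[g].selected:
                    if mid == m:
                        n_sel += 1
                        if coef < 0:
                            n_neg += 1
                        else:
                            n_pos += 1
            out.append(MicroRnaAttribution(
                microrna=m, classifier=sig.classifier, subtype=sig.subtype,
                direction=sig.direction,
                fraction=n_sel / denom,
                fraction_negative=n_neg / denom,
                fraction_positive=n_pos / denom,
                n_genes_fit=denom,
            ))
    return out


def fraction_threshold(attributions, percentile: float = 90.0) -> float:
    """Percentile of the pooled (microRNA x signature) fraction distribution."""
    fracs = np.array([a.fraction for a in attributions], dtype=float)
    if fracs.size == 0:
        raise ValueError("no attributions to threshold")
    thr = float(np.percentile(fracs, percentile))
    if np.all(fracs == fracs[0]):
        logger.warning("all SLR fractions equal %.3f; strict threshold passes none",
                       fracs[0])
    return thr


def final_candidates(attributions, threshold: float, diffexp_results,
                     enrichment_results, mra_results) -> list[CandidateRecord]:
    """Gate the funnel: a candidate record needs survival of stages 1-3 AND
    an SLR fraction strictly above the threshold for the associated signature.

    The associated signature direction is the one that passed stage-2
    enrichment (and stage-3 MRA); ``other_signatures`` lists same-classifier
    signatures whose fraction also exceeds the threshold via SLR alone.
    """
    de_by_key = {(d.microrna, d.classifier, d.subtype): d for d in diffexp_results}
    mra_pass = {(m.microrna, m.classifier, m.subtype, m.direction)
                for m in mra_results if m.passed}
    frac_by_key = {(a.microrna, a.classifier, a.subtype, a.direction): a
                   for a in attributions}
    mra_by_key = {(m.microrna, m.classifier, m.subtype, m.direction): m
                  for m in mra_results}
    records = []
    for enr in enrichment_results:
        key = (enr.microrna, enr.classifier, enr.subtype, enr.direction)
        if key not in mra_pass:
            continue
        de = de_by_key.get((enr.microrna, enr.classifier, enr.subtype))
        attr = frac_by_key.get(key)
        if de is None or attr is None:
            continue
        if not attr.fraction > threshold:
            if attr.fraction == threshold:
                logger.info("association %s sits exactly at the fraction "
                            "threshold; excluded (strict rule)", key)
            continue
        others = sorted(
            f"{a.subtype}.{a.direction}"
            for a in attributions
            if a.microrna == enr.microrna and a.classifier == enr.classifier
            and (a.subtype, a.direction) != (enr.subtype, enr.direction)
            and a.fraction > threshold
        )
        records.append(CandidateRecord(
            microrna=enr.microrna, classifier=enr.classifier, subtype=enr.subtype,
            expression_direction=de.direction, signature_direction=enr.direction,
            slr_fraction=attr.fraction,
            opposite_direction=(de.direction != enr.direction),
            ks_p=de.ks_p, fold_change=de.fold_change,
            enrichment_p_adj=enr.p_adj, oe_ratio=enr.oe_ratio,
            mra_p=mra_by_key[key].fisher_p,
            other_signatures=others,
        ))
    return records
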