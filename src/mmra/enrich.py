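"""Stage 2 — enrichment of predicted microRNA targets in subtype signatures.

For each stage-1 microRNA the overlap between its predicted targets and the
UP/DOWN signature of the subtype where it is differential is scored with a
Bonferroni-adjusted hypergeometric upper-tail p-value and an
observed/expected ratio. Threshold pairs are calibrated per classifier with
a randomized-set FDR: random microRNA sets of the same size are drawn from
the target map and re-tested, and the grid cell minimizing FDR is chosen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import DOWN, UP, EnrichmentResult, EnrichmentThresholds, TargetMap

logger = logging.getLogger("mmra")

__all__ = [
    "hypergeom_enrichment",
    "select_enrichment_thresholds",
    "filter_by_enrichment",
]


def hypergeom_enrichment(targets, signature, universe, n_tests: int = 1,
                         microrna: str = "", classifier: str = "",
                         subtype: str = "", direction: str = UP) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of ``targets`` in ``signature``.

    Targets are intersected with the universe before testing; the signature
    must already be a subset of the universe. p_adj is Bonferroni over
    ``n_tests``; O/E divides the observed overlap by
    |targets|*|signature|/|universe|.
    """
    universe = set(universe)
    signature = set(signature)
    if not universe or not signature:
        raise ValueError("universe and signature must be nonempty")
    if not signature <= universe:
        raise ValueError("signature must be a subset of the universe")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    targets = set(targets) & universe
    k = len(targets & signature)
    n_univ, n_t, n_s = len(universe), len(targets), len(signature)
    if n_t == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, n_univ, n_s, n_t))
    expected = n_t * n_s / n_univ
    oe = k / expected if expected > 0 else 0.0
    return EnrichmentResult(
        microrna=microrna, classifier=classifier, subtype=subtype,
        direction=direction, p_raw=p, p_adj=min(1.0, p * n_tests),
        oe_ratio=float(oe), k_observed=k, n_targets=n_t,
    )


def _tests_for(diffexp_results, target_map: TargetMap, signatures, universe):
    """Enumerate the (diffexp hit, signature) tests of every classifier.

    Each stage-1 microRNA is tested against the UP and the DOWN signature of
    the subtype where it is differential. The Bonferroni family is the
    number of tests performed within the classifier.
    """
    sig_by_key = {(s.classifier, s.subtype, s.direction): s for s in signatures}
    tests = []
    for de in diffexp_results:
        for direction in (UP, DOWN):
            sig = sig_by_key.get((de.classifier, de.subtype, direction))
            if sig is None or not sig.genes & set(universe):
                continue
            tests.append((de, sig))
    return tests


def _run_tests(tests, target_map, universe):
    by_classifier: dict = {}
    for de, _sig in tests:
        by_classifier[de.classifier] = by_classifier.get(de.classifier, 0) + 1
    results = []
    for de, sig in tests:
        targets = target_map.genes(de.microrna)
        if not targets:
            logger.warning("microRNA %s has no mapped targets; enrichment auto-fails",
                           de.microrna)
        results.append(hypergeom_enrichment(
            targets, sig.genes & set(universe), universe,
            n_tests=by_classifier[de.classifier],
            microrna=de.microrna, classifier=de.classifier,
            subtype=de.subtype, direction=sig.direction,
        ))
    return results


def select_enrichment_thresholds(diffexp_results, target_map: TargetMap, signatures,
                                 universe, p_grid, oe_grid, n_iter: int = 1000,
                                 seed=None) -> EnrichmentThresholds:
    """Calibrate per-classifier (p, O/E) thresholds by randomized-set FDR.

    For each classifier and grid cell, ``n_iter`` random microRNA sets of
    the same size as the observed stage-1 set are drawn from all microRNAs
    with mapped targets and re-tested; FDR = mean random significant count /
    observed significant count. The minimizing cell is chosen per
    classifier (ties toward the less stringent pair).
    """
    rng = np.random.default_rng(seed)
    universe = set(universe)
    pool = [m for m in target_map.micrornas if target_map.genes(m) & universe]
    if not pool:
        raise ValueError("no microRNA in the target map has targets in the universe")
    tests = _tests_for(diffexp_results, target_map, signatures, universe)
    observed = _run_tests(tests, target_map, universe)

    classifiers = sorted({de.classifier for de in diffexp_results})
    rows = []
    chosen = {}
    for cls in classifiers:
        obs_cls = [r for r in observed if r.classifier == cls]
        cls_tests = [(de, sig) for de, sig in tests if de.classifier == cls]
        mirnas_cls = sorted({de.microrna for de, _ in cls_tests})
        size = len(mirnas_cls)
        # precompute random-set results: substitute random microRNAs for the
        # observed ones, keeping the (subtype, signature) test structure
        rand_sig = np.zeros((len(p_grid), len(oe_grid)), dtype=float)
        for _ in range(n_iter):
            substitute = dict(zip(
                mirnas_cls,
                rng.choice(pool, size=min(size, len(pool)), replace=False),
            ))
            rand_results = []
            for de, sig in cls_tests:
                targets = target_map.genes(substitute[de.microrna])
                rand_results.append(hypergeom_enrichment(
                    targets, sig.genes & universe, universe,
                    n_tests=len(cls_tests),
                    microrna=substitute[de.microrna], subtype=de.subtype))
            rand_sig += _count_grid(rand_results, p_grid, oe_grid)
        rand_mean = rand_sig / n_iter
        obs_counts = _count_grid(obs_cls, p_grid, oe_grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(obs_counts > 0, rand_mean / obs_counts, np.nan)
        best, best_key = None, None
        for i, p_thr in enumerate(p_grid):
            for j, oe_thr in enumerate(oe_grid):
                rows.append({"classifier": cls, "p_threshold": p_thr,
                             "oe_threshold": oe_thr,
                             "n_observed": obs_counts[i, j],
                             "mean_n_random": rand_mean[i, j],
                             "fdr": fdr[i, j]})
                key = (fdr[i, j] if np.isfinite(fdr[i, j]) else np.inf,
                       -obs_counts[i, j])
                if best is None or key < best:
                    best, best_key = key, (float(p_thr), float(oe_thr))
        chosen[cls] = best_key
    return EnrichmentThresholds(per_classifier=chosen, fdr_table=pd.DataFrame(rows))


def _count_grid(results, p_grid, oe_grid) -> np.ndarray:
    """Count distinct significant microRNAs per grid cell (a microRNA counts
    once even if both its UP and DOWN tests pass)."""
    out = np.zeros((len(p_grid), len(oe_grid)), dtype=float)
    for i, p_thr in enumerate(p_grid):
        for j, oe_thr in enumerate(oe_grid):
            hits = {(r.microrna, r.subtype) for r in results
                    if r.p_adj < p_thr and r.oe_ratio > oe_thr}
            out[i, j] = len(hits)
    return out


def filter_by_enrichment(diffexp_results, thresholds: EnrichmentThresholds,
                         target_map: TargetMap, signatures, universe
                         ) -> list[EnrichmentResult]:
    """Keep the enrichment results meeting their classifier's thresholds.

    A microRNA passes for a subtype when either the UP or the DOWN signature
    test meets both the adjusted-p and the O/E threshold; both passing
    results are emitted when both directions pass.
    """
    universe = set(universe)
    tests = _tests_for(diffexp_results, target_map, signatures, universe)
    results = _run_tests(tests, target_map, universe)
    passing = []
    for r in results:
        thr = thresholds.per_classifier.get(r.classifier)
        if thr is None:
            continue
        p_thr, oe_thr = thr
        if r.p_adj < p_thr and r.oe_ratio > oe_thr:
            passing.append(r)
    return passing
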