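"""Stage 1 — subtype-specific differential microRNA expression.

Subtype "core" samples are the confidently classified ones: nearest-template
FDR below 5% and distance-to-template delta strictly below the 95th
percentile of the pooled delta distribution. Each microRNA is then contrasted
between a subtype's core samples and all remaining samples, excluding the
low-confidence members of the test subtype from both groups. Significance
comes from a bootstrap two-sample Kolmogorov-Smirnov test combined with a
linear fold-change criterion, and the adequacy of the (p, FC) threshold pair
is quantified by a label-permutation FDR over a threshold grid.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    DOWN,
    UP,
    CoreSampleSets,
    DiffExpResult,
    ExpressionMatrix,
    FdrGridResult,
)

logger = logging.getLogger("mmra")

__all__ = [
    "select_core_samples",
    "ks_boot",
    "fold_change",
    "differential_micrornas",
    "permutation_fdr_grid",
]


def select_core_samples(records, classifier: str, fdr_max: float = 0.05,
                        delta_percentile: float = 95.0,
                        use_delta: bool = True) -> CoreSampleSets:
    """Select high-confidence subtype-core samples for one classifier.

    The delta threshold is the given percentile (linear interpolation
    between order statistics) of the pooled delta distribution of all the
    classifier's samples; a core member needs ntp_fdr < fdr_max and delta
    strictly below the threshold. ``use_delta=False`` gives trivial cores
    (FDR filter only) for two-group designs without template distances.
    """
    recs = [r for r in records if r.classifier == classifier]
    if not recs:
        raise ValueError(f"no records for classifier {classifier!r}")
    deltas = np.array([r.delta for r in recs], dtype=float)
    threshold = float(np.percentile(deltas, delta_percentile)) if use_delta else np.inf
    cores: dict = {}
    members: dict = {}
    for r in recs:
        members.setdefault(r.subtype, []).append(r.sample_id)
        if r.ntp_fdr < fdr_max and r.delta < threshold:
            cores.setdefault(r.subtype, []).append(r.sample_id)
    for subtype in members:
        if not cores.get(subtype):
            logger.warning("classifier %s subtype %s has an empty core; skipped",
                           classifier, subtype)
    cores = {s: ids for s, ids in cores.items() if ids}
    return CoreSampleSets(classifier, cores, members, threshold)


def _ks_stat_rows(values: np.ndarray, n1: int) -> np.ndarray:
    """Two-sample KS statistic for each row of ``values``.

    The first ``n1`` columns of each row are group x, the rest group y.
    Tied values are handled by evaluating the ECDF difference only at the
    last element of each tie run.
    """
    values = np.atleast_2d(values)
    b, n = values.shape
    n2 = n - n1
    order = np.argsort(values, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=1)
    is_x = (order < n1).astype(np.float64)
    cum_x = np.cumsum(is_x, axis=1)
    idx = np.arange(1, n + 1, dtype=np.float64)
    diff = np.abs(cum_x / n1 - (idx - cum_x) / n2)
    valid = np.ones((b, n), dtype=bool)
    valid[:, :-1] = sorted_vals[:, :-1] != sorted_vals[:, 1:]
    diff[~valid] = 0.0
    return diff.max(axis=1)


def ks_boot(x, y, n_boot: int = 1000, seed=None) -> float:
    """Bootstrap two-sample Kolmogorov-Smirnov p-value.

    The observed statistic D is compared with ``n_boot`` statistics obtained
    by resampling the pooled sample with replacement into groups of the
    original sizes; p = (1 + #{D_boot >= D}) / (1 + n_boot). The +1
    smoothing keeps p strictly positive, so the attainable floor is
    1/(n_boot + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    # canonical argument order makes the Monte-Carlo p exactly symmetric
    if (y.size, tuple(np.sort(y))) < (x.size, tuple(np.sort(x))):
        x, y = y, x
    d_obs = float(_ks_stat_rows(np.concatenate([x, y]), x.size)[0])
    if d_obs == 0.0:
        return 1.0
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n = pooled.size
    idx = rng.integers(0, n, size=(n_boot, n))
    d_boot = _ks_stat_rows(pooled[idx], x.size)
    return float((1 + np.count_nonzero(d_boot >= d_obs)) / (1 + n_boot))


def fold_change(x_log2, y_log2) -> float:
    """Linear fold change 2^(mean(x) - mean(y)) between log2-scale groups."""
    x = np.asarray(x_log2, dtype=float)
    y = np.asarray(y_log2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    return float(2.0 ** (x.mean() - y.mean()))


def passes_fc(fc: float, fc_thr: float) -> bool:
    """Absolute fold-change criterion: FC > t or FC < 1/t (strict)."""
    return fc > fc_thr or fc < 1.0 / fc_thr


def _contrast_columns(matrix: ExpressionMatrix, cores: CoreSampleSets, subtype: str):
    """Column indices for core-vs-rest, excluding the test subtype's
    low-confidence members from both groups."""
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    core_ids = [s for s in cores.cores.get(subtype, []) if s in col]
    exclude = set(cores.members.get(subtype, [])) - set(core_ids)
    rest_ids = [s for s in matrix.sample_ids
                if s not in exclude and s not in set(core_ids)]
    return (np.array([col[s] for s in core_ids], dtype=int),
            np.array([col[s] for s in rest_ids], dtype=int))


def _test_all(values: np.ndarray, x_idx: np.ndarray, y_idx: np.ndarray,
              n_boot: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """KS-boot p and FC for every row of ``values`` on one contrast."""
    n_feat = values.shape[0]
    ps = np.empty(n_feat)
    fcs = np.empty(n_feat)
    for i in range(n_feat):
        x = values[i, x_idx]
        y = values[i, y_idx]
        ps[i] = ks_boot(x, y, n_boot=n_boot, seed=rng)
        fcs[i] = 2.0 ** (x.mean() - y.mean())
    return ps, fcs


def differential_micrornas(mirna: ExpressionMatrix, cores: CoreSampleSets,
                           p_thr: float = 0.001, fc_thr: float = 2.0,
                           n_boot: int = 1000, seed=None) -> list[DiffExpResult]:
    """Subtype-specific differential microRNAs for one classifier.

    For each subtype, each microRNA is retained when the bootstrap KS
    p-value is below ``p_thr`` and the absolute fold change exceeds
    ``fc_thr`` in the core-vs-rest contrast.
    """
    rng = np.random.default_rng(seed)
    values = mirna.values.to_numpy(dtype=float)
    results = []
    for subtype in sorted(cores.cores):
        x_idx, y_idx = _contrast_columns(mirna, cores, subtype)
        if x_idx.size == 0 or y_idx.size == 0:
            logger.warning("subtype %s: empty contrast group, skipped", subtype)
            continue
        ps, fcs = _test_all(values, x_idx, y_idx, n_boot, rng)
        for i, mid in enumerate(mirna.feature_ids):
            if ps[i] < p_thr and passes_fc(fcs[i], fc_thr):
                results.append(DiffExpResult(
                    microrna=mid, classifier=cores.classifier, subtype=subtype,
                    ks_p=float(ps[i]), fold_change=float(fcs[i]),
                    direction=UP if fcs[i] > 1 else DOWN,
                ))
    return results


def permutation_fdr_grid(mirna: ExpressionMatrix, cores: CoreSampleSets,
                         p_grid, fc_grid, n_perm: int = 1000,
                         n_boot: int = 1000, seed=None) -> FdrGridResult:
    """Label-permutation FDR over a (p threshold, FC threshold) grid.

    For each permutation the sample columns of the microRNA matrix are
    reshuffled (labels fixed) and the stage-1 test is re-run; the FDR of a
    grid cell is the mean permuted significant count divided by the observed
    significant count (NaN when nothing is observed). The recommended pair
    is the minimum-FDR cell, ties broken toward the less stringent pair.
    """
    if len(p_grid) == 0 or len(fc_grid) == 0:
        raise ValueError("threshold grids must be nonempty")
    rng = np.random.default_rng(seed)
    values = mirna.values.to_numpy(dtype=float)
    contrasts = {s: _contrast_columns(mirna, cores, s) for s in sorted(cores.cores)}
    contrasts = {s: c for s, c in contrasts.items() if c[0].size and c[1].size}

    def counts_for(vals) -> np.ndarray:
        ps_all, fcs_all = [], []
        for x_idx, y_idx in contrasts.values():
            ps, fcs = _test_all(vals, x_idx, y_idx, n_boot, rng)
            ps_all.append(ps)
            fcs_all.append(fcs)
        ps = np.concatenate(ps_all)
        fcs = np.concatenate(fcs_all)
        out = np.zeros((len(p_grid), len(fc_grid)), dtype=float)
        for i, p_thr in enumerate(p_grid):
            for j, fc_thr in enumerate(fc_grid):
                out[i, j] = np.count_nonzero(
                    (ps < p_thr) & ((fcs > fc_thr) | (fcs < 1.0 / fc_thr))
                )
        return out

    observed = counts_for(values)
    perm_sum = np.zeros_like(observed)
    n_samples = values.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        perm_sum += counts_for(values[:, perm])
    mean_perm = perm_sum / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, mean_perm / observed, np.nan)

    rows = []
    for i, p_thr in enumerate(p_grid):
        for j, fc_thr in enumerate(fc_grid):
            rows.append({"p_threshold": p_thr, "fc_threshold": fc_thr,
                         "n_observed": observed[i, j],
                         "mean_n_permuted": mean_perm[i, j],
                         "fdr": fdr[i, j]})
    table = pd.DataFrame(rows)
    finite = table.dropna(subset=["fdr"])
    if len(finite):
        # minimum FDR; among ties prefer the least stringent (keeps more
        # candidates for the later, more specific gates)
        best = finite.sort_values(
            ["fdr", "n_observed"], ascending=[True, False], kind="stable"
        ).iloc[0]
        recommended = (float(best["p_threshold"]), float(best["fc_threshold"]))
    else:
        recommended = (float(p_grid[0]), float(fc_grid[0]))
    return FdrGridResult(table=table, recommended=recommended)
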