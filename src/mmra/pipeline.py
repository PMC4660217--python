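"""End-to-end orchestration of the four-stage candidate funnel.

``run_mmra`` executes differential expression -> target enrichment ->
regulon/MRA -> stepwise-regression attribution from one configuration,
persisting every intermediate table, a funnel report (counts at each gate)
and a JSON manifest of all thresholds and child seeds so a run is fully
auditable and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp as de_mod
from . import enrich as enrich_mod
from . import io as mio
from . import regulon as reg_mod
from . import slr as slr_mod
from .types import MraResult, NullModelSpec

logger = logging.getLogger("mmra")

__all__ = ["RunConfig", "PipelineResult", "run_mmra", "run_pipeline"]

EXIT_OK, EXIT_NO_SURVIVORS, EXIT_INPUT_ERROR = 0, 1, 2


@dataclass
class RunConfig:
    """Full-run configuration with the method's default thresholds.

    Stage 1: KS p < 0.001 and absolute FC > 2 on subtype cores (NTP FDR
    < 0.05, delta below the 95th percentile). Stage 2: per-classifier
    (p, O/E) thresholds, 'auto' = randomized-set FDR minimization. Stage 3:
    MI significance p 1e-7, 100 bootstraps, consensus p 1e-12, s.d. filter
    1.2, MRA threshold from the 95th percentile of the null model. Stage 4:
    SLR fraction above the 90th percentile.
    """

    mrna_path: str = ""
    mirna_path: str = ""
    classification_path: str = ""
    signatures_path: str = ""
    targets_path: str = ""
    out_dir: str = "mmra_out"

    core_fdr_max: float = 0.05
    core_delta_percentile: float = 95.0
    use_delta: bool = True

    ks_p_threshold: float = 0.001
    fc_threshold: float = 2.0
    ks_n_boot: int = 1000
    fdr_grid_p: tuple = (0.001, 0.01)
    fdr_grid_fc: tuple = (1.5, 2.0, 2.5)
    n_perm_fdr: int = 1000
    run_fdr_grid: bool = False  # permutation grid is costly; also via `mmra diffexp`

    enrichment_thresholds: str | dict = "auto"
    enrichment_p_grid: tuple = (0.001, 0.01, 0.05)
    enrichment_oe_grid: tuple = (1.5, 2.0, 2.5)
    n_iter_enrichment: int = 1000

    mi_p_target: float = 1e-7
    mi_n_null: int = 100_000
    n_boot_regulon: int = 100
    consensus_p: float = 1e-12
    sd_min: float = 1.2
    mra_percentile: float = 95.0
    null_model: NullModelSpec = field(default_factory=NullModelSpec)
    max_null_regulons: int | None = 15

    slr_percentile: float = 90.0

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = mio.read_config(path)
        null_raw = raw.pop("null_model", None)
        for key in ("fdr_grid_p", "fdr_grid_fc", "enrichment_p_grid",
                    "enrichment_oe_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if null_raw:
            cfg.null_model = NullModelSpec(**null_raw)
        return cfg


@dataclass
class PipelineResult:
    candidates: list
    funnel: dict
    manifest: dict
    diffexp: list = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    regulons: list = field(default_factory=list)
    mra: list = field(default_factory=list)
    attributions: list = field(default_factory=list)
    exit_code: int = EXIT_OK


def _child_seeds(master: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_pipeline(mrna, mirna, records, signatures, target_map,
                 config: RunConfig | None = None) -> PipelineResult:
    """Run the four stages on in-memory inputs and return every artifact."""
    cfg = config or RunConfig()
    seeds = _child_seeds(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "child_seeds": seeds,
                      "config": _config_dict(cfg)}
    funnel: dict = {}

    mrna, mirna, records = mio.align_paired_dataset(mrna, mirna, records)
    classifiers = sorted({r.classifier for r in records})
    universe = sorted(set(mrna.feature_ids) & target_map.gene_space)
    if not universe:
        universe = sorted(mrna.feature_ids)
    manifest["universe_size"] = len(universe)

    # ---- stage 1: differential expression --------------------------------
    all_de = []
    cores_by_classifier = {}
    for cls in classifiers:
        cores = de_mod.select_core_samples(
            records, cls, fdr_max=cfg.core_fdr_max,
            delta_percentile=cfg.core_delta_percentile, use_delta=cfg.use_delta)
        cores_by_classifier[cls] = cores
        all_de.extend(de_mod.differential_micrornas(
            mirna, cores, p_thr=cfg.ks_p_threshold, fc_thr=cfg.fc_threshold,
            n_boot=cfg.ks_n_boot, seed=seeds[0]))
        if cfg.run_fdr_grid:
            grid = de_mod.permutation_fdr_grid(
                mirna, cores, cfg.fdr_grid_p, cfg.fdr_grid_fc,
                n_perm=cfg.n_perm_fdr, n_boot=cfg.ks_n_boot, seed=seeds[5])
            manifest.setdefault("fdr_grid", {})[cls] = {
                "table": grid.table.to_dict(orient="records"),
                "recommended": list(grid.recommended),
            }
    funnel["stage1_differential"] = len({(d.microrna, d.classifier, d.subtype)
                                         for d in all_de})
    funnel["stage1_micrornas"] = len({d.microrna for d in all_de})
    result = PipelineResult([], funnel, manifest, diffexp=all_de)
    if not all_de:
        logger.warning("no differential microRNA at stage 1; pipeline stops")
        result.exit_code = EXIT_NO_SURVIVORS
        return result

    # ---- stage 2: target enrichment ---------------------------------------
    if cfg.enrichment_thresholds == "auto":
        thresholds = enrich_mod.select_enrichment_thresholds(
            all_de, target_map, signatures, universe,
            cfg.enrichment_p_grid, cfg.enrichment_oe_grid,
            n_iter=cfg.n_iter_enrichment, seed=seeds[1])
    else:
        thresholds = enrich_mod.EnrichmentThresholds(
            per_classifier=dict(cfg.enrichment_thresholds),
            fdr_table=pd.DataFrame())
    manifest["enrichment_thresholds"] = {
        k: list(v) for k, v in thresholds.per_classifier.items()}
    enr_pass = enrich_mod.filter_by_enrichment(
        all_de, thresholds, target_map, signatures, universe)
    funnel["stage2_enriched"] = len({(e.microrna, e.classifier, e.subtype)
                                     for e in enr_pass})
    result.enrichment = enr_pass
    if not enr_pass:
        logger.warning("no microRNA passed target enrichment; pipeline stops")
        result.exit_code = EXIT_NO_SURVIVORS
        return result

    # ---- stage 3: regulons + MRA ------------------------------------------
    n_samples = len(mrna.sample_ids)
    mi_thr = reg_mod.mi_significance_threshold(
        n_samples, p_target=cfg.mi_p_target, n_null=cfg.mi_n_null, seed=seeds[2])
    manifest["mi_threshold"] = mi_thr
    hubs = sorted({e.microrna for e in enr_pass})
    regulons = []
    for hub in hubs:
        pre = reg_mod.preprocess_for_network(
            mrna, mirna.row(hub), hub, sd_min=cfg.sd_min)
        regulons.append(reg_mod.build_regulon(
            pre, hub, mi_thr, n_boot=cfg.n_boot_regulon,
            consensus_p=cfg.consensus_p, seed=seeds[3]))
    result.regulons = regulons
    manifest["regulon_sizes"] = {r.hub: len(r) for r in regulons}

    null_regulons = reg_mod.build_null_model(
        mirna, list(cores_by_classifier.values()), regulons, cfg.null_model,
        mrna, mi_thr, n_boot=cfg.n_boot_regulon, consensus_p=cfg.consensus_p,
        sd_min=cfg.sd_min, seed=seeds[4], max_null=cfg.max_null_regulons)
    sig_by_key = {(s.classifier, s.subtype, s.direction): s for s in signatures}
    null_mra = [
        reg_mod.mra_test(nr, s.genes, universe, s.classifier, s.subtype, s.direction)
        for nr in null_regulons for s in signatures
    ]
    mra_thr = reg_mod.mra_threshold_from_null(
        null_mra, percentile=cfg.mra_percentile,
        fallback=cfg.null_model.fallback_mra_threshold)
    manifest["n_null_regulons"] = len(null_regulons)
    manifest["mra_threshold"] = mra_thr

    reg_by_hub = {r.hub: r for r in regulons}
    mra_results: list[MraResult] = []
    for enr in enr_pass:
        sig = sig_by_key[(enr.classifier, enr.subtype, enr.direction)]
        res = reg_mod.mra_test(reg_by_hub[enr.microrna], sig.genes, universe,
                               enr.classifier, enr.subtype, enr.direction)
        res.passed = res.fisher_p <= mra_thr
        mra_results.append(res)
    result.mra = mra_results
    funnel["stage3_mra"] = len({(m.microrna, m.classifier, m.subtype)
                                for m in mra_results if m.passed})
    if funnel["stage3_mra"] == 0:
        logger.warning("no regulon passed the MRA gate; pipeline stops")
        result.exit_code = EXIT_NO_SURVIVORS
        return result

    # ---- stage 4: SLR -------------------------------------------------------
    surviving_hubs = {m.microrna for m in mra_results if m.passed}
    fits = slr_mod.fit_signature_genes(
        mrna, mirna, [reg_by_hub[h] for h in sorted(surviving_hubs)], signatures)
    attributions = slr_mod.aggregate_fractions(
        fits, signatures, eligible_genes=set(mrna.feature_ids))
    result.attributions = attributions
    if not attributions:
        logger.warning("no signature gene could be fitted at stage 4")
        result.exit_code = EXIT_NO_SURVIVORS
        return result
    frac_thr = slr_mod.fraction_threshold(attributions, percentile=cfg.slr_percentile)
    manifest["slr_fraction_threshold"] = frac_thr
    candidates = slr_mod.final_candidates(
        attributions, frac_thr, all_de, enr_pass, mra_results)
    funnel["stage4_final"] = len(candidates)
    result.candidates = candidates
    if not candidates:
        result.exit_code = EXIT_NO_SURVIVORS
    return result


def run_mmra(config: RunConfig) -> PipelineResult:
    """Load inputs from the configured paths, run the funnel, persist outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mrna, mirna, records = mio.load_paired_dataset(
        config.mrna_path, config.mirna_path, config.classification_path)
    signatures = mio.load_signatures(config.signatures_path, style="gmt")
    target_map = mio.read_target_map(config.targets_path)
    result = run_pipeline(mrna, mirna, records, signatures, target_map, config)
    persist_result(result, out)
    return result


def persist_result(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _df([{"microrna": d.microrna, "classifier": d.classifier, "subtype": d.subtype,
          "ks_p": d.ks_p, "fold_change": d.fold_change, "direction": d.direction}
         for d in result.diffexp]).to_csv(out / "diffexp.tsv", sep="\t", index=False)
    _df([{"microrna": e.microrna, "classifier": e.classifier, "subtype": e.subtype,
          "direction": e.direction, "p_raw": e.p_raw, "p_adj": e.p_adj,
          "oe_ratio": e.oe_ratio, "k_observed": e.k_observed}
         for e in result.enrichment]).to_csv(out / "enrichment.tsv", sep="\t",
                                             index=False)
    edges = [{"hub": r.hub, "gene": g, "mi": mi, "support": sup, "support_p": sp}
             for r in result.regulons for g, (mi, sup, sp) in sorted(r.edges.items())]
    _df(edges).to_csv(out / "regulons.tsv", sep="\t", index=False)
    _df([{"microrna": m.microrna, "classifier": m.classifier, "subtype": m.subtype,
          "direction": m.direction, "overlap": m.overlap, "fisher_p": m.fisher_p,
          "passed": m.passed}
         for m in result.mra]).to_csv(out / "mra.tsv", sep="\t", index=False)
    _df([{"microrna": a.microrna, "classifier": a.classifier, "subtype": a.subtype,
          "direction": a.direction, "fraction": a.fraction,
          "fraction_negative": a.fraction_negative,
          "fraction_positive": a.fraction_positive, "n_genes_fit": a.n_genes_fit}
         for a in result.attributions]).to_csv(out / "slr_fractions.tsv", sep="\t",
                                               index=False)
    _df([{"microrna": c.microrna, "classifier": c.classifier, "subtype": c.subtype,
          "expression_direction": c.expression_direction,
          "signature_direction": c.signature_direction,
          "slr_fraction": c.slr_fraction,
          "opposite_direction": c.opposite_direction, "ks_p": c.ks_p,
          "fold_change": c.fold_change, "enrichment_p_adj": c.enrichment_p_adj,
          "oe_ratio": c.oe_ratio, "mra_p": c.mra_p,
          "other_signatures": ";".join(c.other_signatures)}
         for c in result.candidates]).to_csv(out / "candidates.tsv", sep="\t",
                                             index=False)
    with open(out / "funnel.json", "w") as fh:
        json.dump(result.funnel, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)


def _df(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["null_model"] = dataclasses.asdict(cfg.null_model)
    return d
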