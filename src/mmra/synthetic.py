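"""Paired mRNA-microRNA dataset simulator with planted driver microRNAs.

The generator emulates the structure the pipeline is designed to detect: a
cohort partitioned into transcriptional subtypes, where each planted driver
microRNA is downregulated in one subtype and its predicted target genes —
members of that subtype's UP signature — follow the microRNA with a
negative regression slope. Everything else is subtype-independent (decoy
microRNAs, non-signature genes) or subtype-shifted but microRNA-independent
(the remaining signature genes), so each pipeline gate has both true and
null material to act on.

All values are on the log2 scale with Gaussian noise; the simulator makes
no attempt at RNA-seq count realism (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .types import (
    DOWN,
    UP,
    ClassificationRecord,
    ExpressionMatrix,
    SubtypeSignature,
    TargetMap,
)

__all__ = ["SimConfig", "simulate_dataset", "write_dataset"]

CLASSIFIER = "SIM"


@dataclass
class SimConfig:
    """Simulation parameters.

    The defaults are the reference study conditions used throughout the
    test suite: 3 subtypes x 60 samples, 2 planted drivers shifted down by
    1.5 log2 units in their subtype, target genes tied to the driver with
    slope -0.8 and residual s.d. 0.5.
    """

    n_subtypes: int = 3
    n_samples_per_subtype: int = 60
    n_genes: int = 600
    n_micrornas: int = 60
    n_driver_micrornas: int = 2
    driver_shift: float = -1.5       # log2 mean shift of a driver in its subtype
    target_slope: float = -0.8       # regression slope of target genes on the driver
    noise_sd: float = 0.5            # residual s.d. of target genes
    n_targets_in_signature: int = 30
    n_targets_off_signature: int = 20
    n_decoy_targets: int = 50
    up_signature_size: int = 80
    down_signature_size: int = 40
    signature_shift: float = 1.0     # log2 subtype shift of non-target signature genes
    mirna_sd: float = 1.5            # per-sample s.d. of microRNA expression
    low_confidence_fraction: float = 0.10
    seed: int = 7

    def __post_init__(self):
        counts = (self.n_subtypes, self.n_samples_per_subtype, self.n_genes,
                  self.n_micrornas, self.n_driver_micrornas)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.noise_sd <= 0 or self.mirna_sd <= 0:
            raise ValueError("noise s.d. must be > 0")
        if self.n_targets_in_signature > self.up_signature_size:
            raise ValueError("more driver targets requested than UP-signature genes")
        if self.n_driver_micrornas > self.n_micrornas:
            raise ValueError("more drivers than microRNAs")


def simulate_dataset(config: SimConfig):
    """Generate a paired dataset with planted drivers.

    Returns (mrna, mirna, classification records, signatures, target map,
    truth manifest). The manifest records the seed, the planted drivers,
    their subtypes and target genes. Identical seeds give bit-identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_subtypes * cfg.n_samples_per_subtype
    subtypes = [f"ST{i + 1}" for i in range(cfg.n_subtypes)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    sample_subtype = np.repeat(np.arange(cfg.n_subtypes), cfg.n_samples_per_subtype)

    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    mirna_ids = [f"MIR{i + 1:03d}" for i in range(cfg.n_micrornas)]

    # --- signatures: disjoint UP/DOWN gene blocks per subtype -------------
    per_subtype = cfg.up_signature_size + cfg.down_signature_size
    if per_subtype * cfg.n_subtypes > cfg.n_genes:
        raise ValueError("n_genes too small for the requested signature sizes")
    signatures = []
    up_sets, down_sets = [], []
    for s in range(cfg.n_subtypes):
        start = s * per_subtype
        up = gene_ids[start:start + cfg.up_signature_size]
        down = gene_ids[start + cfg.up_signature_size:start + per_subtype]
        up_sets.append(up)
        down_sets.append(down)
        signatures.append(SubtypeSignature(CLASSIFIER, subtypes[s], UP, frozenset(up)))
        signatures.append(SubtypeSignature(CLASSIFIER, subtypes[s], DOWN, frozenset(down)))

    # --- microRNA matrix ---------------------------------------------------
    mirna_base = rng.uniform(2.0, 8.0, size=cfg.n_micrornas)
    mirna_vals = (mirna_base[:, None]
                  + rng.normal(0.0, cfg.mirna_sd, size=(cfg.n_micrornas, n_samples)))
    driver_idx = np.arange(cfg.n_driver_micrornas)
    driver_subtype = driver_idx % cfg.n_subtypes
    for d, s in zip(driver_idx, driver_subtype):
        mirna_vals[d, sample_subtype == s] += cfg.driver_shift

    # --- mRNA matrix -------------------------------------------------------
    gene_base = rng.uniform(4.0, 10.0, size=cfg.n_genes)
    gene_sd = rng.uniform(0.8, 2.2, size=cfg.n_genes)
    mrna_vals = (gene_base[:, None]
                 + gene_sd[:, None] * rng.normal(size=(cfg.n_genes, n_samples)))

    # non-target signature genes are shifted in their subtype, independent of
    # any microRNA; driver targets are overwritten below
    for s in range(cfg.n_subtypes):
        in_s = sample_subtype == s
        for g in up_sets[s]:
            mrna_vals[gene_ids.index(g), in_s] += cfg.signature_shift
        for g in down_sets[s]:
            mrna_vals[gene_ids.index(g), in_s] -= cfg.signature_shift

    # --- planted driver targets and the target map -------------------------
    targets: dict = {}
    truth_targets: dict = {}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    off_signature_pool = [g for g in gene_ids
                          if all(g not in u for u in up_sets)
                          and all(g not in dn for dn in down_sets)]
    for d, s in zip(driver_idx, driver_subtype):
        mid = mirna_ids[d]
        sig_targets = list(rng.choice(up_sets[s], size=cfg.n_targets_in_signature,
                                      replace=False))
        off_targets = list(rng.choice(off_signature_pool,
                                      size=cfg.n_targets_off_signature, replace=False))
        planted = sig_targets + off_targets
        m = mirna_vals[d]
        m_centered = m - m.mean()
        for g in planted:
            i = gene_pos[g]
            mrna_vals[i] = (gene_base[i]
                            + cfg.target_slope * m_centered
                            + rng.normal(0.0, cfg.noise_sd, size=n_samples))
        targets[mid] = set(planted)
        truth_targets[mid] = {"subtype": subtypes[s], "targets": sorted(planted)}

    for j in range(cfg.n_driver_micrornas, cfg.n_micrornas):
        targets[mirna_ids[j]] = set(
            rng.choice(gene_ids, size=min(cfg.n_decoy_targets, cfg.n_genes),
                       replace=False)
        )
    provenance = {(m, g): (2, False) for m, gs in targets.items() for g in gs}
    target_map = TargetMap(targets, provenance)

    # --- classification records --------------------------------------------
    ntp_fdr = rng.uniform(0.0, 0.045, size=n_samples)
    low_conf = rng.random(n_samples) < cfg.low_confidence_fraction
    ntp_fdr[low_conf] = rng.uniform(0.05, 0.20, size=int(low_conf.sum()))
    # scaled Beta keeps delta in [0,1) with a long right tail so the
    # 95th-percentile core rule is exercised
    delta = rng.beta(2.0, 5.0, size=n_samples)
    records = [
        ClassificationRecord(sample_ids[i], CLASSIFIER, subtypes[sample_subtype[i]],
                             float(ntp_fdr[i]), float(delta[i]))
        for i in range(n_samples)
    ]

    mrna = ExpressionMatrix(pd.DataFrame(mrna_vals, index=gene_ids, columns=sample_ids))
    mirna = ExpressionMatrix(pd.DataFrame(mirna_vals, index=mirna_ids, columns=sample_ids))
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "classifier": CLASSIFIER,
        "subtypes": subtypes,
        "drivers": truth_targets,
    }
    return mrna, mirna, records, signatures, target_map, manifest


def write_dataset(config: SimConfig, out_dir) -> dict:
    """Simulate and write the dataset in the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mrna, mirna, records, signatures, tmap, manifest = simulate_dataset(config)
    mio.write_expression_matrix(mrna, out / "mrna.tsv")
    mio.write_expression_matrix(mirna, out / "mirna.tsv")
    mio.write_classification(records, out / "classification.tsv")
    mio.write_gmt(signatures, out / "signatures.gmt")
    mio.write_target_map(tmap, out / "targets.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
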