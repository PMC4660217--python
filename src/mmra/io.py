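"""Readers and writers for the pipeline's tabular formats.

Expression matrices, classification tables, target maps and stage outputs
travel as TSV with a header row; signatures travel either as GMT or as the
two per-gene score-table styles used by the published subtype classifiers;
run configuration is YAML. All identifier matching is exact string match
after upper-casing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    DOWN,
    UP,
    ClassificationRecord,
    ExpressionMatrix,
    SubtypeSignature,
    TargetMap,
)

logger = logging.getLogger("mmra")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_classification",
    "write_classification",
    "load_paired_dataset",
    "load_signatures",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_target_map",
    "combine_target_predictions",
    "read_config",
    "setup_logging",
]


def setup_logging(logfile=None, level=logging.INFO):
    """Structured log to stderr and, optionally, a file."""
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
    return logger


def _norm_id(x) -> str:
    return str(x).strip().upper()


def read_expression_matrix(path, nan_policy: str = "error") -> ExpressionMatrix:
    """Read a features x samples TSV (first column = feature ids).

    nan_policy: 'error' (default) rejects any missing cell; 'drop_feature'
    removes rows containing missing values and logs them.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = [_norm_id(i) for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    if df.isna().to_numpy().any():
        if nan_policy == "drop_feature":
            bad = df.index[df.isna().any(axis=1)].tolist()
            logger.warning("dropping %d features with missing values: %s",
                           len(bad), bad[:5])
            df = df.dropna(axis=0)
        else:
            raise ValueError(f"{path}: missing values (nan_policy='error')")
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_classification(path) -> list[ClassificationRecord]:
    """Read (sample, classifier, subtype, fdr, delta) records from TSV."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"sample", "classifier", "subtype", "fdr", "delta"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: classification table needs columns {sorted(required)}")
    records = [
        ClassificationRecord(
            sample_id=str(r["sample"]).strip(),
            classifier=str(r["classifier"]).strip(),
            subtype=str(r["subtype"]).strip(),
            ntp_fdr=float(r["fdr"]),
            delta=float(r["delta"]),
        )
        for _, r in df.iterrows()
    ]
    seen = set()
    for rec in records:
        key = (rec.sample_id, rec.classifier)
        if key in seen:
            raise ValueError(f"duplicate classification record for {key}")
        seen.add(key)
    return records


def write_classification(records, path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "classifier": r.classifier,
                "subtype": r.subtype,
                "fdr": r.ntp_fdr,
                "delta": r.delta,
            }
            for r in records
        ]
    ).sort_values(["classifier", "sample"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def load_paired_dataset(mrna_path, mirna_path, classification_path,
                        nan_policy: str = "error"):
    """Load and sample-align the paired mRNA/microRNA matrices and labels.

    The three sample sets are intersected; the survivors are ordered
    identically (mRNA column order) in all returned objects, and dropped
    samples are logged. An empty intersection is a hard error.
    """
    mrna = read_expression_matrix(mrna_path, nan_policy)
    mirna = read_expression_matrix(mirna_path, nan_policy)
    records = read_classification(classification_path)
    return align_paired_dataset(mrna, mirna, records)


def align_paired_dataset(mrna: ExpressionMatrix, mirna: ExpressionMatrix, records):
    """Intersect and co-order samples across the three inputs (in-memory)."""
    classified = {r.sample_id for r in records}
    shared = [s for s in mrna.sample_ids
              if s in set(mirna.sample_ids) and s in classified]
    if not shared:
        raise ValueError("no samples shared by the mRNA, microRNA and classification inputs")
    dropped = (set(mrna.sample_ids) | set(mirna.sample_ids) | classified) - set(shared)
    if dropped:
        logger.info("dropped %d unpaired/unclassified samples: %s",
                    len(dropped), sorted(dropped)[:5])
    keep = set(shared)
    records = [r for r in records if r.sample_id in keep]
    return mrna.subset_samples(shared), mirna.subset_samples(shared), records


def read_gmt(path) -> list[SubtypeSignature]:
    """Read signatures from GMT; set name encodes CLASSIFIER.SUBTYPE.DIRECTION."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        name, _desc, genes = fields[0], fields[1], fields[2:]
        parts = name.split(".")
        if len(parts) != 3 or parts[2] not in (UP, DOWN):
            raise ValueError(f"GMT set name {name!r} is not CLASSIFIER.SUBTYPE.UP|DOWN")
        sigs.append(
            SubtypeSignature(parts[0], parts[1], parts[2],
                             frozenset(_norm_id(g) for g in genes if g))
        )
    _check_disjoint(sigs)
    return sigs


def write_gmt(signatures, path) -> None:
    with open(path, "w") as fh:
        for s in sorted(signatures, key=lambda s: s.name):
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\tna\t{genes}\n")


def _check_disjoint(signatures) -> None:
    by_key = {}
    for s in signatures:
        by_key.setdefault((s.classifier, s.subtype), {})[s.direction] = s.genes
    for (cls, sub), d in by_key.items():
        both = d.get(UP, frozenset()) & d.get(DOWN, frozenset())
        if both:
            raise ValueError(
                f"genes listed both UP and DOWN for {cls}/{sub}: {sorted(both)[:5]}"
            )


def load_signatures(path, style: str, classifier: str | None = None,
                    subtype: str | None = None) -> list[SubtypeSignature]:
    """Load subtype signatures.

    style='gmt' reads a GMT file directly. The two score-table styles read
    a per-gene TSV for one (classifier, subtype):

    - style='pam'   : columns (gene, score); UP = score > 0, DOWN = score < 0.
    - style='fc'    : columns (gene, log2fc, adj_p); UP = log2FC > 0.5 and
      adjusted p < 0.05, DOWN = log2FC < -0.5 and adjusted p < 0.05.
    """
    if style == "gmt":
        return read_gmt(path)
    if classifier is None or subtype is None:
        raise ValueError("score-table styles need classifier and subtype")
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    genes = df.iloc[:, 0].map(_norm_id)
    if style == "pam":
        score = df.iloc[:, 1].astype(float)
        up = frozenset(genes[score > 0])
        down = frozenset(genes[score < 0])
    elif style == "fc":
        if not {"log2fc", "adj_p"} <= set(df.columns):
            raise ValueError("fc style needs columns log2fc and adj_p")
        lfc = df["log2fc"].astype(float)
        adjp = df["adj_p"].astype(float)
        up = frozenset(genes[(lfc > 0.5) & (adjp < 0.05)])
        down = frozenset(genes[(lfc < -0.5) & (adjp < 0.05)])
    else:
        raise ValueError(f"unknown signature style {style!r}")
    sigs = [
        SubtypeSignature(classifier, subtype, UP, up),
        SubtypeSignature(classifier, subtype, DOWN, down),
    ]
    _check_disjoint(sigs)
    return sigs


def read_target_map(path) -> TargetMap:
    """Read a prebuilt target map TSV (microrna, gene[, n_databases, validated])."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    targets: dict = {}
    provenance = {}
    for _, r in df.iterrows():
        m, g = _norm_id(r.iloc[0]), _norm_id(r.iloc[1])
        targets.setdefault(m, set()).add(g)
        n_db = int(r["n_databases"]) if "n_databases" in df.columns else 2
        validated = bool(r["validated"]) if "validated" in df.columns else False
        provenance[(m, g)] = (n_db, validated)
    return TargetMap(targets, provenance)


def write_target_map(tmap: TargetMap, path) -> None:
    rows = []
    for m in tmap.micrornas:
        for g in sorted(tmap.targets[m]):
            n_db, validated = tmap.provenance.get((m, g), (2, False))
            rows.append({"microrna": m, "gene": g,
                         "n_databases": n_db, "validated": validated})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def combine_target_predictions(per_database_tables, validated_table=None) -> TargetMap:
    """Combine per-database (microRNA, gene) prediction lists into a TargetMap.

    A pair is retained when at least two databases predict it; every
    validated pair is added unconditionally. The result is invariant to the
    order of the input tables.
    """
    if len(per_database_tables) < 2:
        raise ValueError("need at least two prediction tables (or a prebuilt map)")
    counts: dict = {}
    for table in per_database_tables:
        pairs = {( _norm_id(m), _norm_id(g)) for m, g in _iter_pairs(table)}
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
    validated = set()
    if validated_table is not None:
        validated = {(_norm_id(m), _norm_id(g)) for m, g in _iter_pairs(validated_table)}
    targets: dict = {}
    provenance = {}
    for pair, n in counts.items():
        if n >= 2 or pair in validated:
            targets.setdefault(pair[0], set()).add(pair[1])
            provenance[pair] = (n, pair in validated)
    for pair in validated - set(provenance):
        targets.setdefault(pair[0], set()).add(pair[1])
        provenance[pair] = (counts.get(pair, 0), True)
    return TargetMap(targets, provenance)


def _iter_pairs(table):
    if isinstance(table, pd.DataFrame):
        return list(table.iloc[:, :2].itertuples(index=False, name=None))
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t")
        return list(df.iloc[:, :2].itertuples(index=False, name=None))
    return list(table)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
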