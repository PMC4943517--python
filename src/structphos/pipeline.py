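"""End-to-end workflow: structures -> feature matrix -> selection -> model.

This module is the library face of the command-line tool.  ``extract_features``
turns parsed structures plus annotation/external tables into the labelled
153-column feature matrix; ``select_features``, ``train_model``, ``predict``
and ``evaluate_predictions`` wrap the selection, ensemble and evaluation
modules with file-friendly inputs and reproducibility manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import structphos
from structphos.dataset import (
    enumerate_candidates,
    read_annotations,
    select_negatives,
)
from structphos.ensemble import (
    EnsembleModel,
    asymmetric_bootstrap,
    predict_vote,
    train_ensemble,
)
from structphos.errors import StructphosError
from structphos.evaluation import confusion, metric_set, roc_auc
from structphos.fourbody import train_four_body_table
from structphos.neighborhood_features import FULL_COLUMNS, full_feature_frame
from structphos.selection import mdgi_rank, sbe_select
from structphos.site_features import (
    EXTERNAL_NAMES,
    FeatureContext,
    assemble_site_vector,
)
from structphos.structure import ProteinStructure, parse_structure

log = logging.getLogger(__name__)

KEY_COLUMNS = ["pdb_id", "chain", "seq_num", "residue_type"]


@dataclass
class ExtractConfig:
    cutoff: float = 10.0
    max_edge: float | None = None
    rel_asa_threshold: float = 0.05
    negatives_accessible: bool = False
    fourbody_typing: str = "single"
    normalize_neighborhoods: bool = False


def load_structures(pdb_dir) -> list[ProteinStructure]:
    paths = sorted(Path(pdb_dir).glob("*.pdb"))
    if not paths:
        raise StructphosError(f"no .pdb files under {pdb_dir}")
    return [parse_structure(p.read_text(), pdb_id=p.stem) for p in paths]


def read_annotations_checked(path) -> pd.DataFrame:
    ann = read_annotations(path)
    if len(ann) == 0:
        raise StructphosError("annotation table is empty")
    return ann


def read_external_tables(path) -> dict[str, dict]:
    """External feature TSV -> per-structure residue maps.

    With a ``pdb_id`` column the table is split per structure; without one
    the same map applies to every structure (single-structure projects).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["chain", "seq_num"] + EXTERNAL_NAMES if c not in df.columns]
    if missing:
        from structphos.errors import SchemaError

        raise SchemaError(f"external feature table missing columns: {missing}")

    def to_map(sub: pd.DataFrame) -> dict:
        return {
            (str(r["chain"]), str(r["seq_num"])): {n: float(r[n]) for n in EXTERNAL_NAMES}
            for _, r in sub.iterrows()
        }

    if "pdb_id" in df.columns:
        return {str(pid): to_map(sub) for pid, sub in df.groupby("pdb_id")}
    return {"*": to_map(df)}


def external_column_means(tables: dict[str, dict]) -> dict[str, float]:
    rows = [v for table in tables.values() for v in table.values()]
    if not rows:
        return {}
    return {n: float(np.mean([r[n] for r in rows])) for n in EXTERNAL_NAMES}


def extract_features(
    structures: list[ProteinStructure],
    annotations: pd.DataFrame | None = None,
    external: dict[str, dict] | None = None,
    config: ExtractConfig | None = None,
) -> pd.DataFrame:
    """Labelled 153-column feature matrix over candidate S/T/Y sites.

    The four-body table is trained on the input structures themselves.
    Site vectors are computed for every residue (neighborhood sums need
    them); rows are emitted only for candidates labelled positive or
    negative, with exclusions logged.
    """
    cfg = config or ExtractConfig()
    if not structures:
        raise StructphosError("no structures supplied")
    table = train_four_body_table(
        structures, typing=cfg.fourbody_typing, max_edge=cfg.max_edge
    )
    imputation = external_column_means(external) if external else {}
    rows = []
    n_excluded = 0
    for s in structures:
        ext = None
        if external:
            ext = external.get(s.pdb_id, external.get("*"))
        ctx = FeatureContext.build(
            s, fourbody_table=table, external=ext,
            cutoff=cfg.cutoff, max_edge=cfg.max_edge,
        )
        site_values = {
            r.key: assemble_site_vector(r, ctx, imputation=imputation)
            for r in s.residues()
        }
        candidates = enumerate_candidates(s, annotations)
        rel_asa = {c.key: site_values[c.residue.key].values["asa_rel"] for c in candidates}
        select_negatives(
            candidates,
            rel_asa,
            rel_asa_threshold=cfg.rel_asa_threshold,
            negatives_accessible=cfg.negatives_accessible,
        )
        keep = [c for c in candidates if c.label in ("positive", "negative")]
        n_excluded += sum(1 for c in candidates if c.label == "excluded")
        if not keep:
            continue
        feats = full_feature_frame(
            [c.residue.key for c in keep],
            ctx.egraph,
            ctx.vgraph,
            site_values,
            normalize=cfg.normalize_neighborhoods,
        )
        for c, (_, frow) in zip(keep, feats.iterrows()):
            row = {
                "pdb_id": s.pdb_id,
                "chain": c.residue.chain_id,
                "seq_num": c.residue.seq_num,
                "residue_type": c.residue_type,
                "label": 1 if c.label == "positive" else 0,
                "kinase_family": c.kinase_family or "",
                "deposit_date": c.deposit_date or "",
            }
            row.update(frow.to_dict())
            rows.append(row)
    if not rows:
        raise StructphosError("feature extraction produced zero labelled sites")
    log.info("extracted %d labelled sites (%d excluded)", len(rows), n_excluded)
    df = pd.DataFrame(rows)
    return df[KEY_COLUMNS + ["label", "kinase_family", "deposit_date"] + FULL_COLUMNS]


def split_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    meta = KEY_COLUMNS + ["label", "kinase_family", "deposit_date"]
    feature_cols = [c for c in df.columns if c not in meta]
    return df[feature_cols], df["label"].to_numpy().astype(int)


def select_features(
    matrix: pd.DataFrame,
    top_m: int = 80,
    k: int = 1,
    seed: int = 0,
    n_trees: int = 500,
    skip_sbe: bool = False,
) -> dict:
    """Two-step selection on a labelled matrix; returns a JSON-able report."""
    X, y = split_matrix(matrix)
    ranking = mdgi_rank(X, y, n_trees=n_trees, seed=seed, top_m=top_m)
    result = {
        "top_m": len(ranking.retained),
        "ranking": ranking.table.to_dict(orient="records"),
        "retained": ranking.retained,
    }
    if skip_sbe:
        result["selected"] = ranking.retained
        return result
    trace = sbe_select(X[ranking.retained], y, k=k, seed=seed)
    result["selected"] = trace.best_subset
    result["best_rc"] = trace.best_rc
    result["sbe_steps"] = [
        {"removed": f, "rc": rc} for f, rc in trace.steps
    ]
    return result


def train_model(
    matrix: pd.DataFrame,
    selected: list[str],
    n: int = 5,
    seed: int = 0,
    svm_config: dict | None = None,
) -> EnsembleModel:
    X, y = split_matrix(matrix)
    plan = asymmetric_bootstrap(y, n=n, seed=seed)
    return train_ensemble(
        X[selected].values, y, plan, svm_config=svm_config, feature_names=selected
    )


def predict(model: EnsembleModel, matrix: pd.DataFrame) -> pd.DataFrame:
    X, _ = split_matrix(matrix)
    labels, fractions = predict_vote(model, X[model.feature_names].values)
    out = matrix[[c for c in KEY_COLUMNS if c in matrix.columns]].copy()
    out["vote_fraction"] = fractions
    out["label"] = labels
    return out


def evaluate_predictions(pred: pd.DataFrame, truth: pd.DataFrame) -> dict:
    merged = pred.merge(
        truth[KEY_COLUMNS + ["label"]].rename(columns={"label": "true_label"}),
        on=KEY_COLUMNS,
        validate="one_to_one",
    )
    m = metric_set(confusion(merged["true_label"], merged["label"]))
    report = m.as_dict()
    if merged["true_label"].nunique() == 2:
        report["auc"] = roc_auc(merged["vote_fraction"], merged["true_label"])
    report["n_sites"] = int(len(merged))
    return report


# --------------------------------------------------------------------------
# Reproducibility manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_path, config: dict, outputs: list) -> Path:
    """Config hash, seeds and output checksums, enough to verify a re-run."""
    config_json = json.dumps(config, sort_keys=True, default=str)
    doc = {
        "package_version": structphos.__version__,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {str(p): _sha256(p) for p in outputs},
    }
    manifest_path = Path(str(out_path))
    manifest_path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return manifest_path


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"chain": str, "seq_num": str})
    if "kinase_family" in df.columns:
        df["kinase_family"] = df["kinase_family"].fillna("")
    if "deposit_date" in df.columns:
        df["deposit_date"] = df["deposit_date"].fillna("")
    return df
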