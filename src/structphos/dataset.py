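"""Candidate-site enumeration, positive/negative labelling and splits.

Every serine, threonine or tyrosine residue is a candidate site.
Candidates present in the annotation table are positives.  Negatives must
(1) not be annotated positive anywhere, (2) sit in a protein that contains
at least one positive, and (3) be solvent-inaccessible (relative ASA below
a threshold, 0.05 by default).  Criterion (3) is biologically surprising --
kinases act on exposed residues -- so the opposite direction is available
behind the ``negatives_accessible`` flag; the stated direction is the
default.  Train/test splitting is by annotation deposit date.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from structphos.structure import ProteinStructure, Residue

log = logging.getLogger(__name__)

STY = {"S", "T", "Y"}

ANNOTATION_COLUMNS = [
    "pdb_id", "chain", "seq_num", "residue_type", "kinase_family", "deposit_date",
]


@dataclass
class CandidateSite:
    structure: ProteinStructure
    residue: Residue
    residue_type: str
    label: str = "unlabelled"  # positive | negative | excluded | unlabelled
    kinase_family: str | None = None
    deposit_date: str | None = None
    exclusion_reason: str | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.structure.pdb_id, self.residue.chain_id, self.residue.seq_num)


def read_annotations(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    return df


def enumerate_candidates(
    s: ProteinStructure, annotations: pd.DataFrame | None = None
) -> list[CandidateSite]:
    """One candidate per S/T/Y residue; annotated ones labelled positive."""
    ann_index: dict[tuple[str, str], dict] = {}
    if annotations is not None and len(annotations):
        sub = annotations[annotations["pdb_id"].astype(str) == s.pdb_id]
        for _, row in sub.iterrows():
            ann_index[(str(row["chain"]), str(row["seq_num"]))] = row.to_dict()
    out: list[CandidateSite] = []
    for r in s.residues():
        if r.aa not in STY:
            continue
        cand = CandidateSite(structure=s, residue=r, residue_type=r.aa)
        ann = ann_index.get(r.key)
        if ann is not None:
            if ann.get("residue_type") and ann["residue_type"] != r.aa:
                log.warning("annotation residue_type mismatch at %s", r.key)
            cand.label = "positive"
            cand.kinase_family = ann.get("kinase_family") or None
            cand.deposit_date = ann.get("deposit_date") or None
        out.append(cand)
    return out


def select_negatives(
    candidates: list[CandidateSite],
    rel_asa: dict[tuple[str, str, str], float],
    rel_asa_threshold: float = 0.05,
    negatives_accessible: bool = False,
) -> list[CandidateSite]:
    """Label unannotated candidates negative or excluded (criteria 1-3).

    ``rel_asa`` maps (pdb_id, chain, seq_num) to relative solvent
    accessibility.  The default keeps the stated direction -- negatives must
    be solvent-inaccessible (relative ASA below the threshold);
    ``negatives_accessible=True`` inverts criterion (3).
    """
    proteins_with_positives = {
        c.structure.pdb_id for c in candidates if c.label == "positive"
    }
    for c in candidates:
        if c.label == "positive":
            continue  # criterion (1): annotated positives are never negatives
        if c.structure.pdb_id not in proteins_with_positives:
            c.label = "excluded"
            c.exclusion_reason = "protein has no known positive site"
            continue
        if c.key not in rel_asa:
            raise KeyError(f"no relative ASA for candidate {c.key}")
        accessible = rel_asa[c.key] >= rel_asa_threshold
        wanted_accessible = negatives_accessible
        if accessible == wanted_accessible:
            c.label = "negative"
        else:
            c.label = "excluded"
            c.exclusion_reason = (
                f"relative ASA {rel_asa[c.key]:.3f} fails the "
                f"{'accessibility' if wanted_accessible else 'inaccessibility'} criterion"
            )
    return candidates


def split_by_date(
    candidates: list[CandidateSite], boundary_year: int = 2008
) -> tuple[list[CandidateSite], list[CandidateSite]]:
    """Deposit dates before the boundary year go to train, the rest to test.

    Sites without a date fall into the training split with a warning.
    """
    train: list[CandidateSite] = []
    test: list[CandidateSite] = []
    undated = 0
    for c in candidates:
        if not c.deposit_date:
            undated += 1
            train.append(c)
            continue
        year = int(str(c.deposit_date)[:4])
        (train if year < boundary_year else test).append(c)
    if undated:
        warnings.warn(f"{undated} candidate sites lack deposit dates; kept in train")
    return train, test


def subset_by_kinase(
    candidates: list[CandidateSite], family: str
) -> list[CandidateSite]:
    """Positives of one kinase family plus all negatives."""
    return [
        c
        for c in candidates
        if c.label != "positive" or (c.kinase_family or "").upper() == family.upper()
    ]
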