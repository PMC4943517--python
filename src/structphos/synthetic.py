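"""Synthetic fixtures: toy structures, planted-signal datasets, streams.

Everything the tests and the demo pipeline need is generated here, offline:

* ``synth_structure`` -- a self-avoiding CA chain with realistic consecutive
  spacing (3.8 +/- 0.1 Angstrom) and one pseudo side-chain atom per residue,
  with serine/threonine/tyrosine enriched to 20 % of residues so candidate
  sites are plentiful.
* ``synth_dataset`` -- a labelled feature matrix with standard-normal noise
  columns and a configurable number of planted informative columns whose
  class means differ by an effect size delta, at a configurable class
  imbalance.  This is the ground-truth generator for feature-selection
  recovery and ensemble behaviour.
* ``expected_composition_stream`` -- residue-quadruplet streams whose
  composition counts equal (or are boosted away from) their exact
  multinomial expectation, for calibrating the four-body potential.
* ``write_fixture_project`` -- a small on-disk project (PDB, FASTA,
  annotation TSV, external-feature TSV) for end-to-end runs.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from structphos.fourbody import canonical_quad, multiset_multiplicity
from structphos.site_features import EXTERNAL_NAMES
from structphos.structure import _ONE_TO_THREE, Atom, ProteinStructure, Residue

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STY = "STY"
_OTHER = [a for a in AA20 if a not in _STY]


def _random_letters(rng: np.random.Generator, n: int, sty_fraction: float = 0.2) -> list[str]:
    letters = []
    for _ in range(n):
        if rng.random() < sty_fraction:
            letters.append(_STY[rng.integers(len(_STY))])
        else:
            letters.append(_OTHER[rng.integers(len(_OTHER))])
    return letters


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def synth_structure(
    n: int,
    seed: int = 0,
    chain_id: str = "A",
    pdb_id: str = "SYNT",
    sty_fraction: float = 0.2,
) -> ProteinStructure:
    """Self-avoiding chain of ``n`` residues with CA + pseudo side-chain atoms.

    Consecutive CA-CA distances are 3.8 +/- 0.1 Angstrom; non-consecutive
    CAs stay at least 3.5 Angstrom apart; each residue carries one 'CB'
    pseudo atom 1.5 Angstrom from its CA in a random direction.
    """
    rng = np.random.default_rng(seed)
    letters = _random_letters(rng, n, sty_fraction)
    cas = [np.zeros(3)]
    while len(cas) < n:
        step = 3.8 + rng.uniform(-0.09, 0.09)
        for _ in range(200):
            cand = cas[-1] + step * _random_unit(rng)
            prior = np.array(cas[:-1]) if len(cas) > 1 else None
            if prior is None or np.linalg.norm(prior - cand, axis=1).min() >= 3.5:
                cas.append(cand)
                break
        else:  # dead end: back up one residue and retry
            cas.pop()
            if not cas:
                cas = [np.zeros(3)]
    residues = []
    for i, (aa, ca) in enumerate(zip(letters, cas)):
        cb = ca + 1.5 * _random_unit(rng)
        residues.append(
            Residue(
                chain_id=chain_id,
                resseq=i + 1,
                icode=" ",
                aa=aa,
                resname=_ONE_TO_THREE.get(aa, "UNK"),
                linear_index=i,
                heavy_atoms=[
                    Atom("CA", "C", ca, 1.0),
                    Atom("CB", "C", cb, 1.0),
                ],
            )
        )
    return ProteinStructure(pdb_id=pdb_id, chains={chain_id: residues})


# --------------------------------------------------------------------------
# Planted-signal feature matrices


@dataclass
class SynthConfig:
    n_sites: int = 400
    n_features: int = 200
    n_planted: int = 10
    delta: float = 1.5
    pos_fraction: float = 0.1  # 1:9 imbalance
    seed: int = 0
    planted: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.planted:
            self.planted = list(range(self.n_planted))
        if not set(self.planted) <= set(range(self.n_features)):
            raise ValueError("planted indices outside feature range")
        if self.delta < 0 or not 0 < self.pos_fraction < 1:
            raise ValueError("need delta >= 0 and 0 < pos_fraction < 1")


def synth_dataset(cfg: SynthConfig) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """(X, y, planted feature names).

    Noise columns are standard normal in both classes; planted columns get a
    class-mean gap of ``delta`` (positives shifted up).  Labels honour the
    configured imbalance exactly (floor of the positive fraction).
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = max(1, int(round(cfg.n_sites * cfg.pos_fraction)))
    y = np.zeros(cfg.n_sites, dtype=int)
    y[rng.choice(cfg.n_sites, size=n_pos, replace=False)] = 1
    X = rng.normal(size=(cfg.n_sites, cfg.n_features))
    for j in cfg.planted:
        X[y == 1, j] += cfg.delta
    names = [f"f{j:03d}" for j in range(cfg.n_features)]
    planted_names = [names[j] for j in cfg.planted]
    return pd.DataFrame(X, columns=names), y, planted_names


# --------------------------------------------------------------------------
# Exact-expectation composition streams for the four-body potential


def all_compositions(alphabet: str) -> list[tuple[str, str, str, str]]:
    return [canonical_quad(c) for c in itertools.combinations_with_replacement(sorted(alphabet), 4)]


def expected_composition_stream(
    alphabet: str = "ABCDEFGH",
    n_tetrahedra: int = 102400,
    boost: dict | None = None,
) -> list[tuple[str, str, str, str]]:
    """Composition list whose counts match the uniform multinomial expectation.

    Each composition c receives count n * C_c / |A|^4 (C_c the multiset
    permutation multiplicity), rounded by largest remainder so the total is
    exactly ``n_tetrahedra``.  ``boost`` maps compositions to rate factors
    (e.g. 2.0 plants a composition at twice its expected rate; the rest are
    rescaled proportionally).
    """
    comps = all_compositions(alphabet)
    m = len(alphabet)
    weights = {}
    for c in comps:
        w = multiset_multiplicity(c) / m**4
        if boost:
            w *= boost.get(canonical_quad(c), 1.0)
        weights[c] = w
    total_w = sum(weights.values())
    exact = {c: n_tetrahedra * w / total_w for c, w in weights.items()}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    short = n_tetrahedra - sum(counts.values())
    by_remainder = sorted(comps, key=lambda c: (-(exact[c] - counts[c]), c))
    for c in by_remainder[:short]:
        counts[c] += 1
    stream: list[tuple[str, str, str, str]] = []
    for c in comps:
        stream.extend([c] * counts[c])
    return stream


# --------------------------------------------------------------------------
# On-disk fixture projects

KINASE_FAMILIES = ["PKA", "PKC", "CK2", "SRC", "MAPK"]


def write_fixture_project(
    outdir,
    n_structures: int = 4,
    n_residues: int = 40,
    seed: int = 0,
    positive_fraction: float = 0.4,
    with_external: bool = True,
) -> dict[str, Path]:
    """Write PDB, FASTA, annotation and external-feature fixtures.

    A fraction of each structure's S/T/Y residues is annotated positive with
    a kinase family and a deposit date straddling 2008; external feature
    values are reproducible standard normals keyed by (pdb_id, chain,
    seq_num).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    ann_rows = []
    ext_rows = []
    fasta_lines = []
    pdb_paths = []
    for s_idx in range(n_structures):
        pdb_id = f"SY{s_idx:02d}"
        s = synth_structure(n_residues, seed=seed * 1000 + s_idx, pdb_id=pdb_id)
        p = outdir / f"{pdb_id}.pdb"
        p.write_text(s.to_pdb())
        pdb_paths.append(p)
        for cid, seq in s.sequence.items():
            fasta_lines.append(f">{pdb_id}_{cid}\n{seq}")
        sty = [r for r in s.residues() if r.aa in "STY"]
        n_pos = max(1, int(round(len(sty) * positive_fraction)))
        pos = list(rng.choice(len(sty), size=min(n_pos, len(sty)), replace=False))
        for i in pos:
            r = sty[i]
            year = int(rng.integers(2004, 2013))
            ann_rows.append(
                {
                    "pdb_id": pdb_id,
                    "chain": r.chain_id,
                    "seq_num": r.seq_num,
                    "residue_type": r.aa,
                    "kinase_family": KINASE_FAMILIES[int(rng.integers(len(KINASE_FAMILIES)))],
                    "deposit_date": f"{year}-06-01",
                }
            )
        if with_external:
            for r in s.residues():
                row = {"pdb_id": pdb_id, "chain": r.chain_id, "seq_num": r.seq_num}
                row.update(
                    {name: float(rng.normal()) for name in EXTERNAL_NAMES}
                )
                ext_rows.append(row)
    paths["pdb_dir"] = outdir
    paths["fasta"] = outdir / "sequences.fasta"
    paths["fasta"].write_text("\n".join(fasta_lines) + "\n")
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False)
    if with_external:
        paths["external"] = outdir / "external_features.tsv"
        pd.DataFrame(ext_rows).to_csv(paths["external"], sep="\t", index=False)
    return paths
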