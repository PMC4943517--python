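"""The 51-slot per-residue site-feature vector.

Thirteen feature groups make up the vector: PSSM (20), evolutionary
conservation (1), disorder (6), solvent-accessible area (2), pair potential
(1), atom/residue contacts (2), topographical index (1), physicochemical
(6), four-body pseudo-potential (1), local structural entropy (2),
side-chain energy (6), Voronoi contacts (2) and structural conservation
(1).  Fifteen slots are computed natively from the structure and sequence;
the remaining 36 depend on third-party tools (sequence profiles, disorder
predictors, structure alignment, an energy function) and are ingested from
per-residue TSV tables, with training-set column means imputed when a table
is absent.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from structphos.errors import SchemaError, StructphosError
from structphos.fourbody import FourBodyTable, four_body_score
from structphos.neighborhoods import (
    EuclideanNeighborGraph,
    Tessellation,
    VoronoiNeighborGraph,
)
from structphos.sasa import shrake_rupley, solvent_accessibility
from structphos.structure import ProteinStructure, Residue, min_heavy_atom_distance

# --------------------------------------------------------------------------
# Registry


@dataclass(frozen=True)
class FeatureSlot:
    name: str
    group: str
    provider: str  # "native" | "external"


def _slots(prefix: str, n: int, group: str, provider: str) -> list[FeatureSlot]:
    return [FeatureSlot(f"{prefix}_{i:02d}", group, provider) for i in range(1, n + 1)]


REGISTRY: list[FeatureSlot] = (
    _slots("pssm", 20, "pssm", "external")
    + [FeatureSlot("conservation", "conservation", "external")]
    + _slots("disorder", 6, "disorder", "external")
    + [FeatureSlot("asa_abs", "asa", "native"), FeatureSlot("asa_rel", "asa", "native")]
    + [FeatureSlot("pair_potential", "pair_potential", "external")]
    + [
        FeatureSlot("contacts_atom", "contacts", "native"),
        FeatureSlot("contacts_residue", "contacts", "native"),
    ]
    + [FeatureSlot("topographical", "topographical", "external")]
    + [
        FeatureSlot("phys_hydrophobicity", "physicochemical", "native"),
        FeatureSlot("phys_charge", "physicochemical", "native"),
        FeatureSlot("phys_polarity", "physicochemical", "native"),
        FeatureSlot("phys_volume", "physicochemical", "native"),
        FeatureSlot("phys_isoelectric", "physicochemical", "native"),
        FeatureSlot("phys_aromatic", "physicochemical", "native"),
    ]
    + [FeatureSlot("four_body", "four_body", "native")]
    + [FeatureSlot("lse", "lse", "native"), FeatureSlot("delta_lse", "lse", "native")]
    + _slots("sce", 6, "side_chain_energy", "external")
    + [
        FeatureSlot("voro_contacts_residue", "voronoi_contacts", "native"),
        FeatureSlot("voro_contacts_edges", "voronoi_contacts", "native"),
    ]
    + [FeatureSlot("structural_conservation", "structural_conservation", "external")]
)

GROUP_ARITIES = {
    "pssm": 20,
    "conservation": 1,
    "disorder": 6,
    "asa": 2,
    "pair_potential": 1,
    "contacts": 2,
    "topographical": 1,
    "physicochemical": 6,
    "four_body": 1,
    "lse": 2,
    "side_chain_energy": 6,
    "voronoi_contacts": 2,
    "structural_conservation": 1,
}

FEATURE_NAMES = [s.name for s in REGISTRY]
NATIVE_NAMES = [s.name for s in REGISTRY if s.provider == "native"]
EXTERNAL_NAMES = [s.name for s in REGISTRY if s.provider == "external"]

assert len(REGISTRY) == 51, "site-feature registry must have exactly 51 slots"
assert sum(GROUP_ARITIES.values()) == 51


@dataclass
class SiteFeatureVector:
    values: dict[str, float]
    provenance: dict[str, str]  # computed | supplied | imputed

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


# --------------------------------------------------------------------------
# Sequence window

GAP = "_"


def encode_window(sequence: str, pos: int, flank: int = 7) -> str:
    """15-mer centred on the 1-based position ``pos``, gap-padded at termini."""
    if not 1 <= pos <= len(sequence):
        raise IndexError(f"pos {pos} outside sequence of length {len(sequence)}")
    i = pos - 1
    out = []
    for j in range(i - flank, i + flank + 1):
        out.append(sequence[j] if 0 <= j < len(sequence) else GAP)
    return "".join(out)


# --------------------------------------------------------------------------
# Physicochemical lookup: hydrophobicity (Kyte-Doolittle), net charge at
# pH 7, polarity (Grantham), side-chain volume (Zamyatnin), isoelectric
# point, aromaticity flag.

PHYSICOCHEMICAL = {
    #      KD     chg  pol    vol     pI    arom
    "A": ( 1.8,  0.0,  8.1,  88.6,  6.00, 0.0),
    "R": (-4.5,  1.0, 10.5, 173.4, 10.76, 0.0),
    "N": (-3.5,  0.0, 11.6, 114.1,  5.41, 0.0),
    "D": (-3.5, -1.0, 13.0, 111.1,  2.77, 0.0),
    "C": ( 2.5,  0.0,  5.5, 108.5,  5.07, 0.0),
    "E": (-3.5, -1.0, 12.3, 138.4,  3.22, 0.0),
    "Q": (-3.5,  0.0, 10.5, 143.8,  5.65, 0.0),
    "G": (-0.4,  0.0,  9.0,  60.1,  5.97, 0.0),
    "H": (-3.2,  0.1, 10.4, 153.2,  7.59, 1.0),
    "I": ( 4.5,  0.0,  5.2, 166.7,  6.02, 0.0),
    "L": ( 3.8,  0.0,  4.9, 166.7,  5.98, 0.0),
    "K": (-3.9,  1.0, 11.3, 168.6,  9.74, 0.0),
    "M": ( 1.9,  0.0,  5.7, 162.9,  5.74, 0.0),
    "F": ( 2.8,  0.0,  5.2, 189.9,  5.48, 1.0),
    "P": (-1.6,  0.0,  8.0, 112.7,  6.30, 0.0),
    "S": (-0.8,  0.0,  9.2,  89.0,  5.68, 0.0),
    "T": (-0.7,  0.0,  8.6, 116.1,  5.60, 0.0),
    "W": (-0.9,  0.0,  5.4, 227.8,  5.89, 1.0),
    "Y": (-1.3,  0.0,  6.2, 193.6,  5.66, 1.0),
    "V": ( 4.2,  0.0,  5.9, 140.0,  5.96, 0.0),
}
_PHYS_MEAN = tuple(float(np.mean([v[i] for v in PHYSICOCHEMICAL.values()])) for i in range(6))


def physicochemical(aa: str) -> tuple[tuple[float, ...], bool]:
    """Six scalars for the residue type; unknown types get column means."""
    if aa in PHYSICOCHEMICAL:
        return PHYSICOCHEMICAL[aa], False
    return _PHYS_MEAN, True


# --------------------------------------------------------------------------
# Local structural entropy.  The probability of each residue falling in the
# eight DSSP secondary-structure states is approximated from per-residue
# propensities (Chou-Fasman helix/sheet/turn scales, distributed over the
# eight states), averaged over length-4 sequence windows; LSE of a residue
# is the mean Shannon entropy (bits) of the windows covering it.

_CF = {  # P(helix), P(sheet), P(turn)
    "A": (1.42, 0.83, 0.66), "R": (0.98, 0.93, 0.95), "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46), "C": (0.70, 1.19, 1.19), "E": (1.51, 0.37, 0.74),
    "Q": (1.11, 1.10, 0.98), "G": (0.57, 0.75, 1.56), "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47), "L": (1.21, 1.30, 0.59), "K": (1.16, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60), "F": (1.13, 1.38, 0.60), "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43), "T": (0.83, 1.19, 0.96), "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14), "V": (1.06, 1.70, 0.50),
}

SS_STATES = ("H", "G", "I", "E", "B", "T", "S", "C")


def residue_ss_propensities(aa: str) -> np.ndarray:
    """Normalised 8-state secondary-structure probability row for a residue."""
    h, e, t = _CF.get(aa, (1.0, 1.0, 1.0))
    coil = max(0.3, 3.0 - h - e - t)
    raw = np.array(
        [0.80 * h, 0.15 * h, 0.05 * h, 0.85 * e, 0.15 * e, 0.60 * t, 0.40 * t, coil]
    )
    return raw / raw.sum()


def ss_window_probs(sequence: str, window: int = 4) -> np.ndarray:
    """Per-window 8-state probability rows (mean of per-residue rows).

    A sequence of length n yields n-window+1 rows; sequences shorter than
    the window yield a single row over the whole sequence.
    """
    rows = np.array([residue_ss_propensities(a) for a in sequence])
    if len(sequence) < window:
        return rows.mean(axis=0, keepdims=True)
    n_win = len(sequence) - window + 1
    return np.array([rows[i : i + window].mean(axis=0) for i in range(n_win)])


def local_structural_entropy(ss_probs: np.ndarray, pos: int, window: int = 4) -> float:
    """Mean entropy (bits) of the windows covering 0-based residue ``pos``.

    ``ss_probs`` has one 8-state probability row per length-``window``
    window; up to four windows cover an interior residue, fewer near the
    termini.
    """
    ss_probs = np.asarray(ss_probs, dtype=float)
    if ss_probs.ndim != 2 or ss_probs.shape[1] != len(SS_STATES):
        raise StructphosError("ss_probs must be rows over the 8 SS states")
    if np.any(np.abs(ss_probs.sum(axis=1) - 1.0) > 1e-6) or np.any(ss_probs < -1e-12):
        raise StructphosError("ss_probs rows must be probability distributions")
    starts = [w for w in range(pos - window + 1, pos + 1) if 0 <= w < len(ss_probs)]
    if not starts:
        starts = [min(max(pos, 0), len(ss_probs) - 1)]
    ents = []
    for w in starts:
        p = ss_probs[w]
        nz = p[p > 0]
        ents.append(float(-(nz * np.log2(nz)).sum()))
    return float(np.mean(ents))


def delta_lse(lse_wild: float, lse_variant: float) -> float:
    """Change in local structural entropy from wild type to variant."""
    if not (np.isfinite(lse_wild) and np.isfinite(lse_variant)):
        raise StructphosError("LSE values must be finite")
    return float(lse_variant - lse_wild)


# --------------------------------------------------------------------------
# Contacts


def contact_counts(
    s: ProteinStructure,
    r: Residue,
    atom_cutoff: float = 5.0,
    residue_cutoff: float = 8.0,
) -> tuple[int, int]:
    """(atom contacts, residue contacts) of residue ``r``.

    Atom contacts: hetero-residue heavy-atom pairs within ``atom_cutoff``
    involving ``r``.  Residue contacts: other residues whose minimum
    heavy-atom distance to ``r`` is at most ``residue_cutoff``.
    """
    from scipy.spatial.distance import cdist

    rc = r.coords()
    atom_contacts = 0
    residue_contacts = 0
    for other in s.residues():
        if other.key == r.key:
            continue
        d = cdist(rc, other.coords())
        atom_contacts += int((d <= atom_cutoff).sum())
        if d.min() <= residue_cutoff:
            residue_contacts += 1
    return atom_contacts, residue_contacts


# --------------------------------------------------------------------------
# External feature tables

KEY_COLUMNS = ["chain", "seq_num"]


def read_external_feature_table(doc: str) -> dict[tuple[str, str], dict[str, float]]:
    """Parse a per-residue TSV carrying the 36 external feature slots.

    The header must contain ``chain``, ``seq_num`` and every external slot
    name; unknown extra columns raise a warning and are ignored.
    """
    df = pd.read_csv(io.StringIO(doc) if "\n" in doc or "\t" in doc else doc, sep="\t")
    missing = [c for c in KEY_COLUMNS + EXTERNAL_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"external feature table missing columns: {missing}")
    extra = [c for c in df.columns if c not in KEY_COLUMNS + EXTERNAL_NAMES]
    if extra:
        warnings.warn(f"ignoring unknown external feature columns: {extra}")
    out: dict[tuple[str, str], dict[str, float]] = {}
    for _, row in df.iterrows():
        key = (str(row["chain"]), str(row["seq_num"]))
        out[key] = {c: float(row[c]) for c in EXTERNAL_NAMES}
    return out


# --------------------------------------------------------------------------
# Assembly


@dataclass
class FeatureContext:
    """Precomputed per-structure providers shared across residues."""

    structure: ProteinStructure
    egraph: EuclideanNeighborGraph
    vgraph: VoronoiNeighborGraph
    tessellation: Tessellation | None
    fourbody_table: FourBodyTable | None
    sasa_cache: dict = field(default_factory=dict)
    external: dict[tuple[str, str], dict[str, float]] | None = None

    @classmethod
    def build(
        cls,
        structure: ProteinStructure,
        fourbody_table: FourBodyTable | None = None,
        external: dict | None = None,
        cutoff: float = 10.0,
        max_edge: float | None = None,
    ) -> "FeatureContext":
        from structphos.neighborhoods import (
            centroid_tessellation,
            euclidean_neighbor_graph,
            voronoi_neighbor_graph,
        )
        from structphos.errors import DegenerateGeometryError

        try:
            tess = centroid_tessellation(structure, max_edge=max_edge)
        except DegenerateGeometryError:
            tess = None
        return cls(
            structure=structure,
            egraph=euclidean_neighbor_graph(structure, cutoff=cutoff),
            vgraph=voronoi_neighbor_graph(structure, max_edge=max_edge),
            tessellation=tess,
            fourbody_table=fourbody_table,
            sasa_cache=shrake_rupley(structure),
            external=external,
        )


def assemble_site_vector(
    r: Residue,
    ctx: FeatureContext,
    imputation: dict[str, float] | None = None,
) -> SiteFeatureVector:
    """All 51 site features of a residue, in registry order.

    External slots come from ``ctx.external`` when present, else from the
    ``imputation`` map (training-set column means; 0 when unknown) and are
    flagged ``imputed``.
    """
    values: dict[str, float] = {}
    prov: dict[str, str] = {}

    absolute, relative, asa_imputed = solvent_accessibility(
        ctx.structure, r, _cache=ctx.sasa_cache
    )
    values["asa_abs"], values["asa_rel"] = absolute, relative
    prov["asa_abs"] = "computed"
    prov["asa_rel"] = "imputed" if asa_imputed else "computed"

    ac, rc = contact_counts(ctx.structure, r)
    values["contacts_atom"], values["contacts_residue"] = float(ac), float(rc)
    prov["contacts_atom"] = prov["contacts_residue"] = "computed"

    phys, phys_imputed = physicochemical(r.aa)
    for name, v in zip(
        ["phys_hydrophobicity", "phys_charge", "phys_polarity",
         "phys_volume", "phys_isoelectric", "phys_aromatic"],
        phys,
    ):
        values[name] = float(v)
        prov[name] = "imputed" if phys_imputed else "computed"

    if ctx.tessellation is not None and ctx.fourbody_table is not None:
        values["four_body"] = four_body_score(r, ctx.tessellation, ctx.fourbody_table)
        prov["four_body"] = "computed"
    else:
        values["four_body"] = 0.0
        prov["four_body"] = "imputed"

    seq = ctx.structure.sequence[r.chain_id]
    probs = ss_window_probs(seq)
    values["lse"] = local_structural_entropy(probs, r.linear_index)
    values["delta_lse"] = 0.0  # wild type against itself unless a variant is given
    prov["lse"] = prov["delta_lse"] = "computed"

    values["voro_contacts_residue"] = float(ctx.vgraph.degree(r.key))
    values["voro_contacts_edges"] = float(ctx.vgraph.edge_counts.get(r.key, 0))
    prov["voro_contacts_residue"] = prov["voro_contacts_edges"] = "computed"

    ext = (ctx.external or {}).get(r.key)
    for name in EXTERNAL_NAMES:
        if ext is not None and name in ext and np.isfinite(ext[name]):
            values[name] = float(ext[name])
            prov[name] = "supplied"
        else:
            values[name] = float((imputation or {}).get(name, 0.0))
            prov[name] = "imputed"

    ordered = {n: values[n] for n in FEATURE_NAMES}
    if not all(np.isfinite(v) for v in ordered.values()):
        raise StructphosError(f"non-finite site feature for residue {r.key}")
    return SiteFeatureVector(values=ordered, provenance={n: prov[n] for n in FEATURE_NAMES})
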