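"""Explicit residue/atom model of PDB-format protein structures.

Every downstream geometric primitive (neighbor graphs, tessellations,
surface areas) consumes this model.  Only heavy atoms are retained:
hydrogen and deuterium are dropped at parse time, alternate locations are
resolved to the highest-occupancy conformer, and among HETATM residues only
selenomethionine survives (mapped to M) so the amino-acid alphabet stays
closed over the 20 standard letters plus X.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial.distance import cdist

from structphos.errors import EmptyStructureError, MissingGeometryError, ParseError

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

_ONE_TO_THREE = {v: k for k, v in protein_letters_3to1.items()}


@dataclass(frozen=True)
class Atom:
    """A heavy atom: label, element and Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    icode: str
    aa: str
    heavy_atoms: list[Atom]
    linear_index: int
    resname: str = ""

    @property
    def seq_num(self) -> str:
        """Author residue number with insertion code, e.g. '42' or '42A'."""
        return f"{self.resseq}{self.icode.strip()}"

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_num)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms])


@dataclass
class ProteinStructure:
    pdb_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def sequence(self) -> dict[str, str]:
        return {cid: "".join(r.aa for r in res) for cid, res in self.chains.items()}

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for res in self.chains.values():
            out.extend(res)
        return out

    def __len__(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def get(self, chain_id: str, seq_num: str) -> Residue:
        for r in self.chains[chain_id]:
            if r.seq_num == str(seq_num):
                return r
        raise KeyError((chain_id, seq_num))

    # -- serialization -----------------------------------------------------

    def to_pdb(self) -> str:
        """Serialize the retained heavy atoms back to PDB ATOM records."""
        lines = []
        serial = 1
        for cid, residues in self.chains.items():
            for r in residues:
                resname = r.resname or _ONE_TO_THREE.get(r.aa, "UNK")
                for a in r.heavy_atoms:
                    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                    lines.append(
                        f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {cid:1s}"
                        f"{r.resseq:4d}{r.icode:1s}   "
                        f"{a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
                        f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
                    )
                    serial += 1
            lines.append("TER")
        lines.append("END")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        doc = {
            "pdb_id": self.pdb_id,
            "chains": {
                cid: [
                    {
                        "resseq": r.resseq,
                        "icode": r.icode,
                        "aa": r.aa,
                        "resname": r.resname,
                        "atoms": [
                            {
                                "name": a.name,
                                "element": a.element,
                                "coord": a.coord.tolist(),
                                "occupancy": a.occupancy,
                            }
                            for a in r.heavy_atoms
                        ],
                    }
                    for r in residues
                ]
                for cid, residues in self.chains.items()
            },
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ProteinStructure":
        doc = json.loads(text)
        chains: dict[str, list[Residue]] = {}
        for cid, residues in doc["chains"].items():
            chains[cid] = [
                Residue(
                    chain_id=cid,
                    resseq=r["resseq"],
                    icode=r["icode"],
                    aa=r["aa"],
                    resname=r.get("resname", ""),
                    linear_index=i,
                    heavy_atoms=[
                        Atom(a["name"], a["element"], np.array(a["coord"]), a["occupancy"])
                        for a in r["atoms"]
                    ],
                )
                for i, r in enumerate(residues)
            ]
        return cls(pdb_id=doc["pdb_id"], chains=chains)


def _is_hydrogen(element: str) -> bool:
    return element.strip().upper() in {"H", "D"}


def _pick_conformer(atoms):
    """Highest occupancy wins; ties broken by altloc letter order."""
    return min(atoms, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))


def parse_structure(text: str, pdb_id: str = "") -> ProteinStructure:
    """Parse a PDB-format document into a :class:`ProteinStructure`.

    Hydrogens are dropped; alternate locations keep the highest-occupancy
    conformer; HETATM residues are excluded except selenomethionine (MSE),
    which is mapped to M.  Raises :class:`ParseError` on malformed records
    (the message carries the offending line) and
    :class:`EmptyStructureError` if no residues survive.
    """
    if "ATOM" not in text and "HETATM" not in text:
        raise EmptyStructureError("document contains no ATOM records")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = parser.get_structure(pdb_id or "struct", io.StringIO(text))[0]
    except PDBConstructionException as exc:
        raise ParseError(str(exc)) from exc

    chains: dict[str, list[Residue]] = {}
    seen_keys: set[tuple[str, str]] = set()
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetfield, resseq, icode = res.get_id()
            resname = res.get_resname().strip()
            if hetfield != " " and not (hetfield == "H_MSE" and resname == "MSE"):
                continue
            aa = "M" if resname == "MSE" else protein_letters_3to1.get(resname, "X")
            heavy: list[Atom] = []
            by_name: dict[str, list] = {}
            for atom in res.get_unpacked_list():
                by_name.setdefault(atom.get_name(), []).append(atom)
            for name in by_name:
                atom = _pick_conformer(by_name[name])
                if _is_hydrogen(atom.element):
                    continue
                heavy.append(
                    Atom(
                        name=name,
                        element=atom.element.strip().upper(),
                        coord=np.asarray(atom.get_coord(), dtype=float),
                        occupancy=float(atom.get_occupancy() or 1.0),
                    )
                )
            if not heavy:
                continue
            r = Residue(
                chain_id=chain.id,
                resseq=resseq,
                icode=icode if icode.strip() else " ",
                aa=aa,
                resname=resname,
                heavy_atoms=heavy,
                linear_index=len(residues),
            )
            if r.key in seen_keys:
                raise ParseError(f"duplicate residue key {r.key}")
            seen_keys.add(r.key)
            residues.append(r)
        if residues:
            chains[chain.id] = residues
    structure = ProteinStructure(pdb_id=pdb_id, chains=chains)
    if len(structure) == 0:
        raise EmptyStructureError("no residues after filtering")
    return structure


def side_chain_centroid(r: Residue) -> np.ndarray:
    """Unweighted mean of side-chain heavy-atom coordinates.

    Glycine (and any residue with only backbone atoms) falls back to CA.
    """
    side = [a.coord for a in r.heavy_atoms if a.name not in _BACKBONE]
    if side:
        return np.mean(side, axis=0)
    for a in r.heavy_atoms:
        if a.name == "CA":
            return a.coord.copy()
    raise MissingGeometryError(f"residue {r.key} has neither side-chain atoms nor CA")


def min_heavy_atom_distance(a: Residue, b: Residue) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs (symmetric)."""
    if not a.heavy_atoms or not b.heavy_atoms:
        raise MissingGeometryError("residue without heavy atoms")
    return float(cdist(a.coords(), b.coords()).min())
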