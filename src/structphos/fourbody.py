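"""Four-body statistical pseudo-potential from Delaunay tetrahedra.

Each residue is reduced to its side-chain centroid and the structure is
Delaunay-tessellated; every tetrahedron contributes one residue-quadruplet
composition (an unordered multiset of four one-letter codes).  The score of
a composition is the log-odds of its observed frequency f against the
multinomial expectation p built from the marginal residue frequencies q:

    Q = ln(f / p),    p = C * q_i * q_j * q_k * q_l

where C = 4! / (product of multiplicities!) is the number of distinct
orderings of the multiset.  Compositions never observed get a
pseudo-frequency floor of 1/(2N) by default.  Tetrahedra may optionally be
typed by the number of sequence-adjacent vertex pairs (0-3); the default is
a single untyped class.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from structphos.errors import DegenerateGeometryError, StructphosError
from structphos.neighborhoods import Tessellation, centroid_tessellation
from structphos.structure import ProteinStructure, Residue

Quad = tuple[str, str, str, str]


def canonical_quad(letters) -> Quad:
    """Canonical (sorted) form of a residue quadruplet."""
    q = tuple(sorted(letters))
    if len(q) != 4:
        raise ValueError(f"quadruplet must have 4 letters, got {letters!r}")
    return q  # type: ignore[return-value]


def multiset_multiplicity(quad: Quad) -> int:
    """Number of distinct orderings of the multiset: 4!/prod(counts!)."""
    denom = 1
    for c in Counter(quad).values():
        denom *= math.factorial(c)
    return math.factorial(4) // denom


@dataclass
class FourBodyTable:
    """Log-odds scores for residue-quadruplet compositions per tetrahedron type."""

    counts: dict[int, Counter] = field(default_factory=dict)  # type -> Counter[Quad]
    totals: dict[int, int] = field(default_factory=dict)
    marginal: dict[str, float] = field(default_factory=dict)  # residue letter -> q
    floor: float | None = None  # explicit floor score for unseen compositions

    @classmethod
    def from_compositions(cls, comps, types=None, floor: float | None = None) -> "FourBodyTable":
        """Train from an iterable of 4-letter compositions (optionally typed)."""
        table = cls(floor=floor)
        letter_counts: Counter = Counter()
        comps = list(comps)
        if types is None:
            types = [0] * len(comps)
        if not comps:
            raise StructphosError("cannot train a four-body table on zero tetrahedra")
        for quad, t in zip(comps, types):
            q = canonical_quad(quad)
            table.counts.setdefault(t, Counter())[q] += 1
            table.totals[t] = table.totals.get(t, 0) + 1
            letter_counts.update(q)
        n_letters = sum(letter_counts.values())
        table.marginal = {a: c / n_letters for a, c in letter_counts.items()}
        return table

    # -- frequencies and scores -------------------------------------------

    def observed_frequency(self, quad: Quad, ttype: int = 0) -> float:
        total = self.totals.get(ttype, 0)
        if total == 0:
            return 0.0
        return self.counts.get(ttype, Counter()).get(canonical_quad(quad), 0) / total

    def expected_frequency(self, quad: Quad, ttype: int = 0) -> float:
        q = canonical_quad(quad)
        p = float(multiset_multiplicity(q))
        for letter in q:
            p *= self.marginal.get(letter, 0.0)
        return p

    def score(self, quad: Quad, ttype: int = 0) -> float:
        """Q = ln(f/p); unseen compositions get the configured floor."""
        f = self.observed_frequency(quad, ttype)
        p = self.expected_frequency(quad, ttype)
        if p <= 0.0:
            return 0.0
        if f <= 0.0:
            if self.floor is not None:
                return self.floor
            total = self.totals.get(ttype, 0) or 1
            f = 0.5 / total
        return math.log(f / p)

    def to_rows(self):
        """(quadruplet, type, f, p, Q) rows for TSV export."""
        rows = []
        for t in sorted(self.counts):
            for quad in sorted(self.counts[t]):
                rows.append(
                    (
                        "".join(quad),
                        t,
                        self.observed_frequency(quad, t),
                        self.expected_frequency(quad, t),
                        self.score(quad, t),
                    )
                )
        return rows


def tetrahedron_type(tess: Tessellation, row: np.ndarray, adjacency: bool) -> int:
    """0 if untyped; else the number of sequence-adjacent vertex pairs (0-3)."""
    if not adjacency or tess.point_refs is None:
        return 0
    # point_refs are residue keys in residue order; sequence adjacency means
    # same chain and consecutive position in the tessellated point list.
    t = 0
    idx = sorted(int(i) for i in row)
    for a in idx:
        for b in idx:
            if b <= a:
                continue
            ka, kb = tess.point_refs[a], tess.point_refs[b]
            if ka[0] == kb[0] and abs(a - b) == 1:
                t += 1
    return min(t, 3)


def train_four_body_table(
    structures: list[ProteinStructure],
    typing: str = "single",
    max_edge: float | None = None,
    floor: float | None = None,
) -> FourBodyTable:
    """Count quadruplet compositions over centroid tessellations of structures.

    ``typing='adjacency'`` classes tetrahedra by their number of
    sequence-adjacent vertex pairs; the default ``'single'`` pools everything.
    """
    comps: list[Quad] = []
    types: list[int] = []
    adjacency = typing == "adjacency"
    any_tess = False
    for s in structures:
        residues = s.residues()
        if len(residues) < 4:
            continue
        try:
            tess = centroid_tessellation(s, max_edge=max_edge)
        except DegenerateGeometryError:
            continue
        any_tess = True
        letters = [r.aa for r in residues]
        for row in tess.tetrahedra:
            comps.append(canonical_quad(letters[int(i)] for i in row))
            types.append(tetrahedron_type(tess, row, adjacency))
    if not any_tess or not comps:
        raise StructphosError("no tessellable structures: four-body training failed")
    return FourBodyTable.from_compositions(comps, types, floor=floor)


def four_body_score(
    r: Residue,
    tess: Tessellation,
    table: FourBodyTable,
    typing: str = "single",
) -> float:
    """Mean Q over tetrahedra incident to the residue's centroid; 0 if none."""
    if tess.point_refs is None or r.key not in tess.point_refs:
        raise KeyError(f"residue {r.key} absent from tessellation point set")
    idx = tess.point_refs.index(r.key)
    rows = tess.incident(idx)
    if len(rows) == 0:
        return 0.0
    if tess.point_aas is None:
        raise StructphosError("tessellation lacks residue letters")
    adjacency = typing == "adjacency"
    scores = []
    for ri in rows:
        row = tess.tetrahedra[ri]
        quad = canonical_quad(tess.point_aas[int(i)] for i in row)
        scores.append(table.score(quad, tetrahedron_type(tess, row, adjacency)))
    return float(np.mean(scores))
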