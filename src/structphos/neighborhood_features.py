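"""Structural-neighborhood properties and the 153-dimensional vector.

Every site feature f is mirrored twice: the Euclidean neighborhood property
ENP_f(i) sums f over all residues within 10 Angstrom (minimum heavy-atom
distance) of the target, and the Voronoi/Delaunay neighborhood property
VDP_f(i) sums f over the target's Voronoi-adjacent residues.  Both are raw
sums (a mean-normalised variant is available behind a flag).  The full
vector concatenates the 51 site values with their 51 ENP and 51 VDP
mirrors, suffixed ``.site`` / ``.enp`` / ``.vdp``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from structphos.errors import StructphosError
from structphos.neighborhoods import EuclideanNeighborGraph, VoronoiNeighborGraph
from structphos.site_features import FEATURE_NAMES, SiteFeatureVector

ResidueKey = tuple[str, str]

SITE_COLUMNS = [f"{n}.site" for n in FEATURE_NAMES]
ENP_COLUMNS = [f"{n}.enp" for n in FEATURE_NAMES]
VDP_COLUMNS = [f"{n}.vdp" for n in FEATURE_NAMES]
FULL_COLUMNS = SITE_COLUMNS + ENP_COLUMNS + VDP_COLUMNS

assert len(FULL_COLUMNS) == 153


def enp(
    target: ResidueKey,
    feature: str,
    graph: EuclideanNeighborGraph,
    site_values: dict[ResidueKey, SiteFeatureVector],
    normalize: bool = False,
) -> float:
    """Sum of the feature over the target's Euclidean neighbors (self excluded)."""
    nbrs = graph.neighbors(target)
    vals = []
    for key in nbrs:
        if key not in site_values:
            raise StructphosError(f"neighbor {key} lacks a site feature vector")
        vals.append(site_values[key].values[feature])
    if not vals:
        return 0.0
    return float(np.mean(vals)) if normalize else float(np.sum(vals))


def vdp(
    target: ResidueKey,
    feature: str,
    graph: VoronoiNeighborGraph,
    site_values: dict[ResidueKey, SiteFeatureVector],
    normalize: bool = False,
) -> float:
    """Sum of the feature over the target's Voronoi/Delaunay neighbors."""
    nbrs = graph.neighbors(target)
    vals = []
    for key in nbrs:
        if key not in site_values:
            raise StructphosError(f"neighbor {key} lacks a site feature vector")
        vals.append(site_values[key].values[feature])
    if not vals:
        return 0.0
    return float(np.mean(vals)) if normalize else float(np.sum(vals))


def assemble_full_vector(
    target: ResidueKey,
    egraph: EuclideanNeighborGraph,
    vgraph: VoronoiNeighborGraph,
    site_values: dict[ResidueKey, SiteFeatureVector],
    normalize: bool = False,
) -> dict[str, float]:
    """site || ENP || VDP concatenation over the 51 registry slots (153 values)."""
    if target not in site_values:
        raise StructphosError(f"no site vector for target {target}")
    out: dict[str, float] = {}
    sv = site_values[target]
    for n in FEATURE_NAMES:
        out[f"{n}.site"] = sv.values[n]
    # vectorised neighborhood sums: one pass per block
    e_nbrs = list(egraph.neighbors(target))
    v_nbrs = list(vgraph.neighbors(target))
    agg = np.mean if normalize else np.sum
    for suffix, nbrs in (("enp", e_nbrs), ("vdp", v_nbrs)):
        for n in FEATURE_NAMES:
            vals = [site_values[k].values[n] for k in nbrs]
            out[f"{n}.{suffix}"] = float(agg(vals)) if vals else 0.0
    return out


def full_feature_frame(
    targets: list[ResidueKey],
    egraph: EuclideanNeighborGraph,
    vgraph: VoronoiNeighborGraph,
    site_values: dict[ResidueKey, SiteFeatureVector],
    normalize: bool = False,
) -> pd.DataFrame:
    """Rows = target residues, columns = the 153 named features."""
    rows = [
        assemble_full_vector(t, egraph, vgraph, site_values, normalize=normalize)
        for t in targets
    ]
    df = pd.DataFrame(rows, columns=FULL_COLUMNS)
    df.index = pd.MultiIndex.from_tuples(targets, names=["chain", "seq_num"])
    return df
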