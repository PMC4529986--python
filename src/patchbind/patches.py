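"""Surface neighbor relation and 2-aa/3-aa patch enumeration.

Two surface residues are neighbors when the smallest distance between their
heavy atoms is at most d_N (default 3 A).  A residue with k neighbors yields
C(k, 2) 3-aa patches (the residue plus each unordered neighbor pair) when
k >= 2, a single 2-aa patch when k = 1, and nothing when k = 0 — an
interaction interface is assumed to span at least two residues.  Patches
whose center is a surface RNA-binding residue of the training set are the
positive *template* patches.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import ComplexModel, ResidueModel
from .superposition import Patch

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborIndex",
    "residue_min_distance",
    "build_neighbor_index",
    "build_patches",
    "extract_templates",
]


def residue_min_distance(r1: ResidueModel, r2: ResidueModel) -> float:
    """Smallest heavy-atom distance between two residues (symmetric)."""
    c1 = r1.heavy_coords()
    c2 = r2.heavy_coords()
    d2 = np.sum((c1[:, None, :] - c2[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(d2.min()))


def _seq_sort_key(seq_index: str):
    m = re.match(r"(-?\d+)(.*)", seq_index)
    if m:
        return (int(m.group(1)), m.group(2))
    return (0, seq_index)


@dataclass
class NeighborIndex:
    """Symmetric surface-residue neighbor relation at a distance cutoff d_N."""

    d_N: float
    neighbors: dict[tuple[str, str], list[tuple[str, str]]]
    residue_map: dict[tuple[str, str], ResidueModel] = field(default_factory=dict)

    def neighbor_residues(self, key: tuple[str, str]) -> list[ResidueModel]:
        return [self.residue_map[k] for k in self.neighbors.get(key, [])]

    def degree(self, key: tuple[str, str]) -> int:
        return len(self.neighbors.get(key, []))


def build_neighbor_index(cm: ComplexModel, d_N: float = 3.0,
                         same_chain_only: bool = False) -> NeighborIndex:
    """Build the surface neighbor relation of a complex.

    Only surface residues participate, on both sides of each edge.  By
    default residues of different protein chains may be neighbors (interfaces
    of multimers are continuous surfaces); ``same_chain_only`` restricts the
    relation to within-chain pairs.  Sequence-adjacent residues are treated
    like any others — the rule is purely metric.
    """
    surf = [r for r in cm.residues() if r.is_surface]
    index = NeighborIndex(d_N=d_N, neighbors={r.key: [] for r in surf},
                          residue_map={r.key: r for r in surf})
    if len(surf) < 2:
        return index
    coords = []
    owner = []
    for ri, res in enumerate(surf):
        for a in res.atoms:
            if a.is_heavy:
                coords.append(a.coord)
                owner.append(ri)
    coords = np.asarray(coords)
    owner = np.asarray(owner)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(d_N, output_type="ndarray")
    seen: set[tuple[int, int]] = set()
    for ai, aj in pairs:
        ri, rj = owner[ai], owner[aj]
        if ri == rj:
            continue
        a, b = (ri, rj) if ri < rj else (rj, ri)
        if (a, b) in seen:
            continue
        seen.add((a, b))
        ra, rb = surf[a], surf[b]
        if same_chain_only and ra.chain_id != rb.chain_id:
            continue
        index.neighbors[ra.key].append(rb.key)
        index.neighbors[rb.key].append(ra.key)
    for key in index.neighbors:
        index.neighbors[key].sort(key=lambda k: (k[0], _seq_sort_key(k[1])))
    return index


def _make_patch(center: ResidueModel, others: list[ResidueModel],
                source_id: str, is_template: bool = False) -> Patch:
    members = [center] + others
    pts = np.stack([r.shape_points for r in members])
    return Patch(points=pts,
                 aa_types=tuple(r.aa_type for r in members),
                 origin=(source_id, center.chain_id, center.seq_index),
                 is_template=is_template)


def build_patches(center: ResidueModel, index: NeighborIndex,
                  source_id: str = "", is_template: bool = False) -> list[Patch]:
    """All patches surrounding ``center``.

    Neighbors lacking a complete shape descriptor are dropped first; the
    center must have one itself.  Residue order within a patch (center first,
    then neighbors by ascending sequence index) is a canonical form only —
    d_SS minimizes over residue permutations, so the ordering cannot affect
    any downstream distance.
    """
    if not center.has_shape or not center.is_surface:
        return []
    nbrs = [r for r in index.neighbor_residues(center.key) if r.has_shape]
    nbrs.sort(key=lambda r: (r.chain_id, _seq_sort_key(r.seq_index)))
    k = len(nbrs)
    if k == 0:
        return []
    if k == 1:
        return [_make_patch(center, nbrs, source_id, is_template)]
    return [_make_patch(center, [a, b], source_id, is_template)
            for a, b in itertools.combinations(nbrs, 2)]


def extract_templates(training_complexes, d_N: float = 3.0,
                      same_chain_only: bool = False
                      ) -> tuple[list[Patch], list[Patch]]:
    """Template patches from all surface binding residues of a training set.

    Returns (3-aa templates, 2-aa templates).  Every patch is kept — no
    deduplication — and provenance records the source complex and center
    residue.
    """
    t3: list[Patch] = []
    t2: list[Patch] = []
    for cm in training_complexes:
        index = build_neighbor_index(cm, d_N=d_N, same_chain_only=same_chain_only)
        for res in cm.residues():
            if not (res.is_surface and res.is_binding):
                continue
            for p in build_patches(res, index, source_id=cm.source_id,
                                   is_template=True):
                (t3 if p.m == 3 else t2).append(p)
    logger.info("extracted %d 3-aa and %d 2-aa template patches", len(t3), len(t2))
    return t3, t2
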