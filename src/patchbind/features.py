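"""Per-residue feature vectors: structural (60) + PSSM (20) + propensity (1).

The structural block encodes how the surface around a residue relates to the
representative patches.  With k surface neighbors, the residue's surrounding
patches {X_1..X_K} are compared against each representative Y_j and the
accumulated d_SS forms feature f_j:

* k >= 2 (K = C(k,2) 3-aa patches):  f_j = sum_i d_SS(X_i, Y_j) for the 3-aa
  representatives (j <= 40); the 2-aa block is zero — a 3-aa patch cannot be
  compared with a 2-aa representative.
* k = 1 (one 2-aa patch):  f_j = d_SS(X_1, Y_j) for the 2-aa representatives
  (j > 40); the 3-aa block is zero.
* k = 0: the vector is all-zero and the residue is flagged featureless (and
  excluded from training/evaluation).

The remaining 21 dimensions are the residue's 20 PSSM log-odds scores and its
amino-acid interface propensity (relative frequency at RNA interfaces versus
the protein surface), for a total of 81.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import RepresentativeSet
from .patches import NeighborIndex, build_patches
from .structure import ComplexModel, ResidueModel
from .superposition import dss_to_references

logger = logging.getLogger(__name__)

__all__ = [
    "AA_ORDER",
    "StructuralFeatures",
    "structural_features",
    "load_pssm",
    "compute_propensity",
    "assemble_features",
    "feature_columns",
    "STRUCTURAL_COLUMNS",
    "PSSM_COLUMNS",
    "PROPENSITY_COLUMN",
]

#: PSI-BLAST PSSM column order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

STRUCTURAL_COLUMNS = [f"f{j}" for j in range(1, 61)]
PSSM_COLUMNS = [f"pssm_{a}" for a in AA_ORDER]
PROPENSITY_COLUMN = "propensity"


def feature_columns(structural: bool = True, pssm: bool = True,
                    propensity: bool = True, L: int = 60) -> list[str]:
    """Feature column names for a given block selection (ablation support).

    ``L`` is the structural dimension (the representative count); the default
    matches the standard 40 + 20 representative set.
    """
    cols: list[str] = []
    if structural:
        cols += [f"f{j}" for j in range(1, L + 1)]
    if pssm:
        cols += PSSM_COLUMNS
    if propensity:
        cols.append(PROPENSITY_COLUMN)
    return cols


@dataclass
class StructuralFeatures:
    """The 60 accumulated-distance features of one residue."""

    f: np.ndarray
    k: int
    K: int
    featureless: bool = False


def structural_features(center: ResidueModel, index: NeighborIndex,
                        reps: RepresentativeSet,
                        source_id: str = "") -> StructuralFeatures:
    """Accumulated d_SS of a residue's surrounding patches to each Y_j."""
    n3 = reps.n3
    L = reps.L
    f = np.zeros(L)
    patches = build_patches(center, index, source_id=source_id)
    k = len([r for r in index.neighbor_residues(center.key) if r.has_shape])
    if not patches:
        return StructuralFeatures(f=f, k=k, K=0, featureless=True)
    if patches[0].m == 2:
        # single 2-aa patch against the 2-aa representatives
        f[n3:] = dss_to_references(patches[0], reps.reps_2aa)
        return StructuralFeatures(f=f, k=k, K=0)
    for p in patches:
        f[:n3] += dss_to_references(p, reps.reps_3aa)
    return StructuralFeatures(f=f, k=k, K=len(patches))


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------

_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z])\s+(-?\d+(?:\s+-?\d+)*)")


def load_pssm(pssm_text: str, expected_sequence: str | None = None) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into an (n, 20) integer score matrix.

    Only the first 20 columns (the log-odds block) are read; the weighted
    observed percentages that follow are ignored.  Scores are returned as-is
    with no rescaling.  When ``expected_sequence`` is given, the sequence
    embedded in the matrix must match it exactly.

    Raises
    ------
    ValueError
        If no matrix rows are found, a row is malformed, or the embedded
        sequence mismatches (the error names the offending positions).
    """
    rows: list[list[int]] = []
    seq: list[str] = []
    for line in pssm_text.splitlines():
        m = _PSSM_ROW.match(line)
        if not m:
            continue
        values = [int(v) for v in m.group(3).split()]
        if len(values) < 20:
            raise ValueError(
                f"PSSM row {m.group(1)} has {len(values)} score columns, need 20")
        rows.append(values[:20])
        seq.append(m.group(2).upper())
    if not rows:
        raise ValueError("malformed PSSM: no matrix rows found")
    profile = np.asarray(rows, dtype=int)
    if expected_sequence is not None:
        embedded = "".join(seq)
        if embedded != expected_sequence:
            bad = [i + 1 for i, (a, b) in
                   enumerate(zip(embedded, expected_sequence)) if a != b]
            if len(embedded) != len(expected_sequence):
                raise ValueError(
                    f"PSSM sequence length {len(embedded)} != expected "
                    f"{len(expected_sequence)}")
            raise ValueError(
                f"PSSM sequence mismatch at positions {bad}")
    return profile


# ---------------------------------------------------------------------------
# interface propensity
# ---------------------------------------------------------------------------

def compute_propensity(training_complexes, alpha: float = 1.0) -> dict[str, float]:
    """Interface propensity per amino-acid type, with additive smoothing.

    propensity(a) = [(N_int(a)+alpha) / (N_int+20*alpha)]
                  / [(N_surf(a)+alpha) / (N_surf+20*alpha)]

    where N_int counts surface binding residues of type ``a`` and N_surf all
    surface residues of type ``a``, pooled over the training complexes.  With
    alpha = 0 this is the plain ratio of interface to surface frequencies
    (value 1 when the interface composition equals the surface composition).
    """
    complexes = list(training_complexes)
    if not complexes:
        raise ValueError("empty training set")
    n_int = dict.fromkeys(AA_ORDER, 0)
    n_surf = dict.fromkeys(AA_ORDER, 0)
    for cm in complexes:
        for res in cm.residues():
            if not res.is_surface:
                continue
            n_surf[res.aa_type] += 1
            if res.is_binding:
                n_int[res.aa_type] += 1
    tot_int = sum(n_int.values())
    tot_surf = sum(n_surf.values())
    if tot_surf == 0:
        raise ValueError("training set has no surface residues")
    out = {}
    for a in AA_ORDER:
        p_int = (n_int[a] + alpha) / (tot_int + 20 * alpha)
        p_surf = (n_surf[a] + alpha) / (tot_surf + 20 * alpha)
        out[a] = p_int / p_surf if p_surf > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_features(complexes, reps: RepresentativeSet, pssms: dict,
                      prop: dict[str, float], d_N: float = 3.0,
                      same_chain_only: bool = False) -> pd.DataFrame:
    """One 81-dimension feature row per eligible surface residue.

    ``pssms`` maps (source_id, chain_id) to a PSI-BLAST profile whose rows
    follow the chain's residue order.  Featureless residues (no surface
    neighbor) are excluded with a logged count.  The returned frame carries
    provenance columns (source_id, chain_id, seq_index, aa_type), the 81
    feature columns, and the binding label.
    """
    from .patches import build_neighbor_index

    struct_cols = [f"f{j}" for j in range(1, reps.L + 1)]
    rows = []
    n_featureless = 0
    for cm in complexes:
        index = build_neighbor_index(cm, d_N=d_N, same_chain_only=same_chain_only)
        for chain_id, residues in cm.protein_chains.items():
            key = (cm.source_id, chain_id)
            if key not in pssms:
                raise KeyError(
                    f"missing PSSM for chain {chain_id!r} of {cm.source_id!r}")
            profile = pssms[key]
            if len(profile) != len(residues):
                raise ValueError(
                    f"PSSM for {key} has {len(profile)} rows, chain has "
                    f"{len(residues)} residues")
            for pos, res in enumerate(residues):
                if not (res.is_surface and res.has_shape):
                    continue
                sf = structural_features(res, index, reps, source_id=cm.source_id)
                if sf.featureless:
                    n_featureless += 1
                    continue
                row = {
                    "source_id": cm.source_id,
                    "chain_id": chain_id,
                    "seq_index": res.seq_index,
                    "aa_type": res.aa_type,
                    "label": int(res.is_binding),
                }
                row.update(zip(struct_cols, sf.f))
                row.update(zip(PSSM_COLUMNS, profile[pos].astype(float)))
                row[PROPENSITY_COLUMN] = prop[res.aa_type]
                rows.append(row)
    if n_featureless:
        logger.info("excluded %d featureless (k=0) residues", n_featureless)
    columns = (["source_id", "chain_id", "seq_index", "aa_type", "label"]
               + feature_columns(L=reps.L))
    return pd.DataFrame(rows, columns=columns)
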