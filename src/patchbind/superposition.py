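"""Rigid-body least-squares comparison of surface patches.

A patch is an ordered set of m residues (m = 2 or 3), each contributing the
five shape-descriptor points (N, CA, C, O, side-chain center).  Two patches of
the same size are compared as rigid point sets: the least-squares distance
``d_LS`` is the square root of the minimized sum of squared point deviations
under an optimal proper rotation and translation (scale fixed to 1), solved in
closed form by SVD (Kabsch/Umeyama).  Because the residue correspondence
between two patches is unknown, the structural similarity ``d_SS`` is the
minimum d_LS over all m! residue reorderings of the first patch; the
within-residue point order is fixed and never permuted.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Patch",
    "SuperpositionResult",
    "least_squares_distance",
    "structural_similarity",
    "dls_batch",
    "dss_to_references",
    "save_patches",
    "load_patches",
    "PATCH_POINTS_PER_RESIDUE",
]

#: Number of shape-descriptor points contributed by each residue.
PATCH_POINTS_PER_RESIDUE = 5

#: Distances below this are reported as exactly zero.
ZERO_TOL = 1e-9


@dataclass
class Patch:
    """A rigid point set of 2 or 3 residues, five points per residue.

    ``points`` has shape (m, 5, 3) in residue-major order; the within-residue
    order is fixed (N, CA, C, O, side-chain center).
    """

    points: np.ndarray
    aa_types: tuple[str, ...] = ()
    origin: tuple = ()
    is_template: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1] != PATCH_POINTS_PER_RESIDUE \
                or self.points.shape[2] != 3:
            raise ValueError(
                f"patch points must have shape (m, 5, 3), got {self.points.shape}")
        if self.points.shape[0] not in (2, 3):
            raise ValueError(f"patch size must be 2 or 3, got {self.points.shape[0]}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("patch points must be finite")

    @property
    def m(self) -> int:
        """Number of residues in the patch."""
        return self.points.shape[0]

    def flat(self) -> np.ndarray:
        """All points as an (m*5, 3) array."""
        return self.points.reshape(-1, 3)

    def permuted(self, order: Sequence[int]) -> np.ndarray:
        """Points with the residue blocks reordered, shape (m, 5, 3)."""
        return self.points[np.asarray(order, dtype=int)]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Patch":
        """A copy moved by the rigid motion p -> R p + t."""
        moved = self.points @ np.asarray(rotation).T + np.asarray(translation)
        return Patch(moved, self.aa_types, self.origin, self.is_template)


@dataclass
class SuperpositionResult:
    """Optimal rigid alignment of patch Y onto patch X and its residual.

    ``rotation`` is a proper rotation (det = +1); ``scale`` is fixed at 1 —
    similar patches are assumed to differ only by a rigid motion, never by
    size.  ``d_ls`` is sqrt(sum of squared residuals) in angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray
    d_ls: float
    scale: float = 1.0
    permutation: tuple[int, ...] = field(default_factory=tuple)


def _kabsch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Proper rotation R and translation t minimizing sum ||x - (R y + t)||^2.

    Returns (R, t, d_ls).  The reflection case (det(V U^T) = -1) is corrected
    by flipping the smallest singular direction, so R is always a rotation.
    """
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    xc = x - xm
    yc = y - ym
    # cross-covariance sum_i y'_i x'_i^T
    cov = yc.T @ xc
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate; treat as proper
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = xm - rot @ ym
    resid = xc - yc @ rot.T
    ss = float(np.sum(resid * resid))
    d_ls = float(np.sqrt(max(ss, 0.0)))
    if d_ls < ZERO_TOL:
        d_ls = 0.0
    return rot, t, d_ls


def least_squares_distance(x: Patch, y: Patch) -> SuperpositionResult:
    """Least-squares distance between two equal-size patches.

    Correspondence is positional: the i-th residue of ``x`` is matched to the
    i-th residue of ``y`` and the j-th point to the j-th point.  Use
    :func:`structural_similarity` when the residue correspondence is unknown.

    Raises
    ------
    ValueError
        If the patches contain different numbers of residues.
    """
    if x.m != y.m:
        raise ValueError(f"patch size mismatch: {x.m} vs {y.m}")
    rot, t, d_ls = _kabsch(x.flat(), y.flat())
    return SuperpositionResult(rotation=rot, translation=t, d_ls=d_ls,
                               permutation=tuple(range(x.m)))


def structural_similarity(x: Patch, y: Patch) -> tuple[float, tuple[int, ...]]:
    """Permutation-minimized least-squares distance d_SS between two patches.

    All m! residue reorderings of ``x`` are tried (6 for 3-aa patches, 2 for
    2-aa) and the smallest d_LS is returned together with the winning
    permutation.  Ties go to the first permutation in lexicographic order.
    """
    if x.m != y.m:
        raise ValueError(f"patch size mismatch: {x.m} vs {y.m}")
    yflat = y.flat()
    best: float | None = None
    best_perm: tuple[int, ...] = tuple(range(x.m))
    for perm in itertools.permutations(range(x.m)):
        xp = x.permuted(perm).reshape(-1, 3)
        _, _, d = _kabsch(xp, yflat)
        if best is None or d < best:
            best = d
            best_perm = perm
    assert best is not None
    return best, best_perm


# ---------------------------------------------------------------------------
# batched kernels
# ---------------------------------------------------------------------------

def dls_batch(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Vectorized d_LS for B point-set pairs.

    ``xs`` and ``ys`` have shape (B, N, 3); positional correspondence.  Uses a
    stacked SVD so that large all-pairs computations stay in numpy.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    cov = np.einsum("bni,bnj->bij", yc, xc)
    u, s, vt = np.linalg.svd(cov)
    v = np.transpose(vt, (0, 2, 1))
    det = np.linalg.det(np.einsum("bij,bkj->bik", v, u))
    # rotation with reflection correction D = diag(1, 1, sign(det))
    vd = v.copy()
    vd[:, :, 2] *= np.sign(det)[:, None]
    rot = np.einsum("bij,bkj->bik", vd, u)
    # explicit residuals (numerically stabler than the trace identity)
    resid = xc - np.einsum("bnj,bij->bni", yc, rot)
    ss = np.sum(resid * resid, axis=(1, 2))
    out = np.sqrt(np.clip(ss, 0.0, None))
    out[out < ZERO_TOL] = 0.0
    return out


_PERMS = {m: list(itertools.permutations(range(m))) for m in (2, 3)}


def dss_to_references(query: Patch, references: Sequence[Patch]) -> np.ndarray:
    """d_SS from one query patch to each of R same-size reference patches.

    Evaluates all m! permutations against every reference in a single batched
    SVD call; equal to looping :func:`structural_similarity` (asserted in the
    test suite).
    """
    refs = [r for r in references]
    if not refs:
        return np.zeros(0)
    m = query.m
    for r in refs:
        if r.m != m:
            raise ValueError("reference patch size mismatch")
    perms = _PERMS[m]
    npts = m * PATCH_POINTS_PER_RESIDUE
    xs = np.stack([query.permuted(p).reshape(npts, 3) for p in perms])  # (P, N, 3)
    ys = np.stack([r.flat() for r in refs])  # (R, N, 3)
    nperm, nref = len(perms), len(refs)
    xs_b = np.repeat(xs, nref, axis=0)          # (P*R, N, 3)
    ys_b = np.tile(ys, (nperm, 1, 1))           # (P*R, N, 3)
    d = dls_batch(xs_b, ys_b).reshape(nperm, nref)
    return d.min(axis=0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_COORD_DECIMALS = 4


def patch_to_dict(patch: Patch) -> dict:
    return {
        "aa_types": list(patch.aa_types),
        "origin": list(patch.origin),
        "is_template": patch.is_template,
        "points": np.round(patch.points, _COORD_DECIMALS).tolist(),
    }


def patch_from_dict(d: dict) -> Patch:
    return Patch(
        points=np.asarray(d["points"], dtype=float),
        aa_types=tuple(d.get("aa_types", ())),
        origin=tuple(d.get("origin", ())),
        is_template=bool(d.get("is_template", False)),
    )


def save_patches(patches: Sequence[Patch], path) -> None:
    """Write patches as JSON (coordinates at fixed 4-decimal precision)."""
    payload = {"n": len(patches), "patches": [patch_to_dict(p) for p in patches]}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_patches(path) -> list[Patch]:
    with open(path) as fh:
        payload = json.load(fh)
    return [patch_from_dict(d) for d in payload["patches"]]
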