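"""Self-contained synthetic protein-RNA fixtures.

The generator emits desk-scale PDB files, pseudo-PSSMs and truth tables in
which the only systematic difference between binding and non-binding
residues is geometric: binding residues sit in spatial triads laid out as a
planted motif ("linear": three CA positions collinear at 5 A spacing;
"fork": a stem with two 5 A arms 60 degrees apart) plus Gaussian jitter,
while non-binding triads get random bend angles and orientations.  A
nucleotide (P, O5', C1', N9) is placed 3.0 A from each designated contact
residue and the 25 A group grid keeps it >= 8 A from everything else, so
the 5 A binding rule reproduces the intended labels exactly.

Side chains are idealized (a single CB heavy atom; glycine none): downstream
math consumes only coordinates, so chemical realism is not required.  Each
residue's internal bond lengths and angles are standard, but consecutive
residues are not covalently connected — the chain is a spatial arrangement,
not a polymer.  All outputs are byte-reproducible for a fixed seed and are
consumed only through the public PDB/PSSM readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .features import AA_ORDER
from .structure import AA3TO1
from .superposition import Patch

__all__ = [
    "FixtureSpec",
    "make_toy_complex",
    "make_pseudo_pssm",
    "make_benchmark",
    "load_benchmark",
    "make_planted_patches",
]

AA1TO3 = {v: k for k, v in AA3TO1.items()}

_GRID_SPACING = 25.0
_CA_MOTIF_SPACING = 5.0
_CA_RANDOM_SPACING = 4.4
_EDGE_MARGIN = 0.05  # required neighbor edges must clear d_N by this much


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic benchmark."""

    n_proteins: int = 24
    residues_per_protein: int = 40
    motif: str = "linear"  # "linear" | "fork"
    jitter_sigma: float = 0.2
    contact_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must be in [0, 1]")
        if self.motif not in ("linear", "fork"):
            raise ValueError(f"unknown motif {self.motif!r}")


# ---------------------------------------------------------------------------
# residue geometry
# ---------------------------------------------------------------------------

def _local_residue_template() -> dict[str, np.ndarray]:
    """Idealized residue in a local frame: CA at origin, chain axis +x.

    N-CA 1.46 A, CA-C 1.52 A, N-CA-C 110 deg, C-O 1.23 A at 121 deg,
    CA-CB 1.53 A in the tetrahedral substituent direction.
    """
    a = np.deg2rad(35.0)
    ca = np.zeros(3)
    n = 1.46 * np.array([np.cos(a), 0.0, np.sin(a)])
    c = 1.52 * np.array([-np.cos(a), 0.0, np.sin(a)])
    v = (ca - c) / np.linalg.norm(ca - c)
    p0 = np.array([0.0, 0.0, 1.0])
    p = p0 - (p0 @ v) * v
    p /= np.linalg.norm(p)
    ang = np.deg2rad(121.0)
    o = c + 1.23 * (np.cos(ang) * v + np.sin(ang) * p)
    u1 = n / np.linalg.norm(n)
    u2 = c / np.linalg.norm(c)
    b = u1 + u2
    b /= np.linalg.norm(b)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    cb_dir = -b + perp
    cb = 1.53 * cb_dir / np.linalg.norm(cb_dir)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


_TEMPLATE = _local_residue_template()
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _frame(x_dir: np.ndarray, up: np.ndarray) -> np.ndarray:
    """Right-handed rotation whose local +x maps to ``x_dir``."""
    x = x_dir / np.linalg.norm(x_dir)
    z = up - (up @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(x @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        z = ref - (ref @ x) * x
        nz = np.linalg.norm(z)
    z = z / nz
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _roll(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _residue_atoms(rot: np.ndarray, ca_pos: np.ndarray, with_cb: bool
                   ) -> dict[str, np.ndarray]:
    names = ["N", "CA", "C", "O"] + (["CB"] if with_cb else [])
    return {name: rot @ _TEMPLATE[name] + ca_pos for name in names}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(d2.min()))


# ---------------------------------------------------------------------------
# triad layouts
# ---------------------------------------------------------------------------

def _motif_layout(motif: str) -> tuple[list[np.ndarray], list[np.ndarray],
                                       list[tuple[int, int]]]:
    """CA positions, residue orientations, and required neighbor edges."""
    up = np.array([0.0, 0.0, 1.0])
    s = _CA_MOTIF_SPACING
    if motif == "linear":
        x = np.array([1.0, 0.0, 0.0])
        cas = [np.array([-s, 0.0, 0.0]), np.zeros(3), np.array([s, 0.0, 0.0])]
        rots = [_frame(x, up)] * 3
        edges = [(0, 1), (1, 2)]
    else:  # fork: stem + two arms 60 degrees apart
        a1 = np.array([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0.0])
        a2 = np.array([np.cos(np.deg2rad(30)), -np.sin(np.deg2rad(30)), 0.0])
        cas = [np.zeros(3), s * a1, s * a2]
        rots = [_frame(np.array([1.0, 0.0, 0.0]), up), _frame(a1, up),
                _frame(a2, up)]
        edges = [(0, 1), (0, 2)]
    return cas, rots, edges


def _random_layout(rng: np.random.Generator) -> tuple[list[np.ndarray],
                                                      list[np.ndarray],
                                                      list[tuple[int, int]]]:
    """A random bent triad: spacing 4.4 A, bend angle in [70, 150] degrees."""
    up = np.array([0.0, 0.0, 1.0])
    s = _CA_RANDOM_SPACING
    x = np.array([1.0, 0.0, 0.0])
    bend = np.deg2rad(rng.uniform(70.0, 150.0))
    psi = np.pi - bend  # deflection of the second segment from +x
    phi = rng.uniform(0.0, 2.0 * np.pi)
    d12 = np.array([np.cos(psi), np.sin(psi) * np.cos(phi),
                    np.sin(psi) * np.sin(phi)])
    cas = [-s * x, np.zeros(3), s * d12]
    bis = x + d12
    rots = [
        _frame(x, up) @ _roll(rng.uniform(0, 2 * np.pi)),
        _frame(bis, up) @ _roll(rng.uniform(0, 2 * np.pi)),
        _frame(d12, up) @ _roll(rng.uniform(0, 2 * np.pi)),
    ]
    return cas, rots, [(0, 1), (1, 2)]


def _build_triad(kind: str, motif: str, jitter: float, with_cb: list[bool],
                 rng: np.random.Generator, d_N: float = 3.0,
                 max_tries: int = 200) -> list[dict[str, np.ndarray]]:
    """Atom coordinates for a triad in its local frame.

    Jitter (and for random triads, the bend) is redrawn until the required
    neighbor edges hold at the d_N cutoff, so the emitted neighbor graph is
    guaranteed regardless of the noise draw.
    """
    for _ in range(max_tries):
        if kind == "motif":
            cas, rots, edges = _motif_layout(motif)
        else:
            cas, rots, edges = _random_layout(rng)
        residues = []
        for ca, rot, cb in zip(cas, rots, with_cb):
            atoms = _residue_atoms(rot, ca, cb)
            if jitter > 0:
                atoms = {k: v + rng.normal(0.0, jitter, size=3)
                         for k, v in atoms.items()}
            residues.append(atoms)
        coords = [np.asarray(list(r.values())) for r in residues]
        if all(_min_dist(coords[i], coords[j]) <= d_N - _EDGE_MARGIN
               for i, j in edges):
            return residues
    raise RuntimeError(f"could not realize a valid {kind} triad "
                       f"(jitter={jitter}, motif={motif})")


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------

def _grid_slots(n: int) -> np.ndarray:
    side = 1
    while side ** 3 < n:
        side += 1
    pts = np.array([[i, j, k] for i in range(side) for j in range(side)
                    for k in range(side)], dtype=float)
    return pts[:n] * _GRID_SPACING


def _plan_groups(spec: FixtureSpec, rng: np.random.Generator):
    n = spec.residues_per_protein
    n_triads = n // 3
    n_lone = n - 3 * n_triads
    if n_triads < 1:
        raise ValueError("residues_per_protein must be >= 3")
    n_contacts = round(spec.contact_fraction * n)
    n_binding = int(np.clip(round(n_contacts / 3), 0, n_triads))
    if spec.contact_fraction > 0 and n_binding == 0:
        n_binding = 1
    if 3 * n_binding > n:
        raise ValueError("contact_fraction infeasible for this chain length")
    binding_ids = set(rng.choice(n_triads, size=n_binding, replace=False).tolist())
    return n_triads, n_lone, binding_ids


def make_toy_complex(spec: FixtureSpec, index: int
                     ) -> tuple[str, pd.DataFrame]:
    """One synthetic complex: PDB text plus its truth table.

    The truth table lists, per residue, the intended surface flag (always
    true — the structures are sparse enough that every residue is exposed),
    the intended binding flag, the spatial group id and the residue's role
    (motif-center / motif-end / random / lone).
    """
    rng = np.random.default_rng([spec.seed, index])
    n_triads, n_lone, binding_ids = _plan_groups(spec, rng)
    n_groups = n_triads + n_lone
    slots = _grid_slots(n_groups)
    slot_order = rng.permutation(n_groups)

    seq = rng.choice(list(AA_ORDER), size=spec.residues_per_protein)
    residues = []   # (aa, coords dict, group, role, is_binding)
    rna_atoms = []  # (name, element, coord)
    res_i = 0
    for g in range(n_triads):
        binding = g in binding_ids
        aas = seq[res_i:res_i + 3]
        with_cb = [a != "G" for a in aas]
        kind = "motif" if binding else "random"
        jitter = spec.jitter_sigma if binding else 0.15
        local = _build_triad(kind, spec.motif, jitter, with_cb, rng)
        rot = _random_rotation(rng)
        origin = slots[slot_order[g]]
        center_idx = 1 if (not binding or spec.motif == "linear") else 0
        out_dir = rot @ np.array([0.0, 0.0, 1.0])
        for ri, atoms in enumerate(local):
            placed = {k: rot @ v + origin for k, v in atoms.items()}
            role = "motif-center" if (binding and ri == center_idx) else \
                   "motif-end" if binding else "random"
            residues.append((aas[ri], placed, g, role, binding))
            if binding:
                base = placed["CA"] + 3.0 * out_dir
                for off, (name, elem) in zip(
                        (0.0, 1.3, 2.6, 3.9),
                        (("P", "P"), ("O5'", "O"), ("C1'", "C"), ("N9", "N"))):
                    rna_atoms.append((name, elem, base + off * out_dir))
        res_i += 3
    for li in range(n_lone):
        g = n_triads + li
        aa = seq[res_i]
        rot = _random_rotation(rng)
        placed = {k: rot @ v + slots[slot_order[g]]
                  for k, v in _residue_atoms(np.eye(3), np.zeros(3),
                                             aa != "G").items()}
        residues.append((aa, placed, g, "lone", False))
        res_i += 1

    pdb = _write_pdb(residues, rna_atoms)
    truth = pd.DataFrame([{
        "chain_id": "A",
        "seq_index": str(i + 1),
        "aa_type": aa,
        "group": g,
        "role": role,
        "is_surface": True,
        "is_binding": binding,
    } for i, (aa, _, g, role, binding) in enumerate(residues)])
    return pdb, truth


def _write_pdb(residues, rna_atoms) -> str:
    lines = []
    serial = 1

    def atom_line(serial, name, resname, chain, resseq, coord, element):
        name_f = name if len(name) >= 4 else f" {name:<3s}"
        return (f"ATOM  {serial:5d} {name_f}{resname:>4s} {chain}{resseq:4d}    "
                f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")

    for i, (aa, atoms, _, _, _) in enumerate(residues):
        resname = AA1TO3[aa]
        for name in ("N", "CA", "C", "O", "CB"):
            if name not in atoms:
                continue
            lines.append(atom_line(serial, name, resname, "A", i + 1,
                                   atoms[name], _ATOM_ELEMENTS[name]))
            serial += 1
    lines.append("TER")
    n_nt = len(rna_atoms) // 4
    for nt in range(n_nt):
        for name, elem, coord in rna_atoms[4 * nt:4 * nt + 4]:
            lines.append(atom_line(serial, name, "A", "B", nt + 1, coord, elem))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pseudo-PSSM
# ---------------------------------------------------------------------------

_PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative weight "
    "of gapless real matches to pseudocounts\n")


def make_pseudo_pssm(sequence: str, seed: int = 0, noise: int = 2) -> str:
    """A PSI-BLAST-dialect ASCII PSSM from a substitution-matrix stub.

    Each row is the BLOSUM62 row of the residue's amino acid plus seeded
    integer noise in [-noise, noise]; at noise 0, identical letters get
    identical rows.  The text round-trips through the PSSM reader.
    """
    for ch in sequence:
        if ch not in AA_ORDER:
            raise ValueError(f"invalid amino acid letter {ch!r}")
    blosum = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(seed)
    lines = [_PSSM_HEADER.rstrip("\n"), ""]
    header = "            " + "".join(f"{a:>3s}" for a in AA_ORDER) * 2
    lines.append(header)
    for i, aa in enumerate(sequence):
        scores = np.array([int(blosum[aa][b]) for b in AA_ORDER])
        if noise > 0:
            scores = scores + rng.integers(-noise, noise + 1, size=20)
        row = f"{i + 1:5d} {aa} " + "".join(f"{s:4d}" for s in scores)
        row += "".join(f"{0:4d}" for _ in range(20)) + "  0.36 0.08"
        lines.append(row)
    lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# benchmark assembly
# ---------------------------------------------------------------------------

def _protein_id(index: int) -> str:
    return f"toy{index:03d}"


def make_benchmark(spec: FixtureSpec, outdir) -> dict:
    """Write the full benchmark (PDBs, PSSMs, truth tables, manifest).

    Returns the manifest, which is also written as ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(spec.n_proteins):
        sid = _protein_id(i)
        pdb_text, truth = make_toy_complex(spec, i)
        seq = "".join(truth["aa_type"])
        pssm_text = make_pseudo_pssm(seq, seed=spec.seed * 100003 + i)
        (outdir / f"{sid}.pdb").write_text(pdb_text)
        (outdir / f"{sid}.pssm").write_text(pssm_text)
        truth.to_csv(outdir / f"{sid}.truth.tsv", sep="\t", index=False)
        entries.append({"id": sid, "pdb": f"{sid}.pdb", "pssm": f"{sid}.pssm",
                        "truth": f"{sid}.truth.tsv", "protein_chains": ["A"],
                        "rna_chains": ["B"], "sequence": seq})
    manifest = {"spec": spec.__dict__, "proteins": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_benchmark(spec: FixtureSpec):
    """Build the benchmark in memory, consumed through the public readers.

    Returns (complexes, pssms, truths): un-annotated complexes parsed from
    the emitted PDB text, PSSM profiles keyed by (source_id, chain_id), and
    the truth tables keyed by source_id.
    """
    from .features import load_pssm
    from .structure import load_complex

    complexes, pssms, truths = [], {}, {}
    for i in range(spec.n_proteins):
        sid = _protein_id(i)
        pdb_text, truth = make_toy_complex(spec, i)
        cm = load_complex(pdb_text, ["A"], ["B"], source_id=sid)
        seq = "".join(truth["aa_type"])
        pssm_text = make_pseudo_pssm(seq, seed=spec.seed * 100003 + i)
        pssms[(sid, "A")] = load_pssm(pssm_text, expected_sequence=seq)
        complexes.append(cm)
        truths[sid] = truth
    return complexes, pssms, truths


# ---------------------------------------------------------------------------
# planted patches (for clustering benchmarks)
# ---------------------------------------------------------------------------

def make_planted_patches(motif: str, n: int, jitter_sigma: float = 0.2,
                         seed: int = 0) -> list[Patch]:
    """n jittered copies of a motif triad as ready-made 3-aa patches.

    Each copy is independently jittered and placed under a random rigid
    motion, so within-family d_SS reflects only the jitter while
    between-family d_SS reflects the motif geometry.
    """
    rng = np.random.default_rng(seed)
    cas, rots, _ = _motif_layout(motif)
    out = []
    for i in range(n):
        pts = []
        for ca, rot in zip(cas, rots):
            atoms = _residue_atoms(rot, ca, with_cb=True)
            p = np.stack([atoms[k] for k in ("N", "CA", "C", "O", "CB")])
            pts.append(p + rng.normal(0.0, jitter_sigma, size=p.shape))
        pts = np.stack(pts)
        g = _random_rotation(rng)
        t = rng.uniform(-20, 20, size=3)
        out.append(Patch(points=pts @ g.T + t, aa_types=("A", "A", "A"),
                         origin=(f"planted-{motif}", i), is_template=True))
    return out
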