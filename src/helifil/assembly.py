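"""Filament assembly generation and rigid-body structure comparison.

A monomer positioned with the filament axis on +z is expanded into a
multi-chain assembly by the helical operator: subunit k is the monomer
rotated by k·twist about +z and translated by k·rise along +z.  The module
also measures radial geometry (inner/outer radius of the filament wall) and
superposes structures by least squares (Kabsch) to report RMSDs.
"""

from __future__ import annotations

import math
import string
import warnings

import numpy as np
import pandas as pd

from .symmetry import HelicalSymmetry

__all__ = [
    "Structure",
    "rotation_about_z",
    "build_filament",
    "radial_extents",
    "superpose_rmsd",
    "rmsd_fixed_frame",
    "pair_by_residue",
    "chain_id_for",
]

#: columns of the canonical atom table
ATOM_COLUMNS = ["serial", "name", "resname", "resnum", "chain", "x", "y", "z", "element"]


class Structure:
    """Atom table wrapper: a pandas DataFrame with the ATOM_COLUMNS schema."""

    def __init__(self, atoms: pd.DataFrame):
        missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        coords = atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.atoms = atoms.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    def select(self, chain: str | None = None, atom_names: set[str] | None = None) -> "Structure":
        m = np.ones(len(self.atoms), dtype=bool)
        if chain is not None:
            m &= (self.atoms["chain"] == chain).to_numpy()
        if atom_names is not None:
            m &= self.atoms["name"].isin(atom_names).to_numpy()
        return Structure(self.atoms[m])


_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_for(k: int) -> str:
    """Deterministic chain id for subunit index k: A…Z, a…z, 0…9, then
    two-character ids (AA, AB, …) for larger assemblies."""
    if k < len(_CHAIN_ALPHABET):
        return _CHAIN_ALPHABET[k]
    k -= len(_CHAIN_ALPHABET)
    hi, lo = divmod(k, len(_CHAIN_ALPHABET))
    if hi >= len(_CHAIN_ALPHABET):
        raise ValueError("subunit index too large for chain naming")
    return _CHAIN_ALPHABET[hi] + _CHAIN_ALPHABET[lo]


def rotation_about_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_filament(
    monomer: Structure, sym: HelicalSymmetry, k_range: tuple[int, int]
) -> Structure:
    """Expand a monomer into subunits k_min..k_max (inclusive).

    Subunit k is Rz(k·twist)·X + k·rise·ẑ; one chain per subunit with
    deterministic ids in k order.  Subunit 0, if included, is coordinate-wise
    identical to the input monomer.
    """
    k_min, k_max = k_range
    if k_max < k_min:
        raise ValueError("k_range must satisfy k_min <= k_max")
    if len(monomer.chains()) != 1:
        warnings.warn("monomer has multiple chains; they are merged into one subunit", stacklevel=2)
    base = monomer.coords
    frames = []
    serial = 1
    for idx, k in enumerate(range(k_min, k_max + 1)):
        R = rotation_about_z(k * sym.twist_deg)
        xyz = base @ R.T
        xyz[:, 2] += k * sym.rise_ang
        sub = monomer.atoms.copy()
        sub[["x", "y", "z"]] = xyz
        sub["chain"] = chain_id_for(idx)
        sub["serial"] = np.arange(serial, serial + len(sub))
        serial += len(sub)
        frames.append(sub)
    return Structure(pd.concat(frames, ignore_index=True))


def radial_extents(
    struct: Structure, per_residue_centroid: bool = False
) -> tuple[float, float]:
    """Inner and outer cylindrical radius sqrt(x²+y²) over atoms (or
    per-residue centroids)."""
    if len(struct) == 0:
        raise ValueError("empty structure")
    if per_residue_centroid:
        g = struct.atoms.groupby(["chain", "resnum"])[["x", "y"]].mean()
        r = np.hypot(g["x"], g["y"]).to_numpy()
    else:
        xyz = struct.coords
        r = np.hypot(xyz[:, 0], xyz[:, 1])
    return float(r.min()), float(r.max())


def _kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ||R·a + t − b||²."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cb - R @ ca


def superpose_rmsd(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (rmsd Å, rotation, translation) with rotation proper (det = +1).
    Degenerate (collinear or coincident) point sets are rejected because the
    optimal rotation is then not unique.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("need equally sized (n, 3) coordinate arrays")
    if len(a) < 3:
        raise ValueError("need at least 3 point pairs")
    for pts in (a, b):
        cen = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(cen, tol=1e-9) < 2:
            raise ValueError("degenerate (collinear) point set")
    R, t = _kabsch(a, b)
    moved = a @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rmsd, R, t


def rmsd_fixed_frame(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of paired coordinates without superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired coordinate arrays must have equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pair_by_residue(
    a: Structure,
    b: Structure,
    atom_names: set[str] = frozenset({"CA"}),
    resnum_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pair coordinates of two single-chain structures by residue number and
    atom name intersection.

    Returns (coords_a, coords_b, unpaired_resnums); the default pairs Cα atoms
    only, optionally restricted to a residue-number range.
    """
    def table(s: Structure) -> dict[tuple[int, str], np.ndarray]:
        out = {}
        for row in s.atoms.itertuples():
            if row.name in atom_names and (
                resnum_range is None or resnum_range[0] <= row.resnum <= resnum_range[1]
            ):
                out[(row.resnum, row.name)] = np.array([row.x, row.y, row.z])
        return out

    ta, tb = table(a), table(b)
    keys = sorted(set(ta) & set(tb))
    unpaired = sorted({rn for rn, _ in set(ta) ^ set(tb)})
    if not keys:
        raise ValueError("no common residue/atom pairs")
    return (
        np.stack([ta[k] for k in keys]),
        np.stack([tb[k] for k in keys]),
        unpaired,
    )
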