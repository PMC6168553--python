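"""File formats: PDB/mmCIF structures (via gemmi), MRC image stacks and
spectra, TSV shift/annotation tables, and a simplified NMR-STAR reader.

MRC support covers the 1024-byte standard header with modes 0 (int8),
1 (int16) and 2 (float32) for reading and mode 2 for writing; the pixel size
is carried in the cell/grid fields.  Image stacks are stored z-major
(z = image index).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import ATOM_COLUMNS, Structure
from .simulate import ImageStack

__all__ = [
    "read_structure",
    "write_structure",
    "read_mrc",
    "write_mrc",
    "read_image_stack",
    "write_spectrum",
    "read_shift_table",
    "write_shift_table",
    "read_nmrstar_shifts",
    "read_gold_table",
]


# ---------------------------------------------------------------------------
# structures

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="ignore")[:2048]
    return "mmcif" if "_atom_site" in head or head.startswith("data_") else "pdb"


def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read ATOM/HETATM records from a PDB or mmCIF file into a Structure."""
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    rows = []
    serial = 1
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append(
                    (
                        serial,
                        atom.name,
                        res.name,
                        res.seqid.num,
                        chain.name,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.element.name,
                    )
                )
                serial += 1
    if not rows:
        raise ValueError(f"no atoms found in {path}")
    return Structure(pd.DataFrame(rows, columns=ATOM_COLUMNS))


def write_structure(struct: Structure, path: str | Path, fmt: str = "auto") -> None:
    """Write a Structure as PDB or mmCIF.

    PDB output refuses assemblies whose chain ids exceed one character (use
    mmCIF for >62 subunits).
    """
    import gemmi

    path = Path(path)
    fmt = _detect_format(path, fmt) if fmt == "auto" else fmt
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    for chain_id in struct.chains():
        if fmt == "pdb" and len(str(chain_id)) > 1:
            raise ValueError(
                f"chain id {chain_id!r} does not fit PDB format; write mmCIF instead"
            )
        chain = gemmi.Chain(str(chain_id))
        sub = struct.atoms[struct.atoms["chain"] == chain_id]
        for resnum, res_atoms in sub.groupby("resnum", sort=True):
            res = gemmi.Residue()
            res.name = str(res_atoms.iloc[0]["resname"])
            res.seqid = gemmi.SeqId(int(resnum), " ")
            for row in res_atoms.itertuples():
                atom = gemmi.Atom()
                atom.name = str(row.name)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.element = gemmi.Element(str(row.element))
                atom.serial = int(row.serial)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# MRC

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32}


def write_mrc(data: np.ndarray, path: str | Path, pixel_size_ang: float) -> None:
    """Write a 2D image or 3D stack as MRC mode 2 (float32)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)  # mode
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size_ang, ny * pixel_size_ang, nz * pixel_size_ang
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # axis order
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()), float(data.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())


def read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an MRC file (modes 0/1/2); returns (data[z, y, x], pixel size Å)."""
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode not in _MRC_MODES:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (supported: 0, 1, 2)")
    mx = struct.unpack_from("<3i", raw, 28)[0]
    cella_x = struct.unpack_from("<3f", raw, 40)[0]
    pixel = cella_x / mx if mx > 0 and cella_x > 0 else 1.0
    dtype = _MRC_MODES[mode]
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=1024)
    if data.size != count:
        raise ValueError(f"{path}: truncated MRC data block")
    return data.reshape(nz, ny, nx).astype(np.float64), float(pixel)


def read_image_stack(path: str | Path, pixel_size_ang: float | None = None) -> ImageStack:
    """Read an MRC stack; the header pixel size is used unless overridden."""
    data, px = read_mrc(path)
    return ImageStack(data, pixel_size_ang if pixel_size_ang is not None else px)


def write_spectrum(ps, path: str | Path) -> None:
    """Write a power spectrum as a single-image MRC; the axial sampling is
    stored as the pixel size (for square spectra it equals the radial one)."""
    write_mrc(ps.power.astype(np.float32), path, 1.0 / ps.axial_step / ps.power.shape[0])


# ---------------------------------------------------------------------------
# tables

SHIFT_COLUMNS = ["resnum", "aa", "atom", "shift_ppm"]


def read_shift_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    missing = [c for c in SHIFT_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"{path}: shift table missing columns {missing}")
    return t[SHIFT_COLUMNS]


def write_shift_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_nmrstar_shifts(path: str | Path) -> pd.DataFrame:
    """Simplified NMR-STAR chemical-shift reader.

    Parses the first ``Atom_chem_shift`` loop, using the Comp_index_ID,
    Comp_ID, Atom_ID and Val tags, and keeps CA/CB rows.  Three-letter residue
    codes are converted to one-letter.
    """
    lines = Path(path).read_text().splitlines()
    tags: list[str] = []
    rows = []
    in_loop = False
    collecting = False
    for line in lines:
        ls = line.strip()
        if ls == "loop_":
            in_loop, collecting, tags = True, False, []
            continue
        if in_loop and ls.startswith("_"):
            tags.append(ls.split(".")[-1] if "." in ls else ls.lstrip("_"))
            continue
        if in_loop and ls in ("stop_",):
            if collecting:
                break
            in_loop = False
            continue
        if in_loop and ls and not ls.startswith("#"):
            if not collecting:
                if "Atom_chem_shift" not in line and "Comp_index_ID" not in tags:
                    in_loop = False
                    continue
                collecting = True
            parts = ls.split()
            if len(parts) >= len(tags):
                rows.append(dict(zip(tags, parts)))
    if not rows:
        raise ValueError(f"{path}: no Atom_chem_shift loop found")
    needed = {"Comp_index_ID", "Comp_ID", "Atom_ID", "Val"}
    if not needed.issubset(rows[0]):
        raise ValueError(f"{path}: chemical-shift loop lacks tags {sorted(needed - set(rows[0]))}")
    out = []
    for r in rows:
        atom = r["Atom_ID"].upper()
        if atom not in ("CA", "CB"):
            continue
        comp = r["Comp_ID"].upper()
        aa = _THREE_TO_ONE.get(comp, comp if len(comp) == 1 else "X")
        out.append((int(r["Comp_index_ID"]), aa, atom, float(r["Val"])))
    return pd.DataFrame(out, columns=SHIFT_COLUMNS)


def read_gold_table(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", dtype={"filament_id": str}, keep_default_na=False)
    for c in ("image_id", "particle_id", "location"):
        if c not in t.columns:
            raise ValueError(f"{path}: gold table missing column {c}")
    return t
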