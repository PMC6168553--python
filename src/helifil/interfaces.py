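"""Inter-subunit contact extraction and death-domain interface typing.

Helical death-domain (CARD) assemblies bury three conserved asymmetric
interfaces — type I, II and III — each formed between an "a" surface on one
subunit and a "b" surface on a neighbour at some fixed subunit-index offset.
Which offset realizes which interface type depends on the lattice (units per
turn), so the mapping is established data-driven: contacts are extracted per
offset and matched against curated surface annotations by residue-set
overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .assembly import Structure

__all__ = [
    "Contact",
    "InterfaceAnnotation",
    "load_default_annotations",
    "subunit_contacts",
    "classify_offsets",
    "interface_report",
    "mutation_burial",
]

#: heavy-atom distance defining a contact (Å)
DEFAULT_CUTOFF = 4.0

_CHARGED_GROUP_ATOMS = {
    "ARG": {"NH1", "NH2", "NE"},
    "LYS": {"NZ"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
}


@dataclass(frozen=True)
class Contact:
    offset: int
    resnum_i: int
    atom_i: str
    resnum_j: int
    atom_j: str
    distance: float


@dataclass(frozen=True)
class InterfaceAnnotation:
    type_label: str
    surface_a: frozenset[int]
    surface_b: frozenset[int]
    pairs: tuple[tuple[int, int], ...] = ()

    def validate_range(self, resnum_range: tuple[int, int]) -> None:
        lo, hi = resnum_range
        bad = [r for r in self.surface_a | self.surface_b if not lo <= r <= hi]
        if bad:
            raise ValueError(
                f"type {self.type_label} annotation references residues outside "
                f"{lo}-{hi}: {sorted(bad)}"
            )


def load_default_annotations() -> list[InterfaceAnnotation]:
    """Curated RIP2 CARD type I/II/III surface annotations bundled with the
    package."""
    raw = json.loads(
        resources.files("helifil.data").joinpath("rip2card_interfaces.json").read_text()
    )
    return [
        InterfaceAnnotation(
            a["type"],
            frozenset(a["surface_a"]),
            frozenset(a["surface_b"]),
            tuple((int(i), int(j)) for i, j in a.get("pairs", ())),
        )
        for a in raw["annotations"]
    ]


def _subunit_atoms(assembly: Structure, chain: str) -> pd.DataFrame:
    sub = assembly.atoms[assembly.atoms["chain"] == chain]
    return sub[~sub["element"].str.upper().eq("H")]


def subunit_contacts(
    assembly: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    max_offset: int = 4,
    ref_index: int = 0,
) -> dict[int, list[Contact]]:
    """All heavy-atom pairs within ``cutoff`` between the reference subunit and
    subunit ref_index + k, for k = 1..max_offset, grouped by offset.

    Chains are taken in their order of appearance as subunits 0, 1, ….
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chains = assembly.chains()
    if len(chains) < ref_index + max_offset + 1:
        raise ValueError(
            f"assembly has {len(chains)} subunits; need at least {ref_index + max_offset + 1}"
        )
    ref = _subunit_atoms(assembly, chains[ref_index])
    ref_xyz = ref[["x", "y", "z"]].to_numpy(float)
    tree0 = cKDTree(ref_xyz)
    out: dict[int, list[Contact]] = {}
    for k in range(1, max_offset + 1):
        other = _subunit_atoms(assembly, chains[ref_index + k])
        xyz = other[["x", "y", "z"]].to_numpy(float)
        pairs = tree0.query_ball_point(xyz, cutoff)
        contacts = []
        for j_idx, i_list in enumerate(pairs):
            rj = other.iloc[j_idx]
            for i_idx in i_list:
                ri = ref.iloc[i_idx]
                d = float(np.linalg.norm(ref_xyz[i_idx] - xyz[j_idx]))
                contacts.append(
                    Contact(k, int(ri["resnum"]), ri["name"], int(rj["resnum"]), rj["name"], d)
                )
        contacts.sort(key=lambda c: (c.resnum_i, c.atom_i, c.resnum_j, c.atom_j))
        out[k] = contacts
    return out


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def classify_offsets(
    contacts_by_offset: dict[int, list[Contact]],
    annotations: list[InterfaceAnnotation],
) -> dict[int, tuple[str, float]]:
    """Assign each populated offset the interface type whose a/b surfaces best
    overlap the contacting residue sets (mean Jaccard over both surfaces,
    orientation-symmetric).  Offsets without contacts are labelled "other"."""
    out = {}
    for k, contacts in contacts_by_offset.items():
        if not contacts:
            out[k] = ("other", 0.0)
            continue
        res_i = {c.resnum_i for c in contacts}
        res_j = {c.resnum_j for c in contacts}
        best = ("other", 0.0)
        for ann in annotations:
            fwd = (_jaccard(res_i, set(ann.surface_a)) + _jaccard(res_j, set(ann.surface_b))) / 2
            rev = (_jaccard(res_i, set(ann.surface_b)) + _jaccard(res_j, set(ann.surface_a))) / 2
            score = max(fwd, rev)
            if score > best[1]:
                best = (ann.type_label, score)
        out[k] = best
    return out


def _min_residue_pair_distance(
    assembly: Structure, chains: list[str], res_a: int, res_b: int, max_offset: int
) -> tuple[float, int]:
    """Minimal heavy-atom distance between residues res_a (subunit 0) and
    res_b (subunit k) over k = 1..max_offset, orientation-symmetric."""
    best, best_k = np.inf, 0
    ref = _subunit_atoms(assembly, chains[0])
    for k in range(1, max_offset + 1):
        other = _subunit_atoms(assembly, chains[k])
        for ra, rb in ((res_a, res_b), (res_b, res_a)):
            xa = ref[ref["resnum"] == ra][["x", "y", "z"]].to_numpy(float)
            xb = other[other["resnum"] == rb][["x", "y", "z"]].to_numpy(float)
            if len(xa) == 0 or len(xb) == 0:
                continue
            d = float(np.sqrt(((xa[:, None] - xb[None]) ** 2).sum(-1)).min())
            if d < best:
                best, best_k = d, k
    return best, best_k


def interface_report(
    assembly: Structure,
    annotations: list[InterfaceAnnotation] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    max_offset: int = 4,
    salt_bridge_cutoff: float = 4.0,
) -> pd.DataFrame:
    """Tabulate each annotated residue pair: found/not-found at the cutoff,
    minimal heavy-atom distance, the offset realizing it, and whether the pair
    is a salt-bridge candidate (opposite charged-group N/O atoms within the
    salt-bridge cutoff)."""
    annotations = annotations if annotations is not None else load_default_annotations()
    resnums = assembly.atoms["resnum"]
    rng = (int(resnums.min()), int(resnums.max()))
    for ann in annotations:
        ann.validate_range(rng)
    chains = assembly.chains()
    if len(chains) < max_offset + 1:
        raise ValueError("assembly too short for requested max_offset")
    rows = []
    resname_of = dict(zip(assembly.atoms["resnum"], assembly.atoms["resname"]))
    for ann in annotations:
        for ra, rb in ann.pairs:
            d, k = _min_residue_pair_distance(assembly, chains, ra, rb, max_offset)
            salt = _is_salt_bridge_pair(
                assembly, chains, ra, rb, max_offset, salt_bridge_cutoff, resname_of
            )
            rows.append(
                {
                    "type": ann.type_label,
                    "resnum_a": ra,
                    "resnum_b": rb,
                    "found": bool(d <= cutoff),
                    "min_distance_ang": d if np.isfinite(d) else np.nan,
                    "offset": k,
                    "salt_bridge": salt,
                }
            )
    return pd.DataFrame(rows)


def _is_salt_bridge_pair(
    assembly: Structure,
    chains: list[str],
    res_a: int,
    res_b: int,
    max_offset: int,
    cutoff: float,
    resname_of: dict,
) -> bool:
    na, nb = resname_of.get(res_a), resname_of.get(res_b)
    ga = _CHARGED_GROUP_ATOMS.get(na, set())
    gb = _CHARGED_GROUP_ATOMS.get(nb, set())
    if not ga or not gb:
        return False
    acidic = {"ASP", "GLU"}
    if (na in acidic) == (nb in acidic):
        return False  # like charges
    ref = _subunit_atoms(assembly, chains[0])
    for k in range(1, max_offset + 1):
        other = _subunit_atoms(assembly, chains[k])
        for ra, rb, sa, sb in ((res_a, res_b, ga, gb), (res_b, res_a, gb, ga)):
            xa = ref[(ref["resnum"] == ra) & ref["name"].isin(sa)][["x", "y", "z"]].to_numpy(float)
            xb = other[(other["resnum"] == rb) & other["name"].isin(sb)][
                ["x", "y", "z"]
            ].to_numpy(float)
            if len(xa) and len(xb):
                if np.sqrt(((xa[:, None] - xb[None]) ** 2).sum(-1)).min() <= cutoff:
                    return True
    return False


def mutation_burial(
    assembly: Structure,
    residues: list[int],
    cutoff: float = DEFAULT_CUTOFF,
    max_offset: int = 4,
) -> pd.DataFrame:
    """Per-residue count of inter-subunit heavy-atom contacts and the offsets
    involved — the quantitative rationale for interface-disrupting mutations."""
    known = set(assembly.atoms["resnum"])
    for r in residues:
        if r not in known:
            raise ValueError(f"residue {r} not in model")
    contacts = subunit_contacts(assembly, cutoff, max_offset)
    rows = []
    for r in residues:
        n = 0
        offsets = set()
        for k, cs in contacts.items():
            for c in cs:
                if r in (c.resnum_i, c.resnum_j):
                    n += 1
                    offsets.add(k)
        rows.append({"resnum": r, "n_contacts": n, "offsets": sorted(offsets)})
    return pd.DataFrame(rows)
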