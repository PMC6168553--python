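"""Chemical-shift analysis: secondary shifts, state perturbations, signal
accounting.

Secondary chemical shifts Δδ = δ_observed − δ_random-coil of Cα and Cβ report
on secondary structure (positive ΔδCα indicates helical propensity under this
sign convention).  Comparing per-residue shifts between the solution monomer
and the solid-state filament gives a chemical-shift perturbation map: the sum
|ΔCα| + |ΔCβ| highlights residues whose environment changes on filament
formation, i.e. the subunit interfaces.  Residue-type signal accounting
compares the number of assigned residues of a type against the sequence
composition to localize disordered, unobserved regions.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_random_coil_table",
    "validate_shift_table",
    "secondary_shifts",
    "state_perturbation",
    "signal_accounting",
]

SHIFT_COLUMNS = ["resnum", "aa", "atom", "shift_ppm"]


def load_random_coil_table() -> pd.DataFrame:
    """Bundled random-coil Cα/Cβ reference shifts (ppm), indexed by one-letter
    amino-acid code; Gly has no Cβ value."""
    with resources.files("helifil.data").joinpath("random_coil_shifts.tsv").open() as fh:
        t = pd.read_csv(fh, sep="\t", dtype={"aa": str})
    return t.set_index("aa")


def validate_shift_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHIFT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"shift table missing columns: {missing}")
    if table.duplicated(["resnum", "atom"]).any():
        raise ValueError("duplicate (residue, atom) rows in shift table")
    bad = table[(table["aa"] == "G") & (table["atom"] == "CB")]
    if len(bad):
        raise ValueError(f"glycine rows carry CB entries: residues {bad['resnum'].tolist()}")
    out_of_band = table[(table["shift_ppm"] < 0) | (table["shift_ppm"] > 200)]
    if len(out_of_band):
        raise ValueError("shift values outside the 0-200 ppm sanity band")
    return table


def secondary_shifts(
    obs: pd.DataFrame, rc: pd.DataFrame | None = None, sign_convention: str = "obs_minus_rc"
) -> pd.DataFrame:
    """Per-residue (ΔδCα, ΔδCβ) relative to random coil.

    ``sign_convention`` is 'obs_minus_rc' (default; positive ΔδCα = helical)
    or 'rc_minus_obs'.  Missing atoms yield NaN, never zero.
    """
    validate_shift_table(obs)
    rc = rc if rc is not None else load_random_coil_table()
    if sign_convention not in ("obs_minus_rc", "rc_minus_obs"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    unknown = set(obs["aa"]) - set(rc.index)
    if unknown:
        raise ValueError(f"residue types missing from random-coil table: {sorted(unknown)}")
    wide = obs.pivot_table(
        index=["resnum", "aa"], columns="atom", values="shift_ppm", aggfunc="first"
    ).reset_index()
    for atom, col in (("CA", "ca_ppm"), ("CB", "cb_ppm")):
        if atom not in wide:
            wide[atom] = np.nan
        ref = wide["aa"].map(rc[col])
        delta = wide[atom] - ref
        if sign_convention == "rc_minus_obs":
            delta = -delta
        wide[f"d{atom.lower()}"] = delta
    return wide[["resnum", "aa", "dca", "dcb"]].sort_values("resnum").reset_index(drop=True)


def state_perturbation(
    solution: pd.DataFrame,
    solid: pd.DataFrame,
    threshold_ppm: float = 1.2,
    mode: str = "absolute",
) -> pd.DataFrame:
    """Per-residue chemical-shift perturbation between two states.

    For residues present in both tables, ``sum_ppm`` is |ΔCα| + |ΔCβ| (a term
    is omitted when that atom is missing in either state; ``atoms_used``
    records which contributed).  ``flagged`` marks residues with
    sum >= threshold (mode 'absolute') or |sum − mean(sum)| >= threshold
    (mode 'mean_deviation').  Residues present in only one table are returned
    with ``assessed = False``.
    """
    if threshold_ppm <= 0:
        raise ValueError("threshold must be positive")
    if mode not in ("absolute", "mean_deviation"):
        raise ValueError(f"unknown mode {mode!r}")
    validate_shift_table(solution)
    validate_shift_table(solid)

    def wide(t: pd.DataFrame) -> pd.DataFrame:
        return t.pivot_table(
            index=["resnum", "aa"], columns="atom", values="shift_ppm", aggfunc="first"
        )

    ws, wf = wide(solution), wide(solid)
    idx = ws.index.union(wf.index)
    rows = []
    for resnum, aa in idx:
        in_both = (resnum, aa) in ws.index and (resnum, aa) in wf.index
        total, atoms = 0.0, []
        if in_both:
            for atom in ("CA", "CB"):
                a = ws.at[(resnum, aa), atom] if atom in ws else np.nan
                b = wf.at[(resnum, aa), atom] if atom in wf else np.nan
                if np.isfinite(a) and np.isfinite(b):
                    total += abs(b - a)
                    atoms.append(atom)
        rows.append(
            {
                "resnum": resnum,
                "aa": aa,
                "sum_ppm": total if in_both and atoms else np.nan,
                "atoms_used": "+".join(atoms),
                "assessed": bool(in_both and atoms),
            }
        )
    out = pd.DataFrame(rows).sort_values("resnum").reset_index(drop=True)
    sums = out.loc[out["assessed"], "sum_ppm"]
    if mode == "absolute":
        out["flagged"] = out["assessed"] & (out["sum_ppm"] >= threshold_ppm)
    else:
        centre = sums.mean() if len(sums) else 0.0
        out["flagged"] = out["assessed"] & ((out["sum_ppm"] - centre).abs() >= threshold_ppm)
    return out


def signal_accounting(
    assigned_resnums: set[int],
    sequence: str,
    first_resnum: int,
    residue_types: list[str],
) -> pd.DataFrame:
    """Observed vs expected residue counts per amino-acid type.

    Returns one row per requested type with the number of assigned residues of
    that type, the total in the sequence, and the residue numbers of the
    missing ones.
    """
    positions = {first_resnum + i: aa for i, aa in enumerate(sequence)}
    outside = set(assigned_resnums) - set(positions)
    if outside:
        raise ValueError(f"assigned residues outside sequence: {sorted(outside)}")
    rows = []
    for t in residue_types:
        members = [rn for rn, aa in positions.items() if aa == t]
        observed = [rn for rn in members if rn in assigned_resnums]
        rows.append(
            {
                "type": t,
                "observed": len(observed),
                "expected": len(members),
                "missing_resnums": sorted(set(members) - set(observed)),
            }
        )
    return pd.DataFrame(rows)
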