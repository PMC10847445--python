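"""Truncated, capped active-site model construction.

The receptor is cut down to the residues within a distance cutoff of the
union of all overlaid ligands (default 10 Å; trimmed variants 6/5 Å).
Each cut peptide bond is terminated with a neutral cap that restores the
peptide-bond valence: -NH-CH3 (residue name NME) on the C-terminal side of
a kept segment and -CH=O (residue name FOR) on the N-terminal side. Cap
heavy atoms reuse the backbone coordinates of the removed neighbor residue
so that the truncation perturbs the geometry as little as possible;
hydrogens are added with standard bond lengths (C-H 1.09 Å, N-H 1.01 Å).

Charged residues exposed at the model boundary are kept, not neutralized;
they can be listed with `boundary_charge_report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._data import RESIDUE_CHARGES, STANDARD_AMINO_ACIDS
from .structio import Atom, Molecule, Residue, ResidueKey, StructureModel

DEFAULT_RESIDUE_CHARGE_TABLE: dict[str, int] = {
    **{name: 0 for name in STANDARD_AMINO_ACIDS}, **RESIDUE_CHARGES,
}


@dataclass
class PocketSpec:
    """Configuration of the active-site model.

    cutoff: residue-selection distance in Å (10.0 default; 6.0 or 5.0 for
    trimmed models of large ligands). Waters, ions and cofactors are kept
    only when whitelisted by residue key — structural-water judgment is
    left to the user. ``optimize_cutoff`` records the radius within which
    downstream relaxation is expected to act (documentation only).
    """

    cutoff: float = 10.0
    retained_water_keys: list[ResidueKey] = field(default_factory=list)
    retained_ion_keys: list[ResidueKey] = field(default_factory=list)
    retained_cofactor_keys: list[ResidueKey] = field(default_factory=list)
    optimize_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class Cap:
    kind: str  # "C_terminal_NHCH3" | "N_terminal_CHO"
    anchor: ResidueKey
    atoms: list[Atom]


@dataclass
class PocketModel:
    residues: list[Residue]
    caps: list[Cap]
    waters: list[Residue]
    ions: list[Residue]
    cofactors: list[Residue]
    net_charge: int
    atom_count: int
    spec: PocketSpec

    def all_atoms(self) -> list[Atom]:
        out = [a for r in self.residues for a in r.atoms]
        for cap in self.caps:
            out.extend(cap.atoms)
        for group in (self.waters, self.ions, self.cofactors):
            out.extend(a for r in group for a in r.atoms)
        return out

    def as_structure(self) -> StructureModel:
        """Re-wrap as a StructureModel (caps become FOR/NME residues)."""
        model = StructureModel()
        for res in self.residues:
            model.chains.setdefault(res.key[0], []).append(res)
        for cap in self.caps:
            name = "NME" if cap.kind == "C_terminal_NHCH3" else "FOR"
            key = (cap.anchor[0], name, cap.anchor[2], cap.anchor[3])
            model.chains.setdefault(cap.anchor[0], []).append(
                Residue(key=key, name=name, atoms=cap.atoms))
        model.waters = list(self.waters)
        model.ions = list(self.ions)
        model.cofactors = list(self.cofactors)
        return model


# --------------------------------------------------------------------------
# residue selection
# --------------------------------------------------------------------------

def _disulfide_partners(structure: StructureModel) -> dict[ResidueKey, ResidueKey]:
    """Map CYS residue keys to their disulfide partner (SG-SG < 2.5 Å)."""
    cys = [r for r in structure.residues() if r.name in ("CYS", "CYX")]
    pairs: dict[ResidueKey, ResidueKey] = {}
    for idx, a in enumerate(cys):
        sg_a = a.atom("SG")
        if sg_a is None:
            continue
        for b in cys[idx + 1:]:
            sg_b = b.atom("SG")
            if sg_b is None:
                continue
            if np.linalg.norm(sg_a.coords - sg_b.coords) < 2.5:
                pairs[a.key] = b.key
                pairs[b.key] = a.key
    return pairs


def select_residues(structure: StructureModel, ligands: list[Molecule],
                    cutoff: float, include_disulfide_partners: bool = True
                    ) -> set[ResidueKey]:
    """Residues with ≥1 atom within ``cutoff`` Å of any overlaid-ligand atom.

    Whole residues are the unit of selection. Cysteines whose disulfide
    partner is selected are pulled in as well (avoids cutting S-S bonds),
    unless disabled.
    """
    if not ligands:
        raise ValueError("empty ligand list")
    lig = np.vstack([m.coords for m in ligands])
    selected: set[ResidueKey] = set()
    for res in structure.residues():
        if res.atoms and cdist(res.coords, lig).min() <= cutoff:
            selected.add(res.key)
    if include_disulfide_partners:
        partners = _disulfide_partners(structure)
        changed = True
        while changed:
            changed = False
            for key in list(selected):
                partner = partners.get(key)
                if partner is not None and partner not in selected:
                    selected.add(partner)
                    changed = True
    return selected


# --------------------------------------------------------------------------
# capping
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length direction while placing cap hydrogens")
    return v / n


def _perpendicular(axis: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(axis, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(axis, ref))


def _make_n_cap(removed: Residue, anchor: Residue, serial: int) -> Cap:
    """-CH=O formyl cap on the N-terminal side of a kept segment.

    The formyl C and O sit at the removed neighbor's backbone C/O positions;
    the aldehyde H completes the trigonal plane.
    """
    c, o = removed.atom("C"), removed.atom("O")
    n_anchor = anchor.atom("N")
    if c is None or o is None or n_anchor is None:
        raise ValueError(
            f"cannot cap at {anchor.key}: removed neighbor {removed.key} "
            "lacks backbone C/O or anchor lacks N")
    h_dir = -_unit(_unit(o.coords - c.coords) + _unit(n_anchor.coords - c.coords))
    key = (removed.key[0], "FOR", removed.key[2], removed.key[3])
    atoms = [
        Atom(serial=serial, name="C", element="C", coords=c.coords.copy(), residue_key=key),
        Atom(serial=serial + 1, name="O", element="O", coords=o.coords.copy(), residue_key=key),
        Atom(serial=serial + 2, name="H", element="H",
             coords=c.coords + 1.09 * h_dir, residue_key=key),
    ]
    return Cap(kind="N_terminal_CHO", anchor=anchor.key, atoms=atoms)


def _make_c_cap(removed: Residue, anchor: Residue, serial: int) -> Cap:
    """-NH-CH3 N-methylamide cap on the C-terminal side of a kept segment.

    The amide N and methyl C sit at the removed neighbor's backbone N/CA
    positions; the amide H completes the plane and three methyl hydrogens
    are placed tetrahedrally.
    """
    n, ca = removed.atom("N"), removed.atom("CA")
    c_anchor = anchor.atom("C")
    if n is None or ca is None or c_anchor is None:
        raise ValueError(
            f"cannot cap at {anchor.key}: removed neighbor {removed.key} "
            "lacks backbone N/CA or anchor lacks C")
    key = (removed.key[0], "NME", removed.key[2], removed.key[3])
    hn_dir = -_unit(_unit(c_anchor.coords - n.coords) + _unit(ca.coords - n.coords))
    axis = _unit(ca.coords - n.coords)  # N -> methyl C
    p = _perpendicular(axis)
    q = np.cross(axis, p)
    cos_t, sin_t = np.cos(np.deg2rad(109.47)), np.sin(np.deg2rad(109.47))
    atoms = [
        Atom(serial=serial, name="N", element="N", coords=n.coords.copy(), residue_key=key),
        Atom(serial=serial + 1, name="CH3", element="C", coords=ca.coords.copy(), residue_key=key),
        Atom(serial=serial + 2, name="H", element="H",
             coords=n.coords + 1.01 * hn_dir, residue_key=key),
    ]
    for k, theta in enumerate((0.0, 2 * np.pi / 3, 4 * np.pi / 3)):
        h_dir = cos_t * (-axis) + sin_t * (np.cos(theta) * p + np.sin(theta) * q)
        atoms.append(Atom(serial=serial + 3 + k, name=f"H{k + 1}", element="H",
                          coords=ca.coords + 1.09 * _unit(h_dir), residue_key=key))
    return Cap(kind="C_terminal_NHCH3", anchor=anchor.key, atoms=atoms)


def build_capped_pocket(structure: StructureModel, selection: set[ResidueKey],
                        spec: PocketSpec | None = None,
                        charge_table: dict[str, int] | None = None) -> PocketModel:
    """Assemble the capped pocket from a residue selection.

    Contiguous selected stretches of each chain are kept intact; every cut
    peptide bond receives exactly one cap. Whitelisted waters, ions and
    cofactors are appended and the integer net charge is computed (caps are
    neutral by construction).
    """
    if not selection:
        raise ValueError("empty residue selection")
    spec = spec or PocketSpec()
    table = dict(DEFAULT_RESIDUE_CHARGE_TABLE if charge_table is None else charge_table)

    known = {r.key for r in structure.residues()}
    missing = selection - known
    if missing:
        raise KeyError(f"selection references absent residues: {sorted(missing)}")

    residues: list[Residue] = []
    caps: list[Cap] = []
    serial = 900000
    for chain in structure.chains.values():
        flags = [r.key in selection for r in chain]
        idx = 0
        while idx < len(chain):
            if not flags[idx]:
                idx += 1
                continue
            start = idx
            while idx < len(chain) and flags[idx]:
                idx += 1
            end = idx - 1  # inclusive
            residues.extend(chain[start:end + 1])
            if start > 0:
                caps.append(_make_n_cap(chain[start - 1], chain[start], serial))
                serial += 10
            if end < len(chain) - 1:
                caps.append(_make_c_cap(chain[end + 1], chain[end], serial))
                serial += 10

    def pick(pool: list[Residue], keys: list[ResidueKey], label: str) -> list[Residue]:
        by_key = {r.key: r for r in pool}
        out = []
        for key in keys:
            if key not in by_key:
                raise KeyError(f"retained {label} key {key} not present in structure")
            out.append(by_key[key])
        return out

    waters = pick(structure.waters, spec.retained_water_keys, "water")
    ions = pick(structure.ions, spec.retained_ion_keys, "ion")
    cofactors = pick(structure.cofactors, spec.retained_cofactor_keys, "cofactor")

    model = PocketModel(residues=residues, caps=caps, waters=waters, ions=ions,
                        cofactors=cofactors, net_charge=0, atom_count=0, spec=spec)
    model.net_charge = pocket_charge(model, table)
    model.atom_count = len(model.all_atoms())
    return model


# --------------------------------------------------------------------------
# charge bookkeeping
# --------------------------------------------------------------------------

def pocket_charge(model: PocketModel, charge_table: dict[str, int] | None = None) -> int:
    """Integer net charge: Σ residue charges + Σ ion/cofactor charges.

    Residue charges come from ``charge_table`` (name → integer e); a residue
    missing from the table falls back to the sum of its atoms' formal
    charges only if any are set, otherwise it is an error. Caps are neutral.
    """
    table = DEFAULT_RESIDUE_CHARGE_TABLE if charge_table is None else charge_table
    total = 0
    for res in model.residues:
        if res.name in table:
            total += table[res.name]
        elif any(a.formal_charge for a in res.atoms) or res.formal_charge:
            total += res.formal_charge or sum(a.formal_charge for a in res.atoms)
        else:
            raise KeyError(f"no charge entry for residue {res.name} {res.key}")
    for res in model.ions:
        total += res.formal_charge or sum(a.formal_charge for a in res.atoms)
    for res in model.cofactors:
        total += res.formal_charge or sum(a.formal_charge for a in res.atoms)
    return total


def boundary_charge_report(model: PocketModel, ligands: list[Molecule],
                           distance: float = 8.0,
                           charge_table: dict[str, int] | None = None) -> list[dict]:
    """List charged residues farther than ``distance`` Å from every ligand.

    Truncation can expose such charges at the model boundary; they are kept
    (screened by the solvent model downstream) but flagged for inspection.
    """
    if not ligands:
        raise ValueError("empty ligand list")
    table = DEFAULT_RESIDUE_CHARGE_TABLE if charge_table is None else charge_table
    lig = np.vstack([m.coords for m in ligands])
    report = []
    for res in model.residues:
        charge = table.get(res.name, res.formal_charge)
        if charge == 0 or not res.atoms:
            continue
        dmin = float(cdist(res.coords, lig).min())
        if dmin > distance:
            report.append({"residue": res.key, "charge": charge,
                           "min_distance": dmin})
    return report
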