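"""Molecular structure I/O, graphs and geometry.

Reads and writes PDB v3.3 (fixed columns), Tripos Mol2 and XYZ; maintains
the covalent graph (bond perception from covalent radii, ring membership,
rotatable-bond counting); provides rigid-body superposition (Kabsch) and
closest-approach screening used for representative-receptor selection.

Coordinates are in Å throughout. Atoms are indexed 0-based internally;
PDB serial numbers are preserved for I/O only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from ._data import (
    COVALENT_RADII,
    METAL_ION_CHARGES,
    RECOGNIZED_ELEMENTS,
    WATER_RESNAMES,
)


class ParseError(ValueError):
    """Malformed structure file content."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

ResidueKey = tuple[str, str, int, str]  # (chain id, residue name, number, icode)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    partial_charge: float | None = None
    residue_key: ResidueKey = ("", "", 0, "")
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.element not in RECOGNIZED_ELEMENTS:
            raise ValueError(f"atom {self.serial}: unrecognized element {self.element!r}")

    def copy(self) -> "Atom":
        return dataclasses.replace(self, coords=self.coords.copy())


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: object = 1  # 1 | 2 | 3 | "aromatic"
    in_ring: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class Molecule:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    net_charge: int = 0
    title: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            net_charge=self.net_charge,
            title=self.title,
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        g.add_edges_from(b.key for b in self.bonds)
        return g


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)
    formal_charge: int = 0

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Hierarchical receptor model: chains → ordered residues → atoms.

    Waters, single-atom metal ions and other hetero groups (cofactors) are
    kept apart from the polymer chains.
    """

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    waters: list[Residue] = field(default_factory=list)
    ions: list[Residue] = field(default_factory=list)
    cofactors: list[Residue] = field(default_factory=list)

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        for chain in self.chains.values():
            out.extend(chain)
        return out

    def all_atoms(self) -> list[Atom]:
        out = [a for r in self.residues() for a in r.atoms]
        for group in (self.waters, self.ions, self.cofactors):
            out.extend(a for r in group for a in r.atoms)
        return out

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.all_atoms()], dtype=float).reshape(-1, 3)

    def residue_map(self) -> dict[ResidueKey, Residue]:
        return {r.key: r for r in self.residues()}


# --------------------------------------------------------------------------
# PDB
# --------------------------------------------------------------------------

def _infer_element(record: str, lineno: int) -> str:
    elem = record[76:78].strip() if len(record) >= 78 else ""
    if elem:
        elem = elem.capitalize()
        if elem in RECOGNIZED_ELEMENTS:
            return elem
    # fall back to the leading letters of the atom name
    name = record[12:16]
    letters = "".join(c for c in name if c.isalpha())
    for cand in (letters[:2].capitalize(), letters[:1].upper()):
        if cand in RECOGNIZED_ELEMENTS:
            return cand
    raise ParseError(f"line {lineno}: cannot infer element from {record[:20]!r}")


def parse_pdb(text: str, altloc_policy: str = "A") -> StructureModel:
    """Parse a PDB v3.3 document into a StructureModel.

    Alternate locations: records whose altloc is blank or equals
    ``altloc_policy`` are kept; others are dropped. HOH/WAT residues are
    classified as waters; single-atom HETATM groups of a recognized metal
    element become ions and receive their table formal charge; remaining
    HETATM groups are cofactors.
    """
    if not text.strip():
        raise ParseError("empty PDB input")
    residues: dict[ResidueKey, Residue] = {}
    order: list[ResidueKey] = []
    hetero_keys: set[ResidueKey] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: truncated {rec.strip()} record")
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or " "
            resnum = int(line[22:26])
            icode = line[26].strip()
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed fixed-width field ({exc})") from exc
        if altloc and altloc != altloc_policy:
            continue
        element = _infer_element(line, lineno)
        key: ResidueKey = (chain, resname, resnum, icode)
        atom = Atom(
            serial=serial, name=name, element=element, coords=np.array(xyz),
            residue_key=key, altloc=altloc, is_hetero=(rec == "HETATM"),
        )
        if key not in residues:
            residues[key] = Residue(key=key, name=resname)
            order.append(key)
        residues[key].atoms.append(atom)
        if rec == "HETATM":
            hetero_keys.add(key)
    if not residues:
        raise ParseError("no ATOM/HETATM records found")

    model = StructureModel()
    for key in order:
        res = residues[key]
        if res.name in WATER_RESNAMES:
            model.waters.append(res)
        elif key in hetero_keys and len(res.atoms) == 1 and res.atoms[0].element in METAL_ION_CHARGES:
            charge = METAL_ION_CHARGES[res.atoms[0].element]
            res.atoms[0].formal_charge = charge
            res.formal_charge = charge
            model.ions.append(res)
        elif key in hetero_keys:
            model.cofactors.append(res)
        else:
            model.chains.setdefault(key[0], []).append(res)
    for chain in model.chains.values():
        chain.sort(key=lambda r: (r.key[2], r.key[3]))
    return model


def write_pdb(model: StructureModel, hetero_groups: tuple[str, ...] = ("waters", "ions", "cofactors")) -> str:
    """Serialize a StructureModel (or pocket) back to PDB fixed columns."""
    lines: list[str] = []
    serial = 0

    def emit(res: Residue, hetero: bool) -> None:
        nonlocal serial
        for a in res.atoms:
            serial += 1
            rec = "HETATM" if (hetero or a.is_hetero) else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            chain, resname, resnum, icode = res.key
            x, y, z = a.coords
            lines.append(
                f"{rec}{serial:>5d} {name:<4.4s}{a.altloc or ' ':1s}{resname:<3.3s} "
                f"{chain:1s}{resnum:>4d}{icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2.2s}"
            )

    for chain in model.chains.values():
        for res in chain:
            emit(res, hetero=False)
        lines.append("TER")
    for group in hetero_groups:
        for res in getattr(model, group):
            emit(res, hetero=True)
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Mol2
# --------------------------------------------------------------------------

_MOL2_BOND_ORDERS = {"1": 1, "2": 2, "3": 3, "ar": "aromatic", "am": 1, "du": 1, "un": 1}


def parse_mol2(text: str) -> Molecule:
    """Parse a Tripos Mol2 document (MOLECULE/ATOM/BOND sections).

    Net charge is the sum of the per-atom charge column rounded to the
    nearest integer. Ring flags are recomputed from the bond graph.
    """
    lines = text.splitlines()
    sections: dict[str, list[tuple[int, str]]] = {}
    current: str | None = None
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("@<TRIPOS>"):
            current = line[9:].strip().upper()
            sections.setdefault(current, [])
            continue
        if current is not None and line.strip() and not line.startswith("#"):
            sections[current].append((lineno, line))
    for needed in ("MOLECULE", "ATOM"):
        if needed not in sections:
            raise ParseError(f"Mol2 missing @<TRIPOS>{needed} section")
    if "BOND" not in sections:
        raise ParseError("Mol2 missing @<TRIPOS>BOND section")

    mol_lines = sections["MOLECULE"]
    title = mol_lines[0][1].strip() if mol_lines else ""
    declared_atoms = declared_bonds = None
    if len(mol_lines) > 1:
        counts = mol_lines[1][1].split()
        if counts:
            declared_atoms = int(counts[0])
            declared_bonds = int(counts[1]) if len(counts) > 1 else None

    atoms: list[Atom] = []
    id_map: dict[int, int] = {}
    total_charge = 0.0
    has_charges = False
    for lineno, line in enumerate_section(sections["ATOM"]):
        f = line.split()
        if len(f) < 6:
            raise ParseError(f"line {lineno}: short Mol2 ATOM record")
        atom_id = int(f[0])
        sybyl = f[5]
        element = sybyl.split(".")[0].capitalize()
        if element not in RECOGNIZED_ELEMENTS:
            raise ParseError(f"line {lineno}: unrecognized element {element!r} in {sybyl!r}")
        charge = None
        if len(f) >= 9:
            charge = float(f[8])
            has_charges = True
            total_charge += charge
        id_map[atom_id] = len(atoms)
        atoms.append(Atom(
            serial=atom_id, name=f[1], element=element,
            coords=np.array([float(f[2]), float(f[3]), float(f[4])]),
            partial_charge=charge,
        ))
    if declared_atoms is not None and declared_atoms != len(atoms):
        raise ParseError(
            f"Mol2 header declares {declared_atoms} atoms, found {len(atoms)}")

    bonds: list[Bond] = []
    for lineno, line in enumerate_section(sections["BOND"]):
        f = line.split()
        if len(f) < 4:
            raise ParseError(f"line {lineno}: short Mol2 BOND record")
        order = _MOL2_BOND_ORDERS.get(f[3].lower(), 1)
        bonds.append(Bond(i=id_map[int(f[1])], j=id_map[int(f[2])], order=order))
    if declared_bonds is not None and declared_bonds != len(bonds):
        raise ParseError(
            f"Mol2 header declares {declared_bonds} bonds, found {len(bonds)}")

    net = int(round(total_charge)) if has_charges else 0
    mol = Molecule(atoms=atoms, bonds=bonds, net_charge=net, title=title)
    mol.bonds = _flag_rings(mol)
    return mol


def enumerate_section(entries: list[tuple[int, str]]):
    for lineno, line in entries:
        yield lineno, line


def write_mol2(mol: Molecule) -> str:
    lines = ["@<TRIPOS>MOLECULE", mol.title or "molecule",
             f"{len(mol.atoms)} {len(mol.bonds)} 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for idx, a in enumerate(mol.atoms, start=1):
        q = a.partial_charge if a.partial_charge is not None else float(a.formal_charge)
        x, y, z = a.coords
        lines.append(f"{idx:>6d} {a.name or a.element:<6s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                     f"{a.element:<5s} 1 LIG {q:>9.4f}")
    lines.append("@<TRIPOS>BOND")
    rev = {1: "1", 2: "2", 3: "3", "aromatic": "ar"}
    for idx, b in enumerate(mol.bonds, start=1):
        lines.append(f"{idx:>5d} {b.i + 1:>5d} {b.j + 1:>5d} {rev[b.order]:>4s}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

def parse_xyz(text: str) -> Molecule:
    """Parse an XYZ block; the comment line may carry ``charge=N``."""
    lines = text.strip().splitlines()
    if len(lines) < 2:
        raise ParseError("XYZ input too short")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError("line 1: XYZ atom count missing") from exc
    comment = lines[1]
    charge = 0
    for token in comment.split():
        if token.lower().startswith("charge="):
            charge = int(token.split("=", 1)[1])
    atoms = []
    for lineno, line in enumerate(lines[2:2 + n], start=3):
        f = line.split()
        if len(f) < 4:
            raise ParseError(f"line {lineno}: short XYZ record")
        elem = f[0].capitalize()
        atoms.append(Atom(serial=lineno - 2, name=elem, element=elem,
                          coords=np.array([float(f[1]), float(f[2]), float(f[3])])))
    if len(atoms) != n:
        raise ParseError(f"XYZ declares {n} atoms, found {len(atoms)}")
    return Molecule(atoms=atoms, net_charge=charge)


def write_xyz(mol: Molecule, comment: str | None = None) -> str:
    head = comment if comment is not None else f"charge={mol.net_charge}"
    lines = [str(len(mol.atoms)), head]
    for a in mol.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<3s} {x:>14.8f} {y:>14.8f} {z:>14.8f}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# bond perception and rotatable bonds
# --------------------------------------------------------------------------

def _flag_rings(mol: Molecule) -> list[Bond]:
    """Recompute in_ring flags: an edge is in a ring iff it is not a bridge."""
    g = mol.graph()
    bridges = {tuple(sorted(e)) for e in nx.bridges(g)} if g.number_of_edges() else set()
    return [dataclasses.replace(b, in_ring=b.key not in bridges) for b in mol.bonds]


def perceive_bonds(mol: Molecule, tolerance: float = 1.3) -> Molecule:
    """Add bonds where r < tolerance × (covalent-radius sum).

    Hydrogens are bonded only to their single nearest heavy atom. Ring
    membership is recomputed from graph cycles. Isolated atoms are allowed.
    """
    n = len(mol.atoms)
    out = mol.copy()
    if n < 2:
        out.bonds = []
        return out
    coords = out.coords
    radii = np.array([COVALENT_RADII[a.element] for a in out.atoms])
    is_h = np.array([a.element == "H" for a in out.atoms])
    d = cdist(coords, coords)
    cut = tolerance * (radii[:, None] + radii[None, :])
    bonds: list[Bond] = []
    heavy = np.where(~is_h)[0]
    for i in range(n):
        if is_h[i]:
            if heavy.size == 0:
                # all-hydrogen system (e.g. H2): nearest partner within cutoff
                j = int(np.argmin(np.where(np.arange(n) == i, np.inf, d[i])))
                if d[i, j] < cut[i, j] and i < j:
                    bonds.append(Bond(i=i, j=j))
                continue
            j = int(heavy[np.argmin(d[i, heavy])])
            if d[i, j] < cut[i, j]:
                bonds.append(Bond(i=min(i, j), j=max(i, j)))
        else:
            for j in heavy[heavy > i]:
                if d[i, j] < cut[i, j]:
                    bonds.append(Bond(i=i, j=int(j)))
    # dedupe (H-H case may double-add)
    seen: dict[tuple[int, int], Bond] = {}
    for b in bonds:
        seen.setdefault(b.key, b)
    out.bonds = list(seen.values())
    out.bonds = _flag_rings(out)
    return out


def _is_amide(mol: Molecule, bi: int, bj: int, adjacency: dict[int, list[int]]) -> bool:
    """C–N single bond where the carbon also carries a carbonyl oxygen."""
    ei, ej = mol.atoms[bi].element, mol.atoms[bj].element
    if {ei, ej} != {"C", "N"}:
        return False
    c = bi if ei == "C" else bj
    for b in mol.bonds:
        if c in (b.i, b.j):
            other = b.j if b.i == c else b.i
            if mol.atoms[other].element == "O":
                r = float(np.linalg.norm(mol.atoms[c].coords - mol.atoms[other].coords))
                if b.order == 2 or r <= 1.28:
                    return True
    return False


def count_rotatable_bonds(mol: Molecule, exclude_amide: bool = True) -> int:
    """Count rotatable bonds under the package's documented definition.

    A bond is rotatable iff it is an acyclic single (non-aromatic) bond
    between two heavy atoms, each endpoint has at least one further heavy
    neighbor, and (by default) it is not an amide C–N bond. This is the
    package's own convention; no single community definition exists.
    """
    if not mol.bonds:
        raise ValueError("molecule has no bonds; run perceive_bonds first")
    adjacency: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for b in mol.bonds:
        adjacency[b.i].append(b.j)
        adjacency[b.j].append(b.i)

    def heavy_neighbors(idx: int, excluding: int) -> int:
        return sum(1 for k in adjacency[idx]
                   if k != excluding and mol.atoms[k].element != "H")

    count = 0
    for b in mol.bonds:
        if b.order != 1 or b.in_ring:
            continue
        ai, aj = mol.atoms[b.i], mol.atoms[b.j]
        if ai.element == "H" or aj.element == "H":
            continue
        if heavy_neighbors(b.i, b.j) < 1 or heavy_neighbors(b.j, b.i) < 1:
            continue
        if exclude_amide and _is_amide(mol, b.i, b.j, adjacency):
            continue
        count += 1
    return count


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray  # 3×3 proper rotation
    translation: np.ndarray  # 3-vector
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray,
              pairing: list[tuple[int, int]] | None = None) -> Superposition:
    """Least-squares rigid-body superposition (Kabsch, SVD form).

    ``pairing`` lists (mobile index, reference index) pairs; by default the
    i-th points are paired. Returns a proper rotation (det +1), translation
    and the post-fit RMSD over the paired points.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if pairing is None:
        if len(mobile) != len(reference):
            raise ValueError("unequal point counts require an explicit pairing")
        pairing = [(i, i) for i in range(len(mobile))]
    if len(pairing) < 3:
        raise ValueError("superposition needs at least 3 paired points")
    m = mobile[[p[0] for p in pairing]]
    r = reference[[p[1] for p in pairing]]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    dm, dr = m - mc, r - rc
    if np.linalg.matrix_rank(dm, tol=1e-8) < 2 or np.linalg.matrix_rank(dr, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point configuration")
    h = dm.T @ dr
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def closest_approach(structure: StructureModel, ligands: list[Molecule]) -> float:
    """Minimum protein-atom/ligand-atom distance over all overlaid ligands."""
    if not ligands:
        raise ValueError("empty ligand list")
    pcoords = structure.atom_coords()
    if pcoords.size == 0:
        raise ValueError("structure has no atoms")
    lig = np.vstack([m.coords for m in ligands])
    if lig.size == 0:
        raise ValueError("ligands have no atoms")
    return float(cdist(pcoords, lig).min())


def select_receptor(candidates: list[StructureModel], ligands: list[Molecule],
                    clash_threshold: float = 1.0):
    """Rank candidate receptor structures by closest ligand approach.

    The structure with the *largest* closest-approach distance best
    accommodates the full overlaid ligand set and is selected. Returns
    (selected index, report rows) where each row carries the distance and
    a clash flag (approach below ``clash_threshold`` Å).
    """
    if not candidates:
        raise ValueError("no candidate structures")
    rows = []
    for idx, st in enumerate(candidates):
        d = closest_approach(st, ligands)
        rows.append({"index": idx, "closest_approach": d,
                     "clash": d < clash_threshold})
    best = max(rows, key=lambda r: r["closest_approach"])["index"]
    return best, rows
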