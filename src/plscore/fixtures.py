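"""Deterministic synthetic data for exercising the full scoring pipeline.

Everything here is generated programmatically from a seed (numpy PCG64),
so the package is testable end to end with no downloads and no external
engine. The toy systems emulate the *shape* of the real problem — a small
polypeptide pocket with ionizable residues, structural waters and a
divalent cation; ligand series spanning configurable rotatable-bond
counts and formal charges (−1..+2); affinities generated with a known
linear relation (plus Gaussian noise) to the classical test backend's
score — without any claim of physical realism. Toy "molecules" are chains
of heavy atoms spaced near the Lennard-Jones minimum with an explicit
bond topology, because the classical backend has no bonded terms.

The dataset envelope mirrors the reference benchmark: ligand charges
−1..+2 and rotatable-bond counts 0..25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bench import AffinityRecord, TargetSeries, dG_to_Ki
from .energy import (
    CachingBackend,
    EnergyBackend,
    EnergyResult,
    System,
    make_test_backend,
)
from .pocket import PocketSpec, build_capped_pocket, select_residues
from .scorer import ComplexRecord, ScoringSpec, score_series
from .structio import Atom, Bond, Molecule, Residue, StructureModel, write_mol2, write_pdb
from .thermo import NONE, RELEASE, UPTAKE, ProtonationCase, SpeciesFreeEnergies

# Fixture-only solvation constants for the water species (kcal/mol).
# Arbitrary declared values, clearly non-physical; real use must supply
# experiment-derived constants in configuration.
FIXTURE_SPECIES_G = {"G_H2O": -60.0, "G_OHminus": -40.0, "G_H3Oplus": -50.0}


@dataclass
class FixtureConfig:
    seed: int = 0
    n_residues: int = 12
    n_ligands: int = 12
    rotbond_range: tuple[int, int] = (0, 25)
    charge_range: tuple[int, int] = (-1, 2)
    noise_sd: float = 0.5          # kcal/mol on the planted ΔG
    signal_slope: float = 0.03     # ΔG per unit of test-backend score
    signal_intercept: float = -9.0  # kcal/mol
    n_asp: int = 1
    n_lys: int = 1
    n_waters: int = 2
    with_zn: bool = True
    pocket_cutoff: float = 10.0
    helix_radius: float = 5.5      # Å, widened so the axial ligand channel is open

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("toy pocket needs at least 4 residues")
        lo, hi = self.rotbond_range
        if not (0 <= lo <= hi <= 25):
            raise ValueError("rotbond_range must lie within [0, 25]")
        lo, hi = self.charge_range
        if not (-1 <= lo <= hi <= 2):
            raise ValueError("charge_range must lie within [-1, +2]")

    @property
    def planted_pocket_charge(self) -> int:
        return self.n_lys - self.n_asp + (2 if self.with_zn else 0)


# --------------------------------------------------------------------------
# toy pocket
# --------------------------------------------------------------------------

def make_toy_pocket(config: FixtureConfig) -> StructureModel:
    """Small helical polypeptide with planted charges, waters and a cation.

    Deterministic per seed: same seed → bit-identical structure; different
    seeds perturb coordinates but keep the topology schema. The planted
    net charge of the eventual pocket equals ``config.planted_pocket_charge``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    radius, rise, turn = config.helix_radius, 1.5, np.deg2rad(60.0)
    jitter = rng.normal(0.0, 0.05, size=(n, 3))

    # residue name pattern: charged residues spread over the chain interior
    names = ["ALA"] * n
    charged_slots = np.linspace(1, n - 2, config.n_asp + config.n_lys).astype(int)
    for k, slot in enumerate(charged_slots):
        names[int(slot)] = "ASP" if k < config.n_asp else "LYS"

    model = StructureModel()
    chain: list[Residue] = []
    serial = 1
    ca_prev = None
    for i in range(n):
        theta = i * turn
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        ca = ca + jitter[i]
        ca_next = np.array([radius * np.cos(theta + turn),
                            radius * np.sin(theta + turn), rise * (i + 1)])
        key = (" ", names[i], i + 1, "")
        res = Residue(key=key, name=names[i])

        def add(name: str, element: str, xyz: np.ndarray, fq: int = 0) -> None:
            nonlocal serial
            res.atoms.append(Atom(serial=serial, name=name, element=element,
                                  coords=xyz, formal_charge=fq,
                                  partial_charge=float(fq), residue_key=key))
            serial += 1

        n_pos = (ca + 0.25 * (ca_prev - ca)) if ca_prev is not None \
            else ca + np.array([0.0, 0.0, -1.0])
        c_pos = ca + 0.40 * (ca_next - ca)
        out_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
        o_pos = c_pos + 1.23 * out_dir
        add("N", "N", n_pos)
        add("CA", "C", ca)
        add("C", "C", c_pos)
        add("O", "O", o_pos)
        if names[i] != "GLY":
            add("CB", "C", ca + 1.53 * out_dir)
        if names[i] == "ASP":
            add("OD1", "O", ca + 3.0 * out_dir, fq=-1)
        elif names[i] == "LYS":
            add("NZ", "N", ca + 3.5 * out_dir, fq=1)
        chain.append(res)
        ca_prev = ca
    model.chains[" "] = chain

    z_mid = rise * n / 2.0
    for w in range(config.n_waters):
        angle = 2 * np.pi * (w + 0.5) / max(config.n_waters, 1)
        pos = np.array([(radius + 3.5) * np.cos(angle),
                        (radius + 3.5) * np.sin(angle),
                        z_mid + (w - config.n_waters / 2.0) * 1.2])
        pos = pos + rng.normal(0.0, 0.05, size=3)
        key = (" ", "HOH", 500 + w, "")
        model.waters.append(Residue(key=key, name="HOH", atoms=[
            Atom(serial=serial, name="O", element="O", coords=pos,
                 residue_key=key, is_hetero=True)]))
        serial += 1
    if config.with_zn:
        key = (" ", "ZN", 600, "")
        model.ions.append(Residue(key=key, name="ZN", formal_charge=2, atoms=[
            Atom(serial=serial, name="ZN", element="Zn",
                 coords=np.array([radius, 0.0, -3.0]), formal_charge=2,
                 partial_charge=2.0, residue_key=key, is_hetero=True)]))
    return model


# --------------------------------------------------------------------------
# toy ligands
# --------------------------------------------------------------------------

def make_toy_ligand(n_rotatable: int, net_charge: int, seed: int = 0,
                    spacing: float = 3.85, perturb: float = 0.0) -> Molecule:
    """Heavy-atom chain with exactly ``n_rotatable`` rotatable bonds.

    A linear chain of L heavy atoms with explicit single bonds has L−3
    rotatable bonds under the package definition, so L = n_rotatable + 3.
    Positive formal charges are carried by leading N atoms, a −1 charge by
    a trailing O. Atoms sit near the Lennard-Jones minimum spacing of the
    classical backend so that toy geometries are close to relaxed.
    """
    if n_rotatable < 0:
        raise ValueError("rotatable-bond count must be non-negative")
    if not (-1 <= net_charge <= 2):
        raise ValueError("toy ligand net charge must lie in [-1, +2]")
    rng = np.random.default_rng(seed)
    length = n_rotatable + 3
    elements = ["C"] * length
    charges = [0] * length
    if net_charge >= 1:
        elements[0], charges[0] = "N", 1
    if net_charge == 2:
        elements[min(2, length - 1)] = "N"
        charges[min(2, length - 1)] = 1
    if net_charge == -1:
        elements[-1], charges[-1] = "O", -1
    atoms = []
    for k in range(length):
        xyz = np.array([0.9 * (-1) ** k, 0.0, spacing * k])
        if perturb:
            xyz = xyz + rng.normal(0.0, perturb, size=3)
        atoms.append(Atom(serial=k + 1, name=f"{elements[k]}{k + 1}",
                          element=elements[k], coords=xyz,
                          formal_charge=charges[k],
                          partial_charge=float(charges[k])))
    bonds = [Bond(i=k, j=k + 1) for k in range(length - 1)]
    return Molecule(atoms=atoms, bonds=bonds, net_charge=net_charge,
                    title=f"toy ligand rot={n_rotatable} q={net_charge:+d}")


def _place_in_pocket(mol: Molecule, config: FixtureConfig, offset: float) -> Molecule:
    """Pose the ligand along the pocket channel axis."""
    out = mol.copy()
    z0 = 1.5 * config.n_residues / 2.0 - (len(out.atoms) - 1) * 3.85 / 2.0
    shift = np.array([0.4 * np.cos(offset), 0.4 * np.sin(offset), z0])
    for a in out.atoms:
        a.coords = a.coords + shift
    return out


# --------------------------------------------------------------------------
# toy series (full pipeline)
# --------------------------------------------------------------------------

def make_toy_series(config: FixtureConfig,
                    backend: EnergyBackend | None = None,
                    scoring_spec: ScoringSpec | None = None):
    """Generate complex records plus affinities with a planted linear law.

    Poses are placed in the shared toy pocket, scored with the classical
    test backend, and the "true" binding free energy of ligand i is

        ΔG_i = signal_slope · score_i + signal_intercept + N(0, noise_sd)

    back-converted to a Ki (or, for every third ligand, an IC50 at twice
    the effective Ki). Roughly one record in five is flagged as modeled
    rather than crystal, and every fourth carries a protonation change
    with planted pKa/pH and fixture species energies.

    Returns (records, series, truth) where truth maps ligand id to its
    planted score and ΔG.
    """
    rng = np.random.default_rng(config.seed + 1)
    structure = make_toy_pocket(config)
    backend = backend or CachingBackend(make_test_backend())
    scoring_spec = scoring_spec or ScoringSpec()

    lo, hi = config.rotbond_range
    qlo, qhi = config.charge_range
    ligands, records = [], []
    for i in range(config.n_ligands):
        rot = int(rng.integers(lo, hi + 1))
        q = int(rng.integers(qlo, qhi + 1))
        mol = make_toy_ligand(rot, q, seed=config.seed * 1000 + i, perturb=0.03)
        pose = _place_in_pocket(mol, config, offset=2 * np.pi * i / config.n_ligands)
        ligands.append(pose)

    selection = select_residues(structure, ligands, cutoff=config.pocket_cutoff)
    spec = PocketSpec(
        cutoff=config.pocket_cutoff,
        retained_water_keys=[r.key for r in structure.waters],
        retained_ion_keys=[r.key for r in structure.ions],
    )
    pocket = build_capped_pocket(structure, selection, spec)

    for i, pose in enumerate(ligands):
        if i % 4 == 1:
            direction = UPTAKE if i % 8 == 1 else RELEASE
            pka = float(rng.uniform(5.5, 9.5))
            species = SpeciesFreeEnergies(
                G_L=-10.0, G_LHplus=-12.0 + float(rng.normal(0, 0.5)),
                G_LH=-11.0, G_Lminus=-9.0 + float(rng.normal(0, 0.5)),
                **FIXTURE_SPECIES_G)
            case = ProtonationCase(direction=direction, pKa=pka, pH=7.4,
                                   species_G=species)
        else:
            case = ProtonationCase(direction=NONE)
        records.append(ComplexRecord(
            id=f"LIG{i:03d}", pocket=pocket, ligand_conformers=[pose],
            ligand_net_charge=pose.net_charge, protonation=case, assay_pH=7.4,
            provenance="modeled" if i % 5 == 4 else "crystal"))

    table = score_series(backend, records, scoring_spec)
    if table.attrs["n_failures"]:
        bad = table.loc[table["status"] != "ok", "id"].tolist()
        raise RuntimeError(f"fixture scoring failed for {bad}")

    noise = rng.normal(0.0, config.noise_sd, size=config.n_ligands)
    affinities, flags, truth = {}, {}, {}
    for row, eps in zip(table.itertuples(), noise):
        dg = config.signal_slope * row.total + config.signal_intercept + eps
        ki = dG_to_Ki(dg)
        idx = int(row.Index)
        if idx % 3 == 2:
            aff = AffinityRecord(kind="IC50", value=2.0 * ki, assay_pH=7.4)
        else:
            aff = AffinityRecord(kind="Kd" if idx % 3 else "Ki", value=ki,
                                 assay_pH=7.4)
        affinities[row.id] = aff
        flags[row.id] = records[idx].provenance == "crystal"
        truth[row.id] = {"score": float(row.total), "dG": float(dg)}

    series = TargetSeries(target_id=f"TOY{config.seed:02d}",
                          ligand_ids=[r.id for r in records],
                          affinities=affinities, crystal_flags=flags)
    return records, series, truth


# --------------------------------------------------------------------------
# multi-target statistical benchmark (planted correlation)
# --------------------------------------------------------------------------

def make_statistical_benchmark(seed: int, n_targets: int = 10,
                               n_per_target: int = 500, rho2: float = 0.69,
                               slope: float = 1.0, score_sd: float = 1.5):
    """Score table + series with an exactly known expected correlation.

    Scores are drawn N(−35, score_sd²); the planted free energy is
    ΔG = slope·score − intercept + N(0, σ_n²) with σ_n chosen so that the
    population correlation satisfies ρ² = rho2. The analytic expectation
    reported per target uses the realized signal variance:

        ρ²_t = var(slope·score_t) / (var(slope·score_t) + σ_n²).

    Returns (score_table, series list, expected dict target → ρ²_t).
    """
    if not (0.0 < rho2 < 1.0):
        raise ValueError("rho2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma_n = abs(slope) * score_sd * np.sqrt((1.0 - rho2) / rho2)
    rows, series, expected = [], [], {}
    for t in range(n_targets):
        tid = f"SYN{t:02d}"
        scores = rng.normal(-35.0, score_sd, size=n_per_target)
        noise = rng.normal(0.0, sigma_n, size=n_per_target)
        dg = slope * scores + 27.0 + noise  # ΔG centered near −8 kcal/mol
        lids = [f"{tid}_L{i:03d}" for i in range(n_per_target)]
        affinities = {lid: AffinityRecord(kind="Ki", value=dG_to_Ki(float(g)))
                      for lid, g in zip(lids, dg)}
        flags = {lid: True for lid in lids}
        series.append(TargetSeries(target_id=tid, ligand_ids=lids,
                                   affinities=affinities, crystal_flags=flags))
        rows.extend({"id": lid, "total": float(s)} for lid, s in zip(lids, scores))
        sig_var = float(np.var(slope * scores))
        expected[tid] = sig_var / (sig_var + sigma_n ** 2)
    return pd.DataFrame(rows), series, expected


# --------------------------------------------------------------------------
# engine logs and auxiliary backends
# --------------------------------------------------------------------------

def make_engine_log(energy: float, converged: bool = True,
                    solvation: float | None = None) -> str:
    """Synthetic engine log that parse_engine_output inverts exactly."""
    lines = [" *  SYNTHETIC SEMIEMPIRICAL ENGINE LOG  *", ""]
    lines.append(f"          FINAL HEAT OF FORMATION = {energy:.8f} KCAL/MOL")
    if solvation is not None:
        lines.append(f"          SOLVATION FREE ENERGY = {solvation:.8f} KCAL/MOL")
    lines.append("")
    if converged:
        lines.append(" == MOPAC DONE ==")
    else:
        lines.append(" CALCULATION ABANDONED")
    return "\n".join(lines) + "\n"


class HarmonicBackend(EnergyBackend):
    """Isotropic harmonic well around a reference geometry (test oracle).

    E = k/2 · Σ|x − x0|²; gradient k·(x − x0); solvation identically zero.
    """

    has_gradient = True
    has_solvation = True

    def __init__(self, k: float, x0: np.ndarray):
        self.k = float(k)
        self.x0 = np.asarray(x0, dtype=float).reshape(-1, 3)

    def evaluate(self, system: System, solvated: bool = False) -> EnergyResult:
        d = system.coords - self.x0
        e = 0.5 * self.k * float(np.sum(d ** 2))
        return EnergyResult(e_gas=e, g_solv=0.0 if solvated else None,
                            meta="harmonic test backend")

    def gradient(self, system: System, solvated: bool = False) -> np.ndarray:
        return self.k * (system.coords - self.x0)


# --------------------------------------------------------------------------
# fixture directory emission (CLI)
# --------------------------------------------------------------------------

def write_fixture_dir(config: FixtureConfig, outdir: str | Path) -> Path:
    """Emit pocket PDB, ligand Mol2 files, manifest YAML and truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    structure = make_toy_pocket(config)
    (out / "pocket_source.pdb").write_text(write_pdb(structure))
    records, series, truth = make_toy_series(config)
    (out / "pocket_model.pdb").write_text(write_pdb(records[0].pocket.as_structure()))
    manifest = {"target": series.target_id, "seed": config.seed, "ligands": []}
    for rec in records:
        mol = rec.ligand_conformers[0]
        (out / f"{rec.id}.mol2").write_text(write_mol2(mol))
        aff = series.affinities[rec.id]
        manifest["ligands"].append({
            "id": rec.id, "mol2": f"{rec.id}.mol2",
            "affinity": {"kind": aff.kind, "value_M": aff.value},
            "pH": rec.assay_pH, "crystal": series.crystal_flags[rec.id],
            "net_charge": rec.ligand_net_charge,
            "protonation": rec.protonation.direction,
        })
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    (out / "expected.json").write_text(json.dumps(truth, indent=2))
    return out
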