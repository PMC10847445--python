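"""Per-complex score assembly and batch scoring.

The score of a protein-ligand complex is the sum of five terms, each in
kcal/mol:

    score = dE_int + ddG_solv + dG_conf + dG_Hplus + TdS_penalty

More negative means better predicted binding; the score ranks ligands of
one target and is not an absolute binding free energy. When a crystal
structure contains several conformers of one ligand, all are evaluated
and the one giving the lowest complex total energy (gas + solvation) is
kept. When the ligand's protonation changes upon binding, the bound-form
variant is the one scored in the structure-derived terms and the
proton-transfer term pays for the species conversion.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

from .energy import (
    EnergyBackend,
    System,
    combine,
    desolvation_penalty,
    interaction_energy,
    ligand_strain,
)
from .pocket import PocketModel
from .structio import Molecule
from .thermo import EntropyModel, ProtonationCase, entropy_penalty, proton_transfer_term


@dataclass
class ScoringSpec:
    """Numerical settings of the scoring run."""

    relax_tol: float = 0.1        # kcal/mol/Å, ligand relaxation
    relax_max_steps: int = 2000
    entropy_model: EntropyModel = field(default_factory=EntropyModel)


@dataclass
class ComplexRecord:
    id: str
    pocket: PocketModel
    ligand_conformers: list[Molecule]
    ligand_net_charge: int
    protonation: ProtonationCase = field(default_factory=ProtonationCase)
    assay_pH: float | None = None
    provenance: str = "crystal"  # "crystal" | "modeled"

    def __post_init__(self) -> None:
        if not self.ligand_conformers:
            raise ValueError(f"record {self.id}: needs at least one conformer")
        ref = sorted(self.ligand_conformers[0].elements)
        for conf in self.ligand_conformers[1:]:
            if sorted(conf.elements) != ref:
                raise ValueError(
                    f"record {self.id}: conformers differ in atom composition")
        for conf in self.ligand_conformers:
            if conf.net_charge != self.ligand_net_charge:
                raise ValueError(
                    f"record {self.id}: conformer net charge "
                    f"{conf.net_charge} != declared {self.ligand_net_charge}")


@dataclass
class ScoreComponents:
    dE_int: float
    ddG_solv: float
    dG_conf: float
    dG_Hplus: float
    TdS_penalty: float
    total: float
    chosen_conformer: int

    @classmethod
    def assemble(cls, dE_int: float, ddG_solv: float, dG_conf: float,
                 dG_Hplus: float, TdS_penalty: float,
                 chosen_conformer: int) -> "ScoreComponents":
        # total is the exact floating-point sum of the stored components
        total = dE_int + ddG_solv + dG_conf + dG_Hplus + TdS_penalty
        return cls(dE_int, ddG_solv, dG_conf, dG_Hplus, TdS_penalty,
                   total, chosen_conformer)


def select_conformer(backend: EnergyBackend, record: ComplexRecord) -> int:
    """Index of the conformer with the lowest complex total energy.

    The complex (pocket + ligand) is evaluated with gas + solvation energy;
    ties keep the first occurrence in input order.
    """
    if len(record.ligand_conformers) == 1:
        return 0
    receptor = System.from_pocket(record.pocket)
    best_idx, best_e = 0, None
    for idx, conf in enumerate(record.ligand_conformers):
        try:
            cmplx = combine(receptor, System.from_molecule(conf))
            res = backend.evaluate(cmplx, solvated=backend.has_solvation)
            e = res.total
        except Exception as exc:
            raise RuntimeError(
                f"record {record.id}: backend failed on conformer {idx}: {exc}"
            ) from exc
        if best_e is None or e < best_e:
            best_idx, best_e = idx, e
    return best_idx


def score_complex(backend: EnergyBackend, record: ComplexRecord,
                  spec: ScoringSpec | None = None) -> ScoreComponents:
    """Compute the five score terms and their sum for one complex."""
    spec = spec or ScoringSpec()
    receptor = System.from_pocket(record.pocket)

    idx = select_conformer(backend, record)
    conf = record.ligand_conformers[idx]
    ligand = System.from_molecule(conf)
    cmplx = combine(receptor, ligand)

    def term(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(
                f"record {record.id}: term {name} failed: {exc}") from exc

    dE_int = term("dE_int", lambda: interaction_energy(backend, cmplx, receptor, ligand))
    ddG_solv = term("ddG_solv", lambda: desolvation_penalty(backend, cmplx, receptor, ligand))
    dG_conf = term("dG_conf", lambda: ligand_strain(
        backend, ligand, tol=spec.relax_tol, max_steps=spec.relax_max_steps))
    dG_Hplus = term("dG_Hplus", lambda: proton_transfer_term(record.protonation))
    TdS = term("TdS_penalty", lambda: entropy_penalty(conf, spec.entropy_model))
    return ScoreComponents.assemble(dE_int, ddG_solv, dG_conf, dG_Hplus, TdS, idx)


SCORE_COLUMNS = ["id", "dE_int", "ddG_solv", "dG_conf", "dG_Hplus", "TdS",
                 "total", "conformer", "status", "wall_time_s"]


def score_series(backend: EnergyBackend, records: list[ComplexRecord],
                 spec: ScoringSpec | None = None) -> pd.DataFrame:
    """Score a batch of complexes; one row per record, in input order.

    A failing record is reported in its row (status column) without
    aborting the batch. The table's ``attrs["n_failures"]`` counts them.
    """
    if not records:
        raise ValueError("empty record list")
    spec = spec or ScoringSpec()
    rows = []
    failures = 0
    for rec in records:
        t0 = time.perf_counter()
        try:
            sc = score_complex(backend, rec, spec)
            rows.append({"id": rec.id, "dE_int": sc.dE_int, "ddG_solv": sc.ddG_solv,
                         "dG_conf": sc.dG_conf, "dG_Hplus": sc.dG_Hplus,
                         "TdS": sc.TdS_penalty, "total": sc.total,
                         "conformer": sc.chosen_conformer, "status": "ok",
                         "wall_time_s": time.perf_counter() - t0})
        except Exception as exc:
            failures += 1
            rows.append({"id": rec.id, "dE_int": None, "ddG_solv": None,
                         "dG_conf": None, "dG_Hplus": None, "TdS": None,
                         "total": None, "conformer": None,
                         "status": f"failed: {exc}",
                         "wall_time_s": time.perf_counter() - t0})
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    table.attrs["n_failures"] = failures
    return table
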